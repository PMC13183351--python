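"""A small trainable masked-language-model encoder.

The encoder is a scaled-down bidirectional transformer trained with the
masked-token objective (predict the original identity of randomly masked
subwords from their context). It is implemented directly in numpy — forward
pass, analytic backward pass, and Adam — so that training a desk-scale
profile (2 layers, width 64-128, a few epochs on tens of thousands of
tokens) runs in seconds-to-minutes on one CPU and is deterministic given a
seed. Words are segmented by a byte-pair-encoding subword tokenizer fitted
on the training corpus only; each subword inherits the index of the word it
was split from, which is what aligns encoder states back to argument spans.

Architecture (pre-norm): token + learned position embeddings -> N x
[x + MHAttn(LN(x)); x + FFN(LN(x))] -> final LN. The output projection is
tied to the input embedding table. Argument embeddings are the arithmetic
mean of the final-layer states of all subwords inside the span.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus import RoleDataset, Utterance
from .errors import EncodingAlignmentError

PAD, UNK, MASK = "<pad>", "<unk>", "<mask>"
SPECIALS = (PAD, UNK, MASK)
EOW = "</w>"  # end-of-word marker for BPE


# ---------------------------------------------------------------------------
# BPE tokenizer
# ---------------------------------------------------------------------------

class BpeTokenizer:
    """Byte-pair-encoding subword tokenizer fitted on word-type frequencies."""

    def __init__(self, vocab: list[str], merges: list[tuple[str, str]]):
        self.vocab = list(vocab)
        self.merges = [tuple(m) for m in merges]
        self.token_to_id = {t: i for i, t in enumerate(self.vocab)}
        self._rank = {m: i for i, m in enumerate(self.merges)}
        self._cache: dict[str, list[str]] = {}

    # -- fitting ---------------------------------------------------------
    @classmethod
    def train(cls, sentences: Iterable[Sequence[str]], vocab_size: int = 512,
              ) -> "BpeTokenizer":
        word_freq: Counter[str] = Counter()
        for toks in sentences:
            word_freq.update(toks)
        if not word_freq:
            raise ValueError("cannot fit a tokenizer on an empty corpus")
        # each word as a tuple of symbols ending in EOW
        words = {w: tuple(w) + (EOW,) for w in word_freq}
        alphabet = sorted({s for symbols in words.values() for s in symbols})
        vocab = list(SPECIALS) + alphabet
        merges: list[tuple[str, str]] = []
        while len(vocab) < vocab_size:
            pairs: Counter[tuple[str, str]] = Counter()
            for w, symbols in words.items():
                f = word_freq[w]
                for a, b in zip(symbols, symbols[1:]):
                    pairs[(a, b)] += f
            if not pairs:
                break
            # deterministic tie-break: highest count, then lexicographic
            best = min(pairs.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            merges.append(best)
            merged = best[0] + best[1]
            vocab.append(merged)
            new_words = {}
            for w, symbols in words.items():
                out, i = [], 0
                while i < len(symbols):
                    if (i + 1 < len(symbols)
                            and (symbols[i], symbols[i + 1]) == best):
                        out.append(merged)
                        i += 2
                    else:
                        out.append(symbols[i])
                        i += 1
                new_words[w] = tuple(out)
            words = new_words
        return cls(vocab, merges)

    # -- encoding --------------------------------------------------------
    def segment(self, word: str) -> list[str]:
        if word in self._cache:
            return self._cache[word]
        symbols = list(word) + [EOW]
        while len(symbols) > 1:
            ranked = [
                (self._rank.get((a, b), float("inf")), i)
                for i, (a, b) in enumerate(zip(symbols, symbols[1:]))
            ]
            rank, i = min(ranked)
            if rank == float("inf"):
                break
            symbols[i: i + 2] = [symbols[i] + symbols[i + 1]]
        self._cache[word] = symbols
        return symbols

    def encode_word(self, word: str) -> list[int]:
        unk = self.token_to_id[UNK]
        return [self.token_to_id.get(s, unk) for s in self.segment(word)]

    def encode_tokens(self, tokens: Sequence[str]
                      ) -> tuple[list[int], list[int]]:
        """Encode a token sequence; returns (subword ids, word index of each
        subword) — the alignment used for span averaging."""
        ids: list[int] = []
        word_idx: list[int] = []
        for w, tok in enumerate(tokens):
            sub = self.encode_word(tok)
            ids.extend(sub)
            word_idx.extend([w] * len(sub))
        return ids, word_idx

    # -- persistence -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"vocab": self.vocab, "merges": self.merges})

    @classmethod
    def from_json(cls, text: str) -> "BpeTokenizer":
        doc = json.loads(text)
        return cls(doc["vocab"], [tuple(m) for m in doc["merges"]])

    def __len__(self) -> int:
        return len(self.vocab)


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    vocab_size: int = 512
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 2
    d_ff: int = 128
    max_len: int = 32
    mask_prob: float = 0.15
    epochs: int = 3
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vocab_size", "d_model", "n_layers", "n_heads", "d_ff",
                     "max_len", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.mask_prob < 1.0:
            raise ValueError("mask_prob must be in (0, 1)")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


def _layer_norm_forward(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layer_norm_backward(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    m = dxhat.mean(-1, keepdims=True)
    mx = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m - xhat * mx)
    return dx, dg, db


class MaskedLMEncoder:
    """Tiny pre-norm transformer with a tied masked-token output head."""

    def __init__(self, config: EncoderConfig, tokenizer: BpeTokenizer):
        self.config = config
        self.tokenizer = tokenizer
        self.frozen = False
        self.loss_history: list[float] = []
        rng = np.random.default_rng(config.seed)
        d, f, V, L = config.d_model, config.d_ff, len(tokenizer), config.max_len

        def init(*shape, scale=None):
            scale = scale if scale is not None else 0.02
            return (rng.standard_normal(shape) * scale).astype(np.float64)

        self.params: dict[str, np.ndarray] = {
            "E": init(V, d), "P": init(L, d),
            "gf": np.ones(d), "bf": np.zeros(d),
            "b_out": np.zeros(V),
        }
        for i in range(config.n_layers):
            p = self.params
            for w in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{w}{i}"] = init(d, d)
            for name in ("bq", "bk", "bv", "bo"):
                p[f"{name}{i}"] = np.zeros(d)
            p[f"g1_{i}"] = np.ones(d)
            p[f"be1_{i}"] = np.zeros(d)
            p[f"g2_{i}"] = np.ones(d)
            p[f"be2_{i}"] = np.zeros(d)
            p[f"W1_{i}"] = init(d, f)
            p[f"b1_{i}"] = np.zeros(f)
            p[f"W2_{i}"] = init(f, d)
            p[f"b2_{i}"] = np.zeros(d)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------
    def _forward(self, ids: np.ndarray, pad_mask: np.ndarray,
                 ) -> tuple[np.ndarray, list]:
        """ids (B,T) int, pad_mask (B,T) 1.0 for real tokens.
        Returns final hidden states (B,T,d) and the cache for backprop."""
        cfg, p = self.config, self.params
        B, T = ids.shape
        h = cfg.n_heads
        dh = cfg.d_model // h
        x = p["E"][ids] + p["P"][:T][None, :, :]
        cache: list = [("embed", ids)]
        neg = -1e9 * (1.0 - pad_mask)[:, None, None, :]  # (B,1,1,T)
        for i in range(cfg.n_layers):
            n1, ln1c = _layer_norm_forward(x, p[f"g1_{i}"], p[f"be1_{i}"])
            Q = n1 @ p[f"Wq{i}"] + p[f"bq{i}"]
            K = n1 @ p[f"Wk{i}"] + p[f"bk{i}"]
            Vv = n1 @ p[f"Wv{i}"] + p[f"bv{i}"]
            Qh = Q.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
            Kh = K.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
            Vh = Vv.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
            S = Qh @ Kh.transpose(0, 1, 3, 2) / np.sqrt(dh) + neg
            S -= S.max(-1, keepdims=True)
            A = np.exp(S)
            A /= A.sum(-1, keepdims=True)
            Ch = A @ Vh                                   # (B,h,T,dh)
            C = Ch.transpose(0, 2, 1, 3).reshape(B, T, cfg.d_model)
            O = C @ p[f"Wo{i}"] + p[f"bo{i}"]
            x2 = x + O
            n2, ln2c = _layer_norm_forward(x2, p[f"g2_{i}"], p[f"be2_{i}"])
            Hpre = n2 @ p[f"W1_{i}"] + p[f"b1_{i}"]
            H = np.maximum(Hpre, 0.0)
            F = H @ p[f"W2_{i}"] + p[f"b2_{i}"]
            x3 = x2 + F
            cache.append((i, n1, ln1c, Qh, Kh, Vh, A, C, x, x2, n2, ln2c,
                          Hpre, H))
            x = x3
        nf, lnfc = _layer_norm_forward(x, p["gf"], p["bf"])
        cache.append(("final", x, lnfc))
        return nf, cache

    def _backward(self, dnf: np.ndarray, cache: list) -> dict[str, np.ndarray]:
        cfg, p = self.config, self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        _, _xfin, lnfc = cache[-1]
        dx, dg, db = _layer_norm_backward(dnf, lnfc)
        grads["gf"] += dg
        grads["bf"] += db
        h = cfg.n_heads
        dh = cfg.d_model // h
        for entry in reversed(cache[1:-1]):
            (i, n1, ln1c, Qh, Kh, Vh, A, C, x_in, x2, n2, ln2c,
             Hpre, H) = entry
            B, T, d = n1.shape
            # FFN branch
            dF = dx
            dH = dF @ p[f"W2_{i}"].T
            grads[f"W2_{i}"] += H.reshape(-1, H.shape[-1]).T @ dF.reshape(-1, d)
            grads[f"b2_{i}"] += dF.sum((0, 1))
            dHpre = dH * (Hpre > 0)
            dn2 = dHpre @ p[f"W1_{i}"].T
            grads[f"W1_{i}"] += n2.reshape(-1, d).T @ dHpre.reshape(-1, dHpre.shape[-1])
            grads[f"b1_{i}"] += dHpre.sum((0, 1))
            dx2_ln, dg2, db2 = _layer_norm_backward(dn2, ln2c)
            grads[f"g2_{i}"] += dg2
            grads[f"be2_{i}"] += db2
            dx2 = dx + dx2_ln
            # attention branch
            dO = dx2
            grads[f"Wo{i}"] += C.reshape(-1, d).T @ dO.reshape(-1, d)
            grads[f"bo{i}"] += dO.sum((0, 1))
            dC = dO @ p[f"Wo{i}"].T
            dCh = dC.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
            dA = dCh @ Vh.transpose(0, 1, 3, 2)
            dVh = A.transpose(0, 1, 3, 2) @ dCh
            dS = A * (dA - (dA * A).sum(-1, keepdims=True))
            dQh = dS @ Kh / np.sqrt(dh)
            dKh = dS.transpose(0, 1, 3, 2) @ Qh / np.sqrt(dh)
            dQ = dQh.transpose(0, 2, 1, 3).reshape(B, T, d)
            dK = dKh.transpose(0, 2, 1, 3).reshape(B, T, d)
            dV = dVh.transpose(0, 2, 1, 3).reshape(B, T, d)
            n1f = n1.reshape(-1, d)
            grads[f"Wq{i}"] += n1f.T @ dQ.reshape(-1, d)
            grads[f"bq{i}"] += dQ.sum((0, 1))
            grads[f"Wk{i}"] += n1f.T @ dK.reshape(-1, d)
            grads[f"bk{i}"] += dK.sum((0, 1))
            grads[f"Wv{i}"] += n1f.T @ dV.reshape(-1, d)
            grads[f"bv{i}"] += dV.sum((0, 1))
            dn1 = dQ @ p[f"Wq{i}"].T + dK @ p[f"Wk{i}"].T + dV @ p[f"Wv{i}"].T
            dx_ln, dg1, db1 = _layer_norm_backward(dn1, ln1c)
            grads[f"g1_{i}"] += dg1
            grads[f"be1_{i}"] += db1
            dx = dx2 + dx_ln
        _, ids = cache[0]
        T = ids.shape[1]
        np.add.at(grads["E"], ids, dx)
        grads["P"][:T] += dx.sum(0)
        return grads

    # ------------------------------------------------------------------
    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        self._adam_t += 1
        lr, b1, b2, eps = self.config.lr, 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def _batch_loss_and_grads(self, ids, pad_mask, rng,
                              update: bool) -> float:
        cfg = self.config
        V = len(self.tokenizer)
        mask_id = self.tokenizer.token_to_id[MASK]
        maskable = pad_mask.astype(bool)
        coin = rng.random(ids.shape) < cfg.mask_prob
        target_mask = coin & maskable
        if not target_mask.any():  # force at least one target per batch
            b = int(rng.integers(ids.shape[0]))
            t = int(np.flatnonzero(maskable[b])[0])
            target_mask[b, t] = True
        corrupted = ids.copy()
        # 80% <mask>, 10% random token, 10% unchanged
        r = rng.random(ids.shape)
        corrupted[target_mask & (r < 0.8)] = mask_id
        rand_sel = target_mask & (r >= 0.8) & (r < 0.9)
        corrupted[rand_sel] = rng.integers(len(SPECIALS), V, size=int(rand_sel.sum()))
        nf, cache = self._forward(corrupted, pad_mask)
        rows = nf[target_mask]                      # (M, d)
        targets = ids[target_mask]                  # (M,)
        logits = rows @ self.params["E"].T + self.params["b_out"]
        logits -= logits.max(-1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(-1, keepdims=True)
        M = rows.shape[0]
        loss = float(-np.log(probs[np.arange(M), targets] + 1e-12).mean())
        if update:
            dlogits = probs.copy()
            dlogits[np.arange(M), targets] -= 1.0
            dlogits /= M
            drows = dlogits @ self.params["E"]
            dE_out = dlogits.T @ rows
            dnf = np.zeros_like(nf)
            dnf[target_mask] = drows
            grads = self._backward(dnf, cache)
            grads["E"] += dE_out
            grads["b_out"] += dlogits.sum(0)
            self._adam_step(grads)
        return loss

    # ------------------------------------------------------------------
    def fit(self, sentences: list[list[str]]) -> "MaskedLMEncoder":
        cfg = self.config
        if len(sentences) == 0:
            raise ValueError("empty corpus")
        if len(sentences) < cfg.batch_size:
            raise ValueError(
                f"corpus ({len(sentences)} sentences) smaller than one batch "
                f"({cfg.batch_size})")
        encoded = []
        for toks in sentences:
            ids, _ = self.tokenizer.encode_tokens(toks)
            encoded.append(ids[: cfg.max_len])
        pad_id = self.tokenizer.token_to_id[PAD]
        rng = np.random.default_rng(cfg.seed + 1)
        n = len(encoded)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
                batch = [encoded[j] for j in order[start: start + cfg.batch_size]]
                T = max(len(b) for b in batch)
                ids = np.full((len(batch), T), pad_id, dtype=np.int64)
                pad_mask = np.zeros((len(batch), T))
                for r, b in enumerate(batch):
                    ids[r, : len(b)] = b
                    pad_mask[r, : len(b)] = 1.0
                losses.append(self._batch_loss_and_grads(ids, pad_mask, rng,
                                                         update=True))
            self.loss_history.append(float(np.mean(losses)))
        self.frozen = True
        return self

    # ------------------------------------------------------------------
    def encode(self, tokens: Sequence[str]) -> tuple[np.ndarray, list[int]]:
        """Final-layer states for one utterance (no masking), with the word
        index of each subword."""
        ids, word_idx = self.tokenizer.encode_tokens(tokens)
        ids = ids[: self.config.max_len]
        word_idx = word_idx[: self.config.max_len]
        arr = np.asarray([ids])
        pad = np.ones_like(arr, dtype=float)
        nf, _ = self._forward(arr, pad)
        return nf[0], word_idx


def train_masked_lm(corpus: RoleDataset | list[list[str]],
                    config: EncoderConfig | None = None) -> MaskedLMEncoder:
    """Fit tokenizer and masked-LM encoder on a corpus; returns the frozen
    encoder (training-loss trajectory in ``encoder.loss_history``)."""
    config = config or EncoderConfig()
    if isinstance(corpus, RoleDataset):
        sentences = [list(u.tokens) for u in corpus.utterances.values()]
    else:
        sentences = [list(s) for s in corpus]
    if not sentences:
        raise ValueError("empty corpus")
    tokenizer = BpeTokenizer.train(sentences, vocab_size=config.vocab_size)
    return MaskedLMEncoder(config, tokenizer).fit(sentences)


def embed_argument_contextual(encoder: MaskedLMEncoder, utterance: Utterance,
                              span: tuple[int, int],
                              two_level: bool = False) -> np.ndarray:
    """Mean of the final-layer subword vectors belonging to the span's
    tokens. ``two_level=True`` averages subwords within each word first and
    then words (order-dependent only in the weighting of multi-subword
    words)."""
    states, word_idx = encoder.encode(list(utterance.tokens))
    idx = np.asarray(word_idx)
    start, end = span
    sel = (idx >= start) & (idx < end)
    if not sel.any():
        raise EncodingAlignmentError(
            f"utterance {utterance.id!r}: span {span} lost in tokenization")
    if not two_level:
        return states[sel].mean(0)
    word_means = [states[idx == w].mean(0) for w in range(start, end)
                  if (idx == w).any()]
    return np.mean(word_means, axis=0)
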