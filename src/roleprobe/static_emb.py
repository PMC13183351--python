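"""Context-independent word embeddings with subword composition.

Skip-gram with negative sampling where every word is represented as the
mean of a word-level vector and the vectors of its character n-grams
(hashed into a fixed bucket table). One vector per word *type*: the same
form gets the same representation in every sentence, which is exactly the
contrast with the contextual encoder. Out-of-vocabulary forms still get a
vector through their n-grams.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import RoleDataset

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3


def _fnv1a(s: str) -> int:
    """Deterministic string hash (python's builtin hash is salted)."""
    h = _FNV_OFFSET
    for byte in s.encode("utf-8"):
        h = ((h ^ byte) * _FNV_PRIME) & 0xFFFFFFFFFFFFFFFF
    return h


def _ngrams(word: str, min_n: int, max_n: int) -> list[str]:
    padded = f"<{word}>"
    out = []
    for n in range(min_n, max_n + 1):
        out.extend(padded[i: i + n] for i in range(len(padded) - n + 1))
    return out


@dataclass
class StaticConfig:
    dim: int = 64
    window: int = 2
    negatives: int = 5
    epochs: int = 3
    min_n: int = 3
    max_n: int = 5
    buckets: int = 2000
    lr: float = 0.05
    min_tokens: int = 50
    seed: int = 0


class StaticEmbeddingTable:
    """Trained subword-composed embedding table."""

    def __init__(self, config: StaticConfig, vocab: list[str],
                 w_in: np.ndarray, rows_of: dict[str, np.ndarray]):
        self.config = config
        self.vocab = vocab
        self.word_to_id = {w: i for i, w in enumerate(vocab)}
        self._w_in = w_in            # (n_words + buckets, dim)
        self._rows_of = rows_of      # word -> row indices into w_in

    @property
    def dim(self) -> int:
        return self.config.dim

    def _rows_for(self, word: str) -> np.ndarray:
        if word in self._rows_of:
            return self._rows_of[word]
        cfg = self.config
        n_words = len(self.vocab)
        grams = _ngrams(word, cfg.min_n, cfg.max_n)
        if not grams:  # word shorter than any n-gram window: hash whole form
            grams = [f"<{word}>"]
        return np.asarray(
            [n_words + (_fnv1a(g) % cfg.buckets) for g in grams], dtype=np.int64)

    def vector(self, word: str) -> np.ndarray:
        rows = self._rows_for(word)
        return self._w_in[rows].mean(0)


def train_static_embeddings(corpus: RoleDataset | list[list[str]],
                            config: StaticConfig | None = None,
                            ) -> StaticEmbeddingTable:
    """Train skip-gram-with-negative-sampling subword embeddings.

    Deterministic given ``config.seed``. Raises on an empty corpus or one
    below ``config.min_tokens`` tokens.
    """
    config = config or StaticConfig()
    if isinstance(corpus, RoleDataset):
        sentences = [list(u.tokens) for u in corpus.utterances.values()]
    else:
        sentences = [list(s) for s in corpus]
    if not sentences:
        raise ValueError("empty corpus")
    n_tokens = sum(len(s) for s in sentences)
    if n_tokens < config.min_tokens:
        raise ValueError(
            f"corpus has {n_tokens} tokens, below trainer minimum "
            f"{config.min_tokens}")

    freq = Counter(tok for s in sentences for tok in s)
    vocab = sorted(freq)
    word_to_id = {w: i for i, w in enumerate(vocab)}
    n_words = len(vocab)
    rows_of = {}
    for w in vocab:
        grams = _ngrams(w, config.min_n, config.max_n) or [f"<{w}>"]
        rows = [word_to_id[w]] + [n_words + (_fnv1a(g) % config.buckets)
                                  for g in grams]
        rows_of[w] = np.asarray(rows, dtype=np.int64)

    rng = np.random.default_rng(config.seed)
    w_in = (rng.standard_normal((n_words + config.buckets, config.dim))
            * (0.5 / config.dim))
    w_out = np.zeros((n_words, config.dim))

    # unigram^0.75 negative-sampling distribution
    counts = np.asarray([freq[w] for w in vocab], dtype=float) ** 0.75
    neg_p = counts / counts.sum()

    pairs: list[tuple[int, int]] = []  # (center word id, context word id)
    for s in sentences:
        ids = [word_to_id[t] for t in s]
        for i, c in enumerate(ids):
            lo = max(0, i - config.window)
            hi = min(len(ids), i + config.window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((c, ids[j]))
    pairs_arr = np.asarray(pairs, dtype=np.int64)
    n_pairs = len(pairs_arr)
    total_steps = config.epochs * n_pairs

    step = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, 512):
            batch = pairs_arr[order[start: start + 512]]
            lr = config.lr * max(1e-4, 1.0 - step / total_steps)
            step += len(batch)
            for c_id, ctx_id in batch:
                rows = rows_of[vocab[c_id]]
                h = w_in[rows].mean(0)
                negs = rng.choice(n_words, size=config.negatives, p=neg_p)
                targets = np.concatenate(([ctx_id], negs))
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                v = w_out[targets]                      # (k+1, dim)
                scores = 1.0 / (1.0 + np.exp(-(v @ h)))
                err = scores - labels                   # (k+1,)
                gh = err @ v                            # (dim,)
                w_out[targets] -= lr * err[:, None] * h[None, :]
                w_in[rows] -= lr * gh / len(rows)
    return StaticEmbeddingTable(config, vocab, w_in, rows_of)


def embed_argument_static(table: StaticEmbeddingTable,
                          span_tokens: Sequence[str]) -> np.ndarray:
    """Mean of the per-word static vectors over a span."""
    if not span_tokens:
        raise ValueError("empty span")
    return np.mean([table.vector(t) for t in span_tokens], axis=0)
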