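"""Argument representations: position, case, static and contextual."""

import numpy as np
import pytest

from roleprobe.corpus import ArgumentInstance, Utterance
from roleprobe.errors import FormNotInParadigmError
from roleprobe.features import (case_vector_index, encode_case,
                                encode_position, position_matrix)
from roleprobe.mlm import (BpeTokenizer, EncoderConfig, MaskedLMEncoder,
                           embed_argument_contextual, train_masked_lm)
from roleprobe.static_emb import (StaticConfig, embed_argument_static,
                                  train_static_embeddings)
from roleprobe.synth import CaseParadigm


class TestPositionVector:
    def test_worked_example_agent(self, bite_utterance):
        utt, a, p = bite_utterance
        assert encode_position(a, utt, p).tolist() == [0.0, 1.0, 1.0]

    def test_worked_example_patient(self, bite_utterance):
        utt, a, p = bite_utterance
        assert encode_position(p, utt, a).tolist() == [0.0, 0.0, 1.0]

    def test_sole_initial_preverbal_argument(self):
        utt = Utterance(id="s", register="X", tokens=("they", "cook"))
        a = ArgumentInstance("s", "A", (0, 1), "cook", 1)
        assert encode_position(a, utt, None).tolist() == [1.0, 1.0, 0.0]

    def test_all_achievable_combinations_realised(self, small_corpus):
        """A corpus realising all orders and omissions exhausts every
        feature combination except (first=1, before_verb=0): an argument
        in first position necessarily precedes the verb, because a verb
        earlier in the clause would itself occupy first position."""
        _spec, ds = small_corpus
        X, _ = position_matrix(ds)
        seen = {tuple(row) for row in X}
        achievable = {(f, b, c) for f in (0.0, 1.0) for b in (0.0, 1.0)
                      for c in (0.0, 1.0) if not (f == 1.0 and b == 0.0)}
        assert seen == achievable


@pytest.fixture(scope="module")
def paradigm():
    p = CaseParadigm()
    p.register_lemma("bak", "anim")   # druga-style: all cells distinct
    p.register_lemma("bal", "inan")   # okno-style: NOM/ACC syncretism
    p.register_form("ona", [("NOM", "SG")])  # pronoun, unambiguous
    return p


class TestCaseVector:

    def test_unambiguous_pronoun_single_bit(self, paradigm):
        vec = encode_case("ona", paradigm)
        assert vec.sum() == 1
        assert vec[case_vector_index().index(("NOM", "SG"))] == 1

    def test_nom_acc_syncretic_form_two_bits(self, paradigm):
        vec = encode_case("balo", paradigm)  # inanimate NOM.SG = ACC.SG
        idx = case_vector_index()
        assert vec[idx.index(("NOM", "SG"))] == 1
        assert vec[idx.index(("ACC", "SG"))] == 1
        assert vec.sum() == 2

    def test_animate_accusative_single_bit(self, paradigm):
        vec = encode_case("baku", paradigm)  # distinct ACC.SG form
        assert vec.sum() == 1
        assert vec[case_vector_index().index(("ACC", "SG"))] == 1

    def test_bit_count_equals_possible_cases(self, paradigm):
        for form in ("bak", "baki", "balo", "bala", "ona"):
            vec = encode_case(form, paradigm)
            assert int(vec.sum()) == len(paradigm.possible_cases(form))
            assert (vec.sum() > 1) == paradigm.is_syncretic(form)

    def test_unknown_form_raises(self, paradigm):
        with pytest.raises(FormNotInParadigmError):
            encode_case("zzz", paradigm)


@pytest.fixture(scope="module")
def toy_encoder(small_corpus):
    _spec, ds = small_corpus
    cfg = EncoderConfig(vocab_size=250, d_model=32, n_layers=2, n_heads=2,
                        d_ff=64, epochs=2, batch_size=32, seed=5)
    return train_masked_lm(ds, cfg)


class TestContextualEncoder:
    def test_training_reduces_masked_loss(self, toy_encoder):
        assert toy_encoder.loss_history[-1] < toy_encoder.loss_history[0]

    def test_deterministic_given_seed(self, small_corpus):
        _spec, ds = small_corpus
        cfg = EncoderConfig(vocab_size=150, d_model=16, n_layers=1,
                            n_heads=2, d_ff=32, epochs=1, batch_size=32,
                            seed=9)
        e1 = train_masked_lm(ds, cfg)
        e2 = train_masked_lm(ds, cfg)
        utt = next(iter(ds.utterances.values()))
        v1 = embed_argument_contextual(e1, utt, (0, 1))
        v2 = embed_argument_contextual(e2, utt, (0, 1))
        assert np.abs(v1 - v2).max() == 0.0

    def test_span_embedding_is_subword_mean(self, toy_encoder, small_corpus):
        _spec, ds = small_corpus
        utt = next(u for u in ds.utterances.values() if len(u.tokens) >= 3)
        states, word_idx = toy_encoder.encode(list(utt.tokens))
        idx = np.asarray(word_idx)
        manual = states[(idx >= 0) & (idx < 2)].mean(0)
        vec = embed_argument_contextual(toy_encoder, utt, (0, 2))
        assert np.allclose(vec, manual)

    def test_single_subword_argument_is_that_vector(self, toy_encoder,
                                                    small_corpus):
        _spec, ds = small_corpus
        for utt in ds.utterances.values():
            states, word_idx = toy_encoder.encode(list(utt.tokens))
            counts = np.bincount(word_idx)
            single = np.flatnonzero(counts == 1)
            if single.size:
                w = int(single[0])
                vec = embed_argument_contextual(toy_encoder, utt, (w, w + 1))
                pos = word_idx.index(w)
                assert np.allclose(vec, states[pos])
                return
        pytest.skip("no single-subword token found")

    def test_same_form_different_context_different_vector(self, toy_encoder,
                                                          small_corpus):
        _spec, ds = small_corpus
        # find a form occurring in two different utterances
        seen = {}
        for utt in ds.utterances.values():
            for i, tok in enumerate(utt.tokens):
                if tok in seen and seen[tok][0].tokens != utt.tokens:
                    (u1, i1) = seen[tok]
                    v1 = embed_argument_contextual(toy_encoder, u1,
                                                   (i1, i1 + 1))
                    v2 = embed_argument_contextual(toy_encoder, utt,
                                                   (i, i + 1))
                    cos = float(v1 @ v2 /
                                (np.linalg.norm(v1) * np.linalg.norm(v2)))
                    assert cos < 1.0 - 1e-9
                    return
                seen.setdefault(tok, (utt, i))
        pytest.fail("no repeated form across utterances")

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            train_masked_lm([], EncoderConfig())

    def test_corpus_smaller_than_batch_raises(self):
        with pytest.raises(ValueError):
            train_masked_lm([["a", "b"]] * 5,
                            EncoderConfig(batch_size=32))

    def test_bpe_round_trip_covers_vocab(self, toy_encoder):
        tok = toy_encoder.tokenizer
        for word in ("bak", "balo", "unseenword"):
            pieces = tok.segment(word)
            assert "".join(pieces).replace("</w>", "") == word


@pytest.fixture(scope="module")
def table(small_corpus):
    _spec, ds = small_corpus
    return train_static_embeddings(
        ds, StaticConfig(dim=24, epochs=1, seed=3))


class TestStaticEmbeddings:

    def test_context_invariant_identical_vectors(self, table):
        assert np.array_equal(table.vector("bak"), table.vector("bak"))

    def test_oov_composed_from_ngrams_nonzero(self, table):
        vec = table.vector("bakozzz")
        assert np.isfinite(vec).all() and np.linalg.norm(vec) > 0

    def test_deterministic_given_seed(self, small_corpus):
        _spec, ds = small_corpus
        cfg = StaticConfig(dim=16, epochs=1, seed=8)
        t1 = train_static_embeddings(ds, cfg)
        t2 = train_static_embeddings(ds, cfg)
        assert np.array_equal(t1.vector("bak"), t2.vector("bak"))

    def test_span_embedding_is_word_mean(self, table):
        u = table.vector("bak")
        v = table.vector("balo")
        assert np.allclose(embed_argument_static(table, ["bak", "balo"]),
                           (u + v) / 2)

    def test_below_minimum_tokens_raises(self):
        with pytest.raises(ValueError):
            train_static_embeddings([["a", "b"]],
                                    StaticConfig(min_tokens=50))
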