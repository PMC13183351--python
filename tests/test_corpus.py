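"""Corpus data model, I/O, filters, word-order labelling, size matching."""

import json

import pytest

from roleprobe.corpus import (ArgumentInstance, CaseFrame, ParsedToken,
                              ParsedUtterance, RoleDataset, Utterance,
                              apply_dataset_filters, label_word_order,
                              map_roles_from_frame, read_case_frames_tsv,
                              read_role_dataset, sample_matched_corpus,
                              write_role_dataset)
from roleprobe.errors import (CorpusTooSmallError, OverlappingSpansError,
                              SpanOutOfBoundsError, UnknownRoleError,
                              VerbNotInFramesError)

from conftest import make_dataset


class TestJsonlIO:
    def test_reads_annotated_clause(self, tmp_path):
        rec = {"id": "472754", "register": "CDS",
               "tokens": ["why", "did", "he", "bite", "the", "horse",
                          ",", "Anne", "?"],
               "instances": [{"role": "A", "span": [2, 3],
                              "verb_lemma": "bite", "verb_index": 3}]}
        path = tmp_path / "c.jsonl"
        path.write_text(json.dumps(rec) + "\n")
        ds = read_role_dataset(path)
        assert list(ds.utterances) == ["472754"]
        (inst,) = ds.instances
        assert inst.role == "A"
        assert inst.surface(ds.utterances["472754"]) == ("he",)
        assert ds.verb_inventory == {"bite"}

    def test_empty_file_gives_empty_dataset(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        ds = read_role_dataset(path)
        assert len(ds.utterances) == 0 and len(ds.instances) == 0

    def test_span_beyond_tokens_raises_with_id(self, tmp_path):
        rec = {"id": "bad1", "register": "CDS", "tokens": ["a", "b"],
               "instances": [{"role": "A", "span": [1, 5],
                              "verb_lemma": "v", "verb_index": 0}]}
        path = tmp_path / "bad.jsonl"
        path.write_text(json.dumps(rec) + "\n")
        with pytest.raises(SpanOutOfBoundsError, match="bad1"):
            read_role_dataset(path)

    def test_unknown_role_raises(self):
        with pytest.raises(UnknownRoleError):
            ArgumentInstance(utterance_id="u", role="X", span=(0, 1),
                             verb_lemma="v", verb_index=1)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_role_dataset(tmp_path / "nope.jsonl")

    def test_round_trip_identity(self, small_corpus, tmp_path):
        _spec, ds = small_corpus
        path = tmp_path / "rt.jsonl"
        write_role_dataset(ds, path)
        back = read_role_dataset(path)
        assert set(back.utterances) == set(ds.utterances)
        for uid, utt in ds.utterances.items():
            assert back.utterances[uid].tokens == utt.tokens
        assert sorted(i.key for i in back.instances) == \
            sorted(i.key for i in ds.instances)


class TestCaseFrameMapping:
    @staticmethod
    def _videt_frame():
        return {"videt": CaseFrame(
            verb_lemma="videt",
            mapping=((("nsubj", "NOM"), "A"), (("obj", "ACC"), "P")))}

    @staticmethod
    def _parsed(tokens):
        return ParsedUtterance(id="s1", register="ADS",
                               tokens=tuple(tokens),
                               verb_lemma="videt", verb_index=1)

    def test_nom_subject_and_acc_object_mapped(self):
        toks = [
            ParsedToken("koska", "koska", head=2, deprel="nsubj",
                        cases=frozenset({"NOM"})),
            ParsedToken("vidit", "videt", head=0, deprel="root"),
            ParsedToken("sobaku", "sobaka", head=2, deprel="obj",
                        cases=frozenset({"ACC"})),
        ]
        insts, excluded = map_roles_from_frame(self._parsed(toks),
                                               self._videt_frame())
        assert not excluded
        assert {(i.role, i.span) for i in insts} == {("A", (0, 1)),
                                                     ("P", (2, 3))}

    def test_verb_only_clause_flagged_for_exclusion(self):
        toks = [
            ParsedToken("nu", "nu", head=2, deprel="discourse"),
            ParsedToken("vidit", "videt", head=0, deprel="root"),
        ]
        insts, excluded = map_roles_from_frame(self._parsed(toks),
                                               self._videt_frame())
        assert insts == [] and excluded

    def test_unknown_verb_raises(self):
        with pytest.raises(VerbNotInFramesError):
            map_roles_from_frame(self._parsed([
                ParsedToken("x", "x", head=0, deprel="root")]), {})

    def test_frame_must_assign_both_roles_once(self):
        with pytest.raises(ValueError):
            CaseFrame(verb_lemma="v",
                      mapping=((("nsubj", "NOM"), "A"),
                               (("obj", "ACC"), "A")))

    def test_tsv_frame_table(self, tmp_path):
        path = tmp_path / "frames.tsv"
        path.write_text("verb_lemma\trelation\tcase\trole\n"
                        "videt\tnsubj\tNOM\tA\nvidet\tobj\tACC\tP\n")
        frames = read_case_frames_tsv(path)
        assert frames["videt"].slot_for("nsubj", {"NOM"}) == "A"
        assert frames["videt"].slot_for("obj", {"ACC"}) == "P"


class TestFilters:
    @staticmethod
    def _dataset(n_per_verb):
        rows = []
        for verb, n in n_per_verb.items():
            for k in range(n):
                uid = f"{verb}-{k}"
                rows.append((uid, ["x", verb, "y"],
                             [("A", (0, 1), verb, 1),
                              ("P", (2, 3), verb, 1)]))
        return make_dataset(rows)

    def test_verb_below_threshold_removed_at_boundary(self):
        ds = self._dataset({"keep": 10, "drop": 9})
        out = apply_dataset_filters(ds, min_per_verb=10)
        assert out.verb_inventory == {"keep"}
        assert all(i.verb_lemma == "keep" for i in out.instances)

    def test_all_verbs_below_threshold_gives_empty(self):
        out = apply_dataset_filters(self._dataset({"a": 3, "b": 2}),
                                    min_per_verb=10)
        assert len(out.utterances) == 0

    def test_idempotent(self):
        ds = self._dataset({"keep": 12, "drop": 4})
        once = apply_dataset_filters(ds, min_per_verb=10)
        twice = apply_dataset_filters(once, min_per_verb=10)
        assert set(twice.utterances) == set(once.utterances)
        assert len(twice.instances) == len(once.instances)

    def test_argumentless_utterances_removed(self):
        ds = self._dataset({"keep": 10})
        ds.utterances["orphan"] = Utterance(id="orphan", register="X",
                                            tokens=("just", "verb"))
        out = apply_dataset_filters(ds, min_per_verb=10)
        assert "orphan" not in out.utterances


class TestWordOrderLabel:
    def test_avp_from_worked_example(self, bite_utterance):
        utt, a, p = bite_utterance
        assert label_word_order(utt, [a, p]) == "AVP"

    def test_apv_preverbal_object(self):
        ds = make_dataset([("r1", ["tak", "ty", "paket", "beri"],
                            [("A", (1, 2), "brat", 3),
                             ("P", (2, 3), "brat", 3)])])
        utt = ds.utterances["r1"]
        assert label_word_order(utt, ds.instances) == "APV"

    def test_a_only_clause(self):
        ds = make_dataset([("c1", ["they", "were", "cooking"],
                            [("A", (0, 1), "cook", 2)])])
        assert label_word_order(ds.utterances["c1"], ds.instances) == "AV"

    @pytest.mark.parametrize("order", ["AVP", "APV", "PAV", "PVA", "VAP",
                                       "VPA"])
    def test_recovers_all_six_orders(self, order):
        toks, args, vidx = [], {}, None
        for sym in order:
            if sym == "V":
                vidx = len(toks)
                toks.append("verb")
            else:
                args[sym] = (len(toks), len(toks) + 1)
                toks.append(sym.lower())
        insts = [ArgumentInstance(utterance_id="o", role=r, span=s,
                                  verb_lemma="verb", verb_index=vidx)
                 for r, s in args.items()]
        utt = Utterance(id="o", register="X", tokens=tuple(toks))
        assert label_word_order(utt, insts) == order

    def test_symbol_count_is_overt_args_plus_one(self, small_corpus):
        _spec, ds = small_corpus
        for uid, insts in list(ds.by_utterance().items())[:300]:
            label = label_word_order(ds.utterances[uid], insts)
            assert len(label) == len(insts) + 1

    def test_overlapping_spans_raise(self):
        utt = Utterance(id="x", register="X", tokens=("a", "b", "v"))
        insts = [ArgumentInstance("x", "A", (0, 2), "v", 2),
                 ArgumentInstance("x", "P", (1, 2), "v", 2)]
        with pytest.raises(OverlappingSpansError):
            label_word_order(utt, insts)


class TestSizeMatching:
    @staticmethod
    def _utts(n, length=5):
        return [Utterance(id=f"u{i}", register="X",
                          tokens=tuple(f"t{j}" for j in range(length)))
                for i in range(n)]

    def test_budget_contract(self):
        utts = self._utts(200, length=7)
        out = sample_matched_corpus(utts, 500, seed=3)
        total = sum(len(u.tokens) for u in out)
        assert 500 <= total < 500 + 7

    def test_deterministic_and_seed_sensitive(self):
        utts = self._utts(100)
        a = [u.id for u in sample_matched_corpus(utts, 200, seed=5)]
        b = [u.id for u in sample_matched_corpus(utts, 200, seed=5)]
        c = [u.id for u in sample_matched_corpus(utts, 200, seed=6)]
        assert a == b
        total_c = sum(5 for _ in c)
        assert total_c >= 200  # budget holds under any seed

    def test_budget_equal_to_corpus_returns_all(self):
        utts = self._utts(10)
        out = sample_matched_corpus(utts, 50, seed=0)
        assert sorted(u.id for u in out) == sorted(u.id for u in utts)

    def test_budget_exceeding_corpus_raises(self):
        with pytest.raises(CorpusTooSmallError):
            sample_matched_corpus(self._utts(4), 1000, seed=0)
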