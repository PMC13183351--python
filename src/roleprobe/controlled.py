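"""Controlled generalization test sets.

Generates minimal-pair sentences from templates over a grammar lexicon so
that specific cues to semantic roles can be switched on and off:

* English-like mode — five conditions: ``basic`` (animate A, AVP order),
  ``unprototypical_animacy`` (referent types flipped), ``fronted`` (PAV),
  ``relative_clause`` (PAV with an overt complementizer and a two-word
  matrix continuation), ``passive`` (PVA, "is VERB-ed by"). Pronoun
  variants use case-distinct third-person forms and the case-ambiguous
  second person; number is crossed so that verb agreement is a cue in half
  of the sentences.
* Russian-like mode — four case-syncretism conditions (``non_syncretic``,
  ``both_syncretic``, ``syncretic_A``, ``syncretic_P``) crossed with all
  six {A,P,V} orders; ``both_syncretic`` is only generated where agreement
  disambiguates (differing A/P number), since otherwise the sentence has
  no role cue at all.

Sentences are deliberately allowed to be implausible: the set probes the
limits of what the encoders learned, not naturalistic usage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import ArgumentInstance, RoleDataset, Utterance, label_word_order
from .errors import InfeasibleSplitError
from .synth import GrammarLexicon, CaseParadigm, Noun, Verb, TWO_ARG_ORDERS

ENGLISH_CONDITIONS = ("basic", "unprototypical_animacy", "fronted",
                      "relative_clause", "passive")
RUSSIAN_CONDITIONS = ("non_syncretic", "both_syncretic",
                      "syncretic_A", "syncretic_P")
RUSSIAN_TEST_COMPOSITION = {"APV": 52, "AVP": 24, "PAV": 18,
                            "PVA": 2, "VAP": 2, "VPA": 2}


@dataclass
class ConditionSpec:
    mode: str = "english_like"
    english_conditions: tuple[str, ...] = ENGLISH_CONDITIONS
    russian_conditions: tuple[str, ...] = RUSSIAN_CONDITIONS
    russian_orders: tuple[str, ...] = TWO_ARG_ORDERS
    pronouns: bool = True
    max_noun_pairs: int = 40     # cap on lexical A/P pairings per condition

    def __post_init__(self) -> None:
        if self.mode not in ("english_like", "russian_like"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ControlledSentence:
    utterance: Utterance
    instances: list[ArgumentInstance]
    condition: str
    word_order: str
    syncretic_a: bool
    syncretic_p: bool
    agreement_cue: bool
    pronoun_role: str | None      # which role (if any) is pronominal

    @property
    def id(self) -> str:
        return self.utterance.id

    def meta(self) -> dict:
        return {"condition": self.condition, "word_order": self.word_order,
                "syncretic_A": self.syncretic_a, "syncretic_P": self.syncretic_p,
                "agreement_cue": self.agreement_cue,
                "pronoun_role": self.pronoun_role}


def _english_noun_form(noun: Noun, number: str) -> list[str]:
    return ["the", noun.lemma + ("s" if number == "PL" else "")]


def _default_pairings(lexicon: GrammarLexicon, condition: str,
                      limit: int) -> list[tuple[Verb, Noun, Noun]]:
    animate = [n for n in lexicon.nouns if n.animacy in ("human", "animal")]
    inanimate = [n for n in lexicon.nouns if n.animacy == "inanimate"]
    humans = [n for n in lexicon.nouns if n.animacy == "human"] or animate
    if condition == "unprototypical_animacy":
        a_pool, p_pool = inanimate, humans
    else:
        a_pool, p_pool = animate, inanimate + [n for n in animate if n not in humans]
    out = []
    for k, (verb, a, p) in enumerate(itertools.product(
            lexicon.verbs, a_pool, p_pool)):
        if a.lemma == p.lemma:
            continue
        if verb.allowed_a and a.lemma not in verb.allowed_a:
            continue
        if verb.allowed_p and p.lemma not in verb.allowed_p:
            continue
        out.append((verb, a, p))
        if len(out) >= limit:
            break
    return out


_ADJECTIVES = ("white", "good", "big")


def _build_english(uid: str, condition: str, verb: Verb, a: Noun, p: Noun,
                   a_num: str, p_num: str, pronoun: tuple[str, object] | None,
                   lexicon: GrammarLexicon) -> ControlledSentence | None:
    pronoun_role = pronoun[0] if pronoun else None

    def np_tokens(noun: Noun, number: str, role: str) -> list[str] | None:
        if pronoun_role != role:
            return _english_noun_form(noun, number)
        # the pronoun takes the case of its surface slot: in the passive
        # the P is the nominative subject and the A sits in the by-phrase
        if condition == "passive":
            case = "NOM" if role == "P" else "ACC"
        else:
            case = "NOM" if role == "A" else "ACC"
        form = pronoun[1].form_for(case, number)
        return None if form is None else [form]

    a_toks = np_tokens(a, a_num, "A")
    p_toks = np_tokens(p, p_num, "P")
    if a_toks is None or p_toks is None:
        return None  # pronoun lacks the required case/number cell
    prep = [verb.preposition] if verb.preposition else []
    verb_agr = verb.lemma + ("s" if a_num == "SG" else "")

    if condition in ("basic", "unprototypical_animacy"):
        tokens = a_toks + [verb_agr] + prep + p_toks + ["."]
        verb_index = len(a_toks)
        spans = {"A": (0, len(a_toks)),
                 "P": (verb_index + 1, len(tokens) - 1)}  # prep inside span
    elif condition == "fronted":
        tokens = p_toks + [","] + a_toks + [verb_agr] + ["."]
        spans = {"P": (0, len(p_toks)),
                 "A": (len(p_toks) + 1, len(p_toks) + 1 + len(a_toks))}
        verb_index = len(tokens) - 2
    elif condition == "relative_clause":
        cop = "is" if p_num == "SG" else "are"
        adj = _ADJECTIVES[(len(verb.lemma) + len(a.lemma)) % len(_ADJECTIVES)]
        tokens = p_toks + ["that"] + a_toks + [verb_agr, cop, adj, "."]
        spans = {"P": (0, len(p_toks)),
                 "A": (len(p_toks) + 1, len(p_toks) + 1 + len(a_toks))}
        verb_index = len(p_toks) + 1 + len(a_toks)
    elif condition == "passive":
        aux = "is" if p_num == "SG" else "are"
        tokens = p_toks + [aux, verb.lemma + "ed", "by"] + a_toks + ["."]
        spans = {"P": (0, len(p_toks)),
                 "A": (len(p_toks) + 3, len(tokens) - 1)}
        # the labelled verb is the lexical participle, not the auxiliary
        verb_index = len(p_toks) + 1
    else:
        raise ValueError(condition)

    utt = Utterance(id=uid, register="controlled", tokens=tuple(tokens),
                    language="english_like")
    instances = [
        ArgumentInstance(utterance_id=uid, role=role, span=span,
                         verb_lemma=verb.lemma, verb_index=verb_index,
                         condition=condition)
        for role, span in sorted(spans.items())
    ]
    order = label_word_order(utt, instances)
    return ControlledSentence(
        utterance=utt, instances=instances, condition=condition,
        word_order=order, syncretic_a=pronoun_role == "A" and _pron_ambiguous(
            lexicon, a_toks), syncretic_p=pronoun_role == "P" and
        _pron_ambiguous(lexicon, p_toks),
        agreement_cue=a_num != p_num, pronoun_role=pronoun_role)


def _pron_ambiguous(lexicon: GrammarLexicon, toks: list[str]) -> bool:
    if len(toks) != 1:
        return False
    for pron in lexicon.pronouns:
        if pron.ambiguous and toks[0] in {f for _c, f in pron.forms}:
            return True
    return False


def _build_russian(uid: str, condition: str, order: str, verb: Verb,
                   a: Noun, p: Noun, a_num: str, p_num: str,
                   paradigm: CaseParadigm,
                   lexicon: GrammarLexicon) -> ControlledSentence:
    a_form = paradigm.realise(a.lemma, a.decl_class, "NOM", a_num)
    p_form = paradigm.realise(p.lemma, p.decl_class, verb.p_case, p_num)
    paradigm.register_lemma(a.lemma, a.decl_class)
    paradigm.register_lemma(p.lemma, p.decl_class)
    sync_a = paradigm.is_syncretic(a_form)
    sync_p = paradigm.is_syncretic(p_form)
    verb_agr = verb.lemma + ("et" if a_num == "SG" else "ut")
    prep = [verb.preposition] if verb.preposition else []

    tokens: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    verb_index = -1
    for sym in order:
        if sym == "V":
            verb_index = len(tokens)
            tokens.append(verb_agr)
        elif sym == "A":
            spans["A"] = (len(tokens), len(tokens) + 1)
            tokens.append(a_form)
        else:
            start = len(tokens)
            tokens.extend(prep + [p_form])
            spans["P"] = (start, len(tokens))
    utt = Utterance(id=uid, register="controlled", tokens=tuple(tokens),
                    language="russian_like")
    instances = [
        ArgumentInstance(utterance_id=uid, role=role, span=span,
                         verb_lemma=verb.lemma, verb_index=verb_index,
                         condition=condition)
        for role, span in sorted(spans.items())
    ]
    return ControlledSentence(
        utterance=utt, instances=instances, condition=condition,
        word_order=order, syncretic_a=sync_a, syncretic_p=sync_p,
        agreement_cue=a_num != p_num, pronoun_role=None)


def generate_controlled_sentences(lexicon: GrammarLexicon,
                                  spec: ConditionSpec,
                                  paradigm: CaseParadigm | None = None,
                                  constraints: Mapping[str, Sequence[tuple[str, str]]]
                                  | None = None,
                                  seed: int = 0) -> list[ControlledSentence]:
    """Generate the full deduplicated cross-product of templates x
    permitted noun pairings x number combinations (x pronoun variants for
    the English-like mode)."""
    rng = np.random.default_rng(seed)
    sentences: list[ControlledSentence] = []
    seen: set[tuple[str, ...]] = set()
    counter = itertools.count()

    def admit(s: ControlledSentence | None) -> None:
        if s is None:
            return
        if s.utterance.tokens in seen:
            return
        seen.add(s.utterance.tokens)
        sentences.append(s)

    number_combos = [("SG", "SG"), ("SG", "PL"), ("PL", "SG"), ("PL", "PL")]

    if spec.mode == "english_like":
        for condition in spec.english_conditions:
            pairings = _pairings_for(lexicon, condition, constraints,
                                     spec.max_noun_pairs)
            variants: list[tuple[str, object] | None] = [None]
            if spec.pronouns:
                variants += [(role, pron) for role in ("A", "P")
                             for pron in lexicon.pronouns]
            for verb, a, p in pairings:
                for a_num, p_num in number_combos:
                    for pron in variants:
                        uid = f"ctrl-en-{next(counter):06d}"
                        admit(_build_english(uid, condition, verb, a, p,
                                             a_num, p_num, pron, lexicon))
    else:
        paradigm = paradigm or CaseParadigm()
        sync_nouns = [n for n in lexicon.nouns
                      if paradigm.class_is_syncretic(n.decl_class)]
        plain_nouns = [n for n in lexicon.nouns
                       if not paradigm.class_is_syncretic(n.decl_class)]
        if not sync_nouns or not plain_nouns:
            raise ValueError("russian-like mode needs both a syncretic and a "
                             "non-syncretic declension class")
        pools = {
            "non_syncretic": (plain_nouns, plain_nouns),
            "both_syncretic": (sync_nouns, sync_nouns),
            "syncretic_A": (sync_nouns, plain_nouns),
            "syncretic_P": (plain_nouns, sync_nouns),
        }
        verbs = [v for v in lexicon.verbs if v.p_case == "ACC"]
        for condition in spec.russian_conditions:
            a_pool, p_pool = pools[condition]
            pairs = [(a, p) for a in a_pool for p in p_pool
                     if a.lemma != p.lemma][: spec.max_noun_pairs]
            for order in spec.russian_orders:
                for verb in verbs[:6]:
                    for a, p in pairs:
                        for a_num, p_num in number_combos:
                            if condition == "both_syncretic" and a_num == p_num:
                                continue  # agreement must disambiguate
                            uid = f"ctrl-ru-{next(counter):06d}"
                            admit(_build_russian(uid, condition, order, verb,
                                                 a, p, a_num, p_num,
                                                 paradigm, lexicon))
    return sentences


def _pairings_for(lexicon, condition, constraints, limit):
    if constraints:
        by_lemma_n = {n.lemma: n for n in lexicon.nouns}
        by_lemma_v = {v.lemma: v for v in lexicon.verbs}
        out = []
        for vlem, pairs in constraints.items():
            for a_lem, p_lem in pairs:
                out.append((by_lemma_v[vlem], by_lemma_n[a_lem],
                            by_lemma_n[p_lem]))
        return out[:limit]
    return _default_pairings(lexicon, condition, limit)


# ---------------------------------------------------------------------------
# Study-2 split composition
# ---------------------------------------------------------------------------

@dataclass
class Study2Split:
    train: list[str]   # sentence ids
    val: list[str]
    test: list[str]

    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.val), len(self.test)


def compose_study2_split(sentences: Sequence[ControlledSentence], mode: str,
                         seed: int = 0, train_size: int = 100,
                         val_size: int = 200) -> Study2Split:
    """Compose train (each condition at least once), validation and a test
    set with the prescribed condition mix.

    English-like: the four special conditions each contribute exactly 2
    test sentences (4 argument data points, two per role); the remainder of
    the 100-sentence test set is ``basic``. Russian-like: the test set has
    the fixed word-order composition APV 52 / AVP 24 / PAV 18 / PVA 2 /
    VAP 2 / VPA 2 with syncretism conditions sampled randomly.
    """
    rng = np.random.default_rng(seed)
    by_id = {s.id: s for s in sentences}
    ids = list(by_id)
    rng.shuffle(ids)

    test: list[str] = []
    remaining = set(ids)

    def take(filt, k) -> list[str]:
        cand = [i for i in ids if i in remaining and filt(by_id[i])]
        if len(cand) < k:
            raise InfeasibleSplitError(
                f"need {k} sentences for a test cell, found {len(cand)}")
        chosen = [cand[j] for j in rng.permutation(len(cand))[:k]]
        remaining.difference_update(chosen)
        return chosen

    if mode == "english_like":
        for cond in ("unprototypical_animacy", "fronted", "relative_clause",
                     "passive"):
            test += take(lambda s, c=cond: s.condition == c, 2)
        test += take(lambda s: s.condition == "basic", 92)
    else:
        for order, k in RUSSIAN_TEST_COMPOSITION.items():
            test += take(lambda s, o=order: s.word_order == o, k)

    # training: each condition (english) / each syncretism condition and
    # word order (russian) at least once
    train: list[str] = []
    if mode == "english_like":
        groups = {s.condition for s in sentences}
    else:
        groups = {s.condition for s in sentences} | {s.word_order for s in sentences}
    for g in sorted(groups):
        train += take(lambda s, g=g: s.condition == g or s.word_order == g, 1)
    train += take(lambda s: True, train_size - len(train))
    val = take(lambda s: True, val_size)
    return Study2Split(train=train, val=val, test=test)


def controlled_dataset(sentences: Sequence[ControlledSentence],
                       register_label: str = "controlled") -> RoleDataset:
    utts = {}
    insts = []
    for s in sentences:
        utts[s.id] = s.utterance
        insts.extend(s.instances)
    return RoleDataset(utterances=utts, instances=insts)


def evaluate_generalization(encoders: Mapping[str, object],
                            sentences: Sequence[ControlledSentence],
                            split: Study2Split,
                            probe_seed: int = 0) -> pd.DataFrame:
    """Score the same controlled test set under each register's encoder.

    Each controlled sentence is embedded by *both* encoders (contextual
    representation only); one probe per register is trained on the train
    split and evaluated on the shared test split. Records carry the full
    condition metadata for the downstream hierarchical model.
    """
    from .mlm import embed_argument_contextual
    from .probing import ProbeConfig, train_probe

    by_id = {s.id: s for s in sentences}
    rows: list[dict] = []
    for register, encoder in encoders.items():
        def vectors(ids: list[str]):
            X, insts, metas = [], [], []
            for sid in ids:
                s = by_id[sid]
                for inst in s.instances:
                    X.append(embed_argument_contextual(encoder, s.utterance,
                                                       inst.span))
                    insts.append(inst)
                    metas.append(s.meta())
            return np.vstack(X), insts, metas

        Xtr, tr_i, _ = vectors(split.train)
        Xva, va_i, _ = vectors(split.val)
        Xte, te_i, te_m = vectors(split.test)
        probe = train_probe(Xtr, [i.role for i in tr_i],
                            Xva, [i.role for i in va_i],
                            ProbeConfig(kind="mlp", seed=probe_seed))
        preds = probe.predict(Xte)
        for inst, meta, pred in zip(te_i, te_m, preds):
            rows.append({
                "argument_id": inst.key, "sentence_id": inst.utterance_id,
                "register": register, "role": inst.role,
                "representation": "contextual", "split_id": 1,
                "condition": meta["condition"],
                "word_order": meta["word_order"],
                "syncretism": _syncretism_label(meta),
                "agreement_cue": meta["agreement_cue"],
                "predicted": str(pred),
                "correct": int(str(pred) == inst.role),
            })
    return pd.DataFrame(rows)


def _syncretism_label(meta: dict) -> str:
    a, p = meta["syncretic_A"], meta["syncretic_P"]
    if a and p:
        return "both_syncretic"
    if a:
        return "syncretic_A"
    if p:
        return "syncretic_P"
    return "non_syncretic"
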