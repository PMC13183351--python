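"""Synthetic register-corpus generator.

Builds paired artificial "registers" (child-directed-like vs adult-directed-
like speech) whose controllable statistics — word-order distribution over
{A,P,V} strings, role-conditional lexical entropy, case syncretism, argument
omission, number marking — emulate the contrasts observed between natural
CDS and ADS. The language is verb-frame-driven: the A slot of every verb
takes nominative case, the P slot takes the case its frame demands
(accusative for most verbs). Two typological modes are provided:

* ``russian_like`` — full case paradigm with declension classes, one of
  which has nominative/accusative syncretism in both numbers (inanimate-
  style) while the other marks every cell distinctly (animate-style);
  flexible word order.
* ``english_like`` — no case morphology, determiner + noun arguments,
  near-rigid A-initial word order, agreement suffix on the verb.

Role-conditional lexical choice uses Zipf-like base weights sharpened or
flattened by a per-role concentration parameter ``c``: sampling weights are
``w_i^(1/c)`` renormalised, so entropy is continuous and non-decreasing in
``c`` (``c -> 0`` degenerates to the single heaviest lemma, ``c -> inf``
approaches the uniform maximum-entropy limit). Entropy calibration is by
bisection on ``c`` against the closed-form entropy of the fitted weights.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .corpus import ArgumentInstance, MorphTag, RoleDataset, Utterance
from .entropy import entropy_of_probs
from .errors import SpecValidationError, FormNotInParadigmError

CASES = ("NOM", "ACC", "GEN", "DAT", "INS", "LOC")
NUMBERS = ("SG", "PL")

TWO_ARG_ORDERS = ("AVP", "APV", "PAV", "PVA", "VAP", "VPA")
ONE_ARG_ORDERS = ("AV", "VA", "PV", "VP")

# Suffix tables. The animate-style class marks all 12 (case, number) cells
# distinctly; the inanimate-style class syncretises NOM/ACC in the singular
# and NOM/ACC (and GEN.SG) in the plural.
_SUFFIXES = {
    "anim": {
        ("NOM", "SG"): "", ("ACC", "SG"): "u", ("GEN", "SG"): "y",
        ("DAT", "SG"): "e", ("INS", "SG"): "oj", ("LOC", "SG"): "ine",
        ("NOM", "PL"): "i", ("ACC", "PL"): "ux", ("GEN", "PL"): "ej",
        ("DAT", "PL"): "am", ("INS", "PL"): "ami", ("LOC", "PL"): "ax",
    },
    "inan": {
        ("NOM", "SG"): "o", ("ACC", "SG"): "o", ("GEN", "SG"): "a",
        ("DAT", "SG"): "u", ("INS", "SG"): "om", ("LOC", "SG"): "e",
        ("NOM", "PL"): "a", ("ACC", "PL"): "a", ("GEN", "PL"): "",
        ("DAT", "PL"): "amo", ("INS", "PL"): "amio", ("LOC", "PL"): "axo",
    },
}


class CaseParadigm:
    """Declension table mapping (class, case, number) to surface suffixes,
    with the derived inverse map ``possible_cases(form)``.

    Lemmas (and irregular items such as pronouns) must be registered before
    their forms can be analysed; ``possible_cases`` is exactly the preimage
    of the realisation table over registered items. A form is syncretic iff
    it realises more than one (case, number) cell.
    """

    def __init__(self, suffixes: Mapping[str, Mapping[tuple[str, str], str]] | None = None,
                 cases: Sequence[str] = CASES):
        self.cases = tuple(cases)
        self.suffixes = {k: dict(v) for k, v in (suffixes or _SUFFIXES).items()}
        self._form_cells: dict[str, set[tuple[str, str]]] = {}

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.suffixes)

    def realise(self, lemma: str, decl_class: str, case: str, number: str) -> str:
        try:
            return lemma + self.suffixes[decl_class][(case, number)]
        except KeyError as exc:
            raise FormNotInParadigmError(
                f"no cell ({case},{number}) in class {decl_class!r}") from exc

    def register_lemma(self, lemma: str, decl_class: str) -> None:
        for (case, number), _suffix in self.suffixes[decl_class].items():
            form = self.realise(lemma, decl_class, case, number)
            self._form_cells.setdefault(form, set()).add((case, number))

    def register_form(self, form: str, cells: Iterable[tuple[str, str]]) -> None:
        """Register an irregular form (pronouns) with explicit cells."""
        self._form_cells.setdefault(form, set()).update(cells)

    def possible_cases(self, form: str) -> frozenset[tuple[str, str]]:
        try:
            return frozenset(self._form_cells[form])
        except KeyError:
            raise FormNotInParadigmError(form) from None

    def is_syncretic(self, form: str) -> bool:
        return len(self.possible_cases(form)) > 1

    def class_is_syncretic(self, decl_class: str) -> bool:
        suff = self.suffixes[decl_class]
        return len(set(suff.values())) < len(suff)


@dataclass(frozen=True)
class Noun:
    lemma: str
    decl_class: str
    animacy: str                    # human | animal | inanimate
    role_bias: tuple[float, float]  # (weight as A, weight as P)


@dataclass(frozen=True)
class Pronoun:
    lemma: str
    forms: tuple[tuple[tuple[str, str], str], ...]  # ((case, number), form)
    ambiguous: bool = False

    def form_for(self, case: str, number: str) -> str | None:
        for (c, n), f in self.forms:
            if c == case and n == number:
                return f
        return None


@dataclass(frozen=True)
class Verb:
    lemma: str
    p_case: str = "ACC"          # the case the frame assigns to its P slot
    preposition: str | None = None   # overt adposition heading P, if any
    allowed_a: frozenset[str] = frozenset()  # empty = any noun
    allowed_p: frozenset[str] = frozenset()


@dataclass
class GrammarLexicon:
    nouns: list[Noun]
    verbs: list[Verb]
    pronouns: list[Pronoun] = field(default_factory=list)
    fillers: list[str] = field(default_factory=list)
    mode: str = "russian_like"

    def __post_init__(self) -> None:
        if not self.nouns or not self.verbs:
            raise SpecValidationError("lexicon needs nouns and verbs")

    def noun(self, lemma: str) -> Noun:
        return next(n for n in self.nouns if n.lemma == lemma)


def _syllable_lemmas(n: int, kind: str = "noun") -> list[str]:
    """Deterministic pronounceable CVC lemmas, pairwise distinct, length 3.

    Fixed length guarantees that lemma + suffix is injective in the lemma,
    so paradigm forms of different lemmas can never collide.
    """
    onsets = "bdfgklmnprstvz"
    vowels = "aeiou" if kind == "noun" else "ay"
    codas = "kmnrst" if kind == "noun" else "lvzbd"
    out = []
    for o, v, c in itertools.product(onsets, vowels, codas):
        out.append(o + v + c)
        if len(out) == n:
            return out
    raise ValueError("lemma inventory exhausted")


def default_paradigm() -> CaseParadigm:
    return CaseParadigm()


def default_lexicon(mode: str = "russian_like", n_nouns: int = 120,
                    n_verbs: int = 12) -> GrammarLexicon:
    """A balanced default lexicon: half animate-style (non-syncretic,
    A-biased) nouns, half inanimate-style (syncretic, P-biased)."""
    noun_lemmas = _syllable_lemmas(n_nouns, "noun")
    verb_lemmas = _syllable_lemmas(n_verbs, "verb")
    nouns = []
    for i, lem in enumerate(noun_lemmas):
        animate = i % 2 == 0
        nouns.append(Noun(
            lemma=lem,
            decl_class="anim" if animate else "inan",
            animacy="human" if animate and i % 4 == 0 else
                    ("animal" if animate else "inanimate"),
            role_bias=(0.8, 0.2) if animate else (0.2, 0.8),
        ))
    verbs = [Verb(lemma=v, p_case="ACC") for v in verb_lemmas[:-2]]
    # two frames assign dative Ps (oblique-style), widening case variety
    verbs += [Verb(lemma=v, p_case="DAT",
                   preposition="na" if mode == "russian_like" else "to")
              for v in verb_lemmas[-2:]]
    if mode == "russian_like":
        pronouns = [
            Pronoun("1sg", ((("NOM", "SG"), "ja"), (("ACC", "SG"), "menja"),
                            (("DAT", "SG"), "mne"))),
            Pronoun("3sg", ((("NOM", "SG"), "ona"), (("ACC", "SG"), "ejo"),
                            (("DAT", "SG"), "ej"))),
            Pronoun("1pl", ((("NOM", "PL"), "my"), (("ACC", "PL"), "nas"),
                            (("DAT", "PL"), "nam"))),
            Pronoun("2amb", ((("NOM", "SG"), "vy"), (("ACC", "SG"), "vy"),
                             (("NOM", "PL"), "vy"), (("ACC", "PL"), "vy"),
                             (("DAT", "SG"), "vam"), (("DAT", "PL"), "vam")),
                    ambiguous=True),
        ]
        fillers = ["nu", "tak", "vot"]
    else:
        pronouns = [
            Pronoun("3sg", ((("NOM", "SG"), "she"), (("ACC", "SG"), "her"),
                            (("DAT", "SG"), "her"))),
            Pronoun("3pl", ((("NOM", "PL"), "they"), (("ACC", "PL"), "them"),
                            (("DAT", "PL"), "them"))),
            Pronoun("2amb", ((("NOM", "SG"), "you"), (("ACC", "SG"), "you"),
                             (("NOM", "PL"), "you"), (("ACC", "PL"), "you"),
                             (("DAT", "SG"), "you"), (("DAT", "PL"), "you")),
                    ambiguous=True),
        ]
        fillers = ["well", "so", "oh"]
    return GrammarLexicon(nouns=nouns, verbs=verbs, pronouns=pronouns,
                          fillers=fillers, mode=mode)


_DEFAULT_ORDER_DIST = {
    "russian_like": {"AVP": 0.22, "APV": 0.18, "PAV": 0.08, "PVA": 0.03,
                     "VAP": 0.05, "VPA": 0.02, "AV": 0.22, "VP": 0.12,
                     "PV": 0.05, "VA": 0.03},
    "english_like": {"AVP": 0.62, "AV": 0.18, "VP": 0.14, "PAV": 0.03,
                     "PVA": 0.02, "PV": 0.01},
}


@dataclass
class RegisterSpec:
    """Generative description of one synthetic register."""

    label: str
    lexicon: GrammarLexicon
    paradigm: CaseParadigm
    word_order_dist: dict[str, float]
    concentration: dict[str, float] = field(
        default_factory=lambda: {"A": 1.0, "P": 1.0})
    omission_prob: float = 0.0
    number_dist: dict[str, float] = field(
        default_factory=lambda: {"SG": 0.7, "PL": 0.3})
    pronoun_prob: float = 0.2
    filler_prob: float = 0.3
    syncretic_weight: float = 1.0   # multiplier on syncretic-class lemma weights

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        total = sum(self.word_order_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecValidationError(f"word_order_dist sums to {total}, not 1")
        for order, p in self.word_order_dist.items():
            if p < 0:
                raise SpecValidationError(f"negative probability for {order!r}")
            if order.count("V") != 1 or not set(order) <= {"A", "P", "V"}:
                raise SpecValidationError(f"bad order string {order!r}")
            if "A" not in order and "P" not in order:
                raise SpecValidationError(
                    f"order {order!r} has no overt argument; every utterance "
                    "must keep at least one")
            if len(order) != len(set(order)):
                raise SpecValidationError(f"repeated symbol in {order!r}")
        for key in ("omission_prob", "pronoun_prob", "filler_prob"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise SpecValidationError(f"{key}={v} outside [0,1]")
        if self.omission_prob > 0 and not any(
                len(o) == 2 for o in self.word_order_dist):
            # omission reduces 2-argument orders to 1-argument ones; the
            # reduced strings need no explicit mass, but a spec that forbids
            # one-argument utterances entirely while omitting is inconsistent
            pass
        for role, c in self.concentration.items():
            if c <= 0:
                raise SpecValidationError(f"concentration[{role}]={c} must be > 0")
        if abs(sum(self.number_dist.values()) - 1.0) > 1e-9:
            raise SpecValidationError("number_dist must sum to 1")

    # -- lexical distributions -------------------------------------------
    def noun_weights(self, role: str) -> np.ndarray:
        """Role-conditional sampling weights over the noun inventory."""
        n = len(self.lexicon.nouns)
        base = 1.0 / (np.arange(1, n + 1))      # Zipf-like base weights
        bias = np.array([nn.role_bias[0] if role == "A" else nn.role_bias[1]
                         for nn in self.lexicon.nouns])
        sync = np.array([self.syncretic_weight
                         if self.paradigm.class_is_syncretic(nn.decl_class) else 1.0
                         for nn in self.lexicon.nouns])
        logw = np.log(base * bias * sync) / self.concentration[role]
        logw -= logw.max()          # log-space for extreme concentrations
        w = np.exp(logw)
        return w / w.sum()

    def role_lemma_entropy(self, role: str) -> float:
        """Closed-form entropy (bits) of the role-conditional noun choice."""
        return entropy_of_probs(self.noun_weights(role))


def spec_to_yaml(spec: RegisterSpec) -> str:
    doc = {
        "label": spec.label,
        "mode": spec.lexicon.mode,
        "n_nouns": len(spec.lexicon.nouns),
        "n_verbs": len(spec.lexicon.verbs),
        "word_order_dist": spec.word_order_dist,
        "concentration": spec.concentration,
        "omission_prob": spec.omission_prob,
        "number_dist": spec.number_dist,
        "pronoun_prob": spec.pronoun_prob,
        "filler_prob": spec.filler_prob,
        "syncretic_weight": spec.syncretic_weight,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_yaml(text: str) -> RegisterSpec:
    doc = yaml.safe_load(text)
    mode = doc.get("mode", "russian_like")
    lexicon = default_lexicon(mode, doc.get("n_nouns", 24), doc.get("n_verbs", 12))
    return RegisterSpec(
        label=doc["label"], lexicon=lexicon, paradigm=default_paradigm(),
        word_order_dist={k: float(v) for k, v in doc["word_order_dist"].items()},
        concentration={k: float(v) for k, v in doc.get(
            "concentration", {"A": 1.0, "P": 1.0}).items()},
        omission_prob=float(doc.get("omission_prob", 0.0)),
        number_dist={k: float(v) for k, v in doc.get(
            "number_dist", {"SG": 0.7, "PL": 0.3}).items()},
        pronoun_prob=float(doc.get("pronoun_prob", 0.2)),
        filler_prob=float(doc.get("filler_prob", 0.3)),
        syncretic_weight=float(doc.get("syncretic_weight", 1.0)),
    )


def default_register_spec(label: str = "BASE", mode: str = "russian_like",
                          **overrides) -> RegisterSpec:
    spec = RegisterSpec(
        label=label,
        lexicon=default_lexicon(mode),
        paradigm=default_paradigm(),
        word_order_dist=dict(_DEFAULT_ORDER_DIST[mode]),
    )
    for key, value in overrides.items():
        setattr(spec, key, value)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _register_lexicon_forms(spec: RegisterSpec) -> None:
    for noun in spec.lexicon.nouns:
        spec.paradigm.register_lemma(noun.lemma, noun.decl_class)
    for pron in spec.lexicon.pronouns:
        for cell, form in pron.forms:
            spec.paradigm.register_form(form, [cell])


def _verb_surface(verb: Verb, number: str, mode: str) -> str:
    if mode == "english_like":
        return verb.lemma + ("s" if number == "SG" else "")
    return verb.lemma + ("et" if number == "SG" else "ut")


def _sample_argument(spec: RegisterSpec, role: str, verb: Verb,
                     rng: np.random.Generator) -> dict:
    """Sample one argument: tokens, head morphology, metadata."""
    case = "NOM" if role == "A" else verb.p_case
    number = "SG" if rng.random() < spec.number_dist["SG"] else "PL"
    use_pronoun = spec.lexicon.pronouns and rng.random() < spec.pronoun_prob
    if use_pronoun:
        candidates = [p for p in spec.lexicon.pronouns
                      if p.form_for(case, number) is not None]
        if candidates:
            pron = candidates[rng.integers(len(candidates))]
            form = pron.form_for(case, number)
            return {"tokens": [form], "lemma": pron.lemma, "case": case,
                    "number": number, "pronoun": True,
                    "head_cases": {case}}
    weights = spec.noun_weights(role)
    noun = spec.lexicon.nouns[int(rng.choice(len(weights), p=weights))]
    if spec.lexicon.mode == "english_like":
        form = noun.lemma + ("s" if number == "PL" else "")
        tokens = ["the", form]
        head_cases = {case}
    else:
        form = spec.paradigm.realise(noun.lemma, noun.decl_class, case, number)
        tokens = [form]
        head_cases = {c for c, _n in spec.paradigm.possible_cases(form)}
    return {"tokens": tokens, "lemma": noun.lemma, "case": case,
            "number": number, "pronoun": False, "head_cases": head_cases}


def generate_utterance(spec: RegisterSpec, uid: str,
                       rng: np.random.Generator) -> tuple[Utterance, list[ArgumentInstance]]:
    orders = sorted(spec.word_order_dist)
    probs = np.array([spec.word_order_dist[o] for o in orders])
    order = orders[int(rng.choice(len(orders), p=probs / probs.sum()))]

    # optional omission: reduce a two-argument order by dropping one symbol,
    # never both (every utterance keeps at least one overt argument)
    if len(order) == 3 and spec.omission_prob > 0:
        drop_a = rng.random() < spec.omission_prob
        drop_p = rng.random() < spec.omission_prob
        if drop_a and drop_p:
            drop_p = False
        if drop_a:
            order = order.replace("A", "")
        elif drop_p:
            order = order.replace("P", "")

    verb = spec.lexicon.verbs[int(rng.integers(len(spec.lexicon.verbs)))]
    args = {role: _sample_argument(spec, role, verb, rng)
            for role in order if role != "V"}

    agree_number = args["A"]["number"] if "A" in args else "SG"
    tokens: list[str] = []
    morph: list[MorphTag] = []
    spans: dict[str, tuple[int, int]] = {}
    verb_index = -1

    if spec.lexicon.fillers and rng.random() < spec.filler_prob:
        tokens.append(spec.lexicon.fillers[int(rng.integers(len(spec.lexicon.fillers)))])
        morph.append(MorphTag())

    for sym in order:
        if sym == "V":
            verb_index = len(tokens)
            tokens.append(_verb_surface(verb, agree_number, spec.lexicon.mode))
            morph.append(MorphTag(lemma=verb.lemma, number=agree_number))
        else:
            arg = args[sym]
            start = len(tokens)
            if sym == "P" and verb.preposition is not None:
                tokens.append(verb.preposition)
                morph.append(MorphTag())
            for i, tok in enumerate(arg["tokens"]):
                tokens.append(tok)
                is_head = i == len(arg["tokens"]) - 1
                morph.append(MorphTag(
                    lemma=arg["lemma"] if is_head else None,
                    cases=frozenset(arg["head_cases"]) if is_head else frozenset(),
                    number=arg["number"] if is_head else None))
            spans[sym] = (start, len(tokens))

    utt = Utterance(id=uid, register=spec.label, tokens=tuple(tokens),
                    language=spec.lexicon.mode, morph=tuple(morph))
    instances = [
        ArgumentInstance(utterance_id=uid, role=role, span=span,
                         verb_lemma=verb.lemma, verb_index=verb_index)
        for role, span in spans.items()
    ]
    return utt, instances


def generate_corpus(spec: RegisterSpec, n_utterances: int, seed: int,
                    id_prefix: str | None = None) -> RoleDataset:
    """Generate a gold-annotated corpus of ``n_utterances`` clauses.

    Deterministic given ``seed``. Every utterance keeps at least one overt
    argument; gold instances carry the verb frame's roles by construction.
    """
    if n_utterances <= 0:
        raise ValueError("n_utterances must be positive")
    spec.validate()
    _register_lexicon_forms(spec)
    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else spec.label.lower()
    utterances: dict[str, Utterance] = {}
    instances: list[ArgumentInstance] = []
    for k in range(n_utterances):
        utt, insts = generate_utterance(spec, f"{prefix}-{k:06d}", rng)
        utterances[utt.id] = utt
        instances.extend(insts)
    return RoleDataset(utterances=utterances, instances=instances)


# ---------------------------------------------------------------------------
# Entropy calibration and register pairing
# ---------------------------------------------------------------------------

def calibrate_role_entropy(spec: RegisterSpec, role: str, target_bits: float,
                           tol: float = 1e-6) -> RegisterSpec:
    """Return a spec whose role-conditional lemma entropy equals
    ``target_bits`` (closed form), found by bisection on the concentration.

    The reachable range is (0, log2(n_nouns)]: a zero target collapses the
    distribution onto one lemma, the log2(n) ceiling needs exactly uniform
    weights (concentration -> infinity, approached within ``tol``).
    """
    n = len(spec.lexicon.nouns)
    h_max = math.log2(n)
    if not 0.0 <= target_bits <= h_max + 1e-12:
        raise ValueError(
            f"target {target_bits} bits outside reachable [0, {h_max:.4f}]")

    def entropy_at(c: float) -> float:
        trial = replace(spec, concentration={**spec.concentration, role: c})
        return trial.role_lemma_entropy(role)

    lo, hi = 1e-3, 1e3
    # entropy_at is increasing in c; expand bounds if needed
    while entropy_at(hi) < target_bits - tol and hi < 1e8:
        hi *= 10
    while entropy_at(lo) > target_bits + tol and lo > 1e-9:
        lo /= 10
    if entropy_at(hi) < target_bits - 1e-3:
        raise ValueError(
            f"target {target_bits} bits unreachable (max {entropy_at(hi):.4f} "
            "under these base weights)")
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if entropy_at(mid) < target_bits:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-12:
            break
    c_star = math.sqrt(lo * hi)
    return replace(spec, concentration={**spec.concentration, role: c_star})


def make_register_pair(base: RegisterSpec,
                       deltas: Mapping[str, object] | None = None,
                       ) -> tuple[RegisterSpec, RegisterSpec]:
    """Derive a (CDS-like, ADS-like) spec pair from one base spec.

    The ADS-like spec is the base (relabelled); the CDS-like spec differs
    only in the named dimensions. Supported deltas:

    * ``entropy``: {role: bits} added to the base role-lemma entropy for the
      CDS-like side (negative = lower variability, the natural-speech
      direction).
    * ``syncretic_weight``: multiplier on syncretic-class lemma weights in
      the CDS-like spec (values < 1 reduce syncretic argument forms).
    * ``order_temperature``: exponent T applied as p^(1/T) (renormalised) to
      the CDS-like word-order distribution; T < 1 sharpens it (lower word-
      order entropy).
    * ``pronoun_prob`` / ``omission_prob`` / ``number_dist``: direct
      overrides for the CDS-like spec.
    """
    deltas = dict(deltas or {})
    ads = replace(base, label="ADS",
                  concentration=dict(base.concentration),
                  word_order_dist=dict(base.word_order_dist),
                  number_dist=dict(base.number_dist))
    cds = replace(base, label="CDS",
                  concentration=dict(base.concentration),
                  word_order_dist=dict(base.word_order_dist),
                  number_dist=dict(base.number_dist))

    if "syncretic_weight" in deltas:
        cds.syncretic_weight = base.syncretic_weight * float(deltas.pop("syncretic_weight"))
    if "order_temperature" in deltas:
        T = float(deltas.pop("order_temperature"))
        p = np.array(list(cds.word_order_dist.values())) ** (1.0 / T)
        p /= p.sum()
        cds.word_order_dist = dict(zip(cds.word_order_dist, p.tolist()))
    for key in ("pronoun_prob", "omission_prob"):
        if key in deltas:
            setattr(cds, key, float(deltas.pop(key)))
    if "number_dist" in deltas:
        cds.number_dist = dict(deltas.pop("number_dist"))
    if "entropy" in deltas:
        for role, dbits in dict(deltas.pop("entropy")).items():
            target = ads.role_lemma_entropy(role) + float(dbits)
            cds = calibrate_role_entropy(cds, role, target)
    if deltas:
        raise ValueError(f"unknown delta keys: {sorted(deltas)}")
    cds.validate()
    ads.validate()
    return cds, ads
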