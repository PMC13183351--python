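"""Role-annotated utterance corpora: data model, JSONL/CoNLL-U I/O, filters.

The atomic datum of the whole pipeline is one argument of a bivalent verb,
labelled with its proto-role (A = most agent-like, P = most patient-like).
An :class:`Utterance` holds the tokens; an :class:`ArgumentInstance` ties a
contiguous token span to a role and a verb. A :class:`RoleDataset` bundles
utterances, instances and the verb inventory and is the unit every later
stage (representations, probing, descriptives) consumes.

Token indexing is 0-based with half-open spans. Punctuation counts as a
token (it shifts positions) but is never argument content.
"""

from __future__ import annotations

import json
import logging
import random
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import (
    CorpusTooSmallError,
    OverlappingSpansError,
    SpanOutOfBoundsError,
    UnknownRoleError,
    VerbNotInFramesError,
)

logger = logging.getLogger(__name__)

ROLES = ("A", "P")


@dataclass(frozen=True)
class MorphTag:
    """Optional per-token morphology (used by the case-frame mapping path)."""

    lemma: str | None = None
    cases: frozenset[str] = frozenset()
    number: str | None = None


@dataclass(frozen=True)
class Utterance:
    id: str
    register: str
    tokens: tuple[str, ...]
    language: str = "synthetic"
    morph: tuple[MorphTag, ...] | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError(f"utterance {self.id!r}: tokens must be non-empty")
        if self.morph is not None and len(self.morph) != len(self.tokens):
            raise ValueError(f"utterance {self.id!r}: morph length mismatch")

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


@dataclass(frozen=True)
class ArgumentInstance:
    utterance_id: str
    role: str
    span: tuple[int, int]  # half-open [start, end)
    verb_lemma: str
    verb_index: int
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise UnknownRoleError(
                f"utterance {self.utterance_id!r}: role {self.role!r} not in {ROLES}"
            )
        start, end = self.span
        if not (0 <= start < end):
            raise SpanOutOfBoundsError(
                f"utterance {self.utterance_id!r}: malformed span {self.span}"
            )
        if start <= self.verb_index < end:
            raise ValueError(
                f"utterance {self.utterance_id!r}: verb index {self.verb_index} "
                f"inside argument span {self.span}"
            )

    @property
    def key(self) -> str:
        """Stable identifier for one argument instance."""
        return f"{self.utterance_id}:{self.role}:{self.span[0]}-{self.span[1]}"

    def surface(self, utterance: Utterance) -> tuple[str, ...]:
        return utterance.tokens[self.span[0] : self.span[1]]


@dataclass
class RoleDataset:
    """A corpus of role-annotated utterances.

    ``utterances`` is keyed by utterance id; ``instances`` reference those
    ids. ``verb_inventory`` is derived unless given explicitly.
    """

    utterances: dict[str, Utterance] = field(default_factory=dict)
    instances: list[ArgumentInstance] = field(default_factory=list)
    verb_inventory: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.verb_inventory:
            self.verb_inventory = {i.verb_lemma for i in self.instances}
        self.validate()

    def validate(self) -> None:
        for inst in self.instances:
            utt = self.utterances.get(inst.utterance_id)
            if utt is None:
                raise KeyError(f"instance references unknown utterance {inst.utterance_id!r}")
            if inst.span[1] > len(utt.tokens):
                raise SpanOutOfBoundsError(
                    f"utterance {inst.utterance_id!r}: span {inst.span} exceeds "
                    f"{len(utt.tokens)} tokens"
                )
            if not (0 <= inst.verb_index < len(utt.tokens)):
                raise SpanOutOfBoundsError(
                    f"utterance {inst.utterance_id!r}: verb index {inst.verb_index} "
                    f"out of bounds"
                )
            if inst.verb_lemma not in self.verb_inventory:
                raise ValueError(
                    f"instance verb {inst.verb_lemma!r} missing from verb inventory"
                )

    # -- convenience ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.instances)

    def instances_of(self, utterance_id: str) -> list[ArgumentInstance]:
        return [i for i in self.instances if i.utterance_id == utterance_id]

    def by_utterance(self) -> dict[str, list[ArgumentInstance]]:
        out: dict[str, list[ArgumentInstance]] = defaultdict(list)
        for inst in self.instances:
            out[inst.utterance_id].append(inst)
        return dict(out)

    def total_tokens(self) -> int:
        return sum(len(u.tokens) for u in self.utterances.values())

    def subset(self, utterance_ids: Iterable[str]) -> "RoleDataset":
        keep = set(utterance_ids)
        utts = {uid: u for uid, u in self.utterances.items() if uid in keep}
        insts = [i for i in self.instances if i.utterance_id in keep]
        return RoleDataset(utterances=utts, instances=insts)


@dataclass(frozen=True)
class CaseFrame:
    """Maps a verb's grammatical-relation/case slots to proto-roles.

    e.g. *videt'* 'to see': (nsubj, NOM) -> A, (obj, ACC) -> P.
    """

    verb_lemma: str
    mapping: tuple[tuple[tuple[str, str], str], ...]  # ((relation, case), role)

    def __post_init__(self) -> None:
        roles = [role for _, role in self.mapping]
        if roles.count("A") != 1 or roles.count("P") != 1:
            raise ValueError(
                f"case frame for {self.verb_lemma!r} must assign A and P exactly once"
            )

    def slot_for(self, relation: str, cases: Iterable[str]) -> str | None:
        for (rel, case), role in self.mapping:
            if rel == relation and case in cases:
                return role
        return None


# ---------------------------------------------------------------------------
# JSONL I/O (canonical on-disk format)
# ---------------------------------------------------------------------------

def _utterance_to_record(utt: Utterance, instances: Sequence[ArgumentInstance]) -> dict:
    rec: dict = {
        "id": utt.id,
        "register": utt.register,
        "language": utt.language,
        "tokens": list(utt.tokens),
        "instances": [
            {
                "role": i.role,
                "span": list(i.span),
                "verb_lemma": i.verb_lemma,
                "verb_index": i.verb_index,
                **({"condition": i.condition} if i.condition else {}),
            }
            for i in instances
        ],
    }
    if utt.source:
        rec["source"] = utt.source
    if utt.morph is not None:
        rec["morph"] = [
            {"lemma": m.lemma, "cases": sorted(m.cases), "number": m.number}
            for m in utt.morph
        ]
    return rec


def write_role_dataset(dataset: RoleDataset, path: str | Path) -> None:
    """Write a RoleDataset in the canonical JSONL schema, one utterance per line."""
    path = Path(path)
    by_utt = dataset.by_utterance()
    with path.open("w", encoding="utf-8") as fh:
        for uid in dataset.utterances:
            utt = dataset.utterances[uid]
            fh.write(json.dumps(_utterance_to_record(utt, by_utt.get(uid, [])),
                               ensure_ascii=False) + "\n")


def read_role_dataset(path: str | Path, format: str = "jsonl",
                      frames: Mapping[str, CaseFrame] | None = None) -> RoleDataset:
    """Read a role dataset from disk.

    ``format="jsonl"`` reads the canonical schema. ``format="conllu+frames"``
    reads a CoNLL-U file and derives instances via :func:`map_roles_from_frame`
    (``frames`` required). Unparseable records raise immediately with the
    offending utterance id; nothing is silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "conllu+frames":
        if frames is None:
            raise ValueError("conllu+frames format requires a frame inventory")
        return _read_conllu(path, frames)
    raise ValueError(f"unknown format {format!r}")


def _read_jsonl(path: Path) -> RoleDataset:
    utterances: dict[str, Utterance] = {}
    instances: list[ArgumentInstance] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            morph = None
            if "morph" in rec:
                morph = tuple(
                    MorphTag(lemma=m.get("lemma"),
                             cases=frozenset(m.get("cases", [])),
                             number=m.get("number"))
                    for m in rec["morph"]
                )
            utt = Utterance(
                id=rec["id"], register=rec["register"],
                tokens=tuple(rec["tokens"]),
                language=rec.get("language", "synthetic"),
                morph=morph, source=rec.get("source"),
            )
            if utt.id in utterances:
                raise ValueError(f"{path}:{lineno}: duplicate utterance id {utt.id!r}")
            utterances[utt.id] = utt
            for irec in rec.get("instances", []):
                inst = ArgumentInstance(
                    utterance_id=utt.id, role=irec["role"],
                    span=tuple(irec["span"]), verb_lemma=irec["verb_lemma"],
                    verb_index=irec["verb_index"],
                    condition=irec.get("condition"),
                )
                if inst.span[1] > len(utt.tokens):
                    raise SpanOutOfBoundsError(
                        f"utterance {utt.id!r}: span {inst.span} exceeds "
                        f"{len(utt.tokens)} tokens"
                    )
                instances.append(inst)
    return RoleDataset(utterances=utterances, instances=instances)


# ---------------------------------------------------------------------------
# CoNLL-U ingestion + case-frame mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParsedToken:
    form: str
    lemma: str
    head: int          # 0 = root, else 1-based index
    deprel: str
    cases: frozenset[str] = frozenset()
    number: str | None = None


@dataclass(frozen=True)
class ParsedUtterance:
    id: str
    register: str
    tokens: tuple[ParsedToken, ...]
    verb_lemma: str
    verb_index: int    # 0-based


def iter_conllu(path: Path) -> Iterator[tuple[str, list[ParsedToken]]]:
    """Minimal CoNLL-U reader: yields (sent_id, tokens).

    Multiword-token and empty-node lines (ids containing '-' or '.') are
    skipped; FEATS Case/Number are parsed when present.
    """
    sent_id = ""
    toks: list[ParsedToken] = []
    with path.open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                if line.startswith("# sent_id"):
                    sent_id = line.split("=", 1)[1].strip()
                continue
            if not line.strip():
                if toks:
                    yield sent_id or f"sent{id(toks)}", toks
                sent_id, toks = "", []
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ValueError(f"{path}: malformed CoNLL-U line: {line!r}")
            if "-" in cols[0] or "." in cols[0]:
                continue
            feats = {}
            if cols[5] not in ("_", ""):
                for kv in cols[5].split("|"):
                    k, _, v = kv.partition("=")
                    feats[k] = v
            cases = frozenset(c.upper() for c in feats.get("Case", "").split(",") if c)
            toks.append(ParsedToken(
                form=cols[1], lemma=cols[2],
                head=int(cols[6]) if cols[6] not in ("_", "") else 0,
                deprel=cols[7].split(":")[0],
                cases=cases, number=feats.get("Number"),
            ))
    if toks:
        yield sent_id or "sent_final", toks


ARGUMENT_RELATIONS = ("nsubj", "obj", "obl")


def map_roles_from_frame(parsed: ParsedUtterance,
                         frames: Mapping[str, CaseFrame],
                         include_adposition: bool = True,
                         ) -> tuple[list[ArgumentInstance], bool]:
    """Map dependents of a bivalent verb to proto-roles via its case frame.

    Returns ``(instances, excluded)`` where ``excluded`` is True when both
    arguments are omitted (only the verb is overt) — the caller drops such
    utterances. Dependents whose relation/case match no frame slot yield no
    instance. ``include_adposition`` keeps a case-marking adposition directly
    preceding the argument head inside the span.
    """
    frame = frames.get(parsed.verb_lemma)
    if frame is None:
        raise VerbNotInFramesError(parsed.verb_lemma)
    instances: list[ArgumentInstance] = []
    for idx, tok in enumerate(parsed.tokens):
        if tok.head - 1 != parsed.verb_index:
            continue
        if tok.deprel not in ARGUMENT_RELATIONS:
            continue
        role = frame.slot_for(tok.deprel, tok.cases or {"NOM"})
        if role is None:
            continue
        start, end = idx, idx + 1
        if include_adposition and idx > 0:
            prev = parsed.tokens[idx - 1]
            if prev.deprel == "case" and prev.head - 1 == idx:
                start = idx - 1
        instances.append(ArgumentInstance(
            utterance_id=parsed.id, role=role, span=(start, end),
            verb_lemma=parsed.verb_lemma, verb_index=parsed.verb_index,
        ))
    excluded = not instances
    return instances, excluded


def _read_conllu(path: Path, frames: Mapping[str, CaseFrame]) -> RoleDataset:
    utterances: dict[str, Utterance] = {}
    instances: list[ArgumentInstance] = []
    skipped_verbs: Counter[str] = Counter()
    for sent_id, toks in iter_conllu(path):
        # the target verb: first root/any token whose lemma is in the frames
        verb_idx = next((i for i, t in enumerate(toks) if t.lemma in frames), None)
        if verb_idx is None:
            skipped_verbs[toks[0].lemma if toks else "?"] += 1
            continue
        parsed = ParsedUtterance(
            id=sent_id, register="unknown", tokens=tuple(toks),
            verb_lemma=toks[verb_idx].lemma, verb_index=verb_idx,
        )
        insts, excluded = map_roles_from_frame(parsed, frames)
        if excluded:
            continue
        utt = Utterance(
            id=sent_id, register="unknown",
            tokens=tuple(t.form for t in toks),
            morph=tuple(MorphTag(lemma=t.lemma, cases=t.cases, number=t.number)
                        for t in toks),
        )
        utterances[utt.id] = utt
        instances.extend(insts)
    if skipped_verbs:
        logger.info("conllu ingestion: %d sentences without a frame verb",
                    sum(skipped_verbs.values()))
    return RoleDataset(utterances=utterances, instances=instances)


def read_case_frames_tsv(path: str | Path) -> dict[str, CaseFrame]:
    """Read a TSV frame table (columns: verb_lemma, relation, case, role)."""
    path = Path(path)
    rows: dict[str, list[tuple[tuple[str, str], str]]] = defaultdict(list)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "verb_lemma":  # header
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            verb, relation, case, role = parts
            rows[verb].append(((relation, case.upper()), role))
    return {v: CaseFrame(verb_lemma=v, mapping=tuple(m)) for v, m in rows.items()}


# ---------------------------------------------------------------------------
# Filters, word-order labelling, size matching
# ---------------------------------------------------------------------------

def apply_dataset_filters(dataset: RoleDataset, min_per_verb: int = 10,
                          blocklist: Iterable[str] = ()) -> RoleDataset:
    """Apply the corpus inclusion rules.

    Keeps only verbs with at least ``min_per_verb`` utterances, drops
    utterances in which both arguments are omitted (i.e. utterances with no
    instance at all), and drops ids in ``blocklist`` (manual exclusions such
    as idiomatic uses). Idempotent; logs removal counts.
    """
    block = set(blocklist)
    by_utt = dataset.by_utterance()
    # utterances with zero overt arguments (or blocklisted) go first
    kept_ids = {uid for uid, insts in by_utt.items() if insts and uid not in block}
    n_no_arg = len(dataset.utterances) - len(kept_ids)

    verb_utts: dict[str, set[str]] = defaultdict(set)
    for inst in dataset.instances:
        if inst.utterance_id in kept_ids:
            verb_utts[inst.verb_lemma].add(inst.utterance_id)
    good_verbs = {v for v, utts in verb_utts.items() if len(utts) >= min_per_verb}
    n_verb_drop = len(verb_utts) - len(good_verbs)

    instances = [i for i in dataset.instances
                 if i.utterance_id in kept_ids and i.verb_lemma in good_verbs]
    final_ids = {i.utterance_id for i in instances}
    utterances = {uid: u for uid, u in dataset.utterances.items() if uid in final_ids}
    logger.info(
        "filters: removed %d argument-less/blocked utterances, %d rare verbs; "
        "%d utterances remain", n_no_arg, n_verb_drop, len(utterances))
    return RoleDataset(utterances=utterances, instances=instances,
                       verb_inventory=good_verbs or set())


def label_word_order(utterance: Utterance,
                     instances: Sequence[ArgumentInstance]) -> str:
    """Return the left-to-right string over {A, P, V} for one clause.

    The position of an argument is the index of its span start; omitted
    arguments contribute no symbol; the verb is the frame's bivalent verb
    (auxiliaries are ignored). e.g. "why did he (A) bite (V) the horse (P)"
    -> "AVP".
    """
    if not instances:
        raise ValueError(f"utterance {utterance.id!r}: no instances to label")
    spans = {}
    for inst in instances:
        if inst.utterance_id != utterance.id:
            raise ValueError("instance does not belong to utterance")
        if inst.role in spans:
            raise ValueError(f"utterance {utterance.id!r}: duplicate role {inst.role}")
        spans[inst.role] = inst.span
    if "A" in spans and "P" in spans:
        a, p = spans["A"], spans["P"]
        if a[0] < p[1] and p[0] < a[1]:
            raise OverlappingSpansError(
                f"utterance {utterance.id!r}: A span {a} overlaps P span {p}")
    verb_index = instances[0].verb_index
    positions = [(verb_index, "V")]
    positions += [(span[0], role) for role, span in spans.items()]
    positions.sort()
    return "".join(sym for _, sym in positions)


def sample_matched_corpus(corpus: Sequence[Utterance] | RoleDataset,
                          token_budget: int, seed: int) -> list[Utterance]:
    """Randomly sample whole utterances without replacement until the token
    budget is first met or exceeded (register size-matching)."""
    if isinstance(corpus, RoleDataset):
        utts = list(corpus.utterances.values())
    else:
        utts = list(corpus)
    total = sum(len(u.tokens) for u in utts)
    if total < token_budget:
        raise CorpusTooSmallError(
            f"corpus has {total} tokens < budget {token_budget}")
    rng = random.Random(seed)
    order = list(range(len(utts)))
    rng.shuffle(order)
    out: list[Utterance] = []
    count = 0
    for idx in order:
        out.append(utts[idx])
        count += len(utts[idx].tokens)
        if count >= token_budget:
            break
    return out


def match_dataset_size(dataset: RoleDataset, token_budget: int,
                       seed: int) -> RoleDataset:
    """Size-match a RoleDataset, keeping instances of sampled utterances."""
    sampled = sample_matched_corpus(dataset, token_budget, seed)
    return dataset.subset(u.id for u in sampled)
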