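"""Maximum-likelihood entropy descriptives over role-annotated corpora.

The plug-in (ML) Shannon entropy of a category-count table summarises how
variable a register is along three axes: which surface forms fill each
proto-role, which word orders occur, and which cases mark each role.
Entropies are reported in bits (log base 2) throughout the package.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .corpus import RoleDataset, label_word_order


def entropy_ml(counts: Mapping[str, int] | Counter) -> float:
    """Plug-in Shannon entropy H = -sum p_hat log2 p_hat, in bits.

    Zero-count categories contribute nothing; an all-zero (or empty) table
    is an error because the empirical distribution is undefined.
    """
    values = np.asarray([c for c in counts.values() if c > 0], dtype=float)
    if values.size == 0:
        raise ValueError("entropy_ml: no observations (all counts zero)")
    if np.any(values < 0):
        raise ValueError("entropy_ml: negative counts")
    p = values / values.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_of_probs(p) -> float:
    """Entropy in bits of an explicit probability vector (zeros allowed)."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


@dataclass
class EntropyReport:
    """Entropy descriptives for one dataset, with the raw count tables."""

    register: str
    argument_entropy: dict[str, float] = field(default_factory=dict)   # role -> bits
    word_order_entropy: float = float("nan")
    case_entropy: dict[str, float] = field(default_factory=dict)       # role -> bits
    argument_counts: dict[str, Counter] = field(default_factory=dict)
    word_order_counts: Counter = field(default_factory=Counter)
    case_counts: dict[str, Counter] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = [
            {"type": "argument", "register": self.register, "role": role,
             "entropy_bits": h}
            for role, h in sorted(self.argument_entropy.items())
        ]
        rows.append({"type": "word order", "register": self.register,
                     "role": "A and P", "entropy_bits": self.word_order_entropy})
        rows += [
            {"type": "case", "register": self.register, "role": role,
             "entropy_bits": h}
            for role, h in sorted(self.case_entropy.items())
        ]
        return rows


def describe_dataset(dataset: RoleDataset, paradigm=None) -> EntropyReport:
    """Compute ML entropies of argument forms (per role), word orders, and
    case labels (per role, when morphology or a paradigm is available).

    Argument-form counts are over the surface token sequence of each span
    (forms, not lemmas, mirroring what a learner observes). Case counts use
    the utterance's morph tier when present, else ``paradigm.possible_cases``
    on single-token spans; syncretic forms contribute their full case set
    as one joint label (e.g. "NOM|ACC").
    """
    register = next(iter(dataset.utterances.values())).register if dataset.utterances else "?"
    arg_counts: dict[str, Counter] = {"A": Counter(), "P": Counter()}
    case_counts: dict[str, Counter] = {"A": Counter(), "P": Counter()}
    order_counts: Counter = Counter()

    by_utt = dataset.by_utterance()
    for uid, insts in by_utt.items():
        utt = dataset.utterances[uid]
        order_counts[label_word_order(utt, insts)] += 1
        for inst in insts:
            surface = " ".join(inst.surface(utt))
            arg_counts[inst.role][surface] += 1
            cases = None
            if utt.morph is not None:
                head = inst.span[1] - 1  # span head = last token (dets precede)
                tags = utt.morph[head]
                if tags.cases:
                    cases = sorted(tags.cases)
            if cases is None and paradigm is not None and inst.span[1] - inst.span[0] == 1:
                try:
                    cells = paradigm.possible_cases(utt.tokens[inst.span[0]])
                    cases = sorted({case for case, _num in cells})
                except KeyError:
                    cases = None
            if cases:
                case_counts[inst.role]["|".join(cases)] += 1

    report = EntropyReport(register=register)
    for role in ("A", "P"):
        if arg_counts[role]:
            report.argument_entropy[role] = entropy_ml(arg_counts[role])
        if case_counts[role]:
            report.case_entropy[role] = entropy_ml(case_counts[role])
    if order_counts:
        report.word_order_entropy = entropy_ml(order_counts)
    report.argument_counts = arg_counts
    report.word_order_counts = order_counts
    report.case_counts = case_counts
    return report
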