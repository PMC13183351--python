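"""Feature-based argument representations: position and possible-case vectors.

These are the two "linguistically annotated" representations: unlike the
learned embeddings they hand the classifier an explicit cue (structural
position, case paradigm cell) rather than requiring it to be induced from
raw text.
"""

from __future__ import annotations

import numpy as np

from .corpus import ArgumentInstance, Utterance
from .synth import CaseParadigm, CASES, NUMBERS

DEFAULT_PUNCTUATION = frozenset({",", ".", "?", "!", ";", ":"})


def encode_position(instance: ArgumentInstance, utterance: Utterance,
                    co_instance: ArgumentInstance | None = None,
                    punctuation: frozenset[str] = DEFAULT_PUNCTUATION,
                    ) -> np.ndarray:
    """Three binary features: (is_first_position, is_before_verb,
    other_argument_present).

    "First position" means the span starts at the utterance's first
    non-punctuation token (interjections and fillers do count, so "he" in
    "why did he bite the horse" is not first)."""
    first_idx = 0
    while (first_idx < len(utterance.tokens)
           and utterance.tokens[first_idx] in punctuation):
        first_idx += 1
    is_first = instance.span[0] == first_idx
    before_verb = instance.span[0] < instance.verb_index
    other_present = co_instance is not None
    return np.array([is_first, before_verb, other_present], dtype=float)


def case_vector_index() -> list[tuple[str, str]]:
    """Fixed ordering of the (case, number) cells spanned by case vectors."""
    return [(case, num) for case in CASES for num in NUMBERS]


def encode_case(surface_form: str, paradigm: CaseParadigm) -> np.ndarray:
    """Multi-hot vector over (case, number) cells whose realisation equals
    ``surface_form``. More than one set bit means the form is syncretic."""
    cells = paradigm.possible_cases(surface_form)  # raises if unanalysable
    index = case_vector_index()
    vec = np.zeros(len(index), dtype=float)
    for cell in cells:
        vec[index.index(cell)] = 1.0
    return vec


def position_matrix(dataset, instances=None) -> tuple[np.ndarray, list]:
    """Stack position vectors for a dataset's instances (in order)."""
    insts = list(instances) if instances is not None else list(dataset.instances)
    by_utt = dataset.by_utterance()
    rows = []
    for inst in insts:
        utt = dataset.utterances[inst.utterance_id]
        others = [i for i in by_utt[inst.utterance_id] if i is not inst]
        co = others[0] if others else None
        rows.append(encode_position(inst, utt, co))
    return np.vstack(rows), insts


def case_matrix(dataset, paradigm: CaseParadigm,
                instances=None) -> tuple[np.ndarray, list]:
    """Stack case vectors (head token of each span) for a dataset."""
    insts = list(instances) if instances is not None else list(dataset.instances)
    rows = []
    for inst in insts:
        utt = dataset.utterances[inst.utterance_id]
        head_form = utt.tokens[inst.span[1] - 1]
        rows.append(encode_case(head_form, paradigm))
    return np.vstack(rows), insts
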