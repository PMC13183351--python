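import numpy as np
import pytest

from roleprobe.corpus import ArgumentInstance, RoleDataset, Utterance
from roleprobe.synth import default_register_spec, generate_corpus


@pytest.fixture(scope="session")
def bite_utterance():
    """The worked example clause: 'why did he bite the horse , Anne ?'."""
    utt = Utterance(id="u-bite", register="CDS", language="english",
                    tokens=("why", "did", "he", "bite", "the", "horse",
                            ",", "Anne", "?"))
    a = ArgumentInstance(utterance_id="u-bite", role="A", span=(2, 3),
                         verb_lemma="bite", verb_index=3)
    p = ArgumentInstance(utterance_id="u-bite", role="P", span=(4, 6),
                         verb_lemma="bite", verb_index=3)
    return utt, a, p


@pytest.fixture(scope="session")
def small_corpus():
    """A small russian-like synthetic corpus with gold annotations."""
    spec = default_register_spec("CDS", mode="russian_like")
    return spec, generate_corpus(spec, 1200, seed=42)


@pytest.fixture(scope="session")
def avp_corpus():
    """Deterministic-AVP register: position fully determines role."""
    spec = default_register_spec("DET", mode="russian_like",
                                 word_order_dist={"AVP": 1.0},
                                 filler_prob=0.0)
    return spec, generate_corpus(spec, 1500, seed=7)


def make_dataset(rows):
    """Build a RoleDataset from (id, tokens, [(role, span, verb, vidx)])."""
    utts, insts = {}, []
    for uid, tokens, arg_rows in rows:
        utts[uid] = Utterance(id=uid, register="X", tokens=tuple(tokens))
        for role, span, verb, vidx in arg_rows:
            insts.append(ArgumentInstance(
                utterance_id=uid, role=role, span=tuple(span),
                verb_lemma=verb, verb_index=vidx))
    return RoleDataset(utterances=utts, instances=insts)
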