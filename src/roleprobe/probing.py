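"""The probing protocol: verb-disjoint splits, probe training, evaluation.

The probe asks whether an argument representation carries enough
information to recover the proto-role (A vs P). To block verb-specific
shortcuts, train and evaluation sets never share a verb lemma; training
sets are small (default 100 items) and exactly role-balanced; the whole
protocol is repeated over several verb partitions ("split versions")
because performance fluctuates with which verbs land in training.

Probes: a two-layer perceptron (hidden width 100, at most 20 epochs,
keeping the lowest-validation-loss state) for the learned embedding
representations, and an RBF-kernel SVM for the two feature-based
representations, where it performs on par at lower cost.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .corpus import ArgumentInstance, RoleDataset
from .errors import InfeasibleSplitError

MLP_REPRESENTATIONS = {"contextual", "static"}
SVM_REPRESENTATIONS = {"position", "case"}


@dataclass
class SplitScheme:
    """One verb-disjoint assignment of instances to train/val/test.

    ``unused`` holds leftover instances of *training* verbs beyond the
    balanced training quota; they can join neither side without breaking
    balance or verb disjointness, so they are carried explicitly."""

    split_id: int
    train: list[str]
    val: list[str]
    test: list[str]
    unused: list[str]
    train_verbs: set[str]
    eval_verbs: set[str]

    def all_keys(self) -> list[str]:
        return self.train + self.val + self.test + self.unused


@dataclass
class ProbeConfig:
    kind: str = "mlp"             # mlp | svm
    hidden: int = 100
    max_epochs: int = 20
    loss_source: str = "val"      # which loss picks the kept epoch: val | train
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("mlp", "svm"):
            raise ValueError(f"unknown probe kind {self.kind!r}")
        if self.hidden <= 0 or self.max_epochs <= 0:
            raise ValueError("hidden width and epochs must be positive")


def make_verb_disjoint_splits(dataset: RoleDataset, n_versions: int = 10,
                              train_size: int = 100,
                              val_range: tuple[int, int] = (100, 300),
                              seed: int = 0) -> list[SplitScheme]:
    """Create ``n_versions`` verb-disjoint, role-balanced split schemes.

    Verbs are shuffled and greedily pooled for training until the balanced
    quota (train_size/2 per role) is reachable; the exact training items
    are then sampled from the pool, surplus pool items go to ``unused``.
    All instances of the remaining verbs are shuffled into validation
    (min(val_range[1], available), but at least val_range[0]) and test.
    Deterministic given ``seed``.
    """
    if train_size % 2:
        raise InfeasibleSplitError("train_size must be even for exact balance")
    by_verb: dict[str, list[ArgumentInstance]] = {}
    for inst in dataset.instances:
        by_verb.setdefault(inst.verb_lemma, []).append(inst)
    verbs = sorted(by_verb)
    if len(verbs) < 2:
        raise InfeasibleSplitError(
            "verb-disjoint splits need at least two verbs")
    half = train_size // 2
    schemes = []
    for version in range(n_versions):
        rng = random.Random(seed * 10007 + version)
        order = verbs[:]
        rng.shuffle(order)
        pool: list[ArgumentInstance] = []
        train_verbs: set[str] = set()
        idx = 0
        while idx < len(order):
            v = order[idx]
            pool.extend(by_verb[v])
            train_verbs.add(v)
            idx += 1
            n_a = sum(1 for i in pool if i.role == "A")
            n_p = sum(1 for i in pool if i.role == "P")
            if n_a >= half and n_p >= half:
                break
        else:
            raise InfeasibleSplitError(
                f"cannot reach {half} instances per role: dataset has only "
                f"{sum(1 for i in dataset.instances if i.role == 'A')} A / "
                f"{sum(1 for i in dataset.instances if i.role == 'P')} P")
        eval_verbs = set(order[idx:])
        if not eval_verbs:
            raise InfeasibleSplitError(
                "all verbs consumed by the training pool; nothing left for "
                "validation/test")
        a_pool = [i for i in pool if i.role == "A"]
        p_pool = [i for i in pool if i.role == "P"]
        rng.shuffle(a_pool)
        rng.shuffle(p_pool)
        train = a_pool[:half] + p_pool[:half]
        rng.shuffle(train)
        unused = a_pool[half:] + p_pool[half:]
        eval_insts = [i for v in sorted(eval_verbs) for i in by_verb[v]]
        rng.shuffle(eval_insts)
        lo, hi = val_range
        if len(eval_insts) <= lo:
            raise InfeasibleSplitError(
                f"only {len(eval_insts)} evaluation instances; validation "
                f"alone needs more than {lo}")
        val_size = min(hi, len(eval_insts) - 1)  # >= lo because len > lo
        val = eval_insts[:val_size]
        test = eval_insts[val_size:]
        if not test:
            raise InfeasibleSplitError("no instances left for the test set")
        schemes.append(SplitScheme(
            split_id=version + 1,
            train=[i.key for i in train],
            val=[i.key for i in val],
            test=[i.key for i in test],
            unused=[i.key for i in unused],
            train_verbs=train_verbs,
            eval_verbs=eval_verbs,
        ))
    return schemes


class FrozenProbe:
    """A fitted binary classifier with a fixed decision function."""

    def __init__(self, model, classes: np.ndarray):
        self._model = model
        self.classes_ = classes

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict(np.asarray(X, dtype=float))


def train_probe(train_X: np.ndarray, train_y: Sequence[str],
                val_X: np.ndarray, val_y: Sequence[str],
                config: ProbeConfig) -> FrozenProbe:
    """Fit one probe.

    The perceptron path runs at most ``max_epochs`` passes and keeps the
    parameter state with the lowest validation loss (a config switch
    selects training loss instead); the SVM path fits once. Deterministic
    given ``config.seed``.
    """
    train_X = np.asarray(train_X, dtype=float)
    val_X = np.asarray(val_X, dtype=float)
    y = np.asarray(train_y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if train_X.shape[0] != y.shape[0]:
        raise ValueError("matrix/label length mismatch")

    if config.kind == "svm":
        model = SVC(kernel="rbf", C=config.svm_c)
        model.fit(train_X, y)
        return FrozenProbe(model, classes)

    model = MLPClassifier(hidden_layer_sizes=(config.hidden,),
                          random_state=config.seed, max_iter=1,
                          warm_start=False)
    best_loss, best_state = np.inf, None
    monitor_X = val_X if config.loss_source == "val" else train_X
    monitor_y = np.asarray(val_y) if config.loss_source == "val" else y
    for _epoch in range(config.max_epochs):
        model.partial_fit(train_X, y, classes=classes)
        proba = model.predict_proba(monitor_X)
        loss = log_loss(monitor_y, proba, labels=list(model.classes_))
        if loss < best_loss:
            best_loss = loss
            best_state = (copy.deepcopy(model.coefs_),
                          copy.deepcopy(model.intercepts_))
    model.coefs_, model.intercepts_ = best_state
    return FrozenProbe(model, classes)


def evaluate_probe(probe: FrozenProbe, X: np.ndarray,
                   instances: Sequence[ArgumentInstance],
                   register: str, representation: str,
                   split_id: int) -> list[dict]:
    """One ClassificationRecord per argument (as a plain dict row)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(instances):
        raise ValueError("matrix and instance list differ in length")
    preds = probe.predict(X)
    rows = []
    for inst, pred in zip(instances, preds):
        rows.append({
            "argument_id": inst.key,
            "sentence_id": inst.utterance_id,
            "register": register,
            "role": inst.role,
            "representation": representation,
            "split_id": split_id,
            "condition": inst.condition,
            "predicted": str(pred),
            "correct": int(str(pred) == inst.role),
        })
    return rows


def probe_kind_for(representation: str) -> str:
    if representation in MLP_REPRESENTATIONS:
        return "mlp"
    if representation in SVM_REPRESENTATIONS:
        return "svm"
    raise ValueError(f"unknown representation {representation!r}")


def run_register_experiment(
        datasets: Mapping[str, RoleDataset],
        vectors: Mapping[str, Mapping[str, Mapping[str, np.ndarray]]],
        n_versions: int = 10, train_size: int = 100,
        val_range: tuple[int, int] = (100, 300),
        probe_seed: int = 0, split_seed: int = 0) -> pd.DataFrame:
    """Run the full probing protocol for every register x representation.

    ``vectors[register][representation]`` maps argument keys to vectors
    (built once by the representations stage). Returns the full table of
    per-argument classification records over all splits.
    """
    all_rows: list[dict] = []
    for register, dataset in datasets.items():
        inst_by_key = {i.key: i for i in dataset.instances}
        schemes = make_verb_disjoint_splits(
            dataset, n_versions=n_versions, train_size=train_size,
            val_range=val_range, seed=split_seed)
        for representation, vecmap in vectors[register].items():
            kind = probe_kind_for(representation)
            for scheme in schemes:
                def matrix(keys: list[str]):
                    ks = [k for k in keys if k in vecmap]
                    return (np.vstack([vecmap[k] for k in ks]),
                            [inst_by_key[k] for k in ks])
                Xtr, tr_insts = matrix(scheme.train)
                Xva, va_insts = matrix(scheme.val)
                Xte, te_insts = matrix(scheme.test)
                probe = train_probe(
                    Xtr, [i.role for i in tr_insts],
                    Xva, [i.role for i in va_insts],
                    ProbeConfig(kind=kind, seed=probe_seed))
                all_rows.extend(evaluate_probe(
                    probe, Xte, te_insts, register, representation,
                    scheme.split_id))
    return pd.DataFrame(all_rows)


def accuracy_table(records: pd.DataFrame,
                   by: Sequence[str] = ("register", "representation", "role"),
                   ) -> pd.DataFrame:
    """Aggregate accuracy = mean of correct flags per cell."""
    return (records.groupby(list(by))["correct"].agg(["mean", "count"])
            .rename(columns={"mean": "accuracy", "count": "n"})
            .reset_index())
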