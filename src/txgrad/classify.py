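"""Logistic-regression classification of samples to anatomical divisions.

Binary (above/below the boundary fissure) and multiclass one-vs-rest
variants share a stratified seeded train/test split and an L2-penalized
logistic model fit by L-BFGS. Reports carry per-class accuracy (recall),
a confusion matrix, and an F1 score — binary F1 for the configurable
positive class, micro-averaged F1 pooled over classes for multiclass.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.multiclass import OneVsRestClassifier

from .io_formats import UNASSIGNED, ParcellationVolume, SampleTable

__all__ = [
    "ClassReport",
    "classify_binary",
    "classify_multiclass",
    "sample_division_labels",
    "ABOVE",
    "BELOW",
]

logger = logging.getLogger(__name__)

#: Division labels: anterior of the boundary plane maps to ABOVE.
ABOVE = "above"
BELOW = "below"


@dataclasses.dataclass
class ClassReport:
    classes: list[str]
    confusion: np.ndarray  # true x predicted counts
    per_class_accuracy: dict[str, float]
    overall_accuracy: float
    f1: float
    split_seed: int
    n_train: int
    n_test: int


def _fit_and_report(
    x: np.ndarray,
    labels: np.ndarray,
    train_fraction: float,
    seed: int,
    c: float,
    f1_mode: str,
    positive_class: str | None,
) -> ClassReport:
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    classes = sorted(set(labels.tolist()))
    idx_train, idx_test = train_test_split(
        np.arange(len(labels)),
        train_size=train_fraction,
        random_state=seed,
        shuffle=True,
        stratify=labels,
    )
    for name, idx in (("train", idx_train), ("test", idx_test)):
        present = set(labels[idx].tolist())
        if present != set(classes):
            raise ValueError(
                f"class(es) {sorted(set(classes) - present)} absent from {name} "
                "split; try a different seed"
            )
    # tol on the gradient, matching lbfgs convergence at 1e-6 / 1000 iters
    base = LogisticRegression(C=c, solver="lbfgs", tol=1e-6, max_iter=1000)
    # multiclass is decomposed one-vs-rest: one binary problem per label
    model = base if len(classes) == 2 else OneVsRestClassifier(base)
    model.fit(x[idx_train], labels[idx_train])
    pred = model.predict(x[idx_test])
    true = labels[idx_test]

    k = len(classes)
    index = {cls: i for i, cls in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(true, pred):
        confusion[index[t], index[p]] += 1
    per_class = {
        cls: confusion[i, i] / confusion[i].sum() for i, cls in enumerate(classes)
    }
    overall = float(np.trace(confusion) / confusion.sum())

    if f1_mode == "binary":
        i = index[positive_class]
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
    else:  # micro: pool TP/FP/FN over classes
        tp = np.trace(confusion)
        fp = confusion.sum() - tp
        fn = confusion.sum() - tp
        f1 = 2 * tp / (2 * tp + fp + fn)
    return ClassReport(
        classes=classes,
        confusion=confusion,
        per_class_accuracy={c_: float(v) for c_, v in per_class.items()},
        overall_accuracy=overall,
        f1=float(f1),
        split_seed=seed,
        n_train=len(idx_train),
        n_test=len(idx_test),
    )


def classify_binary(
    samples: np.ndarray,
    labels: list[str],
    train_fraction: float = 0.8,
    seed: int = 0,
    c: float = 1.0,
    positive_class: str = BELOW,
) -> ClassReport:
    """Binary division classification with the F1 of ``positive_class``."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) != 2:
        raise ValueError("binary classification requires exactly two classes")
    return _fit_and_report(
        np.asarray(samples, dtype=float),
        labels,
        train_fraction,
        seed,
        c,
        "binary",
        positive_class,
    )


def classify_multiclass(
    samples: np.ndarray,
    labels: list[str],
    train_fraction: float = 0.8,
    seed: int = 0,
    c: float = 1.0,
) -> ClassReport:
    """One-vs-rest multiclass classification with micro-averaged F1."""
    labels = np.asarray(labels)
    counts = {cls: int((labels == cls).sum()) for cls in set(labels.tolist())}
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValueError("need >= 2 classes with >= 2 samples each")
    return _fit_and_report(
        np.asarray(samples, dtype=float), labels, train_fraction, seed, c, "micro", None
    )


def sample_division_labels(
    assignment: SampleTable, parcellation: ParcellationVolume
) -> tuple[list[int], list[str]]:
    """Division label per assigned sample, inherited from the region legend.

    Returns (indices of included samples, their labels); unassigned samples
    are excluded with the count logged. A region tagged 'none' is an error.
    """
    division_map = {"anterior": ABOVE, "posterior": BELOW}
    kept, labels = [], []
    n_excluded = 0
    for i, rid in enumerate(assignment.region_label):
        if rid == UNASSIGNED:
            n_excluded += 1
            continue
        info = parcellation.legend[int(rid)]
        if info.division not in division_map:
            raise ValueError(f"region {rid} has no anterior/posterior division tag")
        kept.append(i)
        labels.append(division_map[info.division])
    if n_excluded:
        logger.info("excluded %d unassigned samples", n_excluded)
    return kept, labels
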