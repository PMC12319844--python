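"""Stability-based gene selection.

Gene stability is the correlation, over regions, of a gene's mean regional
profile between two disjoint donor groups. Selection keeps the genes
strictly above a percentile of the defined scores; a cross-validated linear
model picks an optimal feature count from a stability ranking; an external
gene-set filter re-selects a fixed-size top set within an allowed list.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, train_test_split

from .io_formats import RegionExpression

__all__ = [
    "StabilityScores",
    "split_half_stability",
    "select_top_percentile",
    "optimize_feature_count",
    "FeatureCountResult",
    "filter_gene_set",
]

logger = logging.getLogger(__name__)

_MIN_SHARED_REGIONS = 3


@dataclasses.dataclass
class StabilityScores:
    """Per-gene split-half correlations with the donor grouping used."""

    gene_ids: list[str]
    score: np.ndarray  # NaN where undefined
    group_a: set[str]
    group_b: set[str]

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.gene_ids),):
            raise ValueError("one score per gene required")
        if self.group_a & self.group_b:
            raise ValueError("donor groups must be disjoint")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.score)


def _group_mean(matrices: list[RegionExpression]) -> np.ndarray:
    stack = np.stack([m.values for m in matrices])
    ok = np.isfinite(stack)
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ok, stack, 0.0).sum(axis=0) / n
    return np.where(n > 0, mean, np.nan)


def split_half_stability(
    donor_matrices: list[RegionExpression],
    group_a: set[str],
    group_b: set[str],
    method: str = "pearson",
) -> StabilityScores:
    """Correlate group-mean regional profiles between two donor halves.

    Per gene: average the regional profiles within each group
    (missing-aware), then correlate the two mean profiles over regions
    non-missing in both. Genes with fewer than 3 shared regions or a
    zero-variance profile are flagged undefined (NaN).
    """
    if not group_a or not group_b:
        raise ValueError("both donor groups must be nonempty")
    if group_a & group_b:
        raise ValueError("donor groups must be disjoint")
    by_id = {m.donor_id: m for m in donor_matrices}
    mats_a = [by_id[d] for d in sorted(group_a)]
    mats_b = [by_id[d] for d in sorted(group_b)]
    ref = donor_matrices[0]
    for m in donor_matrices[1:]:
        if m.gene_ids != ref.gene_ids or m.region_ids != ref.region_ids:
            raise ValueError("donor matrices must share gene and region universes")

    prof_a = _group_mean(mats_a)
    prof_b = _group_mean(mats_b)
    scores = np.full(ref.n_genes, np.nan)
    any_shared = False
    for g in range(ref.n_genes):
        a, b = prof_a[g], prof_b[g]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < _MIN_SHARED_REGIONS:
            continue
        any_shared = True
        a, b = a[ok], b[ok]
        if method == "spearman":
            a, b = rankdata(a), rankdata(b)
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        scores[g] = np.corrcoef(a, b)[0, 1]
    if not any_shared:
        raise ValueError("no gene has enough shared regions between groups")
    return StabilityScores(
        gene_ids=list(ref.gene_ids), score=scores, group_a=set(group_a), group_b=set(group_b)
    )


def select_top_percentile(scores: StabilityScores, percentile: float) -> set[str]:
    """Genes with score strictly above the given percentile of defined scores.

    The percentile uses linear interpolation; with N distinct scores the
    retained count is N - floor(percentile/100 * N).
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    defined = scores.defined
    if not defined.any():
        raise ValueError("no defined stability scores")
    threshold = np.percentile(scores.score[defined], percentile)
    return {
        g
        for g, s, ok in zip(scores.gene_ids, scores.score, defined)
        if ok and s > threshold
    }


@dataclasses.dataclass
class FeatureCountResult:
    optimal_count: int
    counts: np.ndarray
    train_rmse: np.ndarray
    validation_rmse: np.ndarray
    test_rmse: float


def optimize_feature_count(
    sample_matrix: np.ndarray,
    sample_regions: np.ndarray,
    ranking: list[int],
    train_fraction: float = 0.8,
    k_folds: int = 5,
    seed: int = 0,
) -> FeatureCountResult:
    """Pick the prefix of a stability ranking minimizing cross-validated RMSE.

    An ordinary linear model predicts each sample's region ordinal index
    from its expression over the first ``m`` ranked genes; ``m`` sweeps the
    full ranking, k-fold validation RMSE is recorded on the training split,
    and the winner is refit and scored on the held-out test split.
    """
    x = np.asarray(sample_matrix, dtype=float)
    y = np.asarray(sample_regions, dtype=float)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(y) != x.shape[0]:
        raise ValueError("sample_regions must align with sample_matrix rows")
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), train_size=train_fraction, random_state=seed, shuffle=True
    )
    if len(idx_train) < k_folds:
        raise ValueError("fewer training samples than folds")

    counts = np.arange(1, len(ranking) + 1)
    train_rmse = np.empty(len(counts))
    val_rmse = np.empty(len(counts))
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for i, m in enumerate(counts):
        cols = ranking[:m]
        xt, yt = x[np.ix_(idx_train, cols)], y[idx_train]
        fold_rmse = []
        for tr, va in kf.split(xt):
            model = LinearRegression().fit(xt[tr], yt[tr])
            resid = model.predict(xt[va]) - yt[va]
            fold_rmse.append(np.sqrt(np.mean(resid**2)))
        val_rmse[i] = np.mean(fold_rmse)
        model = LinearRegression().fit(xt, yt)
        train_rmse[i] = np.sqrt(np.mean((model.predict(xt) - yt) ** 2))

    best = int(counts[np.argmin(val_rmse)])
    cols = ranking[:best]
    model = LinearRegression().fit(x[np.ix_(idx_train, cols)], y[idx_train])
    resid = model.predict(x[np.ix_(idx_test, cols)]) - y[idx_test]
    test_rmse = float(np.sqrt(np.mean(resid**2)))
    return FeatureCountResult(
        optimal_count=best,
        counts=counts,
        train_rmse=train_rmse,
        validation_rmse=val_rmse,
        test_rmse=test_rmse,
    )


def filter_gene_set(
    scores: StabilityScores,
    allowed: set[str],
    n: int,
    reference: set[str] | None = None,
) -> tuple[set[str], int | None]:
    """Top-``n`` defined-score genes within an external allowed list.

    Sort by score descending (ties toward the lexicographically smaller
    gene id). If the intersection is smaller than ``n``, all of it is
    returned with a logged warning. Returns (selected, overlap with the
    optional reference set).
    """
    if not allowed:
        raise ValueError("allowed gene set must be nonempty")
    candidates = [
        (g, s)
        for g, s, ok in zip(scores.gene_ids, scores.score, scores.defined)
        if ok and g in allowed
    ]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    if len(candidates) < n:
        logger.warning(
            "requested %d genes but only %d pass the filter; returning all",
            n,
            len(candidates),
        )
    selected = {g for g, _ in candidates[:n]}
    overlap = len(selected & reference) if reference is not None else None
    return selected, overlap
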