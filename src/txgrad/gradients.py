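"""Hierarchical clustering, ordering bootstrap, distance-regressed
correlations, and principal-component gradients over regional profiles.

Regions are clustered with Ward linkage on Euclidean distances between
their gene-expression profiles. The dendrogram is *rooted*: at every merge
the subtree containing the profile closest to a designated anchor region is
placed first, so the leaf order is a meaningful 1-D arrangement anchored at
that region. A bootstrap that shuffles gene values within each region
quantifies how often chance reproduces the exact leaf order.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.cluster.hierarchy import linkage

from .io_formats import RegionExpression

__all__ = [
    "OrderingResult",
    "PCResult",
    "cluster_regions",
    "ordering_bootstrap",
    "distance_regressed_correlation",
    "pc_gradients",
    "network_block_summary",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class OrderingResult:
    """Ward linkage with a rooted leaf order and optional bootstrap p."""

    linkage: np.ndarray
    leaf_order: list[str]
    anchor: str
    bootstrap_p: float | None = None
    p_label: str | None = None
    n_boot: int | None = None
    seed: int | None = None

    @property
    def top_split(self) -> tuple[set[str], set[str]]:
        """Leaf sets of the two subtrees below the final merge."""
        n = len(self.leaf_order)
        members: list[set[int]] = [{i} for i in range(n)]
        for a, b, _, _ in self.linkage:
            members.append(members[int(a)] | members[int(b)])
        left, right = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        ids = self._input_ids
        return (
            {ids[i] for i in members[left]},
            {ids[i] for i in members[right]},
        )

    _input_ids: list[str] = dataclasses.field(default_factory=list, repr=False)


@dataclasses.dataclass
class PCResult:
    """Region loadings and explained variance of an SVD decomposition."""

    region_ids: list[str]
    loadings: np.ndarray  # region x component, scaled by singular values
    explained_variance_pct: np.ndarray
    crossover_index: int | None


def _region_key(rid: str):
    try:
        return (0, int(rid))
    except ValueError:
        return (1, rid)


def _rooted_leaf_order(z: np.ndarray, region_ids: list[str], dist_to_anchor: np.ndarray) -> list[str]:
    """Leaf order with, at every merge, the subtree whose closest-to-anchor
    profile is nearest placed first (ties -> lower region id)."""
    n = len(region_ids)
    # per node: (min distance to anchor, best region key, leaf list in order)
    nodes: list[tuple[float, tuple, list[int]]] = [
        (float(dist_to_anchor[i]), _region_key(region_ids[i]), [i]) for i in range(n)
    ]
    for a, b, _, _ in z:
        na, nb = nodes[int(a)], nodes[int(b)]
        first, second = (na, nb) if (na[0], na[1]) <= (nb[0], nb[1]) else (nb, na)
        nodes.append((first[0], first[1], first[2] + second[2]))
    return [region_ids[i] for i in nodes[-1][2]]


def cluster_regions(expr: RegionExpression, anchor: str) -> OrderingResult:
    """Ward/Euclidean clustering of regional profiles with rooted ordering.

    Regions that are entirely missing are dropped first (and logged).
    """
    expr, dropped = expr.drop_missing_regions()
    if dropped:
        logger.info("dropping %d regions with no samples: %s", len(dropped), dropped)
    if expr.n_regions < 2:
        raise ValueError("need at least 2 regions to cluster")
    if anchor not in expr.region_ids:
        raise ValueError(f"anchor region {anchor!r} not among regions")
    if np.isnan(expr.values).any():
        raise ValueError("expression matrix contains missing entries")
    profiles = expr.values.T  # region x gene
    z = linkage(profiles, method="ward")
    anchor_profile = profiles[expr.region_ids.index(anchor)]
    dist = np.linalg.norm(profiles - anchor_profile, axis=1)
    order = _rooted_leaf_order(z, expr.region_ids, dist)
    return OrderingResult(
        linkage=z, leaf_order=order, anchor=anchor, _input_ids=list(expr.region_ids)
    )


def _position_vector(order: list[str], region_ids: list[str]) -> np.ndarray:
    pos = {r: i for i, r in enumerate(order)}
    return np.array([pos[r] for r in region_ids], dtype=float)


def ordering_bootstrap(
    expr: RegionExpression,
    anchor: str,
    n_boot: int,
    seed: int = 0,
    shuffle_unit: str = "within_region",
) -> OrderingResult:
    """Bootstrap test of the rooted leaf order.

    Each iteration independently permutes the gene values within every
    region's profile (``shuffle_unit="within_region"``, default) or permutes
    whole profiles across regions (``"across_regions"``), re-clusters, and
    measures the Euclidean distance between position-by-region vectors of
    the bootstrap and true orderings. The p-value is the fraction of
    iterations at distance exactly zero; when that count is zero the label
    reports ``p < 1/n_boot``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if shuffle_unit not in ("within_region", "across_regions"):
        raise ValueError("unknown shuffle_unit")
    expr, _ = expr.drop_missing_regions()
    true = cluster_regions(expr, anchor)
    true_pos = _position_vector(true.leaf_order, expr.region_ids)

    rng = np.random.default_rng(seed)
    values = expr.values
    zeros = 0
    for _ in range(n_boot):
        if shuffle_unit == "within_region":
            shuffled = np.empty_like(values)
            for j in range(values.shape[1]):
                shuffled[:, j] = rng.permutation(values[:, j])
        else:
            shuffled = values[:, rng.permutation(values.shape[1])]
        boot = RegionExpression(
            region_ids=list(expr.region_ids),
            gene_ids=list(expr.gene_ids),
            values=shuffled,
            donor_id=expr.donor_id,
        )
        boot_order = cluster_regions(boot, anchor).leaf_order
        boot_pos = _position_vector(boot_order, expr.region_ids)
        if np.linalg.norm(boot_pos - true_pos) == 0.0:
            zeros += 1

    p = zeros / n_boot
    label = f"p < {1.0 / n_boot:g}" if zeros == 0 else f"p = {p:g}"
    return OrderingResult(
        linkage=true.linkage,
        leaf_order=true.leaf_order,
        anchor=anchor,
        bootstrap_p=p,
        p_label=label,
        n_boot=n_boot,
        seed=seed,
        _input_ids=list(expr.region_ids),
    )


def distance_regressed_correlation(
    expr: RegionExpression, centroids: dict[str, np.ndarray]
) -> np.ndarray:
    """Pairwise profile correlations with inter-region distance regressed out.

    Pearson correlations of gene profiles for every region pair are
    regressed (OLS with intercept) on pairwise centroid Euclidean distance;
    the symmetric residual matrix is returned with a zero diagonal.
    """
    expr, _ = expr.drop_missing_regions()
    missing = [r for r in expr.region_ids if r not in centroids]
    if missing:
        raise ValueError(f"centroids missing for regions: {missing}")
    n = expr.n_regions
    iu = np.triu_indices(n, k=1)
    if len(iu[0]) < 3:
        raise ValueError("need at least 3 region pairs for the regression")
    corr = np.corrcoef(expr.values.T)
    xyz = np.array([centroids[r] for r in expr.region_ids], dtype=float)
    dist = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)

    c = corr[iu]
    d = dist[iu]
    design = np.column_stack([np.ones_like(d), d])
    beta, *_ = np.linalg.lstsq(design, c, rcond=None)
    resid = c - design @ beta
    out = np.zeros((n, n))
    out[iu] = resid
    out += out.T
    logger.debug("distance regression slope %.4g intercept %.4g", beta[1], beta[0])
    return out


def pc_gradients(
    expr: RegionExpression, axis_order: list[str], n_components: int
) -> PCResult:
    """SVD gradients of the gene x region matrix.

    The matrix is centered across regions per gene; region loadings are the
    right singular vectors scaled by their singular values. Component signs
    are fixed so the first region of ``axis_order`` (the anchor) loads
    positive on every component. ``crossover_index`` is the position in
    ``axis_order`` of the first region whose PC1 loading sign differs from
    its predecessor's, or None if PC1 never changes sign.
    """
    expr, _ = expr.drop_missing_regions()
    if n_components > min(expr.n_genes, expr.n_regions):
        raise ValueError("n_components exceeds matrix rank bound")
    unknown = [r for r in axis_order if r not in expr.region_ids]
    if unknown:
        raise ValueError(f"axis_order regions not in matrix: {unknown}")
    x = expr.values - expr.values.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s**2))
    explained = 100.0 * s**2 / total if total > 0 else np.zeros_like(s)
    loadings = vt.T * s  # region x component

    anchor_idx = expr.region_ids.index(axis_order[0])
    for k in range(loadings.shape[1]):
        if loadings[anchor_idx, k] < 0:
            loadings[:, k] = -loadings[:, k]

    pc1 = {r: loadings[i, 0] for i, r in enumerate(expr.region_ids)}
    crossover = None
    signs = [np.sign(pc1[r]) for r in axis_order]
    prev = None
    for i, sgn in enumerate(signs):
        if sgn == 0:
            continue
        if prev is not None and sgn != prev:
            crossover = i
            break
        prev = sgn
    return PCResult(
        region_ids=list(expr.region_ids),
        loadings=loadings[:, :n_components],
        explained_variance_pct=explained[:n_components],
        crossover_index=crossover,
    )


def network_block_summary(
    corr: np.ndarray, region_ids: list[str], blocks: dict[str, str]
) -> dict[tuple[str, str], float]:
    """Mean off-diagonal correlation within and between region blocks."""
    unlabeled = [r for r in region_ids if r not in blocks]
    if unlabeled:
        raise ValueError(f"regions without block label: {unlabeled}")
    labels = np.array([blocks[r] for r in region_ids])
    out: dict[tuple[str, str], float] = {}
    names = sorted(set(labels))
    for i, a in enumerate(names):
        for b in names[i:]:
            mask_a, mask_b = labels == a, labels == b
            block = corr[np.ix_(mask_a, mask_b)]
            if a == b:
                vals = block[~np.eye(block.shape[0], dtype=bool)]
            else:
                vals = block.ravel()
            if vals.size == 0:
                logger.warning("block pair (%s, %s) has no off-diagonal entries", a, b)
                continue
            out[(a, b)] = float(vals.mean())
    return out
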