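"""Donor probe tables -> region x gene matrices.

Four stages: pooled intensity-based probe filtering, cross-donor
representative-probe selection, sample-to-parcel assignment with a bounded
search expansion, and region aggregation followed by two-pass (sample-wise
then gene-wise) z-scoring.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .io_formats import (
    UNASSIGNED,
    ParcellationVolume,
    ProbeTable,
    RegionExpression,
    SampleTable,
)

_MIN_SHARED_REGIONS = 3

__all__ = [
    "intensity_filter",
    "probe_region_means",
    "select_representative_probe",
    "assign_samples",
    "aggregate_by_region",
    "normalize_two_pass",
    "group_average",
]


def intensity_filter(probes: list[ProbeTable], level: float) -> set[str]:
    """Retain probes whose pooled above-noise fraction is >= ``level``.

    Samples are pooled across all donors; the comparison is inclusive.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must be in [0, 1]")
    if not probes:
        raise ValueError("no probe tables supplied")
    ref = probes[0].probe_ids
    for pt in probes[1:]:
        if pt.probe_ids != ref:
            raise ValueError("donors must share an identical probe id list")
    above = np.zeros(len(ref), dtype=int)
    total = 0
    for pt in probes:
        above += pt.above_noise.sum(axis=1)
        total += pt.n_samples
    frac = above / total
    return {pid for pid, f in zip(ref, frac) if f >= level}


def probe_region_means(
    probes: ProbeTable,
    samples: SampleTable,
    region_ids: list[str],
    probe_subset: set[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Mean expression per probe per region for one donor.

    Regions without samples are NaN. Returns (probe ids, probe x region).
    """
    keep = (
        [i for i, p in enumerate(probes.probe_ids) if p in probe_subset]
        if probe_subset is not None
        else list(range(probes.n_probes))
    )
    expr = probes.expression[keep, :]
    out = np.full((len(keep), len(region_ids)), np.nan)
    labels = np.asarray(samples.region_label)
    for j, rid in enumerate(region_ids):
        mask = labels == rid
        if mask.any():
            out[:, j] = expr[:, mask].mean(axis=1)
    return [probes.probe_ids[i] for i in keep], out


def _pairwise_spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman correlation of two profiles over jointly non-missing regions.

    NaN when fewer than 3 shared regions or either profile is constant.
    """
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan
    ra, rb = rankdata(a[ok]), rankdata(b[ok])
    if np.std(ra) == 0 or np.std(rb) == 0:
        return np.nan
    return float(np.corrcoef(ra, rb)[0, 1])


def select_representative_probe(
    probes: list[ProbeTable],
    region_means: dict[str, tuple[list[str], np.ndarray]],
) -> dict[str, str]:
    """Pick one probe per gene by cross-donor profile reproducibility.

    For each candidate probe the Spearman correlation of its regional mean
    profile is computed between every unordered donor pair and averaged;
    the probe with the highest average wins. Undefined correlations
    (constant or under-sampled profiles) are omitted from the average; a
    probe with no defined pair ranks last. Single-probe genes keep their
    probe. Ties break toward the lexicographically smaller probe id.

    ``region_means`` maps donor_id -> (probe ids, probe x region means),
    e.g. from :func:`probe_region_means` on a shared parcellation.
    """
    donor_ids = [pt.donor_id for pt in probes]
    profiles: dict[str, dict[str, np.ndarray]] = {}  # probe -> donor -> profile
    for did in donor_ids:
        pids, mat = region_means[did]
        for i, pid in enumerate(pids):
            profiles.setdefault(pid, {})[did] = mat[i]

    gene_probes: dict[str, list[str]] = {}
    seen = set()
    for pt in probes:
        for pid, gene in zip(pt.probe_ids, pt.gene_symbols):
            if pid in profiles and pid not in seen:
                gene_probes.setdefault(gene, []).append(pid)
                seen.add(pid)

    pairs = [
        (donor_ids[i], donor_ids[j])
        for i in range(len(donor_ids))
        for j in range(i + 1, len(donor_ids))
    ]

    # Missing regions come from unsampled parcels, so the NaN pattern is a
    # per-donor property shared by all probes. That lets each donor pair be
    # ranked and correlated in one vectorized pass; rows with irregular NaN
    # patterns fall back to the per-pair shared-region computation.
    multi = sorted({p for pids in gene_probes.values() if len(pids) > 1 for p in pids})
    pidx = {p: i for i, p in enumerate(multi)}
    mats = {
        did: np.array([profiles[p][did] for p in multi]) if multi else np.empty((0, 0))
        for did in donor_ids
    }
    r_sum = np.zeros(len(multi))
    r_cnt = np.zeros(len(multi), dtype=int)
    for a, b in pairs:
        ma, mb = mats[a], mats[b]
        shared = np.all(np.isfinite(ma), axis=0) & np.all(np.isfinite(mb), axis=0)
        # exact iff the probe's own pairwise mask equals the shared mask
        own = np.isfinite(ma) & np.isfinite(mb)
        inexact = ~np.all(own == shared[None, :], axis=1)
        if shared.sum() >= _MIN_SHARED_REGIONS:
            ra = rankdata(ma[:, shared], axis=1)
            rb = rankdata(mb[:, shared], axis=1)
            sa, sb = ra.std(axis=1), rb.std(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                za = (ra - ra.mean(axis=1, keepdims=True)) / sa[:, None]
                zb = (rb - rb.mean(axis=1, keepdims=True)) / sb[:, None]
                r = np.mean(za * zb, axis=1)
            r[(sa == 0) | (sb == 0)] = np.nan
        else:
            r = np.full(len(multi), np.nan)
        for i in np.nonzero(inexact)[0]:
            r[i] = _pairwise_spearman(profiles[multi[i]][a], profiles[multi[i]][b])
        ok = np.isfinite(r)
        r_sum[ok] += r[ok]
        r_cnt[ok] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        score_by_probe = np.where(r_cnt > 0, r_sum / np.maximum(r_cnt, 1), -np.inf)

    chosen: dict[str, str] = {}
    for gene, pids in gene_probes.items():
        if len(pids) == 1:
            chosen[gene] = pids[0]
            continue
        best_pid, best_score = None, -np.inf
        for pid in sorted(pids):
            score = float(score_by_probe[pidx[pid]])
            if score > best_score:
                best_pid, best_score = pid, score
        chosen[gene] = best_pid if best_pid is not None else sorted(pids)[0]
    return chosen


def assign_samples(
    samples: SampleTable,
    parcellation: ParcellationVolume,
    max_expand_mm: float = 2.0,
) -> SampleTable:
    """Assign each sample to a parcel.

    (1) If the sample's containing voxel is labeled, take that label.
    (2) Otherwise consider every labeled voxel whose center lies within
    ``max_expand_mm`` (Euclidean, mm): a single candidate label wins
    outright; among multiple labels the one whose region centroid is
    nearest the sample wins (centroid-distance ties -> lowest region id).
    (3) Otherwise the sample stays unassigned.
    """
    if max_expand_mm < 0:
        raise ValueError("max_expand_mm must be nonnegative")
    labeled_vox = np.argwhere(parcellation.labels != 0)
    labeled_mm = parcellation.voxel_to_mm(labeled_vox)
    labeled_ids = parcellation.labels[tuple(labeled_vox.T)]

    out = []
    vox_idx = np.round(parcellation.mm_to_voxel(samples.coords_mm)).astype(int)
    shape = parcellation.labels.shape
    for i in range(samples.n_samples):
        ijk = vox_idx[i]
        if np.all((ijk >= 0) & (ijk < shape)):
            lab = int(parcellation.labels[tuple(ijk)])
            if lab != 0:
                out.append(str(lab))
                continue
        d = np.linalg.norm(labeled_mm - samples.coords_mm[i], axis=1)
        near = labeled_ids[d <= max_expand_mm]
        cands = np.unique(near)
        if len(cands) == 0:
            out.append(UNASSIGNED)
        elif len(cands) == 1:
            out.append(str(int(cands[0])))
        else:
            best = min(
                (int(c) for c in cands),
                key=lambda c: (
                    float(np.linalg.norm(parcellation.legend[c].centroid_mm - samples.coords_mm[i])),
                    c,
                ),
            )
            out.append(str(best))
    return SampleTable(
        donor_id=samples.donor_id,
        sample_ids=list(samples.sample_ids),
        coords_mm=samples.coords_mm.copy(),
        region_label=out,
    )


def aggregate_by_region(
    probes: ProbeTable,
    representative: dict[str, str],
    assignment: SampleTable,
    region_ids: list[str],
) -> RegionExpression:
    """Per-donor gene x region matrix: mean representative-probe expression
    over the donor's samples assigned to each region (NaN where empty)."""
    probe_index = {p: i for i, p in enumerate(probes.probe_ids)}
    genes = sorted(representative)
    rows = np.array([probe_index[representative[g]] for g in genes])
    expr = probes.expression[rows, :]
    labels = np.asarray(assignment.region_label)
    values = np.full((len(genes), len(region_ids)), np.nan)
    counts = np.zeros(len(region_ids), dtype=int)
    for j, rid in enumerate(region_ids):
        mask = labels == rid
        counts[j] = mask.sum()
        if counts[j]:
            values[:, j] = expr[:, mask].mean(axis=1)
    return RegionExpression(
        region_ids=list(region_ids),
        gene_ids=genes,
        values=values,
        donor_id=probes.donor_id,
        sample_counts=counts,
    )


def _zscore(x: np.ndarray, axis: int) -> np.ndarray:
    """NaN-aware z-score along ``axis``; zero-variance slices become zeros."""
    ok = np.isfinite(x)
    n = ok.sum(axis=axis, keepdims=True)
    filled = np.where(ok, x, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=axis, keepdims=True) / n
        var = (np.where(ok, (x - mean) ** 2, 0.0)).sum(axis=axis, keepdims=True) / n
        sd = np.sqrt(var)
        out = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return np.where(ok, out, np.nan)


def normalize_two_pass(expr: RegionExpression) -> RegionExpression:
    """Z-score each column (sample/region) over genes, then each gene row
    over columns. Missing entries are ignored and preserved."""
    v = expr.values
    defined_cols = np.sum(~np.all(np.isnan(v), axis=0))
    if expr.n_genes < 2 or defined_cols < 2:
        raise ValueError("need >= 2 genes and >= 2 non-missing columns")
    with np.errstate(invalid="ignore"):
        v = _zscore(v, axis=0)
        v = _zscore(v, axis=1)
    return RegionExpression(
        region_ids=list(expr.region_ids),
        gene_ids=list(expr.gene_ids),
        values=v,
        donor_id=expr.donor_id,
        sample_counts=None if expr.sample_counts is None else expr.sample_counts.copy(),
    )


def group_average(donor_matrices: list[RegionExpression]) -> RegionExpression:
    """Entry-wise missing-aware mean over donors; counts are summed."""
    if not donor_matrices:
        raise ValueError("empty donor list")
    ref = donor_matrices[0]
    for m in donor_matrices[1:]:
        if m.gene_ids != ref.gene_ids or m.region_ids != ref.region_ids:
            raise ValueError("donor matrices must share gene and region universes")
    stack = np.stack([m.values for m in donor_matrices])
    ok = np.isfinite(stack)
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ok, stack, 0.0).sum(axis=0) / n
    mean = np.where(n > 0, mean, np.nan)
    counts = None
    if all(m.sample_counts is not None for m in donor_matrices):
        counts = np.sum([m.sample_counts for m in donor_matrices], axis=0)
    return RegionExpression(
        region_ids=list(ref.region_ids),
        gene_ids=list(ref.gene_ids),
        values=mean,
        donor_id="group",
        sample_counts=counts,
    )
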