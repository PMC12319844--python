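"""High-level in-memory pipeline over a synthetic (or pre-loaded) cohort.

Convenience wrapper chaining simulation, preprocessing and gene selection;
the CLI performs the same steps through files so stages can be re-run
individually.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import gene_select, preprocess, synthetic
from .io_formats import ParcellationVolume, ProbeTable, RegionExpression, SampleTable


@dataclasses.dataclass
class CohortAnalysis:
    """Everything the downstream gradient/classification stages consume."""

    spec: synthetic.SimulationSpec
    parcellation: ParcellationVolume
    truth: dict
    probe_tables: list[ProbeTable]
    sample_tables: list[SampleTable]
    donor_matrices: list[RegionExpression]
    group: RegionExpression
    representative: dict[str, str]
    scores: gene_select.StabilityScores
    selected: set[str]

    @property
    def axis_order(self) -> list[str]:
        """Regions ordered anterior to posterior (descending centroid y)."""
        parc = self.parcellation
        return [
            str(r)
            for r in sorted(
                parc.region_ids, key=lambda r: -float(parc.legend[r].centroid_mm[1])
            )
        ]

    def selected_expression(self) -> RegionExpression:
        return self.group.subset_genes(sorted(self.selected))


def analyze_cohort(
    spec: synthetic.SimulationSpec,
    noise_level: float = 0.5,
    max_expand_mm: float = 2.0,
    percentile: float = 90.0,
) -> CohortAnalysis:
    """Simulate a cohort and run it through preprocessing + gene selection.

    The donor split for stability scoring is the first half of donors
    against the second half, by position.
    """
    parc = synthetic.make_parcellation(spec)
    region_ids = [str(r) for r in parc.region_ids]
    probe_tables, sample_tables = [], []
    for d in range(spec.n_donors):
        pt, st = synthetic.make_donor(spec, d)
        probe_tables.append(pt)
        sample_tables.append(preprocess.assign_samples(st, parc, max_expand_mm))

    retained = preprocess.intensity_filter(probe_tables, noise_level)
    means = {
        pt.donor_id: preprocess.probe_region_means(pt, st, region_ids, retained)
        for pt, st in zip(probe_tables, sample_tables)
    }
    representative = preprocess.select_representative_probe(probe_tables, means)

    donor_matrices = []
    for pt, st in zip(probe_tables, sample_tables):
        agg = preprocess.aggregate_by_region(pt, representative, st, region_ids)
        donor_matrices.append(preprocess.normalize_two_pass(agg))
    group = preprocess.group_average(donor_matrices)

    donors = [m.donor_id for m in donor_matrices]
    half = len(donors) // 2
    scores = gene_select.split_half_stability(
        donor_matrices, set(donors[:half]), set(donors[half:])
    )
    selected = gene_select.select_top_percentile(scores, percentile)
    return CohortAnalysis(
        spec=spec,
        parcellation=parc,
        truth=synthetic.truth_report(spec),
        probe_tables=probe_tables,
        sample_tables=sample_tables,
        donor_matrices=donor_matrices,
        group=group,
        representative=representative,
        scores=scores,
        selected=selected,
    )


def sample_feature_matrix(
    analysis: CohortAnalysis,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Pooled sample x selected-gene features plus region labels per sample.

    Each donor's representative-probe expression over the selected genes is
    two-pass normalized at the sample level before pooling; unassigned
    samples are dropped.
    """
    genes = sorted(analysis.selected)
    feats, regions, donors = [], [], []
    for pt, st in zip(analysis.probe_tables, analysis.sample_tables):
        rows = [pt.probe_ids.index(analysis.representative[g]) for g in genes]
        donor_mat = RegionExpression(
            region_ids=list(pt.sample_ids),
            gene_ids=genes,
            values=pt.expression[rows, :],
            donor_id=pt.donor_id,
        )
        norm = preprocess.normalize_two_pass(donor_mat).values.T
        for i, rid in enumerate(st.region_label):
            if rid == "unassigned":
                continue
            feats.append(norm[i])
            regions.append(rid)
            donors.append(pt.donor_id)
    return np.array(feats), regions, donors
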