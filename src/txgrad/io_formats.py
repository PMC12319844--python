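"""File formats and domain containers for the gradient-analysis pipeline.

All tabular files are tab-delimited UTF-8 with a header row. Coordinates are
millimetres in MNI-152 convention (RAS), and labeled volumes use the
voxel-center convention: the label at integer index ``i`` sits at
``affine @ (i, 1)``.

Floats are written with 17 significant digits so that write/read round-trips
are bit-exact for IEEE-754 doubles.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "UNANNOTATED",
    "UNASSIGNED",
    "DIVISIONS",
    "ProbeTable",
    "SampleTable",
    "RegionInfo",
    "ParcellationVolume",
    "RegionExpression",
    "read_probe_table",
    "write_probe_table",
    "read_sample_table",
    "write_sample_table",
    "read_parcellation",
    "write_parcellation",
    "read_region_expression",
    "write_region_expression",
    "run_cli",
]

#: Marker for probes without a gene annotation.
UNANNOTATED = "unannotated"
#: Marker for samples that could not be matched to any region.
UNASSIGNED = "unassigned"
#: Allowed values of the per-region division tag.
DIVISIONS = ("anterior", "posterior", "none")

_FLOAT_FMT = "%.17g"


@dataclasses.dataclass
class ProbeTable:
    """Per-donor probe-level expression with gene annotation and noise flags.

    Attributes
    ----------
    donor_id : str
        Donor identifier.
    probe_ids : list of str
        One id per expression row.
    gene_symbols : list of str
        Gene symbol per probe; :data:`UNANNOTATED` if no annotation exists.
    expression : ndarray, shape (n_probes, n_samples)
        Normalized expression values.
    above_noise : ndarray of bool, shape (n_probes, n_samples)
        True where the probe signal exceeded background noise.
    sample_ids : list of str
        Column labels, aligned with the paired :class:`SampleTable`.
    """

    donor_id: str
    probe_ids: list[str]
    gene_symbols: list[str]
    expression: np.ndarray
    above_noise: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.above_noise = np.asarray(self.above_noise, dtype=bool)
        if self.expression.shape != self.above_noise.shape:
            raise ValueError(
                "expression/above_noise shape mismatch: "
                f"{self.expression.shape} vs {self.above_noise.shape}"
            )
        if len(self.probe_ids) != self.expression.shape[0]:
            raise ValueError("probe_ids length does not match expression rows")
        if len(self.gene_symbols) != len(self.probe_ids):
            raise ValueError("gene_symbols length does not match probe_ids")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


@dataclasses.dataclass
class SampleTable:
    """Per-donor tissue samples with stereotaxic coordinates.

    ``region_label`` holds the assigned parcel id as a string, or
    :data:`UNASSIGNED`.
    """

    donor_id: str
    sample_ids: list[str]
    coords_mm: np.ndarray  # (n_samples, 3)
    region_label: list[str]

    def __post_init__(self) -> None:
        self.coords_mm = np.asarray(self.coords_mm, dtype=float)
        if self.coords_mm.shape != (len(self.sample_ids), 3):
            raise ValueError("coords_mm must have shape (n_samples, 3)")
        if not np.all(np.isfinite(self.coords_mm)):
            raise ValueError("coords_mm must be finite")
        if len(self.region_label) != len(self.sample_ids):
            raise ValueError("region_label length does not match sample_ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclasses.dataclass
class RegionInfo:
    """Legend entry: region name, division tag, and centroid in mm."""

    name: str
    division: str
    centroid_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.division not in DIVISIONS:
            raise ValueError(f"division must be one of {DIVISIONS}, got {self.division!r}")


@dataclasses.dataclass
class ParcellationVolume:
    """Integer-labeled 3-D volume with affine and region legend.

    Label 0 is background. Legend centroids are always recomputed from the
    volume (mean of labeled voxel centers mapped through the affine).
    """

    labels: np.ndarray
    affine: np.ndarray
    legend: dict[int, RegionInfo]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D volume")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        present = set(np.unique(self.labels).tolist()) - {0}
        orphans = sorted(present - set(self.legend))
        if orphans:
            raise ValueError(f"orphan labels: {orphans}")
        self.recompute_centroids()

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.legend)

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (n, 3) to mm coordinates of voxel centers."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map mm coordinates (n, 3) to continuous voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def recompute_centroids(self) -> None:
        for rid, info in self.legend.items():
            voxels = np.argwhere(self.labels == rid)
            if len(voxels) == 0:
                info.centroid_mm = None
                continue
            info.centroid_mm = self.voxel_to_mm(voxels).mean(axis=0)


@dataclasses.dataclass
class RegionExpression:
    """Region x gene expression matrix for one donor or the group average.

    ``values`` is gene x region; regions never sampled carry NaN, not zeros.
    """

    region_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    donor_id: str = "group"
    sample_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.region_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.region_ids)} regions)"
            )
        if self.sample_counts is not None:
            self.sample_counts = np.asarray(self.sample_counts, dtype=int)
            if self.sample_counts.shape != (len(self.region_ids),):
                raise ValueError("sample_counts must have one entry per region")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "RegionExpression":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return RegionExpression(
            region_ids=list(self.region_ids),
            gene_ids=list(gene_ids),
            values=self.values[idx, :],
            donor_id=self.donor_id,
            sample_counts=None if self.sample_counts is None else self.sample_counts.copy(),
        )

    def drop_missing_regions(self) -> tuple["RegionExpression", list[str]]:
        """Drop regions where every gene is NaN; return (subset, dropped ids)."""
        keep = ~np.all(np.isnan(self.values), axis=0)
        dropped = [r for r, k in zip(self.region_ids, keep) if not k]
        return (
            RegionExpression(
                region_ids=[r for r, k in zip(self.region_ids, keep) if k],
                gene_ids=list(self.gene_ids),
                values=self.values[:, keep],
                donor_id=self.donor_id,
                sample_counts=None if self.sample_counts is None else self.sample_counts[keep],
            ),
            dropped,
        )


# ---------------------------------------------------------------------------
# probe tables
# ---------------------------------------------------------------------------

def read_probe_table(
    path: str | Path,
    annotation_path: str | Path,
    noise_path: str | Path | None = None,
    donor_id: str | None = None,
) -> ProbeTable:
    """Read a probe x sample expression TSV plus its probe->gene annotation.

    Probes missing from the annotation are flagged :data:`UNANNOTATED`, not
    dropped. If ``noise_path`` is None all entries are treated as above noise.
    """
    path = Path(path)
    expr = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    probe_ids = [str(p) for p in expr.index]
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    if ann.shape[1] < 2:
        raise ValueError("annotation file needs probe and gene columns")
    mapping = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
    gene_symbols = [mapping.get(p, UNANNOTATED) for p in probe_ids]

    if noise_path is not None:
        noise = pd.read_csv(noise_path, sep="\t", index_col=0)
        if noise.shape != expr.shape:
            raise ValueError(
                f"expression/noise shape mismatch: {expr.shape} vs {noise.shape}"
            )
        above = noise.to_numpy().astype(bool)
    else:
        above = np.ones(expr.shape, dtype=bool)

    return ProbeTable(
        donor_id=donor_id if donor_id is not None else path.stem,
        probe_ids=probe_ids,
        gene_symbols=gene_symbols,
        expression=expr.to_numpy(dtype=float),
        above_noise=above,
        sample_ids=[str(c) for c in expr.columns],
    )


def write_probe_table(
    table: ProbeTable,
    path: str | Path,
    annotation_path: str | Path,
    noise_path: str | Path,
) -> None:
    """Write expression, annotation and noise-flag TSVs for one donor."""
    expr = pd.DataFrame(table.expression, index=table.probe_ids, columns=table.sample_ids)
    expr.index.name = "probe_id"
    expr.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    ann = pd.DataFrame({"probe_id": table.probe_ids, "gene_symbol": table.gene_symbols})
    ann.to_csv(annotation_path, sep="\t", index=False)
    noise = pd.DataFrame(
        table.above_noise.astype(int), index=table.probe_ids, columns=table.sample_ids
    )
    noise.index.name = "probe_id"
    noise.to_csv(noise_path, sep="\t")


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "donor_id": str, "region_label": str},
        float_precision="round_trip",
    )
    donor = str(df["donor_id"].iloc[0]) if len(df) else "unknown"
    return SampleTable(
        donor_id=donor,
        sample_ids=[str(s) for s in df["sample_id"]],
        coords_mm=df[["x", "y", "z"]].to_numpy(dtype=float),
        region_label=[str(r) for r in df["region_label"]],
    )


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "donor_id": table.donor_id,
            "x": table.coords_mm[:, 0],
            "y": table.coords_mm[:, 1],
            "z": table.coords_mm[:, 2],
            "region_label": table.region_label,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# parcellations
# ---------------------------------------------------------------------------

def read_parcellation(volume_path: str | Path, legend_path: str | Path) -> ParcellationVolume:
    """Load a labeled NIfTI volume and its TSV legend.

    Centroids are recomputed from the volume under the voxel-center
    convention; any centroid columns in the legend file are ignored. Raises
    if the volume holds non-integer data or contains labels absent from the
    legend.
    """
    img = nib.load(str(volume_path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError("parcellation volume must contain integer labels")
        data = np.round(data).astype(np.int32)
    legend_df = pd.read_csv(legend_path, sep="\t", dtype={"name": str, "division": str})
    legend: dict[int, RegionInfo] = {}
    for _, row in legend_df.iterrows():
        division = str(row["division"]) if "division" in legend_df.columns else "none"
        legend[int(row["region_id"])] = RegionInfo(name=str(row["name"]), division=division)
    return ParcellationVolume(labels=data, affine=img.affine, legend=legend)


def write_parcellation(parc: ParcellationVolume, volume_path: str | Path, legend_path: str | Path) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int32), parc.affine)
    nib.save(img, str(volume_path))
    rows = []
    for rid in parc.region_ids:
        info = parc.legend[rid]
        c = info.centroid_mm
        rows.append(
            {
                "region_id": rid,
                "name": info.name,
                "division": info.division,
                "centroid_x": np.nan if c is None else c[0],
                "centroid_y": np.nan if c is None else c[1],
                "centroid_z": np.nan if c is None else c[2],
            }
        )
    pd.DataFrame(rows).to_csv(legend_path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# region expression matrices
# ---------------------------------------------------------------------------

def write_region_expression(matrix: RegionExpression, path: str | Path) -> None:
    """Write a gene x region matrix as TSV, regions in stored order.

    Emits ``#donor_id`` and ``#sample_counts`` comment lines so a read-back
    restores the full container. Values round-trip bit-exactly.
    """
    if matrix.n_genes == 0 or matrix.n_regions == 0:
        raise ValueError("refusing to write an empty RegionExpression")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#donor_id\t{matrix.donor_id}\n")
        if matrix.sample_counts is not None:
            counts = "\t".join(str(int(c)) for c in matrix.sample_counts)
            fh.write(f"#sample_counts\t{counts}\n")
        fh.write("gene_id\t" + "\t".join(str(r) for r in matrix.region_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            vals = "\t".join(_FLOAT_FMT % v for v in row)
            fh.write(f"{gene}\t{vals}\n")


def read_region_expression(path: str | Path) -> RegionExpression:
    donor_id = "group"
    sample_counts = None
    header_lines = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, rest = line[1:].rstrip("\n").partition("\t")
            if key == "donor_id":
                donor_id = rest
            elif key == "sample_counts":
                sample_counts = np.array([int(x) for x in rest.split("\t")])
    df = pd.read_csv(
        path, sep="\t", index_col=0, skiprows=header_lines, float_precision="round_trip"
    )
    return RegionExpression(
        region_ids=[str(c) for c in df.columns],
        gene_ids=[str(g) for g in df.index],
        values=df.to_numpy(dtype=float),
        donor_id=donor_id,
        sample_counts=sample_counts,
    )


def run_cli(args: Sequence[str]) -> int:
    """Run the command-line interface; returns the process exit status."""
    import click

    from .cli import main

    try:
        main(list(args), standalone_mode=False)
    except SystemExit as exc:
        return int(exc.code or 0)
    except click.ClickException as exc:
        exc.show()
        return exc.exit_code or 1
    except (KeyError, ValueError, FileNotFoundError) as exc:
        import sys

        print(f"error: {exc}", file=sys.stderr)
        return 1
    return 0
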