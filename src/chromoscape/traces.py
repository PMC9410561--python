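"""Ingestion of single-cell chromatin trace tables and conversion to
distance / contact matrix ensembles.

Chromatin tracing reports, per cell (or chromosome copy), one 3D coordinate
for each consecutive genomic bin of a traced region.  This module reads such
tables, applies the standard quality filter (keep structures with more than a
given fraction of measured bins), fills the remaining missing bins by
nearest-neighbour interpolation along the genomic axis, and converts each
structure into a rotation/translation-invariant pairwise Euclidean distance
matrix.  Distances can further be thresholded into binary contact matrices
with a resolution-specific cutoff (e.g. 500 nm at 50 kb).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import TraceFormatError, ValidationError

__all__ = [
    "TraceEnsemble",
    "DistanceEnsemble",
    "ContactEnsemble",
    "StructureSummary",
    "TraceDialect",
    "read_traces",
    "write_traces",
    "filter_structures",
    "impute_missing",
    "compute_distance_matrices",
    "to_contact_matrices",
    "radius_of_gyration",
    "summarize_structures",
    "save_distance_ensemble",
    "load_distance_ensemble",
    "save_contact_ensemble",
    "load_contact_ensemble",
    "write_contact_triplets",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TraceEnsemble:
    """N single-cell structures of m genomic bins with 3D coordinates in nm.

    ``mask[a, i]`` is True where bin ``i`` of structure ``a`` was measured;
    coordinates under a False mask are undefined (stored as NaN).
    """

    coords: np.ndarray          # (N, m, 3) float, nm
    mask: np.ndarray            # (N, m) bool
    bin_starts: np.ndarray      # (m,) genomic start coordinates, bp
    resolution: int             # bin size, bp
    region_label: str = ""
    condition_label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.bin_starts = np.asarray(self.bin_starts)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (N, m, 3)")
        n, m = self.coords.shape[:2]
        # N = 0 is legal (the QC filter may empty an ensemble)
        if m < 2:
            raise ValidationError("need m >= 2 bins")
        if self.mask.shape != (n, m):
            raise ValidationError("mask shape must match coords")
        if len(self.bin_starts) != m:
            raise ValidationError("bin_starts length must equal m")
        if not np.isfinite(self.coords[self.mask]).all():
            raise ValidationError("coordinates must be finite where measured")

    @property
    def n_structures(self) -> int:
        return self.coords.shape[0]

    @property
    def n_bins(self) -> int:
        return self.coords.shape[1]

    @property
    def n_measured(self) -> np.ndarray:
        """Measured-bin count per structure."""
        return self.mask.sum(axis=1)

    def is_complete(self) -> bool:
        return bool(self.mask.all())


@dataclass
class DistanceEnsemble:
    """N symmetric m x m pairwise Euclidean distance matrices (nm)."""

    matrices: np.ndarray        # (N, m, m) float, nm
    bin_starts: np.ndarray
    resolution: int
    region_label: str = ""
    condition_label: str = ""

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.bin_starts = np.asarray(self.bin_starts)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValidationError("matrices must have shape (N, m, m)")
        if not np.isfinite(self.matrices).all():
            raise ValidationError("distance matrices must be finite")
        if (self.matrices < 0).any():
            raise ValidationError("distances must be non-negative")

    @property
    def n_structures(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrices.shape[1]

    def mean_map(self) -> np.ndarray:
        """Population-averaged distance map."""
        return self.matrices.mean(axis=0)

    def radii_of_gyration(self) -> np.ndarray:
        """R_g per structure from the distance matrix.

        Uses the identity Rg^2 = (1 / 2 m^2) * sum_ij d_ij^2, which needs no
        coordinates and is therefore available downstream of any rigid-motion
        removal.
        """
        m = self.n_bins
        return np.sqrt((self.matrices ** 2).sum(axis=(1, 2)) / (2.0 * m * m))


@dataclass
class ContactEnsemble:
    """Binary contact matrices obtained by distance thresholding."""

    matrices: np.ndarray        # (N, m, m) uint8
    cutoff: float               # nm
    bin_starts: np.ndarray = field(default_factory=lambda: np.array([]))
    resolution: int = 0

    @property
    def n_structures(self) -> int:
        return self.matrices.shape[0]


@dataclass
class StructureSummary:
    """Per-structure radius of gyration and measured-bin count."""

    rg: np.ndarray
    n_measured: np.ndarray


# ---------------------------------------------------------------------------
# reading / writing trace tables
# ---------------------------------------------------------------------------

@dataclass
class TraceDialect:
    """Column mapping for a delimited trace table.

    Either ``bin_index`` or ``genomic_start`` must name a column.  When only
    ``bin_index`` is present, genomic starts are synthesised as
    ``index * resolution``.  ``unit_multiplier`` converts the stored
    coordinate unit to nm (1000 for tables in um).
    """

    copy_id: str = "copy"
    bin_index: Optional[str] = "bin"
    genomic_start: Optional[str] = None
    x: str = "x"
    y: str = "y"
    z: str = "z"
    region: Optional[str] = None
    unit_multiplier: float = 1.0
    delimiter: Optional[str] = None
    resolution: int = 30_000

    @classmethod
    def from_mapping(cls, mapping: dict) -> "TraceDialect":
        return cls(**mapping)


def read_traces(
    path: Union[str, Path],
    dialect: Optional[Union[TraceDialect, dict]] = None,
    region_label: str = "",
    condition_label: str = "",
) -> TraceEnsemble:
    """Read a delimited (optionally gzipped) trace table into a TraceEnsemble.

    Rows absent for a (copy, bin) combination, and rows with non-finite
    coordinates, yield masked bins.  Copies are ordered by first appearance in
    the file; bins by genomic coordinate.
    """
    if dialect is None:
        dialect = TraceDialect()
    elif isinstance(dialect, dict):
        dialect = TraceDialect.from_mapping(dialect)

    sep = dialect.delimiter
    df = pd.read_csv(path, sep=sep if sep is not None else None, engine="python")

    bin_col = dialect.genomic_start or dialect.bin_index
    if bin_col is None:
        raise TraceFormatError("dialect must name a bin_index or genomic_start column")
    needed = [dialect.copy_id, bin_col, dialect.x, dialect.y, dialect.z]
    for col in needed:
        if col not in df.columns:
            raise TraceFormatError(f"mandatory column {col!r} missing from trace table")

    if dialect.region is not None and dialect.region in df.columns:
        regions = df[dialect.region].unique()
        if region_label:
            df = df[df[dialect.region] == region_label]
            if df.empty:
                raise ValidationError(f"no rows for region {region_label!r}")
        elif len(regions) > 1:
            raise ValidationError(
                f"table interleaves regions {list(regions)}; pass region_label to select one"
            )
        elif len(regions) == 1:
            region_label = str(regions[0])

    if dialect.genomic_start is not None:
        starts = np.sort(df[bin_col].unique()).astype(np.int64)
        diffs = np.diff(starts)
        resolution = int(np.median(diffs)) if len(diffs) else dialect.resolution
    else:
        idx = df[bin_col].astype(int)
        resolution = dialect.resolution
        starts = np.arange(idx.max() + 1, dtype=np.int64) * resolution
        df = df.assign(**{bin_col: idx * resolution})
        # fall through: treat synthesized starts as genomic coordinates
    start_to_col = {s: i for i, s in enumerate(starts)}
    m = len(starts)

    copies = list(dict.fromkeys(df[dialect.copy_id]))  # first-appearance order
    copy_to_row = {c: i for i, c in enumerate(copies)}
    n = len(copies)

    coords = np.full((n, m, 3), np.nan)
    mask = np.zeros((n, m), dtype=bool)
    seen = set()
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        a = copy_to_row[rec[dialect.copy_id]]
        s = rec[bin_col]
        if s not in start_to_col:
            raise ValidationError(f"bin start {s} not on the common genomic grid")
        i = start_to_col[s]
        if (a, i) in seen:
            raise ValidationError(f"duplicate record for copy {rec[dialect.copy_id]!r} bin {i}")
        seen.add((a, i))
        xyz = np.array([rec[dialect.x], rec[dialect.y], rec[dialect.z]], dtype=float)
        xyz = xyz * dialect.unit_multiplier
        if np.isfinite(xyz).all():
            coords[a, i] = xyz
            mask[a, i] = True

    return TraceEnsemble(
        coords=coords,
        mask=mask,
        bin_starts=starts,
        resolution=resolution,
        region_label=region_label,
        condition_label=condition_label,
    )


def write_traces(ens: TraceEnsemble, path: Union[str, Path],
                 dialect: Optional[TraceDialect] = None) -> None:
    """Write an ensemble back to the delimited dialect `read_traces` accepts.

    Masked bins are simply omitted, matching how published tracing tables
    represent missing localisations.
    """
    if dialect is None:
        dialect = TraceDialect(genomic_start="genomic_start")
    bin_col = dialect.genomic_start or dialect.bin_index
    rows = []
    for a in range(ens.n_structures):
        for i in range(ens.n_bins):
            if not ens.mask[a, i]:
                continue
            key = ens.bin_starts[i] if dialect.genomic_start else i
            rows.append(
                {dialect.copy_id: a, bin_col: key,
                 dialect.x: ens.coords[a, i, 0] / dialect.unit_multiplier,
                 dialect.y: ens.coords[a, i, 1] / dialect.unit_multiplier,
                 dialect.z: ens.coords[a, i, 2] / dialect.unit_multiplier}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QC, imputation, distances
# ---------------------------------------------------------------------------

def filter_structures(ens: TraceEnsemble, min_fraction: float = 0.9) -> TraceEnsemble:
    """Keep structures with strictly more than ``min_fraction`` measured bins.

    The inequality is strict, so ``min_fraction=1.0`` retains nothing (a fully
    measured structure has exactly, not more than, 100% of its bins).
    """
    if not 0 < min_fraction <= 1:
        raise ValidationError("min_fraction must lie in (0, 1]")
    frac = ens.n_measured / ens.n_bins
    keep = frac > min_fraction
    if not keep.any():
        warnings.warn("quality filter removed every structure", UserWarning)
    return replace(ens, coords=ens.coords[keep], mask=ens.mask[keep])


def impute_missing(ens: TraceEnsemble) -> TraceEnsemble:
    """Fill missing bins with the nearest measured bin along the genome.

    Distance is genomic (|bin_start difference|); an exact tie between a
    left and right neighbour resolves to the lower genomic index.  Missing
    bins at either chain end take the one-sided nearest measured bin.
    """
    if (ens.n_measured == 0).any():
        bad = int(np.where(ens.n_measured == 0)[0][0])
        raise ValidationError(f"structure {bad} has no measured bins; cannot impute")
    coords = ens.coords.copy()
    starts = ens.bin_starts.astype(float)
    for a in range(ens.n_structures):
        row_mask = ens.mask[a]
        if row_mask.all():
            continue
        measured = np.where(row_mask)[0]
        for i in np.where(~row_mask)[0]:
            d = np.abs(starts[measured] - starts[i])
            j = measured[np.argmin(d)]  # argmin takes the first (lower index) on ties
            coords[a, i] = coords[a, j]
    return replace(ens, coords=coords, mask=np.ones_like(ens.mask))


def compute_distance_matrices(ens: TraceEnsemble) -> DistanceEnsemble:
    """Pairwise Euclidean distances between all bins of each structure."""
    if not ens.is_complete():
        raise ValidationError("ensemble has missing bins; run impute_missing first")
    if not np.isfinite(ens.coords).all():
        raise ValidationError("non-finite coordinate encountered")
    mats = np.stack([squareform(pdist(ens.coords[a])) for a in range(ens.n_structures)])
    return DistanceEnsemble(
        matrices=mats,
        bin_starts=ens.bin_starts,
        resolution=ens.resolution,
        region_label=ens.region_label,
        condition_label=ens.condition_label,
    )


def to_contact_matrices(dens: DistanceEnsemble, cutoff: float) -> ContactEnsemble:
    """Threshold distances into binary contacts (d <= cutoff; diagonal 1)."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    mats = (dens.matrices <= cutoff).astype(np.uint8)
    idx = np.arange(dens.n_bins)
    mats[:, idx, idx] = 1
    return ContactEnsemble(matrices=mats, cutoff=float(cutoff),
                           bin_starts=dens.bin_starts, resolution=dens.resolution)


def radius_of_gyration(structure: np.ndarray) -> float:
    """Root-mean-square distance of the points from their centroid (nm)."""
    pts = np.asarray(structure, dtype=float)
    centroid = pts.mean(axis=0)
    return float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))


def summarize_structures(ens: TraceEnsemble) -> StructureSummary:
    """R_g (over measured bins only) and measured-bin count per structure."""
    rg = np.array([
        radius_of_gyration(ens.coords[a][ens.mask[a]]) if ens.mask[a].any() else np.nan
        for a in range(ens.n_structures)
    ])
    return StructureSummary(rg=rg, n_measured=ens.n_measured)


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def save_distance_ensemble(dens: DistanceEnsemble, path: Union[str, Path]) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("matrices", data=dens.matrices, compression="gzip")
        f.create_dataset("bin_starts", data=np.asarray(dens.bin_starts))
        f.attrs["resolution"] = dens.resolution
        f.attrs["region_label"] = dens.region_label
        f.attrs["condition_label"] = dens.condition_label


def load_distance_ensemble(path: Union[str, Path]) -> DistanceEnsemble:
    with h5py.File(path, "r") as f:
        return DistanceEnsemble(
            matrices=f["matrices"][...],
            bin_starts=f["bin_starts"][...],
            resolution=int(f.attrs["resolution"]),
            region_label=str(f.attrs.get("region_label", "")),
            condition_label=str(f.attrs.get("condition_label", "")),
        )


def save_contact_ensemble(cens: ContactEnsemble, path: Union[str, Path]) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("matrices", data=cens.matrices, compression="gzip")
        f.create_dataset("bin_starts", data=np.asarray(cens.bin_starts))
        f.attrs["cutoff"] = cens.cutoff
        f.attrs["resolution"] = cens.resolution


def load_contact_ensemble(path: Union[str, Path]) -> ContactEnsemble:
    with h5py.File(path, "r") as f:
        return ContactEnsemble(
            matrices=f["matrices"][...],
            cutoff=float(f.attrs["cutoff"]),
            bin_starts=f["bin_starts"][...],
            resolution=int(f.attrs["resolution"]),
        )


def write_contact_triplets(cens: ContactEnsemble, out_dir: Union[str, Path],
                           prefix: str = "structure") -> Sequence[Path]:
    """Write each contact matrix as sparse (bin_i, bin_j, 1) triplets.

    One whitespace-delimited text file per structure, upper triangle
    including the diagonal, as consumed by contact-based boundary callers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for a in range(cens.n_structures):
        mat = cens.matrices[a]
        ii, jj = np.nonzero(np.triu(mat))
        path = out_dir / f"{prefix}_{a:04d}.txt"
        np.savetxt(path, np.column_stack([ii, jj, np.ones_like(ii)]), fmt="%d")
        paths.append(path)
    return paths
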