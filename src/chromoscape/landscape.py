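"""Chromosome structural landscapes.

Every single-cell distance matrix is centred by subtracting the elementwise
median matrix of the ensemble, h^a = d^a - median(d); the pairwise dot
product s_ab = sum_ij h^a_ij h^b_ij over all matrix elements compares how two
cells deviate from the population median; PCA on the resulting N x N
comparison matrix projects the cells into a low-dimensional "structural
landscape" in which the first component tracks overall compaction (radius of
gyration) and the second tracks domain reorganisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .exceptions import DegenerateLandscapeWarning, ValidationError
from .traces import DistanceEnsemble

__all__ = [
    "CenteredEnsemble",
    "ComparisonMatrix",
    "median_center",
    "comparison_matrix",
    "StructuralLandscape",
    "LandscapeResult",
    "pca_landscape",
    "joint_landscape",
    "partition_by_pc",
    "group_average_maps",
    "pc_regime_proportions",
]


@dataclass
class CenteredEnsemble:
    """Median-centred distance matrices h^a = d^a - elementwise median."""

    centered: np.ndarray        # (N, m, m)
    median_matrix: np.ndarray   # (m, m)
    conditions: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))


@dataclass
class ComparisonMatrix:
    """Gram-like pairwise structure comparison matrix s_ab."""

    s: np.ndarray               # (N, N), symmetric PSD
    conditions: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    @property
    def n_structures(self) -> int:
        return self.s.shape[0]


def median_center(dens: DistanceEnsemble,
                  conditions: Optional[Sequence] = None) -> CenteredEnsemble:
    """Subtract the elementwise median matrix from every structure.

    The even-N median is the midpoint of the two central order statistics, so
    the elementwise median of the centred stack is zero (exactly for odd N).
    """
    if dens.n_structures < 2:
        raise ValidationError("median centering needs at least 2 structures")
    med = np.median(dens.matrices, axis=0)
    cond = _as_conditions(conditions, dens)
    return CenteredEnsemble(centered=dens.matrices - med, median_matrix=med,
                            conditions=cond)


def comparison_matrix(cens: CenteredEnsemble) -> ComparisonMatrix:
    """s_ab = sum_ij h^a_ij h^b_ij, the unrestricted double sum.

    Both triangles contribute (the diagonal adds zero since h_ii = 0), so s is
    the Gram matrix of the flattened centred matrices: symmetric and positive
    semidefinite, with s_aa the squared Frobenius norm of h^a.
    """
    n = cens.centered.shape[0]
    flat = cens.centered.reshape(n, -1)
    s = flat @ flat.T
    s = 0.5 * (s + s.T)  # enforce exact symmetry against rounding
    return ComparisonMatrix(s=s, conditions=cens.conditions)


def _as_conditions(conditions, dens: DistanceEnsemble) -> np.ndarray:
    if conditions is not None:
        return np.asarray(list(conditions), dtype=object)
    label = dens.condition_label or ""
    return np.asarray([label] * dens.n_structures, dtype=object)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class StructuralLandscape:
    """PCA landscape model over one or more distance ensembles.

    Parameters
    ----------
    ensembles
        A single DistanceEnsemble, or a list of them sharing the same bin
        grid.  A list is pooled: one pooled median matrix, one pooled
        comparison matrix, one PCA, with each structure keeping the condition
        label of the ensemble it came from.
    n_components
        Number of principal components to retain (must be <= N - 1).

    Examples
    --------
    >>> model = StructuralLandscape(dens, n_components=2)
    >>> res = model.fit()
    >>> res.pc_scores.shape
    (N, 2)
    """

    def __init__(self,
                 ensembles: Union[DistanceEnsemble, Sequence[DistanceEnsemble]],
                 n_components: int = 2):
        if isinstance(ensembles, DistanceEnsemble):
            ensembles = [ensembles]
        ensembles = list(ensembles)
        if not ensembles:
            raise ValidationError("at least one ensemble required")
        grid = ensembles[0].bin_starts
        for e in ensembles[1:]:
            if e.n_bins != ensembles[0].n_bins or not np.array_equal(e.bin_starts, grid):
                raise ValidationError("ensembles have mismatched bin grids")
        self.ensembles = ensembles
        self.n_components = int(n_components)

        mats = np.concatenate([e.matrices for e in ensembles], axis=0)
        conds = np.concatenate([
            np.asarray([e.condition_label or str(k)] * e.n_structures, dtype=object)
            for k, e in enumerate(ensembles)
        ])
        self.pooled = DistanceEnsemble(
            matrices=mats, bin_starts=grid, resolution=ensembles[0].resolution,
            region_label=ensembles[0].region_label,
        )
        self.conditions = conds

    def fit(self) -> "LandscapeResult":
        n = self.pooled.n_structures
        if self.n_components > n - 1:
            raise ValidationError("n_components must be <= N - 1")
        cens = median_center(self.pooled, conditions=self.conditions)
        cm = comparison_matrix(cens)
        rg = self.pooled.radii_of_gyration()

        col_var = cm.s.var(axis=0)
        if np.allclose(col_var, 0.0, atol=1e-12 * max(1.0, abs(cm.s).max() ** 2)):
            warnings.warn("comparison matrix carries no variance; landscape is degenerate",
                          DegenerateLandscapeWarning)
            scores = np.zeros((n, self.n_components))
            evr = np.zeros(self.n_components)
        else:
            pca = PCA(n_components=self.n_components, svd_solver="full")
            scores = pca.fit_transform(cm.s)  # rows of s as observations, column-centred
            evr = pca.explained_variance_ratio_
            scores = _fix_signs(scores, rg)
        return LandscapeResult(
            pc_scores=scores,
            explained_variance_fraction=evr,
            conditions=self.conditions,
            rg=rg,
            comparison=cm,
            dens=self.pooled,
        )


def _fix_signs(scores: np.ndarray, rg: Optional[np.ndarray]) -> np.ndarray:
    """Deterministic sign convention: PC1 correlates positively with R_g,
    PC2 (and higher PCs) have non-negative skewness."""
    scores = scores.copy()
    if rg is not None and scores.shape[1] >= 1 and np.std(scores[:, 0]) > 0:
        r = np.corrcoef(scores[:, 0], rg)[0, 1]
        if np.isfinite(r) and r < 0:
            scores[:, 0] *= -1
    for k in range(1, scores.shape[1]):
        if np.std(scores[:, k]) > 0 and stats.skew(scores[:, k]) < 0:
            scores[:, k] *= -1
    return scores


@dataclass
class LandscapeResult:
    """Fitted structural landscape.

    ``pc_scores[a, k]`` is structure a's projection on PC k+1 after the sign
    convention (PC1 up with R_g, PC2 skew non-negative).
    """

    pc_scores: np.ndarray                  # (N, K)
    explained_variance_fraction: np.ndarray
    conditions: np.ndarray
    rg: np.ndarray
    comparison: ComparisonMatrix
    dens: DistanceEnsemble

    @property
    def n_structures(self) -> int:
        return self.pc_scores.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.pc_scores,
            columns=[f"PC{k + 1}" for k in range(self.pc_scores.shape[1])],
        )
        df.insert(0, "structure_id", np.arange(self.n_structures))
        df.insert(1, "condition", self.conditions)
        df["Rg"] = self.rg
        return df

    def summary(self) -> str:
        lines = [
            "Chromosome structural landscape",
            "=" * 33,
            f"structures: {self.n_structures}   components: {self.pc_scores.shape[1]}",
            "explained variance fraction: "
            + ", ".join(f"PC{k + 1}={v:.3f}"
                        for k, v in enumerate(self.explained_variance_fraction)),
        ]
        if np.std(self.pc_scores[:, 0]) > 0:
            r = np.corrcoef(self.pc_scores[:, 0], self.rg)[0, 1]
            lines.append(f"corr(PC1, Rg): {r:+.3f}")
        for c in pd.unique(self.conditions):
            lines.append(f"condition {c!r}: n={int((self.conditions == c).sum())}")
        return "\n".join(lines)

    # -- downstream groupings -------------------------------------------------

    def partition_by_pc(self, pc: int = 1, n_groups: int = 5) -> np.ndarray:
        return partition_by_pc(self, pc=pc, n_groups=n_groups)

    def group_average_maps(self, assignment: np.ndarray) -> dict:
        return group_average_maps(self.dens, assignment)

    def regime_proportions(self, n_bins: int = 10) -> pd.DataFrame:
        return pc_regime_proportions(self, n_bins=n_bins)

    def plot(self, ax=None, color_by: str = "rg"):
        """Scatter the landscape in the PC1-PC2 plane."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if color_by == "rg":
            sc = ax.scatter(self.pc_scores[:, 0], self.pc_scores[:, 1],
                            c=self.rg, cmap="coolwarm", s=12)
            plt.colorbar(sc, ax=ax, label="Rg (nm)")
        else:
            for c in pd.unique(self.conditions):
                sel = self.conditions == c
                ax.scatter(self.pc_scores[sel, 0], self.pc_scores[sel, 1],
                           s=12, label=str(c))
            ax.legend()
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        return ax


def pca_landscape(cm: ComparisonMatrix, n_components: int = 2,
                  rg: Optional[np.ndarray] = None) -> LandscapeResult:
    """Functional PCA entry point on a precomputed comparison matrix.

    Rows of s are treated as observations with column-mean centering.  The
    result carries no distance ensemble, so group-average maps are
    unavailable from it; prefer :class:`StructuralLandscape` when the
    ensemble is at hand.
    """
    n = cm.n_structures
    if n_components > n - 1:
        raise ValidationError("n_components must be <= N - 1")
    col_var = cm.s.var(axis=0)
    if np.allclose(col_var, 0.0, atol=1e-12 * max(1.0, abs(cm.s).max() ** 2)):
        warnings.warn("comparison matrix carries no variance; landscape is degenerate",
                      DegenerateLandscapeWarning)
        scores = np.zeros((n, n_components))
        evr = np.zeros(n_components)
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        scores = pca.fit_transform(cm.s)
        evr = pca.explained_variance_ratio_
        scores = _fix_signs(scores, rg)
    conds = cm.conditions if len(cm.conditions) == n else \
        np.asarray([""] * n, dtype=object)
    return LandscapeResult(pc_scores=scores, explained_variance_fraction=evr,
                           conditions=conds, rg=rg if rg is not None else np.full(n, np.nan),
                           comparison=cm, dens=None)


def joint_landscape(ensembles: List[DistanceEnsemble],
                    n_components: int = 2) -> LandscapeResult:
    """Pool several conditions into one landscape (single pooled median)."""
    return StructuralLandscape(ensembles, n_components=n_components).fit()


# ---------------------------------------------------------------------------
# groupings along the PCs
# ---------------------------------------------------------------------------

def partition_by_pc(ls: LandscapeResult, pc: int = 1, n_groups: int = 5) -> np.ndarray:
    """Contiguous rank groups along a PC (1-based index).

    Structures are sorted by the chosen PC score (ties broken by structure
    index) and split into near-equal contiguous groups; when N is not
    divisible the earliest groups take the remainder.
    """
    n = ls.n_structures
    if not 1 <= n_groups <= n:
        raise ValidationError("n_groups must lie in [1, N]")
    scores = ls.pc_scores[:, pc - 1]
    order = np.lexsort((np.arange(n), scores))  # stable: index breaks ties
    base, rem = divmod(n, n_groups)
    sizes = [base + 1 if g < rem else base for g in range(n_groups)]
    assignment = np.empty(n, dtype=int)
    pos = 0
    for g, size in enumerate(sizes):
        assignment[order[pos:pos + size]] = g
        pos += size
    return assignment


def group_average_maps(dens: DistanceEnsemble, assignment: np.ndarray) -> dict:
    """Elementwise mean distance map per group; empty groups are omitted."""
    assignment = np.asarray(assignment)
    if len(assignment) != dens.n_structures:
        raise ValidationError("assignment length must equal N")
    maps = {}
    for g in range(int(assignment.max()) + 1):
        sel = assignment == g
        if not sel.any():
            warnings.warn(f"group {g} is empty; map omitted", UserWarning)
            continue
        maps[g] = dens.matrices[sel].mean(axis=0)
    return maps


def pc_regime_proportions(ls: LandscapeResult, n_bins: int = 10,
                          pc: int = 1) -> pd.DataFrame:
    """Condition proportions within equal-width regimes along a PC.

    The PC range [min, max] is split into ``n_bins`` equal-width intervals,
    each half-open on the right except the last (right-closed so the maximum
    falls in the final regime).  Empty regimes report NaN for every
    condition; occupied regimes' proportions sum to 1.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    labels = pd.unique(ls.conditions)
    if len(labels) < 1:
        raise ValidationError("landscape carries no condition labels")
    x = ls.pc_scores[:, pc - 1]
    lo, hi = x.min(), x.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    # right-open intervals except the last
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        total = sel.sum()
        row = {"regime": b, "lo": edges[b], "hi": edges[b + 1], "n": int(total)}
        for lab in labels:
            row[str(lab)] = (ls.conditions[sel] == lab).sum() / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
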