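"""Ensemble Structure Similarity Index (SSI).

A weighted network is built over single-cell structures: edge weights are
rescaled Pearson correlations w_ij = (1 + c_ij) / 2 between rows of the
pairwise structure comparison matrix, thresholded at a percentile (50th by
default) of all edge weights.  Each node's SSI is the Shannon-Jayne network
entropy of its edge-weight proportions,

    S_i = -(1 / log k_i) * sum_{j in N(i)} p_ij log p_ij,
    p_ij = w_ij / sum_{k in N(i)} w_ik,

bounded in [0, 1] and equal to 1 exactly when all incident weights are
equal.  The median S_i over nodes (the "ensemble SSI") measures how
continuous the conformational ensemble is: smooth one-parameter families
score high, ensembles split into discrete clusters score low.  Because
observed values compress near 1, reports also carry the affine transform
1000 * (S - 0.99).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import EmptyNetworkError, ValidationError
from .landscape import comparison_matrix, median_center, ComparisonMatrix
from .traces import DistanceEnsemble

__all__ = [
    "SimilarityNetwork",
    "SSIResult",
    "row_correlation",
    "rescale_correlations",
    "build_network",
    "node_ssi",
    "all_node_ssi",
    "transform_ssi",
    "EnsembleSSI",
    "ensemble_ssi_distribution",
]


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def row_correlation(cm: Union[ComparisonMatrix, np.ndarray]) -> np.ndarray:
    """Pearson correlation between each pair of full rows of the comparison
    matrix (diagonal entries included).

    Constant rows have undefined correlations; their entries are returned as
    NaN with a warning and such nodes are dropped downstream.
    """
    s = cm.s if isinstance(cm, ComparisonMatrix) else np.asarray(cm, dtype=float)
    if s.shape[0] < 3:
        raise ValidationError("row correlation needs at least 3 structures")
    sd = s.std(axis=1)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} constant row(s) have undefined correlations; "
            "these nodes are excluded", UserWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(s)
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    return c


def rescale_correlations(c: np.ndarray) -> np.ndarray:
    """Map correlations from [-1, 1] onto [0, 1]: w = 0.5 * (1 + c)."""
    return 0.5 * (1.0 + np.asarray(c, dtype=float))


@dataclass
class SimilarityNetwork:
    """Thresholded weighted graph over structures (or genomic bins).

    ``weights`` is the full symmetric weight matrix; ``adjacency`` marks the
    retained edges (no self-edges).  ``p[i, j] = w_ij / sum_k w_ik`` over
    node i's neighbourhood.
    """

    weights: np.ndarray         # (n, n)
    adjacency: np.ndarray       # (n, n) bool
    threshold: float
    node_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.node_ids is None:
            self.node_ids = np.arange(self.weights.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def neighborhood(self, i: int) -> np.ndarray:
        return np.where(self.adjacency[i])[0]

    def edge_proportions(self, i: int) -> np.ndarray:
        """p_ij over the neighbourhood of i (uniform if all weights are 0)."""
        nb = self.neighborhood(i)
        w = self.weights[i, nb]
        tot = w.sum()
        if tot == 0:
            return np.full(len(nb), 1.0 / len(nb)) if len(nb) else w
        return w / tot

    def to_networkx(self):
        """Export the retained edges as a networkx Graph."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        g.add_weighted_edges_from(
            (self.node_ids[i], self.node_ids[j], float(self.weights[i, j]))
            for i, j in zip(ii, jj)
        )
        return g

    def edge_list(self) -> np.ndarray:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([ii, jj, self.weights[ii, jj]])


def build_network(w: np.ndarray, percentile: float = 50.0,
                  node_ids: Optional[np.ndarray] = None) -> SimilarityNetwork:
    """Threshold a weight matrix at a percentile of its edge weights.

    The threshold is the linear-interpolation percentile of all off-diagonal
    upper-triangle weights (NaN weights, from excluded nodes, ignored);
    edges strictly above the threshold are retained, self-edges never.
    """
    w = np.asarray(w, dtype=float)
    if not 0 <= percentile < 100:
        raise ValidationError("percentile must lie in [0, 100)")
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = w[iu]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise EmptyNetworkError("no finite edge weights to threshold")
    threshold = float(np.percentile(vals, percentile))
    with np.errstate(invalid="ignore"):
        adj = w > threshold
    adj &= ~np.eye(n, dtype=bool)
    adj &= np.isfinite(w)
    if not adj.any():
        raise EmptyNetworkError(
            f"threshold {threshold:.4g} (percentile {percentile}) removed every edge; "
            "retry with a lower percentile")
    return SimilarityNetwork(weights=np.where(np.isfinite(w), w, 0.0),
                             adjacency=adj, threshold=threshold,
                             node_ids=node_ids)


# ---------------------------------------------------------------------------
# Shannon-Jayne node entropy
# ---------------------------------------------------------------------------

def node_ssi(net: SimilarityNetwork, node: int) -> float:
    """S_i for one node; NaN for isolated nodes, 1.0 for degree-1 nodes.

    Degree 0 leaves the formula undefined (the node is excluded from
    medians); degree 1 makes it 0/0 and is defined as 1 (a single edge holds
    all the weight trivially).
    """
    k = int(net.degrees[node])
    if k == 0:
        return np.nan
    if k == 1:
        return 1.0
    p = net.edge_proportions(node)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(k))


def all_node_ssi(net: SimilarityNetwork) -> np.ndarray:
    """Vectorised S_i for every node (NaN where degree is 0)."""
    w = np.where(net.adjacency, net.weights, 0.0)
    k = net.degrees.astype(float)
    tot = w.sum(axis=1)
    out = np.full(net.n_nodes, np.nan)
    multi = k >= 2
    if multi.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            p = w[multi] / tot[multi, None]
            plogp = np.where(p > 0, p * np.log(p), 0.0)
            out[multi] = -plogp.sum(axis=1) / np.log(k[multi])
        # all-zero-weight neighbourhoods: proportions are uniform by convention
        zero_tot = multi & (tot == 0)
        out[zero_tot] = 1.0
    out[k == 1] = 1.0
    return out


def transform_ssi(s):
    """Affine display transform 1000 * (s - 0.99); order preserving."""
    return 1000.0 * (np.asarray(s, dtype=float) - 0.99)


# ---------------------------------------------------------------------------
# ensemble SSI with resampling
# ---------------------------------------------------------------------------

@dataclass
class SSIResult:
    """Per-node SSI, transformed values and resampled median distribution.

    ``ensemble_ssi_raw`` is the median raw S_i over nodes with defined SSI;
    ``ensemble_ssi`` its transformed counterpart (the transform is monotone
    affine, so it commutes with the median).  ``resampled_medians`` holds the
    median transformed SSI of each resampling iteration (NaN where an
    iteration's subnetwork lost every edge).
    """

    raw_ssi: np.ndarray
    transformed_ssi: np.ndarray
    ensemble_ssi_raw: float
    ensemble_ssi: float
    resampled_medians: np.ndarray
    n_sample: int
    n_iter: int
    seed: Optional[int]
    percentile: float

    def summary(self) -> str:
        med = np.nanmedian(self.resampled_medians) if len(self.resampled_medians) else np.nan
        q1, q3 = (np.nanpercentile(self.resampled_medians, [25, 75])
                  if len(self.resampled_medians) else (np.nan, np.nan))
        return "\n".join([
            "Ensemble structure similarity index",
            "=" * 35,
            f"nodes: {len(self.raw_ssi)}   threshold percentile: {self.percentile}",
            f"ensemble SSI (raw): {self.ensemble_ssi_raw:.6f}",
            f"ensemble SSI (transformed): {self.ensemble_ssi:.4f}",
            f"resampling: n_sample={self.n_sample}, n_iter={self.n_iter}, seed={self.seed}",
            f"resampled medians (transformed): median={med:.4f}, IQR=[{q1:.4f}, {q3:.4f}]",
        ])

    def to_dict(self) -> dict:
        return {
            "ensemble_ssi_raw": self.ensemble_ssi_raw,
            "ensemble_ssi_transformed": self.ensemble_ssi,
            "resampled_median": float(np.nanmedian(self.resampled_medians))
            if len(self.resampled_medians) else None,
            "n_sample": self.n_sample,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "percentile": self.percentile,
        }


class EnsembleSSI:
    """Model object computing the ensemble SSI of a distance ensemble.

    Parameters
    ----------
    dens
        Distance ensemble (or a precomputed ComparisonMatrix).
    percentile
        Edge-weight percentile for network thresholding (default 50).
    n_sample, n_iter
        Resampling: per iteration ``n_sample`` structures are drawn without
        replacement, the corresponding principal submatrix of the full
        comparison matrix is re-thresholded into a fresh network, and the
        median transformed node SSI recorded.  Defaults follow the published
        protocol (200 structures, 1000 iterations).
    seed
        Root seed; per-iteration seeds are spawned deterministically.
    resample_mode
        "network" (default) rebuilds the whole network per subsample, so the
        percentile threshold adapts to the subsample; "node" reuses the
        full-network node SSIs and subsamples those values (sensitivity
        alternative).
    include_diagonal
        Whether row correlations use full rows (default) or mask the two
        self-entries of each pair (sensitivity alternative).
    """

    def __init__(self, dens: Union[DistanceEnsemble, ComparisonMatrix],
                 percentile: float = 50.0,
                 n_sample: Optional[int] = None, n_iter: int = 1000,
                 seed: Optional[int] = None,
                 resample_mode: str = "network",
                 include_diagonal: bool = True):
        if isinstance(dens, DistanceEnsemble):
            self.cm = comparison_matrix(median_center(dens))
        else:
            self.cm = dens
        n = self.cm.n_structures
        self.percentile = float(percentile)
        self.n_sample = int(n_sample) if n_sample is not None else min(200, n)
        if self.n_sample > n:
            raise ValidationError("n_sample cannot exceed the number of structures")
        self.n_iter = int(n_iter)
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")
        self.seed = seed
        if resample_mode not in ("network", "node"):
            raise ValidationError("resample_mode must be 'network' or 'node'")
        self.resample_mode = resample_mode
        self.include_diagonal = include_diagonal

    # -- internals -----------------------------------------------------------

    def _node_ssi_for(self, s: np.ndarray) -> np.ndarray:
        c = row_correlation(s)
        if not self.include_diagonal:
            # mask each pair's two self-entries and recompute correlations
            c = _correlation_excluding_self(s)
        w = rescale_correlations(c)
        net = build_network(w, percentile=self.percentile)
        return all_node_ssi(net)

    def fit(self) -> SSIResult:
        s_full = self.cm.s
        raw = self._node_ssi_for(s_full)
        transformed = transform_ssi(raw)
        ens_raw = float(np.nanmedian(raw))

        medians = np.empty(self.n_iter)
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(self.n_iter)
        n = s_full.shape[0]
        if self.resample_mode == "node":
            for it, child in enumerate(children):
                rng = np.random.default_rng(child)
                idx = rng.choice(n, size=self.n_sample, replace=False)
                medians[it] = np.nanmedian(transformed[idx])
        else:
            for it, child in enumerate(children):
                rng = np.random.default_rng(child)
                idx = np.sort(rng.choice(n, size=self.n_sample, replace=False))
                sub = s_full[np.ix_(idx, idx)]
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", UserWarning)
                        sub_ssi = self._node_ssi_for(sub)
                    medians[it] = np.nanmedian(transform_ssi(sub_ssi))
                except EmptyNetworkError:
                    warnings.warn(f"iteration {it}: subnetwork lost every edge; "
                                  "recorded as NaN", UserWarning)
                    medians[it] = np.nan

        return SSIResult(
            raw_ssi=raw,
            transformed_ssi=transformed,
            ensemble_ssi_raw=ens_raw,
            ensemble_ssi=float(transform_ssi(ens_raw)),
            resampled_medians=medians,
            n_sample=self.n_sample,
            n_iter=self.n_iter,
            seed=self.seed,
            percentile=self.percentile,
        )


def _correlation_excluding_self(s: np.ndarray) -> np.ndarray:
    """Pairwise row correlation with columns i and j masked for pair (i, j)."""
    n = s.shape[0]
    c = np.empty((n, n))
    np.fill_diagonal(c, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            keep = np.ones(n, dtype=bool)
            keep[[i, j]] = False
            a, b = s[i, keep], s[j, keep]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                c[i, j] = c[j, i] = np.nan
                continue
            c[i, j] = c[j, i] = np.corrcoef(a, b)[0, 1]
    return np.clip(c, -1.0, 1.0)


def ensemble_ssi_distribution(dens: Union[DistanceEnsemble, ComparisonMatrix],
                              n_sample: int = 200, n_iter: int = 1000,
                              seed: Optional[int] = None,
                              percentile: float = 50.0,
                              **kwargs) -> SSIResult:
    """Functional wrapper around :class:`EnsembleSSI`."""
    return EnsembleSSI(dens, percentile=percentile, n_sample=n_sample,
                       n_iter=n_iter, seed=seed, **kwargs).fit()
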