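"""Unsupervised epileptogenic-zone detection by weighted consensus clustering.

Pipeline per seizure/band: mlEVC is quantized to {-1, 0, +1} by percentile
thresholding (fraction ``d``), the quantized matrices of all seizures and both
high-frequency bands are concatenated column-wise, and a thin SVD yields node
features (left singular vectors u1..u4, z-scored).  For each of the five
feature subsets K = {{u1,u2},{u1,u3},{u2,u3},{u1,u2,u3},{u1,u2,u3,u4}} a
centroid-linkage agglomerative clustering is cut at the final merge; the
smaller group is the presumptive target (with a 3-way back-step when it holds
fewer than 5% of the nodes).  Runs are scored by ``perf = sep/comp`` where
``sep`` is the squared centroid distance and ``comp`` the product of the mean
pairwise distance and the target's radius.  Per (coupling c, threshold d) the
valid runs vote with weight ``perf`` into a probability vector ``w`` that is
binarized at ``theta = (n-1)/n`` (0.5 when n = 1); the binary votes, weighted
by cell performance, accumulate over the full (c, d) grid into a global weight
per node, and 1-D k-means (k=3) on those weights yields the predicted EZ as
the cluster with the largest mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .multilayer import MlEVC

__all__ = [
    "QuantizedCentrality",
    "FeatureSpace",
    "ClusterRun",
    "ConsensusResult",
    "EvaluationReport",
    "quantize",
    "assemble_features",
    "cluster_run",
    "vote_threshold",
    "cd_consensus",
    "global_consensus",
    "detect_ez",
    "detect_ez_from_mlevc",
    "evaluate_vs_resection",
    "FEATURE_SETS",
    "DEFAULT_C_GRID",
    "DEFAULT_D_GRID",
]

DEFAULT_C_GRID = tuple(list(range(1, 11)) + [15])
DEFAULT_D_GRID = tuple(np.round(np.arange(0.1, 0.81, 0.1), 10))
#: index subsets of (u1, u2, u3, u4)
FEATURE_SETS = ((0, 1), (0, 2), (1, 2), (0, 1, 2), (0, 1, 2, 3))
MIN_TARGET_FRACTION = 0.05


@dataclass
class QuantizedCentrality:
    values: np.ndarray  # (N, T) over {-1, 0, +1}
    d: float
    degenerate: bool = False  # all-equal input, tie policy decided everything


@dataclass
class FeatureSpace:
    """Thin SVD of the concatenated quantized centrality matrix."""

    U: np.ndarray  # (N, k) left singular vectors, sign-canonicalized
    svals: np.ndarray
    V: np.ndarray  # (T_tot, k) right singular vectors
    seg_lengths: list[int]  # columns per (seizure, band) segment, in order
    seg_keys: list[tuple] = field(default_factory=list)  # (seizure_id, band)

    @property
    def t_tot(self) -> int:
        return self.V.shape[0]

    def features(self, n: int = 4) -> np.ndarray:
        """First ``n`` left singular vectors, z-scored across nodes."""
        U = self.U[:, :n]
        mu = U.mean(axis=0)
        sd = U.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (U - mu) / sd


@dataclass
class ClusterRun:
    labels: np.ndarray  # binary, 1 = presumptive target
    sep: float
    comp: float
    valid: bool
    feature_set: tuple[int, ...] = ()

    @property
    def perf(self) -> float:
        return self.sep / self.comp if self.valid else 0.0


@dataclass
class ConsensusResult:
    w_global: np.ndarray
    ez_nodes: np.ndarray  # indices
    detected: bool
    cell_perf: dict = field(default_factory=dict)  # (c, d) -> cell weight
    cell_labels: dict = field(default_factory=dict)  # (c, d) -> binary vector
    n_runs_attempted: int = 0
    labels: list[str] = field(default_factory=list)


@dataclass
class EvaluationReport:
    categories: list[str]  # per node: 'EZ' | 'RnEZ' | 'nR'
    detected: bool
    fpr: float | None


def quantize(m: MlEVC | np.ndarray, d: float) -> QuantizedCentrality:
    """Three-level percentile quantization of the flattened N*T values.

    Top ``d/2`` fraction -> +1, bottom ``d/2`` -> -1, rest 0.  Boundary ties
    are broken by stable (value, flat index) order so the counts are exactly
    ``round(d/2 * N*T)``.
    """
    if not 0 < d < 1:
        raise ValueError("d must lie in (0, 1)")
    values = m.values if isinstance(m, MlEVC) else np.asarray(m)
    flat = values.ravel()
    k = int(round(d / 2.0 * flat.size))
    order = np.argsort(flat, kind="stable")
    q = np.zeros(flat.size, dtype=int)
    if k > 0:
        q[order[:k]] = -1
        q[order[-k:]] = 1
    degenerate = bool(flat.size > 1 and np.all(flat == flat[0]))
    return QuantizedCentrality(q.reshape(values.shape), d, degenerate)


def assemble_features(quantized: list[QuantizedCentrality], keys: list[tuple] | None = None) -> FeatureSpace:
    """Column-concatenate quantized matrices (seizure-major, band-minor order)
    and take the thin SVD; left singular vectors are sign-canonicalized."""
    if not quantized:
        raise ValueError("no quantized matrices supplied")
    n = quantized[0].values.shape[0]
    if any(q.values.shape[0] != n for q in quantized):
        raise ValueError("node count mismatch across quantized matrices")
    X = np.concatenate([q.values for q in quantized], axis=1).astype(float)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    idx = np.argmax(np.abs(U), axis=0)
    flip = np.sign(U[idx, np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    U = U * flip
    V = Vt.T * flip
    return FeatureSpace(
        U, s, V, [q.values.shape[1] for q in quantized], list(keys or [])
    )


def _target_from_cut(assign: np.ndarray, rank: int) -> np.ndarray:
    """Boolean mask of the ``rank``-th smallest cluster (0 = smallest)."""
    ids, counts = np.unique(assign, return_counts=True)
    order = np.argsort(counts, kind="stable")
    return assign == ids[order[rank]]


def cluster_run(features: np.ndarray, feature_set: tuple[int, ...] = ()) -> ClusterRun:
    """One agglomerative run on a (N, dim) feature matrix.

    Centroid linkage on Euclidean distances, cut into two groups before the
    last merge; the smaller group is the presumptive target.  If it holds
    fewer than 5% of the nodes the cut backs up to three groups and the
    second-smallest group becomes the target.  A run is valid only when the
    target has at least two members and nonzero compactness.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 nodes to cluster")
    if np.allclose(X, X[0]):
        return ClusterRun(np.zeros(n, dtype=int), 0.0, 0.0, False, feature_set)
    Z = linkage(X, method="centroid")
    assign2 = fcluster(Z, 2, criterion="maxclust")
    target = _target_from_cut(assign2, 0)
    if target.sum() < MIN_TARGET_FRACTION * n:
        assign3 = fcluster(Z, 3, criterion="maxclust")
        if len(np.unique(assign3)) >= 3:
            target = _target_from_cut(assign3, 1)
    labels = target.astype(int)
    m = int(target.sum())
    if m < 2 or m == n:
        return ClusterRun(labels, 0.0, 0.0, False, feature_set)
    Xt, Xo = X[target], X[~target]
    cen_t = Xt.mean(axis=0)
    cen_o = Xo.mean(axis=0)
    sep = float(np.sum((cen_o - cen_t) ** 2))
    pair_d = pdist(Xt)
    radius = float(np.linalg.norm(Xt - cen_t, axis=1).max())
    comp = float(pair_d.mean()) * radius
    if comp == 0.0:
        return ClusterRun(labels, sep, 0.0, False, feature_set)
    return ClusterRun(labels, sep, comp, True, feature_set)


def vote_threshold(n_valid: int) -> float:
    """Binarization threshold ``theta = (n-1)/n`` for ``n`` valid runs.

    With a single valid run the majority rule degenerates to 0.5, i.e. that
    run's labels pass through unchanged (votes are compared strictly above
    the threshold).
    """
    return (n_valid - 1) / n_valid if n_valid >= 2 else 0.5


def cd_consensus(runs: list[ClusterRun]):
    """Perf-weighted vote of valid runs at one (c, d) cell.

    Returns ``(w_cd, l_cd, cell_perf, n_valid)``; with no valid runs the
    labels are all zero and the cell weight is 0.
    """
    valid = [r for r in runs if r.valid]
    n_nodes = len(runs[0].labels)
    if not valid:
        return np.zeros(n_nodes), np.zeros(n_nodes, dtype=int), 0.0, 0
    perfs = np.array([r.perf for r in valid])
    L = np.stack([r.labels for r in valid])
    w = perfs @ L / perfs.sum()
    n = len(valid)
    l = (w > vote_threshold(n)).astype(int)
    return w, l, float(perfs.sum()), n


def _kmeans_1d(w: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    return km.fit_predict(w.reshape(-1, 1))


def global_consensus(
    cell_perf: dict,
    cell_labels: dict,
    n_nodes: int,
    seed: int = 0,
    labels: list[str] | None = None,
    n_runs_attempted: int = 0,
) -> ConsensusResult:
    """Accumulate perf-weighted binary votes over the (c, d) grid and segment
    the resulting node weights with 1-D k-means (k=3); the cluster with the
    largest mean weight is the predicted EZ."""
    w_global = np.zeros(n_nodes)
    for key, perf in cell_perf.items():
        w_global = w_global + perf * cell_labels[key]
    if np.all(w_global == 0):
        return ConsensusResult(
            w_global, np.array([], dtype=int), False, dict(cell_perf),
            dict(cell_labels), n_runs_attempted, list(labels or []),
        )
    k = min(3, len(np.unique(w_global)))
    assign = _kmeans_1d(w_global, k, seed)
    ids = np.unique(assign)  # k-means may leave a cluster empty on degenerate w
    means = np.array([w_global[assign == i].mean() for i in ids])
    ez = np.flatnonzero(assign == ids[int(np.argmax(means))])
    return ConsensusResult(
        w_global, ez, True, dict(cell_perf), dict(cell_labels),
        n_runs_attempted, list(labels or []),
    )


def detect_ez(
    series_by_key,
    c_grid=DEFAULT_C_GRID,
    d_grid=DEFAULT_D_GRID,
    seed: int = 0,
    mlevc_cache: dict | None = None,
):
    """Full grid consensus from normalized connectivity stacks.

    Parameters
    ----------
    series_by_key
        Mapping ``(seizure_id, band) -> ConnectivitySeries`` (normalized,
        high-frequency), ordered seizure-major then band.
    c_grid, d_grid
        Interlayer coupling and quantization-threshold grids.
    mlevc_cache
        Optional dict to reuse mlEVC computations across calls; filled with
        ``(key, c) -> MlEVC``.

    Returns
    -------
    ConsensusResult
    """
    from .multilayer import mlevc_from_series

    keys = list(series_by_key)
    if not keys:
        raise ValueError("no connectivity series supplied")
    first = series_by_key[keys[0]]
    n_nodes = first.n_nodes
    node_labels = list(first.labels)
    cache = {} if mlevc_cache is None else mlevc_cache

    mlevc_by_c = {}
    for c in c_grid:
        mats = []
        for key in keys:
            ck = (key, c)
            if ck not in cache:
                cache[ck] = mlevc_from_series(series_by_key[key], c, seed=seed)
            mats.append(cache[ck])
        mlevc_by_c[c] = mats
    return detect_ez_from_mlevc(
        mlevc_by_c, keys, d_grid=d_grid, seed=seed, node_labels=node_labels
    )


def detect_ez_from_mlevc(
    mlevc_by_c: dict,
    keys: list[tuple],
    d_grid=DEFAULT_D_GRID,
    seed: int = 0,
    node_labels: list[str] | None = None,
) -> ConsensusResult:
    """Grid consensus from precomputed mlEVC matrices.

    ``mlevc_by_c`` maps each coupling value to the list of per-(seizure, band)
    mlEVC matrices in the order of ``keys``.
    """
    first = next(iter(mlevc_by_c.values()))[0]
    n_nodes = first.values.shape[0]
    cell_perf: dict = {}
    cell_labels: dict = {}
    attempted = 0
    for c, mats in mlevc_by_c.items():
        for d in d_grid:
            quantized = [quantize(m, d) for m in mats]
            space = assemble_features(quantized, keys)
            feats = space.features(4)
            runs = []
            for fset in FEATURE_SETS:
                runs.append(cluster_run(feats[:, list(fset)], fset))
                attempted += 1
            _, l_cd, perf_cd, _ = cd_consensus(runs)
            cell_perf[(c, d)] = perf_cd
            cell_labels[(c, d)] = l_cd
    return global_consensus(
        cell_perf, cell_labels, n_nodes, seed=seed,
        labels=list(node_labels or (first.labels or [])),
        n_runs_attempted=attempted,
    )


def evaluate_vs_resection(result: ConsensusResult, resected: np.ndarray) -> EvaluationReport:
    """Node categories (EZ / RnEZ / nR), detection flag and false-positive rate.

    ``fpr = |predicted EZ outside resection| / |non-resected nodes|``.
    """
    resected = np.asarray(resected, dtype=bool)
    n = len(resected)
    predicted = np.zeros(n, dtype=bool)
    predicted[result.ez_nodes] = True
    if not resected.any():
        cats = ["EZ" if p else "nR" for p in predicted]
        return EvaluationReport(cats, bool(predicted.any()), None)
    # false-positive predictions (outside the resection) are kept in nR so the
    # regional EZ group contains only in-resection predicted nodes
    cats = []
    for p, r in zip(predicted, resected):
        if p and r:
            cats.append("EZ")
        elif r:
            cats.append("RnEZ")
        else:
            cats.append("nR")
    detected = bool((predicted & resected).any())
    n_nonres = int((~resected).sum())
    fpr = float((predicted & ~resected).sum() / n_nonres) if n_nonres else 0.0
    return EvaluationReport(cats, detected, fpr)
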