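"""Quantization, consensus clustering and EZ prediction."""

import numpy as np
import pytest

from ictalnet.ezdetect import (
    DEFAULT_C_GRID,
    DEFAULT_D_GRID,
    FEATURE_SETS,
    assemble_features,
    cd_consensus,
    cluster_run,
    detect_ez_from_mlevc,
    evaluate_vs_resection,
    global_consensus,
    quantize,
    vote_threshold,
)
from ictalnet.multilayer import MlEVC


def test_quantize_counts_are_exact():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((10, 10))
    q = quantize(x, 0.1)  # 100 values, d/2 = 5% each tail
    assert np.count_nonzero(q.values == 1) == 5
    assert np.count_nonzero(q.values == -1) == 5
    assert np.count_nonzero(q.values == 0) == 90
    q = quantize(x, 0.8)
    assert np.count_nonzero(q.values == 1) == 40
    assert np.count_nonzero(q.values == -1) == 40
    assert np.count_nonzero(q.values == 0) == 20


def test_quantize_counts_exact_under_ties():
    x = np.zeros((5, 20))  # all equal: pure tie-breaking
    q = quantize(x, 0.4)
    assert q.degenerate
    assert np.count_nonzero(q.values == 1) == 20
    assert np.count_nonzero(q.values == -1) == 20


def test_quantize_marks_extremes():
    x = np.arange(100.0).reshape(10, 10)
    q = quantize(x, 0.2)  # top/bottom 10 values
    flat = q.values.ravel()
    assert np.all(flat[:10] == -1)
    assert np.all(flat[-10:] == 1)
    assert np.all(flat[10:90] == 0)


def test_quantize_is_invariant_to_monotone_maps():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((8, 12))
    q1 = quantize(x, 0.3).values
    q2 = quantize(np.exp(x), 0.3).values  # strictly increasing map
    assert np.array_equal(q1, q2)


def test_quantize_validates_threshold():
    with pytest.raises(ValueError):
        quantize(np.zeros((4, 4)), 0.0)
    with pytest.raises(ValueError):
        quantize(np.zeros((4, 4)), 1.0)


def test_assemble_features_reconstructs_input():
    rng = np.random.default_rng(2)
    qs = [quantize(rng.standard_normal((6, 5)), 0.4) for _ in range(3)]
    keys = [("sz1", "b1"), ("sz1", "b2"), ("sz2", "b1")]
    space = assemble_features(qs, keys)
    X = np.concatenate([q.values for q in qs], axis=1).astype(float)
    recon = space.U @ np.diag(space.svals) @ space.V.T
    assert np.allclose(recon, X, atol=1e-10)
    assert space.seg_lengths == [5, 5, 5]
    assert space.seg_keys == keys
    # z-scored features: zero mean, unit variance per column
    f = space.features(4)
    assert np.allclose(f.mean(axis=0), 0, atol=1e-10)
    assert np.allclose(f.std(axis=0), 1, atol=1e-10)


def test_cluster_run_hand_oracle():
    """Two points at (0,0),(0,1), 38 points at (5,0):
    sep = 5^2 + 0.5^2 = 25.25, comp = 1 * 0.5 = 0.5, perf = 50.5."""
    X = np.vstack([[0.0, 0.0], [0.0, 1.0], np.tile([5.0, 0.0], (38, 1))])
    run = cluster_run(X)
    assert run.valid
    assert np.array_equal(np.flatnonzero(run.labels), [0, 1])
    assert run.sep == pytest.approx(25.25)
    assert run.comp == pytest.approx(0.5)
    assert run.perf == pytest.approx(50.5)


def test_cluster_run_backs_up_to_three_clusters():
    """A single far outlier (under 5% of nodes) forces the 3-way cut; the
    second-smallest group becomes the target."""
    rng = np.random.default_rng(3)
    X = np.vstack([
        [100.0, 100.0],                                # lone outlier
        np.tile([0.0, 5.0], (3, 1)) + 0.01 * rng.standard_normal((3, 2)),
        np.tile([0.0, 0.0], (26, 1)) + 0.01 * rng.standard_normal((26, 2)),
    ])
    run = cluster_run(X)
    assert run.valid
    assert np.array_equal(np.flatnonzero(run.labels), [1, 2, 3])


def test_cluster_run_degenerate_inputs():
    X = np.tile([1.0, 2.0], (10, 1))
    run = cluster_run(X)
    assert not run.valid and run.perf == 0.0
    with pytest.raises(ValueError):
        cluster_run(np.zeros((3, 2)))


def test_vote_threshold_formula():
    assert vote_threshold(1) == 0.5
    assert vote_threshold(2) == 0.5
    assert vote_threshold(4) == 0.75
    assert vote_threshold(10) == 0.9


def test_cd_consensus_single_run_passes_through():
    """n = 1 valid run: theta = 0.5, so its labels survive unchanged."""
    from ictalnet.ezdetect import ClusterRun

    labels = np.array([1, 1, 0, 0, 0])
    runs = [
        ClusterRun(labels, 4.0, 2.0, True),
        ClusterRun(np.zeros(5, dtype=int), 0.0, 0.0, False),
    ]
    w, l, perf, n = cd_consensus(runs)
    assert n == 1
    assert np.array_equal(l, labels)
    assert perf == pytest.approx(2.0)
    assert np.array_equal(w, labels.astype(float))


def test_cd_consensus_majority_is_strict():
    """Four equal-perf runs: a node voted by 3/4 sits exactly at theta = 0.75
    and is excluded; unanimity is required to clear the strict threshold."""
    from ictalnet.ezdetect import ClusterRun

    L = np.array([
        [1, 1, 0, 0],
        [1, 1, 0, 0],
        [1, 1, 0, 0],
        [1, 0, 1, 0],
    ])
    runs = [ClusterRun(row, 2.0, 1.0, True) for row in L]
    w, l, perf, n = cd_consensus(runs)
    assert n == 4
    assert np.allclose(w, [1.0, 0.75, 0.25, 0.0])
    assert np.array_equal(l, [1, 0, 0, 0])
    assert perf == pytest.approx(8.0)


def test_cd_consensus_weighted_vote_oracle():
    from ictalnet.ezdetect import ClusterRun

    runs = [
        ClusterRun(np.array([1, 1, 0, 0]), 3.0, 1.0, True),  # perf 3
        ClusterRun(np.array([1, 0, 1, 0]), 1.0, 1.0, True),  # perf 1
    ]
    w, l, perf, n = cd_consensus(runs)
    assert np.allclose(w, [1.0, 0.75, 0.25, 0.0])
    # theta = (2-1)/2 = 0.5
    assert np.array_equal(l, [1, 1, 0, 0])


def _exact_kmeans_1d(w, k):
    """Optimal 1-D k-means by dynamic programming over sorted prefixes."""
    x = np.sort(w)
    n = len(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x**2)])

    def cost(i, j):  # SSE of x[i:j]
        s, q, m = csum[j] - csum[i], csq[j] - csq[i], j - i
        return q - s * s / m

    D = np.full((k + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    split = np.zeros((k + 1, n + 1), dtype=int)
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            for i in range(kk - 1, j):
                c = D[kk - 1, i] + cost(i, j)
                if c < D[kk, j]:
                    D[kk, j] = c
                    split[kk, j] = i
    # recover boundaries
    bounds = [n]
    j = n
    for kk in range(k, 0, -1):
        j = split[kk, j]
        bounds.append(j)
    bounds = bounds[::-1]
    labels_sorted = np.empty(n, dtype=int)
    for g in range(k):
        labels_sorted[bounds[g] : bounds[g + 1]] = g
    order = np.argsort(w)
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, D[k, n]


def test_global_consensus_matches_exact_1d_kmeans():
    """The k = 3 segmentation of the node weights is globally optimal, and the
    top segment is the predicted EZ."""
    rng = np.random.default_rng(4)
    w = np.concatenate([
        rng.uniform(0.0, 0.5, 12), rng.uniform(4.0, 5.0, 5), rng.uniform(10.0, 11.0, 3)
    ])
    cell_perf = {("c", "d"): 1.0}
    cell_labels = {("c", "d"): w}  # single cell carrying the weights directly
    res = global_consensus(cell_perf, cell_labels, len(w), seed=0)
    assert res.detected
    exact, _ = _exact_kmeans_1d(w, 3)
    means = [w[exact == g].mean() for g in range(3)]
    expected_ez = np.flatnonzero(exact == int(np.argmax(means)))
    assert np.array_equal(np.sort(res.ez_nodes), np.sort(expected_ez))


def test_global_consensus_no_votes_means_no_detection():
    res = global_consensus({("c", "d"): 0.0}, {("c", "d"): np.zeros(6)}, 6)
    assert not res.detected
    assert res.ez_nodes.size == 0


def _toy_mlevc_by_c(n=20, t=10, seed=0, contrast=True):
    """Random mlEVC stacks with (optionally) four high-centrality nodes."""
    rng = np.random.default_rng(seed)
    keys = [("sz1", (80.0, 140.0)), ("sz1", (140.0, 200.0))]
    out = {}
    for c in DEFAULT_C_GRID:
        mats = []
        for _ in keys:
            v = rng.uniform(0.5, 1.0, size=(n, t))
            if contrast:
                v[:4] += 2.0
            mats.append(MlEVC(v, c))
        out[c] = mats
    return out, keys


def test_full_grid_attempts_440_runs():
    """11 couplings x 8 thresholds x 5 feature sets = 440 clustering runs."""
    mlevc_by_c, keys = _toy_mlevc_by_c()
    res = detect_ez_from_mlevc(mlevc_by_c, keys)
    assert len(DEFAULT_C_GRID) == 11
    assert len(DEFAULT_D_GRID) == 8
    assert len(FEATURE_SETS) == 5
    assert res.n_runs_attempted == 440
    assert len(res.cell_perf) == 88


def test_grid_consensus_recovers_contrasted_nodes():
    mlevc_by_c, keys = _toy_mlevc_by_c(seed=1, contrast=True)
    res = detect_ez_from_mlevc(mlevc_by_c, keys)
    assert res.detected
    assert set(res.ez_nodes) == {0, 1, 2, 3}


def test_detection_is_deterministic():
    mlevc_by_c, keys = _toy_mlevc_by_c(seed=2)
    r1 = detect_ez_from_mlevc(mlevc_by_c, keys, seed=5)
    r2 = detect_ez_from_mlevc(mlevc_by_c, keys, seed=5)
    assert np.array_equal(r1.ez_nodes, r2.ez_nodes)
    assert np.array_equal(r1.w_global, r2.w_global)


def test_evaluate_vs_resection_categories_and_fpr():
    from ictalnet.ezdetect import ConsensusResult

    res = ConsensusResult(
        w_global=np.arange(6.0), ez_nodes=np.array([0, 5]), detected=True
    )
    resected = np.array([True, True, False, False, False, False])
    rep = evaluate_vs_resection(res, resected)
    # node 0: predicted & resected -> EZ; node 1: resected only -> RnEZ;
    # node 5: predicted outside the resection -> stays nR (false positive)
    assert rep.categories == ["EZ", "RnEZ", "nR", "nR", "nR", "nR"]
    assert rep.detected
    assert rep.fpr == pytest.approx(1 / 4)
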