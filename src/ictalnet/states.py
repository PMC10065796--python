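"""Brain-state clustering of seizure evolution.

The right singular vectors of the concatenated quantized centrality matrix
describe the network topology of every connectivity window.  The top three
vectors are split per seizure and band, despiked with a Hampel filter
(15-point window, 3 x 1.4826 x MAD), re-concatenated per band into six
feature vectors, and every 4-of-6 feature combination is clustered with
k-means over a range of state counts.  The combination/count with the highest
mean silhouette defines the brain states; per-seizure state sequences and the
aggregate transition matrix summarize seizure evolution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .ezdetect import FeatureSpace

__all__ = [
    "StateFeatures",
    "StateModel",
    "hampel_filter",
    "clean_right_vectors",
    "select_state_model",
    "transitions",
]

HAMPEL_WINDOW = 15  # total points (7 each side)
HAMPEL_NSIGMA = 3.0
MAD_SCALE = 1.4826
DEFAULT_K_RANGE = tuple(range(2, 9))


@dataclass
class StateFeatures:
    """Six cleaned feature vectors (3 singular vectors x 2 bands).

    Each column of ``S`` has length T_tot/2 = total windows per band; rows are
    aligned across bands.  ``window_seizure`` maps each row to its seizure.
    """

    S: np.ndarray  # (n_windows, 6)
    window_seizure: list[str]
    window_t0: np.ndarray | None = None


@dataclass
class StateModel:
    chosen_features: tuple[int, ...]
    k: int
    assignments: np.ndarray
    centers: np.ndarray
    silhouette: float
    weak: bool = False  # silhouette < 0.25


def hampel_filter(
    x: np.ndarray,
    window: int = HAMPEL_WINDOW,
    n_sigma: float = HAMPEL_NSIGMA,
) -> np.ndarray:
    """Sliding-window outlier replacement.

    A point is replaced by the median of its ``window``-point centered
    neighbourhood when it deviates from that median by strictly more than
    ``n_sigma * 1.4826 * MAD``; windows truncate at the edges.
    """
    x = np.asarray(x, dtype=float)
    out = x.copy()
    half = window // 2
    n = len(x)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = x[lo:hi]
        med = np.median(seg)
        sigma = MAD_SCALE * np.median(np.abs(seg - med))
        if np.abs(x[i] - med) > n_sigma * sigma:
            out[i] = med
    return out


def clean_right_vectors(
    space: FeatureSpace,
    n_vectors: int = 3,
    window: int = HAMPEL_WINDOW,
) -> StateFeatures:
    """Split v1..v3 per (seizure, band) segment, Hampel-despike each segment,
    and re-concatenate per band into the six state-feature vectors."""
    if not space.seg_keys:
        raise ValueError("feature space lacks (seizure, band) segment keys")
    bands = []
    for key in space.seg_keys:
        if key[1] not in bands:
            bands.append(key[1])
    if len(bands) != 2:
        raise ValueError(f"expected two bands, found {bands}")
    bounds = np.concatenate([[0], np.cumsum(space.seg_lengths)])
    cols = []
    seizure_ids = None
    for vi in range(n_vectors):
        v = space.V[:, vi]
        for band in bands:
            parts, sids = [], []
            for si, key in enumerate(space.seg_keys):
                if key[1] != band:
                    continue
                seg = v[bounds[si] : bounds[si + 1]]
                parts.append(hampel_filter(seg, window))
                sids.extend([key[0]] * len(seg))
            cols.append(np.concatenate(parts))
            if seizure_ids is None:
                seizure_ids = sids
    S = np.stack(cols, axis=1)  # order: (v1,b1),(v1,b2),(v2,b1),...
    return StateFeatures(S, list(seizure_ids))


def select_state_model(
    features: StateFeatures,
    k_range=DEFAULT_K_RANGE,
    seed: int = 0,
    n_restarts: int = 10,
) -> StateModel:
    """Grid over 4-of-6 feature combinations and state counts; the model with
    the highest mean silhouette wins (ties: smaller k, then earlier
    combination in lexicographic order)."""
    S = features.S
    mu, sd = S.mean(axis=0), S.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (S - mu) / sd
    n = Z.shape[0]
    best = None
    for combo in itertools.combinations(range(S.shape[1]), 4):
        X = Z[:, combo]
        for k in k_range:
            if k >= n:
                continue
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
            assign = km.fit_predict(X)
            if len(np.unique(assign)) < 2:
                continue
            sil = float(silhouette_score(X, assign))
            cand = (sil, -k, [-c for c in combo])
            if best is None or cand > best[0]:
                best = (cand, combo, k, assign, km.cluster_centers_, sil)
    if best is None:
        raise ValueError("no feasible clustering (too few windows)")
    _, combo, k, assign, centers, sil = best
    return StateModel(combo, k, assign, centers, sil, weak=sil < 0.25)


def transitions(model: StateModel, window_seizure: list[str]):
    """Per-seizure collapsed state sequences and aggregate transition counts.

    Consecutive repeats collapse to one state; transitions are never counted
    across seizure boundaries.  Returns ``(sequences, count_matrix)`` with
    ``count_matrix[i, j]`` the number of i -> j transitions.
    """
    assign = np.asarray(model.assignments)
    if len(assign) != len(window_seizure):
        raise ValueError("assignments and seizure ids differ in length")
    k = int(assign.max()) + 1
    counts = np.zeros((k, k), dtype=int)
    sequences: dict[str, list[int]] = {}
    seen = []
    for sid in window_seizure:
        if sid not in sequences:
            sequences[sid] = []
            seen.append(sid)
    for a, sid in zip(assign, window_seizure):
        seq = sequences[sid]
        if not seq or seq[-1] != a:
            seq.append(int(a))
    for sid in seen:
        seq = sequences[sid]
        for a, b in zip(seq[:-1], seq[1:]):
            counts[a, b] += 1
    return sequences, counts
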