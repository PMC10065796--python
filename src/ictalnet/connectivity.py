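"""Windowed functional-connectivity networks.

High-frequency (80-140, 140-200 Hz) synchrony is measured by pair-wise lagged
coherence, which keeps only the non-instantaneous (imaginary cross-spectral)
part of coherence and is therefore immune to zero-lag volume conduction.  For
a frequency bin with cross-spectrum :math:`S_{xy}` and auto-spectra
:math:`S_{xx}, S_{yy}`,

.. math:: \\rho^2 = \\frac{\\mathrm{Im}(S_{xy})^2}{S_{xx} S_{yy} - \\mathrm{Re}(S_{xy})^2}

and the in-band bins are averaged.  Low-frequency (3-50 Hz) propagation
networks use the phase lag index (PLI), the absolute mean sign of the
instantaneous phase difference of the analytic signals.

Each seizure yields an ``N x N x T`` stack from 2.5 s sliding windows (80%
overlap for the high-frequency bands, 90% for the low band); every edge is
z-scored against a pre-ictal baseline and squashed into (0, 1) by a logistic
map before any multilayer analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import Recording

__all__ = [
    "ConnectivitySeries",
    "BaselineStats",
    "sliding_windows",
    "lagged_coherence_matrix",
    "pli_matrix",
    "compute_connectivity_series",
    "compute_baseline",
    "baseline_normalize",
]

STD_FLOOR = 1e-6

#: sliding-window parameters
WINDOW_S = 2.5
HF_OVERLAP = 0.8
LF_OVERLAP = 0.9


@dataclass
class ConnectivitySeries:
    """``N x N x T`` stack of per-window connectivity matrices."""

    values: np.ndarray  # (N, N, T)
    band: tuple[float, float]
    window_s: float
    overlap: float
    t0: np.ndarray  # window-center times (s), length T
    metric: str = "lagged_coherence"
    labels: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must be (N, N, T)")
        self.t0 = np.asarray(self.t0, dtype=float)
        if self.t0.shape != (self.values.shape[2],):
            raise ValueError("t0 length must equal layer count")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_layers(self) -> int:
        return self.values.shape[2]

    @property
    def hop_s(self) -> float:
        return self.window_s * (1.0 - self.overlap)

    @property
    def samples_per_s(self) -> float:
        """Connectivity sampling rate (2 samples/s for 2.5 s, 80% overlap)."""
        return 1.0 / self.hop_s

    def select_layers(self, mask: np.ndarray) -> "ConnectivitySeries":
        return ConnectivitySeries(
            self.values[:, :, mask],
            self.band,
            self.window_s,
            self.overlap,
            self.t0[mask],
            self.metric,
            list(self.labels),
            self.normalized,
        )


@dataclass
class BaselineStats:
    """Per-edge mean/std over pre-ictal windows (std floored at 1e-6)."""

    mean: np.ndarray
    std: np.ndarray
    n_windows: int
    floored: np.ndarray | None = None  # boolean mask of floored edges


def sliding_windows(n_samples: int, fs: float, window_s: float, overlap: float):
    """Start indices (samples) of maximal fully-contained sliding windows.

    ``hop = window_s * (1 - overlap)``; a partial trailing window is
    discarded.  Returns ``(starts, win_len)``.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    win = int(round(window_s * fs))
    hop = int(round(window_s * (1.0 - overlap) * fs))
    if hop < 1:
        raise ValueError("window/overlap combination yields empty hop")
    if n_samples < win:
        raise ValueError("segment shorter than one window")
    n_win = (n_samples - win) // hop + 1
    return np.arange(n_win) * hop, win


def _cross_spectra(window: np.ndarray, fs: float, nperseg: int):
    """Welch cross-spectral matrix from Hann sub-segments, 50% overlap.

    Returns ``(S, freqs)`` with ``S`` of shape (n_ch, n_ch, n_bins).
    """
    n_ch, n = window.shape
    nperseg = min(nperseg, n)
    step = max(1, nperseg // 2)
    starts = np.arange(0, n - nperseg + 1, step)
    taper = signal.windows.hann(nperseg, sym=False)
    segs = np.stack([window[:, s : s + nperseg] for s in starts], axis=1)
    segs = (segs - segs.mean(axis=-1, keepdims=True)) * taper
    spec = np.fft.rfft(segs, axis=-1)  # (n_ch, n_seg, n_bins)
    S = np.einsum("isf,jsf->ijf", spec, spec.conj()) / len(starts)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return S, freqs


def lagged_coherence_matrix(
    window: np.ndarray,
    band: tuple[float, float],
    fs: float,
    subseg_s: float = 0.5,
) -> np.ndarray:
    """Pair-wise lagged coherence averaged over in-band frequency bins.

    Symmetric, values in [0, 1], zero diagonal.  Zero-variance channels get 0
    on all their pairs (with a warning).
    """
    window = np.asarray(window, dtype=float)
    S, freqs = _cross_spectra(window, fs, int(round(subseg_s * fs)))
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError(f"no frequency bins inside band {band}")
    S = S[:, :, in_band]
    auto = np.real(np.einsum("iif->if", S))
    dead = auto.max(axis=1) <= 0
    if dead.any():
        warnings.warn("zero-variance channel(s) in window; their pairs set to 0")
    denom = auto[:, None, :] * auto[None, :, :] - np.real(S) ** 2
    num = np.imag(S) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        rho2 = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    out = rho2.mean(axis=2)
    out = np.clip(0.5 * (out + out.T), 0.0, 1.0)
    out[dead, :] = 0.0
    out[:, dead] = 0.0
    np.fill_diagonal(out, 0.0)
    return out


def pli_matrix(window: np.ndarray, band=None, fs=None) -> np.ndarray:
    """Phase lag index from band-limited analytic signals.

    ``PLI_xy = |mean_t sign(Im(z_x z_y*))|``; the input is expected to be
    band-limited already (``band``/``fs`` are accepted for interface symmetry
    and used only for validation).
    """
    window = np.asarray(window, dtype=float)
    if band is not None and fs is not None and band[1] >= fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist")
    z = signal.hilbert(window, axis=-1)
    dead = window.std(axis=-1) == 0
    if dead.any():
        warnings.warn("zero-variance channel(s) in window; their pairs set to 0")
    phase = np.exp(1j * np.angle(z))
    cross = np.einsum("it,jt->ijt", phase, phase.conj())
    out = np.abs(np.sign(np.imag(cross)).mean(axis=-1))
    out[dead, :] = 0.0
    out[:, dead] = 0.0
    np.fill_diagonal(out, 0.0)
    return out


_METRICS = {"lagged_coherence": lagged_coherence_matrix, "pli": pli_matrix}


def compute_connectivity_series(
    rec: Recording,
    band: tuple[float, float],
    metric: str = "lagged_coherence",
    window_s: float = WINDOW_S,
    overlap: float = HF_OVERLAP,
    start_sample: int = 0,
    stop_sample: int | None = None,
) -> ConnectivitySeries:
    """Raw (un-normalized) windowed connectivity stack for one band.

    ``rec`` must already be band-limited to ``band`` (see
    :func:`ictalnet.preprocessing.bandpass_band`); window-center times are in
    seconds of the original recording.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    stop = rec.n_samples if stop_sample is None else stop_sample
    data = rec.data[:, start_sample:stop]
    starts, win = sliding_windows(data.shape[1], rec.fs, window_s, overlap)
    func = _METRICS[metric]
    mats = np.empty((rec.n_channels, rec.n_channels, len(starts)))
    for k, s in enumerate(starts):
        mats[:, :, k] = func(data[:, s : s + win], band, rec.fs)
    t0 = (start_sample + starts + win / 2.0) / rec.fs
    return ConnectivitySeries(
        mats, band, window_s, overlap, t0, metric, rec.labels, normalized=False
    )


def compute_baseline(series: ConnectivitySeries) -> BaselineStats:
    """Per-edge mean/std across pre-ictal windows of a raw series."""
    if series.n_layers < 2:
        raise ValueError("baseline needs at least 2 windows")
    if series.n_layers < 5:
        warnings.warn(f"baseline from only {series.n_layers} windows")
    mean = series.values.mean(axis=2)
    std = series.values.std(axis=2, ddof=1)
    floored = std < STD_FLOOR
    std = np.maximum(std, STD_FLOOR)
    return BaselineStats(mean, std, series.n_layers, floored)


def logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def baseline_normalize(
    series: ConnectivitySeries,
    base: BaselineStats,
    transform=logistic,
) -> ConnectivitySeries:
    """Edge-wise z-score against the pre-ictal baseline, mapped into (0, 1).

    The default squashing map is the logistic ``1/(1+exp(-z))``; any monotone
    map of the z-score into (0, 1) can be passed instead.
    """
    z = (series.values - base.mean[:, :, None]) / base.std[:, :, None]
    out = transform(z)
    out = 0.5 * (out + np.swapaxes(out, 0, 1))
    idx = np.arange(series.n_nodes)
    out[idx, idx, :] = 0.0
    return ConnectivitySeries(
        out,
        series.band,
        series.window_s,
        series.overlap,
        series.t0.copy(),
        series.metric,
        list(series.labels),
        normalized=True,
    )
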