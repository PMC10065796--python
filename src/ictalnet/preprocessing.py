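"""Bipolar montage and zero-delay filtering.

The preprocessing chain mirrors standard SEEG practice: adjacent same-shaft
contacts are subtracted to form bipolar channels (suppressing volume-conducted
common-mode activity), the DC offset is removed, a linear-phase Kaiser-window
FIR band-pass (3-200 Hz) is applied with its group delay compensated, and
line noise at 60/120/180 Hz is removed with zero-phase recursive notches.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .recording import ChannelInfo, Recording

__all__ = [
    "bipolar_montage",
    "preprocess",
    "bandpass_band",
    "design_fir_bandpass",
]

#: Kaiser design targets reproducing the reference filter length at 1 kHz.
FIR_RIPPLE_DB = 60.0
FIR_TRANSITION_HZ = 0.5
#: Wider transition for the narrower per-band filters.
BAND_TRANSITION_HZ = 2.0

NOTCH_FREQS_HZ = (60.0, 120.0, 180.0)
NOTCH_BW_HZ = 1.0


def bipolar_montage(rec: Recording) -> Recording:
    """Build the adjacent-pair bipolar montage.

    One output channel per pair of same-shaft contacts with consecutive
    contact indices, ``data = contact_i - contact_{i+1}``.  A pair is kept
    only if both parents lie in gray matter; the bipolar resection flag is
    true only when both parents are resected.
    """
    if any(c.bipolar for c in rec.channels):
        raise ValueError("input already bipolar; montage cannot be re-applied")
    by_shaft: dict[str, list[int]] = {}
    for idx, ch in enumerate(rec.channels):
        by_shaft.setdefault(ch.shaft, []).append(idx)

    rows = []
    chans = []
    for shaft, idxs in by_shaft.items():
        idxs = sorted(idxs, key=lambda i: rec.channels[i].contact_index)
        for a, b in zip(idxs[:-1], idxs[1:]):
            ca, cb = rec.channels[a], rec.channels[b]
            if cb.contact_index != ca.contact_index + 1:
                continue  # gap in the shaft
            if not (ca.gray_matter and cb.gray_matter):
                continue
            rows.append(rec.data[a] - rec.data[b])
            chans.append(
                ChannelInfo(
                    label=f"{ca.label}-{cb.label}",
                    shaft=shaft,
                    contact_index=ca.contact_index,
                    gray_matter=True,
                    resected=ca.resected and cb.resected,
                    bipolar=True,
                )
            )
    if not rows:
        raise ValueError("bipolar montage produced no channels")
    return Recording(np.asarray(rows), rec.fs, chans, list(rec.annotations))


def design_fir_bandpass(
    band: tuple[float, float],
    fs: float,
    transition_hz: float = FIR_TRANSITION_HZ,
    ripple_db: float = FIR_RIPPLE_DB,
) -> np.ndarray:
    """Design an odd-length linear-phase Kaiser-window FIR band-pass.

    The order is derived from a fixed transition-width/ripple specification so
    it scales with the sampling rate rather than being hard-coded.
    """
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi:
        raise ValueError(f"invalid band {band}")
    if f_hi >= fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist for fs={fs}")
    numtaps, beta = signal.kaiserord(ripple_db, transition_hz * 2.0 / fs)
    numtaps |= 1  # odd length -> integer group delay, type-I linear phase
    return signal.firwin(
        numtaps, [f_lo, f_hi], window=("kaiser", beta), pass_zero=False, fs=fs
    )


def _fir_zero_delay(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR and shift out its group delay."""
    delay = (len(taps) - 1) // 2
    n = data.shape[-1]
    full = signal.oaconvolve(data, taps[None, :], axes=-1)
    return full[..., delay : delay + n]


def _notch_sos(f0: float, fs: float, bw_hz: float = NOTCH_BW_HZ) -> np.ndarray:
    lo, hi = f0 - bw_hz / 2.0, f0 + bw_hz / 2.0
    return signal.butter(3, [lo, hi], btype="bandstop", fs=fs, output="sos")


def preprocess(
    rec: Recording,
    band: tuple[float, float] = (3.0, 200.0),
    notch_freqs: tuple[float, ...] = NOTCH_FREQS_HZ,
) -> Recording:
    """DC removal, 3-200 Hz zero-delay FIR band-pass and line-noise notches.

    The notch is an order-6 recursive band-stop of 1 Hz bandwidth applied
    forward-backward (zero phase); notch frequencies above Nyquist are
    skipped (e.g. 180 Hz at fs=500 is inside the band and kept).
    """
    if rec.fs <= 2 * band[1]:
        raise ValueError(
            f"fs={rec.fs} too low for a {band[1]} Hz band edge (needs fs > {2*band[1]})"
        )
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    taps = design_fir_bandpass(band, rec.fs)
    data = _fir_zero_delay(data, taps)
    for f0 in notch_freqs:
        if f0 + NOTCH_BW_HZ / 2.0 >= rec.fs / 2:
            continue
        sos = _notch_sos(f0, rec.fs)
        data = signal.sosfiltfilt(sos, data, axis=-1)
    return rec.copy_with(data=data)


def bandpass_band(
    rec: Recording,
    band: tuple[float, float],
    transition_hz: float = BAND_TRANSITION_HZ,
) -> Recording:
    """Zero-delay linear-phase FIR band-limited copy (e.g. 80-140 Hz)."""
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi < rec.fs / 2:
        raise ValueError(f"invalid band {band} for fs={rec.fs}")
    taps = design_fir_bandpass(band, rec.fs, transition_hz=transition_hz)
    return rec.copy_with(data=_fir_zero_delay(rec.data, taps))
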