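"""Shared fixtures: tiny synthetic recordings and a minimal EDF writer."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from ictalnet import pipeline
from ictalnet.recording import ChannelInfo, Recording, SeizureAnnotation
from ictalnet.synthetic import SimConfig, simulate_recording


def write_edf16(path: Path, data: np.ndarray, fs: float, labels: list[str]) -> Path:
    """Write a minimal 16-bit EDF file (one data record)."""
    data = np.asarray(data, dtype=float)
    n_sig, n_samp = data.shape
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    duration = n_samp / fs

    def pad(text, width):
        s = str(text)[:width]
        return s + " " * (width - len(s))

    header = "".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2020 X X X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(256 * (n_sig + 1), 8),
            pad("", 44),
            pad(1, 8),
            pad(f"{duration:g}", 8),
            pad(n_sig, 4),
        ]
    )
    for field, width in [
        (labels, 16),
        (["" for _ in labels], 80),
        (["uV" for _ in labels], 8),
        ([f"{phys_min:g}" for _ in labels], 8),
        ([f"{phys_max:g}" for _ in labels], 8),
        ([str(dig_min) for _ in labels], 8),
        ([str(dig_max) for _ in labels], 8),
        (["" for _ in labels], 80),
        ([str(n_samp) for _ in labels], 8),
        (["" for _ in labels], 32),
    ]:
        header += "".join(pad(v, width) for v in field)
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip((data - phys_min) * gain + dig_min, dig_min, dig_max)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(digital.astype("<i2").tobytes())
    return path


def tiny_unipolar_recording(fs: float = 500.0, seconds: float = 2.0) -> Recording:
    """Deterministic 2-shaft, 3-contact recording for montage tests."""
    rng = np.random.default_rng(0)
    n = int(fs * seconds)
    data = rng.standard_normal((6, n))
    chans = [
        ChannelInfo("A1", "A", 0), ChannelInfo("A2", "A", 1), ChannelInfo("A3", "A", 2),
        ChannelInfo("B1", "B", 0), ChannelInfo("B2", "B", 1), ChannelInfo("B3", "B", 2),
    ]
    return Recording(data, fs, chans)


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated seizure, shared across tests."""
    cfg = SimConfig(seizure_s=20.0, preictal_s=30.0, postictal_s=8.0, seed=7)
    rec, truth = simulate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def sim_prepared(sim_small):
    """The same recording after montage + preprocessing."""
    _, rec, truth = sim_small
    return pipeline.prepare_recording(rec), truth


@pytest.fixture(scope="session")
def hf_series(sim_prepared):
    """Normalized 80-140 Hz lagged-coherence stack of the shared recording."""
    rec, truth = sim_prepared
    return pipeline.normalized_band_series(rec, (80.0, 140.0)), truth
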