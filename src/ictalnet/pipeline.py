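"""End-to-end orchestration: recording -> networks -> EZ -> states -> dynamics.

These helpers chain the library modules at the standard parameter values
(2.5 s windows, 80%/90% overlap, 80-140 / 140-200 / 3-50 Hz bands,
c in {1..10, 15}, d in {0.1..0.8}) and are what the CLI, the examples and the
acceptance analyses call.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import regional as reg
from .connectivity import (
    HF_OVERLAP,
    LF_OVERLAP,
    WINDOW_S,
    ConnectivitySeries,
    baseline_normalize,
    compute_baseline,
    compute_connectivity_series,
)
from .ezdetect import (
    DEFAULT_C_GRID,
    DEFAULT_D_GRID,
    ConsensusResult,
    detect_ez,
    evaluate_vs_resection,
)
from .preprocessing import bandpass_band, bipolar_montage, preprocess
from .recording import Recording
from .synthetic import SimulatedSeizure

__all__ = [
    "HF_BANDS",
    "LF_BAND",
    "prepare_recording",
    "normalized_band_series",
    "seizure_layers",
    "detection_inputs",
    "run_ez_detection",
    "regional_interval_table",
    "PatientResult",
]

HF_BANDS = ((80.0, 140.0), (140.0, 200.0))
LF_BAND = (3.0, 50.0)
BASELINE_S = 60.0  # pre-ictal baseline length (clipped to what exists)
BASELINE_GAP_S = 5.0  # baseline ends this long before onset


def prepare_recording(rec: Recording) -> Recording:
    """Bipolar montage followed by the standard preprocessing filters."""
    return preprocess(bipolar_montage(rec))


def _baseline_mask(series: ConnectivitySeries, onset_s: float) -> np.ndarray:
    half = series.window_s / 2.0
    hi = onset_s - BASELINE_GAP_S
    lo = max(0.0, hi - BASELINE_S)
    return (series.t0 - half >= lo) & (series.t0 + half <= hi)


def normalized_band_series(
    rec_pre: Recording,
    band: tuple[float, float],
    metric: str = "lagged_coherence",
    overlap: float = HF_OVERLAP,
    window_s: float = WINDOW_S,
) -> ConnectivitySeries:
    """Band-limit, window, and baseline-normalize a preprocessed recording.

    The baseline is the per-edge mean/std over pre-ictal windows ending
    5 s before the (first) annotated onset.
    """
    if not rec_pre.annotations:
        raise ValueError("recording has no seizure annotation")
    onset_s = rec_pre.annotations[0].onset_sample / rec_pre.fs
    brec = bandpass_band(rec_pre, band)
    raw = compute_connectivity_series(brec, band, metric, window_s, overlap)
    mask = _baseline_mask(raw, onset_s)
    if mask.sum() < 2:
        raise ValueError("not enough pre-ictal windows for a baseline")
    base = compute_baseline(raw.select_layers(mask))
    return baseline_normalize(raw, base)


def seizure_layers(series: ConnectivitySeries, onset_s: float, term_s: float) -> ConnectivitySeries:
    """Windows fully contained in [onset, termination]."""
    half = series.window_s / 2.0
    mask = (series.t0 - half >= onset_s) & (series.t0 + half <= term_s)
    if not mask.any():
        raise ValueError("no windows inside the seizure")
    return series.select_layers(mask)


def detection_inputs(sims: list[SimulatedSeizure]) -> dict:
    """Seizure-major, band-minor map of normalized ictal HF stacks.

    Returns ``(series_by_key, prepared)`` where ``prepared`` maps seizure id
    to the preprocessed bipolar recording.
    """
    series_by_key: dict = {}
    prepared: dict = {}
    for sim in sims:
        rec = prepare_recording(sim.recording)
        prepared[sim.seizure_id] = rec
        ann = rec.annotations[0]
        onset_s, term_s = ann.onset_sample / rec.fs, ann.termination_sample / rec.fs
        for band in HF_BANDS:
            norm = normalized_band_series(rec, band)
            series_by_key[(sim.seizure_id, band)] = seizure_layers(norm, onset_s, term_s)
    return series_by_key, prepared


@dataclass
class PatientResult:
    consensus: ConsensusResult
    categories: list[str]
    detected: bool
    fpr: float | None
    sensitivity: float | None = None


def run_ez_detection(
    sims: list[SimulatedSeizure],
    c_grid=DEFAULT_C_GRID,
    d_grid=DEFAULT_D_GRID,
    seed: int = 0,
) -> PatientResult:
    """Full consensus EZ detection for one patient's seizures, evaluated
    against the resection flags carried by the bipolar channels."""
    series_by_key, prepared = detection_inputs(sims)
    result = detect_ez(series_by_key, c_grid, d_grid, seed=seed)
    any_rec = next(iter(prepared.values()))
    resected = np.array([c.resected for c in any_rec.channels])
    report = evaluate_vs_resection(result, resected)
    truth_ez = set(sims[0].truth.ez_bipolar)
    predicted = set(np.asarray(result.labels)[result.ez_nodes]) if result.labels else set()
    sens = len(predicted & truth_ez) / len(truth_ez) if truth_ez else None
    return PatientResult(result, report.categories, report.detected, report.fpr, sens)


def regional_interval_table(
    sims: list[SimulatedSeizure],
    bands=HF_BANDS,
    metric: str = "lagged_coherence",
    overlap: float = HF_OVERLAP,
    periods=reg.HF_PERIODS,
    categories_by_seizure: dict | None = None,
    subtract_preictal_grand_mean: bool = False,
) -> pd.DataFrame:
    """Interval means of the three regional measures across a cohort.

    Categories default to the planted ground truth; pass
    ``categories_by_seizure`` to use predicted-EZ categories instead.
    Returns one row per (seizure, band, measure, period); with
    ``subtract_preictal_grand_mean`` the per-seizure/band pre-ictal grand
    mean over all node pairs is removed from every value.
    """
    tables = []
    for sim in sims:
        rec = prepare_recording(sim.recording)
        ann = rec.annotations[0]
        onset_s = ann.onset_sample / rec.fs
        term_s = ann.termination_sample / rec.fs
        if categories_by_seizure is not None:
            cats = categories_by_seizure[sim.seizure_id]
        else:
            cats = sim.truth.categories(rec.labels)
        key = f"{sim.patient_id}/{sim.seizure_id}"
        for band in bands:
            norm = normalized_band_series(rec, band, metric=metric, overlap=overlap)
            trace = reg.regional_traces(norm, cats, seizure_id=key)
            trace = reg.to_unit_time(trace, onset_s, term_s)
            table = reg.interval_means(trace, periods)
            if subtract_preictal_grand_mean:
                t_norm_full = (norm.t0 - onset_s) / (term_s - onset_s)
                gm = reg.grand_mean_connectivity(norm, t_norm_full, periods["pre-ictal"])
                table = reg.normalize_to_grand_mean(table, gm)
            table["patient_id"] = sim.patient_id
            table["age"] = sim.age
            table["epilepsy_duration"] = sim.epilepsy_duration
            tables.append(table)
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# artifact store for the CLI


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_provenance(out_dir: Path, stage: str, cfg: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = {"stage": stage, "config_hash": config_hash(cfg), "config": cfg}
    (out_dir / f"{stage}.provenance.json").write_text(json.dumps(rec, indent=1, default=str))


def require_artifact(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the `{producer}` command first"
        )
    return path
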