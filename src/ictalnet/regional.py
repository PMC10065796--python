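"""Regional connectivity dynamics across the normalized seizure axis.

Nodes are grouped as predicted EZ, resected-non-EZ (RnEZ) and non-resected
(nR); three synchrony traces — EZ-nR, RnEZ-nR and nR-nR — average the
normalized connectivity over all cross-group (and distinct within-nR) node
pairs per window.  Seizure time is rescaled so onset maps to 0 and
termination to 1; interval statistics are taken over fixed fractions of the
seizure length L (high-frequency: pre-ictal (-0.3,-0.1)L, mid-seizure
(0.3,0.5)L, post-ictal (1,1.2)L; low-frequency: pre-ictal, early-seizure
(0,0.2)L, pre-termination (0.8,1)L), and the J = 18 pairwise comparisons
(3 measure pairs x 3 periods + 3 period pairs x 3 measures) are tested with
the paired percentile bootstrap of the one-step M-estimator under a Hochberg
step-up correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivitySeries
from .robust import (
    RobustTestResult,
    bootstrap_regression,
    hochberg,
    outlier_filter,
    paired_percentile_bootstrap,
)

__all__ = [
    "RegionalTrace",
    "HF_PERIODS",
    "LF_PERIODS",
    "MEASURES",
    "regional_traces",
    "to_unit_time",
    "interval_means",
    "grand_mean_connectivity",
    "normalize_to_grand_mean",
    "resample_unit_grid",
    "pairwise_comparisons",
    "build_comparison_family",
    "robust_regression",
    "hysteresis_correlation",
]

MEASURES = ("EZ-nR", "RnEZ-nR", "nR-nR")
HF_PERIODS = {"pre-ictal": (-0.3, -0.1), "mid-seizure": (0.3, 0.5), "post-ictal": (1.0, 1.2)}
LF_PERIODS = {"pre-ictal": (-0.3, -0.1), "early-seizure": (0.0, 0.2), "pre-termination": (0.8, 1.0)}
UNIT_GRID = np.linspace(-0.3, 1.2, 151)


@dataclass
class RegionalTrace:
    """The three regional synchrony time series for one seizure/band."""

    values: dict  # measure -> 1-D array (may be missing if a group is empty)
    t0: np.ndarray  # window-center times (s)
    t_norm: np.ndarray | None = None  # normalized seizure time per window
    seizure_id: str = ""
    band: tuple[float, float] | None = None
    L: float | None = None  # seizure length (s)


def _pair_mean(values: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Mean over the rows x cols edge set for every layer."""
    sub = values[np.ix_(rows, cols)]
    return sub.mean(axis=(0, 1))


def regional_traces(
    series: ConnectivitySeries,
    categories,
    seizure_id: str = "",
) -> RegionalTrace:
    """EZ-nR / RnEZ-nR / nR-nR per-window mean connectivity.

    ``categories`` is a length-N sequence over {'EZ', 'RnEZ', 'nR'} (predicted
    EZ with false positives already removed).  A measure whose group is empty
    is omitted from the result with a warning.
    """
    cats = np.asarray(list(categories))
    if len(cats) != series.n_nodes:
        raise ValueError("categories length must match node count")
    ez = np.flatnonzero(cats == "EZ")
    rnez = np.flatnonzero(cats == "RnEZ")
    nr = np.flatnonzero(cats == "nR")
    out = {}
    if len(nr) == 0:
        raise ValueError("no non-resected nodes; regional measures undefined")
    if len(ez):
        out["EZ-nR"] = _pair_mean(series.values, ez, nr)
    else:
        warnings.warn("empty EZ group; EZ-nR undefined")
    if len(rnez):
        out["RnEZ-nR"] = _pair_mean(series.values, rnez, nr)
    else:
        warnings.warn("empty RnEZ group; RnEZ-nR undefined")
    if len(nr) >= 2:
        iu = np.triu_indices(len(nr), k=1)
        sub = series.values[np.ix_(nr, nr)]
        out["nR-nR"] = sub[iu].mean(axis=0)
    return RegionalTrace(out, series.t0.copy(), None, seizure_id, series.band)


def to_unit_time(trace: RegionalTrace, onset_s: float, termination_s: float) -> RegionalTrace:
    """Map window-center times onto the normalized seizure axis.

    Onset maps to 0, termination to 1; L = termination - onset.  Windows are
    kept on [-0.3, 1.2]; insufficient pre/post context truncates with a
    warning.
    """
    L = termination_s - onset_s
    if L <= 0:
        raise ValueError("termination must follow onset")
    t_norm = (trace.t0 - onset_s) / L
    mask = (t_norm >= -0.3) & (t_norm <= 1.2)
    if t_norm.min() > -0.3 + 1e-9 or t_norm.max() < 1.2 - 1e-9:
        warnings.warn(
            f"trace covers [{t_norm.min():.2f}, {t_norm.max():.2f}] of [-0.3, 1.2]"
        )
    return RegionalTrace(
        {k: v[mask] for k, v in trace.values.items()},
        trace.t0[mask],
        t_norm[mask],
        trace.seizure_id,
        trace.band,
        L,
    )


def resample_unit_grid(trace: RegionalTrace, grid: np.ndarray = UNIT_GRID) -> dict:
    """Linear interpolation of each measure onto a common normalized grid."""
    if trace.t_norm is None:
        raise ValueError("call to_unit_time first")
    return {k: np.interp(grid, trace.t_norm, v) for k, v in trace.values.items()}


def interval_means(trace: RegionalTrace, periods: dict) -> pd.DataFrame:
    """Mean of each measure over each half-open normalized interval [a, b)."""
    if trace.t_norm is None:
        raise ValueError("call to_unit_time first")
    rows = []
    for period, (a, b) in periods.items():
        sel = (trace.t_norm >= a) & (trace.t_norm < b)
        if not sel.any():
            raise ValueError(f"no samples inside period {period} {a, b}")
        for measure, v in trace.values.items():
            rows.append(
                {
                    "seizure_id": trace.seizure_id,
                    "band": trace.band,
                    "measure": measure,
                    "period": period,
                    "value": float(v[sel].mean()),
                    "n": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


def grand_mean_connectivity(
    series: ConnectivitySeries, t_norm: np.ndarray, period: tuple[float, float]
) -> float:
    """Average synchrony between all distinct node pairs inside a period."""
    a, b = period
    sel = (t_norm >= a) & (t_norm < b)
    if not sel.any():
        raise ValueError(f"no windows inside period {period}")
    iu = np.triu_indices(series.n_nodes, k=1)
    return float(series.values[:, :, sel][iu].mean())


def normalize_to_grand_mean(summary: pd.DataFrame, grand_mean: float) -> pd.DataFrame:
    """Subtract a grand-mean synchrony level from interval values."""
    out = summary.copy()
    out["value"] = out["value"] - grand_mean
    return out


def build_comparison_family(periods=("pre-ictal", "mid-seizure", "post-ictal")):
    """The J = 18 family: 3 measure pairs per period + 3 period pairs per measure."""
    family = []
    measure_pairs = [(MEASURES[0], MEASURES[1]), (MEASURES[0], MEASURES[2]), (MEASURES[1], MEASURES[2])]
    for period in periods:
        for m1, m2 in measure_pairs:
            family.append(("measure", period, m1, m2))
    period_pairs = [(periods[0], periods[1]), (periods[0], periods[2]), (periods[1], periods[2])]
    for measure in MEASURES:
        for p1, p2 in period_pairs:
            family.append(("period", measure, p1, p2))
    return family


def pairwise_comparisons(
    table: pd.DataFrame,
    periods=("pre-ictal", "mid-seizure", "post-ictal"),
    B: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the J = 18 paired robust bootstrap comparisons with Hochberg FDR.

    ``table`` holds one row per (seizure_id, band, measure, period) with a
    ``value`` column; seizure x band rows are the paired observations.
    """
    piv = table.pivot_table(
        index=["seizure_id", "band"], columns=["measure", "period"], values="value"
    )
    family = build_comparison_family(periods)
    results: list[RobustTestResult] = []
    rng = np.random.default_rng(seed)
    for kind, fixed, a, b in family:
        if kind == "measure":
            x = piv[(a, fixed)].to_numpy()
            y = piv[(b, fixed)].to_numpy()
            name = f"{a} vs {b} @ {fixed}"
        else:
            x = piv[(fixed, a)].to_numpy()
            y = piv[(fixed, b)].to_numpy()
            name = f"{a} vs {b} @ {fixed}"
        res = paired_percentile_bootstrap(
            x, y, B=B, seed=int(rng.integers(2**31 - 1)), comparison=name
        )
        results.append(res)
    p_adj = hochberg([r.p_raw for r in results])
    rows = []
    for res, pa in zip(results, p_adj):
        rows.append(
            {
                "comparison": res.comparison,
                "estimate": res.estimate,
                "p_raw": res.p_raw,
                "p_hochberg": float(pa),
                "B": res.B,
            }
        )
    return pd.DataFrame(rows)


def robust_regression(x, y, B: int = 10_000, seed: int = 0):
    """Bootstrap Theil-Sen regression of normalized synchrony on a predictor."""
    return bootstrap_regression(np.asarray(x), np.asarray(y), B=B, seed=seed)


def hysteresis_correlation(
    lf_preterm: np.ndarray,
    hf_postictal: np.ndarray,
    B: int = 10_000,
    seed: int = 0,
):
    """Pre-termination low-frequency vs post-ictal high-frequency association.

    Per-seizure values (high-frequency averaged over its two bands) are
    trimmed with the projection outlier rule, then regressed with the
    bootstrap Theil-Sen estimator.  Returns ``(RegressionResult, keep_mask)``.
    """
    pts = np.column_stack([lf_preterm, hf_postictal])
    keep = outlier_filter(pts, rule="projection")
    res = bootstrap_regression(pts[keep, 0], pts[keep, 1], B=B, seed=seed)
    return res, keep
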