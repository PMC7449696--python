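"""Chaperone-induction kinetics.

The single-cell readout of the heat shock response is Ssa4 (an inducible
Hsp70) tagged with mCherry.  Per timepoint of recovery, induction is
summarized as the median over gated labeled cells of red fluorescence divided
by forward scatter (a per-cell size normalization), expressed as a fold change
over the same statistic in unstressed cells from the same experiment — so an
unstressed sample sits at fold change 1 by construction.

The fold-change time course is fitted, in the log domain, with a constrained
four-parameter logistic

    fold(t) = a / (1 + exp(-b * (t - c))) + d,   d >= 1

whose midpoint ``c`` (min) is the induction delay — the quantity that shifts
when intracellular acidification during shock is prevented.  Continuous-flow
pH traces are smoothed with a centered sliding-window average; the centered
window means an apparent pre-shock drift appears at sharp transitions, a
smoothing artifact callers should expect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "InductionCurve",
    "InductionFit",
    "induction_model",
    "fold_change_curve",
    "fit_induction",
    "induction_delay",
    "sliding_window",
]

MIN_CELLS_DEFAULT = 1000
NO_INDUCTION_FLOOR = 0.05  # amplitude below which a fit is flagged "no induction"


def induction_model(t, a, b, c, d):
    """Constrained logistic fold-change model, vectorized over time (min)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        return a / (1.0 + np.exp(-b * (t - c))) + d


@dataclass
class InductionCurve:
    """Fold change (relative to unstressed) per recovery timepoint."""

    timepoints: np.ndarray  # min, strictly increasing
    fold_change: np.ndarray
    n_cells: np.ndarray
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.fold_change = np.asarray(self.fold_change, dtype=float)
        self.n_cells = np.asarray(self.n_cells, dtype=int)
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if (self.fold_change < 0).any():
            raise ValueError("fold change cannot be negative")


@dataclass
class InductionFit:
    a: float
    b: float
    c: float
    d: float
    rss: float  # in the log domain the fit is performed in
    converged: bool
    no_induction: bool = False

    def predict(self, t):
        return induction_model(t, self.a, self.b, self.c, self.d)


def _median_red_per_fsc(events: pd.DataFrame, per_cell: bool) -> float:
    red = events["ch_red"].to_numpy(float)
    fsc = events["fsc_area"].to_numpy(float)
    if per_cell:
        return float(np.median(red / fsc))
    return float(np.median(red) / np.median(fsc))


def fold_change_curve(
    timecourse: pd.DataFrame,
    baseline: pd.DataFrame,
    per_cell_ratio: bool = True,
    min_cells: int = MIN_CELLS_DEFAULT,
    time_column: str = "timepoint_min",
) -> InductionCurve:
    """Median red-per-FSC fold change over baseline, per timepoint.

    ``timecourse`` holds gated, strain-split events for every recovery
    timepoint (``time_column`` distinguishes them); ``baseline`` holds
    unstressed cells acquired in the same experiment at the same detector
    voltages.  ``per_cell_ratio`` selects median-of-(red/FSC) (default) vs
    ratio-of-medians; the two agree whenever red and FSC differ by a scale
    family.  Timepoints with fewer than ``min_cells`` cells are refused —
    medians over thin samples are not comparable across the curve.
    """
    base_stat = _median_red_per_fsc(baseline, per_cell_ratio)
    if not np.isfinite(base_stat) or base_stat <= 0:
        raise ValueError(f"baseline red/FSC statistic must be positive, got {base_stat}")
    times, folds, counts = [], [], []
    for t, group in timecourse.groupby(time_column, sort=True):
        n = len(group)
        if n < min_cells:
            raise ValueError(
                f"timepoint {t}: {n} cells < required minimum {min_cells}"
            )
        times.append(float(t))
        folds.append(_median_red_per_fsc(group, per_cell_ratio) / base_stat)
        counts.append(n)
    if not times:
        raise ValueError("timecourse contains no timepoints")
    return InductionCurve(np.array(times), np.array(folds), np.array(counts))


def fit_induction(
    curve: InductionCurve,
    min_points: int = 5,
    fold_floor: float = 1e-6,
) -> InductionFit:
    """Fit the constrained logistic to log fold change.

    Fluorescence fold changes are multiplicative, so residuals are taken
    between log(model) and log(data); the baseline parameter is box-
    constrained to d >= 1 (an uninduced population cannot sit below its own
    unstressed reference).  Four deterministic starts; best RSS wins.  A
    fitted amplitude below ``NO_INDUCTION_FLOOR`` flags the curve as flat.
    """
    t = curve.timepoints
    y = curve.fold_change
    if len(t) < min_points:
        raise ValueError(f"{len(t)} timepoints < required {min_points} for a 4-parameter fit")
    n_floored = int((y <= fold_floor).sum())
    logy = np.log(np.maximum(y, fold_floor))

    def residuals(theta):
        return np.log(np.maximum(induction_model(t, *theta), fold_floor)) - logy

    span = float(t.max() - t.min())
    amp0 = max(float(y.max() - y.min()), 1e-3)
    lower = np.array([0.0, 1e-4, t.min() - span, 1.0])
    upper = np.array([np.inf, 1.0, t.max() + span, np.inf])
    starts = [
        np.array([amp0, 4.0 / max(span, 1.0), float(np.median(t)), 1.0]),
        np.array([amp0, 0.05, float(np.quantile(t, 0.25)), 1.0]),
        np.array([amp0, 0.05, float(np.quantile(t, 0.75)), 1.0]),
        np.array([amp0, 0.2, float(np.median(t)), max(float(y.min()), 1.0)]),
    ]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lower + 1e-9, None)
        try:
            sol = optimize.least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol.x, rss)
    if best is None:
        raise RuntimeError("induction fit failed to converge from every start")
    a, b, c, d = (float(v) for v in best[0])
    fit = InductionFit(a=a, b=b, c=c, d=d, rss=best[1], converged=True,
                       no_induction=a < NO_INDUCTION_FLOOR)
    fit.n_floored = n_floored  # type: ignore[attr-defined]
    return fit


def induction_delay(fit: InductionFit) -> float:
    """Induction delay = midpoint of the fitted logistic, in minutes.

    A flat ("no induction") curve has no midpoint; NaN is returned.
    """
    if fit.no_induction or not fit.converged:
        return float("nan")
    return float(fit.c)


def sliding_window(
    t: np.ndarray,
    y: np.ndarray,
    window: float,
    by_count: bool = False,
) -> np.ndarray:
    """Centered moving average of an event-time series.

    ``window`` is a full width in minutes (default) or in events
    (``by_count``).  Edge points average over the truncated window.  Because
    the window is centered, a sharp step is smeared symmetrically into a ramp
    of the window's width — including *before* the step.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    order = np.argsort(t, kind="stable")
    ts, ys = t[order], y[order]
    csum = np.concatenate([[0.0], np.cumsum(ys)])
    if by_count:
        half = max(int(window) // 2, 0)
        idx = np.arange(len(ts))
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, len(ts))
    else:
        lo = np.searchsorted(ts, ts - window / 2.0, side="left")
        hi = np.searchsorted(ts, ts + window / 2.0, side="right")
    smooth_sorted = (csum[hi] - csum[lo]) / (hi - lo)
    out = np.empty_like(smooth_sorted)
    out[order] = smooth_sorted
    return out
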