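"""Competitive-fitness estimation from labeled:spike-in count ratios.

A stressed, fluorescently labeled population is mixed with unlabeled,
exponentially growing reference ("spike-in") cells and followed by flow
cytometry.  Under constant exponential growth the log count ratio is linear in
time:

    ln[ (n_lab(t) / n_ref(t)) * (n_ref(0) / n_lab(0)) ] = (r_lab - r_ref) * t

so the slope of an ordinary least-squares line through the log-ratio series is
the growth-rate difference — the selection coefficient.  Only the early,
linear portion of recovery is fitted (default windows: 100 min for untreated
cells, 160 min with ionophore treatment, whose induction is delayed).

Two controls correct the raw slope: a mix-in control (both strains treated
identically) isolates the strain-label effect, and a mock control (treatment
without heat) isolates the treatment effect; both are subtracted in rate
space, which for exponential growth composes additively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GrowthSeries",
    "FitnessEstimate",
    "log_ratio_series",
    "fit_growth_difference",
    "apply_corrections",
    "relative_to_arrest",
    "WINDOW_UNTREATED_MIN",
    "WINDOW_IONOPHORE_MIN",
]

WINDOW_UNTREATED_MIN = 100.0
WINDOW_IONOPHORE_MIN = 160.0


@dataclass
class GrowthSeries:
    """Labeled and spike-in event counts per timepoint of one competition."""

    timepoints: np.ndarray  # min
    n_labeled: np.ndarray
    n_spike: np.ndarray
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.n_labeled = np.asarray(self.n_labeled, dtype=float)
        self.n_spike = np.asarray(self.n_spike, dtype=float)
        if not (len(self.timepoints) == len(self.n_labeled) == len(self.n_spike)):
            raise ValueError("timepoints and count arrays must have equal length")
        if (self.n_labeled < 0).any() or (self.n_spike < 0).any():
            raise ValueError("event counts must be non-negative")


@dataclass
class FitnessEstimate:
    """Slope (r_labeled - r_ref, 1/min) with its SE and correction provenance."""

    slope: float
    stderr: float
    window: float
    n_points: int
    intercept: float = 0.0
    corrections: dict = field(default_factory=dict)
    curvature_warning: bool = False


def log_ratio_series(series: GrowthSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint y(t) = ln[(n_lab(t)/n_ref(t)) * (n_ref(0)/n_lab(0))].

    Timepoints where either count is zero carry no ratio information and are
    dropped (no pseudocounts); the drop count is recorded nowhere silently —
    callers get only the retained points, and fewer than 3 retained points is
    an error.
    """
    t = series.timepoints
    order = np.argsort(t)
    t, nl, ns = t[order], series.n_labeled[order], series.n_spike[order]
    if nl[0] <= 0 or ns[0] <= 0:
        raise ValueError("initial labeled and spike counts must both be positive")
    keep = (nl > 0) & (ns > 0)
    t, nl, ns = t[keep], nl[keep], ns[keep]
    if len(t) < 3:
        raise ValueError(f"only {len(t)} timepoints with nonzero counts; need >= 3")
    y = np.log((nl / ns) * (ns[0] / nl[0]))
    return t, y


def fit_growth_difference(
    t: np.ndarray,
    y: np.ndarray,
    window: float = WINDOW_UNTREATED_MIN,
    curvature_tol: float = 2.0,
) -> FitnessEstimate:
    """OLS slope of the log-ratio series restricted to t <= window.

    The intercept is free (it absorbs the initial mixing fraction, which the
    slope is invariant to).  As a linearity check, the per-point RSS of a fit
    over the full series is compared with the windowed fit; a ratio above
    ``curvature_tol`` sets ``curvature_warning``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if window <= 0:
        raise ValueError(f"fitting window must be positive, got {window}")
    inside = t <= window
    if inside.sum() < 3:
        raise ValueError(
            f"window {window} min retains {int(inside.sum())} points; need >= 3"
        )
    res = stats.linregress(t[inside], y[inside])
    warn = False
    if inside.sum() < len(t):
        full = stats.linregress(t, y)
        rss_w = np.mean((y[inside] - (res.intercept + res.slope * t[inside])) ** 2)
        rss_f = np.mean((y - (full.intercept + full.slope * t)) ** 2)
        if rss_w > 0 and rss_f / rss_w > curvature_tol:
            warn = True
    return FitnessEstimate(
        slope=float(res.slope),
        stderr=float(res.stderr) if np.isfinite(res.stderr) else np.nan,
        window=float(window),
        n_points=int(inside.sum()),
        intercept=float(res.intercept),
        curvature_warning=warn,
    )


def apply_corrections(
    raw: FitnessEstimate,
    mock: FitnessEstimate | None = None,
    mixin: FitnessEstimate | None = None,
) -> FitnessEstimate:
    """Subtract control slopes from the raw selection coefficient.

    corrected = raw - mixin - (mock - mixin) = raw - mock, where the mix-in
    slope is the strain-label bias and (mock - mixin) the treatment-only
    effect.  With only one control supplied, that component alone is removed.
    All estimates must share the fitting window.
    """
    slope = raw.slope
    corrections: dict[str, float] = {}
    for name, est in (("mock", mock), ("mixin", mixin)):
        if est is not None and est.window != raw.window:
            raise ValueError(
                f"{name} control fitted with window {est.window}, raw used {raw.window}"
            )
    mixin_slope = mixin.slope if mixin is not None else 0.0
    mock_slope = mock.slope if mock is not None else mixin_slope
    corrections["mixin"] = mixin_slope
    corrections["treatment"] = mock_slope - mixin_slope
    slope = raw.slope - mixin_slope - (mock_slope - mixin_slope)
    return FitnessEstimate(
        slope=float(slope),
        stderr=raw.stderr,
        window=raw.window,
        n_points=raw.n_points,
        intercept=raw.intercept,
        corrections=corrections,
        curvature_warning=raw.curvature_warning,
    )


def relative_to_arrest(est: FitnessEstimate, r_ref: float) -> float:
    """Express the slope as distance from complete growth arrest.

    A fully arrested labeled population has r_lab = 0, i.e. slope = -r_ref;
    subtracting that bound maps arrest to 0 and matched growth to r_ref.  The
    reference's absolute rate r_ref is e.g. ln(2)/70 per min for diploid cells
    doubling every 70 min.
    """
    if r_ref <= 0:
        raise ValueError(f"reference growth rate must be positive, got {r_ref}")
    return float(est.slope + r_ref)
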