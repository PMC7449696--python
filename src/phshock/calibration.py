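"""Ratiometric pHluorin calibration.

pHluorin is a GFP variant whose excitation spectrum shifts with pH: the ratio R
of fluorescence excited at 405 nm to fluorescence excited at 488 nm is a
monotone function of pH.  Cells equilibrated in buffers of known pH (with an
ionophore collapsing the membrane proton gradient) give one background-corrected
median ratio per buffer, and those points are fitted to a four-parameter
logistic

    R(pH) = a / (1 + exp(-b * (pH - c))) + d

with span ``a``, steepness ``b`` (1/pH), midpoint ``c`` (pH units) and offset
``d``.  The effective pKa of the sensor is the pH at which R is midway between
its asymptotes ``R_min`` and ``R_max``, i.e. the root of
``log((R - R_max) / (R_min - R)) = 0``; analytically this is ``c``, and the
numeric root-finder is kept as a cross-check.  Inverting the fitted curve
converts per-cell ratios to intracellular pH.

A calibration is an explicit input to every conversion: instrument gain drifts
between sessions, so a fresh curve is fitted per experiment.  The absolute
ratios may differ between sessions while the effective pKa stays put.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "CalibrationError",
    "CalibrationFit",
    "sigmoid",
    "subtract_background",
    "calibration_points",
    "fit_calibration",
    "effective_pka",
    "ratio_to_ph",
]

FORMAT_VERSION = 1


class CalibrationError(ValueError):
    """Raised for under-determined or non-sigmoidal calibration input."""


def sigmoid(ph, a, b, c, d):
    """Four-parameter logistic ratio model, vectorized over ``ph``."""
    ph = np.asarray(ph, dtype=float)
    return a / (1.0 + np.exp(-b * (ph - c))) + d


@dataclass
class CalibrationFit:
    """Fitted ratio-vs-pH curve plus the backgrounds used to correct ratios.

    ``r_min``/``r_max`` are the asymptotic ratios ``min(d, a+d)`` and
    ``max(d, a+d)``; ``pka_eff`` is the Eq.-2 root (numerically equal to ``c``).
    """

    a: float
    b: float
    c: float
    d: float
    rss: float
    n_points: int
    background_405: float = 0.0
    background_488: float = 0.0
    grid_min: float = np.nan
    grid_max: float = np.nan
    pka_eff: float = field(init=False)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise CalibrationError(f"ratio span a must be positive, got {self.a}")
        if self.b == 0:
            raise CalibrationError("steepness b must be nonzero (curve must be monotone)")
        self.pka_eff = effective_pka(self)

    @property
    def r_min(self) -> float:
        return min(self.d, self.a + self.d)

    @property
    def r_max(self) -> float:
        return max(self.d, self.a + self.d)

    def predict(self, ph):
        return sigmoid(ph, self.a, self.b, self.c, self.d)

    # -- versioned text serialization ------------------------------------
    def to_json(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        payload["format_version"] = FORMAT_VERSION
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationFit":
        payload = json.loads(text)
        version = payload.pop("format_version", None)
        if version != FORMAT_VERSION:
            raise CalibrationError(f"unsupported calibration format version: {version}")
        payload.pop("pka_eff", None)
        return cls(**payload)


def subtract_background(
    events: pd.DataFrame,
    background_405: float,
    background_488: float,
) -> pd.DataFrame:
    """Background-correct both pHluorin channels and compute per-event ratios.

    Backgrounds are autofluorescence medians of unlabeled cells measured in the
    matching matrix (media or buffer).  Events driven non-positive in either
    channel are flagged (``ratio_excluded``) and get a missing ratio rather
    than a fabricated one.
    """
    if background_405 is None or background_488 is None:
        raise CalibrationError("background medians (405, 488) are required; none recorded")
    out = events.copy()
    corr405 = out["ch405"] - float(background_405)
    corr488 = out["ch488"] - float(background_488)
    bad = (corr405 <= 0) | (corr488 <= 0)
    ratio = np.where(bad, np.nan, corr405 / np.where(bad, 1.0, corr488))
    out["ratio405_488"] = ratio
    out["ratio_excluded"] = bad.to_numpy()
    out.attrs = dict(events.attrs)
    out.attrs["n_ratio_excluded"] = int(bad.sum())
    return out


def calibration_points(tables: dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Collapse per-buffer event tables to one (buffer_ph, median_ratio) row each.

    Tables must already carry ``ratio405_488`` (see :func:`subtract_background`).
    """
    rows = []
    for ph, table in sorted(tables.items()):
        med = float(np.nanmedian(table["ratio405_488"]))
        rows.append({"buffer_ph": float(ph), "median_ratio": med})
    points = pd.DataFrame(rows)
    if not np.isfinite(points["median_ratio"]).all() or (points["median_ratio"] <= 0).any():
        raise CalibrationError("non-finite or non-positive median ratio among calibration points")
    return points


def _initial_guesses(ph: np.ndarray, r: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start inits from midpoint/quartile heuristics."""
    span = float(r.max() - r.min())
    offs = float(r.min())
    ph_mid = float(np.median(ph))
    ph_lo, ph_hi = np.quantile(ph, [0.25, 0.75])
    width = max(float(ph.max() - ph.min()), 1e-6)
    starts = [
        np.array([span, 4.0 / width, ph_mid, offs]),
        np.array([span, 1.0, ph_lo, offs]),
        np.array([span, 1.0, ph_hi, offs]),
        np.array([span, 8.0 / width, ph_mid, offs]),
    ]
    return starts


def fit_calibration(
    points: pd.DataFrame,
    min_points: int = 5,
    min_span: float = 2.0,
    min_ratio_range: float = 0.05,
    background_405: float = 0.0,
    background_488: float = 0.0,
) -> CalibrationFit:
    """Least-squares fit of the four-parameter logistic to buffer medians.

    Requires at least ``min_points`` buffers spanning ``min_span`` pH units
    (four parameters need overdetermination) and a relative ratio range of at
    least ``min_ratio_range`` (flat data are not a sigmoid).  The canonical
    sign convention is b > 0 (ratio increasing with pH); descending data are
    fitted after reflecting the pH axis and reported with b < 0, which the
    inversion and the effective-pKa root handle symmetrically.

    Bounded least squares from four deterministic starts; best RSS wins, ties
    broken toward the smallest ``|b|``.
    """
    ph = np.asarray(points["buffer_ph"], dtype=float)
    r = np.asarray(points["median_ratio"], dtype=float)
    if len(ph) < min_points:
        raise CalibrationError(
            f"under-determined calibration: {len(ph)} points < required {min_points}"
        )
    if ph.max() - ph.min() < min_span:
        raise CalibrationError(
            f"buffer grid spans {ph.max() - ph.min():.2f} pH units; need >= {min_span}"
        )
    rel_range = (r.max() - r.min()) / max(abs(np.median(r)), 1e-12)
    if rel_range < min_ratio_range:
        raise CalibrationError(
            f"non-sigmoidal data: relative ratio range {rel_range:.3g} below floor {min_ratio_range}"
        )

    # Descending data are fitted after reflecting about the pH axis.
    ascending = r[np.argmax(ph)] >= r[np.argmin(ph)]
    ph_fit = ph if ascending else -ph

    def residuals(theta):
        return sigmoid(ph_fit, *theta) - r

    width = float(ph.max() - ph.min())
    lower = np.array([1e-9, 1e-3, ph_fit.min() - width, -np.inf])
    upper = np.array([np.inf, 1e3, ph_fit.max() + width, np.inf])
    best = None
    for x0 in _initial_guesses(ph_fit, r):
        x0 = np.clip(x0, lower + 1e-12, np.where(np.isfinite(upper), upper - 1e-12, x0))
        try:
            sol = optimize.least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun**2))
        key = (round(rss, 12), abs(sol.x[1]))
        if best is None or key < best[0]:
            best = (key, sol.x, rss)
    if best is None:
        raise CalibrationError("calibration optimizer failed to converge from every start")

    a, b, c, d = best[1]
    rss = best[2]
    if not ascending:
        b, c = -b, -c  # undo the pH-axis reflection
    return CalibrationFit(
        a=float(a), b=float(b), c=float(c), d=float(d),
        rss=rss, n_points=len(ph),
        background_405=background_405, background_488=background_488,
        grid_min=float(ph.min()), grid_max=float(ph.max()),
    )


def effective_pka(fit) -> float:
    """pH at which the ratio is midway between its asymptotes.

    Solves ``log((R(pH) - R_max) / (R_min - R(pH))) = 0`` by bracketing
    root-finding on the fitted curve.  For the logistic this root is exactly
    the midpoint parameter ``c``; the numeric solve guards against any future
    change of curve family.
    """
    a, b, c, d = fit.a, fit.b, fit.c, fit.d
    r_lo, r_hi = min(d, a + d), max(d, a + d)

    def log_asymptote_ratio(ph):
        with np.errstate(over="ignore", divide="ignore"):
            r = sigmoid(ph, a, b, c, d)
            return np.log((r_hi - r) / (r - r_lo))

    halfwidth = 1.0
    while halfwidth < 1e6:
        lo, hi = c - halfwidth, c + halfwidth
        try:
            f_lo, f_hi = log_asymptote_ratio(lo), log_asymptote_ratio(hi)
        except FloatingPointError:
            break
        if np.isfinite(f_lo) and np.isfinite(f_hi) and f_lo * f_hi < 0:
            return float(optimize.brentq(log_asymptote_ratio, lo, hi, xtol=1e-12))
        halfwidth *= 2.0
    return float(c)


def ratio_to_ph(fit: CalibrationFit, ratio) -> tuple[np.ndarray, int]:
    """Invert the calibration curve: per-event ratio -> intracellular pH.

        pH = c - (1/b) * ln(a / (R - d) - 1)

    Ratios at or outside the open interval (r_min, r_max) have no preimage and
    become NaN — they are counted and reported, never clamped, so the tails of
    the pH distribution are not fabricated.  Returns ``(ph, n_out_of_range)``.
    """
    r = np.asarray(ratio, dtype=float)
    inside = (r > fit.r_min) & (r < fit.r_max)
    ph = np.full(r.shape, np.nan)
    rr = r[inside]
    with np.errstate(divide="ignore", invalid="ignore"):
        ph[inside] = fit.c - np.log(fit.a / (rr - fit.d) - 1.0) / fit.b
    n_out = int(np.size(r) - inside.sum() - np.isnan(r).sum())
    return ph, n_out
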