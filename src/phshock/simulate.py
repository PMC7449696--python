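"""Synthetic cytometry and expression data with known ground truth.

Every pipeline input can be generated here with its generating parameters
retained, so each estimator in the package can be exercised against truth:

* :func:`simulate_calibration` — per-buffer event tables whose noise-free
  median 405:488 ratio equals the calibration sigmoid at the buffer pH;
* :func:`simulate_recovery` — a stress-recovery time course with class-
  conditional structure: cells first return to the resting pH, and only
  pH-recovered cells become eligible for high chaperone expression (the
  dependency the single-cell analysis is designed to detect); budding state
  drives forward-scatter pulse width; spike-in and BV421-bright events are
  mixed in as configured;
* :func:`simulate_competition` — multinomially sampled labeled vs spike-in
  counts under exact exponential growth;
* :func:`simulate_expression` — regulon-structured tpm tables where heat
  shock induces the stress regulons and an acidification effect multiplies
  only designated gene sets.

Noise is multiplicative lognormal per channel (flow signals are positive and
right-skewed), parameterized by a coefficient of variation and centered so
the *median* of the noise factor is exactly 1 — medians are the summary
statistic used throughout the analysis, so with CV -> 0 every generator's
summary equals its generating formula.  All generators take explicit seeds;
there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import sigmoid
from .fitness import GrowthSeries
from .kinetics import InductionCurve, induction_model

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_calibration",
    "simulate_recovery",
    "simulate_competition",
    "simulate_expression",
    "simulate_induction_curve",
]


@dataclass(frozen=True)
class SimTruth:
    """Generating parameters: the ground-truth counterpart of every estimate."""

    # ratio-vs-pH sigmoid (span, steepness 1/pH, midpoint pH, offset)
    calib_a: float = 2.0
    calib_b: float = 1.5
    calib_c: float = 7.0
    calib_d: float = 0.3
    background_405: float = 20.0
    background_488: float = 50.0
    # induction logistic (amplitude, rate 1/min, midpoint min, baseline >= 1)
    ind_a: float = 9.0
    ind_b: float = 0.05
    ind_c: float = 120.0
    ind_d: float = 1.0
    # pH-recovery logistic midpoint (min); recovery precedes induction
    recovery_c: float = 90.0
    recovery_b: float = 0.08
    ph_resting: float = 7.5
    ph_resting_sd: float = 0.10
    ph_stressed: float = 6.9
    ph_stressed_sd: float = 0.15
    # competition growth rates (1/min); reference = ln(2)/70 min doubling
    r_labeled: float = 0.0056
    r_ref: float = 0.009902
    # regulon effect sizes: acidification fold per TF name
    regulon_effects: tuple = (("Hsf1", 4.0),)
    induction_fold: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ind_d < 1:
            raise ValueError("induction baseline d must be >= 1")
        if any(eff <= 0 for _, eff in self.regulon_effects):
            raise ValueError("regulon fold effects must be positive")
        for name in ("r_labeled", "r_ref"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def calib_params(self) -> tuple[float, float, float, float]:
        return (self.calib_a, self.calib_b, self.calib_c, self.calib_d)

    @property
    def induction_params(self) -> tuple[float, float, float, float]:
        return (self.ind_a, self.ind_b, self.ind_c, self.ind_d)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generators.

    Defaults follow the assay design: >= 10 000 events per timepoint, buffers
    every 0.5 pH unit from 4.5 to 8.5, recovery sampled over four hours.
    """

    n_events: int = 10_000
    channel_cv: float = 0.05
    buffer_ph_grid: tuple = tuple(np.arange(4.5, 8.51, 0.5).round(2))
    timepoints_min: tuple = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0)
    # recovery-timecourse composition
    spike_fraction: float = 0.0
    bv421_bright_fraction: float = 0.0
    debris_fraction: float = 0.0
    # expression bimodality: log-mean separation of high vs low red, in sds
    mixture_separation_sd: float = 8.0
    red_log_sd: float = 0.25
    # budding
    fsc_width_means: tuple = (10.0, 14.0)
    fsc_width_sd: float = 1.0
    budding_base: float = 0.25
    budding_amplitude: float = 0.35
    budding_peak_min: float = 120.0
    budding_width_min: float = 40.0
    # expression matrices
    n_background_genes: int = 2000
    tpm_cv: float = 0.2
    n_replicates: int = 2
    # per-timepoint (between-experiment) fold-change noise for curve studies
    curve_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        for name in ("channel_cv", "tpm_cv", "curve_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        grid = np.asarray(self.buffer_ph_grid, dtype=float)
        if grid.size and np.any(np.diff(grid) <= 0):
            raise ValueError("buffer pH grid must be strictly increasing")
        fractions = self.spike_fraction + self.bv421_bright_fraction + self.debris_fraction
        for name in ("spike_fraction", "bv421_bright_fraction", "debris_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if fractions > 1 + 1e-12:
            raise ValueError("event-class fractions sum to more than 1")


def _log_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal factor with median exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(sigma * rng.standard_normal(size))


# typical instrument-scale magnitudes (arbitrary units)
_BASE_488 = 2000.0
_BASE_RED = 500.0
_BASE_FSC = 50_000.0
_BASE_SSC = 20_000.0
_SPIKE_AUTOFLUOR = 10.0
_BASE_BV421 = 50.0


def _scatter_channels(rng, cv, n, debris=None):
    fsc = _BASE_FSC * _log_noise(rng, max(cv, 0.15), n)
    ssc = _BASE_SSC * _log_noise(rng, max(cv, 0.15), n)
    if debris is not None and debris.any():
        fsc[debris] /= 10.0
        ssc[debris] /= 10.0
    return fsc, ssc


def simulate_calibration(
    config: SimConfig, truth: SimTruth
) -> dict[float, pd.DataFrame]:
    """One event table per calibration buffer.

    Per buffer pH x, the pHluorin channels are constructed so that after
    background subtraction the noise-free median 405:488 ratio equals the
    generating sigmoid at x: ch488 = bg488 + B*e1, ch405 = bg405 + R(x)*B*e2
    with e1, e2 independent median-1 lognormal factors.
    """
    grid = tuple(config.buffer_ph_grid)
    if not grid:
        raise ValueError("empty buffer pH grid")
    if min(grid) < 4.0 or max(grid) > 9.0:
        raise ValueError("buffer grid must lie within [4.0, 9.0]")
    rng = np.random.default_rng(truth.seed)
    out: dict[float, pd.DataFrame] = {}
    for ph in grid:
        n = config.n_events
        r = float(sigmoid(ph, *truth.calib_params))
        ch488 = truth.background_488 + _BASE_488 * _log_noise(rng, config.channel_cv, n)
        ch405 = truth.background_405 + r * _BASE_488 * _log_noise(rng, config.channel_cv, n)
        fsc, ssc = _scatter_channels(rng, config.channel_cv, n)
        table = pd.DataFrame({
            "fsc_area": fsc,
            "fsc_width": rng.normal(config.fsc_width_means[0], config.fsc_width_sd, n),
            "ssc": ssc,
            "ch405": ch405,
            "ch488": ch488,
            "ch_red": _BASE_RED * 0.02 * _log_noise(rng, config.channel_cv, n),
            "ch_bv421": _BASE_BV421 * _log_noise(rng, config.channel_cv, n),
        })
        table.attrs = {"buffer_ph": float(ph), "sample_id": f"calib_pH{ph:g}",
                       "true_ratio": r, "seed": truth.seed}
        out[float(ph)] = table
    return out


def simulate_recovery(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Stress-recovery time course with per-cell truth labels.

    Generative structure, per labeled cell at recovery time t:

    * pH-recovered with probability following a logistic in t (midpoint
      ``truth.recovery_c``); recovered cells draw pH ~ N(resting, sd),
      non-recovered ~ N(stressed, sd);
    * only recovered cells may be high expressors, with conditional
      probability following the induction logistic (midpoint ``truth.ind_c``);
      log red fluorescence is a two-component mixture separated by
      ``config.mixture_separation_sd`` sds, rescaled per timepoint so the
      population-median red-per-FSC fold change follows the induction
      logistic exactly (the curve the kinetics module estimates);
    * budding probability follows a Gaussian hump peaking at
      ``config.budding_peak_min``; FSC pulse width is a two-component
      Gaussian tied to budding state.

    Spike-in cells (unlabeled, dim in both pHluorin channels), BV421-bright
    events, and small-scatter debris are mixed in at the configured
    fractions.  Truth columns are prefixed ``true_``.
    """
    rng = np.random.default_rng(truth.seed + 1)
    frames = []
    sep = config.mixture_separation_sd * config.red_log_sd
    for t in config.timepoints_min:
        n = config.n_events
        spike = rng.random(n) < config.spike_fraction
        debris = rng.random(n) < config.debris_fraction
        with np.errstate(over="ignore"):
            p_rec = 1.0 / (1.0 + np.exp(-truth.recovery_b * (t - truth.recovery_c)))
        recovered = rng.random(n) < p_rec
        true_ph = np.where(
            recovered,
            rng.normal(truth.ph_resting, truth.ph_resting_sd, n),
            rng.normal(truth.ph_stressed, truth.ph_stressed_sd, n),
        )
        with np.errstate(over="ignore"):
            p_high_given_rec = 1.0 / (1.0 + np.exp(-truth.ind_b * (t - truth.ind_c)))
        high = recovered & (rng.random(n) < p_high_given_rec)
        budded = rng.random(n) < _budding_probability(t, config)

        ratio = sigmoid(true_ph, *truth.calib_params)
        e1 = _log_noise(rng, config.channel_cv, n)
        e2 = _log_noise(rng, config.channel_cv, n)
        ch488 = np.where(spike, _SPIKE_AUTOFLUOR * e1, _BASE_488 * e1) + truth.background_488
        ch405 = np.where(spike, _SPIKE_AUTOFLUOR * e2, ratio * _BASE_488 * e2) + truth.background_405

        # rescale so the noise-free population median fold equals the logistic
        p_high = p_rec * p_high_given_rec
        fold_target = induction_model(t, *truth.induction_params) \
            / induction_model(config.timepoints_min[0], *truth.induction_params)
        log_shift = np.log(fold_target) - _mixture_log_median(
            p_high, sep, config.red_log_sd)
        log_red = np.log(_BASE_RED) + log_shift + np.where(high, sep, 0.0) \
            + config.red_log_sd * rng.standard_normal(n)
        ch_red = np.where(spike, _BASE_RED * 0.02 * _log_noise(rng, config.channel_cv, n),
                          np.exp(log_red))
        fsc, ssc = _scatter_channels(rng, config.channel_cv, n, debris)
        fsc_width = np.where(
            budded,
            rng.normal(config.fsc_width_means[1], config.fsc_width_sd, n),
            rng.normal(config.fsc_width_means[0], config.fsc_width_sd, n),
        )
        bright = rng.random(n) < config.bv421_bright_fraction
        bv421 = _BASE_BV421 * np.where(bright, 20.0, 1.0) * _log_noise(rng, config.channel_cv, n)

        frames.append(pd.DataFrame({
            "timepoint_min": float(t),
            "fsc_area": fsc,
            "fsc_width": fsc_width,
            "ssc": ssc,
            "ch405": ch405,
            "ch488": ch488,
            "ch_red": ch_red,
            "ch_bv421": bv421,
            "true_ph": true_ph,
            "true_recovered": recovered,
            "true_expression": np.where(high, "high", "low"),
            "true_budded": np.where(budded, "budded", "unbudded"),
            "true_strain": np.where(spike, "spike", "labeled"),
            "true_debris": debris,
            "true_bv421_bright": bright,
        }))
    events = pd.concat(frames, ignore_index=True)
    events.attrs = {"seed": truth.seed, "condition": "recovery",
                    "n_events_per_timepoint": config.n_events}
    return events


def _mixture_log_median(p_high: float, sep: float, sd: float) -> float:
    """Median of log of the two-component lognormal red mixture.

    Components N(0, sd) and N(sep, sd) with weights (1-p, p); the median
    solves (1-p)*Phi(x/sd) + p*Phi((x-sep)/sd) = 1/2.
    """
    from scipy import optimize, stats

    if sd <= 0:
        return sep if p_high > 0.5 else 0.0

    def cdf(x):
        return (1 - p_high) * stats.norm.cdf(x / sd) \
            + p_high * stats.norm.cdf((x - sep) / sd) - 0.5

    lo, hi = -10 * sd, sep + 10 * sd
    return float(optimize.brentq(cdf, lo, hi))


def _budding_probability(t: float, config: SimConfig) -> float:
    hump = np.exp(-((t - config.budding_peak_min) ** 2)
                  / (2.0 * config.budding_width_min**2))
    return float(config.budding_base + config.budding_amplitude * hump)


def simulate_competition(
    r_labeled: float,
    r_ref: float,
    mix0: float = 1.0,
    timepoints=(0.0, 30.0, 60.0, 90.0, 120.0, 150.0),
    depth: int | None = 10_000,
    seed: int = 0,
) -> GrowthSeries:
    """Labeled vs spike-in counts under exact exponential growth.

    Expected population sizes are n_x(t) = n_x(0) * exp(r_x * t); observed
    counts at each timepoint are a binomial draw of ``depth`` events from the
    expected composition.  ``depth=None`` disables sampling and returns the
    expected (continuous) counts, for closed-form checks.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if len(timepoints) < 2:
        raise ValueError("need at least 2 timepoints")
    if depth is not None and depth < 1:
        raise ValueError(f"sampling depth must be >= 1, got {depth}")
    n_lab = mix0 * np.exp(r_labeled * timepoints)
    n_ref = np.exp(r_ref * timepoints)
    if depth is None:
        labeled, spikes = n_lab, n_ref
    else:
        rng = np.random.default_rng(seed)
        p = n_lab / (n_lab + n_ref)
        labeled = rng.binomial(depth, p).astype(float)
        spikes = depth - labeled
    return GrowthSeries(
        timepoints=timepoints,
        n_labeled=labeled,
        n_spike=spikes,
        condition={"r_labeled": r_labeled, "r_ref": r_ref, "mix0": mix0,
                   "depth": depth, "seed": seed},
    )


def simulate_induction_curve(
    truth: SimTruth,
    timepoints=None,
    channel_cv: float = 0.0,
    curve_cv: float = 0.0,
    seed: int = 0,
    n_cells: int = 5000,
) -> InductionCurve:
    """Fold-change curve sampled from the induction logistic.

    Two noise sources compose multiplicatively:

    * ``channel_cv`` — per-event lognormal noise on red fluorescence and
      forward scatter; each timepoint's value is the median of
      red/FSC over ``n_cells`` events, normalized by an equally sampled
      unstressed baseline, so the curve inherits only the (small) sampling
      error of a median over thousands of cells;
    * ``curve_cv`` — per-timepoint lognormal noise on the median itself,
      emulating between-experiment variation.
    """
    t = np.asarray(
        timepoints if timepoints is not None else (0, 30, 60, 90, 120, 150, 180, 210, 240),
        dtype=float,
    )
    rng = np.random.default_rng(seed)
    fold_true = induction_model(t, *truth.induction_params)
    if channel_cv > 0:
        base = np.median(
            _log_noise(rng, channel_cv, n_cells) / _log_noise(rng, channel_cv, n_cells)
        )
        fold = np.array([
            np.median(f * _log_noise(rng, channel_cv, n_cells)
                      / _log_noise(rng, channel_cv, n_cells)) / base
            for f in fold_true
        ])
    else:
        fold = fold_true.copy()
    fold = fold * _log_noise(rng, curve_cv, len(t))
    return InductionCurve(t, fold, np.full(len(t), n_cells),
                          condition={"seed": seed, "channel_cv": channel_cv,
                                     "curve_cv": curve_cv})


def simulate_expression(
    regulons,
    config: SimConfig,
    truth: SimTruth,
    renormalize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regulon-structured tpm matrix plus its sample sheet.

    Design: {mock, shock} x {acidification allowed, prevented} under one
    translation-inhibited state (cycloheximide), ``config.n_replicates``
    replicates each.  Per gene g: basal abundance lognormal; shock multiplies
    stress-regulon members by ``truth.induction_fold``; the acidification
    effect for a TF in ``truth.regulon_effects`` multiplies its members only
    in the shock+allowed condition, so the allowed/prevented ratio recovers
    the planted effect.  Columns are renormalized to sum to 10^6 unless
    ``renormalize=False`` (exact small-scale checks).
    """
    regulons = list(regulons)
    all_set_genes = [g for r in regulons for g in r.genes]
    if len(set(all_set_genes)) != len(all_set_genes):
        raise ValueError("gene sets must be disjoint after exclusion")
    background = [f"bg{i:04d}" for i in range(config.n_background_genes)]
    # set members drawn from the background universe must not duplicate columns
    genes = list(dict.fromkeys(all_set_genes + background))
    if not genes:
        raise ValueError("empty gene universe")
    rng = np.random.default_rng(truth.seed + 2)
    basal = np.exp(rng.normal(np.log(50.0), 1.0, len(genes)))
    effects = dict(truth.regulon_effects)
    acid_mult = np.ones(len(genes))
    shock_mult = np.ones(len(genes))
    index = pd.Index(genes, name="gene")
    stress_tfs = {tf for tf, _ in truth.regulon_effects} | {"Hsf1", "Msn2/4"}
    for r in regulons:
        sel = index.get_indexer(list(r.genes))
        sel = sel[sel >= 0]
        if r.tf in stress_tfs:
            shock_mult[sel] = truth.induction_fold
        if r.tf in effects:
            acid_mult[sel] = effects[r.tf]

    columns, meta = {}, []
    for temperature in ("mock", "shock"):
        for acid in ("allowed", "prevented"):
            for rep in range(1, config.n_replicates + 1):
                mu = basal.copy()
                if temperature == "shock":
                    mu = mu * shock_mult
                    if acid == "allowed":
                        mu = mu * acid_mult
                vals = mu * _log_noise(rng, config.tpm_cv, len(genes))
                if renormalize:
                    vals = vals / vals.sum() * 1e6
                name = f"{temperature}_{acid}_rep{rep}"
                columns[name] = vals
                meta.append({"sample": name, "temperature": temperature,
                             "acidification": acid, "translation": "cycloheximide",
                             "replicate": rep})
    tpm = pd.DataFrame(columns, index=index)
    samples = pd.DataFrame(meta)
    tpm.attrs = {"seed": truth.seed, "renormalized": renormalize}
    return tpm, samples
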