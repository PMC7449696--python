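"""Two-component Gaussian-mixture subpopulation calls and class comparisons.

Two single-cell classifications in the recovery assay reduce to the same
primitive, a univariate two-component Gaussian mixture with a posterior-
probability cutoff:

* expression class — log Ssa4-mCherry fold change separates high- from
  low-inducing cells (fluorescence is multiplicative, hence the log domain);
* budding state — forward-scatter pulse width, proportional to the length of
  the cell (or cell-plus-bud) crossing the laser, separates budded from
  unbudded cells on the linear scale.

Cells whose posterior for both components falls below the cutoff (default
0.90) are labeled ambiguous and excluded from class statistics.  Downstream
summaries — budded fraction over recovery, fraction of cells inside the
resting pH range, and rank-sum comparisons of intracellular pH between
classes — live here too.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "MixtureFit",
    "RestingRange",
    "fit_two_component",
    "classify",
    "budded_fraction",
    "fraction_in_range",
    "compare_class_ph",
]

DEFAULT_CUTOFF = 0.90


@dataclass(frozen=True)
class RestingRange:
    """Resting intracellular pH band of untreated cells (defaults ~7.3-7.8)."""

    lower: float = 7.3
    upper: float = 7.8

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"resting range requires lower < upper, got {self}")
        if not (6.5 <= self.lower and self.upper <= 8.5):
            raise ValueError(f"resting range {self} outside plausible [6.5, 8.5]")


@dataclass
class MixtureFit:
    """Ordered (mu1 < mu2) two-component Gaussian mixture in the fit domain."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    converged: bool
    domain: str  # "linear" | "log"
    posteriors: np.ndarray  # (n, 2), columns ordered by component mean
    poorly_separated: bool = False

    @property
    def separation(self) -> float:
        pooled = np.sqrt(float(self.sds[0] ** 2 + self.sds[1] ** 2) / 2.0)
        return float(self.means[1] - self.means[0]) / max(pooled, 1e-300)

    def posterior_high(self, x) -> np.ndarray:
        """p(upper component | x) for new observations in the *data* domain."""
        x = np.asarray(x, dtype=float)
        if self.domain == "log":
            x = np.log(x)
        logp = np.stack([
            np.log(self.weights[k]) + stats.norm.logpdf(x, self.means[k], self.sds[k])
            for k in (0, 1)
        ])
        logp -= logp.max(axis=0, keepdims=True)
        p = np.exp(logp)
        return p[1] / p.sum(axis=0)


def fit_two_component(values, domain: str = "linear", max_iter: int = 500) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture with deterministic starts.

    ``domain`` selects the scale the Gaussians live on: "log" for
    multiplicative quantities (fluorescence fold change), "linear" for
    additive ones (pulse width).  Initialization is deterministic — a split
    at the median plus two quantile splits (0.25 and 0.75); the
    best log-likelihood wins, ties broken toward the larger component
    separation.  Components are reported ordered by mean.  A variance floor
    of (1e-6 x data range)^2 prevents EM collapse on degenerate data; fits
    whose means differ by less than one pooled sd are flagged
    ``poorly_separated``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if domain == "log":
        if (x <= 0).any():
            raise ValueError("log-domain mixture requires strictly positive values")
        x = np.log(x)
    elif domain != "linear":
        raise ValueError(f"unknown domain {domain!r}")
    if len(x) < 50:
        raise ValueError(f"mixture fit needs >= 50 finite values, got {len(x)}")

    data_range = float(x.max() - x.min())
    reg = max(1e-6 * data_range, 1e-12) ** 2
    X = x.reshape(-1, 1)

    def split_init(q_cut: float) -> dict:
        cut = np.quantile(x, q_cut)
        left, right = x[x <= cut], x[x > cut]
        if len(left) == 0 or len(right) == 0:
            left = right = x
        w = max(min(len(left) / len(x), 0.99), 0.01)
        var_floor = max(reg, 1e-12)
        variances = np.array([
            max(np.var(left), var_floor), max(np.var(right), var_floor)
        ])
        return {
            "means_init": np.array([[np.mean(left)], [np.mean(right)]]),
            "weights_init": np.array([w, 1.0 - w]),
            "precisions_init": (1.0 / variances).reshape(2, 1, 1),
        }

    best: tuple | None = None
    for q_cut in (0.5, 0.25, 0.75):
        init = split_init(q_cut)
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            reg_covar=reg,
            max_iter=max_iter,
            n_init=1,
            means_init=init["means_init"],
            weights_init=init["weights_init"],
            precisions_init=init["precisions_init"],
            random_state=0,
        )
        gm.fit(X)
        ll = float(gm.score(X)) * len(x)
        mu = gm.means_.ravel()
        sep = abs(mu[1] - mu[0])
        key = (round(ll, 9), sep)
        if best is None or key > best[0]:
            best = (key, gm)
    gm = best[1]

    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.reshape(2)[order])
    weights = gm.weights_[order]
    post = gm.predict_proba(X)[:, order]
    pooled = np.sqrt(float(sds[0] ** 2 + sds[1] ** 2) / 2.0)
    return MixtureFit(
        means=means,
        sds=sds,
        weights=weights,
        log_likelihood=float(gm.score(X)) * len(x),
        converged=bool(gm.converged_),
        domain=domain,
        posteriors=post,
        poorly_separated=(means[1] - means[0]) < pooled,
    )


def classify(
    fit: MixtureFit,
    cutoff: float = DEFAULT_CUTOFF,
    names: tuple[str, str] = ("low", "high"),
    ambiguous: str = "ambiguous",
) -> np.ndarray:
    """Assign each fitted observation to a component by posterior cutoff.

    An observation is labeled with a component only if its posterior for that
    component is at least ``cutoff``; otherwise it is ``ambiguous`` and must
    be excluded from class statistics.  Cutoffs at or below 0.5 would let an
    observation qualify for both components and are rejected.
    """
    if cutoff <= 0.5:
        raise ValueError(f"posterior cutoff must exceed 0.5, got {cutoff}")
    post_hi = fit.posteriors[:, 1]
    labels = np.full(len(post_hi), ambiguous, dtype=object)
    labels[post_hi >= cutoff] = names[1]
    labels[(1.0 - post_hi) >= cutoff] = names[0]
    return labels


def budded_fraction(
    timepoints: np.ndarray,
    labels: np.ndarray,
    budded: str = "budded",
    ambiguous: str = "ambiguous",
    summary_window: tuple[float, float] = (90.0, 120.0),
) -> tuple[pd.DataFrame, float]:
    """Budded fraction among non-ambiguous cells per timepoint, plus a
    windowed mean (default over 90-120 min of recovery, the interval used to
    summarize the post-arrest budding peak).

    Timepoints with no confidently classified cell yield NaN.
    """
    t = np.asarray(timepoints, dtype=float)
    lab = np.asarray(labels, dtype=object)
    rows = []
    for tp in np.unique(t):
        sel = lab[t == tp]
        confident = sel[sel != ambiguous]
        frac = float((confident == budded).mean()) if len(confident) else np.nan
        rows.append({"timepoint_min": float(tp), "fraction_budded": frac,
                     "n_confident": int(len(confident))})
    series = pd.DataFrame(rows)
    lo, hi = summary_window
    in_win = series[(series["timepoint_min"] >= lo) & (series["timepoint_min"] <= hi)]
    window_mean = float(in_win["fraction_budded"].mean()) if len(in_win) else float("nan")
    return series, window_mean


def fraction_in_range(ph_values, resting: RestingRange) -> float:
    """Fraction of non-missing pH values inside the resting band (inclusive)."""
    ph = np.asarray(ph_values, dtype=float)
    ph = ph[np.isfinite(ph)]
    if len(ph) == 0:
        raise ValueError("no finite pH values: cannot compute resting-range fraction")
    return float(((ph >= resting.lower) & (ph <= resting.upper)).mean())


def compare_class_ph(group_a, group_b, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney (Wilcoxon rank-sum) comparison of two classes.

    Exact enumeration when both groups have at most ``exact_max_n``
    observations and no cross-group ties; the tie-corrected normal
    approximation otherwise.  Identical constant groups carry no ordering
    information and return p = 1.  Returns ``(U, p)`` with U counted for the
    first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"both groups need n >= 3, got {len(a)} and {len(b)}")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= exact_max_n and len(b) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def exact_rank_sum_p(group_a, group_b) -> float:
    """Brute-force two-sided rank-sum p by enumerating all group assignments.

    Independent of :func:`compare_class_ph`; usable only for tiny groups
    (the enumeration is over C(n_a + n_b, n_a) label assignments).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = stats.rankdata(pooled)
    observed = abs(ranks[:n_a].sum() - n_a * (len(pooled) + 1) / 2.0)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        stat = abs(ranks[list(combo)].sum() - n_a * (len(pooled) + 1) / 2.0)
        total += 1
        if stat >= observed - 1e-12:
            count += 1
    return count / total
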