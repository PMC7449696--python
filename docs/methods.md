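# Methods

## Calibration model

The pHluorin excitation ratio is modeled as a four-parameter logistic in pH,
R(pH) = a/(1 + exp(−b(pH − c))) + d, with span a > 0, steepness b (1/pH),
midpoint c (pH units) and offset d.  The asymptotes are R_min = min(d, a+d)
and R_max = max(d, a+d); the effective pKa is the root of
log((R − R_max)/(R_min − R)) = 0, found by bracketing root-finding on the
fitted curve.  For this curve family the root is identically the midpoint c,
and the numeric solve is retained as a guard on the identity (verified to
1e-6 in the acceptance suite).  Fitting is bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective) from four
deterministic midpoint/quartile starts; the best RSS wins, ties broken
toward the smallest |b|.  The canonical sign convention is b > 0 (R rising
with pH); descending data are fitted after reflecting the pH axis and
reported with b < 0, which both the inversion and the pKa root handle
symmetrically.

Fits are refused rather than degraded when under-determined: fewer than 5
buffers, a grid spanning under 2 pH units, or a relative ratio range below
5% (non-sigmoidal data).  Ratio-to-pH conversion inverts the fitted curve
per cell; ratios outside the open interval (R_min, R_max) have no preimage
and become missing values with a reported count — never clamped, so the
tails of pH distributions are not fabricated.  A calibration fit is an
explicit argument to conversion because detector gains drift between
sessions; the absolute ratios may vary while the effective pKa is stable
(the gain-invariance test doubles a and d and requires the pKa to move
≤ 0.01 pH).  Per-cell ratios are converted through the population-level fit;
per-cell calibration is not attempted.

## Induction kinetics

Per recovery timepoint, induction is the median over gated labeled cells of
red fluorescence divided by forward scatter area, normalized to the same
statistic in unstressed cells (fold change 1 by construction).  The
per-cell-ratio-then-median form is the default; ratio-of-medians is a
config switch, and the two agree for scale-family distributions.  Curves
are fitted in the log domain (fluorescence noise is multiplicative) with
the constrained logistic fold(t) = a/(1+exp(−b(t−c))) + d, box constraint
d ≥ 1: a population cannot sit below its own unstressed baseline, and the
constraint keeps flat curves from drifting.  Fitted amplitudes below 0.05
are flagged "no induction" and yield a missing delay rather than a
meaningless midpoint.  Timepoints with fewer than 1000 cells are refused by
default (medians over thin samples are not comparable across a curve).

Continuous pH traces are smoothed with a centered sliding-window average
(default window configurable; edges use truncated windows).  A centered
window smears a sharp transition symmetrically — including *before* a
step — so an apparent pre-stress pH drift at the shock boundary is a
smoothing artifact, not signal.

## Mixture classification

Both single-cell classifications (high/low expression on log fold change;
budded/unbudded on linear FSC pulse width) use a univariate two-component
Gaussian mixture fitted by EM (`sklearn.mixture.GaussianMixture` as the
engine) with deterministic initialization: data splits at the 0.25, 0.50
and 0.75 quantiles seed means, weights and precisions; the best
log-likelihood wins, ties broken toward the larger component separation.  A
variance floor of (1e-6 × data range)² prevents collapse on degenerate
data.  Components are reported ordered by mean, and cells are assigned a
class only when the posterior reaches the cutoff (default 0.90 for both
classifications); everything else is ambiguous and excluded from class
statistics.  Fits whose means differ by less than one pooled standard
deviation are flagged poorly separated.  The expression domain is log
because fluorescence is multiplicative; pulse width stays linear because it
is proportional to transit length.

The resting pH band defaults to [7.3, 7.8].  Its exact bounds are an
assumption (consistent with a resting pH near 7.5) and are configurable;
outputs label the band used.

Rank comparisons between classes use the two-sided Mann–Whitney U
(`scipy.stats.mannwhitneyu`): exact when both groups have ≤ 12
observations without cross-group ties, otherwise the tie-corrected normal
approximation.  Identical constant groups return p = 1.  An independent
brute-force enumeration over label assignments cross-checks the exact
branch in the tests.

## Competitive fitness

Under constant exponential growth the log of the labeled:spike-in count
ratio, re-anchored to its initial mixing fraction, is linear in time with
slope r_lab − r_ref (the selection coefficient).  The estimator is OLS with
free intercept over the early linear window — 100 min for untreated cells,
160 min with ionophore treatment, whose delayed induction also delays
departure from linearity; a windowed-vs-full RSS comparison warns on
curvature.  Zero-count timepoints are dropped without pseudocounts (a zero
carries no ratio information at cytometry depths).  Mock (treatment without
heat) and mix-in (both strains treated identically) control slopes are
subtracted in rate space, which composes additively for exponential growth:
corrected = raw − mixin − (mock − mixin).  Slopes are optionally re-expressed
relative to complete arrest (slope + r_ref, with r_ref = ln2/70 min for
diploid cells), mapping a fully arrested population to 0.

## Regulon scoring

tpm tables are averaged across replicates within condition before ratios
(the per-replicate-ratio alternative is exposed for sensitivity analysis).
Per gene, induction fold change is (shock + ψ)/(mock + ψ) and acidification
fold change is (shock-with-acidification + ψ)/(shock-without + ψ) within
one translation state; the pseudocount ψ defaults to 1 tpm to stabilize
low-abundance genes and may be set to 0 for exact arithmetic.  Ratios are
summarized in log2 (multiplicative scale); ECDFs are reported on the ratio
scale.  Regulons with fewer than 4 genes are dropped, and genes in the
Hsf1 or Msn2/4 sets are excluded from every other regulon and from the
background, so the canonical heat shock sets cannot leak signal into
bystander sets.  Each regulon's acidification ratios are rank-tested
against background genes; across regulons the pipeline applies
Benjamini–Hochberg adjustment by default.

Because tpm is compositional (columns sum to 10⁶), a genuinely 4× induced
gene set occupying a visible fraction of the transcriptome pulls member
ratios slightly below 4 and background ratios slightly below 1; the
member/background ratio of medians is preserved.  The tests pin this
behavior down in closed form.

## Synthetic data

The generators emulate the assay's study conditions with explicit seeds and
no global state.  Channel noise is multiplicative lognormal with median
exactly 1 (flow signals are positive and right-skewed; the assay's summary
statistics are medians, so with noise off every generator's summary equals
its generating formula to machine precision — a tested invariant).  The
noise magnitude per channel is a configuration default (CV 0.05), not a
measured quantity: the assay does not report per-channel noise.

Defaults are the assay's own scales: 10,000 events per timepoint; buffers
every 0.5 pH unit from 4.5 to 8.5; recovery sampled every 30 min over 4 h;
calibration sigmoid (a, b, c, d) = (2, 1.5, 7, 0.3) with channel
backgrounds (20, 50); induction logistic (9, 0.05 /min, 120 min, 1);
resting pH N(7.5, 0.10), stressed pH N(6.9, 0.15); reference growth rate
ln2/70 ≈ 0.0099 /min; a 40-gene Hsf1-style regulon with a 4× acidification
effect over 2000 background genes at tpm CV 0.2 with 2 replicates per
condition.

The recovery generator encodes the dependency the analysis is designed to
detect: cells first return to the resting pH (logistic in time, midpoint
90 min), and only pH-recovered cells are eligible for high expression
(conditional probability following the induction logistic).  Per timepoint
the two-component log-red mixture is shifted so that the population median
red-per-FSC fold change follows the induction logistic exactly; near the
midpoint the median falls in the low-density valley between modes, where
its sampling variance is intrinsically elevated.  Budding state follows a
Gaussian hump peaking at 120 min of recovery (base 0.25, amplitude 0.35)
and drives a two-component FSC-width mixture.  Spike-in cells are dim in
both pHluorin channels; BV421-bright events and small-scatter debris mix in
at configured fractions.

What the generators do *not* model: optics (spectral spillover,
compensation), doublets beyond pulse width, day-to-day drift of gains
within an experiment, cell-cycle-correlated expression, read-level RNA-seq
error (tpm is the input boundary), or regulon overlap beyond the curated
exclusion rule.  Passing recovery tests therefore demonstrate estimator
correctness under the stated generative assumptions, not robustness to
instrument artifacts.

For induction-curve studies the generator separates two noise channels:
per-event channel CV (the curve value is the median over n cells, default
5000, inheriting only the small sampling error of a median) and a
per-timepoint between-experiment CV.  The delay-recovery studies use the
per-event channel at CV 0.1; with multiplicative curve-level noise of that
size the midpoint of a 9-point logistic is only identifiable to about
±5 min (1 sd), which is the regime the between-experiment knob exposes.

## Numerical choices and problem sizes

Optimizers are deterministic multi-start bounded least squares throughout;
EM uses deterministic quantile initializations.  Ties in fit selection are
broken by explicit rules (RSS then smallest |b|; log-likelihood then larger
separation).  Fold changes at or below zero are floored at 1e-6 with a
logged count before log-domain fitting.  Manifests hash the analysis
configuration (output paths excluded) and contain no timestamps, so
identical runs are byte-identical — verified file-by-file in the tests.

The verification studies use 100 seeded calibration experiments (9 buffers
× 5000 events), 50 induction curves, 200 competition series at depth
10,000, and 100 expression experiments (≈2100 genes × 8 samples); these
sizes give the recovery-rate estimates ~2–5% binomial resolution while the
whole suite remains quick to run.
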