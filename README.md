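# phshock

Analysis pipeline for studying how transient intracellular acidification
gates the heat shock response in budding yeast.

When *S. cerevisiae* is heat-shocked, its plasma membrane leaks protons and
the cytosol transiently acidifies from its resting pH (~7.5) toward ~6.8.
Whether this drop is damage or signal is testable with four kinds of
quantitative data, and this package implements the estimator for each:

1. **Ratiometric pHluorin calibration** (`phshock.calibration`).  The
   405:488 nm excitation ratio *R* of the pHluorin biosensor is fitted
   against buffers of known pH with a four-parameter logistic

   *R*(pH) = *a* / (1 + e^(−*b*(pH−*c*))) + *d*,

   the effective p*K*ₐ is the root of log((*R*−*R*max)/(*R*min−*R*)) = 0,
   and inverting the fit converts per-cell ratios to intracellular pH.

2. **Induction kinetics** (`phshock.kinetics`).  Ssa4-mCherry (an inducible
   Hsp70 reporter) fold change over unstressed cells is fitted in the log
   domain with a constrained logistic fold(*t*) = *a*/(1+e^(−*b*(*t*−*c*))) + *d*,
   *d* ≥ 1; the midpoint *c* is the induction delay.

3. **Subpopulation structure** (`phshock.subpop`).  Two-component Gaussian
   mixtures with a 0.90 posterior cutoff classify cells into high/low
   expressors (log fold change) and budded/unbudded (forward-scatter pulse
   width); Mann–Whitney rank tests compare intracellular pH between classes.

4. **Competitive fitness** (`phshock.fitness`).  Stressed, labeled cells are
   mixed with unlabeled exponentially growing spike-in cells; the slope of
   ln[(n_lab(t)/n_ref(t)) · (n_ref(0)/n_lab(0))] over the linear early
   window is the selection coefficient r_lab − r_ref.

5. **Regulon scoring** (`phshock.regulon`).  From tpm tables, per-gene heat
   shock induction and acidification fold changes (shock-with vs
   shock-without acidification) are summarized per transcription-factor
   regulon (GMT input, ≥4 genes, Hsf1/Msn2-4 members excluded from other
   sets) with rank-sum tests against background genes.

Event selection (`phshock.gating`) reproduces scatter gating against an
unstressed reference, BV421-bright exclusion and strain splitting.  All
inputs can be generated with known ground truth by `phshock.simulate`, and
`phshock.pipeline` orchestrates end-to-end runs with reproducibility
manifests.  A `phshock` command-line tool wraps every stage.

## Worked example

```python
import numpy as np
from phshock import simulate, calibration, kinetics, fitness

truth = simulate.SimTruth(seed=1)
cfg = simulate.SimConfig(n_events=5000, channel_cv=0.05)
tables = simulate.simulate_calibration(cfg, truth)
corrected = {ph: calibration.subtract_background(t, truth.background_405, truth.background_488)
             for ph, t in tables.items()}
fit = calibration.fit_calibration(calibration.calibration_points(corrected))
print(f"effective pKa: {fit.pka_eff:.3f} (true midpoint {truth.calib_c})")

curve = simulate.simulate_induction_curve(truth, channel_cv=0.1, seed=1)
ind = kinetics.fit_induction(curve)
print(f"induction delay: {kinetics.induction_delay(ind):.1f} min (true {truth.ind_c:.0f})")

series = simulate.simulate_competition(0.0056, 0.0099, depth=10_000,
                                       timepoints=(0, 30, 60, 90, 120, 150), seed=1)
est = fitness.fit_growth_difference(*fitness.log_ratio_series(series), window=160.0)
print(f"selection coefficient: {est.slope:+.5f}/min +- {est.stderr:.5f} (true -0.00430)")
```

prints

```
effective pKa: 6.996 (true midpoint 7.0)
induction delay: 120.0 min (true 120)
selection coefficient: -0.00415/min +- 0.00017 (true -0.00430)
```

The effective p*K*ₐ of the sensor is recovered to 0.004 pH from 9 noisy
buffer measurements; the induction midpoint to sub-minute precision from a
9-timepoint curve of medians over 5000 cells; and the planted growth-rate
difference to within its own standard error from multinomially sampled
counts at 10,000 events per timepoint.

Or from the shell:

```
phshock simulate recovery --seed 1 --out runs/sim
phshock run recovery --seed 1 --out runs/recovery
phshock run regulon  --seed 1 --out runs/regulon
```

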