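# rsfpm — flexible parametric relative-survival models and their knot sensitivity

Population-based cancer survival is usually reported as *relative
survival*: the all-cause survival of the patients divided by the
expected survival of a comparable, cancer-free general population taken
from a life table.  Flexible parametric models (FPMs) estimate it by
modelling the log cumulative excess hazard with restricted cubic
splines in log time,

    ln H(t|x) = s(ln t | γ, k0) + x β + Σ_j s(ln t | δ_j, k_j) x_j ,

where the last sum carries time-dependent (non-proportional) covariate
effects.  The analyst must choose the spline degrees of freedom (df) for
the baseline, the main effect of age and the time-dependent effect of
age — and a recurring practical question is how sensitive the reported
estimates are to those choices.

This package implements the full machinery needed to ask that question
on registry-style data, for biostatisticians and cancer-epidemiology
analysts:

* restricted cubic splines with quantile-based knot placement;
* life-table expected mortality (exact annual-band integration);
* period analysis (delayed entry) and the 2nd/98th-percentile age
  constraint;
* the FPM excess-hazard likelihood with analytic score, fitted by
  quasi-Newton iterations;
* age-specific, age-group and internally/externally age-standardised
  predictions with delta-method confidence intervals;
* Ederer II and Pohar Perme non-parametric estimators with delayed
  entry;
* the sensitivity protocol itself: a 60-model df grid
  ({3..7} × {3..5} × {2..5}), minimum-AIC/BIC selection, and
  percentage-point difference tables against the reference model
  (5, 3, 3), including a packaged transcription of published difference
  tables for ten English cancer types;
* a synthetic-registry generator with closed-form ground truth, so the
  whole pipeline is testable without any data access.

See `docs/methods.md` for the model, estimator dialects, and all
numerical conventions.

## Worked example

```python
import rsfpm as R
from rsfpm.fpm import ModelConfig, fit_fpm
from rsfpm.sensitivity import GridSpec, run_grid, select_models

params = R.SimulationParams(n=20_000, seed=20260922)   # registry-like cohort
lt     = R.simulate_lifetable(params)
cohort = R.simulate_cohort(params, lt)
cohort, lo, hi = R.winsorise_age(cohort)               # 2nd/98th pct age clamp
rows   = R.apply_period_window(cohort, (2011.0, 2014.0))

fit = fit_fpm(rows, lt, ModelConfig(5, 3, 3), age_low=lo, age_high=hi)
for age in (55, 65, 75, 85):
    est  = float(R.relative_survival_curve(fit, age, [5.0]).estimate[0])
    true = float(R.true_relative_survival(params, age, 5.0))
    print(f"age {age}: 5-year relative survival {est:.3f} (truth {true:.3f})")
```

prints

```
age 55: 5-year relative survival 0.746 (truth 0.739)
age 65: 5-year relative survival 0.651 (truth 0.650)
age 75: 5-year relative survival 0.546 (truth 0.543)
age 85: 5-year relative survival 0.412 (truth 0.421)
```

— the reference model recovers the generating five-year relative
survival to within one percentage point at every conventional
prediction age.  Running the full grid shows the knot-choice robustness
directly: across all 60 converged models the internally age-standardised
estimate spans about 0.3 percentage points.

The same pipeline is packaged as numbered drivers:

```sh
python analysis/01_simulate.py          # synthetic cohort + life table
python analysis/02_fit_reference.py     # reference model, predictions vs truth
python analysis/03_grid_sensitivity.py  # 60-model grid, selection, differences
python analysis/04_nonparametric.py     # Ederer II / Pohar Perme comparison
python analysis/05_published_summaries.py  # published-table summary statistics
```

each of which writes its tables under `results/`.  A thin CLI
(`rsfpm simulate|fit|grid|nonparam|compare|summarise`) exposes the same
steps for file-based inputs.

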