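# trajsurv

Joint modeling of a longitudinal biomarker and a time-to-event outcome,
built for the question every HIV/CD4 registry analysis eventually asks:
*given a patient's CD4 history up to today, what is their risk of dying
within the next few years — and which joint-modeling framework predicts
that risk better?*

The package implements the two standard frameworks over one shared data
model and lets them compete as dynamic prognostic tools:

- **SREM** (shared random-effect model). The transformed marker follows a
  linear mixed model, `Y_i(t) = β₀ + β₁·sex + β₂·addiction + β₃·age + b_{i0}
  + (β₄ + b_{i1})·t + ε`, and the same random intercept and slope enter a
  Weibull proportional-hazards model: `λ_i(t) = λ₀(t)·exp(α₁·sex + α₂·addiction
  + α₃·age + α₄·b_{i0} + α₅·b_{i1})`. The marginal likelihood integrates the
  bivariate random effects by adaptive Gauss–Hermite quadrature.
- **JLCM** (joint latent class model). The population is a finite mixture
  of G latent classes; each class has its own trajectory intercept/slope
  and its own proportional hazard factor, and the marker and event are
  conditionally independent given class. The likelihood is exact (closed
  form per class). The class number is chosen by BIC among candidates
  whose conditional-independence score test (χ², df = 2) is not rejected.

On top of both: empirical-Bayes posteriors, posterior classification,
dynamic risk prediction `P(event in (s, s+t] | history ≤ s, alive at s)`
over a landmark grid (default s = 1, 1.5, …, 8 years, t = 3 years), and
time-dependent ROC/AUC comparison with a landmark case/control
construction. A synthetic-cohort generator reproduces the structure of the
motivating registry (n ≈ 213, ~24% deaths, ~82% male, median 5 visits), so
the entire workflow is testable without any data download. The science and
numerics are documented in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a heterogeneous three-class cohort, fit both frameworks, select
the class number, and compare predictive accuracy:

```python
import numpy as np
from trajsurv.simulate import separated_jlcm_config, simulate_jlcm_cohort
from trajsurv.data import filter_eligible, summarize_cohort
from trajsurv.jlcm import (fit_jlcm, conditional_independence_score_test,
                           select_num_classes)
from trajsurv.srem import fit_srem
from trajsurv.predict import batch_dynamic_predictions
from trajsurv.accuracy import compare_models

cohort = simulate_jlcm_cohort(separated_jlcm_config(n_subjects=250), seed=1)
data = filter_eligible(cohort.dataset, min_measurements=2).dataset

srem_fit = fit_srem(data)
candidates = []
for G in (1, 2, 3):
    fit = fit_jlcm(data, G, n_starts=3, seed=G)
    candidates.append((G, fit, conditional_independence_score_test(fit, data)))
sel = select_num_classes(candidates)

preds = {"SREM": batch_dynamic_predictions(srem_fit, data),
         "JLCM": batch_dynamic_predictions(candidates[-1][1], data)}
comp = compare_models(data, preds, np.arange(1.0, 8.01, 0.5), 3.0)
```

With summary printing added at each step, this run produces (seed 1):

```
n=213  deaths=46 (21.6%)  median visits=6
SREM: loglik=-1137.12  converged=True
JLCM G=1: loglik=-1138.19  P=14  score=2.277 (p=0.3202)
JLCM G=2: loglik=-1120.85  P=21  score=0.278 (p=0.8704)
JLCM G=3: loglik=-1081.70  P=28  score=2.062 (p=0.3567)
selected G=3
 G       bic  score_p
 1 2351.4364   0.3202
 2 2354.2793   0.8704
 3 2313.5064   0.3567
 class  n_assigned  proportion_pct  mean_max_posterior
     1          78           36.62               0.945
     2          58           27.23               0.960
     3          77           36.15               0.961
average AUC: {'SREM': 0.729, 'JLCM': 0.838}
```

Reading it: the three-class model wins on BIC (2313.5) with the
conditional-independence assumption tenable (p = 0.30); classification is
sharp (mean maximal posterior probabilities ≈ 0.95); and because this
cohort's class-specific mortality is not a monotone function of the CD4
trajectory, the latent-class model's dynamic predictions discriminate
markedly better than the shared-random-effect model's (average landmark
AUC 0.84 vs 0.73).

## Command line

The same workflow is scriptable:

```bash
trajsurv simulate --generator JLCM --truth separated --n 250 --seed 1 --out cohort/
trajsurv fit-jlcm --measurements cohort/measurements.csv --subjects cohort/subjects.csv \
         --classes 3 --starts 3 --seed 7 --out fit.json
trajsurv run-all --config examples/demo.yaml   # full pipeline from a YAML config
```

`run-all` writes the complete bundle — cohort summary, SREM fit table,
class-enumeration table (loglik, P, BIC, score test), selected-class fit
table, classification quality, class-specific survival curves, per-subject
dynamic predictions, the AUC comparison, martingale residuals and a run
log with seeds and versions — and re-running the same config and seed
reproduces every CSV byte for byte.

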