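# actipred

Actigraphy-based modelling of motor activity in depressed inpatients and
prediction of the hospital discharge date.

Psychiatric wards lack objective tools for tracking recovery and timing
discharge. Wrist-worn inertial sensors classify each minute of a daily
2-hour observation block into five states (running, walking, standing,
sitting, lying). `actipred` turns those streams into two daily statistics —
**Activity Time** and **Rest Time**, the best contiguous 30-minute window of
activity-category (resp. rest-category) minutes — and asks two questions:

1. **Does activity rise over the admission?** A two-level hierarchical
   Bayesian linear model regresses normalized Activity Time on Progress
   Towards Discharge, PTD = DoA / length of stay ∈ (0, 1]:

       y_ij = x_ij^T w_j + ε_ij,   w_j ~ N(μ_w, Σ_w),  ε_ij ~ N(0, σ²)

   fitted by empirical Bayes (GLS + EM, monotone in the marginal
   likelihood). A positive population slope μ_w[1] means the ward's
   activity increases as discharge approaches.

2. **Can early activity predict the discharge date?** A hierarchical
   Gaussian process — a shared upper-level function g plus per-patient
   deviations f_n, y = g(x) + f_n(x) + noise with squared-exponential
   kernels — regresses PTD on (Activity Time, Rest Time, DoA). For a new
   patient, each day the most similar training inpatient is selected by
   predictive-likelihood maximization and borrowed as the regressor; the
   predicted progress converts to a date via total = DoA / PTD̂. The
   package ships a mean-trained-PTD baseline and a random-forest
   comparison, plus a leave-one-patient-out harness.

No clinical recordings are bundled; a synthetic cohort generator reproduces
the study conditions (23 patients, stays 5–64 days with median ≈ 20.5,
population trend μ_w ≈ (0.445, 0.123), day noise σ ≈ 0.28) and is itself
first-class, tested code. See `docs/methods.md` for models, parameters and
limitations.

## Worked example

A ward mixing two archetypes — fast improvers (~1 week, high rising
activity) and slow improvers (~4 weeks, low shallow activity) — is where
the hierarchy earns its keep:

```python
from actipred import (two_archetype_configs, generate_clustered_cohort,
                      build_feature_table, HGLMData, fit_hglm,
                      population_line, population_interval)
from actipred.evaluation import HGPPredictor, loo_evaluate
from actipred.baselines import MeanPTDBaseline

cohort = generate_clustered_cohort(two_archetype_configs(), seed=1)
table = build_feature_table(cohort)          # one row per patient-day

post = fit_hglm(HGLMData.from_features(table))
print(population_line(post))                 # (0.688, 0.069)
print(population_interval(post))             # (0.057, 0.081)

hgp  = loo_evaluate(lambda: HGPPredictor(n_restarts=2, maxiter=100), table)
base = loo_evaluate(MeanPTDBaseline, table)
print(hgp.overall_mae, base.overall_mae)     # 1.87 vs 5.38 days
print(dict(hgp.buckets))                     # {'<1': 2, '1-3': 5, '3-5': 1, ...}
```

The fitted population slope 0.069 (78% band 0.057–0.081, excluding zero)
says activity rises towards discharge. The hierarchical GP's leave-one-out
mean absolute discharge error of 1.9 days beats the mean-progress baseline's
5.4 days because the similarity step routes each held-out patient to a
same-archetype regressor, while the baseline averages fast and slow stays
into a systematically wrong pace.

The same pipeline runs from the shell:

```sh
actipred simulate --seed 1 --out sim/
actipred features --states sim/states.csv --truth sim/truth.csv --out features.csv
actipred fit-hglm --features features.csv --out hglm.json
actipred evaluate --features features.csv --predictors hgp,mean_ptd --out eval/
actipred run-all --seed 1 --out run/        # everything, with a manifest
```

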