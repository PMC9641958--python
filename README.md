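# landmarkcox

Dynamic prediction of long-term renal allograft survival by landmarking.

After a kidney transplant, biomarkers such as glomerular filtration rate
(GFR), proteinuria and hematocrit are measured at every follow-up visit. A
conventional ("static") Cox model uses only the values known at
transplantation, so its predictions go stale as the patient's condition
evolves. `landmarkcox` implements the landmarking alternative for
clinicians and biostatisticians who need predictions that update: at each
prediction time s on a predetermined grid, the subjects still at risk are
kept, their covariates are evaluated as of s, and survival over the next w
years is modelled. Stacking all landmark datasets and fitting one Cox
super-model with polynomial landmark-time interactions,

```
h(t | Z, s) = h0(t) · exp( Zᵀ(s) β(s) + θ(s) ),      s < t ≤ s + w
β_k(u) = β_k0 + β_k1 u + β_k2 u²,   θ(u) = θ1 u + θ2 u²,   u = (s − s0)/(sL − s0)
```

yields, for any patient and any prediction time, the conditional survival
S(s + w | s, Z) = exp(−∫ h dt), and for any covariate the standardised
dynamic hazard ratio HR^w(s) = exp(β_k(u(s))) with Wald intervals.

The package provides:

- **`LandmarkSuperModel` / `StaticCoxModel`** — sklearn-style estimators
  for the dynamic super-model and its baseline-only comparator;
- **a Cox engine** with Breslow ties, delayed entry (counting-process risk
  sets) and cluster-robust variances — the combination stacked landmark
  data requires;
- **evaluation**: per-landmark Harrell's C-index and IPCW Brier score with
  subject-level Monte Carlo cross-validation;
- **a synthetic cohort generator** with known ground-truth effects,
  calibrated to the renal allograft study design this method comes from
  (n = 407, quarterly visits, ~87% five-year survival, median follow-up
  ~12 years);
- **a CLI** (`landmarkcox simulate | fit | predict | evaluate | report`).

## Worked example

```python
import numpy as np
from landmarkcox import (LandmarkSuperModel, SimulationParams,
                         kaplan_meier, simulate_cohort)

cohort, visits = simulate_cohort(SimulationParams(n_subjects=407, seed=1))
print("events:", int(cohort.event.sum()), "median follow-up:",
      round(float(np.median(cohort.time_years)), 2), "years")
# events: 97 median follow-up: 11.42 years

km = kaplan_meier(cohort.time_years.to_numpy(), cohort.event.to_numpy())
print(f"5-year survival: {km.at(5.0):.3f}")
# 5-year survival: 0.882

model = LandmarkSuperModel(window=5.0).fit(cohort, visits)   # 41 landmarks on [0, 10]
print(model.coefficient_table()[["term", "coef", "se_robust", "p_robust"]].round(3))
#            term   coef  se_robust  p_robust
#             age -0.431      0.091     0.000
#          weight  0.444      0.102     0.000
#      hematocrit  0.182      0.216     0.400
#    hematocrit:u -1.265      0.571     0.027
#             gfr -0.487      0.248     0.050
#           gfr:u -1.190      0.590     0.044
#     proteinuria  0.146      0.040     0.000
#   proteinuria:u  0.535      0.235     0.023
# proteinuria:u^2 -0.679      0.282     0.016
#         theta:u  2.485      2.324     0.285
#       theta:u^2  2.111      1.435     0.141

print(model.dynamic_hr("hematocrit", s_values=[0.0, 4.0]).to_frame().round(3))
#  landmark    hr  ci_lower  ci_upper
#       0.0 1.199     0.786     1.831
#       4.0 0.723     0.533     0.981
```

Each `coef` is a log hazard ratio per conventional unit (age per 10 years,
weight per 10 kg, hematocrit per 10 percentage points, GFR per 10 ml/min,
proteinuria per 1 g/24 h); `:u` terms are interactions with the
standardised prediction time, so `hematocrit:u < 0` means hematocrit's risk
effect fades at later prediction times — visible in the dynamic HR, which
starts above 1 (not significant) at s = 0 and falls to 0.72 (significant)
by s = 4 years. Per-patient trajectories come from
`model.individual_trajectory(...)`, which returns the conditional 5-year
survival at every landmark plus the real-time within-window survival
curves.

To benchmark dynamic against static prediction:

```python
from landmarkcox import CVPlan, make_grid, monte_carlo_cv
tidy = monte_carlo_cv(cohort, visits, make_grid(0, 10, 0.25, 5),
                      CVPlan(iterations=200, seed=0))
```

which returns per-landmark and overall C-index/Brier means for both models
on held-out subjects.

## Input formats

Cohort CSV: `id,time_years,event,age,sex,weight` (one row per subject,
`event` 1 = allograft failure). Longitudinal CSV:
`id,obstime,hematocrit,proteinuria,gfr` (one row per visit; empty cells are
missing, resolved only by the landmarking carry-forward rule). A
column-rename mapping in the CLI config adapts externally distributed
datasets with different headers.

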