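# glandmark

Dynamic risk prediction from longitudinal cohort data by **generalized
landmark analysis (GLA)**: kernel-localized weighted Cox models indexed by
one or two *landmark variables*, with the classical landmark analysis (LA)
and the static prediction model (SPM) as special cases and comparators, and
a censoring-adjusted accuracy protocol (time-dependent AUC and Brier score
with IPCW, half-split cross-validation, subject-level bootstrap).

## Who this is for

Biostatisticians and epidemiologists who develop prognostic models from
longitudinal studies — repeated clinic visits with time-varying covariates
(e.g., eGFR in chronic kidney disease), a terminal event, and right
censoring — and who want predictions that adapt to the patient's *current*
state rather than to the study's baseline.

## The model

Stack one record per clinic visit made while the subject is still at risk:
covariates Z_ij observed at visit time t_ij, residual follow-up
T_ij = T_i − t_ij, event indicator δ_ij = δ_i.  GLA models the residual
survival from each visit with a Cox working model whose *every* parameter is
indexed by the landmark variable V (a strong time-varying predictor such as
eGFR, or the visit time itself):

    λ(u | Z(s)) = λ0(u, V(s)) · exp{ β(V(s))ᵀ Z̄(s) },   u ≥ 0,

where Z̄ excludes V (its effect is absorbed into the local baseline hazard,
and optionally re-entered linearly within the neighborhood).  Estimation is
local-constant: rows receive kernel weights W_ij = K_h(|V* − V_ij|)
(Epanechnikov or uniform; a uniform kernel is exactly caliper matching), and
a weighted Cox partial likelihood is maximized under working independence
with a weighted Breslow baseline hazard.  The bandwidth is adaptive via a
span γ ∈ (0, 1]: the ⌈γN⌉-th smallest distance between V* and the training
landmark values; γ is chosen by cross-validated Brier score.  The predicted
event probability within horizon τ is

    p* = 1 − exp{ −Λ̂0(τ, V*) · exp(β̂(V*)ᵀ Z̄) }.

Setting V = time since baseline recovers classical LA; a full-span uniform
kernel recovers a single pooled landmark Cox model; SPM is that pooled fit
restricted to the baseline rows.

## Worked example

The synthetic cohort below emulates a CKD-like study in which the log
hazard ratio of a binary exposure *flips sign* over the biomarker range
(+1 below eGFR 44, −1 above 46) — invisible to any global linear model:

```python
import numpy as np
from glandmark import (GLARisk, StaticCoxRisk, simulate_cohort,
                       cross_validated_compare)
from glandmark.simulate import drifted_config

cohort, truth = simulate_cohort(drifted_config(n_subjects=1000, seed=11))

gla = GLARisk(landmark_variables=("egfr",), span=0.2,
              covariates=["age", "exposure"],
              adjust_landmark_linear=True).fit(cohort)
for v in (32.0, 60.0):
    beta = gla._local_fit(np.array([v])).coefficients["exposure"]
    print(f"local log-HR of exposure at eGFR {v:.0f}: {beta:+.2f}")

methods = {
    "SPM": StaticCoxRisk(covariates=["egfr", "age", "exposure"]),
    "GLA(eGFR)": GLARisk(landmark_variables=("egfr",), span=0.2,
                         covariates=["age", "exposure"],
                         adjust_landmark_linear=True, grid_size=15),
}
res = cross_validated_compare(cohort, methods, "SPM", [3.0], n_splits=2,
                              n_boot=200, seed=11, bootstrap="predictions")
print(res[["method", "auc", "brier", "delta_rel_brier",
           "delta_abs_auc"]].round(4).to_string(index=False))
```

Output:

```
local log-HR of exposure at eGFR 32: +0.80
local log-HR of exposure at eGFR 60: -1.17
   method    auc  brier  delta_rel_brier  delta_abs_auc
      SPM 0.7827 0.1487           0.0000         0.0000
GLA(eGFR) 0.8074 0.1428          -0.0391         0.0247
```

The local fits recover the sign flip (truth ±1), and localizing on the
biomarker lowers the cross-validated Brier score by ~3.9% relative to the
static benchmark (negative `delta_rel_brier` is better) while raising the
3-year AUC by 0.025.

## Command line

All subcommands share one YAML config (see `glandmark.config`) and write a
`manifest.json` with seeds and input digests:

```
glandmark simulate    --config run.yaml --out-dir sim/
glandmark fit         --config run.yaml --visits sim/visits.csv --outcomes sim/outcomes.csv --at 35 --out-dir fit/
glandmark predict     --config run.yaml --visits ... --outcomes ... --queries q.csv --out-dir pred/
glandmark select-span --config run.yaml --visits ... --outcomes ... --out-dir span/
glandmark evaluate    --config run.yaml --visits ... --outcomes ... --out-dir eval/
```

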