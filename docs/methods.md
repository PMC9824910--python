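# Methods

## Data model and the landmark dataset

A cohort couples a long-format visits table (subject id, visit time since
baseline, covariate snapshot) with a one-row-per-subject outcomes table
(observed follow-up time `T_i = min(T̃_i, C_i)`, event indicator
`δ_i = 1{T̃_i ≤ C_i}`).  Censoring is assumed independent of the event time
and of the covariates, and visit times are assumed non-informative.  Visit
times within a subject are strictly increasing with the first visit at time
0; all times are numeric offsets in a consistent (but arbitrary) unit.

The landmark dataset stacks one row per visit made strictly before the
follow-up time (`t_ij < T_i`; a visit exactly at `T_i` carries no residual
follow-up and is dropped, counted in a diagnostic).  Each row carries the
residual time `T_ij = T_i − t_ij` and the subject's event indicator.
Missing covariate values are not imputed; such visits are dropped with a
warning.  Rolling history features (windowed mean, least-squares slope) can
be appended per visit; windows with fewer than two observations default to
slope 0 and mean equal to the current value.

## Localization

Weights localize the fit on 1 or 2 landmark variables V at the query value
V\*.  Per variable the distance is `|V* − V_ij|`, divided by the training
standard deviation when `standardize=True` (the default — weights are then
invariant to the measurement scale of V; whether to standardize before
forming bivariate weights is genuinely open, so it is a flag).  Kernels:

* Epanechnikov: `(4h)⁻¹ (1 − u²) 1(|u| ≤ 1)`, `u = distance/h`;
* uniform: `(2h)⁻¹ 1(|u| ≤ 1)` — exactly caliper matching with caliper `h`.

The normalizing constants are retained for definiteness but are immaterial:
the weighted partial likelihood is exactly invariant to the overall weight
scale (proved in tests).  The bivariate case uses a product kernel with
per-variable bandwidths, the standard multivariate local-constant
construction, which preserves the per-variable matching interpretation.
Only local-constant (kernel) estimation is provided; no local polynomials.

The span-based adaptive bandwidth is the `⌈γN⌉`-th order statistic of the
distances (no interpolation), so a uniform kernel is guaranteed at least
`⌈γN⌉` matched rows.  If that order statistic is 0, the smallest strictly
positive distance is used; if every distance is 0 the localization is
degenerate and an error is raised.  A sparse-neighborhood guard requires a
minimum effective event count around the query (kernel-weighted event
count, normalized so the largest weight counts 1; default 10,
configurable).  The guard errs rather than silently widening the
neighborhood, and the error suggests the smallest feasible span.

## Weighted Cox estimation

The local fit maximizes the weighted Breslow partial log-likelihood on the
residual-time scale under working independence (repeated rows of one
subject are treated as independent; uncertainty is handled downstream by
subject-level resampling, so no analytic sandwich variance is computed).
Numerical choices:

* covariates are centered at their weighted means; coefficients are
  reported on the original scale and the center is stored with the fit;
* covariates constant across positive-weight rows are dropped with a
  warning;
* weights are normalized internally to mean 1, making convergence
  tolerances scale-free;
* Newton–Raphson from β = 0 with up to 20 step-halvings per step; stop
  when the score norm < 1e−7 or the relative log-likelihood change
  < 1e−9 (max 100 iterations); the fit is flagged converged only when the
  final score norm is < 1e−6;
* ties are handled by the weighted Breslow approximation (weighted Efron
  is nonstandard, and Breslow composes cleanly with weights);
* ‖β‖ exceeding a bound (default 50) flags monotone likelihood; the fit is
  returned unconverged rather than erroring.

The weighted Breslow cumulative baseline hazard
`Λ̂0(u) = Σ_{event times ≤ u} (Σ tied-event weights) / (Σ risk-set W e^η)`
is a right-continuous step function evaluated at the largest jump ≤ τ.  The
horizon-τ risk is `1 − exp{−Λ̂0(τ) e^{β̂ᵀ(Z − center)}}`; a horizon beyond
the largest residual event time is flagged as extrapolated.

## Prediction strategies

* **SPM** (static prediction model): a unit-weight Cox fit on the baseline
  rows only (one row per subject).  When validated at follow-up visits, the
  covariates observed *at the visit* are plugged into the baseline-trained
  model by default and the risk is read over `[0, τ]` of the baseline time
  scale — the only reading that yields visit-level static predictions
  comparable with the dynamic methods.  A carry-forward mode (baseline
  covariates at every visit) is also implemented; the choice is a
  configuration switch and is recorded in run manifests.
* **LA** = GLA localizing on the visit time.  In this classical mode the
  time effect is absorbed entirely into the local baseline hazard, so the
  landmark variable is *not* re-entered linearly by default.
* **GLA** on arbitrary landmark variable(s): per query, compute weights,
  fit the local weighted Cox, predict.  By default the landmark variables
  are additionally adjusted linearly inside each neighborhood
  (`adjust_landmark_linear`), which guards against within-neighborhood
  trend bias; for time-only localization the default is off, matching the
  classical parameterization.

Per-query refitting is the reference semantics.  A grid-precompute mode
(univariate localization only) fits at quantile grid points of V, drops
grid points failing the sparse-neighborhood guard with a warning, and for
each query linearly interpolates the *log cumulative hazard* implied by the
two bracketing grid fits.  On test cohorts the grid mode agrees with
per-query fits to < 0.05 maximum (and < 0.01 mean) absolute probability
difference; the tolerance is asserted in the test suite.

An advisory (on by default) warns when neither the visit time nor an
age-like covariate appears anywhere in the model, since the timing of the
longitudinal data is then lost; it is a warning rather than an error
because legitimate reduced models exist (e.g., parameter-recovery studies).

## Span selection

The span grid is scored by cross-validated Brier score (the primary
criterion — it uses the actual predicted probabilities, whereas the AUC
uses only ranks), averaged over half-splits of the subjects, with a
bootstrap standard error from subject-level resampling of the validation
records.  Among spans whose Brier lies within one SE of the best, the
smallest is selected.  Spans failing the sparse-neighborhood guard are
excluded; if all fail, the error reports the smallest feasible span.

## Accuracy assessment

Censoring is adjusted by inverse-probability-of-censoring weighting with
`G`, the Kaplan–Meier estimator of the censoring distribution on residual
time pooled over the validation rows (censoring plays the "event" role;
working independence across rows).  At horizon τ:

* cases `{T ≤ τ, δ = 1}` get weight `1/G(T−)`, controls `{T > τ}` get
  `1/G(τ)`, records censored before τ get weight 0;
* the time-dependent AUC is the weighted concordance over case–control
  pairs with half credit for tied predictions (the cumulative/dynamic
  construction); with no censoring it reduces exactly to the Mann–Whitney
  statistic;
* the Brier score is the weighted mean of `(1{T ≤ τ} − p*)²` over all
  records; with no censoring it is the plain mean squared error.

These constructions are fixed here as the standard estimators of the
cited literature; the no-censoring reductions and a hand-computed censored
fixture are asserted exactly in tests.  The product-limit step of the
censoring estimator is implemented directly in numpy because it sits inside
bootstrap inner loops; it is cross-checked against lifelines' estimator.

The validation protocol halves the subjects, fits every method on the
training half, predicts at every eligible validation visit (optionally
filtered into strata such as biomarker bands or visit-time bands), and
reports per-method AUC/Brier with 95% bootstrap percentile intervals and
benchmark differences — relative for the Brier score
(`ΔBS_rel = (BS_m − BS_bench)/BS_bench`), absolute for the AUC.  Splits are
repeated (default 5) and results averaged; defaults mirror a full analysis
(5 splits, 2000 bootstrap draws), while tests and the acceptance script run
scaled down (2 splits, 200 draws).  Bootstrap resampling is at the subject
level to respect within-subject dependence, with training and validation
resampled independently; refitting per training resample is the default,
and a labeled prediction-only fast mode resamples only the validation
records.  Per-split seeds derive deterministically from the master seed.
Delta CIs are computed jointly (both methods on the same resample).

## Synthetic cohorts

The simulator emulates a chronic-disease cohort: roughly annual visits
(Gaussian jitter, floored gaps), an eGFR-like biomarker with a
subject-level linear random-effects trajectory measured with noise (floored
at a small positive value), an age-like and a binary covariate, independent
exponential censoring with an administrative cutoff, and a proportional-
hazards event process driven by the *current latent* biomarker with
per-covariate log hazard ratios that are piecewise-linear in the biomarker
— so the true local coefficient at any biomarker value is well-defined for
recovery tests.  Event times are drawn by inversion from a
piecewise-constant hazard on a fine latent grid (default 0.05 time units,
configurable); beyond the grid the hazard is held at its last value, which
makes the all-effects-zero null *exactly* exponential (asserted by a
Kolmogorov–Smirnov check at n = 5000).

Two canonical scenarios fix the study conditions used throughout the tests:

* **drifted**: the binary covariate's log hazard ratio is +1 below the
  biomarker knot at 44 and −1 above 46.  The biomarker progresses slowly
  here (mean slope −0.5/year) so a subject observed at value v stays on one
  side of the knot over the prediction window; under fast decline the
  post-visit trajectory crosses the knot and *no* landmark working model is
  locally correct — the recognized difficulty of simulating
  landmark-correct data — which would make "the true local coefficient"
  ill-defined.  Recovery is asserted as: the mean local estimate over 20
  replicates lies within two empirical standard errors (the replicate SD)
  of the truth at interior query points on each side.
* **homogeneous**: constant coefficients; used to check that localization
  does not fabricate spurious accuracy gains (deltas stay within bootstrap
  noise).

The default (non-scenario) configuration keeps the faster CKD-like decline
(−2.5/year).  What passing these tests does *not* show: performance under
informative visit schedules, dependent censoring, covariate missingness,
left truncation, or real-data covariate distributions — none of which the
generator emulates.

## Known limitations

* No interval censoring, competing risks, recurrent events, or
  left-truncation adjustment; no time-varying coefficients in residual
  time; no stratified baselines or penalization.
* At most two landmark variables (kernel estimation in higher dimension is
  data-hungry); no Mahalanobis distances.
* The grid-precompute mode interpolates between local fits and is an
  approximation; per-query refitting is the reference.
* Near-separated neighborhoods (monotone likelihood) are flagged, not
  resolved; consider a larger span.
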