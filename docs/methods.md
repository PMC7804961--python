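# Methods

`toolplast` re-implements, as a tested pipeline, the statistical analysis of
tool-use-induced body-representation plasticity across puberty: reach-to-grasp
kinematics before (PRE) and after (POST) tool use, modelled against a
developmental covariate (the puberty score, PS, an integer on 5–20), with the
developmental reversal of the tool-use effect localised by a crossing-point /
interval-of-equivalence procedure.  This note documents the models, the
synthetic-data generator that stands in for the archived cohort, the numerical
choices, and the limits of what the test suite demonstrates.

## Kinematic parameters

Each reach-to-grasp trial is summarised by nine parameters.  The transport
(reaching) component: latency and amplitude of the wrist acceleration peak,
the wrist velocity peak, and the wrist deceleration peak (the deceleration
amplitude is reported as a positive magnitude).  The grip (grasping)
component: the maximum grip aperture (MGA, peak Euclidean thumb–index
distance, mm) and its latency.  Finally the movement time, from movement
onset to stabilised grasp.  Latencies are in ms relative to the detected
onset.

Event rules:

* **Onset** — first sample at or after switch release where wrist speed
  ≥ 10 mm/s (threshold configurable).
* **Stabilised grasp (end)** — first sample after the grip-closure phase at
  which the grip-aperture rate stays below 5 mm/s for ≥ 50 ms while wrist
  speed is below 20 mm/s.  No operational definition of "stabilised grasp"
  is standard; these thresholds are this package's formalisation and are all
  configurable (`DetectionConfig`).

Positions are low-pass filtered with a zero-phase 4th-order Butterworth
filter, cutoff 10 Hz at 200 Hz sampling — the conventional choice for reach
kinematics; zero-phase filtering adds no latency bias.  Speed is the norm of
the differentiated filtered wrist position and acceleration the derivative
of speed.  The filter can be disabled.  Two extraction details matter
numerically:

* Peak values and latencies are refined by a local least-squares parabola
  around the sampled argmax.  The acceleration extrema of a bell-shaped
  reach are shallow, and after low-pass filtering the differentiation noise
  is band-limited (so adjacent samples are correlated); a wider window
  (±15 samples) is used there, against ±5 for the speed peak.
* The MGA is measured on the *unfiltered* aperture: no differentiation is
  involved, the marker noise (0.01 mm) is negligible at that scale, and
  filtering would only smear the asymmetric opening/closing peak and bias
  its latency.

Expected extraction accuracy (verified by the round-trip tests): amplitudes
within 2%; latencies within one sample period (5 ms) plus a ~10 ms bound
covering the filter's interaction with asymmetric extrema and the
sample-aligned onset rule.

## Statistical models

Per parameter (or meta-parameter), a random-intercept linear mixed model on
trial-level rows:

    y ~ condition + poly(PS, d) + condition : poly(PS, d) + (1 | subject)

* The condition factor (PRE/POST session, or FIRST/LAST tool block) is coded
  sum-to-zero as −½ / +½.  Type III Wald χ² tests are only coding-invariant
  under sum-to-zero coding, and this makes the condition coefficient the
  POST−PRE shift at the covariate origin.
* `poly(PS, d)` is an orthonormal polynomial basis (degree d = 1 or 2) built
  by the Forsythe three-term recurrence on the observed covariate values;
  the stored recurrence coefficients evaluate the basis exactly at the knots
  and on out-of-sample grids.  Fitted values and Type III p-values are
  invariant to replacing the basis with raw centered powers (tested).
* Estimation: REML for coefficient and Wald reporting; ML refits for the
  likelihood-ratio comparison of d = 2 vs d = 1 (χ², 2 df: quadratic main
  effect + quadratic interaction; quadratic selected when p < 0.05).  The
  degree selected on the meta-parameter is then used for every parameter of
  that task.
* Wald tests are per-term block χ² = β̂ᵀV⁻¹β̂ with df = block size; no
  Satterthwaite/Kenward–Roger correction and no multiple-testing correction
  across parameters (raw p-values are reported).
* A singular fit (random-intercept variance at zero) is flagged, not fatal.
  Optimisation uses statsmodels `MixedLM` with bfgs → powell → cg fallbacks,
  keeping the best finite likelihood.

**Meta-parameter.**  The nine parameters are summarised by the first
principal component of their correlation matrix (correlation, not
covariance, so the component is unit-independent).  Scores are the
standardized parameters projected on the first eigenvector, sign-fixed so
the velocity-amplitude loading is positive.  The PCA is computed on
trial-level rows pooling both conditions, and the loadings are then fixed
for scoring all rows — one score per trial enters the same mixed model.
Component-wise "global p-values" (reaching: 6 parameters; grasping: 2) are
the Wald tests on each component's own first-PC model.  Subject-mean PCA and
loading definition on PRE-only rows would be alternatives; trial-level
pooled rows are the default because the meta-parameter is used as a
trial-level dependent variable.

**Arm-length estimation.**  The outcome is 100·estimate/veridical forearm
length, which removes growth-driven differences in actual arm length; the
analysis is exactly invariant to rescaling estimates and forearms together
(tested).  **Gesture imitation** totals (0–72, one per subject) use simple
OLS regressions, degree 1 vs 2, selected by the same likelihood-ratio rule
(1 df).

## Crossing point and interval of equivalence

From a fitted model, both condition curves are predicted on a puberty grid
(default 5 → 20, step 0.01 — far finer than the integer scale, so
interpolation error is negligible) at the fixed-effect level.  The POST−PRE
difference has delta-method standard error √(cᵀVc) with c the difference of
the design rows; each grid point gets a two-sided Wald z-test.  Testing is
pointwise at the 5% level by default (no simultaneous band), matching the
per-point significance convention of the procedure.

* **Crossing point** — sign-change root of the difference curve, linearly
  interpolated between grid points.  Multiple sign changes: all roots are
  reported; the primary one is the root inside the widest non-significant
  run.
* **Interval of equivalence** — the maximal contiguous run of grid points
  with p > α containing the crossing.  Endpoints are exact in JSON output
  and rounded outward to integers in table-style output.  When the run
  reaches the scale boundary the interval is simply truncated there (the
  maximal-run rule).
* **No crossing** (possible on user data): the result is flagged
  `no_reversal` and the interval, if any, is anchored at the minimum-|z|
  grid point rather than failing.

Aggregation across parameters reports the mean and median of the
per-parameter crossings, with the meta-parameter's crossing and its global
interval as the primary estimate.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes, so
every stage has a hermetic test bed with known ground truth.

**Cohort.**  Puberty scores follow the published per-score sample counts
(n = 90, scores 5–20); integer counts summing to the cohort size are
reproduced exactly.  Height and forearm length are drawn around the
published per-score means with Gaussian jitter (SDs 7 cm and 1.8 cm — chosen
to match the published per-score ranges); the within-score correlation is
solved analytically so the cohort-level height–forearm Pearson correlation
equals the configured 0.89 in expectation.  Tool length is assigned by the
published height thresholds (≤122 cm → 25 cm, <147 cm → 32 cm, else 40 cm).

**Trial parameters.**  Each parameter follows

    y = β₀ + b_subj + β₁·s + f(PS) + g(PS)·s + ε,

with s = ∓½ the condition contrast, b_subj ~ N(0, σ²_subj),
ε ~ N(0, σ²_res), and f, g polynomials of degree ≤ 2 on the raw puberty
scale.  Setting a *target crossing* c\* adjusts the constant of g so the
population POST−PRE difference is exactly zero at c\* (machine-precision
testable).  Default effects place the reversal at PS 16 with linear g,
signed so early-puberty subjects show larger amplitudes / shorter latencies
after tool use and late-puberty subjects the adult-like reverse; the
arm-length generator places its reversal at PS 7.5.  The study reports no
variance components, so σ_subj and σ_res are documented assumptions per
parameter (e.g. 40/60 mm/s for the velocity peak), sized to give realistic
trial-to-trial scatter.  Half of the residual variance is carried by a
trial-level component shared across parameters (latencies loading +,
amplitudes −), emulating slow-vs-fast trials without changing marginal
variances.

**Trajectories.**  The wrist follows a minimum-jerk path whose distance and
duration realise the row's peak speed (v_max = 1.875·D/T) and movement time;
grip aperture opens from 30 mm along a raised cosine to the row's MGA at its
latency, then closes to the 25 mm object width, completing at 85% of the
movement so that the stabilised-grasp time is governed by the robust
wrist-speed criterion rather than by the aperture-rate tail (where low-pass
ringing at the closure kink would otherwise dominate).  Acceleration and
deceleration parameters are therefore the minimum-jerk-implied values
(|a|_max = (10/√3)·D/T²; extrema at τ = (3∓√3)/6).  Ground truth stored with
each recording holds the *analytic* values of the extraction estimands —
onset as the root of the 10 mm/s speed crossing, end from the closed-form
settle times — so round-trip comparisons are like-with-like.  Marker noise
defaults to the device resolution (0.01 mm).

What the generator does **not** emulate: trajectory curvature and corrective
sub-movements, double-peaked velocity profiles, marker dropout, session
order or fatigue effects, heteroscedastic or non-Gaussian noise, and any
dependence of kinematics on tool length beyond the parameter effects.
Passing tests therefore demonstrate that the pipeline recovers the modelled
structure under its own assumptions — not that those assumptions hold for
any particular real dataset.

## Calibration and recovery (what the suite verifies)

Problem sizes were chosen to keep each check sharp at desk scale:

* Type I error of the interaction Wald test: 500 cohorts of 30 subjects × 6
  trials/session — rejection rate within 5% ± 1.5%.
* LRT selection: ~5% quadratic under a linear truth (500 replicates, 20 × 4);
  ≥95% under a quadratic interaction reaching 5 residual SDs at the scale
  ends (200 replicates).
* Crossing recovery at study scale (90 subjects × 18 trials/session, 100
  replicates): median meta-parameter crossing within ±0.5 of the injected
  16; the interval of equivalence contains 16 in ≥90% of replicates.
* Round-trip trajectory recovery (100 trials) and closed-form minimum-jerk
  oracles at the tolerances given above.

`scripts/acceptance.py` recomputes all of these from scratch for any seed.

## Known limitations

* Only random intercepts — no random slopes or crossed random effects, as in
  the modelled analysis.
* Wald χ² inference is mildly anticonservative in very small cohorts (the
  calibration checks bound this at the simulated sizes).
* The crossing point has no uncertainty interval of its own; the interval of
  equivalence is a pointwise, not simultaneous, band.
* Grasp-end detection assumes a single closure followed by stillness;
  re-grasps or lifts inside the recording window will confuse it.
* The OSF reproduction path (`reproduce_study`) maps arbitrary column
  schemas but has only been exercised against synthetic exports; the
  archive's native schema must be supplied via the mapping config.
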