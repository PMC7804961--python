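# toolplast

Reach-to-grasp kinematics and developmental mixed-model analysis of
**tool-use-induced body-representation plasticity across puberty**.

Using a tool changes how adults subsequently move their free hand — longer
latencies and smaller peaks, as if the arm were represented as longer
("tool incorporation").  A developmental study of this effect measures
reach-to-grasp movements before (PRE) and after (POST) tool use in
participants spanning the whole pubertal range, scores each participant on a
5–20 puberty scale (PS), and asks *where on that scale the tool-use effect
reverses* from the child pattern (faster, larger movements after tool use)
to the adult pattern.  `toolplast` implements that entire analysis as a
reusable, tested pipeline, plus a synthetic-data generator that reproduces
the statistical structure of such a study so every stage can be validated
without the original recordings.

The package is aimed at motor-control and developmental researchers who want
to run this analysis on their own motion-capture data, reproduce the
published results from the archived dataset (OSF accession
[3g9mz](https://osf.io/3g9mz/)), or study the procedure's statistical
behaviour by simulation.

## What it computes

1. **Kinematic extraction** (`toolplast.kinematics`) — from 200 Hz marker
   trajectories (wrist, thumb, index), nine trial-level parameters:
   latencies and amplitudes of the wrist acceleration, velocity and
   deceleration peaks; maximum grip aperture (MGA) and its latency; and
   movement time from onset (speed ≥ 10 mm/s after switch release) to
   stabilised grasp.  Zero-phase Butterworth filtering, configurable
   thresholds.
2. **Mixed models** (`toolplast.lmm`) — per parameter, a random-intercept
   model on trial-level rows,

       y ~ condition + poly(PS, d) + condition : poly(PS, d) + (1 | subject)

   with sum-to-zero condition coding and an orthonormal polynomial puberty
   basis; Type III Wald χ² tests; the degree d (1 vs 2) selected by an ML
   likelihood-ratio test on a **meta-parameter** — the first principal
   component of the correlation matrix of the nine parameters.
3. **Crossing point & interval of equivalence** (`toolplast.crossing`) — the
   PRE and POST curves are predicted on a fine puberty grid; the crossing
   point is where their difference changes sign, and the interval of
   equivalence is the contiguous run of puberty scores where the difference
   is not significant at the 5% level (pointwise Wald z-tests).
4. **Full analyses** (`toolplast.pipeline`) — free-hand PRE/POST, tool-use
   FIRST/LAST block, arm-length estimation (on the percent-of-veridical
   scale) and gesture-imitation regression, each producing a structured
   report with Wald tables, PCA summaries, a crossing table and full
   provenance.
5. **Synthetic cohorts** (`toolplast.simulate`) — cohorts matching the
   published sample structure, trial-level parameters with a configurable
   crossing point, and full minimum-jerk marker trajectories with analytic
   ground truth.

See [docs/methods.md](docs/methods.md) for the models, assumptions and
numerical choices.

## Worked example

Simulate a study-scale cohort whose tool-use effect reverses at PS 16, run
the free-hand analysis, and locate the reversal:

```python
import toolplast as tp

cohort = tp.generate_cohort(90, seed=1)                 # published PS counts
effects = tp.default_effect_specs(target_crossing=16.0)
trials = tp.generate_trial_parameters(cohort, effects, n_trials=18, seed=2)

report = tp.run_freehand_analysis(trials)
print("degree selected:", report.degree_selected)
print("meta-parameter crossing:", round(report.aggregate["meta_crossing"], 2),
      "interval:", report.aggregate["meta_interval_int"])
print(report.crossing_table().to_string(index=False))
```

Output:

```
degree selected: 1
meta-parameter crossing: 16.04 interval: (15, 17)
     parameter  crossing_point  interval_lo  interval_hi
   acc_latency       16.227236         14.0         19.0
 acc_amplitude       15.725273         15.0         17.0
   vel_latency       16.443616         15.0         18.0
 vel_amplitude       15.692758         15.0         17.0
   dec_latency       16.573443         15.0         18.0
 dec_amplitude       16.001834         15.0         17.0
   mga_latency       15.959787         15.0         17.0
           mga       16.110679         15.0         17.0
 movement_time       15.920416         14.0         18.0
       Average       16.072782          NaN          NaN
        Median       16.001834          NaN          NaN
Meta-parameter       16.038130         15.0         17.0
```

Every parameter's PRE/POST curves cross near the injected PS 16, the
meta-parameter (the primary estimate) localises the reversal at 16.04 with
an equivalence interval of [15, 17], and the likelihood-ratio test selects the
linear basis — correct here, since the injected interaction is linear in PS.

The same pipeline runs from raw recordings (`tp.extract_table` →
`tp.run_freehand_analysis`) and from the shell:

```bash
toolplast simulate --config cohort.yaml --seed 1 --out sim/
toolplast extract  --in sim/trials --out trials.csv
toolplast freehand --trials sim/trials_long.csv --out report.json
toolplast reproduce --data-dir osf_download/ --config mapping.yaml --out repro.json
```

`toolplast reproduce` re-runs all analyses on a local copy of the archived
study data and compares crossing points, explained variances and LRT
statistics against the published values at documented tolerances.

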