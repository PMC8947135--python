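# clutterflight

Stereo videogrammetry, flight kinematics and heteroskedastic mixed-model
analysis for honeybees (*Apis mellifera*) transiting a cluttered obstacle
field in a laboratory wind tunnel.

## The problem

Bees foraging in natural landscapes constantly choose between flying *above*
clutter (vegetation-like obstacles) or *within* it, often while contending
with wind. The measurement chain implemented here quantifies how that route
choice and the wind condition shape flight performance, for an experiment in
which single bees fly along a 200 × 191 × 1150 mm tunnel containing a field
of vertical columns (7 mm diameter, three rows of five, two unobstructed
57-mm corridors) of one of five heights (11, 40, 69, 98, 127 mm), in still
air or a 0.54 m/s wind, filmed by two synchronized high-speed cameras at
500 frames/s.

The package covers every stage of the analysis:

- **scene geometry** (`scene`) — tunnel/obstacle layout, corridor and
  clearance queries, the ceiling "excluded zone" (top 15 mm);
- **camera model** (`camera`) — pinhole projection with two-term radial
  distortion, undistortion, midpoint two-view triangulation, and a fixture
  stereo rig;
- **2D measurement** (`tracking`) — median-background subtraction, blob
  detection with intensity-weighted centroids, and single-target
  constant-velocity Kalman tracking with Munkres (Hungarian) assignment
  and gating;
- **3D trajectories** (`trajectory`, `smoothing`) — frame-wise stereo
  fusion, clipping to the obstacle-field transit, excluded-zone screening,
  and quintic smoothing splines with GCV-selected penalty whose analytic
  derivative supplies velocities;
- **flight metrics** (`kinematics`) — per transit: median altitude
  z̃ above the floor, altitudinal range, altitude relative to the obstacle
  tops (z̃ − h), the categorical route (above iff z̃ − h > 0), median
  horizontal ground speed, lateral excursion (IQR of lateral position),
  entry→exit speed change, and obstacle clearance;
- **inference** (`mixedlm`, `analysis`) — the statsmodels-style model core:
  `HeteroskedasticLMM`, a random-intercept (bee identity) linear mixed model
  y_ij = x_ij′β + b_i + e_ij with b_i ~ N(0, σ_b²) and varIdent-style
  stratified residual variances e_ij ~ N(0, σ_g(ij)²), fitted by REML (or
  ML); AIC model selection over the eight variance structures and over the
  three altitude definitions; containment-df Wald F tests; Tukey
  (studentized-range) marginal contrasts; response transforms (x² for
  altitude, log₁₀ for range and speed, ∛ for excursion); Levene checks;
  first-vs-last paired t-tests;
- **synthetic data** (`synthetic`) — a seeded generator of ground-truth
  flights with the experiment's design (58 bees, one field height each,
  5–13 flights, blocked wind, alternating direction) and injected,
  recoverable effect structure, observed through the stereo rig with pixel
  noise and dropout; a small frame renderer exercises the detection stage.

Raw flight videos of this kind are rarely deposited, so the generator is the
package's data source: every stage is testable end-to-end with no downloads,
and recovery of the injected effect sizes through the *entire* chain is the
headline validation.

## Worked example

```python
from clutterflight import (BehaviorConfig, simulate_experiment,
                           process_experiment, effect_summary,
                           required_airspeed)

exp = simulate_experiment(BehaviorConfig(n_bees=8, seed=5))
metrics, rejects, _ = process_experiment(exp)
print(f"kept {len(metrics)} of {len(exp.flights)} flights")
for k, v in effect_summary(metrics).items():
    print(f"{k:36s} {v:8.2f}")
```

prints

```
kept 71 of 71 flights
speed_above_vs_within_pct               42.96
excursion_above_vs_within_pct           30.35
excursion_wind_vs_still_pct             21.76
speed_tailwind_vs_still_down_pct        17.49
still_air_ground_speed_m_s               0.35
median_altitudinal_range_mm             20.38
```

Each percent value is 100·(median_A/median_B − 1) of the recovered
per-flight metrics: bees routed above the obstacles fly ~40% faster and
cast ~36% more widely than bees threading the corridors, wind widens
casting ~19%, and tailwinds speed up down-tunnel flights ~23%; an 8-bee run
recovers these with a few points of sampling noise. Holding the preferred
0.32 m/s ground speed in a 0.54 m/s tailwind requires flying backwards
relative to the air:

```python
>>> required_airspeed(0.32, +0.54)
-0.22
```

The mixed model itself follows statsmodels conventions:

```python
from clutterflight.analysis import fit_lmm, ModelSpec
fit = fit_lmm(metrics, ModelSpec("ground_speed", "route * wind * direction",
                                 ("field_height",)))
print(fit.summary())   # coefficients, sigma_b, per-stratum residual sd, AIC
print(fit.anova())     # containment-df F table
```

A thin CLI wraps the library: `clutterflight all --seed 1 --out run1/`
simulates, tracks, reconstructs and analyzes in one go, writing
provenance-stamped CSV/JSON artifacts (`metrics.csv`, `rejects.csv`,
`trajectories.csv`, `stats_summary.json`).

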