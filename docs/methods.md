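# Methods

This note documents the models and procedures the package implements, the
assumptions behind the synthetic generator, and the numerical choices that
were genuinely open.

## Coordinate frame and scene

World frame: x runs along the tunnel axis (down-tunnel positive), y is
lateral (centerline 0), z is altitude above the floor; mm, right-handed.
The obstacle field's row layout is derived from the corridor width: rows
are spaced so the edge-to-edge gap between adjacent rows equals 57 mm
(center-to-center pitch = corridor width + column diameter = 64 mm), with
the middle row on the centerline. With three 7-mm rows and two 57-mm
corridors in a 200-mm tunnel the outer-row-to-wall gap works out to
~32.5 mm center-to-wall; the corridor width is treated as the
authoritative dimension. The field's longitudinal extent defaults to the
central 40% of the tunnel (x ∈ [345, 805] mm) with columns evenly spaced —
the longitudinal span of the rows is not otherwise constrained, so this is
a declared default, not an inference. A flight is discarded when any raw
reconstructed altitude strictly exceeds 176 mm (ceiling 191 mm minus the
15-mm excluded zone); a sample exactly on the boundary is kept.

## Camera model and triangulation

Each camera is a pinhole with two radial distortion terms: world → camera
by R, t; perspective division; x_d = x_n (1 + k₁r² + k₂r⁴); pixels via
(f_x, f_y) and the principal point. Tangential distortion is excluded —
two radial terms are ample for the mild lenses modeled. Undistortion is
fixed-point iteration (20 iterations or 1e−12), accurate to <1e−9
normalized units over |k₁| ≤ 0.2, |k₂| ≤ 0.05.

Triangulation back-projects the two undistorted rays and takes the
**midpoint of their common perpendicular** (chosen over homogeneous DLT
for its direct geometric error semantics); the mean reprojection distance
over both views is reported per sample, and near-parallel rays
(1 − |d_a·d_b| < 1e−6) raise a degenerate-geometry error.

The fixture rig places two 1280×800, f = 1500 px cameras at
(1500, ±520, 1000) mm aimed at the field center (575, 0, 95) — above and
beyond the up-tunnel end, on opposing sides, viewing down the tunnel
length — with mild barrel distortion (k₁ = −0.08, k₂ = 0.01). Camera
poses, fields of view and distances are fixture constants chosen so the
working section fills the frames and 0.5 px pixel noise maps to ~0.8 mm
median 3D error; calibration estimation itself is out of scope and
parameters are inputs (JSON).

## Detection and tracking

Background is the per-pixel median of the frame stack; detection
thresholds |frame − background| and labels 8-connected components,
reporting intensity-weighted centroids (sub-pixel accuracy on compact
blobs) sorted by area. Tracking is a constant-velocity Kalman filter on
(u, v, du, dv) with discrete white-acceleration process noise
(σ_a = 1.0 px/frame², σ_meas = 0.7 px — declared defaults; no tuning
values exist to inherit), Euclidean gating at 25 px, and Munkres
assignment of gated detections to the prediction (scipy's
linear-sum-assignment solver). Unmatched frames coast on the prediction;
ten consecutive coasts end a track; the longest track wins. One bee flies
per trial, but assignment stays general so reflections/distractors are
handled. In place of an interactive track-checking step, a
median-absolute-deviation pass relabels per-frame displacements beyond
5 MAD as coasted and bridges them linearly — no human in the loop.

## Smoothing and velocities

Each axis of a reconstructed transit is smoothed by a penalized quintic
B-spline minimizing RSS + λ∫(f‴)², the natural quintic smoothing-spline
penalty (quintics are unpenalized, so λ → 0 reproduces degree-≤5
polynomials exactly). The penalty Gram matrix is exact (third derivatives
of quintic B-splines are piecewise quadratic; 3-point Gauss–Legendre per
interval). λ = "auto" minimizes GCV(λ) = n·RSS/(n − tr H)² over a
17-point log grid spanning 16 decades with one local refinement pass — the
wide grid matters because at 500 Hz the useful λ sits many decades above
the naive trace-ratio scale. Interior knots are capped at 120 (knots at
every ~3rd–10th sample for typical transits), far denser than the ≤5 Hz
flight dynamics. Velocity is the spline's analytic first derivative.
Altitude statistics default to the smoothed trajectory (a config switch
selects raw positions); the excluded-zone rule always uses raw clipped
positions, since discard decisions concern where the bee actually flew.

## Flight metrics

Per clipped transit: ground speed = median of √(v_x² + v_y²) (horizontal
plane only); lateral excursion = IQR of y under the type-7 (linear
interpolation) quantile convention — IQR values depend on the convention,
so it is pinned and tested; altitude = median z; range = max z − min z;
altitude_obstacle = median z − field height; route = "above" iff
altitude_obstacle > 0, with the boundary assigned to "within". The
entry→exit speed change uses mean horizontal speed over the last vs first
10% of samples (the window width is a declared choice). A collision flag
marks minimum horizontal clearance ≤ 6 mm (order of a bee's body
half-width); it is approximate — whether wing grazes count is not
resolvable from centroid data. Required airspeed is ground speed minus
signed wind speed (tailwind positive), so holding 0.32 m/s over ground in
a 0.54 m/s tailwind needs −0.22 m/s, i.e. flying backwards relative to
the air.

## The mixed model

`HeteroskedasticLMM` fits y_ij = x_ij′β + b_i + e_ij with a bee random
intercept b_i ~ N(0, σ_b²) and residuals e_ij ~ N(0, σ_g(ij)²) stratified
by any subset of {wind, direction, field height} (varIdent-style; each
stratum's σ is a free parameter, no reference-level scaling). β is
profiled out by GLS; the restricted (or full) log-likelihood is maximized
over (log σ_b, log σ_g) by L-BFGS-B with per-group Cholesky solves.
AIC = −2·loglik + 2·(p_fixed + 1 + n_strata) under either criterion.
Checks in the test suite: exact agreement with OLS in the σ_b → 0 limit,
a brute-force profiled-likelihood grid oracle, and recovery of simulated
variance ratios.

Model selection follows the two searches the analysis needs. (1) Variance
structures: the homoskedastic base plus all seven non-empty stratification
subsets, ranked by **REML** AIC (identical fixed effects). (2) Altitude
definitions for the performance metrics: continuous altitude-above-floor
crossed with field height, continuous altitude-above-obstacles, or the
categorical route, each with wind × direction terms and
altitude-by-wind/direction interactions, ranked by **ML** AIC because the
fixed-effects designs differ and REML likelihoods are then not
comparable; REML criteria remain available on each fit. Responses are
transformed before fitting: altitude², log₁₀ range, log₁₀ speed,
∛ excursion.

Denominator df use the containment method: a term whose design columns
are constant within every bee is tested on n_bees − p_between df,
anything else on n_obs − n_bees − p_within df (e.g. a 5-level
between-bee factor with 58 bees gives F(4, 53); a within-bee factor in a
548-flight, 20-parameter design gives F(1, 475)). Marginal contrasts
average model predictions over the other factors' observed levels (equal
weights, continuous covariates at their means) and adjust pairwise
p-values with the studentized-range (Tukey) distribution at the
containment df. Levene's test defaults to mean centering (classic), with
a median-center option. First-vs-last paired t-tests run per wind stratum
because wind is blocked within each bee's session and so covaries with
flight number. Significance threshold 0.05 throughout.

## The synthetic generator

The generator emulates the study conditions, not bee cognition: metrics
depend only on positional statistics, so casting is a two-frequency
sinusoid (1.8 + 0.45 Hz, random phases) rather than an optic-flow control
law, and no aerodynamics, wing kinematics or collision dynamics are
modeled. Design: 58 bees, one field height each (uniform), 5–13 flights
(uniform, mean 9), wind blocked within a session with random starting
condition, direction alternating.

Injected structure (defaults = the study conditions):

- Route is Bernoulli per height: p_within = 0 / 0.05 / 0.10 / 0.25 / 0.55
  at 11/40/69/98/127 mm — zero at the control height (too short to enter)
  and a majority within at the tallest, rising monotonically in between
  (the intermediate values are declared, not measured).
- Ground speed is constant within a transit, drawn lognormally
  (per-flight log-sd 0.10, per-bee intercept log-sd 0.08) around the
  condition median: tailwind ×1.23, headwind ×1.00 (headwind speeds match
  still air), within-route ÷1.40. The above-route still-air base is
  solved from the lognormal mixture CDF so the **pooled** still-air
  median over both routes is exactly 0.32 m/s, which is how the preferred
  speed is defined. The forward component is v_x = √(s² − v_y²), so the
  horizontal ground speed equals the drawn value at every sample and
  ratios of group medians equal the configured ratios by construction.
- Lateral excursion: the casting waveform is rescaled so the in-field IQR
  equals a lognormal draw (log-sd 0.12) around the condition median —
  12 mm within-route/still (a declared scale, plausible for a 57-mm
  corridor), ×1.36 above-route, ×1.19 in wind. Within-route flights are
  centered in a randomly chosen corridor; the window-dependent coupling
  between casting scale and transit window is resolved by three fixed-point
  iterations.
- Altitude is a mean-reverting wander (AR(1) at 25 Hz, cubic-splined to
  500 Hz, so it survives smoothing) rescaled so the in-field range equals
  a lognormal draw (log-sd 0.25) around 20.9 mm, around a route-dependent
  level: above-route at the ~100 mm preference, shifted +22.2/+26.6 mm at
  the 98/127-mm fields, but never below field top + 22 mm (the preference
  + shift alone would sit exactly at the 127-mm field top, contradicting
  an above-route transit — the published shifts describe the pooled
  population, while the generator's constraint applies to above-route
  flights); within-route at min(preference, 0.7·height). Levels are
  clipped so each flight respects its route and the tunnel bounds.
- Per-bee altitude intercepts: sd 6 mm.

Observation adds isotropic pixel noise (default 0.5 px), independent
detection dropout (default 0.02), and optional distractors; the renderer
(speckled background + Gaussian blob) exists at fixture scale to exercise
the detection stage.

What passing tests show — and don't: the chain recovers *this* structure
(smooth casting, constant-speed transits, lognormal effects) to
sub-millimetre/percent accuracy; real bees add wingbeat-frequency body
oscillation, exposure blur, occlusions by columns, non-stationary speed
profiles and calibration error, none of which are emulated. Recovery here
validates the machinery, not field-readiness for arbitrary footage.

## Problem sizes and determinism

The acceptance script runs the full default experiment (58 bees, ~520
flights, detection-level observation, no rendering) and reports
percent-difference effect recoveries and the median altitudinal range;
the test suite's end-to-end fixture uses 36 bees (~320 flights) and the
model-selection study uses 50 replicates of the truth-level generator —
sizes chosen to keep a full run in the minutes range on one CPU while
leaving the recovered quantities' sampling noise well inside their
tolerances. All randomness flows from a single integer seed through
numpy Generators; rerunning any stage with the same seed reproduces its
artifacts byte-for-byte (provenance headers carry version, seed and
config hash).

## Known limitations

- The Kalman tracker is single-target; identity maintenance across
  multiple animals is out of scope.
- Containment df is a convention, not an exact small-sample theory;
  Satterthwaite/Kenward–Roger approximations are not implemented.
- GCV occasionally undersmooths very short transits (<50 samples); the
  fixed-λ override exists for such cases.
- The collision metric uses a spherical-body approximation at centroid
  level.
- REML/ML optimization is single-start; the profiled surface is smooth
  and unimodal for these designs, and non-convergence is flagged on the
  results object rather than raised.
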