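# Methods

This note documents the models and procedures implemented in `clutterlab`,
the parameter choices made where the experimental description leaves the
design open, and what the synthetic-data generators do and do not emulate.

## Coordinate and unit conventions

All lengths are millimetres, time in seconds, speeds in m s⁻¹.  The tunnel
is a 2000 × 500 × 300 mm box; x runs along the tunnel axis from the clutter
entrance (feeding-chamber side, x = 0) to the hive-side exit (x = 2000);
y is lateral with 0 on the midline (positive = left); z is height.

## Environment generation

Obstacle layouts are drawn by uniform rejection sampling: candidate axis
positions are uniform over the footprint (keeping 60 mm from the end
planes and 15 mm from the side walls) and accepted when the edge-to-edge
gap to every placed obstacle is at least 70 mm.  Two readings of the
"minimal distance of 7 cm" constraint are possible (centre-to-centre vs
edge-to-edge); the edge-to-edge reading is enforced because it is the
conservative one — it is the gap a bee can actually fly through.  The
physical obstacles are full-height 10 × 3 mm cuboids; they are modelled as
vertical axes with a 5 mm circular cross-section, a simplification well
below the resolution any clearance metric here requires.  The second
training environment keeps identical obstacle positions and marks the 32
obstacles nearest the central long axis transparent.  Generation is a pure
function of (config, seed); infeasible packings fail loudly after bounded
restarts rather than degrading the constraint.

## Flight simulator

`simulate_trajectory` integrates a kinematic waypoint-attraction agent at
100 Hz (the recording rate of the original videos).  Per step the velocity
relaxes (rate 4 s⁻¹) toward a desired velocity composed of a goal term
along +x, an attraction toward the bee's lateral route-preference curve,
and a mid-height preference; obstacles inside a 120 mm sensing radius add
an inverse-distance repulsion (the radius is halved for transparent
obstacles, default factor 0.5, emulating their lower visual salience);
Gaussian velocity noise is injected as an Ornstein–Uhlenbeck process whose
stationary SD equals `speed_jitter_sd`.  A hard post-step projection keeps
every sample more than 8 mm from any obstacle axis, so simulated flights
never collide by construction.  Exploratory behaviour is generated by
reversal episodes: at trial *k* their count is Poisson with mean
`n_reversals0 · exp(−exploration_decay · (k−1))`, so naive flights wander
back and forth and experienced flights are direct.  A flight that fails to
reach the exit within the 300 s cap raises a timeout, mirroring the
experimental 5-minute abort rule.

Defaults: cruise speed 0.37 m s⁻¹ (the mean flight speed reported for bees
in this kind of clutter), jitter SD 0.08 m s⁻¹, `n_reversals0 = 6`,
`exploration_decay = 0.5`, between-bee lateral offset SD 60 mm.  The
simulator is a behavioural stand-in that reproduces the qualitative
phenomena the pipeline must detect (exploration → directness, per-bee
route corridors, collision-free clearances); it makes no claim about
bumblebee sensorimotor control, visual processing or learning mechanisms.

## Route-corridor sampler

`sample_route_population` generates analysis-ready directed trajectories
with an exactly known variance structure, which is what calibrating the
similarity index requires.  Bee *i* owns a smooth lateral curve b_i(x) —
a constant offset carrying 60% of the between-bee variance plus two
harmonics carrying 20% each, giving pointwise SD exactly `between_sd` —
and flight *j* adds an independent smooth deviation with pointwise SD
`within_sd` (constant plus four harmonic pairs, equal shares).  With
`between_sd = 0` all flights are i.i.d. (the exchangeability null); with
`between_sd ≫ within_sd` the population is strongly idiosyncratic.
Defaults (60 mm between, 15 mm within, 16 bees × 8 flights) are the
calibration conditions used throughout the tests and the acceptance
script.

What these generators do **not** emulate: measurement noise and tracking
dropouts, wall-following and ceiling effects, saccadic flight structure,
inter-trial memory dynamics, or any asymmetry of the physical setup.
Passing tests therefore demonstrate that the pipeline recovers known
ground truth under clean conditions, not that real recordings would yield
the same effect sizes.

## Preprocessing

The low-pass filter is a second-order Butterworth at 2 Hz applied
forward–backward (Gustafsson's method, which minimises end transients).
Zero-phase filtering is used because positional metrics must not be
time-shifted; the effective magnitude response is the square of the
second-order design, i.e. −6 dB at the cutoff.  Trimming removes samples
within 250 mm of the entrance/exit planes by axial (x) distance — arc
length would differ only for strongly looping ends, which the directedness
rule excludes anyway.  Walking crossings are flagged by a conjunction:
median height below 20 mm **and** median ground speed below 0.05 m s⁻¹
(both config-exposed; no numeric rule is given for the original manual
exclusion).  A flight is *directed* when no drop from the running maximum
of x exceeds 100 mm — small obstacle-avoidance backtracks pass, while
tunnel-scale returns fail; the threshold is strict (`excursion > limit`
rejects).  The characteristics table uses filtered, non-walking flights of
all trials; the similarity analysis additionally requires trimmed,
directed flights from trial 5 onward.  Exclusions are logged with one
primary reason each (priority: walking > not-directed > too-short).

## Flight characteristics

Flight time is last minus first timestamp.  Path length and speed are
3-D (a config switch provides horizontal ground speed; the original
description does not fix the dimensionality).  Sinuosity is path length
over the straight-line distance between the flight's first and last
samples; 1 is a perfectly direct flight.  Speed is central-differenced,
and its variability is the sample SD (n−1 denominator everywhere; a
single-object SD is reported as 0).  Lateral statistics (SD, median,
quartiles with linear interpolation) use y only.  Object clearance is the
minimum horizontal distance from any sample to the obstacle's central
axis, computed for every obstacle whose x lies within the flight's axial
span ("passed" objects); distances are to the axis, not the surface, which
is a constant 5 mm offset shared by all obstacles and therefore irrelevant
to comparisons.

## Similarity index

Distances between flights are symmetric Hausdorff distances on the
top-view (x, y) sample sets (`scipy.spatial.distance.directed_hausdorff`
in both directions; a 3-D switch exists).  For bee *i* with n_i directed
flights, the index numerator — the SD of its n_i(n_i−1)/2 within-bee
pairwise distances — has no sampling degree of freedom and is held fixed;
each of the 1000 bootstrap replicates redraws n_i trajectories *without*
replacement from all directed trajectories of the same environment (focal
bee included, matching the plain reading of "randomly selected
trajectories of the population") and uses the SD of their pairwise
distances as the denominator.  Sample size is matched to n_i so both SDs
estimate spread from equal-sized sets.  Replicates with a zero denominator
are redrawn (capped).  The per-bee index is the mean over replicates; the
population-level test is a two-sided one-sample Wilcoxon signed-rank
against 1, exact when n ≤ 25 with no ties or zeros, else the
tie-corrected normal approximation.  Bees need at least 3 directed flights
(the smallest number giving ≥ 3 pairwise distances).

Calibration, verified in the tests: under exchangeability the grand mean
of per-bee indices sits within 1 ± 0.15 (the ratio-of-SDs estimator is
slightly biased upward at small n_i — Jensen's inequality on 1/SD — which
the band absorbs); under the 60/15 mm corridor conditions every per-bee
index falls below 1 and the median is ≈ 0.22.

## Statistical models

The six characteristics are strictly positive and right-skewed, so the
default family is a linear mixed model on the log scale with a per-bee
random intercept; sinuosity, bounded below by 1, is transformed as
log(sinuosity − 1 + δ) with δ = 10⁻³.  A gamma GLM with log link is
available as an alternative family for fixed-effects fits (no gamma GLMM
backend exists in the dependency set, and the log-LMM covers the
random-intercept case).  All fits feeding likelihood-ratio tests use ML,
not REML.  Several optimizers are attempted and the best likelihood kept,
because the profiled random-effect variance occasionally stalls under a
single method; a residual negative likelihood ratio is treated as a
convergence failure and flagged, never reported as evidence.  The test of
the random intercept halves the χ²₁ tail (the variance is on its boundary
under the null).  Environment is a between-bee factor: likelihood-ratio
p-values for it are calibrated at ≈ 16 bees per environment (verified by
simulation) but anticonservative for much smaller cohorts — the group
comparisons, not the LRT, are the primary between-environment statistic
at small n.  Naive/experienced contrasts use a two-sided Wilcoxon
rank-sum z-test with tie and continuity corrections, Bonferroni-corrected
over the six characteristics; "naive" is each bee's earliest recorded
non-excluded flight and "experienced" its final one, so per-bee
availability governs group sizes.

## Pipeline and reproducibility

One master seed feeds documented SeedSequence substreams (environment,
each environment's simulation, the similarity bootstrap; per-flight
streams use spawn key (bee index, trial)), so any stage or single flight
can be regenerated in isolation.  No output carries a timestamp; every
CSV carries a provenance header (package version, config hash, master
seed), and identical config + seed reproduces every numeric artifact
byte-for-byte.

Problem sizes: the default demo experiment is 8 bees × 15 trials × 2
environments with a 1000-replicate bootstrap.  The test suite exercises
reduced versions (e.g. 4 bees × 8 trials for end-to-end determinism,
200 simulation replicates for the LRT null calibration, 100 for coverage
checks) — sizes chosen to make the statistical assertions stable while
keeping the suite quick to run.

## Known limitations

- The simulator's obstacle repulsion is isotropic and memoryless; real
  bees weigh frontal vs lateral cues and learn object constellations.
- The walking and directedness rules are operationalizations of manual
  exclusions; their thresholds are defensible but not fitted to data.
- The gamma family lacks a random intercept.
- The similarity denominator pool includes the focal bee; excluding it
  would shift indices slightly upward at small populations.
- Hausdorff distance ignores time and direction; two flights tracing the
  same corridor in opposite directions are "similar" by construction.
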