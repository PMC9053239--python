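# Methods

## The lattice model

Cells occupy single sites of an `l × l` grid with no-flux boundaries: edge
sites simply have fewer von Neumann neighbours, and boundary-truncated
neighbourhoods are everywhere normalised by their actual size.  The model
deliberately excludes migration, pushing, mutation/phenotype switching,
stroma and spatially varying drug; its point is to isolate competition for
space between a drug-sensitive and a pre-existing fully resistant
population.

### Per-step update rule

Rates are specified per day and applied over a step `dt` as probabilities
`p = rate · dt` (not `1 − e^{−rate·dt}`; the difference is O((r·dt)²) and
the linear form matches the definition of turnover as a fraction of the
division rate).  With the default `r_S = 0.027 d⁻¹` and `dt = 1 d`,
per-step probabilities stay small.

One step proceeds as follows.  Only cells occupying a site at the start of
the step act, in a uniformly random order; daughters placed during the step
do not act until the next one.  Each cell, in turn:

1. dies with probability `δ_T dt` (site freed immediately); otherwise
2. attempts division with probability `r_S dt` or `r_R dt`.  An attempt
   with no empty neighbour at that moment is recorded as *blocked*.  An
   unblocked sensitive attempt is killed by drug with probability
   `d_D D/D_max` (cell removed, no daughter); otherwise a same-type daughter
   fills a uniformly chosen empty neighbour site, and occupancy updates
   immediately, so earlier events within a step constrain later ones.

This serialization is one consistent reading of the model's rate
description; any consistent scheme converges to the same dynamics as
`dt → 0`.  Since no event removes a cell other than the acting one, the
"still alive" check is vacuous and the rule is a pure sequential pass.  The
update is implemented as a numba kernel, reseeded on every step from a
`SeedSequence`-derived 31-bit stream, making a step a pure function of
(state, run seed, step index): runs are bitwise reproducible, and a matched
continuous/adaptive pair shares its per-step streams.  The test suite
validates the kernel against an exhaustive enumeration of the probability
tree (all processing orders × event outcomes) on small lattices via a
chi-square test.

### Seeding

`N0 = round(n0 l²)` cells are placed (round-half-even), of which
`R0 = round(f_R N0)` are resistant, floored at 1 whenever `f_R > 0` —
seeding is integral, and a nominal resistant fraction should not silently
produce a fully sensitive tumour.  Three geometries: uniform random
placement; rectangular resistant nests (for the one-cluster/two-cluster
experiments) with sensitive cells scattered over the remaining sites; and a
densely packed central disk (the `N0` sites nearest the centre, ties broken
lexicographically).  Nest *separation* is the edge-to-edge gap in lattice
sites along the axis joining the nests, placed symmetrically about the
centre; two 2×2 nests at separation 0 reproduce the single 2×4 block
exactly.

### Treatment and outcome

The dosing controller is evaluated once per step, before the lattice
update, from the current burden; thresholds can therefore be overshot by
one step, which is accepted.  Adaptive withdrawal triggers at
`N < (1 − w) N0` (default `w = 0.5`) and resumption at `N ≥ N0` — resumption
uses `≥` because exact equality is unattainable on a discrete stochastic
trajectory.  Progression is the first time `N ≥ 1.2 N0` with `t ≥ 150 d`;
the 150-day floor absorbs brief overshoots at the end of early off-cycles,
and is applied identically under both schedules.  Cure is `N = 0`; runs
reaching the ten-year horizon (`t_end = 3650 d`) are censored.  A *cycle*
is counted at each resumption after a completed excursion below the
withdrawal threshold.  TTP gains are reported in months of 30.4375 days
(365.25/12).

## The mean-field twin

The ODE system shares all rates with the lattice, with `K = l²`.  The
sensitive drug factor `(1 − 2 d_D D/D_max)` makes net sensitive growth
negative at full dose with `d_D = 0.75`: drug kill at division costs both
the mother and the prospective daughter.  Integration uses adaptive
explicit Runge–Kutta (`RK45` by default, `DOP853` selectable) piecewise
between dose switches, with the threshold crossings located by integrator
event functions and the hysteresis state carried across segments — unlike
the lattice model, switching is exact here.  Progression uses the same
20%/150-day criterion, located by linear interpolation on the daily output
grid.  Default tolerances are `rtol = atol = 1e-8`; the logistic closed-form
check uses `1e-10`.

In the mean-field model adaptive therapy is never inferior to continuous
therapy; on the lattice it can be, through stochastic nest extinction and
competition-induced branching morphology — this qualitative difference is
asserted by the test suite, and quantitative lattice/ODE agreement is
deliberately not.

## Competition metrics

- **Blocked fraction**: blocked/attempted divisions pooled over a trailing
  window, reported as missing where no attempts occurred.
- **Neighbourhood composition**: fractions of sensitive/resistant/empty
  among each resistant cell's existing neighbours, averaged over resistant
  cells; sums to 1 by construction.
- **Per-capita growth**: centred difference of log counts over a window
  (default 10 d), missing at zero counts.
- **Nest summary**: 4-connected resistant components (matching the
  interaction neighbourhood); convexity of a component is its area divided
  by the area of the convex hull of the union of its unit squares.  The
  pixel-union convention keeps single cells well-defined (convexity 1) and
  scores every rectangle exactly 1; it matches the "solidity" measure of
  common imaging toolkits.

## Experiments

Per-replicate seeds derive from `SeedSequence(base_seed, spawn_key=(condition,
replicate))`, so sweep tables are byte-identical across runs and independent
of execution order.  Censoring is flagged per pair and gains are reported
with medians/quartiles alongside means.

The growth-law study seeds resistant-only, drug-free populations: counts ≤ 8
as a single compact rectangle (small populations grow as one colony), larger
counts scattered uniformly.  Each mean trajectory is aligned onto the
logistic reference by starting it at the time the logistic curve reaches its
initial count; sub/super-logistic character is summarised by time to half
capacity and by the signed area between the curves.  From two cells growth
is strongly sub-logistic (surface-limited); from thousands of scattered
cells it is super-logistic early on (every cell borders empty space).

## Fitting longitudinal burden series

Normalised total cell number `N(t)/N0` is compared directly to the
normalised burden measurement (e.g. PSA relative to its value at treatment
start).  The objective is the RMSE between the data and the replicate-mean
model trajectory (25 stochastic replicates per candidate by default;
deterministic for the ODE engine), linearly interpolated to the observation
times.  Replicate seeds are fixed across optimiser evaluations (common
random numbers), making the objective deterministic.  When a series carries
recorded on/off intervals the simulation is driven by them; otherwise by
the adaptive threshold controller — both readings are supported because
trial data typically record the schedule, while pure simulation studies do
not.

Global search is basin-hopping with a Powell local refinement under box
bounds, repeated from 10 uniform-random starting points (50 basin-hopping
steps for 2 free parameters, 75 for 4), keeping the restart with the lowest
AIC, computed as `m ln(RSS/m) + 2k` (Gaussian likelihood up to constants).
Three variants: Model 1 frees (n0, f_R, c_R, d_T); Model 2 frees (n0, f_R)
with (c_R, d_T) = (0.78, 0.14); Model 3 frees (c_R, d_T) with (n0, f_R) =
(0.59, 0.04).  Default bounds are [0, 1] for cost and turnover — the fixed
cohort-mean cost of 0.78 in Model 2 shows the search space must extend
beyond the 0–50% range used in the simulation sweeps.

### Synthetic cohorts

`generate_synthetic_cohort` stands in for trial data so the fitting
machinery is testable offline: each patient with known (n0, f_R, c_R, d_T)
is simulated under the threshold-driven on/off protocol, sampled at a
monthly cadence (30 d), subjected to multiplicative log-normal observation
noise, and normalised to baseline; the recorded on/off intervals accompany
the series.  The generator emulates the sampling cadence, normalisation and
schedule-driven cycling of intermittent-therapy PSA series.  It does *not*
emulate PSA production kinetics (burden is proxied by cell number directly),
3-D growth, measurement floors/limits of detection, or patient selection
effects — parameter-recovery results on synthetic cohorts therefore
demonstrate the optimiser and the identifiability of (c_R, d_T) under the
model's own assumptions, not clinical estimation accuracy.

Cycle detection on sampled series uses inset thresholds (excursion
registered at the corridor midpoint, return within 2% of baseline), since a
monthly-sampled trajectory essentially never touches the exact switching
values.  The fast/slow cycling classification threshold (default 365 d) is
a configuration value, not a scientific claim.

## Problem sizes and numerical choices

Benchmark experiments use 50 matched pairs per condition (sweeps in the
original study design use 250–1000 replicates; 50 keeps the standard error
of mean TTP gains around 0.5 months at the headline condition while keeping
the full suite fast).  The chi-square kernel validation uses 10⁵ one-step
replicates with bins of expected count ≥ 5 lumped into a tail.  Parameter
recovery uses 10 noise-free synthetic patients fitted with the ODE engine
(2 restarts × 5 basin-hopping steps; the noise-free landscape is smooth and
unimodal in practice).  Bootstrap orderings use 2000 resamples.

Known limitations: the rate→probability linearisation mildly distorts
high-rate regimes (`r dt` near 1); the one-step controller lag slightly
biases adaptive switching relative to the exact-event ODE; censored arms
make pair gains undefined (flagged, excluded from means); and 2-D surface
growth is slower than real (3-D, vascularised) tumour growth, so fitted
turnover values are not directly interpretable clinically.
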