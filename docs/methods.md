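# Methods

## The model

`hrssm` treats a tracked animal's positions as a hidden Markov state
estimated from receiver detection counts.

**Movement (process) model.**  Within its active hours the animal follows a
bivariate Ornstein–Uhlenbeck (OU) process: white-noise forcing of intensity
ε (m²/min per coordinate, independent coordinates — circular home ranges
only) plus a linear restoring force of strength k (min⁻¹) toward the
home-range center.  The discrete transition over Δt minutes is exact (no
Euler error): an AR(1) with coefficient e^(−kΔt) and innovation s.d.
σ(Δt) = sqrt(ε(1 − e^(−2kΔt))/(2k)).  σ is evaluated via `expm1` so it is
continuous through k = 0, where it takes the Brownian limit sqrt(εΔt); this
matters for samplers that wander near k = 0.  The stationary distribution is
Gaussian with per-coordinate variance ε/(2k), so the distance from the
center is Rayleigh and the 95% occupancy radius is sqrt(−ε ln 0.05 / k).
The pair (k, radius) is the reporting parameterization used throughout;
ε is always the derived quantity.

**Observation model.**  One ping per minute; receiver j detects a ping
emitted at distance d with probability invlogit(α_day + β_day d).
Detections of the same ping by different receivers are conditionally
independent given position.  Counts pooled over a step of m minutes are
modelled Binomial(m, PD) with the latent position held constant within the
step.  This is exact for a motionless animal and an approximation otherwise;
its consequences are quantified below.

**Inference.**  The joint posterior of (center_x, center_y, k, radius) and
the latent per-step positions is sampled by Metropolis-within-Gibbs:

- center coordinates: Gaussian random walk on the natural scale;
- k and radius: random walk on the log scale (with Jacobian), respecting
  positivity and spanning the order-of-magnitude uncertainty typical of
  short tracks;
- a joint "ridge" move that rescales k while holding ε = radius²k/ln 20
  fixed (radius ← radius·e^(−δ/2) when k ← k·e^δ).  On short tracks the
  posterior is tight in ε but diffuse along the (k → 0, radius → ∞)
  direction; the ridge move traverses that direction directly and is what
  keeps R̂ < 1.1 at desk-scale chain lengths;
- latent positions: single-site Gaussian random walks, updated as
  alternating even/odd blocks (conditionally independent given neighbours),
  vectorized across the block.

Proposal scales adapt toward target acceptance rates (0.44 scalar,
0.30 latent) during burn-in only, so the post-burn-in kernel is fixed and
the chain targets the exact posterior.  Any sampler with the same stationary
distribution is conformant; the contract is distributional.

Default chain settings follow common practice for this model class: 3
chains, 10,000 burn-in iterations, 10,000 post-burn-in iterations thinned
by 10.  `MCMCConfig.scaled_down()` (2,000 + 2,000, thin 5) is the desk-scale
profile used by the replication studies and the acceptance script.
Convergence is the classic Gelman–Rubin potential scale reduction factor per
parameter; a fit with any R̂ ≥ 1.1 is returned but flagged, and replication
studies exclude such fits from coverage rather than conflating sampler
failure with model miscoverage.

**Priors.**  k ~ Uniform(0, 1 min⁻¹); radius ~ Normal, truncated at zero
(negative radii are meaningless; truncation is the minimal fix), default
mean 0 and s.d. 10⁴ m; center coordinates ~ Normal(0, 10⁶ m).  All defaults
are nearly flat relative to a coastal array's extent.  Informative radius
priors can be supplied as (mean, sd) or BUGS-style (mean, precision); a
bounded uniform is also available.

## Initialization and numerical choices

- Chains start from data-driven values: detection-weighted centroids of
  receiver coordinates (per step for latents, overall for the center),
  k = 0.01 min⁻¹, radius = twice the spread of the step centroids — plus
  per-chain jitter so the convergence diagnostic is honest.
- Detection probabilities are evaluated with the logit clamped at ±36:
  invisible at double precision, but keeps exp() finite and the curve
  monotone for extreme calibrations.
- Steps with zero detections on every receiver are retained; under the
  likelihood they correctly say "probably far from all receivers".
  An entirely zero matrix still runs but is flagged weakly identifiable.
- Pooling blocks are aligned within days and never straddle a night, so the
  step length must divide the 840-min active day (15 min → 56 rows/day;
  a 90-min step does not divide 840 and is rejected).
- Overnight gaps: the species modelled is inactive and buried at night, so
  by default consecutive active days chain contiguously — the overnight
  transition is an ordinary one-step transition (`night_gap="contiguous"`).
  The alternative `"elapsed"` policy spans the full wall-clock night,
  letting the process relax toward the center; both the simulator and the
  likelihood accept the flag.
- Replicate seeding uses `numpy.random.SeedSequence(base_seed,
  spawn_key=(replicate,))`: auditable, parallel-safe, reproducible in
  isolation.

## What the synthetic generator emulates

The generator reproduces the canonical validation design: a 5×5 grid of
omnidirectional receivers at 300-m spacing; 12 tracking days of 14 active
hours at one ping per minute (10,080 positions); four movement-parameter
combinations crossing slow/fast exploration (k = 0.001, 0.01 min⁻¹) with
small/large ranges (radius = 245, 387 m); and a day-varying detection
calibration.  The default calibration — α = 1.0 ± 0.1, β = −0.006 ± 0.0003
across days — gives a 50%-detection distance of 167 m and ~47 expected
detections per 15-min step for a fish near the array center, matching the
published detection rates for this design, with a realistic ceiling
(detectability ≈ 0.73 immediately next to a receiver: collisions and
ambient noise keep real arrays well below 1).

It does **not** emulate: physical acoustics (multipath, thermoclines,
currents), transmitter code collisions, environmental covariates in the
detection curve beyond the day index, elliptical or multi-state home
ranges, or tag loss/mortality.  Passing tests therefore demonstrate
statistical correctness of the estimator under the model's own assumptions
plus the documented within-step-movement misspecification — not robustness
to every field condition.

## Problem sizes in the shipped studies

Full-fidelity replication (50 replicates, 12 days, 10,000 burn-in) is a
cluster-scale computation.  The shipped studies use a scaled-down profile
chosen as the smallest design that still exercises every code path and
yields interpretable coverage: 3 tracking days, 10 replicates,
`MCMCConfig.scaled_down()` chains, with the R̂ < 1.1 gate unchanged.  The
long-run simulator checks use ~2×10⁶ one-minute positions, enough to
estimate the stationary variance to ~1% and the occupancy radius to well
under 1% at k = 0.01.

## The time-step bias, and a known discrepancy

Pooling detections over longer steps degrades estimation of k for
fast-exploring fish: within a 30-min step a fish with k = 0.01 min⁻¹ moves
~100 m (s.d.), so the static-position binomial likelihood is badly
misspecified and k's coverage collapses (the package's scaled studies show
k coverage falling from ~90% at 15-min pooling to ~40–60% at 30-min, while
radius and center remain well covered).  The *direction* of the failure in
this implementation is underestimation: the pooled counts are best
explained by a latent path that behaves like the within-step average of the
true path, and block-averaging raises the lag-1 autocorrelation above
e^(−kΔt) (direct moment computation on true simulated paths gives an
implied k ≈ 0.006 at 30-min pooling for true k = 0.01).  Field reports for
this design describe the bias as overestimation instead; within the
detection-rate and detection-range constraints of that design we could not
reproduce that sign — reconstruction noise in the latents would have to
dominate the averaging effect, which requires far less informative counts
than the design produces.  Users should treat k estimates at ≥30-min
pooling as unreliable in either direction and prefer 15-min or finer steps,
which is also the practical recommendation in the field.

## Known limitations

- Movement parameters are constant over the track: no behavioural states,
  no time-varying k, ε or center, no hierarchical multi-fish pooling.
- Home ranges are circular (isotropic noise); elliptical variants require a
  correlated-noise OU not implemented here.
- Coordinates are planar meters (e.g., UTM); no geographic CRS handling.
- The calibration (α, β) series is estimated in a separate step and treated
  as known by the state-space fit; its uncertainty is not propagated.
- Runtime grows linearly in steps × receivers × iterations; month-long
  series at fine steps call for the full profile and patience, or a
  different inference backend.
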