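# Methods

## Model overview

`ctlsim` simulates cytotoxic T lymphocytes (CTL) patrolling a planar tissue
of immobile cells and controlling a spreading infection. The tissue is a
lattice of `n_rows × n_cols` sites (default 320×320 = 102 400 cells) of
diameter 10 µm with toroidal boundary conditions, so the simulated patch
behaves as if embedded among statistically similar neighbours. Sites carry
one of four labels — non-susceptible, susceptible, infected, dead — and are
never created or destroyed. CTL and virions move off-lattice with
floating-point positions; positions are coarse-grained to a 1 µm grid for
contact detection. All agents update at a fixed time step (1 s at full
scale; 5–10 s in reduced presets), with per-step event probabilities
`1 − exp(−rate·δt)` so that every event is an exponential waiting time
regardless of the step; configuration validation rejects any step at which
a per-step probability reaches 0.1.

### Infection

Infected cells die cytopathically with a 1.4-day half-life and spread in
one of two modes:

- **diffuse** — each infected cell converts one uniformly chosen
  susceptible cell at rate `r + ln2/1.4` per day, with cytopathic death
  retained, so the realised net growth rate equals the target `r` (default
  1/day, doubling time ln 2/r ≈ 16.6 h). A `diffuse_literal` flag instead
  applies the literal rate `r` with cytopathic death disabled; either way
  uncontrolled growth is `r`. No virions are involved.
- **clustered** — infected cells emit virions (calibrated rate, see below)
  from their surface in uniformly random fixed directions; virions travel
  in straight lines (default 10 µm/min), are cleared with a 4 h half-life,
  and infect the first susceptible cell whose centre comes within the
  contact radius. This is a deliberately minimal mechanism for generating
  compact foci, not a model of intercellular transmission.

### CTL behaviour

A CTL is a three-state machine. *Searching*: persistent random walk —
straight segments of 25 µm joined by turns through a uniform deviate on
[−45°, +45°] (a discrete ±45° option exists); with probability
`chemotaxis_prob` a turn instead points exactly at the nearest living
infected cell (conjugated targets included; with no infected cells the turn
falls back to random). Turns occur at segment ends, scan completions and
lysis/release events, and never change speed. *Scanning*: on entering
contact with a new uninfected living cell the CTL pauses for the scan time
(5 s). *Conjugated*: contact with an infected cell starts a fixed 30 min
handling time, after which the target dies and the CTL resumes searching.
Multiple CTL may bind one target without changing the lysis time, which is
governed by the first-attached CTL; when a target dies, every attached CTL
is released immediately with a turn event. A CTL can kill repeatedly.

Contact detection uses an *entering* rule: a contact fires only when the
coarse-grained position crosses from outside to inside the contact disc of
a site centre, and the most recently scanned site is excluded until a
distinct contact occurs. Being inside a disc is not itself a contact — this
prevents a CTL that has just finished scanning from instantly re-scanning
the neighbours it is already touching, which would let scan-time-limited
oscillations dominate the surveillance rate. Dead cells are not scannable
and are never chemotaxis targets, but their sites persist.

### Protocol

A run seeds one infected cell at a uniformly random site, grows the
infection without CTL to a prescribed count `I_C`, then places `n_ctl` CTL
uniformly at random and continues to extinction, saturation or `t_max`
days. Founder infections that die out before `I_C` are rerun on a fresh
random substream and counted. Outcomes are classified extinct if the
infected count reaches zero, otherwise by the sign of the OLS gradient of
the infected count over the final 12 h (negative → extinct).

## Dual engine

The update rules are implemented twice: a readable pure-Python/numpy
reference engine (`step`, `ctl_update`, `diffuse_infect_step`) operating on
`TissueWorld` objects, and a numba-compiled whole-run kernel
(`ctlsim.engine.run_abm`) used by `run_simulation` and every
replicate-heavy experiment. Both apply the same per-step order — virions;
infected-cell production/infection and cytopathic death; CTL in freshly
shuffled order — and the test suite checks their emergent statistics
(surveillance rates, growth rates) against each other, so the reference
engine serves as an independent oracle for the kernel. Kernel runs are
bit-reproducible from a single integer seed; replicate and retry seeds are
spawned from `numpy.random.SeedSequence`.

## Calibrations

**Surveillance rate.** The rate `k` (distinct-cell scans per CTL per
minute) is measured by placing 100 CTL on uninfected, non-susceptible
tissue and counting completed scans. `k` rises monotonically with the
contact radius, which is therefore calibrated by bisection against a target
rate. With velocity 7.5 µm/min and 5 s scans, a contact radius of 7.21 µm
(frozen as the package default) yields `k ≈ 1.1` cells/min. The same
geometry at 0.18 µm/min yields `k ≈ 0.0298` cells/min rather than the
0.022 sometimes quoted for such slow cells; this is structural, not a
tuning failure. Any kinetics of the form `time-per-cell = a + b/v` with a
non-negative stationary component `a` (scan time) and speed-independent
path geometry `b` that passes through (7.5 µm/min, 1.1 cells/min) gives
0.026–0.029 cells/min at 0.18 µm/min; matching both literature rates
exactly would require `a ≈ −11 s`. We therefore calibrate to the fast
rate and use the *measured* slow rate of the same geometry wherever a `k`
is needed (e.g. the `r/k` normalisation of critical densities), keeping
the simulator self-consistent.

**Virion production.** For clustered infections the growth rate is set by
virion production, speed and clearance, with production dominant. The
calibration sweeps production rates around a centre (default ±5% in 21
points; the test preset uses wider, coarser sweeps), runs replicate
CTL-free growth simulations, estimates each run's growth rate by log-linear
OLS on the infected count from the point it first reaches 50 cells
(avoiding founder stochasticity), regresses mean growth on production, and
solves for the target `r`. The package default (1.527 virions/cell/day,
64×64 tissue, 10 s steps) was frozen from this procedure and re-simulating
at it recovers `r = 1`/day within the replicate CI.

## Deterministic comparators

The simple mass-action model `dT/dt = (r − kC)T` is evaluated in closed
form; its critical density is `r/k` (with `r` converted to per-minute and
`C`, `T` as fractions of surveyable cells). The extended model follows the
conjugate age density `X(t, τ)`: free targets grow at `r` and enter
conjugation at rate `k·C_free·T` (the boundary inflow `X(t, 0)`);
conjugates age deterministically and at age `h` the target dies and the CTL
returns to the free pool; conjugated targets neither replicate nor are
re-attacked. Total CTL `C_free + ∫X dτ` is conserved by construction
(`C_free` is recomputed from the conjugate total every step, holding the
invariant to round-off).

Numerics: age transport uses a uniform τ grid with time step equal to the
age resolution (escalator-boxcar: exact advection, no numerical diffusion).
Two first-order biases are corrected: half of each newly formed cohort is
held back one step so the mean age at death is exactly `h`, and the
reaction step uses a midpoint estimate of `C_free` (deaths release and
conjugation binds CTL gradually across a step). The scheme remains globally
first-order in Δτ because cohorts have finite width; the default
resolution Δτ = h/300 puts the discretisation error well below 0.1% even
with ~40% of the CTL pool sequestered, and halving Δτ moves trajectories
by <0.1% (tested). The critical density of the extended model is found by
bisection on the sign of the fitted log-linear growth rate of free targets
over the final 20% of a 20-day horizon, with a coarser Δτ = h/60 (only the
sign matters there); it reduces exactly to `r/k` at `h = 0` and tracks the
quasi-steady-state estimate `r(1 + kT₀h)/k` within a few percent.

## Critical-density estimation

The stochastic `C*` is the CTL fraction at which 50% of replicates go
extinct. `extinction_probability` runs independent replicates at a density
and reports the extinct proportion with a Wilson interval. The adaptive
search evaluates broadly spaced guesses, widens geometrically until the 50%
crossing is bracketed, then bisects on the proportion point estimate
(ties at exactly 0.5 move toward smaller C) until the bracket width falls
below a tolerance, retaining every evaluated point. The sigmoid
`p(C) = C^α/(C^α + C*^α)` — the two-parameter Hill form, which pins
`p(0) = 0`, `p(C*) = ½`, `p(∞) = 1` — is fitted to all points by
Nelder–Mead in log-parameter space, minimising replicate-weighted least
squares (a binomial-likelihood loss is available), with three starts of
increasing steepness. On synthetic curves the fit recovers noiseless
parameters to 10⁻⁴ relative, and `C*` to within 5% under binomial noise at
200 replicates per point.

## What the synthetic conditions do and do not show

The generator's conditions are the study conditions: immobile target cells
on a planar lattice, a single calibrated growth rate, fixed handling time,
perfect recognition on contact, and chemotaxis as an idealised
"point-at-nearest-target" turn with unlimited range. Passing tests shows
that the implementation reproduces the model's internal predictions (the
mass-action limit, handling-time inflation of `C*`, the clustered and
chemotactic contrasts) — not that real tissues obey them. In particular
target-cell motility, eclipse phases, epitope dynamics, non-lytic
suppression and 3-D geometry are all outside the model (the 3-D lattice
return probability is computed only as a plausibility argument for why
search should be more limiting in 3-D).

## Problem sizes used by the test suite

Full-scale runs (320×320, 1 s steps, 200 replicates per density) mirror
the reference protocol but take hours to days; the package's own
verification uses proportionally matched reductions, chosen once: a 64×64
tissue with the infected fraction at CTL introduction matched to full
scale (1% ≈ 41 cells; 4% for handling-limited cells; 0.4% for
early-introduction chemotaxis), 10 s steps for slow-CTL (0.18 µm/min)
regimes and 5 s steps for fast-CTL (7.5 µm/min) regimes so the 5 s scan
time is resolved, 15 days (slow) or 8 days (fast) of simulated control,
and 50 replicates per density for the relative-`C*` estimate (20 per arm
for the one-sided clustered-vs-diffuse and chemotaxis contrasts). The
surveillance calibration itself runs at full agent count (100–200 CTL).
Directional claims are tested as one-sided Fisher exact comparisons of
extinction counts at matched densities bracketing the 50% crossing, which
is equivalent in direction to comparing the fitted `C*` values but far
cheaper.

## Known limitations and interpretations

- Whether dead cells remain scannable, whether conjugated infected cells
  keep producing virions (default: yes, they are living targets until
  lysed), and the fate of additionally bound CTL on a shared dying target
  (default: immediate release) are not constrained by the sources for this
  model family; each is an explicit switch or documented default.
- The two literature surveillance rates cannot be reproduced by one contact
  geometry (see Calibrations); the fast rate is authoritative for
  calibration here.
- Scan and handling durations are quantised to whole time steps (ceil), so
  a 10 s step stretches the 5 s scan to 10 s; fast-CTL experiments
  therefore use a 5 s step.
- At reduced scale the CTL count at the fast-regime critical density is
  small (single digits), so density granularity contributes visibly to the
  extinction-curve steepness there; the slow regime (≈100 CTL at `C*`)
  does not have this issue.
- The clustered-vs-diffuse contrast for fast CTL is a genuine scale
  property that reduced tissues cannot show. With 25 µm persistence and
  7.5 µm/min velocity the CTL motility diffusion constant is
  D ≈ 94 µm²/min, giving a diffusive search range of roughly 2 mm over an
  8-day control window. On the full 3.2 mm tissue a CTL far from a single
  focus therefore never finds it, which is what makes clustered infections
  require more CTL; on 0.64–1.28 mm tissues every CTL reaches the focus
  within the run, and the short within-focus search time plus retention of
  CTL at the focus make clusters as easy as, or easier than, diffuse
  infections. We measured no separation at 64×64 and a reversal at
  128×128; the corresponding directional check in the test suite asserts
  the full-scale direction and is expected to fail at reduced scale.
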