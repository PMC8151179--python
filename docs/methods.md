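# Methods

## Model

The granulator barrel is modelled as a chain of well-mixed compartments.
The state in each compartment is a particle number density n(x, t) over
the internal coordinate x = particle volume (μm³), discretized on a
fixed grid.  Each compartment evolves the population balance

    ∂n/∂t = ½∫₀ˣ β(x−ε, ε) n(x−ε) n(ε) dε − n(x)∫₀^∞ β(x, ε) n(ε) dε
            + ∫ₓ^∞ b(ε, x) S(ε) n(ε) dε − S(x) n(x)

over a dimensionless horizon of 1.0 per compartment; the rate constants
β₀ and S₀ absorb the (unmodelled) residence time.  The wetting zone
(conveying elements, low shear) carries aggregation only; kneading
zones add breakage.  Each compartment's outlet feeds the next, so
simulated PSDs can be compared against samples taken at ports along the
barrel.

### Aggregation kernels

The aggregation kernel factors as β₀·β(x, ε) — a constant efficiency
times a collision frequency.  Classical kernels (sum, product) cannot
turn a unimodal feed bimodal, so all variants superimpose a step on a
product-type frequency; combinations of particles beyond a critical
size aggregate faster:

* **tanh double step** — low plateau `top2` for small combinations, high
  plateau `top1` beyond `R2`, zero beyond `R1`, each step smoothed by a
  hyperbolic tangent of width δ.  The step condition compares
  s = (x² + ε²)^½ (volume space) with R³, R in μm.  Defaults place the
  second step at 7000 μm equivalent diameter — above every admissible
  grid, so particles cannot aggregate out of the system — and use sharp
  smoothers (δ = 10 in volume units).
* **circle step** — the sharp single-step limit of the above on the same
  circular locus.
* **square step** — the step condition is separable and evaluated in
  equivalent-diameter space: the multiplier `step` applies as soon as
  *either* partner exceeds R (μm).  Powers 1/3 on each volume.
* **square step, tunable power** — same locus with exponent p (default
  2/5) on each volume, decoupling the spacing of the two granule modes
  from the feed.

Convention note: the printed step conditions of the circle/tanh
variants are dimensionally loose (volumes against a length).  This
package evaluates the circular loci in volume space against R³ and the
square loci in equivalent-diameter space against R, which keeps R in μm
on all variants and makes R for the square step snap naturally onto the
grid's representative diameters.

### Breakage

Selection is linear in the cube root of mother volume, S(m) = S₀·m^⅓.
The daughter law combines erosion and binary breakage: a fraction
`fprim` of mother mass leaves as fragments whose *equivalent diameters*
are Gaussian N(μ, σ²) (μ, σ in μm), the rest splits uniformly in
daughter volume (two daughters on average).  The erosion Gaussian is
deliberately expressed in equivalent-diameter space so μ has the same
units and meaning as the critical size R — the parameter-reduction
protocol ties μ = R.

## Discretization

* **Grid** — geometric in volume, 35 bins spanning diameters 1–4000 μm
  by default; edges at geometric midpoints, outer edges half a ratio
  step out.  Largest representative diameter must stay below 7000 μm.
  The grid is fixed within any one analysis.
* **Aggregation** — fixed-pivot sectional scheme: a newborn aggregate of
  volume v_i + v_j is split between the bracketing representative sizes
  with weights conserving both number and mass exactly (in exact
  arithmetic).  Pairs whose aggregate would exceed the largest
  representative volume do not react at all (neither birth nor death),
  so no mass flows over the top of the grid.
* **Breakage** — per-bin daughter numbers integrate the daughter law in
  closed form (normal CDF in equivalent-diameter space; the binary term
  is elementary).  The continuous law is only approximately
  mass-conserving — the Gaussian is truncated at both ends and carries a
  cubic-moment bias of (1 + 3σ²/μ²) — so every mother column is rescaled
  to conserve mass exactly; a solver that leaks mass would invalidate
  every downstream conservation check.  A mother whose daughter law has
  no representable mass receives an identity column (breakage no-op).
* **Time integration** — `scipy.integrate.solve_ivp` with LSODA,
  rtol 10⁻⁸, atol 10⁻¹⁰ × initial total number.  LSODA behaves like an
  explicit Adams method in the non-stiff regimes and switches to BDF
  automatically; this matters because calibration explores rate
  constants up to β₀ = 10⁻⁶ and S₀ = 10², where the system is stiff and
  a purely explicit integrator either stalls or undershoots.  Total
  mass is a linear invariant of the right-hand side and is preserved by
  the integrator to roundoff; the solver still verifies a relative
  drift below 10⁻⁶ and treats terminal negatives beyond the absolute
  tolerance as failures (smaller undershoots are clipped and logged).

## Calibration objective and noise floor

Two PSDs are compared by the energy distance (a maximum mean
discrepancy) between their volume-fraction views, supported on the
representative diameters in μm (a log-diameter option exists but is off
by default; whether the original analyses weighted by volume or number
is not documented, and volume fractions are what the instruments
report).  The measurement-error threshold is the median — robust to
outlying repeats — of all pairwise distances among repeated
measurements.  A swept parameter is *practically identifiable* at that
error level iff exactly one swept value brings the simulation below the
threshold.

## Parameter reduction

The depletion point — the size class where the fines peak of a bimodal
wetting-zone PSD dies out toward larger sizes — is detected as the
first local minimum after the first local maximum of the
volume-fraction curve, smoothed by a centred width-3 moving average; a
peak requires a strict rise into it so flat baselines never count, and
ties break toward the smaller size.  Votes across process conditions
(majority, ties toward smaller) give one depletion class per
formulation.

Forward simulations with the sharp square-step kernel show the detected
class sits exactly two size classes above the generating R, for
structural reasons: particles in the first class strictly above R gain
the stepped aggregation channel against the entire fines population, so
the collapse starts one class above R; and the width-3 smoothing
displaces the minimum one further class while its window still contains
the fines tail.  `reduce_parameters` therefore maps the voted depletion
class down by `DEPLETION_TO_R_OFFSET = 2` classes to obtain R.  The
offset was constant across every tested regime (rate scales, step
heights, feed shapes, kernel powers, noise up to scale 0.1).  The
protocol then sets μ = R, σ = 50 μm (neither tight nor broad erosion),
leaving two free wetting parameters (step, β₀) and three free kneading
parameters (β₀, S₀, fprim).

## Particle swarm optimization

A seeded global-best PSO (swarm 30, 150 iterations, inertia 0.72,
cognitive = social = 1.49 — standard constriction-type settings; the
budget is sized for desk-scale studies) minimizes the energy distance.
Bounds are handled by reflection with velocity damping.  Early stopping
on a 40-iteration stall or an objective below 10⁻¹².  Rate constants
(β₀ in [10⁻¹⁶, 10⁻⁶], S₀ in [10⁻⁵, 10²]) are searched in log₁₀ space:
their plausible ranges span decades, and a linear search concentrates
the initial swarm in the extreme-rate regime where a compensating
aggregation/breakage balance reliably traps the optimizer away from the
true basin (observed as a stable spurious optimum with objective ≈ 4).
`step` ∈ [1, 10⁴] and `fprim` ∈ [0, 1] are searched linearly.  A
failed simulation yields an infinite objective; if more than half the
initial swarm is infeasible the bounds are rejected.  Results record
the seed and the per-iteration best-objective trace and are
reproducible end-to-end.

## Synthetic data

No granulation PSD measurements are deposited, so the package generates
its own study inputs:

* **Preblend** — lognormal in diameter (median 50 μm, geometric SD 1.6 —
  typical of a milled lactose/MCC blend), evaluated deterministically on
  the grid (density × local bin width), scaled to 3×10⁸ particles per
  reference volume.  The total number sets the aggregation timescale:
  at the reference efficiency β₀ = 7×10⁻¹² it gives an O(1) extent of
  aggregation per residence time, producing partial fines depletion and
  clear bimodality rather than either a frozen or a fully-granulated
  PSD.
* **Reference conditions** — tanh kernel with R2 = 500 μm, top1 = 10,
  top2 = 1, β₀ = 7×10⁻¹²; square-step counterpart with R snapped to the
  representative nearest 500 μm and step = 50; kneading truth
  β₀ = 2×10⁻¹², S₀ = 2×10⁻³, fprim = 0.3, μ = R, σ = 50 μm.  These were
  chosen once, from forward-simulation scans, to reproduce the
  canonical qualitative picture (surviving fines peak, detectable
  depletion point, moderate breakage).
* **Measurement noise** — multiplicative log-normal per bin, amplitude
  growing linearly from 0.5× to 1.5× the base scale toward the coarse
  bins (repeated measurements of granular material scatter more at
  large sizes); replicates are renormalized to the parent's total
  volume.  Liquid-to-solid ratio is represented only through its
  modelled consequences (higher β₀ ⇒ smaller surviving fines peak), as
  no quantitative L/S → parameter mapping is available.

What passing tests on these data do and do not show: they demonstrate
that the algorithms are implemented correctly and that the protocol is
self-consistent (parameters used to generate data are recovered).  They
do not validate the model against real granulation physics — real
preblends are not exactly lognormal, instrument noise is not exactly
log-normal multiplicative, and real residence-time and liquid effects
are absorbed into per-compartment rate constants.

## Numerical choices and degenerate inputs

* Depletion detection returns a flagged "no depletion point" outcome
  (None) for unimodal curves; `reduce_parameters` then raises, advising
  full calibration of R.
* Plateau detection uses maximal runs whose min-max range stays below
  `flat_tol` (default 10⁻³) on the min-max-normalized profile; NaN
  points (failed simulations) terminate runs and are excluded from
  normalization.
* Intermediate-level counting uses a tolerance of 1% of the plateau gap.
* Zero-mass PSDs are rejected as degenerate wherever a volume-fraction
  view is required.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`).

## Problem sizes

The shipped analyses use the 35-bin grid, 201-point R2 sweeps, 10
noisy repeats for the noise floor, and single-compartment PSO runs
(≤ 4500 forward simulations each, a few milliseconds per simulation).
These sizes reproduce the qualitative phenomena sharply and keep any
analysis runnable on a laptop within minutes.

## Known limitations

* One internal coordinate (volume); liquid content, porosity and shape
  are not tracked, and rate constants are per-compartment lumps with no
  throughput/screw-speed dependence.
* The depletion-to-R offset of 2 classes is tied to the sharp
  square-step kernel and the width-3 smoother; markedly different
  kernels or smoothing windows would need the offset re-derived.
* The fixed-pivot scheme suppresses aggregates beyond the top
  representative; with feeds concentrated near the grid top this
  becomes a physical truncation, so grids should span the expected
  granule sizes with headroom.
* PSO convergence to the global basin is empirical, not guaranteed; the
  recovery checks run at fixed seeds, and independent seeds were
  observed to agree to well under 1%.
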