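# Methods

## The model

`oikofeed` models carbon uptake by a single *Oikopleura dioica* as a chain
of two buffered pools.  Environmental food carbon FC (µgC l⁻¹) is filtered
into the house contents HOU, ingested from the house into the gut contents
GUT, and assimilated from the gut into the organism.  Each flux is a
Michaelis–Menten function of its own substrate — filtration of the external
concentration, ingestion of the house content, assimilation of the gut
content — so each step saturates independently, mirroring the separate
mechanical structures (tail pump and filters, mouth and pharyngeal filter,
digestive epithelium) that carry it.  All maxima share a common allometric
factor BO^b and temperature factor t10^T.

Two discrete processes interrupt the smooth dynamics:

* **House renewal.**  The house is discarded (HOU → detritus pool DET) and
  replaced by an empty one at fixed intervals given by the renewal
  configuration.  Renewal times are scheduled deterministically at every
  multiple of the lifespan from the start of the run.
* **Egestion.**  The gut has a hard capacity `nbfp·fpp·BO^b`.  On reaching
  it, one pellet of weight `fpp·BO^b` moves to the faecal pool FEC.  Pellet
  formation is thus driven purely by gut filling: if ingestion stops, pellet
  production stops.

The model deliberately omits growth, respiration, reproduction, the carbon
cost of house production, and any particle-size selectivity (it is meant
for mono-algal feeding conditions where size selection is uniform).  Body
weight is a forcing constant within a run.

### Parameters

| symbol | meaning | units | default |
|--------|---------|-------|---------|
| f    | max filtration intake at 0 °C | µgC µgC⁻ᵇ d⁻¹ | 3.7 |
| kf   | filtration half-saturation (external food) | µgC l⁻¹ | 150 |
| b    | allometric exponent | – | 0.9 |
| t10  | 10th root of Q10 | – | 1.06 |
| i    | max ingestion intake at 0 °C | µgC µgC⁻ᵇ d⁻¹ | 1.2232 |
| ki   | ingestion half-saturation (house content) | µgC µgC⁻ᵇ | 0.0282 |
| a    | max assimilation intake at 0 °C | µgC µgC⁻ᵇ d⁻¹ | 0.4818 |
| ka   | assimilation half-saturation (gut content) | µgC µgC⁻ᵇ | 0.0029 |
| fpp  | faecal pellet size proportion | µgC µgC⁻ᵇ | 0.0175 |
| nbfp | mean pellets resident in the gut | – | 3.368 |

The defaults are the canonical calibrated set; `HIGH_FPP_PARAMETERS`
(fpp = 0.03) is an alternative preset reflecting in-situ gut-volume
estimates, which raises the gut capacity of a 1 µgC animal from 0.059 to
about 0.10 µgC.  Internal units are days and µgC d⁻¹ throughout; hours and
minutes appear only at reporting interfaces.  The constraints a < i and
ka < ki (assimilation cannot outpace ingestion) are enforced by the
parameter type and by the estimation layer.

### House lifespan

The empirical temperature regression for house renewal is not reproduced
here; the lifespan is a pluggable configuration (`HouseRenewalTable` or any
callable `T → hours`).  The shipped default is a nearest-anchor table pinned
at 15 °C → 2.91 h and extended to 10 °C → 4.12 h and 20 °C → 2.06 h by a
Q10 ≈ 2 decline, valid for 10–20 °C (±2.5 °C); temperatures outside raise a
configuration error.  All quantitative reference values in the tests are at
15 °C, where the anchor is exact.

### Allometry

Trunk length is converted to carbon weight by a two-stage power-law
composition (trunk → total length → weight) with pluggable coefficients.
The shipped reference configuration is a synthetic anchor fit: a log-log
least-squares power law through the three published pairs (350 µm, 0.62 µgC),
(637 µm, 3.97 µgC), (690 µm, 4.93 µgC), split over a nominal 4× trunk-to-
total factor.  It reproduces the anchors within 2 % and stands in for the
original regressions, which are not redistributed.

## Numerics

The dynamics between events are smooth and non-stiff (the right-hand side
is bounded by the rate maxima), so the integrator is a fixed-step classical
4th-order Runge–Kutta scheme with step ≤ 1e-4 d (≈8.6 s), implemented as a
numba kernel.  Design choices that matter:

* **Segments.**  Scheduled times (renewals, food-schedule breakpoints, run
  end) delimit segments inside which the forcing is constant; steps never
  straddle a segment boundary, so renewal times are hit exactly.
* **Egestion events** are unscheduled state events.  A step that carries GUT
  across capacity is bisected (64 iterations) to locate the crossing, the
  pre-egestion state is recorded at the event time, and one pellet weight is
  subtracted.  Capacity minus one pellet is strictly positive (nbfp > 1),
  so a single subtraction always suffices at this step size.
* **Coincident events.**  A renewal at the same instant as an egestion check
  is applied first; it does not change GUT, so only the event-log order is
  affected.
* **Exact carbon balance.**  The running integrals of the three fluxes are
  advanced with the same RK4 stage weights as the states, making
  `filtered = ΔHOU + ΔDET + ΔGUT + ΔFEC + assimilated` an algebraic identity
  of the scheme; the trajectory check holds to ~1e-13 relative.
* **Pool depletion.**  Substrate-empty pools are protected by clamping: if a
  step would drive a pool below zero (possible only for extreme parameter
  proposals during calibration), the overdraw is charged back to the
  outgoing flux, preserving the balance exactly.
* **Four-cycle runs** start from an all-zero state and include the start-up
  transient, matching the published simulation protocol.  Runs are either a
  number of house cycles or an absolute duration; starvation runs keep
  renewing houses by default (new houses start empty), with a flag to
  disable renewal for single-cycle protocols.

## Derived statistics

Time-averaged rates are computed from the flux integrals over the run (or,
optionally, over the final complete house cycle, which excludes the start-up
transient).  The efficiencies I/F and A/I are exactly weight-independent by
construction; the trajectories of HOU and GUT scale exactly as BO^b.

Two defecation-interval statistics are reported.  The plain DI is the mean
of all pellet-to-pellet intervals (the interval from run start to the first
pellet is a start-up artefact and never counted).  Within each house cycle,
however, the interval shrinks monotonically to a settled cadence as
ingestion recovers from the post-renewal empty house, so intervals that span
a renewal carry the same artefact.  The *steady* DI therefore averages the
last non-renewal-spanning interval of each cycle; it is the cadence at which
the pellet-production rate saturates, and the gut passage time is defined on
it: GPT = DI_steady × nbfp.  At 15 °C, FC = 150 µgC l⁻¹ this gives ≈55 min,
consistent with a pellet-rate plateau near 3.5 h⁻¹.

The *apparent* half-saturation of a mean rate with respect to external food
is read off a sweep: the plateau is the value at the top of the grid (no
fitting choice), and the half level is located by monotone linear
interpolation.  The sweep must genuinely saturate — the curve may not rise
by more than 0.1 % of the plateau over the final grid step — otherwise a
range error is raised; the identity "exact Michaelis curve in → its K out"
holds once the grid top is far above K.  With the default grid (0–800,
plateau at 800) mean ingestion halves at ≈31 µgC l⁻¹ and mean assimilation
at ≈11 µgC l⁻¹.  The assimilation value is a robust property of the model
(insensitive to averaging window, grid density and body weight): below the
pellet onset the assimilation rate is input-limited (A ≈ F), which pins its
half level near the concentration where filtration reaches half the
saturated mean.

## Starvation protocols

An alimentary interruption sets the food to zero instantly.  Filtration
stops at once; the house keeps feeding the gut until it empties through
ingestion; the gut then drains through assimilation.  A compartment's
emptying time runs from the shortage until its content falls below 1 % of
what it held at the shortage (the reference content is taken at the first
sample after the shortage, so an event coinciding with the interruption is
already applied).  The house time follows the full post-interruption
trajectory and is truncated at the next scheduled discard if the 1 % level
is not reached before it.  The gut time zeroes the house at the moment of
interruption so the gut drains by assimilation alone; two variants exist —
a fixed initial gut of 0.05 µgC (≈1.31 h at 15 °C, matching the implicit
closed-form drain time t = [(X₀−X₁) + K·ln(X₀/X₁)]/Vmax), and the natural
gut content at interruption, which makes the time fluctuate with the
faecal-pellet phase (≈1.14–1.48 h).  Interruption sweeps place the
interruption at evenly spaced moments of the fourth house cycle
(three lead-in cycles, so the organism is in its quasi-stationary regime);
the default resolution of 100 moments resolves the pellet-phase oscillation.

## Calibration

The four parameters θ = (i, ki, a, ka) are estimated by least squares
against condition-tagged observations; for each parameter proposal the model
runs four house cycles from a zero state at every distinct condition
(temperature, food, body weight) and the matching summary quantity is
compared in the observation's units.  The cost is the unweighted sum of
squared errors by default — keeping the residual-variance scaling of the
covariance consistent when the noise is homoscedastic — with optional
per-observation weights for other noise models.

The optimiser is a hybrid: `scipy.optimize.dual_annealing` (no local
search) over a bounded box, followed by bounded L-BFGS-B.  Both stages work
in the transformed space z = (ln i, ln ki, ln a/i, ln ka/ki): logarithms
even out the parameter scales and the ratio coordinates make the strict
ordering constraints part of the box geometry rather than a penalty cliff.
The quasi-Newton stage is followed by a Nelder–Mead polish and a final
L-BFGS-B pass, because the cost surface carries weak kinks (egestion events
crossing cycle boundaries) that can stall a finite-difference line search
slightly above the optimum.  With the default six-series design and
noise-free observations, recovery of all four components is exact to within
numerical precision across seeds.

Uncertainty comes from the Gauss–Newton Hessian 2 JᵀJ (central-difference
Jacobian of the residual vector; positive semidefinite by construction),
scaled as cov(θ̂) = σ̂²(JᵀJ)⁻¹ with σ̂² = cost/(n−4).  95 % intervals are
the 2.5/97.5 percentiles of a multivariate-normal sample around θ̂, and the
mean relative cost change across the feasible draws measures how flat the
cost is inside the sampled cloud.  A non-positive-definite Hessian raises,
with an optional eigenvalue-clipping remediation that is always flagged.
`fit_least_squares` (scipy's trust-region-reflective solver on the residual
vector) is provided as the refit of choice for replicate studies started
near a known solution.

### Synthetic observations and what they certify

`generate_synthetic_observations` emulates the structure of the calibration
conditions: six series over a 10–400 µgC l⁻¹ food gradient — filtration,
ingestion and assimilation rates plus assimilation efficiency at 15 °C for
a 3.97 µgC organism, ingestion efficiency at 15 °C, and an ingestion series
at 20 °C for a 0.62 µgC organism — with optional absolute or relative
Gaussian noise (floored at zero).  Pellet-rate observations are supported by
the cost function but excluded from the default design: a counted rate
responds to parameters in discrete jumps, which suits the annealing stage
but degrades finite-difference gradients.

Passing recovery tests on this surface certifies the estimation machinery
(cost, search, covariance), not the field accuracy of the parameter values:
the synthetic generator shares the forward model, has no model error, and
its noise is Gaussian and independent, none of which holds for laboratory
data.  One structural property carries over to any data of this type: at
quasi-steady feeding each rate equals its input regardless of its
half-saturation constant, so ka (and to a lesser degree ki) is informed
only by start-up transients and the ~5 % gut-full depression of A.  Under
5 % relative noise ka is effectively unidentifiable — (a, ka) trade off
along a ridge — while the observable they control, the effective
assimilation plateau a·cap/(ka + cap), remains well determined.  The
replicate coverage study therefore uses small absolute noise (σ = 0.01 µgC
d⁻¹), where the problem is locally identifiable and the linearised
intervals attain near-nominal coverage.

## Known limitations

* The house-lifespan table and the allometric reference coefficients are
  anchored approximations, not the original regressions; users with access
  to those regressions should supply them via the configuration.
* Temperature is constant within a run; fluctuating temperature, stochastic
  house loss, particle-size selectivity, growth and respiration are out of
  scope.
* Pellet production is driven by gut filling alone, so the model produces no
  pellets below ≈27–30 µgC l⁻¹ of food; real animals egest (smaller, less
  compacted) pellets there, and gut-throughput statistics below the onset
  should not be trusted.
* The apparent assimilation half-saturation of the model (≈11 µgC l⁻¹) sits
  below the commonly quoted ≈15 µgC l⁻¹; see the statistics section above
  for why the model's value is structurally pinned.
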