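# Methods

This note documents the models implemented in `scpsim`, the parameter
choices behind them, what the synthetic data emulate, and the numerical
conventions a user extending the package should know.

## The Search-Capture-Pull model

**Degrees of freedom.** Two nodes in a plane — a formin node at the origin
and a myosin node a distance `initial_separation` away on the +x axis —
plus the particles of `n_filaments` (default 2) actin filaments anchored to
the formin node.  Simulations are two-dimensional: both the reconstituted
bead assay (TIRF plane) and the cell cortex confine the mechanics to a
quasi-2D region, and dimensionality is a structural assumption of the
model, not a parameter.

**Energetics and forces.**

- Stretching: every actin segment, the node tether and the motor link are
  harmonic springs `U = ½k(l − l0)²`.  The actin `k = 0.25 pN/nm` is
  deliberately softer than the measured filament stiffness — a standard
  coarse-graining that leaves the slow mechanics unchanged while allowing
  practical time steps.  Springs whose rest length differs from `l0` (the
  node tether at `D/2`, the growing first segment) have stiffness rescaled
  inversely with rest length (`k·l0/rest`), i.e. constant material modulus.
- Bending: interior particle triples carry `U = ½κ(φ)²` about the straight
  configuration with `κ = kBT·Lp/l0`, which targets a persistence length
  `Lp` (default 10 µm for F-actin).
- Anchoring torque: the filament's emanation angle is held at its initial
  value by a pure couple on the first actin segment — equal and opposite
  forces `F = (k_rot/l0)(θ − θ0)` perpendicular to the segment on
  particles 1 and 2 (`k_rot = 400 pN·nm`), where θ is the segment's
  orientation.  Measuring θ on one lever (say, node-to-particle-1) while
  applying the couple to a different one is not torque-balanced and pumps
  energy into the first segment, so the angle and the couple share the
  same lever by construction.
- Motor link: a spring from the myosin node to a material point on the
  filament (lever-rule force distribution between the flanking particles).
  Its rest length is fixed at the capture distance so the link is born
  force-free; a rest length unrelated to the capture geometry would inject
  a large artificial force at the instant of capture.

**Integration.** Overdamped Langevin dynamics with the two-noise update

    R(t+dt) = R(t) + dt·F/ζ + sqrt(kBT·dt/(2ζ)) · (W(t+dt) + W(t)),

which reuses the previous step's unit Gaussian draw; consecutive steps are
correlated such that the long-time diffusion coefficient is exactly
`kBT/ζ` (verified to <5% over 10⁶ steps in the acceptance suite).  Node
drag is Stokes (`6πηR`) unless overridden; filament particles use the rod
formula `ζ = 4πη·l0/(ln(l0/2a) + 0.84)` with actin radius `a = 3.5 nm`.
The integrator aborts with a diagnostic if any particle moves more than
`l0` in one step.

**Polymerization and mechano-inhibition.** The formin-proximal first
segment's rest length grows linearly at `elong_rate · 2.7 nm/subunit`;
reaching `2·l0` inserts a midpoint particle and resets the rest length.
The formin load is the extensional force on this segment,
`F_formin = k(t)(l(t) − l0(t))`.  With inhibition enabled, growth pauses
while the formin's load estimate exceeds `F_cut` (default 0.1 pN) and
resumes when it drops; arrest is reversible (a latched mode sits behind
`latched_arrest`).

The load estimate needs care, because `F_cut` is far below the thermal
force scale of a coarse-grained spring: the instantaneous first-segment
force fluctuates with r.m.s. `sqrt(k·kBT) ≈ 1 pN`, so a literal
instantaneous threshold at 0.1 pN would toggle arrest ~50% of the time
with no motor at all, halving the unloaded elongation rate the assays
show at full speed.  The arrest rule therefore thresholds an exponential
moving average of the load (response time `f_smooth_tau`, default 5 s —
long against the load's own correlation time `ζ_node/k ≈ 1 s`, short
against the tens-of-seconds coalescence process; `f_smooth_tau = 0`
recovers the literal instantaneous rule).  Two load channels feed it,
and either one above `F_cut` arrests growth:

1. the first-segment extension force, and
2. for a filament held by an engaged, actively cycling motor: the motor's
   load (its spring force projected against the walking direction),
   clamped at zero.  This channel represents the slack-independent,
   thermally mediated ("entropic-spring") transmission of myosin force to
   the formin, which 100-nm rigid segments cannot carry — a discrete
   chain only develops base tension once geometrically taut, whereas the
   mechanism being modeled inhibits the formin at ~0.1 pN regardless of
   filament slack.  The clamp reflects that a filament transmits tension
   but not sub-segment compression; the active-cycling gate reflects that
   a passively bound (non-stepping) motor generates no sustained
   directional load — without it, clamping would rectify the symmetric
   thermal fluctuation of the motor spring and inactivated-myosin
   controls would spuriously inhibit.

**Myosin events.** Motor behavior runs on a coarser clock `t_event`
(default 0.05 s).  Each event, a filament without a link attaches if its
nearest particle lies within the capture radius (110% of the node radius);
links never detach.  Existing links walk toward the formin-bound barbed
end by `v·t_event` along the contour, with the linear force–velocity law
`v = v0(1 − F/F_stall)` clamped to `[0, 2v0]`; `F` is the motor-spring
force projected on the walking direction, resisting loads positive.  The
walk clamps at the first actin particle.

**Presets.**

| parameter | in vitro | in vivo | basis |
|---|---|---|---|
| node diameter | 1000 nm | 50 nm | bead vs node size |
| node drag ζ | 2.1×10⁻³ pN·s/nm | 0.21 pN·s/nm | measured effective bead drag; 100× for membrane anchoring |
| filament viscosity | 0.012 Pa·s | 0.3 Pa·s | buffer vs cytoplasm |
| elongation | 10 subs/s | 75 subs/s | ~8× faster in vivo |
| v₀ (motor) | 100 nm/s | scanned (default 60) | — |
| initial separation | 5000 nm | 500 nm | assay geometry; internode distance in the broad band |
| dt | 5×10⁻⁶ s | 2×10⁻⁵ s | stability: dt ≪ ζ_particle/k |

The integration step is set by the stiffest spring against the smallest
drag (`dt ≲ 0.2·ζ/k`); at the in vitro filament drag this forces
`dt = 5 µs`.  `F_stall = 6 pN` and `F_cut = 0.1 pN` are model choices (the
two thresholds are deliberately independent parameters): `F_cut` sits at
the force scale reaching the formin in these geometries, and `F_stall` is
set so that a handful of engaged heads pulling against the in vivo node
drag operate in the shallow part of the force–velocity curve.  All
parameters are plain dataclass fields and config-overridable.

**Outputs.** Each run records node separation, per-filament formin load
and motor load at event resolution.  The coalescence speed is the negative
least-squares slope of separation vs time from capture to termination;
runs with less than 5 s of post-capture record are excluded.  Speed scans
average over captured runs and report the jackknife s.d. of the mean.

## MSD microrheology

Time-averaged MSD over all displacement pairs is the default (the
origin-based single-pair curve is available and equal in expectation for
stationary-increment processes); both coordinates are summed so free
diffusion follows `MSD = 4Dt`.  The anomalous exponent is the slope of
log MSD vs log lag over lags 1–10 (the fit window is a convention of this
package); classes are sub-diffusive (α ≤ 0.8, boundary closed downward),
diffusive (0.8 < α ≤ 1.05) and super-diffusive (α > 1.05).  `D` is a
through-origin fit of MSD against lag, divided by 4.  Conversions use
`kBT = 4.11 pN·nm` (298 K) by default and the unit identity
`1 pN·s/nm² = 10⁶ Pa·s`; round-trip consistency of ζ, η and D is enforced
by tests.  No drift or localization-error corrections are applied.

A note on internal consistency of reference values: a diffusion
coefficient near `3.9×10⁴ nm²/s` for a 500-nm bead is what the relations
`ζ = kBT/D ≈ 1.1×10⁻⁴ pN·s/nm` and `η ≈ 0.012 Pa·s` jointly imply; the
package trusts the relations, and its synthetic diffusive population is
generated in that regime.

## Head-engagement integral

Heads are uniform over the full bead surface or over the node hemisphere
facing the filament.  The head-to-filament distance for a head at (θ, φ)
is `D = sqrt((R sinθ cosφ)² + (R + d − R cosθ)²)` — the filament runs
parallel to the y axis past the near pole and each head binds at its own y
position.  The engaged count is `N·⟨G(D)⟩` over the occupied surface:
θ ∈ [0, π] with 4π normalization (sphere) or θ ∈ [0, π/2] with 2π
(hemisphere), preserving the property that `G ≡ 1` returns exactly N.
Quadrature restricts the outer integral to the θ ring where the Gaussian
reach is non-negligible (the integrand is a narrow spherical band), then
applies an adaptive rule to an absolute tolerance well under 10⁻³ heads;
a uniform-on-the-surface Monte-Carlo estimator with standard errors serves
as the independent oracle in tests.

## Capture-Pull metrics and FH1 scanning

Tension `T = contour/separation` is scale-invariant; values within 0.1%
below 1 (digitization noise) clamp to 1, larger violations raise.  The
taut/slack boundary is inclusive on the taut side (high: 1 ≤ T ≤ 1.15).
Elongation-rate triples normalize to the pre-capture rate; the
"baseline resumed" convenience filter accepts events whose post-capture
rate returns within ±50% of baseline (a configurable convention — no
quantitative standard exists).  Poly-proline tracks are maximal runs of
≥ 4 prolines; runs longer than 12 split N-terminally into chunks of 12
with the remainder last (the raw run length is retained per track so other
splitting conventions can be recomputed); FH2 distances are strict residue
gaps, 1-based inclusive coordinates.

## Synthetic data: what it does and does not emulate

- **Brownian tracks**: exact Gaussian increments at the 5-s tracking
  interval, ≥ 20 frames.  **Sub-diffusive tracks**: fractional Brownian
  motion with Hurst `α/2`, sampled exactly by circulant embedding of the
  fractional-Gaussian-noise covariance (dense Cholesky fallback), so
  `MSD ∝ t^α` by construction.  fBm is a modeling choice: the downstream
  pipeline only consumes the MSD exponent, and fBm is the simplest process
  with an exact one.  Real coverslip-interaction sub-diffusion need not be
  fBm, and tracks carry no localization noise by default (a Gaussian noise
  knob exists) — so passing tests demonstrate pipeline correctness on
  idealized transport, not robustness to imaging artifacts.
- **Arc filaments**: circular arcs with analytically known
  contour/chord ratios.
- **PBT sequences**: proline-free random background with planted runs,
  guaranteed maximal by construction.

## Scales used in the shipped analyses

The in vivo scans use a 500-nm starting separation, 8–12 replicates per
motor speed and a 75-s horizon; the in vitro drivers use a 2-µm starting
separation.  These are the package's desk-scale study sizes: the
coalescence speed is a post-capture force-balance property and is
insensitive to where the search started, while search time and filament
length (hence cost) grow steeply with separation.  The persistence-length
check initializes filaments from the equilibrium bending distribution and
relaxes them for 0.3 s before sampling, so it probes whether the
integrator *preserves* the thermal ensemble rather than whether it can
reach it from a straight start; the fitted Lp uses the 2D relation
`⟨t(0)·t(s)⟩ = exp(−s/2Lp)`.

## Known limitations

- No filament severing, cofilin, excluded volume, filament–filament
  interactions, membrane mechanics, or per-head stochastic binding
  kinetics (motors are a mean-field link with a force–velocity law).
- Two nodes only; ring-scale behavior is out of scope.
- The motor never detaches; post-capture statistics therefore describe a
  permanently engaged connection.  One visible consequence: with a
  non-pulling motor (v0 = 0, the inactivated-myosin control) the
  uninhibited filament keeps elongating and slowly drags the permanently
  attached node outward, so the control shows a modest systematic
  *apart*-drift rather than pure diffusion; the defining property — no
  approach without active pulling — holds regardless.
- The MSD stage fits ideal power laws; confined or tethered motion is not
  modeled.
- Quantitative agreement of simulated operating points carries the
  uncertainty of the coarse-grained parameter set (k, k_rot, F_cut,
  F_stall, t_event are model choices); the package's checks therefore use
  order-of-magnitude and factor-two comparisons for those quantities.
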