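# Methods

## Kinetic model

A filament barbed end is modelled as a continuous-time Markov chain over
four occupancy states — free (B), formin-bound (BF), CP-capped (BC) and
the ternary complex (BFC).  Association steps are bimolecular with
pseudo-first-order propensity `k_on · [X]` under the instantaneous solution
composition; dissociation steps are unimolecular.  The ternary complex is
treated as a single kinetic state regardless of assembly order: the
complex formed by capping a formin-bound end and the one formed by formin
binding a capped end have indistinguishable dissociation kinetics within
experimental error, so the formation order is carried only as a bookkeeping
tag recoverable from a trace's transition history and never enters any
propensity.

Closed forms used by the estimators follow directly from the two-channel
first-order decay of the complex: survival `exp(−(k′₋C+k′₋F)t)`, the BF
appearance curve `f_BF·(1−exp(−(k′₋C+k′₋F)t))` with
`f_BF = k′₋C/(k′₋C+k′₋F)`, and the transient-exposure plateau
`(1−exp(−k′₊F·[F]·T_expo))·f_BF`.  The plateau expression neglects
spontaneous uncapping of BC and resolution of the complex during the
exposure itself; it is accurate when `T_expo ≪ 1/(k′₋C+k′₋F)` and when the
complex is stable in the absence of actin (see the gating assumption
below).

Equilibrium dissociation constants are computed as `k_off/k_on` and
reported in nM while all computation is done in µM — the asymmetry mirrors
how affinities are conventionally tabulated and avoids silent
thousand-fold unit errors.  Thermodynamic consistency of the binding cycle
is summarized by the ratio `K_C·K′_F/(K_F·K′_C)`, which is 1 for a
perfectly balanced cycle; on the reference constants it evaluates to 0.75,
well inside the factor-of-two band that independently measured rate
constants can be expected to achieve.

## Simulator

Each filament is an exact Gillespie (direct-method) realization of the
chain under a piecewise-constant flow protocol.  Waiting times are
exponential in the total outgoing rate; because they are memoryless, the
clock is simply redrawn at segment boundaries, which is exact.  Solution
exchange is treated as instantaneous (the real dead time is below one
second and below the frame interval).

Design choices, in decreasing order of consequence:

* **The ternary complex is kinetically locked without actin.**  Both
  resolution channels (BFC → BF and BFC → BC) are gated on the presence of
  profilin–actin.  Displacement of CP by formin demonstrably requires
  actin, and transient-exposure titrations behave as if freshly formed
  complexes survive the exposure intact: their plateau collapses onto a
  single function of the dose `[F]·T_expo`, which would fail if the
  complex shed formin at ~6×10⁻³ s⁻¹ during long exposures.  The gate is a
  single boolean (`bfc_decay_requires_actin`) and the ungated scheme is
  available for sensitivity checks.
* **Elongation is deterministic drift**, a state- and condition-dependent
  velocity (subunits/s) integrated between transitions.  Capped states do
  not grow.  Per-monomer shot noise is irrelevant here because every
  inferred quantity depends only on switching times between velocity
  regimes.  Velocities scale linearly with profilin–actin referenced to
  1 µM: 44.2 subunits/s for mDia1-driven growth (measured), twice the
  free-end velocity for FMNL2 (its known processive acceleration), and a
  configurable 10 subunits/s for free ends (not constrained by the fitted
  kinetics; it only affects regime classification).
* **Anchoring geometry.**  In `formin_anchored` mode any transition that
  removes formin from the barbed end (BFC → BC or BF → B) detaches the
  filament immediately and ends its observation; flow-drag detachment is
  not modelled (the emulated assays run at low flow specifically to avoid
  it).  `seed_anchored` filaments never detach.
* **Randomness.**  One master seed; per-filament child streams are PCG64
  generators keyed by counter through `SeedSequence(master, spawn_key=(i,))`,
  so populations are reproducible bit-for-bit and any single filament can
  be regenerated in isolation.

## Observation model

The camera sees a length trajectory, not states.  `observe()` samples the
true length at a finite frame rate (default 3 frames/s), adds Gaussian
length noise (default 1 subunit), estimates velocity over a short forward
window (default 3 s), classifies frames into paused/slow/fast with
thresholds halfway between the expected regime velocities of the current
solution, and suppresses regime runs shorter than a detection limit
(default 2 s).  Detected events are `arrest`, `resume_slow`,
`resume_fast`, `detach`; every filament contributes either events or an
explicit right-censored row per flow segment, so downstream CDFs can count
100% of monitored filaments.  In a segment with no elongation substrate
nothing is classifiable and no events are emitted — as in the real assay.
In the noiseless, fine-frame, zero-window limit detected times converge to
the true transition times; at the defaults, detection shifts times by a
fraction of the smoothing window (≲0.5 s), negligible against the ≳25 s
mean waiting times being estimated.

## Inference

CDFs are fitted as they would be fitted from a plot: the empirical step
function is evaluated on a uniform grid spanning the entire observation
window — plateau included — and least squares is run on those points.
Fitting only the step values at the event times is markedly biased at
small n (the empirical CDF reaches 1 at the last event while the model
never does; at n≈30 the bias exceeds +50%), whereas the whole-window fit
is unbiased to ~3% at n=27 in simulation.  A censored maximum-likelihood
alternative (`method="mle"`) is provided and agrees with the default on
clean data.  Amplitude handling: fixed at 1 for capping-arrest fits
(every filament converts), free for ternary-decay fits (the plateau *is*
the branch fraction).  With `by_total` normalization, truncating the
window at two mean lifetimes biases the fitted rate by under 15% (tested).

k_obs-versus-concentration regression is through the origin by default —
at usable concentrations the dissociation contribution to the intercept is
two orders of magnitude below k_obs — with a free-intercept option.
Branch rates come from `k′₋C = f_BF·k_obs`, `k′₋F = k_obs − k′₋C` with
first-order (delta-method) error propagation; the two outputs sum to the
input rate by construction.  The plateau surface is fitted by weighted
least squares over the `[F]·T_expo` grid with the branch fraction bounded
to (0, 1]; fixing it at 1 reduces the model to plain exponential
saturation in the dose.  All other uncertainties use a nonparametric
bootstrap that resamples *filaments* — the independent experimental
unit — never individual time points.

## Experiment designs and problem sizes

The built-in designs mirror the original acquisitions at their original
filament counts: capping titration at 50/100/200 nM CP with 29/27/36
filaments; ternary-complex partition with 76 formin-anchored filaments;
mDia1 exposure titration over {10, 20, 40} nM × {15, 30, 60, 120} s with
91/50/69 filaments per concentration (the 30 s exposure matches the
documented condition; the other exposure times fill out the dose axis,
which a two-parameter saturation fit needs); FMNL2 titration over
{250, 500, 750} nM × {15, 30, 60} s.  Observation windows default to
600 s per condition segment, a configuration parameter since the real
windows are not documented.  Asymptotic checks scale these counts up to
10⁴ filaments per condition; the headline recovery script uses 10⁵
filaments for the branch-fraction simulation, 10⁴ per concentration for
the capping titration and 500 per grid point for the plateau titration.

## What the synthetic data do and do not emulate

Emulated: exponential waiting times with state- and solution-dependent
rates, piecewise flow protocols, the two anchoring geometries,
frame-rate-limited event detection with a minimum detectable event
duration, length noise, and explicit right-censoring.  Not emulated:
pixel-level kymograph rendering, photobleaching, pointed-end dynamics,
flow mechanics, nucleotide-state effects on the rates, and any coupling
between anchoring chemistry and the rate constants (the two geometries
yield somewhat different CP association constants in reality; the
simulator takes whichever rate set it is given and invents no mechanism
connecting them).  Passing recovery tests therefore demonstrate that the
estimators are consistent and correctly calibrated for data that follow
the kinetic scheme — not that real filaments do.

## Known limitations

* The plateau-equation fit inherits the scheme's approximations; with the
  actin gate disabled, long exposures at high formin bias the recovered
  k′₊F upward by tens of percent.
* The free-end velocity and the FMNL2 free-end dissociation rate are not
  experimentally pinned; defaults are stated above and configurable.
  Neither enters any recovered quantity at leading order.
* The tabulated mDia1 free-end affinity (0.0034 nM) differs slightly from
  the ratio of the measured on/off rates (0.0028 nM); both numbers are
  carried and neither is adjusted.
* Bootstrap standard errors assume filaments are exchangeable within a
  condition; day-to-day experimental variability between replicate
  preparations is outside the generative model.
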