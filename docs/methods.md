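# Methods

## The system and the measurements being modelled

Photosystem II (PSII) oxidizes water at the oxygen-evolving complex (OEC),
a Mn4CaO5 cluster that cycles through the Kok states S0 → S1 → S2 → S3 →
(S4) → S0, advancing one step per saturating flash and releasing one O2
per turn.  A fast bare-platinum (Joliot-type) electrode records the
flash-locked O2 signal of a thin membrane layer.  Two experiment families
are modelled:

1. **Flash trains.** Sixteen saturating flashes, 300 ms apart, give a
   damped period-4 oscillation of the per-flash O2 amplitude.  Amplitudes
   are reported relative to the third flash (Y3), the first O2-producing
   flash when dark-adapted centers sit mostly in S1.
2. **Variable-interval protocols.** One early interval (between flashes
   1–2 or 2–3) is varied between 5 and 500 ms while the rest stay at
   300 ms; the normalized third-flash amplitude Y3(Δt) rises with the
   interval and saturates, and its rise resolves a fast (~ms) and a slow
   (~tens of ms) mode of oxygen release.

All times are milliseconds.  No experimental data ship with the package;
the synthetic-data module generates every input from the published
parameter sets (`flashox.presets`), which also serve as the generating
truths of the recovery suites.

## Forward models of the flash pattern

### Five-state model

State vector (S0, S1, S2, S3, S4′), components summing to one.  A flash
advances S_i → S_{i+1} with probability 1 − α_i (α_i is the *miss* of that
transition) for i = 0, 1, 2.  Of the advancing S3 flux, a fraction *d*
releases O2 promptly and returns to S0 (short-lived S4); the remaining
1 − *d* enters the metastable pool S4′ (the longer-lived S4 isomer), which
is inert to further flashes and relaxes to S0 — releasing its O2 slowly —
as a first-order process with time constant `tau_s4p` (default 150 ms).

The detected amplitude of flash *n* (1-based) is

    A_n = C^(n-1) · [ fast_n + slow_n · w ],     w = 1 − exp(−window_ms / tau_s4p)

where `fast_n`/`slow_n` are the prompt yield and the freshly created slow
pool, *w* is the fraction of the slow release falling inside the
amplitude-detection window (`window_ms`, default 30 ms), and *C* ∈ (0, 1]
is a per-flash geometric damping attributed to depletion of the
plastoquinone acceptor pool.  Design choices behind this detection model:

* *C* damps the **detected amplitude only**; the state vector conserves
  probability exactly.  The damping reflects acceptor-side limitation, not
  donor-side center loss.
* S4′ surviving a flash re-enters the cycle only through its first-order
  decay.  Delayed S0 re-entry (at 300 ms spacing with τ = 150 ms, ~13.5 %
  of a flash's slow pool is still dark at the next flash) plus the window
  weighting are what make *d* identifiable from pattern shape at all.
* `tau_s4p` and `window_ms` are plumbing constants of this realization,
  configurable but never fitted: a uniformly spaced train cannot separate
  them from *d*.
* Flashes are instantaneous (the ~3 µs flash width is ignored).

### Kok variants

The classic homogeneous model uses one miss α for every transition and,
optionally, a double-hit fraction γ that advances centers two steps in one
flash, applied from S0 and S1 only; α + γ ≤ 1.  All release is prompt.
Setting equal α_i and *d* = 1 in the five-state model reproduces the
equal-miss Kok variant exactly (a tested nesting relation).

## Fitting the pattern and the pfq statistic

Fits act on Y3-normalized patterns and minimize

    pfq = (1/N) Σ_n (obs_n − model_n)²,

the mean squared residual of normalized amplitudes.  This realization of
the fit-quality statistic reproduces the order of magnitude (5e-3 … 2e-2)
reported for fits of real 16-flash data.  The optimizer is bounded
trust-region least squares (`scipy.optimize.least_squares`) from a
deterministic multistart: equal-miss starts on {0, 0.2, 0.4, 0.6, 0.8} ×
d ∈ {0.1, 0.5, 0.9}, plus starts carrying the dominant miss on S2 → S3 —
independently established as the least efficient Kok step — with the
initial distribution read off the first four amplitudes.  The three
initial occupancies (S0, S1, S2) are fitted with clipped renormalization
onto the simplex and S3 is the remainder.

### Identifiability: what one flash train determines

A central, deliberately documented finding of this implementation: the
mapping from the nine parameters (α0..α3, d, C, S0, S1, S2) to the
16-amplitude normalized sequence is **not injective**.  Exactly flat
directions exist (numerically: Jacobian null spaces of rank 1–2 at the
published parameter sets, and distant solutions reproducing the sequence
to machine precision) of two kinds:

* discrete relabelings that move the dominant miss to a different
  transition with a compensating initial distribution;
* continuous families trading α_i against S_i at fixed total miss.

Along all of these, the **total miss** Σα_i, the damping ratio *C*, and
(to within a few hundredths for most parameter draws) the fast fraction
*d* are invariant — these are the robustly identified quantities.  To
report a unique parameter set the fit returns a *canonical* member of the
optimal family, selected by anchoring the initial distribution to its
direct readout from the data: in Y3-normalized units the first and second
amplitudes approximate the initial S3 and S2 occupancies.  Concretely,
runs whose pfq is within a factor 1.5 (plus 1e-10 absolute) of the best
are treated as statistically equivalent; among them the fit picks the
smallest anchor mismatch (S3 − Y1)² + (S2 − Y2)², breaking remaining ties
by lower total miss, then lower *d*; finally an anchor-penalized polish
(pattern residuals weighted 1e4 against the anchor terms) slides the
solution along any exactly flat direction to the anchor-consistent member.
This canonicalization is the same stabilizing argument used when fitting
the real measurements — the first four amplitudes pin the initial states —
made explicit and deterministic.  The recovery suites show that it returns
the published parameter rows from their own synthetic patterns; for
arbitrary parameter draws the guaranteed statements are about pfq, total
miss, *C* and *d*, and about reproducibility of the canonical member, not
about every individual α_i.

`n_free` reports the number of actually optimized parameters: 9 by
default, 8 when *C* is supplied as fixed (the count quoted for the model
when *C* is handled separately).

## Relaxation kinetics

Y3 versus the varied interval t follows the saturating two-phase law

    Y3(t) = A_fast (1 − exp(−t/τ_fast)) + A_slow (1 − exp(−t/τ_slow)),

with τ_fast < τ_slow by convention and the single-phase model encoded as
A_fast = 0.  Fits use the same bounded least-squares machinery from a
deterministic multistart over time-constant pairs; parameter standard
errors come from the residual covariance at the optimum.  A fitted
τ_fast/τ_slow above 0.8, or a second amplitude below 1 % of the total, is
flagged as effectively single-component.

**Component count selection** compares one- and two-phase fits with the
small-sample corrected AIC on Gaussian residuals (k = 3 and 5 including
the noise variance); the richer model must beat the penalty.  At the
measurement noise scale (σ = 0.02, 3 replicates on the ten-point grid)
this keeps one component for truly single-exponential data in ≳ 95 % of
replicates while always detecting the well-separated control phases.  The
criterion choice is this package's; the underlying observation ("two
components necessary" / "one sufficient") is stated without one.

**Fixed-τ counter-check**: with both time constants frozen the model is
linear in the amplitudes and is solved by non-negative least squares; the
residual report quantifies whether a preparation's kinetics can be
explained with another preparation's phases.

**Normalization chain** (three stages, tracked by a state tag so a
dataset cannot be normalized twice): (1) each measurement's Y3 is divided
by the sum of its 16 amplitudes (Ys), cancelling sample loading; (2)
division by the series' mean standard ratio Y3(300)/Ys(300) — every
series must contain at least one all-300 ms standard measurement; (3)
each series is rescaled so its mean over the 200–500 ms window (closed
interval, standards included) matches the pooled mean, putting independent
series on one curve.

## Synthetic data

The generators define the study conditions:

* **Patterns**: 16 flashes at 300 ms; Gaussian amplitude noise of σ = 0.02
  on the Y3-normalized scale (the visual scale of published error bars),
  truncated at zero and renormalized per replicate; 3 replicates per
  measurement, averaged before fitting, as in the measurement protocol.
  Truncation biases near-zero flashes by ~0.4 σ; tests account for it.
* **Kinetics**: interval grid {5, 10, 20, 40, 80, 120, 200, 300, 400,
  500} ms spanning the protocol range, 3 replicates per interval; the
  dt = 300 ms entries are the flagged standard measurements.  Both
  varied-pair protocols use the identical law, reflecting the linear
  S-state sequence.
* **Monte-Carlo oracle**: per-center stochastic sampling of the identical
  transition rules (10⁶ centers in the acceptance property), the
  brute-force check of the deterministic ensemble recursion.
* **Traces**: phenomenological electrode model — each flash injects a
  peak-normalized double-exponential pulse, (1 − e^(−t/τ_rise)) e^(−t/τ_elec)
  (defaults 2 and 6 ms), whose peak carries the detected amplitude; the
  slow release not captured in the window is added as a low, broad tail
  with the S4′ time constant at area scaling consistent with the pulse;
  linear baseline drift and Gaussian current noise on top.  Amplitude
  readout is peak-minus-baseline (max over 30 ms after the flash minus the
  mean over 20 ms before it), windows checked against neighboring flashes.
  Real electrode signals depend strongly on sample contact and thickness;
  this model exists to exercise extraction and normalization plumbing, not
  electrochemistry, and the readout is isolated so an integrated-charge
  variant could be swapped in.
* **Variable-interval traces** reuse a fast-instrument configuration
  (τ_rise = 0.7 ms, τ_elec = 2 ms, window 4.5 ms, baseline 2 ms) so that a
  5 ms interval is resolvable; the yield deficit of a depressed flash 3 is
  carried to flash 4 (centers that fail to fire, fire later), conserving
  Ys as the normalization chain assumes.

What the generators do **not** emulate: absolute current units, electrode
polarization physics, light saturation, signal-shape dependence on sample
geometry, inter-series drift of sample activity, or correlated noise.
Passing recovery tests therefore demonstrate the correctness and
stability of the estimation pipeline under the stated statistical model,
not instrument-specific robustness.

## Numerical conventions and degenerate inputs

* Probability conservation is exact by construction; validated to 1e-9
  after arbitrary flash/relaxation sequences.
* Flash indices are 1-based (Y3 = third flash).  C applies as C^(n−1):
  flash 1 undamped.
* Degenerate parameters (α_i = 1, d = 0, empty initial states) are legal
  inputs; fits clip to bounds rather than reject.
* Normalization requires a third-flash amplitude above 1e-12 of the
  pattern maximum.
* Problem sizes: recovery fits use the 16-flash train and the ten-point
  interval grid; calibration experiments use 200 replicates; the oracle
  comparison uses 10⁶ centers.  A reduced multistart (8 starts) backs the
  replicate-heavy suites, which assert only degeneracy-class invariants;
  acceptance fits always use the full 33-start procedure.

## Known limitations

* Individual α_i and S_i from a single 16-flash pattern are meaningful
  only relative to the documented anchoring convention; comparing them
  across datasets assumes the same convention (as comparisons of published
  fits implicitly do).
* The S4′ detection convention (window capture + flash-inert pool) is one
  defensible realization of the "longer-lived S4 isomer"; alternatives
  (e.g. full capture of slow release in the next period) would change the
  meaning of `tau_s4p` and `window_ms` but leave the identified invariants
  intact.
* The biexponential analysis treats Y3(Δt) values as arising directly from
  the relaxation law; mechanistic linkage of τ_fast/τ_slow to individual
  S-state microsteps is out of scope.
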