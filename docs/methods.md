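# Methods

This note documents the models, conventions and numerical choices behind
`coordlearn`, in the order data flows through the package.

## 1. The movement generator

### Model

A bimanual trial is generated as a pair of sinusoids whose relative phase
φ(t) (degrees) carries all of the interesting structure:

    left(t)  = A sin(ω t)
    right(t) = A sin(ω t + φ(t)·π/180)

with A = 300 screen units, ω = 2π·1 Hz, sampled at 60 Hz for 20 s by
default. φ evolves by an Euler–Maruyama discretisation (dt = 1/60 s) of a
stochastic differential equation:

    dφ = [ −a sin φ − 2b sin 2φ + c sin(φ* − φ) ]·(180/π) dt + σ dW

where φ* is the target phase, the first two drift terms are the negative
gradient of the classic bistable coordination potential
V(φ) = −a cos φ − b cos 2φ, c ≥ 0 is a learned attraction toward the
target, and σ is the phase diffusion in degrees/√s. φ(0) = φ*.

The intrinsic potential gives the three stylised facts of bimanual
coordination that the analysis pipeline presumes: 0° and 180° are the only
stable phases (for b/a > 1/4), 0° is the deeper attractor, and 90° sits on
the repelling ridge between them. The single knob c ("coupling strength")
plays the role of skill: a training schedule is simply a sequence of
SkillStates with increasing c.

### Default parameters

| parameter | default | units | why |
|---|---|---|---|
| intrinsic_a | 0.5 | 1/s-scale drift | with b, sets 0°/180° attractor stiffness a+4b vs 4b−a |
| intrinsic_b | 0.5 | same | b/a = 1 keeps 180° clearly stable but shallower than 0° |
| noise_sd (σ) | 25 | deg/√s | produces mean PTT20 ≈ 0.89 / 0.78 / 0.03 at 0°/180°/90° for an untrained performer — the right stability ordering, with magnitudes in the range typical of untrained adults |
| coupling c | 0 | — | untrained; c ≈ 4–6 produces trained-level 90° performance (PTT20 0.7–0.9) |

These defaults were fixed once, from the stylised facts above, and define
the package's standard study conditions.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: phase-
dependent stability, trial-to-trial stochasticity, skill-dependent
improvement at the trained phase, and seedable determinism. It does not
model amplitude or frequency errors (the left channel is metronomic),
fatigue, within-trial learning, asymmetries between hands, or any
physiology of ageing — faster and slower learners differ only through
their coupling schedules. Passing tests therefore certify the *pipeline*
(scoring, protocol, staircases, statistics), not any claim about how
humans generate movement.

## 2. Kinematic scoring

* **Filtering.** 2nd-order Butterworth, 10 Hz cut-off, applied forward–
  backward (`sosfiltfilt`, odd-reflection padding) so the filter is
  zero-phase — essential, since phase is the quantity being measured.
  Filter order and padding are conventional choices; a pure 1 Hz sinusoid
  passes with < 0.01 % amplitude error.
* **Differentiation.** Central differences on the filtered signal (2nd-
  order one-sided at the ends). At 60 Hz this underestimates a 1 Hz
  velocity amplitude by ≈ 0.2 %.
* **Edge transient.** Any zero-phase filtering of a finite record leaves a
  small transient at the first/last ≈ 2 samples; its derivative can
  perturb the phase estimate there by a few degrees (worst case ~5° when a
  channel starts at an extremum). With 1200-sample trials the effect on
  PTT is ≤ 2/1200 and no samples are trimmed by default; a `trim`
  parameter is available.
* **Phase convention.** The continuous phase is
  atan2(position/Â, velocity/(Â·2π·f̂)) unwrapped, with Â the half
  peak-to-peak amplitude and f̂ the dominant spectral frequency (falling
  back to a caller hint). A literal two-quadrant arctan of V/X would lose
  quadrant information and mix units; the atan2-of-normalised-components
  form recovers 2πft + c exactly for a clean sinusoid. Because position
  and velocity are scaled by the same Â, a wrong amplitude estimate
  cancels in the ratio — which is why the position-perturbed displays
  (Section 4) still score correctly.
* **Folding.** Relative phase = left − right wrapped to (−180°, 180°],
  then folded by absolute value to [0°, 180°], pooling lead and lag as is
  standard in this literature. Distance on the folded scale is the
  minimum of the three candidate arcs |s−t|, s+t, 360−s−t, so values near
  both folds behave circularly.
* **Band edges.** A sample exactly at the bandwidth counts as on target
  (closed band). PTT is monotone in bandwidth by construction; the ±10°
  re-scoring used for bias control is the same operation with a smaller
  band.

## 3. Training protocol

Implemented exactly as specified by the design: 30 trials per session;
feedback on all trials except every fifth; knowledge-of-results comments
per quartile of the percentage score with shared printed edges (25, 50,
75 %) resolved half-open upward; bandwidth fades 30→25→20→15→10° when
PTT20 > 0.5 (strictly) on at least 20 of 30 trials; training stops after
two consecutive qualifying sessions (> 0.6 on ≥ 20 trials) once the
bandwidth is at 10°, or after 10 sessions. The stop rule is evaluated
after the fading step inside the same session update, and the 0.5
criterion counts all 30 trials (whether the check should exclude the
no-feedback trials is not specified by the design; counting all 30 is the
documented choice).

## 4. Psychophysics

* **Staircases.** Two independent 1-up/2-down staircases (one per side of
  90°) with up step 10°, down step 0.5488 × 10° = 5.488°, initial
  difference 30°, stop at 8 reversals. Before the first error the
  staircase descends on every correct response (by the down step — the
  descent step size is a documented choice); the first error is the first
  reversal. The difference is floored at 1°, where a 2AFC pair would
  otherwise be identical. Interleaving picks uniformly at random among
  unfinished staircases from the session's seeded generator.
* **Threshold.** Mean reversal difference excluding the first reversal,
  per staircase, averaged over the two staircases.
* **Convergence caveat.** With asymmetric steps the zero-drift equilibrium
  satisfies p²·Δdown = (1 − p²)·Δup, i.e. p ≈ 0.804 for this ratio: the
  staircase hovers near the observer's ~80 %-correct difference, not the
  70.71 % point of classical equal-step theory, and reversal peaks
  overshoot by the 10° up step. For a Weibull observer of slope 3.5 whose
  70.71 % point is 15°, the mean reversal estimate is ≈ 18°. This bias is
  a property of the procedure, shared by the human data it emulates; the
  estimator is still a valid within-subject measure because training
  effects are assessed as *changes* in the same biased quantity.
* **Observer.** P(correct | Δ) = 0.5 + (0.5 − lapse)·F(Δ), F a cumulative
  Weibull scaled so P(threshold_70) = √0.5 at zero lapse. Defaults:
  slope 3.5 (a typical psychometric steepness for discrimination tasks),
  lapse 0.02. The convergence tests use lapse 0 so the 70.71 % point is
  exact.
* **Position perturbation.** The top dot's amplitude is redrawn uniformly
  on [0.25·A, A_max] at each of its own zero crossings, keeping its
  instantaneous phase ωt continuous; the bottom dot runs at the fixed
  phase offset with amplitude yoked to half the top's. The lower bound
  enforces midline crossing, the upper bound the screen. Scoring the
  perturbed pair with the kinematics pipeline recovers the nominal
  relative phase within 3° (the amplitude normalisation cancels in
  atan2), while the half-cycle amplitude sequence has positive variance —
  destroying relative-position information, which is the point.

## 5. Statistics

* **Contrast test.** L_i = Σ_j x_ij λ_j per participant; t = L̄/√(s²_L/n),
  df = n − 1; p two-sided (sidedness is configurable by the caller using
  the returned t). The effect size is g = L̄/s_L = t/√n with no
  small-sample correction — this is the operational definition that
  reproduces the published (t, g) pairs exactly. Zero contrast variance
  raises an error rather than returning ±∞.
* **Multiplicity.** Holm–Bonferroni step-down over the family of untrained
  phases tested in one analysis (six phases), via
  `statsmodels.stats.multitest`.
* **Proportion of transfer.** (post − baseline at a transfer phase) ÷
  (post − baseline at the criterion phase), a signed fraction; the
  criterion phase maps to 1. This orientation (transfer change over
  criterion change) is the one consistent with reported transfer
  percentages in this literature.
* **Learning curves.** PTT20 = a·exp(−b/S) fitted by bounded nonlinear
  least squares (a ∈ [0, 1.5], b ∈ [0, 20], initial a = max of the data,
  b = 1); the model is monotone and well-conditioned on 3–10 session
  means, and a noiseless curve is recovered to 1e−6. Sessions are
  numbered consecutively from 1 = Baseline; participants who stopped
  early contribute their available sessions at their own consecutive
  indices (how the original analyses aligned 7–9-session participants on
  a 10-session axis is unknowable from the design; consecutive indexing
  is the package's choice). The learning rate is the analytic derivative
  (a·b/S²)·exp(−b/S) at S = 1, which matches a central finite difference
  to 1e−6.

## 6. Problem sizes in the test suite

Monte-Carlo tests use sizes chosen to make the tested property decisive at
small cost: 2,000 null replicates for the type-I-error check (binomial SE
≈ 0.005 at α = 0.05), 200 staircase sessions and 200 noisy-curve fits for
convergence and recovery, 40 trials per phase for the stability ordering,
and 12 trials/session × 10 sessions per virtual group for the end-to-end
learning-rate ordering (the ordering is robust to the per-session trial
count; 30 would only tighten it).

## 7. Known limitations

* The SDE's degree/radian mixed parameterisation (drift computed in
  radians, scaled to degrees) is a convenience; a, b, c are therefore
  rate-like but not directly comparable to published oscillator-model
  coefficients.
* The generator's left channel is deterministic; only relative phase is
  stochastic. Scores are insensitive to this, but amplitude-based
  performance measures would not be derivable from these data.
* The staircase threshold estimator inherits the asymmetric-step bias
  described above; absolute thresholds from it should be interpreted
  relative to the procedure, not as the 70.71 % point of an underlying
  psychometric function.
* `simulate_study` applies one SkillState per session to *all* target
  phases of that session, i.e. learned coupling generalises fully within
  a session; differential transfer across phases is not modelled.
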