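# Methods

This note documents the models, numerical choices and known limitations of
`phasematch`. It is the package's own account of its science; every
empirical statement here is computed by the test suite or by
`scripts/acceptance.py`.

## The task

An agent (or participant) makes rhythmic grasping movements paced by a
fixation dot whose size oscillates sinusoidally at ~0.5 Hz, closing the hand
as the dot shrinks. The hand is seen only as a virtual hand driven by a data
glove; delaying the virtual hand by 500 ms decouples vision from
proprioception ("incongruent" conditions). The 2×2 within-subject design
crosses *instructed modality* (match the target with the seen virtual hand,
VH, or with the felt real hand, RH) with *visuo-proprioceptive congruence*.
Under incongruence only one modality can be phase-matched to the target, so
the instruction dictates which sensory stream should dominate — the
operational handle on selective attention.

## Simulation model

### Generative process (the world)

Two hidden states: the target state `x_t` and the hand state `x_h`, both in
radians. The target advances at the constant rate `t_t = 1/40` per time bin
(bins of `dt = 1/120 s`, i.e. 3 rad/s, period 2π/3 ≈ 2.094 s — the nominal
"0.5 Hz" of the task description is this rounded). The hand integrates
action `a` through a motor time constant `t_a = 16.67 ms` (2 bins):
`dx_h = a / (t_a/dt)` per bin, which makes `a = 0.05` the stationary value
during steady tracking. Three noise-free sensory channels:

    s_target = sin(x_t)
    s_prop   = sin(x_h)
    s_vis    = sin(x_h − v)

where the hidden cause `v` is the visuo-proprioceptive displacement: 0 when
congruent, 0.35 rad when the seen hand is delayed (0.35 rad / 3 rad·s⁻¹ ≈
117 ms; the behavioural 500 ms delay is *not* mapped onto this value — the
mismatch is inherited from the study design and left as-is). Process
fluctuations are suppressed (log-precision 16), so the single simulated
movement stands in for an average over noise realizations.

### Generative model (the agent)

Same sensory form with the *believed* cause in place of the true one. The
believed hand state is driven by the hand–target displacement — `x_t − x_h`
under the RH instruction and `x_t − (x_h − v)` under VH, where the perceived
visual delay must additionally be compensated. A static Gaussian prior on
the cause (mean 0, log-precision 3) encodes the life-long association of
seen and felt hand postures; the cause belief is initialized at 0
(congruent) or 0.35 (incongruent), carrying the trial information. The
"ideal" agents of the comparison conditions instead move the prior mean onto
the true displacement.

Sensory log-precisions default to (proprioception, vision) = (3, 4).
Attention presets add +1 to the instructed modality's channel (HA) or to the
non-instructed one (HD). The target channel keeps log-precision 4 throughout
and is never touched by attention. The motion of hidden states carries
log-precision 3 (unstated in the task description; chosen once so that the
dynamics prior is strong enough to carry beliefs through the sinusoid's
ambiguous peaks without drowning out sensory evidence — see below).

### Generalized coordinates and the belief/action updates

All dynamic quantities are embedded to order n = 4 (position, velocity,
acceleration, jerk) — enough to represent a 3 rad/s sinusoid with negligible
truncation error at 1/120 s steps. Scalar precisions are expanded over
orders with a Gaussian autocorrelation model: for correlation length `s`
(in bins), the covariance between derivative orders i and j of a
unit-variance fluctuation is `(−1)^j ρ^(i+j)(0)` with
`ρ(h) = exp(−h²/(2s²))`; its inverse is the generalized precision. The
default `s = 1/2` bin, the classical generalized-filtering choice. (Larger
smoothness values — e.g. 2 bins — induce strong cross-order precision
couplings that destabilize the conflict conditions.)

Beliefs follow `μ̇ = Dμ − κ ∂F/∂μ` and action `ȧ = −κ ∂F/∂a`, where `D` is
the derivative (shift) operator, `F` the sum of half precision-weighted
squared errors (constant log-determinant terms omitted; they do not affect
any gradient), and κ the update gain. The action gradient is taken through
the true generative process: action enters the hand velocity, hence orders
≥ 1 of the sensory embedding of the hand channels; the target channel is not
controllable.

Two implementation details matter for correctness claims:

* **Exact sensory embeddings.** The task's generalized sensory predictions
  and the process's generalized sensory outputs are exact truncated Taylor
  series of the sinusoidal mappings (computed by series recurrences), with
  analytic Jacobians. A first-order expansion around order-0 beliefs —
  the generic fallback in the engine — cannot represent the sinusoid's
  curvature where `cos → 0` (it would require unbounded second-order
  beliefs), which destabilizes inference under sensory conflict. The
  generic fallback carries exact Hessian-corrected gradients, so in both
  routes the belief update is the exact gradient of the implemented free
  energy (verified against central finite differences at 1e−5 relative
  tolerance).

* **Update gain κ = 0.25 per bin.** The phase of a sinusoidally observed,
  monotonically advancing state is only locally identifiable: `sin(π−x) =
  sin(x)`, so a retreating trajectory explains the sensory data equally
  well, differing only in the motion prior. At κ = 1 the belief update is
  fast enough to flip onto the reflected branch at every sensory peak
  (where the two branches merge) and the simulated hand oscillates by
  reversing instead of advancing. At κ ≤ 0.25 the motion prior carries
  beliefs through the momentarily ambiguous region; results plateau between
  0.25 and 0.125. Beliefs are therefore also initialized flow-consistently
  (velocity order = believed flow at the prior mean); the world starts at
  rest, which preserves the initiation transient visible in the traces.

### Integration

The joint world/action/belief system is integrated by local linearization:
over each bin, `z ← z + (e^{hJ} − I) J⁻¹ f(z)` in the augmented-matrix form
that tolerates singular Jacobians, with `J` refreshed by finite differences
every 10 bins. A trust region (adaptive step halving whenever a proposed
jump exceeds 0.5 in any coordinate) keeps the update inside the
linearization's validity during stiff transients; an explicit Euler
fallback is selectable. Integration is fully deterministic: identical
condition specifications yield bitwise-identical traces. A divergence guard
aborts with the offending step when any state magnitude exceeds 1e6.

### Simulated conditions and summaries

The registry exposes 12 unique conditions (the four ideal-belief ones, the
two congruent conditions shared between ideal and realistic agents, and the
six realistic incongruent ones: default/HA/HD × VH/RH). Trials run 14 s by
default: summaries discard the first movement cycle (initiation transient)
and the wavelet estimator needs its own edge margins plus at least one full
period, which requires ≥ ~12.2 s at 0.477 Hz. Lags are estimated with the
same wavelet estimator used for behavioural data, applied to the true world
signals `sin(x_h)` and `sin(x_h − v)` against `sin(x_t)`; per-channel mean
squared prediction errors (order 0, unweighted and precision-weighted) are
averaged over the same window.

Reference behaviour reproduced by the test suite: ideal agents track the
instructed modality to < 20 ms with post-transient errors < 1e−2; realistic
incongruent agents show |lag(HA)| < |lag(default)| < |lag(HD)| for the
instructed modality in both tasks, with the virtual−real lag difference
conserved at the displacement (116.7 ms) to within 2 bins and RMS action
within 20% across attention presets.

## Behavioural analysis chain

* **Preprocessing**: the grasp signal is the mean of the four non-thumb
  glove channels (sensor f1 is the thumb); no further preprocessing.
  Zero-mean/unit-peak normalization exists for condition-average display
  only and provably does not move the phase.
* **Phase lag**: both series are transformed with a complex Morlet wavelet
  (centre frequency parameter ω₀ = 6; PyWavelets `cmor2.0-0.95493`) at the
  scale matching the task frequency. The per-sample angular difference of
  the coefficients is averaged as unit phasors (circular mean) over a
  window that excludes two temporal standard deviations of the wavelet
  envelope at each edge (the cone of influence; σ_t = ω₀/(2π f₀) seconds).
  The mean is removed before transforming because the complex Morlet is
  only approximately admissible. Lag = Δφ/(2π f₀) seconds, positive when
  the signal trails the reference, wrapped to (−T/2, T/2]. On noiseless
  shifted sinusoids the estimator is exact to below one sample for any
  shift within half a period.
* **Aggregation**: per participant × condition, trial lags are combined by
  the circular mean of their phasors. The virtual-hand series is the real
  grasp delayed by the rendering delay in incongruent trials (initial
  posture held during the delay; that edge falls inside the wavelet
  margin) and identical to it in congruent trials.
* **Statistics**: the 2×2 within-subject ANOVA is computed from the three
  paired contrasts — with two-level factors each effect's F is exactly the
  squared paired t with df (1, n−1); the implementation is cross-checked
  against statsmodels' AnovaRM in the tests. Post-hoc comparisons are
  two-tailed paired t-tests with Bonferroni correction (p × m, capped at
  1). Ratings use Friedman's test and Wilcoxon signed-rank tests reported
  as normal-approximation z (zero differences dropped, mid-ranks,
  tie-corrected variance, continuity correction), Bonferroni-corrected.

## Synthetic cohorts

The generator emulates the study design: 24 participants × 4 conditions ×
6 trials (2 runs of 3), 32 s trials (16 cycles at exactly 0.5 Hz) sampled
at 60 Hz, a 500 ms virtual-hand delay under incongruence, and 7-point
ratings for two questions. Per condition a participant lag is drawn as
Normal(condition mean, 0.06 s) with per-trial jitter Normal(0, 0.03 s); the
grasp waveform maps into five finger channels through per-participant
gains (the thumb's is smallest) with additive Gaussian sensor noise
(sd 0.02 of the glove range) clipped to [0, 1]. The target's 12% size
modulation follows the extrema-ratio convention (max/min = 1.12).

The *effect* preset's condition means mirror the behavioural pattern
qualitatively: small common lags in congruent conditions (0.04 s), the real
hand leading by most of the delay under the VH instruction (−0.38 s, so the
seen hand is nearly on target) and dragged partway under the RH instruction
(−0.12 s). The *null* preset sets all four means equal. Ratings come from a
shifted-latent-Gaussian model thresholded onto 1–7; under the effect preset
Q1 (difficulty) rises under incongruence (most for VH) and Q2 (attention
focus) follows the instructed modality; the null preset has no condition
shifts. True trial lags and per-finger gains are written to a clearly
separated `truth_synthetic.csv` sidecar for recovery tests.

What the generator does *not* model: biomechanical grasp kinematics,
learning or adaptation across trials, non-Gaussian lag distributions,
drifting sensor baselines. Passing tests therefore demonstrate that the
analysis chain recovers the statistical structure it assumes, not that it
is robust to every artefact of real glove data.

Repeated-cohort calibration studies (e.g. the 1000-cohort type-I-error
check of the ANOVA interaction) draw participant × condition lag tables
directly from the generator's lag layer rather than synthesizing and
re-estimating half a million waveforms; the estimator's exactness and the
full generate→estimate→aggregate recovery are established by separate
checks.

Known calibration caveat: on heavily tied 7-point ordinal data Friedman's
chi-square approximation is conservative, so its null rejection rate sits
somewhat below the nominal 5% (the tests assert non-inflation rather than
two-sided calibration). The continuous-lag ANOVA interaction is calibrated
two-sidedly (5% ± 2% over 1000 cohorts).

## Degenerate inputs and edge cases

Flat signals raise an undefined-phase error; series shorter than the edge
margins plus one period are rejected; lags beyond half a period are
rejected at generation and wrapped at estimation; zero-variance paired
differences are flagged degenerate rather than silently reported;
participants missing a condition are excluded from the lag table with a
warning; all-tied ratings raise a degenerate-input error.

## Limitations

* The simulation layer realizes a single dynamical level plus a static
  cause prior; deeper hierarchies, parameter learning and stochastic
  process noise are out of scope.
* The exact wavelet family, scale grid and averaging window of the original
  behavioural analysis are unreported; the choices above are labelled
  reconstructions, and output metadata records them.
* The congruent VH/RH degeneracy is exact for the static maps but only
  approximate (∼3e−3) dynamically, because the VH agent's cause belief is
  transiently excited through its flow coupling during initiation.
* Update gain, state-motion precision and smoothness are not stated by the
  task description; they were fixed once (κ = 0.25, log-precision 3,
  s = 1/2 bin) and all are exposed in configuration for sensitivity
  analyses.
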