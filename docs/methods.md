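# Methods

This note documents the model, the numerical conventions, the synthetic
data, and the design decisions taken where the design was genuinely open.

## Task and protocol

The arena is a disc of radius 2 a.u. Two wells of radius 0.3 sit at
c₁ = (−0.43, 0.43) and c₂ = (0.43, −0.43); c₁ is baited for the 80
initial-learning trials (8 days × 10), c₂ for the 120 reversal trials
(12 days × 10). Trials start at (−1.6, −1.2) or (1.6, 1.2) — both of norm
exactly 2, which fixes the wall radius — five times each per day in random
order with at most three consecutive same-side starts (a flag disables the
run-length constraint). A trial ends on reward detection (plus a 300 ms
consummatory pause with all input silenced), immediately on touching the
empty well, or by timeout at T_max = 15 s. Well contact is evaluated once
per time step on the updated position; reward takes precedence in the
(geometrically impossible) case of double containment. Between trials all
neural activity is reset; the feedforward weights persist, including
across the stage switch. There is no model counterpart of the physical
maze rotations or the stationarity-removal rule of the animal protocol.

## Network

**Place cells.** 121 Gaussian place fields (peak 400 Hz, width
σ = 0.4) on an 11×11 lattice spanning [−2, 2]² — the unique regular
construction with 121 cells at the stated spacing; the corner cells lie
outside the circular wall and contribute negligibly. Spiking is the
per-step Bernoulli discretisation of an inhomogeneous Poisson process at
dt = 1 ms (maximum per-step probability 0.4); a guard rejects time steps
with rate·dt > 1.

**Action ring.** 40 neurons with preferred directions
aⱼ = a₀(sin 2πj/N, cos 2πj/N), a₀ = 0.08 a.u./step. Membrane potentials
follow the simplified Spike Response Model: feedforward and lateral EPSPs
with kernel ε (ε₀ = 20, τₘ = 20 ms, τₛ = 5 ms) and a refractory kernel
χe^(−(t−t̂)/τₘ), χ = −5 mV. Spiking is escape-rate stochastic,
λ(u) = λ₀e^((u−θ)/Δu) with λ₀ = 60 Hz, θ = 16 mV, Δu = 2 mV; the per-step
spike probability λ·dt is clipped at 1. Firing rates are estimated online
by filtering each spike train with the normalised kernel γ
(τ_γ = 50 ms, ν_γ = 20 ms), giving ρ in spikes/ms; the population vector
(1/N)Σρⱼaⱼ is the displacement applied per step, with specular reflection
of the radial component at the wall. Hz↔per-ms conversions happen in
exactly one place (the rate→probability products); all kernel time
constants are in ms.

**Only-after-own-spike summation.** The membrane sums run over spikes
arriving after the neuron's own last spike. This is implemented exactly by
clearing a neuron's feedforward and lateral accumulators when it spikes.
Spikes arriving in the same step as the neuron's own spike are treated as
*after* it (they are delivered on the next step); since ε(0) = 0 the
convention has no effect at first order. A neuron never receives its own
spikes (the lateral sum excludes k = j even though the lateral matrix
carries w₋/N on its diagonal).

**Lateral connectivity.** w^lat = w₋/N + w₊f/N with w₋ = −300,
w₊ = 100. The similarity profile in its literal form, (1−δⱼₖ)e^(ψcos(θⱼ−θₖ)) with
ψ = 20, reaches e^20 ≈ 5·10⁸ and is dimensionally incompatible with
mV-scale potentials, so the default profile is row-normalised to mean 1
over k ≠ j (g = N·e^(ψcosΔθ)/Σ_{k≠j}e^(ψcosΔθ)), which preserves the
w₊/w₋ budget and the excite-similar/inhibit-dissimilar structure.
The raw profile remains available (`lateral.normalised: false`). The
normalisation scale is the model's one genuinely free constant: scanning
the near-neighbour gain shows a sharp threshold (below ≈5 the activity
bump never ignites and the agent cannot navigate; above it the ring
behaves as here), with no intermediate regime, so the mean-1 choice is
not a sensitive tuning.

**Boundary synapses.** Feedforward synapses from boundary place cells
(centres within one lattice spacing of the wall, ‖xᵢ‖ ≥ radius − σ) onto
actions pointing outward there (aⱼ·xᵢ > 0, strict, leaving tangential
actions unmasked) are pinned to zero, excluded from plasticity and from
the weight bounds. One lattice ring is the minimal reading of "boundary".

## Plasticity (sn-Plast)

Coincidences use the symmetric window W(Δt) = e^(−|Δt|/τ), τ = 10 ms,
with the **all-pairs** convention: every (pre, post) spike pair of a trial
contributes once, exponentially discounted; simultaneous pairs contribute
W(0) = 1. Online, this is a pair of exponential traces (one per place
cell, one per action neuron, decay τ); the current step's pre spikes enter
the pre trace before pairing so a simultaneous pair is counted exactly
once. The equivalence to the explicit double sum is oracle-tested to 1e−9.

* **ACh branch (exploration).** Depression is instantaneous and permanent
  at coincidence time: Δw = −η_ACh × mass, applied every step. The
  eligibility flag is off without dopamine, so no decaying memory is
  involved in the depression itself.
* **Eligibility.** The same coincidence mass also accumulates into a
  per-synapse trace decaying with τₑ = 2 s, maintained continuously so
  dopamine can act retroactively.
* **DA branch (reward).** One-shot at reward detection:
  Δw = +η_DA × eligibility, after which the trace is cleared. During the
  consummatory pause place input is zero, so no post-reward coincidences
  arise. Timeout and wrong-well trials deliver no dopamine. The
  eligibility is also cleared at every trial end: the inter-trial reset
  clears all activity but not weights, and τₑ = 2 s is far below any
  realistic inter-trial interval.

Weights are clipped to [w_min, w_max] = [1, 3] after every update, so the
state is always valid; masked synapses stay at exactly 0 and accumulate no
eligibility. With both modulators absent (η = 0) no weight ever changes —
ACh-phase updates are elementwise ≤ 0 and DA updates ≥ 0 by construction.

## Simulation engines

`run_session`/`run_trial` default to a numba-compiled fused step loop that
consumes pre-drawn uniforms from a numpy `Generator` (one row of 161 per
step), making it a pure function of its inputs; the eligibility matrix is
stored rebased by a scalar decay factor so the dense per-step decay
multiply is avoided. A pure-NumPy reference engine steps through the same
sequence using the public per-module operations and the identical random
stream; an equivalence test compares the two paths trial-for-trial
(outcome, latency, final weights to 1e−9). Seeding is hierarchical: a
session seed spawns independent per-day (schedule) and per-trial streams,
so any single trial is reproducible in isolation.

## Fitting and group sampling

The full grid crosses η_DA ∈ {7.5e−4 … 2.75e−3, step 2e−4} (11 levels)
with ratios η_ACh:η_DA ∈ {0 … 1, step 0.02} (51 levels): 561 pairs.
A *bank* holds one simulated session per grid point per iteration and is
shared across all subjects of a cohort (per-subject regeneration would be
statistically equivalent and strictly wasteful). Per iteration the
RMSE-minimising grid point is selected — ties broken to the lowest η_ACh,
then the lowest η_DA, a deterministic rule conservative about cholinergic
effect sizes — and the estimate and fitted curve are the means of the
winners. Fitting a curve taken from the bank returns its generating point
exactly. Stage-wise fitting is available by slicing the curve to one
stage's days before calling `rmse_daily`.

**Reduced grid.** Desk-scale analyses use every 2nd η_DA level (6, step
4e−4) × five interior ratios {0.1, 0.3, 0.5, 0.7, 0.9}, with 3–5
iterations. The ratio axis deliberately samples the interior: on the
η_ACh = 0 line dopamine is structurally unidentifiable (without
cholinergic unlearning, reversal is uniformly slow at every η_DA), and
that degenerate line is 2% of the full grid but would be 17–20% of a
coarse axis through zero, distorting the recovery analysis relative to
the full design.

**Sampling regions.** Group parameter draws are uniform over polygons in
the (η_DA, ratio) plane, snapped to grid points. The reference regions are
defined only graphically, so the defaults are rectangular approximations spanning the full η_DA range in the regime where reversal
improves with ACh: control ratio ∈ [0.10, 0.40], reduced-ACh
ratio ∈ [0.00, 0.32]. The overlap was set once, by Monte-Carlo, so that
study-sized cohorts (8 + 16 control vs 21 reduced) yield a
Kruskal–Wallis significance fraction in the mid range (~0.5–0.6, neither
floor nor ceiling), and then frozen; tests assert only a broad
qualitative band.

## Behavioural statistics

The shared trial-record schema is `subject, group, stage, day, trial,
outcome` with `group ∈ {GFP, light_off, light_on}` and `stage ∈ {0, 1}`;
synthetic and real cohorts pass the same validator. Daily success curves
are per-(stage, day) percentages; the **days-to-criterion** measure is the
earliest day from which the 80% daily rate is reached *and maintained* to
the end of the stage, with never-reaching subjects censored at stage
length + 1 (the worst rank, as rank-based tests receive them).

The fixed-effects logistic regression models the per-trial success logit
on: intercept, two group contrasts (light-on is the reference level, so
the contrasts and the group-by-stage interactions measure
control-vs-silenced differences), a trial regressor, a stage indicator,
trial-by-stage, and the two group-by-stage contrasts. The trial regressor
is a running index within stage (1…80, restarting 1…120 at reversal); the
alternative day.trial decimal coding would rescale the trial coefficients
without changing their signs. Estimation is maximum likelihood via IRLS
(statsmodels GLM, binomial family; tolerance 1e−8 on the deviance, ≤100
iterations), with Wald z tests. Rank-deficient designs raise; separation
is flagged when any coefficient exceeds 20 in absolute value (a logit of
20 pins fitted probabilities within 2e−9 of 0/1 — on behavioural data
scales that only occurs under (quasi-)separation) or when the backend
itself detects perfect separation. The mixed-model design (subject
intercepts and subject trial slopes) is exported for external GLMM
machinery; random-effects likelihoods are not estimated here.
Kruskal–Wallis uses the tie-corrected H with the χ² approximation; the
all-values-identical degenerate case is defined as H = 0, p = 1.

## Synthetic cohorts

Default sizes mirror the study: 8 GFP, 16 light-off, 21 light-on.

* **Mechanistic** subjects draw (η_ACh, η_DA) from their group's region
  (controls vs reduced-ACh) and run the full spiking session; the hidden
  truth table is returned separately so recovery tests cannot leak it.
* **GLM** subjects draw Bernoulli outcomes from the fixed-effects logit
  plus Gaussian subject intercepts (sd 0.5) and trial slopes (sd 0.008).
  The default coefficients were chosen once so curves start near 50%,
  approach ceiling within a stage, reset at reversal, and favour controls
  in the reversal interactions. Calibration checks of the fixed-effects
  refit generate with the subject-effect SDs at zero, so the fitted model
  is exactly the generating model and nominal Wald coverage is the correct
  expectation; with nonzero SDs the marginal fit is attenuated by design.

What the generators do **not** emulate: within-day fatigue or motivation
drifts, forgetting between days, innate side biases, stage-inconsistent
individual styles, or any odour/visual-cue confounds. Passing tests
therefore show the pipeline's statistical machinery is calibrated and the
model's group-level predictions are reproduced — not that the generator
spans all real behavioural variability.

## Problem sizes and determinism

All stochastic checks fix their seeds. The standard analysis sizes are:
20 seeds per condition for the two-condition reversal contrast, 10–16
seeds per point for the ratio sweep, a 30-point × 3–5-iteration bank with
20–24 agents for recovery, 30–40 replicate cohorts for regression
coverage, 1000–2000 replicates for the sampling/power experiments. A full
200-trial session takes ~1.5 s on one CPU with the compiled engine; the
full 561 × 100 bank is the long-running mode and is not exercised by the
test suite.

## Known limitations

* Initial-stage learning at default parameters reaches ceiling within
  ~2 days — faster than the group behavioural curves the model is meant to
  reproduce, which take several.
  The consequence is that the initial stage carries little information
  about η_DA, so dopamine identifiability rests almost entirely on the
  reversal transition. With one 20-day session per agent, the rank
  correlation between true and estimated η_DA plateaus around 0.5–0.65 at
  the reduced scale regardless of bank density or iteration count
  (agent-curve noise, not bank noise, is binding); η_ACh recovery is
  robust (≈0.75–0.93). The recovery analysis reports both.
* Neuromodulator amplitudes are constant: no reward-prediction-error
  dopamine, no negative feedback on omission, no state-dependent ACh.
* The escape-rate nonlinearity is unbounded above; per-step spike
  probabilities are clipped at 1 and potentials in the working regime
  regularly exceed the soft threshold.
* Wall handling is purely reflective; there is no head-direction or
  outward-facing start posture.
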