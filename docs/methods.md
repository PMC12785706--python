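# Methods

## Model

Two response codes accumulate evidence in discrete time. With
activations `a_c` (correct response) and `a_e` (error response), step
size `dt` (ms), leak `k` (1/ms), lateral inhibition `β` (1/ms),
diffusion scale `σ` (per √ms) and independent standard-normal draws ξ
per code and step:

    a_i ← max(0, a_i + dt·(I_i(t) − k·a_i − β·a_j) + σ·√dt·ξ_i)

The first code to reach the threshold `θ` determines the response; the
reaction time is the crossing time plus a residual (non-decision) time
drawn from a normal distribution truncated at zero.

**External input.** The controlled input from the task-relevant feature
is constant once it switches on: `ΔI_rel` to the correct code and
`1 − ΔI_rel` to the error code. The sum-to-one constraint, together
with the fixed threshold, anchors the scale of the parameters — a
requirement all sequential-sampling models share. The automatic input
from the task-irrelevant stimulus location starts at stimulus onset
(t = 0), before the controlled input, which switches on at a lead time
drawn per trial from `N(lead_mean, lead_sd)` truncated at zero. Its
time course is the step response of a critically damped second-order
high-pass filter,

    h(t) = ΔI_irr · (1 − t/τ) · e^(−t/τ),

which starts at `ΔI_irr`, crosses zero at `t = τ`, reverses sign, and
decays to zero with zero total area. It is applied antisymmetrically:
`+h(t)` to the code on the stimulus side and `−h(t)` to the other code,
so the total external input is preserved. In congruent trials the
stimulus side is the side of the correct response; in incongruent
trials it is the opposite side.

**Preparation.** On each trial one response is *expected*; the expected
code starts at `prep_bias` (< θ) and the other at zero. Without
response cues the frequent response is expected with probability π and
the infrequent one otherwise; with always-valid cues each response
class has its own preparation probability (π_freq, π_infr), applied to
the required response.

**Variants.**

* *preparation* — only the expectation state varies; all inputs common.
* *+attention* — `ΔI_rel` takes one value when the stimulus appears on
  the side of the expected response and another when it appears
  opposite.
* *+contingency* — `ΔI_rel` and `ΔI_irr` both depend on the
  task-irrelevant stimulus location (frequent-response side vs.
  infrequent-response side), the two locations carrying mostly
  congruent vs. mostly incongruent trials under unequal response
  frequencies.
* *+shielding* — for prepared responses the automatic input is
  initially weaker (`shield_irr_amplitude ≤ ΔI_irr`) and declines more
  slowly (`shield_irr_tau ≥ τ`). Shielding attaches to the trial's
  preparation state (prepared = expected equals required); the
  alternative reading — shielding the prepared response's identity even
  when the other response is required — was considered and not adopted,
  since the preparation state is what the cueing literature
  manipulates.

## Why biased preparation modulates the Simon effect

Two features of the calibrated regime are essential. First,
`lead_mean ≈ τ`: by the time the controlled input becomes effective,
the automatic input has (on average) crossed zero, so the activation
gap between congruent and incongruent trials *converges* from then on —
delta plots decline. Second, unprepared trials start lower and cross
later, deeper into the convergence, so their congruency effect is
smaller. At π = 0.9 the frequent-response conditions are dominated by
prepared (early-crossing, large-effect) trials and the
infrequent-response conditions by unprepared ones, producing the
modulation; with near-equal class-specific preparation probabilities it
collapses.

## Default parameters

Printed, field-standard values: `ΔI_rel = 0.55`, `ΔI_irr = 0.29`,
`τ = 100 ms`, `lead_mean = 100 ms`, `π = 0.9`. The remaining dynamics
parameters have no published values at this parameterization's scale
and were calibrated once, forward from the model, so that the
generator's defaults produce summaries on the empirical scale of
75/25 Simon experiments — mean RT ≈ 390 ms (frequent) / 405 ms
(infrequent), error rates between ≈ 0% (frequent congruent) and ≈ 10%
(infrequent incongruent), Simon effects ≈ 30 vs. ≈ 19 ms, declining
delta plots:

| parameter | value | role |
|---|---|---|
| `leak` k | 0.005 /ms | self-inhibition; sets the negatively accelerated rise |
| `lateral` β | 0.005 /ms | inter-code competition; β = k keeps the activation difference neutrally stable |
| `noise_sd` σ | 0.18 /√ms | diffusion; sets error rates and RT spread |
| `threshold` θ | 40 | decision criterion (scale anchor with the input sum) |
| `prep_bias` | 12 | head start of the expected code (30% of θ) |
| `lead_sd` | 30 ms | trial-to-trial lead variability |
| `resid_mean`, `resid_sd` | 190, 25 ms | non-decision time |
| `dt` | 1 ms | integration step |
| `max_time` | 3000 ms | decision deadline; timeouts flagged and excluded |

## Numerics

* Heun (trapezoidal) predictor–corrector for the drift with the
  controlled-input onset weighted by its exact overlap with each step;
  additive Euler–Maruyama noise; activations floored at zero after the
  full step. The deterministic path is second-order accurate in `dt`;
  crossing times at `dt = 1 ms` agree with a `dt/100` reference within
  1 ms over broad parameter grids.
* Threshold crossings are linearly interpolated within the crossing
  step. If both codes cross in one step the earlier interpolated
  crossing wins; exact ties go to the correct code (probability-zero
  under noise).
* Truncated normals (lead, residual) are sampled exactly via the
  truncated distribution, not by clipping.
* Quantiles are linear interpolations of order statistics (the numpy
  default), fixed and documented for reproducibility.
* The Qn-type robust scale is the k-th smallest pairwise absolute
  difference, `k = C(h,2)`, `h = ⌊n/2⌋ + 1`, times the consistency
  factor 2.2219, with no finite-sample correction.
* Delta-plot trend coefficients use an orthonormal (unit-norm)
  polynomial basis built by the Emerson recurrence on the unequally
  spaced quantile-pair means; `c0` is level × √n, `c1` slope, `c2`
  curvature. Any fixed normalization supports comparisons across
  conditions; unit norm is used throughout.
* G² floors a predicted bin proportion at `0.5/N_sim` only where the
  observed count is positive, so outcomes the simulation never produced
  contribute a finite penalty; zero-count bins contribute nothing.
* The outlier rule (RT < 100 ms or > mean + 3 SD, sample SD) is applied
  once per participant × condition, not iterated.

## Fitting

Stage 1 minimizes the RMS of deviations between observed and simulated
error rates (as proportions) and nine RT deciles (in seconds), unit
weights — the two families are then numerically comparable. Stage 2
starts from the stage-1 solution and minimizes G² over 11 bins per
condition (errors + 10 decile bins of correct RTs, bounded by the
*observed* deciles), summed across all four conditions. Both stages use
bounded Nelder–Mead simplex search; every evaluation simulates a fixed
number of trials per condition (default 20 000) with common random
numbers — preparation states, leads, and residuals are fixed uniform
draws pushed through the corresponding quantile functions, and the
diffusion stream is re-seeded identically — so the objective is a
deterministic function of the parameters and fits are bit-reproducible
by seed. Free parameters are rescaled to the unit cube of their bounds
so the simplex explores all directions at comparable resolution, and
stage 1 is run from the supplied start plus ``n_restarts`` seeded
random starts (default 1), keeping the best, which guards against
stalls on the shallow, slightly jagged simulation objective. AIC per replicate is G² + 2k with k the length of the
variant's free-parameter ledger. Prediction intervals are the central
95% of summary statistics over replicate simulations at the observed
per-condition trial counts (trial-level noise only; participant
heterogeneity is not resampled).

Before pooling, trials are screened per participant × condition.
Pooling uses `y_ij = m· + (x_ij − m_i) · q·/q_i` with `m_i`, `q_i`
computed per participant across *all four conditions'* correct RTs;
this preserves within-participant condition differences exactly, which
a per-condition transform would remove, and is the reading adopted
here.

## Synthetic data

The generator emulates three designs: 10 × 48 trials (480/participant,
16 participants), 2 × 10 × 32 (640, 16 participants), and 8 × 48 with
always-valid cues (384, 24 participants); 75/25 response frequencies,
congruency balanced within response class, conditions balanced exactly
within blocks where divisible. Inter-participant heterogeneity is a
multiplicative RT scale `exp(N(0, 0.1))` and an additive shift
`N(0, 15 ms)` — enough structure for the pooling stage to have real
work to do. What the generator does **not** emulate: practice blocks
and feedback screens, sequential effects (post-error slowing,
congruency-sequence effects), fatigue or drift over blocks, premature
responses beyond the 100-ms floor, and cue–stimulus-interval effects
(the cueing intervals are recorded in the trial table but do not enter
the simulator, which represents preparation solely by π). Passing tests
therefore demonstrate internal consistency of model, analysis, and
fitting machinery on data whose generating process is known — not that
the model captures every feature of empirical Simon-task data.

## Problem sizes

Distribution-level checks use 100 000 trials per condition; fitting
evaluations use 20 000 trials per condition; AIC replicate
distributions default to 100 × 100 000 but are configurable. Recovery
studies fit three free parameters (π, ΔI_irr, lead mean) with the
others fixed at their generating values; fitting larger ledgers works
but takes correspondingly longer and recovers the scale-anchored
parameters (θ, σ) only up to the usual trade-offs. The recovery study
simulates 48 participants of the 480-trial design: ΔI_irr is informed
mainly by the size of the two Simon effects, whose sampling error at
16 participants (≈ 950 trials per infrequent cell) is already ≈ 10% of
the effect — of the same order as the ±15% recovery tolerance — so the
study size is chosen to keep data-side noise clearly below the
tolerance being verified. Even so, the recovered amplitude has a
replication standard deviation of roughly 8% across master seeds —
dominated by the Monte-Carlo shift of the objective's optimum at
20 000 simulated trials per condition per evaluation — while π and the
lead are recovered much more tightly (≈ ±0.01 and ≈ ±5 ms).

## Known limitations

* The modulation mechanism depends on `lead_mean ≈ τ`; conflict tasks
  without an irrelevant-feature lead (flanker-type timing, or lagging
  irrelevant features) need not show it, and the package makes no claim
  there.
* Lateral inhibition acts on the (already floored, hence nonnegative)
  activations of the other code; the alternative convention
  (inhibition from above-baseline activation only) coincides with this
  one under the zero floor.
* With very low noise and strong preparation the frequent-congruent
  error rate is ≈ 0, so its error bin is empty and the G² floor
  activates routinely; this is logged behaviour, not an error.
* Timeouts (no crossing by 3000 ms) are excluded downstream, mirroring
  the design-level exclusion of very slow responses.
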