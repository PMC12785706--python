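"""Extended leaky, competing accumulator (LCA) for conflict tasks.

Two response codes — one for the correct response, one for the error
response — accumulate evidence until one of them reaches a threshold.
The per-step increment is the sum of external stimulus-related input,
self-inhibition (leak), lateral inhibition from the other code, and
Gaussian diffusion noise; activations are floored at zero.

The external input has two components:

* a *controlled* (relevant) input that switches on at a variable lead
  time after stimulus onset and stays constant: ``rel_input`` to the
  correct code and ``1 - rel_input`` to the error code (the sum-to-one
  constraint anchors the parameter scale);
* an *automatic* (irrelevant) input from the task-irrelevant stimulus
  location that starts at stimulus onset, pushes toward the code on the
  stimulus side, and decays like the step response of a critically
  damped second-order high-pass filter — it crosses zero once (at
  ``irr_tau``) and reverses sign before vanishing.

Response expectation is modelled as an initial activation head start
(``prep_bias``) on the expected code.  Model variants modulate the
per-trial inputs (attention, contingency) or the irrelevant input of
prepared responses (shielding); see :class:`VariantSpec`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats


class Response(str, enum.Enum):
    """Response-frequency class of a response (or of a screen side)."""

    FREQUENT = "frequent"
    INFREQUENT = "infrequent"

    def other(self) -> "Response":
        return Response.INFREQUENT if self is Response.FREQUENT else Response.FREQUENT


class Congruency(str, enum.Enum):
    CONGRUENT = "congruent"
    INCONGRUENT = "incongruent"


class Variant(str, enum.Enum):
    PREPARATION = "preparation"
    ATTENTION = "attention"
    CONTINGENCY = "contingency"
    SHIELDING = "shielding"


def stimulus_side(required: Response, congruency: Congruency) -> Response:
    """Side of the stimulus, labelled by the response whose side it is on.

    Congruent trials present the stimulus on the side of the required
    response; incongruent trials on the opposite side.
    """
    if congruency is Congruency.CONGRUENT:
        return required
    return required.other()


@dataclass(frozen=True)
class ModelParameters:
    """All LCA and input-timecourse parameters for one model variant.

    Units: times in ms, rates in 1/ms, inputs and activations are
    dimensionless; ``noise_sd`` is the diffusion scale per sqrt(ms).
    """

    rel_input: float = 0.55      # controlled input to the correct code
    irr_amplitude: float = 0.29  # initial magnitude of the automatic input
    irr_tau: float = 100.0       # zero-crossing time of the automatic input
    lead_mean: float = 100.0     # mean lead of irrelevant over relevant input
    lead_sd: float = 30.0
    leak: float = 0.005          # self-inhibition k
    lateral: float = 0.005       # lateral inhibition beta
    noise_sd: float = 0.18       # diffusion sigma per sqrt(ms)
    threshold: float = 40.0
    prep_bias: float = 12.0      # initial activation of the expected code
    resid_mean: float = 190.0    # residual (non-decision) time
    resid_sd: float = 25.0
    dt: float = 1.0              # Euler step
    max_time: float = 3000.0     # decision deadline

    def __post_init__(self) -> None:
        if not 0.0 < self.rel_input < 1.0:
            raise ValueError(f"rel_input must be in (0, 1), got {self.rel_input}")
        if self.irr_amplitude < 0.0:
            raise ValueError("irr_amplitude must be >= 0")
        if self.irr_tau <= 0.0:
            raise ValueError("irr_tau must be > 0")
        for name in ("lead_mean", "lead_sd", "leak", "lateral", "noise_sd",
                     "prep_bias", "resid_mean", "resid_sd"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        if self.threshold <= 0.0:
            raise ValueError("threshold must be > 0")
        if self.prep_bias >= self.threshold:
            raise ValueError("prep_bias must be below threshold")
        if self.dt <= 0.0:
            raise ValueError("dt must be > 0")
        if self.max_time <= 0.0:
            raise ValueError("max_time must be > 0")


@dataclass(frozen=True)
class VariantSpec:
    """A model variant and the parameters it adds to the base model.

    ``pi_freq`` is the probability of expecting (preparing) the frequent
    response.  Without response cues the infrequent response is expected
    in the remaining trials, so ``pi_infr`` is ignored and equals
    ``1 - pi_freq``.  With always-valid cues (``cued=True``) each
    response class has its own preparation probability and the required
    response is prepared with probability ``pi_freq`` / ``pi_infr``.

    ``free_parameter_names`` is the ledger of free parameters used as
    the AIC penalty count k.
    """

    variant: Variant = Variant.PREPARATION
    pi_freq: float = 0.9
    pi_infr: float | None = None
    cued: bool = False
    # +attention: relevant input depends on whether the stimulus is on
    # the side of the expected response
    attention_rel_same: float | None = None
    attention_rel_opposite: float | None = None
    # +contingency: inputs depend on the irrelevant stimulus location
    contingency_rel_freqside: float | None = None
    contingency_rel_infrside: float | None = None
    contingency_irr_freqside: float | None = None
    contingency_irr_infrside: float | None = None
    # +shielding: irrelevant input of prepared responses is initially
    # weaker and declines more slowly
    shield_irr_amplitude: float | None = None
    shield_irr_tau: float | None = None
    free_parameter_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_freq <= 1.0:
            raise ValueError("pi_freq must be in [0, 1]")
        if self.pi_infr is not None and not 0.0 <= self.pi_infr <= 1.0:
            raise ValueError("pi_infr must be in [0, 1]")
        required = {
            Variant.PREPARATION: (),
            Variant.ATTENTION: ("attention_rel_same", "attention_rel_opposite"),
            Variant.CONTINGENCY: (
                "contingency_rel_freqside", "contingency_rel_infrside",
                "contingency_irr_freqside", "contingency_irr_infrside"),
            Variant.SHIELDING: ("shield_irr_amplitude", "shield_irr_tau"),
        }[Variant(self.variant)]
        for name in required:
            if getattr(self, name) is None:
                raise ValueError(f"{self.variant} variant requires {name}")

    @property
    def k_free(self) -> int:
        return len(self.free_parameter_names)

    def prepared_probability(self, required: Response) -> float:
        """P(the required response is the expected one) for a trial class."""
        pi_infr = 1.0 - self.pi_freq if self.pi_infr is None else self.pi_infr
        if self.cued:
            return self.pi_freq if required is Response.FREQUENT else pi_infr
        # without cues the frequent response is expected with P = pi_freq
        if required is Response.FREQUENT:
            return self.pi_freq
        return 1.0 - self.pi_freq


@dataclass(frozen=True)
class TrialContext:
    """Condition of a single trial."""

    required_response: Response
    congruency: Congruency
    expected_response: Response

    @property
    def stimulus_side(self) -> Response:
        return stimulus_side(self.required_response, self.congruency)

    @property
    def prepared(self) -> bool:
        return self.expected_response is self.required_response


@dataclass(frozen=True)
class SimulatedTrial:
    rt: float | None  # ms, decision + residual; None when timed out
    correct: bool
    timed_out: bool


@dataclass
class ConditionSummary:
    """Summary of one (frequency class, congruency) cell."""

    required_response: Response
    congruency: Congruency
    n_trials: int
    n_errors: int
    n_timeouts: int
    error_pct: float
    quantile_probs: np.ndarray
    quantiles: np.ndarray
    correct_rts: np.ndarray = field(repr=False)

    @property
    def mean_rt(self) -> float:
        return float(np.mean(self.correct_rts))


DEFAULT_QUANTILE_PROBS = np.arange(0.1, 0.95, 0.1)


def irrelevant_timecourse(t, amplitude: float, tau: float, sign: int = 1):
    """Automatic-input time course A*(1 - t/tau)*exp(-t/tau).

    The step response of a critically damped second-order high-pass
    filter: equals ``sign * amplitude`` at t=0, crosses zero at t=tau,
    reverses sign, and decays to zero with zero total area.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    out = sign * amplitude * (1.0 - t / tau) * np.exp(-t / tau)
    return out if out.ndim else float(out)


def resolve_trial_parameters(base: ModelParameters, variant: VariantSpec,
                             ctx: TrialContext) -> ModelParameters:
    """Effective parameters for one trial under a model variant."""
    v = Variant(variant.variant)
    if v is Variant.PREPARATION:
        return base
    if v is Variant.ATTENTION:
        same = ctx.stimulus_side is ctx.expected_response
        rel = variant.attention_rel_same if same else variant.attention_rel_opposite
        return replace(base, rel_input=rel)
    if v is Variant.CONTINGENCY:
        on_freq_side = ctx.stimulus_side is Response.FREQUENT
        if on_freq_side:
            return replace(base,
                           rel_input=variant.contingency_rel_freqside,
                           irr_amplitude=variant.contingency_irr_freqside)
        return replace(base,
                       rel_input=variant.contingency_rel_infrside,
                       irr_amplitude=variant.contingency_irr_infrside)
    if v is Variant.SHIELDING:
        if ctx.prepared:
            return replace(base,
                           irr_amplitude=variant.shield_irr_amplitude,
                           irr_tau=variant.shield_irr_tau)
        return base
    raise ValueError(f"unknown variant {variant.variant!r}")


def _truncated_normal(mean, sd, size, rng) -> np.ndarray:
    """Normal(mean, sd) truncated at zero (exact, not clipped)."""
    if np.all(sd == 0):
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                               size=size, random_state=rng)


def _simulate_decisions(rel: np.ndarray, amp: np.ndarray, tau: np.ndarray,
                        lead: np.ndarray, irr_sign: np.ndarray,
                        prepared: np.ndarray, p: ModelParameters,
                        rng: np.random.Generator):
    """Vectorized Euler–Maruyama integration of a batch of trials.

    Per-trial inputs may differ (variant resolution, lead variability);
    the dynamic parameters (leak, lateral, noise, threshold, dt) are
    shared.  Returns (decision_time, correct, timed_out).

    Numerics: the drift is advanced with Heun's (trapezoidal)
    predictor-corrector and the relevant-input onset enters as its
    exact overlap fraction with each step, so the deterministic path is
    second-order accurate in dt; additive diffusion noise is applied
    Euler-Maruyama style and activations are floored at zero after the
    full step.  Crossing times are linearly interpolated within the
    crossing step; when both codes cross in the same step the earlier
    interpolated crossing wins (ties go to the correct code).
    """
    n = rel.shape[0]
    dt = p.dt
    sqdt = math.sqrt(dt)
    n_steps = int(round(p.max_time / dt))
    theta = p.threshold

    a_c = np.where(prepared, p.prep_bias, 0.0).astype(float)
    a_e = np.where(prepared, 0.0, p.prep_bias).astype(float)

    idx = np.arange(n)
    decision = np.full(n, np.nan)
    correct = np.zeros(n, dtype=bool)

    rel_a, amp_a, tau_a = rel[idx], amp[idx], tau[idx]
    lead_a, sign_a = lead[idx], irr_sign[idx]

    for step in range(n_steps):
        t = step * dt
        # irrelevant input at both step endpoints (trapezoid through Heun)
        h0 = sign_a * amp_a * (1.0 - t / tau_a) * np.exp(-t / tau_a)
        t1 = t + dt
        h1 = sign_a * amp_a * (1.0 - t1 / tau_a) * np.exp(-t1 / tau_a)
        # relevant input weighted by its exact overlap with the step
        frac_on = np.clip((t1 - lead_a) / dt, 0.0, 1.0)
        rel_c = frac_on * rel_a
        rel_e = frac_on * (1.0 - rel_a)

        noise = rng.standard_normal((2, a_c.shape[0]))
        prev_c, prev_e = a_c, a_e
        f0_c = rel_c + h0 - p.leak * prev_c - p.lateral * prev_e
        f0_e = rel_e - h0 - p.leak * prev_e - p.lateral * prev_c
        pred_c = np.maximum(prev_c + dt * f0_c, 0.0)
        pred_e = np.maximum(prev_e + dt * f0_e, 0.0)
        f1_c = rel_c + h1 - p.leak * pred_c - p.lateral * pred_e
        f1_e = rel_e - h1 - p.leak * pred_e - p.lateral * pred_c
        a_c = prev_c + 0.5 * dt * (f0_c + f1_c) + p.noise_sd * sqdt * noise[0]
        a_e = prev_e + 0.5 * dt * (f0_e + f1_e) + p.noise_sd * sqdt * noise[1]
        np.maximum(a_c, 0.0, out=a_c)
        np.maximum(a_e, 0.0, out=a_e)

        hit_c = a_c >= theta
        hit_e = a_e >= theta
        hit = hit_c | hit_e
        if hit.any():
            w = np.nonzero(hit)[0]
            with np.errstate(divide="ignore", invalid="ignore"):
                frac_c = np.where(hit_c[w],
                                  (theta - prev_c[w]) / (a_c[w] - prev_c[w]),
                                  np.inf)
                frac_e = np.where(hit_e[w],
                                  (theta - prev_e[w]) / (a_e[w] - prev_e[w]),
                                  np.inf)
            win_c = frac_c <= frac_e
            frac = np.where(win_c, frac_c, frac_e)
            g = idx[w]
            decision[g] = t + frac * dt
            correct[g] = win_c
            keep = ~hit
            idx = idx[keep]
            if idx.size == 0:
                break
            a_c, a_e = a_c[keep], a_e[keep]
            rel_a, amp_a, tau_a = rel_a[keep], amp_a[keep], tau_a[keep]
            lead_a, sign_a = lead_a[keep], sign_a[keep]

    timed_out = np.isnan(decision)
    return decision, correct, timed_out


def _context_arrays(base: ModelParameters, variant: VariantSpec,
                    required: np.ndarray, congruent: np.ndarray,
                    prepared: np.ndarray):
    """Vectorized counterpart of :func:`resolve_trial_parameters`.

    ``required``: True for frequent-response trials; ``congruent`` and
    ``prepared`` boolean per trial.  Returns (rel, amp, tau, irr_sign).
    """
    n = required.shape[0]
    rel = np.full(n, base.rel_input)
    amp = np.full(n, base.irr_amplitude)
    tau = np.full(n, base.irr_tau)
    # stimulus on the frequent-response side?
    stim_freq_side = np.where(congruent, required, ~required)
    v = Variant(variant.variant)
    if v is Variant.ATTENTION:
        # expected response frequent? prepared <-> expected == required
        expected_freq = np.where(prepared, required, ~required)
        same = stim_freq_side == expected_freq
        rel = np.where(same, variant.attention_rel_same,
                       variant.attention_rel_opposite)
    elif v is Variant.CONTINGENCY:
        rel = np.where(stim_freq_side, variant.contingency_rel_freqside,
                       variant.contingency_rel_infrside)
        amp = np.where(stim_freq_side, variant.contingency_irr_freqside,
                       variant.contingency_irr_infrside)
    elif v is Variant.SHIELDING:
        amp = np.where(prepared, variant.shield_irr_amplitude, amp)
        tau = np.where(prepared, variant.shield_irr_tau, tau)
    irr_sign = np.where(congruent, 1.0, -1.0)
    return rel, amp, tau, irr_sign


def simulate_trials(base: ModelParameters, variant: VariantSpec,
                    required: np.ndarray, congruent: np.ndarray,
                    prepared: np.ndarray, rng: np.random.Generator,
                    lead: np.ndarray | None = None,
                    resid: np.ndarray | None = None):
    """Simulate a batch of trials with given boolean condition arrays.

    ``lead`` and ``resid`` may be supplied (e.g. common random numbers
    during fitting); otherwise they are drawn from the truncated
    normals defined by ``base``.  Returns (rt, correct, timed_out); rt
    is NaN for timeouts.
    """
    n = required.shape[0]
    rel, amp, tau, irr_sign = _context_arrays(
        base, variant, required, congruent, prepared)
    if lead is None:
        lead = _truncated_normal(base.lead_mean, base.lead_sd, n, rng)
    decision, correct, timed_out = _simulate_decisions(
        rel, amp, tau, np.asarray(lead, dtype=float), irr_sign,
        prepared, base, rng)
    if resid is None:
        resid = _truncated_normal(base.resid_mean, base.resid_sd, n, rng)
    rt = decision + np.asarray(resid, dtype=float)
    rt[timed_out] = np.nan
    return rt, correct, timed_out


def simulate_trial(params: ModelParameters, ctx: TrialContext,
                   rng: np.random.Generator) -> SimulatedTrial:
    """Simulate a single trial (parameters already variant-resolved)."""
    required = np.array([ctx.required_response is Response.FREQUENT])
    congruent = np.array([ctx.congruency is Congruency.CONGRUENT])
    prepared = np.array([ctx.prepared])
    rt, correct, timed_out = simulate_trials(
        params, VariantSpec(variant=Variant.PREPARATION),
        required, congruent, prepared, rng)
    if timed_out[0]:
        return SimulatedTrial(rt=None, correct=False, timed_out=True)
    return SimulatedTrial(rt=float(rt[0]), correct=bool(correct[0]),
                          timed_out=False)


def draw_prepared(variant: VariantSpec, required: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw per-trial preparation states from the variant's pi.

    ``required``: boolean array, True = frequent response required.
    """
    u = rng.random(required.shape[0])
    p_freq = variant.prepared_probability(Response.FREQUENT)
    p_infr = variant.prepared_probability(Response.INFREQUENT)
    return u < np.where(required, p_freq, p_infr)


def simulate_condition(params: ModelParameters, variant: VariantSpec,
                       condition: tuple[Response, Congruency], n: int,
                       rng: np.random.Generator,
                       quantile_probs: Sequence[float] = DEFAULT_QUANTILE_PROBS,
                       ) -> ConditionSummary:
    """Simulate ``n`` trials of one condition cell and summarize them.

    Expectation states are drawn per trial from the variant's
    preparation probabilities.  Timed-out trials are excluded from RTs
    and error counting, and recorded in ``n_timeouts``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    req_resp, congr = condition
    required = np.full(n, req_resp is Response.FREQUENT)
    congruent = np.full(n, congr is Congruency.CONGRUENT)
    prepared = draw_prepared(variant, required, rng)
    rt, correct, timed_out = simulate_trials(
        params, variant, required, congruent, prepared, rng)
    ok = ~timed_out
    if not ok.any():
        raise RuntimeError("all trials timed out")
    n_valid = int(ok.sum())
    n_err = int((~correct[ok]).sum())
    crts = rt[ok & correct]
    probs = np.asarray(quantile_probs, dtype=float)
    if crts.size >= probs.size:
        qs = np.quantile(crts, probs)
    else:
        qs = np.full(probs.shape, np.nan)
    return ConditionSummary(
        required_response=req_resp, congruency=congr,
        n_trials=n_valid, n_errors=n_err,
        n_timeouts=int(timed_out.sum()),
        error_pct=100.0 * n_err / n_valid,
        quantile_probs=probs, quantiles=qs, correct_rts=crts)


def noise_free_decision_time(params: ModelParameters, ctx: TrialContext,
                             lead: float | None = None,
                             dt: float | None = None) -> float:
    """Deterministic threshold-crossing time of the coupled ODE.

    Integrates the noise-free dynamics with an Euler scheme at step
    ``dt`` (default: ``params.dt``) and interpolates the crossing.
    Serves as a reference when run at a much finer step.  Returns NaN
    if neither code crosses before ``max_time``.
    """
    p = params if dt is None else replace(params, dt=dt)
    if lead is None:
        lead = p.lead_mean
    rel = np.array([p.rel_input])
    amp = np.array([p.irr_amplitude])
    tau = np.array([p.irr_tau])
    sign = np.array([1.0 if ctx.congruency is Congruency.CONGRUENT else -1.0])
    prepared = np.array([ctx.prepared])
    noiseless = replace(p, noise_sd=0.0)
    decision, _, timed_out = _simulate_decisions(
        rel, amp, tau, np.array([float(lead)]), sign, prepared,
        noiseless, np.random.default_rng(0))
    return float("nan") if timed_out[0] else float(decision[0])
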