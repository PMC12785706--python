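"""Experimental designs, synthetic datasets, and power computations.

Encodes three within-participant Simon-task designs with unequal
response frequencies (75% / 25%): a single-session baseline, a
two-session variant, and a response-cued variant in which every trial
carries an always-valid cue for the required response.  Trial tables
realize the exact per-block condition frequencies, and synthetic
multi-participant datasets are generated from the accumulator model
with per-participant location/scale heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (Congruency, ModelParameters, Response, VariantSpec,
                    draw_prepared, simulate_trials, stimulus_side)

CONDITIONS: tuple[tuple[Response, Congruency], ...] = (
    (Response.FREQUENT, Congruency.CONGRUENT),
    (Response.FREQUENT, Congruency.INCONGRUENT),
    (Response.INFREQUENT, Congruency.CONGRUENT),
    (Response.INFREQUENT, Congruency.INCONGRUENT),
)


@dataclass(frozen=True)
class DesignSpec:
    """A full experiment design.

    ``p_frequent_response`` is the marginal probability of the frequent
    response; within each response class, congruent and incongruent
    trials occur with probability ``p_congruent_within_response``.
    """

    name: str
    n_test_blocks: int
    trials_per_block: int
    n_sessions: int = 1
    p_frequent_response: float = 0.75
    p_congruent_within_response: float = 0.5
    cueing: str = "none"  # "none" | "always-valid"
    rt_floor_ms: float = 100.0
    n_participants: int = 16

    def __post_init__(self) -> None:
        for p in (self.p_frequent_response, self.p_congruent_within_response):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.cueing not in ("none", "always-valid"):
            raise ValueError(f"unknown cueing mode {self.cueing!r}")

    @property
    def total_trials(self) -> int:
        return self.n_sessions * self.n_test_blocks * self.trials_per_block


#: Built-in presets mirroring the three designs.
PRESETS: Mapping[str, DesignSpec] = {
    "exp1": DesignSpec("exp1", n_test_blocks=10, trials_per_block=48,
                       n_participants=16),
    "exp2": DesignSpec("exp2", n_test_blocks=10, trials_per_block=32,
                       n_sessions=2, n_participants=16),
    "exp3": DesignSpec("exp3", n_test_blocks=8, trials_per_block=48,
                       cueing="always-valid", n_participants=24),
}


@dataclass(frozen=True)
class ParticipantVariability:
    """Inter-participant RT heterogeneity applied to simulated trials.

    Each participant receives a multiplicative scale factor
    ``exp(N(0, log_scale_sd))`` and an additive shift ``N(0, shift_sd)``
    ms, emulating individual differences in overall speed and spread
    that the pooling stage must undo.
    """

    log_scale_sd: float = 0.1
    shift_sd: float = 15.0

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        scale = float(np.exp(rng.normal(0.0, self.log_scale_sd))) \
            if self.log_scale_sd > 0 else 1.0
        shift = float(rng.normal(0.0, self.shift_sd)) if self.shift_sd > 0 else 0.0
        return scale, shift


def expected_condition_counts(design: DesignSpec) -> dict[tuple[Response, Congruency], float]:
    """Expected per-participant trial counts for the four condition cells."""
    total = design.total_trials
    out = {}
    for resp, congr in CONDITIONS:
        p_resp = design.p_frequent_response if resp is Response.FREQUENT \
            else 1.0 - design.p_frequent_response
        p_congr = design.p_congruent_within_response \
            if congr is Congruency.CONGRUENT else 1.0 - design.p_congruent_within_response
        out[(resp, congr)] = total * p_resp * p_congr
    return out


@dataclass(frozen=True)
class ContingencyTable:
    """Joint and conditional location/congruency proportions.

    With unequal response frequencies the task-irrelevant stimulus
    location on the frequent-response side carries mostly congruent
    trials and the other side mostly incongruent ones, even though both
    locations are equally frequent overall.
    """

    joint: dict[tuple[Response, Congruency], float]
    p_congruent_given_location: dict[Response, float]


def contingency_table(design: DesignSpec) -> ContingencyTable:
    """Location-congruency contingency implied by the response frequencies."""
    joint_by_cell = {}
    loc_mass: dict[Response, float] = {Response.FREQUENT: 0.0,
                                       Response.INFREQUENT: 0.0}
    loc_congruent: dict[Response, float] = {Response.FREQUENT: 0.0,
                                            Response.INFREQUENT: 0.0}
    for resp, congr in CONDITIONS:
        p_resp = design.p_frequent_response if resp is Response.FREQUENT \
            else 1.0 - design.p_frequent_response
        p_congr = design.p_congruent_within_response \
            if congr is Congruency.CONGRUENT else 1.0 - design.p_congruent_within_response
        p = p_resp * p_congr
        joint_by_cell[(resp, congr)] = p
        loc = stimulus_side(resp, congr)
        loc_mass[loc] += p
        if congr is Congruency.CONGRUENT:
            loc_congruent[loc] += p
    conditional = {loc: (loc_congruent[loc] / loc_mass[loc]) if loc_mass[loc] else 0.0
                   for loc in loc_mass}
    return ContingencyTable(joint=joint_by_cell,
                            p_congruent_given_location=conditional)


def _block_counts(design: DesignSpec, rng: np.random.Generator) -> np.ndarray:
    """Condition counts for one block (len-4 array ordered as CONDITIONS)."""
    probs = []
    for resp, congr in CONDITIONS:
        p_resp = design.p_frequent_response if resp is Response.FREQUENT \
            else 1.0 - design.p_frequent_response
        p_congr = design.p_congruent_within_response \
            if congr is Congruency.CONGRUENT else 1.0 - design.p_congruent_within_response
        probs.append(p_resp * p_congr)
    probs = np.asarray(probs)
    exact = probs * design.trials_per_block
    if np.allclose(exact, np.round(exact)):
        return np.round(exact).astype(int)
    # not evenly divisible: keep floors, assign the remainder multinomially
    base = np.floor(exact).astype(int)
    short = design.trials_per_block - base.sum()
    if short > 0:
        resid = exact - base
        extra = rng.multinomial(short, resid / resid.sum())
        base = base + extra
    return base


def build_trial_table(design: DesignSpec, rng: np.random.Generator,
                      participants: int | None = None) -> pd.DataFrame:
    """Randomized multi-participant trial table realizing the design.

    Conditions are balanced exactly within each block when the block
    length divides evenly, otherwise remainders are assigned
    multinomially.  Always-valid cueing adds a ``cue`` column equal to
    the required response.
    """
    n_part = design.n_participants if participants is None else participants
    rows = []
    for part in range(1, n_part + 1):
        for session in range(1, design.n_sessions + 1):
            for block in range(1, design.n_test_blocks + 1):
                counts = _block_counts(design, rng)
                cells = np.repeat(np.arange(4), counts)
                rng.shuffle(cells)
                for trial, cell in enumerate(cells, start=1):
                    resp, congr = CONDITIONS[cell]
                    rows.append((part, session, block, trial,
                                 resp.value, congr.value,
                                 stimulus_side(resp, congr).value))
    df = pd.DataFrame(rows, columns=["participant", "session", "block", "trial",
                                     "required_response", "congruency",
                                     "stimulus_side"])
    if design.cueing == "always-valid":
        df["cue"] = df["required_response"]
    return df


def generate_synthetic_dataset(design: DesignSpec,
                               params: ModelParameters,
                               variant: VariantSpec,
                               variability: ParticipantVariability | None = None,
                               seed: int | np.random.SeedSequence = 0,
                               participants: int | None = None,
                               ) -> tuple[pd.DataFrame, dict]:
    """Simulate a complete multi-participant dataset from the model.

    Returns the tidy trial table (one row per trial, with ``rt_ms``,
    ``correct``, ``expected_response`` and ``timed_out`` columns) and a
    ground-truth record of the generating parameters for recovery
    studies.  Per-participant scale/shift factors are applied to the
    simulated RTs.  For cued designs the preparation state is drawn per
    trial from the class-specific preparation probability; otherwise
    the frequent response is expected with probability ``pi_freq``.
    """
    if variability is None:
        variability = ParticipantVariability()
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    table_rng = np.random.default_rng(ss.spawn(1)[0])
    n_part = design.n_participants if participants is None else participants
    table = build_trial_table(design, table_rng, participants=n_part)

    frames = []
    part_seeds = ss.spawn(n_part)
    truth_participants = {}
    for pseed, (part, sub) in zip(part_seeds, table.groupby("participant", sort=True)):
        rng = np.random.default_rng(pseed)
        scale, shift = variability.draw(rng)
        required = (sub["required_response"] == Response.FREQUENT.value).to_numpy()
        congruent = (sub["congruency"] == Congruency.CONGRUENT.value).to_numpy()
        prepared = draw_prepared(variant, required, rng)
        rt, correct, timed_out = simulate_trials(
            params, variant, required, congruent, prepared, rng)
        sub = sub.copy()
        expected = np.where(prepared, sub["required_response"],
                            np.where(required, Response.INFREQUENT.value,
                                     Response.FREQUENT.value))
        sub["expected_response"] = expected
        sub["rt_ms"] = shift + scale * rt
        sub["correct"] = correct
        sub["timed_out"] = timed_out
        truth_participants[int(part)] = {"scale": scale, "shift": shift}
        frames.append(sub)
    data = pd.concat(frames, ignore_index=True)
    truth = {
        "design": asdict(design),
        "params": asdict(params),
        "variant": {k: (v.value if hasattr(v, "value") else v)
                    for k, v in asdict(variant).items()},
        "participants": truth_participants,
        "seed_entropy": ss.entropy,
    }
    return data, truth


# ---------------------------------------------------------------------------
# power computations (one-sample / paired t-test, noncentral t)

def _nct_cdf(x: float, df: int, nc: float) -> float:
    with np.errstate(all="ignore"):
        val = stats.nct.cdf(x, df, nc)
    if np.isnan(val):  # extreme noncentrality: normal asymptote
        val = stats.norm.cdf(x - nc)
    return float(val)


def _t_power(n: int, d: float, alpha: float, tails: int) -> float:
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == 2:
        tc = stats.t.ppf(1.0 - alpha / 2.0, df)
        return 1.0 - _nct_cdf(tc, df, nc) + _nct_cdf(-tc, df, nc)
    tc = stats.t.ppf(1.0 - alpha, df)
    return 1.0 - _nct_cdf(tc, df, nc)


def minimum_sample_size(d: float, alpha: float = 0.05, power: float = 0.9,
                        tails: int = 2, n_max: int = 10 ** 6) -> int:
    """Smallest n for which a one-sample t-test reaches the target power.

    Uses the exact noncentral-t power function with noncentrality
    ``d * sqrt(n)``.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if d <= 0:
        raise ValueError("d must be > 0")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    n = 2
    while n <= n_max:
        if _t_power(n, d, alpha, tails) >= power:
            return n
        # jump ahead when far from target to keep the search fast
        n += 1 if n < 1000 else max(1, n // 100)
    raise ValueError(f"power {power} unreachable for d={d} below n={n_max}")


def critical_effect_size(n: int, alpha: float = 0.05, power: float = 0.9,
                         tails: int = 1) -> float:
    """Effect size at which a one-sample t-test attains the target power."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    f = lambda d: _t_power(n, d, alpha, tails) - power
    lo, hi = 1e-8, 100.0
    if f(hi) < 0:
        raise ValueError("no root in (0, 100)")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))
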