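"""Two-stage quantile/G2 model fitting and AIC model comparison.

Fitting proceeds in two stages on pooled condition summaries: a first
stage minimizes the root-mean-square deviation between observed and
simulated error percentages and RT quantiles, and a second stage,
started from the stage-1 solution, minimizes the likelihood-ratio
statistic G2 over the frequencies of errors and of correct RTs in the
bins bounded by the nine observed deciles.  Because RT distributions
are only available by simulation, every objective evaluation simulates
a fixed number of trials per condition with common random numbers, so
the objective is a deterministic (if noisy-in-parameters) function and
derivative-free simplex search applies.  Model comparison uses
AIC = G2 + 2k computed over replicate simulations at the fitted
parameters, which makes the Monte-Carlo spread of the criterion
explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (Congruency, ModelParameters, Response, VariantSpec,
                    simulate_trials)
from .design import CONDITIONS
from . import rtstats

NINE_PROBS = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1))

_VARIANT_FIELDS = frozenset({
    "pi_freq", "pi_infr",
    "attention_rel_same", "attention_rel_opposite",
    "contingency_rel_freqside", "contingency_rel_infrside",
    "contingency_irr_freqside", "contingency_irr_infrside",
    "shield_irr_amplitude", "shield_irr_tau",
})

#: default search bounds per free parameter
DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "pi_freq": (0.5, 1.0),
    "pi_infr": (0.0, 1.0),
    "rel_input": (0.5, 0.75),
    "irr_amplitude": (0.0, 1.0),
    "irr_tau": (20.0, 400.0),
    "lead_mean": (0.0, 300.0),
    "lead_sd": (0.0, 150.0),
    "prep_bias": (0.0, 35.0),
    "noise_sd": (0.01, 1.0),
    "resid_mean": (50.0, 400.0),
    "resid_sd": (0.0, 150.0),
    "attention_rel_same": (0.5, 0.75),
    "attention_rel_opposite": (0.5, 0.75),
    "contingency_rel_freqside": (0.5, 0.75),
    "contingency_rel_infrside": (0.5, 0.75),
    "contingency_irr_freqside": (0.0, 1.0),
    "contingency_irr_infrside": (0.0, 1.0),
    "shield_irr_amplitude": (0.0, 1.0),
    "shield_irr_tau": (20.0, 600.0),
}


@dataclass
class ObservedSummary:
    """Pooled summary of one condition used by both fit stages."""

    required_response: Response
    congruency: Congruency
    n_trials: int               # errors + correct, after screening
    n_errors: int
    error_pct: float
    quantile_probs: np.ndarray
    quantiles: np.ndarray       # nine deciles of pooled correct RTs
    bin_counts: np.ndarray      # [errors, 10 correct-RT decile bins]

    def __post_init__(self) -> None:
        if int(np.sum(self.bin_counts)) != self.n_trials:
            raise ValueError("bin counts must sum to the trial count")
        if np.any(np.diff(self.quantiles) < 0):
            raise ValueError("quantiles must be nondecreasing")


def _bin_counts(rts: np.ndarray, edges: np.ndarray, n_errors: int) -> np.ndarray:
    counts = np.empty(edges.size + 2, dtype=int)
    counts[0] = n_errors
    idx = np.searchsorted(edges, rts, side="right")
    counts[1:] = np.bincount(idx, minlength=edges.size + 1)
    return counts


def summarize_observed(trials: pd.DataFrame,
                       probs: Sequence[float] = NINE_PROBS,
                       min_correct: int = 10,
                       ) -> dict[tuple[Response, Congruency], ObservedSummary]:
    """Pool screened trials across participants and summarize per condition.

    Expects the tidy trial schema (``participant``, ``required_response``,
    ``congruency``, ``rt_ms``, ``correct``), already outlier-screened.
    Correct RTs are pooled with the per-participant linear transform
    (location to the grand mean, spread by the ratio of robust scales,
    estimated per participant across all conditions), then each
    condition is reduced to its error percentage, nine deciles, and the
    frequencies of errors and of correct RTs in the decile bins.
    """
    probs = np.asarray(probs, dtype=float)
    correct_df = trials[trials["correct"]]
    samples = {pid: sub["rt_ms"].to_numpy()
               for pid, sub in correct_df.groupby("participant")}
    pooling = rtstats.pool_participants(samples)

    # map transformed values back to rows (order within participant preserved)
    pooled_rt = np.empty(len(correct_df))
    for pid, sub in correct_df.groupby("participant"):
        pooled_rt[correct_df.index.get_indexer(sub.index)] = pooling.transformed[pid]
    correct_df = correct_df.assign(pooled_rt=pooled_rt)

    out = {}
    for resp, congr in CONDITIONS:
        mask = (trials["required_response"] == resp.value) & \
               (trials["congruency"] == congr.value)
        cond = trials[mask]
        n_total = int(len(cond))
        n_err = int((~cond["correct"]).sum())
        crts = correct_df[(correct_df["required_response"] == resp.value) &
                          (correct_df["congruency"] == congr.value)]["pooled_rt"].to_numpy()
        if crts.size < max(min_correct, probs.size):
            raise ValueError(
                f"condition {resp.value}/{congr.value} has only {crts.size} "
                "correct trials; quantile summary undefined")
        qs = rtstats.quantiles(crts, probs)
        out[(resp, congr)] = ObservedSummary(
            required_response=resp, congruency=congr,
            n_trials=n_total, n_errors=n_err,
            error_pct=100.0 * n_err / n_total,
            quantile_probs=probs, quantiles=qs,
            bin_counts=_bin_counts(crts, qs, n_err))
    return out


def screen_trials(trials: pd.DataFrame, floor: float = 100.0,
                  sd_mult: float = 3.0) -> pd.DataFrame:
    """Apply the outlier rule per participant and condition cell.

    Removes timed-out trials and RTs below the floor or above the
    per-cell mean plus ``sd_mult`` SD (computed once per cell on all
    responses, correct and error alike).
    """
    df = trials[~trials.get("timed_out", pd.Series(False, index=trials.index))]
    df = df[np.isfinite(df["rt_ms"])]
    keep_idx = []
    for _, sub in df.groupby(["participant", "required_response", "congruency"]):
        rt = sub["rt_ms"].to_numpy()
        hi = rt.mean() + sd_mult * rt.std(ddof=1) if rt.size > 1 else np.inf
        keep_idx.append(sub.index[(rt >= floor) & (rt <= hi)])
    return df.loc[np.concatenate([i.to_numpy() for i in keep_idx])].sort_index()


# ---------------------------------------------------------------------------
# simulated condition summaries (common random numbers)

@dataclass
class SimulatedSummary:
    error_prop: float
    mean_rt: float
    quantiles: np.ndarray
    bin_props: np.ndarray | None  # [error, 10 bins] given observed edges


def _simulate_summary(params: ModelParameters, variant: VariantSpec,
                      condition: tuple[Response, Congruency], n: int,
                      seed: np.random.SeedSequence,
                      probs: np.ndarray,
                      observed_edges: np.ndarray | None) -> SimulatedSummary:
    """One condition's simulated summary with reproducible randomness.

    Preparation states, input leads, and residual times are produced by
    pushing fixed uniform draws through the respective quantile
    functions, so that re-evaluating at nearby parameters reuses the
    same underlying random numbers (common random numbers).
    """
    s_aux, s_noise = seed.spawn(2)
    aux = np.random.default_rng(s_aux)
    u_prep, u_lead, u_resid = aux.random((3, n))

    req, congr = condition
    required = np.full(n, req is Response.FREQUENT)
    congruent = np.full(n, congr is Congruency.CONGRUENT)
    prepared = u_prep < variant.prepared_probability(req)

    def trunc_ppf(u, mean, sd):
        if sd == 0:
            return np.full(n, float(mean))
        a = (0.0 - mean) / sd
        return stats.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)

    lead = trunc_ppf(u_lead, params.lead_mean, params.lead_sd)
    resid = trunc_ppf(u_resid, params.resid_mean, params.resid_sd)
    rng = np.random.default_rng(s_noise)
    rt, correct, timed_out = simulate_trials(
        params, variant, required, congruent, prepared, rng,
        lead=lead, resid=resid)
    ok = ~timed_out
    n_valid = int(ok.sum())
    if n_valid == 0:
        raise RuntimeError("all simulated trials timed out")
    crts = rt[ok & correct]
    n_err = n_valid - crts.size
    err_prop = n_err / n_valid
    qs = np.quantile(crts, probs) if crts.size >= probs.size \
        else np.full(probs.shape, np.nan)
    if observed_edges is not None and crts.size:
        counts = _bin_counts(crts, observed_edges, 0)[1:]
        bin_props = np.concatenate(
            [[err_prop], (1.0 - err_prop) * counts / counts.sum()])
    else:
        bin_props = None
    return SimulatedSummary(error_prop=err_prop,
                            mean_rt=float(crts.mean()) if crts.size else np.nan,
                            quantiles=qs, bin_props=bin_props)


# ---------------------------------------------------------------------------
# objectives

def stage1_objective(observed: Mapping, simulated: Mapping,
                     quantile_weight: float = 1.0,
                     error_weight: float = 1.0) -> float:
    """RMS of weighted deviations over error rates and RT quantiles.

    Quantiles enter in seconds and error rates as proportions, which
    puts both statistic families on a comparable numeric range under
    unit weights.
    """
    if set(observed) != set(simulated):
        raise ValueError("condition sets differ between observed and simulated")
    devs = []
    for key, obs in observed.items():
        sim = simulated[key]
        devs.append(error_weight * (obs.error_pct / 100.0 - sim.error_prop))
        dq = (np.asarray(obs.quantiles) - np.asarray(sim.quantiles)) / 1000.0
        devs.extend(quantile_weight * dq)
    devs = np.asarray(devs, dtype=float)
    if np.any(~np.isfinite(devs)):
        return np.inf
    return float(np.sqrt(np.mean(devs ** 2)))


def g2_statistic(observed_counts, predicted_props,
                 eps_floor: float | None = None) -> float:
    """Likelihood-ratio discrepancy 2 * sum O * ln(O / (N p)).

    ``observed_counts`` and ``predicted_props`` are matching sequences
    of per-condition arrays (error bin first, then RT bins).  Predicted
    proportions are floored at ``eps_floor`` (default 0.5 / sum(p's
    condition count)) and renormalized, so observed outcomes the
    simulation never produced contribute a finite penalty.
    """
    total = 0.0
    for O, p in zip(observed_counts, predicted_props):
        O = np.asarray(O, dtype=float)
        p = np.asarray(p, dtype=float)
        if O.shape != p.shape:
            raise ValueError("bin structure mismatch")
        if np.any(O < 0) or np.any(p < 0):
            raise ValueError("negative counts or proportions")
        n = O.sum()
        floor = (0.5 / n if eps_floor is None else eps_floor)
        nz = O > 0
        # floor only where the simulation produced no mass but data exist
        p = np.where(nz, np.maximum(p, floor), p)
        total += 2.0 * float(np.sum(O[nz] * np.log(O[nz] / (n * p[nz]))))
    return max(total, 0.0)


# ---------------------------------------------------------------------------
# two-stage fit

@dataclass
class FitConfig:
    """Budgets and reproducibility knobs for a two-stage fit."""

    trials_per_condition: int = 20_000
    stage1_maxfev: int = 200
    stage2_maxfev: int = 200
    n_restarts: int = 1  # additional stage-1 starts (best result kept)
    seed: int = 0
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    quantile_probs: tuple = NINE_PROBS


@dataclass
class FitResult:
    params: ModelParameters
    variant: VariantSpec
    free_names: tuple[str, ...]
    estimates: dict[str, float]
    stage1_value: float
    g2: float
    k: int
    converged: bool
    n_evaluations: int
    seed: int
    aic_mean: float | None = None
    aic_sd: float | None = None

    @property
    def aic(self) -> float:
        return self.g2 + 2 * self.k


def _apply_free(base: ModelParameters, variant: VariantSpec,
                names: Sequence[str], values: Sequence[float]):
    pkw, vkw = {}, {}
    for name, value in zip(names, values):
        (vkw if name in _VARIANT_FIELDS else pkw)[name] = float(value)
    params = replace(base, **pkw) if pkw else base
    var = replace(variant, **vkw) if vkw else variant
    return params, var


def fit_model(observed: Mapping, base_params: ModelParameters,
              variant: VariantSpec, config: FitConfig | None = None,
              free_names: Sequence[str] | None = None) -> FitResult:
    """Two-stage fit of a model variant to pooled condition summaries.

    Stage 1 minimizes the RMS quantile/error-rate deviation; stage 2
    refines the stage-1 solution under G2.  Both stages use bounded
    Nelder-Mead simplex search on a simulation-based objective with
    common random numbers (the same seed sequence for every
    evaluation), so two runs with identical seeds return identical
    results.  ``free_names`` defaults to the variant's free-parameter
    ledger.
    """
    cfg = config or FitConfig()
    names = tuple(free_names if free_names is not None
                  else variant.free_parameter_names)
    if not names:
        raise ValueError("no free parameters to fit")
    probs = np.asarray(cfg.quantile_probs, dtype=float)
    bounds = []
    x0 = []
    for name in names:
        b = cfg.bounds.get(name, DEFAULT_BOUNDS.get(name))
        if b is None:
            raise ValueError(f"no bounds known for parameter {name!r}")
        bounds.append(b)
        current = getattr(variant, name, None) if name in _VARIANT_FIELDS \
            else getattr(base_params, name)
        if current is None:
            current = 0.5 * (b[0] + b[1])
        x0.append(float(np.clip(current, *b)))

    master = np.random.SeedSequence(cfg.seed)
    cond_seeds = {key: s for key, s in zip(observed, master.spawn(len(observed)))}
    n_eval = [0]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def from_unit(u):  # search runs on the unit cube for uniform scaling
        return lo + np.asarray(u) * (hi - lo)

    def simulate_all(x, with_bins):
        params, var = _apply_free(base_params, variant, names, x)
        sims = {}
        for key, obs in observed.items():
            edges = np.asarray(obs.quantiles) if with_bins else None
            # re-spawning from a fixed parent reproduces the same streams
            seed = np.random.SeedSequence(
                entropy=cond_seeds[key].entropy,
                spawn_key=cond_seeds[key].spawn_key)
            sims[key] = _simulate_summary(
                params, var, key, cfg.trials_per_condition, seed, probs, edges)
        n_eval[0] += 1
        return sims

    def f_stage1(u):
        try:
            return stage1_objective(observed,
                                    simulate_all(from_unit(u), with_bins=False))
        except RuntimeError:
            return np.inf

    def f_stage2(u):
        try:
            sims = simulate_all(from_unit(u), with_bins=True)
        except RuntimeError:
            return np.inf
        return g2_statistic([observed[k].bin_counts for k in observed],
                            [sims[k].bin_props for k in observed])

    u0 = (np.asarray(x0) - lo) / (hi - lo)
    unit = [(0.0, 1.0)] * len(names)

    def wide_simplex(u, spread):
        # a broad initial simplex keeps early steps above the Monte-Carlo
        # jitter of the simulation objective
        verts = [np.clip(u, 0.0, 1.0)]
        for i in range(len(u)):
            v = u.copy()
            v[i] = v[i] + spread if v[i] + spread <= 1.0 else v[i] - spread
            verts.append(np.clip(v, 0.0, 1.0))
        return np.asarray(verts)

    starts = [u0]
    restart_rng = np.random.default_rng(master.spawn(1)[0])
    for _ in range(max(0, cfg.n_restarts)):
        starts.append(restart_rng.uniform(0.15, 0.85, len(names)))
    res1 = None
    for start in starts:
        opts1 = {"maxfev": cfg.stage1_maxfev, "xatol": 1e-3, "fatol": 0.0,
                 "initial_simplex": wide_simplex(np.asarray(start), 0.25)}
        r = optimize.minimize(f_stage1, start, method="Nelder-Mead",
                              bounds=unit, options=opts1)
        if res1 is None or r.fun < res1.fun:
            res1 = r
    opts2 = {"maxfev": cfg.stage2_maxfev, "xatol": 1e-3, "fatol": 0.0,
             "initial_simplex": wide_simplex(res1.x, 0.1)}
    res2 = optimize.minimize(f_stage2, res1.x, method="Nelder-Mead",
                             bounds=unit, options=opts2)
    best = from_unit(res2.x if np.isfinite(res2.fun) else res1.x)
    params, var = _apply_free(base_params, variant, names, best)
    estimates = dict(zip(names, (float(v) for v in best)))
    return FitResult(params=params, variant=var, free_names=names,
                     estimates=estimates,
                     stage1_value=float(res1.fun), g2=float(res2.fun),
                     k=len(names), converged=bool(res1.success or res2.success),
                     n_evaluations=n_eval[0], seed=cfg.seed)


# ---------------------------------------------------------------------------
# AIC distribution and prediction intervals

@dataclass
class AicDistribution:
    samples: np.ndarray
    k: int

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=1))


def aic_distribution(params: ModelParameters, variant: VariantSpec,
                     observed: Mapping, replicates: int = 100,
                     trials: int = 100_000, seed: int = 0,
                     k: int | None = None) -> AicDistribution:
    """Replicate G2 evaluations at fixed parameters, fresh seeds each.

    AIC per replicate is G2 + 2k with k from the variant's
    free-parameter ledger (overridable).
    """
    kk = variant.k_free if k is None else k
    probs = np.asarray(NINE_PROBS)
    master = np.random.SeedSequence(seed)
    out = np.empty(replicates)
    for r, rep_seed in enumerate(master.spawn(replicates)):
        sims = {}
        for key, cond_seed in zip(observed, rep_seed.spawn(len(observed))):
            sims[key] = _simulate_summary(
                params, variant, key, trials, cond_seed,
                probs, np.asarray(observed[key].quantiles))
        g2 = g2_statistic([observed[k_].bin_counts for k_ in observed],
                          [sims[k_].bin_props for k_ in observed])
        out[r] = g2 + 2 * kk
    return AicDistribution(samples=out, k=kk)


@dataclass
class PredictionIntervals:
    """Central 95% simulation intervals for summary statistics."""

    mean_rt: dict       # condition -> (lo, hi)
    error_pct: dict     # condition -> (lo, hi)
    delta: dict         # frequency class -> (lo[5], hi[5]) arrays
    delta_probs: np.ndarray
    replicates: int


def prediction_intervals(params: ModelParameters, variant: VariantSpec,
                         n_per_condition: Mapping, replicates: int = 1000,
                         seed: int = 0, level: float = 0.95,
                         delta_probs=rtstats.DELTA_PROBS) -> PredictionIntervals:
    """Simulation intervals at the observed trial counts.

    Each replicate simulates every condition at its observed n and
    computes mean RT, error percentage, and the delta plots for the
    frequent and infrequent response class; the central ``level``
    interval over replicates is returned per statistic.
    """
    probs = np.asarray(delta_probs, dtype=float)
    master = np.random.SeedSequence(seed)
    conds = list(n_per_condition)
    mean_rt = {c: [] for c in conds}
    err = {c: [] for c in conds}
    deltas = {Response.FREQUENT: [], Response.INFREQUENT: []}
    for rep_seed in master.spawn(replicates):
        sims = {}
        for key, cseed in zip(conds, rep_seed.spawn(len(conds))):
            sim = _simulate_summary(params, variant, key,
                                    int(n_per_condition[key]), cseed,
                                    probs, None)
            mean_rt[key].append(sim.mean_rt)
            err[key].append(100.0 * sim.error_prop)
            sims[key] = sim
        for resp in (Response.FREQUENT, Response.INFREQUENT):
            qc = sims[(resp, Congruency.CONGRUENT)].quantiles
            qi = sims[(resp, Congruency.INCONGRUENT)].quantiles
            deltas[resp].append(qi - qc)
    alpha = (1.0 - level) / 2.0
    pct = lambda a: (np.quantile(np.asarray(a), alpha, axis=0),
                     np.quantile(np.asarray(a), 1.0 - alpha, axis=0))
    return PredictionIntervals(
        mean_rt={c: pct(mean_rt[c]) for c in conds},
        error_pct={c: pct(err[c]) for c in conds},
        delta={r: pct(deltas[r]) for r in deltas},
        delta_probs=probs, replicates=replicates)
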