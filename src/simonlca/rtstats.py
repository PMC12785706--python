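"""Reaction-time distribution statistics.

Outlier screening, empirical quantiles, delta plots with orthogonal
polynomial trend coefficients, a Qn-type robust scale estimator, and
cross-participant pooling of RT distributions by per-participant linear
transformation (Sternberg's method), which aligns each participant's
location and robust scale before combining trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: consistency factor mapping the pairwise-difference order statistic to
#: the standard deviation of a normal sample (asymptotic, no
#: finite-sample correction); fixed so that results are reproducible
QN_CONSISTENCY = 2.2219

DELTA_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class ConditionSample:
    """Correct-response RTs of one condition with error/outlier counts."""

    rts: np.ndarray
    n_errors: int = 0
    n_outliers: int = 0

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        if np.any(self.rts <= 0):
            raise ValueError("RTs must be positive")


def screen_outliers(rts, floor: float = 100.0,
                    sd_mult: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Split a sample into kept and removed RTs.

    Removes values below ``floor`` ms or above the sample mean plus
    ``sd_mult`` standard deviations; mean and SD are computed once on
    the full input (no iteration).
    """
    x = np.asarray(rts, dtype=float)
    if x.size == 0:
        raise ValueError("empty RT sample")
    ceiling = x.mean() + sd_mult * x.std(ddof=1) if x.size > 1 else np.inf
    bad = (x < floor) | (x > ceiling)
    return x[~bad], x[bad]


def quantiles(rts, probs) -> np.ndarray:
    """Empirical quantiles by linear interpolation of order statistics."""
    x = np.asarray(rts, dtype=float)
    p = np.asarray(probs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probs must lie strictly inside (0, 1)")
    if x.size < p.size:
        raise ValueError("sample smaller than the number of quantiles")
    return np.quantile(x, p)  # default linear interpolation


def emerson_basis(x, max_order: int = 2) -> np.ndarray:
    """Orthonormal polynomial basis on (generally unequally spaced) x.

    Built by the Emerson three-term recurrence: each polynomial of the
    next degree is the monomial-shifted previous one, orthogonalized
    against its two predecessors and scaled to unit norm.  Returns an
    array of shape ``(max_order + 1, len(x))``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < max_order + 1:
        raise ValueError("need at least max_order + 1 points")
    if np.allclose(x, x[0]):
        raise ValueError("x values are degenerate (all equal)")
    basis = np.empty((max_order + 1, n))
    prev = np.zeros(n)
    cur = np.ones(n) / np.sqrt(n)
    basis[0] = cur
    for order in range(1, max_order + 1):
        alpha = np.sum(x * cur * cur)
        beta = np.sum(x * cur * prev)
        nxt = (x - alpha) * cur - beta * prev
        norm = np.linalg.norm(nxt)
        if norm < 1e-12 * max(1.0, np.abs(x).max() ** order):
            raise ValueError("degenerate abscissae: basis collapsed")
        nxt /= norm
        basis[order] = nxt
        prev, cur = cur, nxt
    return basis


def fit_orthogonal_polys(x, y, max_order: int = 2) -> np.ndarray:
    """Trend coefficients of y on the orthonormal polynomial basis in x.

    ``c[k]`` is the inner product of y with the degree-k basis
    polynomial; the implied reconstruction equals the least-squares
    polynomial fit of degree ``max_order``.
    """
    y = np.asarray(y, dtype=float)
    basis = emerson_basis(x, max_order)
    if y.size != basis.shape[1]:
        raise ValueError("x and y lengths differ")
    return basis @ y


@dataclass
class DeltaPlot:
    """Quantile-wise congruency effect against quantile-pair means."""

    quantile_probs: np.ndarray
    deltas: np.ndarray  # incongruent - congruent quantiles (ms)
    means: np.ndarray   # pairwise quantile means (ms)
    c0: float = np.nan  # level
    c1: float = np.nan  # slope
    c2: float = np.nan  # curvature

    @property
    def slope(self) -> float:
        """Least-squares slope of deltas against means (ms per ms)."""
        return float(np.polyfit(self.means, self.deltas, 1)[0])


def delta_plot(congruent: ConditionSample | np.ndarray,
               incongruent: ConditionSample | np.ndarray,
               probs=DELTA_PROBS) -> DeltaPlot:
    """Delta plot of two conditions' RT distributions.

    Plots quantile differences (incongruent minus congruent) against
    the means of the quantile pairs, with level/slope/curvature
    coefficients on the orthonormal polynomial basis when at least
    three quantiles are requested.
    """
    cong = congruent.rts if isinstance(congruent, ConditionSample) else congruent
    incg = incongruent.rts if isinstance(incongruent, ConditionSample) else incongruent
    p = np.asarray(probs, dtype=float)
    qc = quantiles(cong, p)
    qi = quantiles(incg, p)
    deltas = qi - qc
    means = (qi + qc) / 2.0
    dp = DeltaPlot(quantile_probs=p, deltas=deltas, means=means)
    if p.size >= 3 and not np.allclose(means, means[0]):
        c = fit_orthogonal_polys(means, deltas, max_order=2)
        dp.c0, dp.c1, dp.c2 = (float(v) for v in c)
    return dp


def robust_scale(x) -> float:
    """Qn-type robust scale: an order statistic of pairwise distances.

    The k-th smallest of the ``|x_i - x_j|`` (i < j) with
    ``k = C(h, 2)``, ``h = floor(n/2) + 1``, multiplied by the
    consistency factor :data:`QN_CONSISTENCY`.  Translation invariant
    and scale equivariant; zero only for degenerate samples.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("robust scale needs at least 2 observations")
    i, j = np.triu_indices(n, k=1)
    diffs = np.abs(x[i] - x[j])
    h = n // 2 + 1
    k = h * (h - 1) // 2
    kth = np.partition(diffs, k - 1)[k - 1]
    return float(QN_CONSISTENCY * kth)


@dataclass
class PoolingSummary:
    """Result of pooling RT samples across participants."""

    participant_ids: list
    means: np.ndarray          # m_i
    scales: np.ndarray         # q_i
    grand_mean: float          # m.
    grand_scale: float         # q.
    transformed: dict = field(repr=False)  # id -> transformed RTs

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate([self.transformed[i] for i in self.participant_ids])


def pool_participants(samples: dict) -> PoolingSummary:
    """Pool per-participant RT samples via y = m. + (x - m_i) * q. / q_i.

    Every participant's sample is recentred on the grand mean of the
    individual means and rescaled by the ratio of the grand robust
    scale to the individual one, so that between-participant location
    and spread differences are removed while each participant's trial
    ordering is preserved.
    """
    if not samples:
        raise ValueError("no participants to pool")
    ids = list(samples.keys())
    means, scales = [], []
    for pid in ids:
        x = np.asarray(samples[pid], dtype=float)
        if x.size < 2:
            raise ValueError(f"participant {pid!r} has fewer than 2 RTs")
        q = robust_scale(x)
        if q == 0.0:
            raise ValueError(f"participant {pid!r} has zero robust scale")
        means.append(x.mean())
        scales.append(q)
    means = np.asarray(means)
    scales = np.asarray(scales)
    m_dot = float(means.mean())
    q_dot = float(scales.mean())
    transformed = {}
    for pid, m_i, q_i in zip(ids, means, scales):
        x = np.asarray(samples[pid], dtype=float)
        transformed[pid] = m_dot + (x - m_i) * (q_dot / q_i)
    return PoolingSummary(participant_ids=ids, means=means, scales=scales,
                          grand_mean=m_dot, grand_scale=q_dot,
                          transformed=transformed)
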