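"""Umbrella-trial multiple testing over all subset strategies.

An umbrella trial has ``l`` disjoint biomarker strata ``S_1, ..., S_l``,
each pairing an experimental treatment ``E_i`` against a shared control.
Beyond the stratum-wise comparisons one tests, for every non-empty subset
``S`` of strata, the hypothesis ``H_S: theta_S <= 0`` about the
prevalence-weighted average effect ``theta_S = sum_{i in S} (pi_i/pi_S)
theta_i`` of applying the strategy in the union of the strata in ``S``.
The subset statistics ``T_S`` come from one least-squares fit of the
two-parameter-per-stratum linear model ``Y_ij = mu_i + theta_i X_ij + eps``
(pooled residual variance, ``N - 2l`` degrees of freedom) and are compared
single-step against a common threshold: the upper ``alpha``-quantile of
``max_S T_S`` for FWER-control, or the smaller PWER-calibrated value that
only averages each stratum's multiplicity over the subsets that contain it.
The selected strategy is the argmax subset among the rejected ones.

Effect configurations are parameterized by the fraction ``q`` of true
nulls, the relative half-range ``tau`` of the positive effects and their
weighted mean ``theta_overall``, which pin down a unique equidistant grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pwer_core
from .nulldist import enumerate_subsets, umbrella_null_model, union_tail
from .structure import build_structure
from .trial_simulator import largest_remainder

__all__ = [
    "UmbrellaDesign",
    "SelectionOutcome",
    "PerformanceTable",
    "effect_grid",
    "fit_subset_statistics",
    "select_subset",
    "pwer_critical_value_umbrella",
    "fwer_critical_value_umbrella",
    "run_performance_study",
]


@dataclass(frozen=True)
class UmbrellaDesign:
    """``l`` disjoint strata, total sample size ``N``, 1:1 arms per stratum."""

    l: int
    N: int = 1056
    prevalences: tuple[float, ...] | None = None
    sigma: float = 1.0
    alpha: float = 0.025
    theta_overall: float = 0.1
    intercepts: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.l < 1:
            raise ValueError("l must be >= 1")
        pi = (
            np.full(self.l, 1.0 / self.l)
            if self.prevalences is None
            else np.asarray(self.prevalences, dtype=float)
        )
        if pi.shape != (self.l,) or abs(pi.sum() - 1.0) > 1e-9 or np.any(pi <= 0):
            raise ValueError("prevalences must be l positive numbers summing to 1")
        object.__setattr__(self, "prevalences", tuple(pi))
        if self.N <= 2 * self.l:
            raise ValueError(f"N = {self.N} must exceed 2l = {2 * self.l}")
        mu = (
            np.zeros(self.l)
            if self.intercepts is None
            else np.asarray(self.intercepts, dtype=float)
        )
        object.__setattr__(self, "intercepts", tuple(mu))

    def structure(self):
        return build_structure([((i,), p) for i, p in enumerate(self.prevalences, 1)])

    def arm_sizes(self) -> tuple[np.ndarray, np.ndarray]:
        n = largest_remainder(self.N, np.asarray(self.prevalences))
        n_treat = n // 2
        return n_treat, n - n_treat

    def subsets(self) -> list[tuple[int, ...]]:
        return enumerate_subsets(self.l)


@dataclass(frozen=True)
class SelectionOutcome:
    selected: tuple[int, ...]  # empty tuple = no claim
    statistics: dict[tuple[int, ...], float] = field(repr=False)
    threshold: float = np.nan


def effect_grid(l: int, q: float, tau: float, theta_overall: float) -> np.ndarray:
    """The unique equidistant effect vector with characteristics (q, tau).

    ``q * l`` zeros followed by ``l - q*l`` equidistant positive effects from
    ``theta_overall (1 - tau)`` to ``theta_overall (1 + tau)``; the positives
    average to ``theta_overall`` and have relative half-range ``tau``
    (equal stratum prevalences assumed).
    """
    l0 = q * l
    if abs(l0 - round(l0)) > 1e-9:
        raise ValueError(f"q*l = {l0} must be an integer")
    l0 = int(round(l0))
    if not 0 <= l0 <= l:
        raise ValueError("q must be in [0, 1]")
    if not 0.0 <= tau < 1.0:
        raise ValueError(f"tau must be in [0, 1), got {tau}")
    lp = l - l0
    if lp <= 1 and tau != 0.0:
        raise ValueError("tau must be 0 with at most one positive effect")
    if lp == 0:
        return np.zeros(l)
    if theta_overall <= 0:
        raise ValueError("theta_overall must be positive when q < 1")
    lo, hi = theta_overall * (1.0 - tau), theta_overall * (1.0 + tau)
    positives = np.linspace(lo, hi, lp) if lp > 1 else np.array([theta_overall])
    return np.concatenate([np.zeros(l0), positives])


# ---------------------------------------------------------------------------
# statistics from subject-level data
# ---------------------------------------------------------------------------

def fit_subset_statistics(trial: pd.DataFrame, design: UmbrellaDesign) -> dict:
    """One-sided t statistics ``T_S`` from a subject-level umbrella trial.

    Least squares of the stratum-intercept/stratum-effect model reduces, for
    this balanced-by-stratum design, to the per-stratum arm-mean differences
    ``theta_hat_i`` and the pooled residual variance on ``N - 2l`` degrees of
    freedom.
    """
    l = design.l
    pi = np.asarray(design.prevalences)
    theta_hat = np.empty(l)
    sse = 0.0
    n_treat = np.empty(l)
    n_ctrl = np.empty(l)
    N = len(trial)
    if N <= 2 * l:
        raise ValueError("N <= 2l: residual degrees of freedom exhausted")
    for i in range(1, l + 1):
        sub = trial[trial["stratum"] == str(i)]
        yt = sub.loc[sub["arm"] == f"T{i}", "outcome"].to_numpy()
        yc = sub.loc[sub["arm"] == "C", "outcome"].to_numpy()
        if len(yt) == 0 or len(yc) == 0:
            raise ValueError(f"stratum {i} is missing a treatment or control arm")
        theta_hat[i - 1] = yt.mean() - yc.mean()
        n_treat[i - 1], n_ctrl[i - 1] = len(yt), len(yc)
        sse += ((yt - yt.mean()) ** 2).sum() + ((yc - yc.mean()) ** 2).sum()
    sigma2 = sse / (N - 2 * l)
    if sigma2 <= 0:
        raise ValueError("zero residual variance: t statistics undefined")
    var_i = 1.0 / n_treat + 1.0 / n_ctrl
    out = {}
    for S in design.subsets():
        idx = [i - 1 for i in S]
        a = pi[idx] / pi[idx].sum()
        est = float(a @ theta_hat[idx])
        se = float(np.sqrt(sigma2 * (a**2 @ var_i[idx])))
        out[S] = est / se
    return out


def select_subset(statistics: dict, c: float) -> SelectionOutcome:
    """Argmax selection: the maximizing subset if its statistic exceeds ``c``.

    Exact ties are broken toward the smaller cardinality, then
    lexicographically — the enumeration order of the subsets.
    """
    if not statistics:
        raise ValueError("no statistics to select from")
    keys = sorted(statistics, key=lambda S: (len(S), S))
    values = np.array([statistics[S] for S in keys])
    best = int(np.argmax(values))
    if values[best] > c:
        return SelectionOutcome(selected=keys[best], statistics=dict(statistics), threshold=c)
    return SelectionOutcome(selected=(), statistics=dict(statistics), threshold=c)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def pwer_critical_value_umbrella(design: UmbrellaDesign, alpha: float | None = None) -> float:
    """PWER threshold: root of ``sum_i pi_i P0(U_{S : i in S} T_S >= c) = alpha``.

    With equal prevalences the strata are exchangeable, so one union
    probability suffices; otherwise the generic calibrator is used.
    """
    alpha = design.alpha if alpha is None else alpha
    model = umbrella_null_model(design)
    pi = np.asarray(design.prevalences)
    if np.allclose(pi, pi[0]):
        pos = model.label_positions((1,))
        f = lambda c: union_tail(model, pos, c)
        c, _, _ = pwer_core._calibrate(f, alpha, model, len(pos))
        return float(c)
    return pwer_core.critical_value(design.structure(), model, alpha).c_star


def fwer_critical_value_umbrella(design: UmbrellaDesign, alpha: float | None = None) -> float:
    """Upper ``alpha``-quantile of ``max_S T_S`` under the global null."""
    alpha = design.alpha if alpha is None else alpha
    model = umbrella_null_model(design)
    return pwer_core.fwer_critical_value(model, alpha)


# ---------------------------------------------------------------------------
# vectorized trial replication and the performance study
# ---------------------------------------------------------------------------

def simulate_subset_statistics(
    design: UmbrellaDesign,
    theta: np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """Replicated ``T_S`` vectors (n_reps x (2^l - 1)), subject-level noise.

    Each replicate draws all ``N`` subject residuals, reduces them to arm
    means and the pooled error sum of squares, and forms the same statistics
    as :func:`fit_subset_statistics`.
    """
    l, N, sigma = design.l, design.N, design.sigma
    theta = np.asarray(theta, dtype=float)
    n_treat, n_ctrl = design.arm_sizes()
    sizes = np.empty(2 * l, dtype=int)
    sizes[0::2], sizes[1::2] = n_treat, n_ctrl
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    pi = np.asarray(design.prevalences)
    subsets = design.subsets()
    A = np.zeros((len(subsets), l))
    for r, S in enumerate(subsets):
        idx = [i - 1 for i in S]
        A[r, idx] = pi[idx] / pi[idx].sum()
    var_i = 1.0 / n_treat + 1.0 / n_ctrl
    se_unit = np.sqrt((A**2) @ var_i)  # * sigma_hat
    dof = N - 2 * l
    out = np.empty((n_reps, len(subsets)))
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        eps = sigma * rng.standard_normal((b, N))
        gsum = np.add.reduceat(eps, starts, axis=1)
        gmean = gsum / sizes
        sse = (eps**2).sum(axis=1) - (sizes * gmean**2).sum(axis=1)
        sigma_hat = np.sqrt(sse / dof)
        theta_hat = (gmean[:, 0::2] + theta) - gmean[:, 1::2]
        out[done : done + b] = (theta_hat @ A.T) / (sigma_hat[:, None] * se_unit)
        done += b
    return out


@dataclass(frozen=True)
class PerformanceTable:
    table: pd.DataFrame
    n_reps: int
    seed: int


def _scenario_measures(T, subsets, theta, pi, c, theta_overall):
    """Power, correct/false selection fractions and RAE for one threshold."""
    false_null = np.array([any(theta[i - 1] > 0 for i in S) for S in subsets])
    rejected = T > c
    power = rejected[:, false_null].any(axis=1) if false_null.any() else np.zeros(len(T), bool)
    best = np.argmax(T, axis=1)
    claimed = T[np.arange(len(T)), best] > c
    pi_S = np.array([pi[[i - 1 for i in S]].sum() for S in subsets])
    pi_plus = np.array([pi[[i - 1 for i in S if theta[i - 1] > 0]].sum() for S in subsets])
    benefit = np.array([sum(pi[i - 1] * theta[i - 1] for i in S) for S in subsets])
    correct = np.where(claimed, pi_plus[best] / pi_S[best], 0.0)
    false = np.where(claimed, (pi_S - pi_plus)[best] / pi_S[best], 0.0)
    delivered = np.where(claimed, benefit[best], 0.0)
    n = len(T)
    rae = 100.0 * delivered.mean() / theta_overall if theta_overall > 0 else 0.0
    return {
        "power": 100.0 * power.mean(),
        "correct": 100.0 * correct.mean(),
        "false": 100.0 * false.mean(),
        "rae": rae,
        "mc_se_power": 100.0 * np.sqrt(power.mean() * (1 - power.mean()) / n),
        "mc_se_false": 100.0 * false.std(ddof=1) / np.sqrt(n),
    }


def run_performance_study(
    design: UmbrellaDesign,
    scenarios,
    n_reps: int = 10_000,
    seed: int = 0,
    thresholds: tuple[float, float] | None = None,
) -> PerformanceTable:
    """Simulate the umbrella procedure under PWER- and FWER-control.

    ``scenarios`` is a list of ``(q, tau)`` pairs; the weighted mean positive
    effect is ``design.theta_overall``.  Both methods are evaluated on the
    same simulated trials (common random numbers), so the documented
    dominance relations (identical non-empty selections whenever the FWER
    method claims one; larger delivered effect under PWER-control) hold
    replicate by replicate.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    if thresholds is not None:
        c_p, c_f = thresholds  # pre-computed (e.g. shared across studies)
    else:
        c_p = pwer_critical_value_umbrella(design)
        c_f = fwer_critical_value_umbrella(design)
    subsets = design.subsets()
    pi = np.asarray(design.prevalences)
    rows = []
    for s_idx, (q, tau) in enumerate(scenarios):
        theta = effect_grid(design.l, q, tau, design.theta_overall)
        theta_overall = design.theta_overall if q < 1 else 0.0
        rng = np.random.default_rng([seed, s_idx])
        T = simulate_subset_statistics(design, theta, n_reps, rng)
        for method, c in (("PWER", c_p), ("FWER", c_f)):
            meas = _scenario_measures(T, subsets, theta, pi, c, theta_overall)
            rows.append(
                {"l": design.l, "q": q, "tau": tau, "method": method,
                 "threshold": c, **meas, "n_reps": n_reps}
            )
    return PerformanceTable(table=pd.DataFrame(rows), n_reps=n_reps, seed=seed)
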