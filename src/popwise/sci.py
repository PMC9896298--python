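"""Simultaneous confidence intervals dual to the PWER test.

Inverting the single-step PWER test gives Wald-type bounds
``theta~_i = theta^_i - c* SE_i`` (lower), ``theta^_i + c* SE_i`` (upper),
where ``c*`` is the PWER-calibrated threshold.  These intervals control an
*average simultaneous coverage*: for a randomly drawn future patient, the
probability that every bound relevant to that patient's stratum is correct
is at least ``1 - alpha``, i.e.

    sum_J pi_J P( theta~_j <= theta_j  for all j affecting J ) >= 1 - alpha.

Two-sided intervals intersect the two one-sided constructions and carry
twice the one-sided non-coverage, so a two-sided level-``alpha`` interval
uses the ``alpha/2`` one-sided threshold.  Only Wald-type (pivotal,
shift-equivariant) statistics are implemented; a user-supplied monotone
statistic family can be inverted with :func:`invert_statistic_family`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pwer_core
from .nulldist import JointNullModel
from .structure import PopulationStructure

__all__ = ["SCIResult", "sci_bounds", "coverage_simulation", "invert_statistic_family"]

SIDES = ("lower", "upper", "two_sided")


@dataclass(frozen=True)
class SCIResult:
    estimates: np.ndarray
    standard_errors: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    c_star: float
    alpha: float
    side: str
    table: pd.DataFrame = field(repr=False)


def sci_bounds(
    estimates,
    standard_errors,
    structure: PopulationStructure,
    model: JointNullModel,
    alpha: float = 0.025,
    side: str = "lower",
) -> SCIResult:
    """Wald-type simultaneous bounds dual to the PWER test at level alpha."""
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(standard_errors, dtype=float)
    if est.shape != (model.k,) or se.shape != (model.k,):
        raise ValueError(f"need one (estimate, SE) pair per hypothesis ({model.k})")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    level = alpha / 2.0 if side == "two_sided" else alpha
    c = pwer_core.critical_value(structure, model, level).c_star
    lower = est - c * se if side in ("lower", "two_sided") else np.full_like(est, -np.inf)
    upper = est + c * se if side in ("upper", "two_sided") else np.full_like(est, np.inf)
    table = pd.DataFrame(
        {
            "hypothesis": [("+".join(map(str, lab))) for lab in model.labels],
            "estimate": est,
            "se": se,
            "lower": lower,
            "upper": upper,
        }
    )
    return SCIResult(
        estimates=est, standard_errors=se, lower=lower, upper=upper,
        c_star=c, alpha=alpha, side=side, table=table,
    )


def invert_statistic_family(statistic, c_star: float, lo: float, hi: float,
                            tol: float = 1e-10) -> float:
    """Lower bound ``min{delta : T(delta) <= c*}`` for a monotone family.

    ``statistic(delta)`` must be non-increasing in ``delta`` (as Wald
    statistics are); the bound is located by bisection on ``[lo, hi]``.
    """
    if statistic(hi) > c_star:
        raise ValueError("statistic(hi) still exceeds c*; enlarge the bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if statistic(mid) <= c_star:
            hi = mid
        else:
            lo = mid
    return hi


def coverage_simulation(
    structure: PopulationStructure,
    model: JointNullModel,
    theta,
    n_reps: int = 10_000,
    seed: int = 0,
    alpha: float = 0.025,
    side: str = "lower",
) -> dict:
    """Monte-Carlo average simultaneous coverage of the dual bounds.

    Draws estimate vectors from the joint model shifted by ``theta`` (Wald
    pivotality: SEs taken as 1 without loss of generality), forms the
    bounds, and averages the strata-wise simultaneous-coverage indicators
    with the prevalence weights.
    """
    if n_reps < 1000:
        raise ValueError("n_reps must be at least 1000")
    if model.family != "normal":
        raise ValueError("coverage simulation implemented for normal models")
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (model.k,))
    level = alpha / 2.0 if side == "two_sided" else alpha
    c = pwer_core.critical_value(structure, model, level).c_star
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(
        model.correlation + 1e-12 * np.eye(model.k)
    )
    Z = rng.standard_normal((n_reps, model.k)) @ L.T
    # theta^ = theta + Z; lower bound correct iff Z_j <= c, upper iff Z_j >= -c
    if side == "lower":
        ok = Z <= c
    elif side == "upper":
        ok = Z >= -c
    else:
        ok = (Z <= c) & (Z >= -c)
    coverage = 0.0
    for J, pi_J in structure.strata.items():
        pos = model.label_positions(J)
        cov_J = ok[:, pos].all(axis=1).mean() if pos else 1.0
        coverage += pi_J * cov_J
    se = np.sqrt(coverage * (1.0 - coverage) / n_reps)
    return {"coverage": float(coverage), "se": float(se), "c_star": float(c),
            "alpha": alpha, "side": side, "n_reps": n_reps}
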