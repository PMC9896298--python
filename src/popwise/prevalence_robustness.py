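"""Robustness of PWER-control when prevalences must be estimated.

In practice the stratum prevalences are unknown: the trial observes
multinomial stratum counts, plugs the maximum-likelihood estimates into the
calibration, and tests with the resulting critical value.  The *true* PWER
of that data-driven threshold — evaluated with the true prevalences but the
correlation structure conditional on the realized counts — is then a random
variable, and this module measures its mean over repeated recruitment for
the two single-trial two-population scenarios.

Because the critical value depends on the data only through the count
vector, replicates with identical counts share one calibration; results are
cached per count triple, which makes the full grid-by-replicate study cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .nulldist import bivariate_normal_cdf, corr_two_pop_from_counts

__all__ = [
    "RobustnessResult",
    "default_grid",
    "true_pwer_given_counts",
    "robustness_study",
]

_SCENARIOS = ("two_pop_unequal", "two_pop_equal")


@dataclass(frozen=True)
class RobustnessResult:
    table: pd.DataFrame
    n_reps: int
    seed: int


def default_grid(step: float = 0.05, max_sum: float = 0.95):
    """Complement-prevalence pairs ``(pi_{1}, pi_{2})`` with sum <= max_sum."""
    vals = np.arange(step, max_sum + 1e-12, step)
    return [
        (float(a), float(b))
        for a in vals
        for b in vals
        if a + b <= max_sum + 1e-12
    ]


def _two_pop_pwer(c: float, p1: float, p2: float, p12: float, rho: float,
                  test1: bool, test2: bool) -> float:
    """PWER of the two-population design at threshold ``c``.

    ``test1``/``test2`` flag whether the corresponding hypothesis is testable
    (a population with no recruited patient has no statistic and can never be
    rejected).
    """
    sf = norm.sf(c)
    total = 0.0
    if test1:
        total += p1 * sf
    if test2:
        total += p2 * sf
    if p12 > 0:
        if test1 and test2:
            total += p12 * (1.0 - bivariate_normal_cdf(c, c, rho))
        elif test1 or test2:
            total += p12 * sf
    return total


@lru_cache(maxsize=100_000)
def _calibrate_from_counts(
    scenario: str, n1: int, n2: int, n12: int, alpha: float, pi_min: float | None
):
    """Critical value and conditional correlation implied by realized counts."""
    N = n1 + n2 + n12
    test1, test2 = n1 + n12 > 0, n2 + n12 > 0
    rho = (
        corr_two_pop_from_counts(scenario, n1, n2, n12)
        if (test1 and test2)
        else 0.0
    )
    p = np.array([n1, n2, n12], dtype=float) / N
    if pi_min is not None:
        from .structure import _floor_and_renormalize

        floored = _floor_and_renormalize(
            {(1,): p[0], (2,): p[1], (1, 2): p[2]}, pi_min
        )
        p = np.array([floored[(1,)], floored[(2,)], floored[(1, 2)]])
    if not (test1 or test2):
        raise ValueError("no testable hypothesis")
    f = lambda c: _two_pop_pwer(c, p[0], p[1], p[2], rho, test1, test2)
    lo = norm.ppf(1 - alpha) - 1e-9
    hi = norm.ppf(1 - alpha / 2) + 1.0
    if f(lo) <= alpha:
        c = lo + 1e-9  # a single testable hypothesis: marginal quantile
    else:
        c = brentq(lambda x: f(x) - alpha, lo, hi, xtol=1e-10)
    return float(c), float(rho), test1, test2


def true_pwer_given_counts(
    scenario: str,
    counts: tuple[int, int, int],
    true_prevalences: tuple[float, float, float],
    alpha: float = 0.025,
    pi_min: float | None = None,
) -> tuple[float, float]:
    """(critical value, true PWER) for one realized count vector.

    The critical value is calibrated from the ML prevalence estimates and the
    count-conditional correlation; the returned PWER plugs that value into
    the error rate with the *true* prevalences and the same conditional
    correlation.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"scenario must be one of {_SCENARIOS}")
    n1, n2, n12 = (int(v) for v in counts)
    c, rho, test1, test2 = _calibrate_from_counts(
        scenario, n1, n2, n12, float(alpha), pi_min
    )
    p1, p2, p12 = true_prevalences
    return c, _two_pop_pwer(c, p1, p2, p12, rho, test1, test2)


def robustness_study(
    scenario: str,
    grid=None,
    N: int = 50,
    alpha: float = 0.025,
    n_reps: int = 10_000,
    seed: int = 0,
    pi_min: float | None = None,
) -> RobustnessResult:
    """Mean true PWER over multinomial recruitment, per true-prevalence point.

    ``grid`` lists complement-prevalence pairs ``(pi_{1}, pi_{2})``; the
    intersection takes the rest.  Per replicate, stratum counts are drawn
    multinomially, the threshold is calibrated from the estimated
    prevalences, and the true PWER of that threshold is recorded.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    if grid is None:
        grid = default_grid()
    rows = []
    for g_idx, (p1, p2) in enumerate(grid):
        p12 = 1.0 - p1 - p2
        if p12 < -1e-12:
            raise ValueError(f"grid point ({p1}, {p2}) exceeds total mass 1")
        p12 = max(p12, 0.0)
        rng = np.random.default_rng([seed, g_idx])
        draws = rng.multinomial(N, [p1, p2, p12], size=n_reps)
        uniq, inverse = np.unique(draws, axis=0, return_inverse=True)
        vals = np.empty(len(uniq))
        for u, (n1, n2, n12) in enumerate(uniq):
            _, vals[u] = true_pwer_given_counts(
                scenario, (n1, n2, n12), (p1, p2, p12), alpha, pi_min
            )
        pwers = vals[inverse]
        sd = float(pwers.std(ddof=1))
        rows.append(
            {
                "pi1": p1,
                "pi2": p2,
                "pi12": p12,
                "N": N,
                "mean_true_pwer": float(pwers.mean()),
                "se": sd / np.sqrt(n_reps),
                "sd_single": sd,
                "n_reps": n_reps,
            }
        )
    return RobustnessResult(table=pd.DataFrame(rows), n_reps=n_reps, seed=seed)
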