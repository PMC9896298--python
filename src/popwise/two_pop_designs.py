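"""Design calculators for two overlapping populations.

Covers the two benchmark settings for comparing PWER- with FWER-control:

* *independent samples*: one treatment tested in two disjoint samples from
  two overlapping biomarker populations, so the z-statistics are
  independent.  Here the PWER threshold has a closed form, and the FWER
  threshold is Šidák's ``c_F* = Phi^{-1}(sqrt(1 - alpha))``.
* *single trial*: both populations recruited into one study with a shared
  control, either with different treatments (1:1:1 in the intersection) or
  with one treatment (1:1 per stratum); the statistics are positively
  correlated with the closed-form correlations from
  :mod:`popwise.nulldist`.

The cost of multiplicity adjustment is summarized by the sample-size
inflation factor
``q_alpha(c) = ((z_{1-beta} + c) / (z_{1-beta} + z_{1-alpha}))^2``:
how much larger each population's sample must be, relative to an unadjusted
design, to keep marginal power ``1 - beta`` at critical value ``c``.  The
non-centrality per unit sample size cancels in this ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import pwer_core
from .nulldist import two_pop_model
from .structure import build_structure

__all__ = [
    "TwoPopDesign",
    "critical_value_independent",
    "sidak_critical_value",
    "sample_size_inflation",
    "inflation_curve",
]

TWO_POP_SCENARIOS = ("two_pop_independent", "two_pop_unequal", "two_pop_equal")


@dataclass(frozen=True)
class TwoPopDesign:
    """Two overlapping populations of equal size with intersection ``pi12``."""

    pi12: float
    scenario: str = "two_pop_independent"
    alpha: float = 0.025
    beta: float = 0.2
    sigma: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.pi12 <= 1.0:
            raise ValueError(f"pi12 must be in [0, 1], got {self.pi12}")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.beta < 1.0):
            raise ValueError("alpha and beta must be in (0, 1)")
        if self.scenario not in TWO_POP_SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def pi_complement(self) -> float:
        return (1.0 - self.pi12) / 2.0

    def structure(self):
        entries = []
        if self.pi12 < 1.0:
            entries += [((1,), self.pi_complement), ((2,), self.pi_complement)]
        entries += [((1, 2), self.pi12)] if self.pi12 > 0 else []
        return build_structure(entries)


def sidak_critical_value(alpha: float, k: int = 2) -> float:
    """FWER threshold for ``k`` independent standard normal statistics."""
    return float(norm.ppf((1.0 - alpha) ** (1.0 / k)))


def critical_value_independent(alpha: float, pi12: float) -> float:
    """Closed-form PWER threshold for two independent statistics.

    Solving ``(1 - pi) (1 - Phi(c)) + pi (1 - Phi(c)^2) = alpha`` as a
    quadratic in ``Phi(c)`` gives

        c_P* = Phi^{-1}( [-(1 - pi) + sqrt((1 - pi)^2 + 4 pi (1 - alpha))]
                         / (2 pi) )

    with the continuous limit ``Phi^{-1}(1 - alpha)`` at ``pi = 0`` (no
    intersection: unadjusted testing) and Šidák's value at ``pi = 1``.
    """
    if not 0.0 <= pi12 <= 1.0:
        raise ValueError(f"pi12 must be in [0, 1], got {pi12}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if pi12 == 0.0:
        return float(norm.ppf(1.0 - alpha))
    q = 1.0 - pi12
    phi_c = (-q + np.sqrt(q * q + 4.0 * pi12 * (1.0 - alpha))) / (2.0 * pi12)
    return float(norm.ppf(phi_c))


def sample_size_inflation(c: float, alpha: float = 0.025, beta: float = 0.2) -> float:
    """Inflation factor ``q_alpha(c)`` relative to the unadjusted design."""
    if not np.isfinite(c):
        raise ValueError("critical value must be finite")
    z_beta = norm.ppf(1.0 - beta)
    z_alpha = norm.ppf(1.0 - alpha)
    return float(((z_beta + c) / (z_beta + z_alpha)) ** 2)


def _thresholds(design: TwoPopDesign) -> tuple[float, float]:
    """(c_PWER, c_FWER) for one design point."""
    if design.scenario == "two_pop_independent":
        c_p = critical_value_independent(design.alpha, design.pi12)
        c_f = sidak_critical_value(design.alpha)
        return c_p, c_f
    structure = design.structure()
    if design.pi12 == 0.0:
        # disjoint populations: no common patient, PWER needs no adjustment
        model = two_pop_model(structure, design.scenario)
        c_p = float(norm.ppf(1.0 - design.alpha))
    else:
        model = two_pop_model(structure, design.scenario)
        c_p = pwer_core.critical_value(structure, model, design.alpha).c_star
    c_f = pwer_core.fwer_critical_value(model, design.alpha)
    return c_p, c_f


def inflation_curve(
    scenario: str,
    alpha: float = 0.025,
    beta: float = 0.2,
    grid=None,
) -> pd.DataFrame:
    """Critical values and inflation factors over a grid of overlap sizes.

    Returns columns ``pi12, c_pwer, c_fwer, q_pwer, q_fwer``.  The default
    grid is the 41-point lattice ``0, 0.025, ..., 1``.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 41)
    rows = []
    for pi12 in np.asarray(grid, dtype=float):
        design = TwoPopDesign(pi12=pi12, scenario=scenario, alpha=alpha, beta=beta)
        c_p, c_f = _thresholds(design)
        rows.append(
            {
                "pi12": pi12,
                "c_pwer": c_p,
                "c_fwer": c_f,
                "q_pwer": sample_size_inflation(c_p, alpha, beta),
                "q_fwer": sample_size_inflation(c_f, alpha, beta),
            }
        )
    return pd.DataFrame(rows)
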