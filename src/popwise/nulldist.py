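"""Joint null distributions of the test statistics and tail probabilities.

Under the least favourable (global null) configuration the vector of test
statistics is multivariate normal — or multivariate t when a pooled residual
variance is estimated — with unit marginals and a correlation matrix that is
determined by the design: the allocation rule, the stratum sample sizes and
whether treatments or controls are shared.  This module builds those models
for the named design scenarios and evaluates the multivariate tail
probabilities every error-rate computation reduces to.

Numerical notes
---------------
Bivariate normal rectangle probabilities use Owen's T function and are exact
to machine precision.  Dimensions three and up go through scipy's randomized
quasi-Monte-Carlo quadrature with a fixed internal seed, so repeated calls
return identical values ("deterministic to tolerance": absolute tolerance
about 1e-8 for normal models and 1e-6 for Student-t models at the default
point budgets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import owens_t
from scipy.stats import multivariate_normal, multivariate_t, norm
from scipy.stats import t as student_t

from .structure import PopulationStructure, parse_subset, format_subset

__all__ = [
    "JointNullModel",
    "bivariate_normal_cdf",
    "corr_two_pop_unequal_treatments",
    "corr_two_pop_equal_treatments",
    "corr_two_pop_from_counts",
    "corr_nested_single_treatment",
    "two_pop_model",
    "model_for_scenario",
    "umbrella_null_model",
    "joint_tail",
    "union_tail",
    "marginal_quantile",
    "SCENARIOS",
]

#: fixed quadrature seed — all QMC evaluations are reproducible run-to-run
_QUAD_SEED = 186283
#: default absolute tolerance / point budget for normal QMC (dims >= 3)
_NORMAL_ABSEPS = 1e-8
_NORMAL_MAXPTS = 20_000_000
#: default point budget for Student-t QMC (no abseps control in scipy)
_T_MAXPTS = 1_500_000

SCENARIOS = (
    "two_pop_independent",
    "two_pop_unequal",
    "two_pop_equal",
    "nested",
    "umbrella",
    "custom",
)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointNullModel:
    """Joint distribution of the test statistics under the global null.

    Parameters
    ----------
    correlation
        ``k x k`` correlation matrix (symmetric, unit diagonal, PSD).
    labels
        One entry per statistic: the tuple of population indices the
        hypothesis affects.  For population-level hypotheses ``H_i`` the
        label is ``(i,)``; for umbrella subset hypotheses ``H_S`` it is the
        subset ``S`` itself.
    family
        ``"normal"`` or ``"student_t"``.
    df
        Degrees of freedom (Student-t only).
    """

    correlation: np.ndarray
    labels: tuple[tuple[int, ...], ...]
    family: str = "normal"
    df: int | None = None
    quad_abseps: float = field(default=_NORMAL_ABSEPS, compare=False)
    quad_maxpts: int = field(default=0, compare=False)

    def __post_init__(self):
        R = np.atleast_2d(np.asarray(self.correlation, dtype=float))
        object.__setattr__(self, "correlation", R)
        object.__setattr__(self, "labels", tuple(tuple(l) for l in self.labels))
        k = R.shape[0]
        if R.shape != (k, k):
            raise ValueError("correlation must be square")
        if len(self.labels) != k:
            raise ValueError("one label per statistic required")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("correlation must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("correlation must be positive semi-definite")
        if self.family not in ("normal", "student_t"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "student_t":
            if self.df is None or self.df < 1:
                raise ValueError("student_t family needs df >= 1")
        if self.quad_maxpts == 0:
            default = _NORMAL_MAXPTS if self.family == "normal" else _T_MAXPTS
            object.__setattr__(self, "quad_maxpts", default)

    @property
    def k(self) -> int:
        return self.correlation.shape[0]

    def label_positions(self, stratum: tuple[int, ...]) -> list[int]:
        """Positions of the statistics whose hypothesis affects stratum ``J``.

        A hypothesis affects a stratum when its target population intersects
        it, i.e. when its label shares an index with ``J``.
        """
        J = set(stratum)
        return [j for j, lab in enumerate(self.labels) if J & set(lab)]


# ---------------------------------------------------------------------------
# bivariate normal CDF via Owen's T (exact, fast)
# ---------------------------------------------------------------------------

def _owen_term(x: float, num: float, den: float) -> float:
    # T(x, num/den) with the x -> 0 limit arctan(a)/(2 pi)
    if den == 0.0:
        if num == 0.0:
            return 0.0
        return float(np.arctan(np.inf if num > 0 else -np.inf)) / (2 * np.pi)
    return float(owens_t(x, num / den))


def bivariate_normal_cdf(h: float, k: float, rho: float) -> float:
    """``P(X <= h, Y <= k)`` for standard bivariate normal with correlation rho."""
    if np.isnan(h) or np.isnan(k):
        raise ValueError("NaN bound in bivariate normal CDF")
    if h == -np.inf or k == -np.inf:
        return 0.0
    if h == np.inf:
        return float(norm.cdf(k))
    if k == np.inf:
        return float(norm.cdf(h))
    if rho >= 1.0 - 1e-14:
        return float(norm.cdf(min(h, k)))
    if rho <= -1.0 + 1e-14:
        return float(max(0.0, norm.cdf(h) + norm.cdf(k) - 1.0))
    if h == 0.0 and k == 0.0:
        return 0.25 + float(np.arcsin(rho)) / (2 * np.pi)
    s = np.sqrt(1.0 - rho * rho)
    th = _owen_term(h, k - rho * h, h * s)
    tk = _owen_term(k, h - rho * k, k * s)
    beta = 0.5 if (h * k < 0 or (h * k == 0 and h + k < 0)) else 0.0
    val = 0.5 * (norm.cdf(h) + norm.cdf(k)) - th - tk - beta
    return float(min(1.0, max(0.0, val)))


# ---------------------------------------------------------------------------
# generic multivariate CDF dispatch
# ---------------------------------------------------------------------------

#: ridge added to rank-deficient correlation sub-matrices.  Subset statistics
#: can be exact linear combinations of each other (an umbrella statistic for a
#: union is a weighted sum of the stratum statistics), making sub-matrices
#: singular; the ridge perturbs rectangle probabilities by O(1e-7), well below
#: the quadrature tolerance.
_PD_RIDGE = 1e-6


def _ensure_positive_definite(R: np.ndarray) -> np.ndarray:
    if np.linalg.eigvalsh(R).min() < 1e-8:
        k = R.shape[0]
        R = (R + _PD_RIDGE * np.eye(k)) / (1.0 + _PD_RIDGE)
    return R


def _mv_cdf(upper: np.ndarray, model: JointNullModel, positions: list[int]) -> float:
    """CDF of the sub-vector at ``upper`` (handles +/-inf coordinates)."""
    upper = np.asarray(upper, dtype=float)
    if np.any(upper == -np.inf):
        return 0.0
    finite = upper < np.inf
    pos = [p for p, f in zip(positions, finite) if f]
    upper = upper[finite]
    if len(pos) == 0:
        return 1.0
    R = model.correlation[np.ix_(pos, pos)]
    if model.family == "normal":
        if len(pos) == 1:
            return float(norm.cdf(upper[0]))
        if len(pos) == 2:
            return bivariate_normal_cdf(upper[0], upper[1], R[0, 1])
        R = _ensure_positive_definite(R)
        val = multivariate_normal.cdf(
            upper,
            mean=np.zeros(len(pos)),
            cov=R,
            maxpts=model.quad_maxpts,
            abseps=model.quad_abseps,
            releps=0.0,
            rng=np.random.default_rng(_QUAD_SEED),
        )
        return float(min(1.0, max(0.0, val)))
    # Student-t
    if len(pos) == 1:
        return float(student_t.cdf(upper[0], df=model.df))
    R = _ensure_positive_definite(R)
    val = multivariate_t.cdf(
        upper,
        loc=np.zeros(len(pos)),
        shape=R,
        df=model.df,
        maxpts=model.quad_maxpts,
        random_state=np.random.default_rng(_QUAD_SEED),
    )
    return float(min(1.0, max(0.0, val)))


def union_tail(model: JointNullModel, positions, thresholds) -> float:
    """``P(Z_j >= c_j for at least one j)`` over the given statistic positions."""
    positions = list(positions)
    if not positions:
        raise ValueError("empty statistic subset")
    thresholds = np.broadcast_to(
        np.asarray(thresholds, dtype=float), (len(positions),)
    )
    return 1.0 - _mv_cdf(thresholds, model, positions)


def joint_tail(model: JointNullModel, subset, c: float) -> float:
    """``P(max_{j in subset} Z_j >= c)`` — the strata-wise rejection probability."""
    return union_tail(model, subset, c)


def marginal_quantile(model: JointNullModel, p: float) -> float:
    """Upper ``p``-level marginal quantile (same for every statistic)."""
    if model.family == "normal":
        return float(norm.ppf(p))
    return float(student_t.ppf(p, df=model.df))


# ---------------------------------------------------------------------------
# closed-form correlations for the named two-population scenarios
# ---------------------------------------------------------------------------

def corr_two_pop_unequal_treatments(pi12: float) -> float:
    """Correlation of the two z-statistics with different treatments.

    Two overlapping populations of equal size share one control.  The
    complements randomize 1:1 to treatment or control, the intersection
    1:1:1 to the two treatments and control; the population mean in each arm
    is estimated by the prevalence-weighted mean of the stratum means.  The
    shared intersection control induces ``rho = (3/2) pi12 / (1 + 2 pi12)``.
    """
    if not 0.0 <= pi12 <= 1.0:
        raise ValueError(f"pi12 must be in [0, 1], got {pi12}")
    return 1.5 * pi12 / (1.0 + 2.0 * pi12)


def corr_two_pop_equal_treatments(pi12: float) -> float:
    """Correlation with a single treatment in both equally sized populations.

    1:1 randomization within every stratum; each population statistic pools
    its complement and the intersection, so both the treatment and control
    samples overlap: ``rho = 2 pi12 / (1 + pi12)``.
    """
    if not 0.0 <= pi12 <= 1.0:
        raise ValueError(f"pi12 must be in [0, 1], got {pi12}")
    return 2.0 * pi12 / (1.0 + pi12)


def corr_two_pop_from_counts(scenario: str, n1: float, n2: float, n12: float) -> float:
    """Conditional correlation of (Z1, Z2) given realized stratum counts.

    Generalizes the closed forms above to arbitrary (possibly unequal)
    counts ``n_{1}, n_{2}, n_{1,2}``; arm sizes are treated as the exact
    fractional splits of the allocation rule, which is what conditioning on
    the stratum totals requires asymptotically.  Returns 0 when the
    intersection is empty.  Raises when a population has no patients at all
    (its statistic is undefined — callers drop the hypothesis).
    """
    if min(n1, n2, n12) < 0:
        raise ValueError("negative counts")
    if n1 + n12 == 0 or n2 + n12 == 0:
        raise ValueError("a population has no patients; statistic undefined")
    if n12 == 0:
        return 0.0
    if scenario in ("two_pop_unequal", "unequal_treatments"):
        rho = np.empty(2)
        var = np.empty(2)
        b = np.empty(2)
        for i, nc in enumerate((n1, n2)):
            a_i = nc / (nc + n12)
            b[i] = n12 / (nc + n12)
            v = 6.0 * b[i] ** 2 / n12
            if nc > 0:
                v += 4.0 * a_i**2 / nc
            var[i] = v
        cov = 3.0 * b[0] * b[1] / n12
        return float(cov / np.sqrt(var[0] * var[1]))
    if scenario in ("two_pop_equal", "equal_treatments"):
        return float(n12 / np.sqrt((n1 + n12) * (n2 + n12)))
    if scenario == "two_pop_independent":
        return 0.0
    raise ValueError(f"unknown two-population scenario {scenario!r}")


def corr_nested_single_treatment(structure: PopulationStructure) -> np.ndarray:
    """Correlation matrix for a chain of nested populations, one treatment.

    With 1:1 randomization in every stratum and sample sizes proportional to
    the prevalences, the pooled z-statistic of the inner population is a
    sub-sample mean difference of the outer one, giving
    ``Corr(Z_i, Z_j) = sqrt(pi_j / pi_i)`` for ``j > i`` where ``pi_i`` is
    the total prevalence of population ``P_i``.
    """
    if not structure.is_nested():
        raise ValueError("structure is not a nested chain P_1 > P_2 > ... > P_m")
    m = structure.m
    pi = np.array([structure.population_prevalence(i) for i in range(1, m + 1)])
    if np.any(pi <= 0):
        raise ValueError("nested chain has a zero-prevalence population")
    R = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            R[i, j] = R[j, i] = np.sqrt(pi[j] / pi[i])
    return R


# ---------------------------------------------------------------------------
# scenario -> model builders
# ---------------------------------------------------------------------------

def two_pop_model(structure: PopulationStructure, scenario: str) -> JointNullModel:
    """Bivariate normal null model for the two-population scenarios."""
    if structure.m != 2:
        raise ValueError("two-population scenario needs m = 2")
    pi12 = structure.prevalence((1, 2))
    p1, p2 = structure.prevalence((1,)), structure.prevalence((2,))
    if scenario == "two_pop_independent":
        rho = 0.0
    elif scenario in ("two_pop_unequal", "two_pop_equal"):
        if abs(p1 - p2) > 1e-9:
            raise ValueError(
                "closed-form correlations assume equal complement prevalences; "
                "use corr_two_pop_from_counts for the asymmetric case"
            )
        rho = (
            corr_two_pop_unequal_treatments(pi12)
            if scenario == "two_pop_unequal"
            else corr_two_pop_equal_treatments(pi12)
        )
    else:
        raise ValueError(f"unknown two-population scenario {scenario!r}")
    R = np.array([[1.0, rho], [rho, 1.0]])
    return JointNullModel(correlation=R, labels=((1,), (2,)))


def model_for_scenario(
    structure: PopulationStructure,
    scenario: str,
    correlation: np.ndarray | None = None,
    family: str = "normal",
    df: int | None = None,
) -> JointNullModel:
    """Build the joint null model implied by a named design scenario."""
    if scenario in ("two_pop_independent", "two_pop_unequal", "two_pop_equal"):
        return two_pop_model(structure, scenario)
    if scenario == "nested":
        R = corr_nested_single_treatment(structure)
        labels = tuple((i,) for i in range(1, structure.m + 1))
        return JointNullModel(correlation=R, labels=labels)
    if scenario == "custom":
        if correlation is None:
            raise ValueError("custom scenario needs a correlation matrix")
        labels = tuple((i,) for i in range(1, structure.m + 1))
        return JointNullModel(
            correlation=correlation, labels=labels, family=family, df=df
        )
    raise ValueError(
        f"unknown scenario {scenario!r}; choose from {SCENARIOS}"
    )


# ---------------------------------------------------------------------------
# umbrella-trial model: joint t of all subset statistics
# ---------------------------------------------------------------------------

def enumerate_subsets(l: int) -> list[tuple[int, ...]]:
    """All non-empty subsets of {1..l}, by cardinality then lexicographic."""
    from itertools import combinations

    out: list[tuple[int, ...]] = []
    for size in range(1, l + 1):
        out.extend(combinations(range(1, l + 1), size))
    return out


def umbrella_null_model(design) -> JointNullModel:
    """Joint Student-t null model of all ``2^l - 1`` subset statistics.

    ``design`` carries ``l`` disjoint strata with prevalences ``pi_i``, a
    total sample size ``N`` and a 1:1 treatment:control split per stratum.
    The statistic for subset ``S`` tests the prevalence-weighted average
    effect ``theta_S = sum_{i in S} (pi_i / pi_S) theta_i``; with a pooled
    residual variance the vector of statistics is multivariate t with
    ``N - 2l`` degrees of freedom and a correlation matrix determined by the
    contrast vectors and the per-stratum arm sizes.
    """
    l, N = design.l, design.N
    if l > 12:
        raise ValueError("l > 12 would enumerate more than 2^12 subsets")
    if N <= 2 * l:
        raise ValueError(f"N = {N} must exceed 2l = {2 * l}")
    pi = np.asarray(design.prevalences, dtype=float)
    from .trial_simulator import largest_remainder

    n = largest_remainder(N, pi)
    n_treat = n // 2
    n_ctrl = n - n_treat
    if np.any(n_treat < 1) or np.any(n_ctrl < 1):
        raise ValueError("every stratum needs at least one subject per arm")
    var_i = 1.0 / n_treat + 1.0 / n_ctrl  # Var(theta_hat_i) / sigma^2
    subsets = enumerate_subsets(l)
    A = np.zeros((len(subsets), l))  # contrast weights pi_i / pi_S
    for r, S in enumerate(subsets):
        idx = [i - 1 for i in S]
        A[r, idx] = pi[idx] / pi[idx].sum()
    cov = A @ np.diag(var_i) @ A.T
    d = np.sqrt(np.diag(cov))
    R = cov / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return JointNullModel(
        correlation=R,
        labels=tuple(subsets),
        family="student_t",
        df=int(N - 2 * l),
    )


# ---------------------------------------------------------------------------
# correlation matrix CSV round-trip
# ---------------------------------------------------------------------------

def write_correlation_csv(model: JointNullModel, path) -> None:
    import pandas as pd

    names = [format_subset(lab) for lab in model.labels]
    pd.DataFrame(model.correlation, index=names, columns=names).to_csv(path)


def read_correlation_csv(path, family: str = "normal", df: int | None = None) -> JointNullModel:
    import pandas as pd

    frame = pd.read_csv(path, index_col=0)
    labels = tuple(parse_subset(str(c)) for c in frame.columns)
    return JointNullModel(
        correlation=frame.to_numpy(dtype=float), labels=labels, family=family, df=df
    )
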