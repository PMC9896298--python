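"""Seeded generator of subject-level trial data.

This is the synthetic backbone of every simulation in the package: subjects
carry a stratum label, a treatment arm and a normal outcome
``Y = mu_stratum + theta_arm * 1[treated] + eps`` with i.i.d. ``N(0, sigma^2)``
errors.  Stratum membership is deterministic by default (counts are the
largest-remainder rounding of ``N * pi_J``, matching designs where the sample
perfectly reflects the prevalences); multinomial membership is available for
studies of estimated prevalences.

Allocation rules by scenario
----------------------------
``two_pop_unequal``
    1:1 to ``T_i``/``C`` in the complements, 1:1:1 to ``T1``/``T2``/``C`` in
    the intersection (shared control).
``two_pop_equal`` / ``nested``
    a single treatment ``T``: 1:1 to ``T``/``C`` within every stratum.
``umbrella``
    disjoint strata, stratum ``i`` randomizes 1:1 to ``T_i``/``C``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .structure import PopulationStructure, format_subset

__all__ = [
    "largest_remainder",
    "simulate_trial",
    "two_pop_statistics",
    "simulate_two_pop_statistics",
]


def largest_remainder(N: int, probs) -> np.ndarray:
    """Round ``N * probs`` to integers summing to ``N`` (largest remainder).

    Ties in the fractional parts are broken toward the earlier entry, so the
    result is deterministic.
    """
    probs = np.asarray(probs, dtype=float)
    raw = N * probs
    base = np.floor(raw).astype(int)
    short = N - base.sum()
    if short > 0:
        order = np.lexsort((np.arange(len(probs)), -(raw - base)))
        base[order[:short]] += 1
    return base


def _arm_plan(structure: PopulationStructure, scenario: str):
    """Per-stratum list of (arm label, share) pairs for the allocation rule."""
    plan = {}
    for J in structure.subsets:
        if scenario in ("two_pop_equal", "nested", "single_treatment"):
            plan[J] = [("T", 0.5), ("C", 0.5)]
        elif scenario == "two_pop_unequal":
            if len(J) == 1:
                plan[J] = [(f"T{J[0]}", 0.5), ("C", 0.5)]
            else:
                plan[J] = [("T1", 1 / 3), ("T2", 1 / 3), ("C", 1 / 3)]
        elif scenario == "umbrella":
            if len(J) != 1:
                raise ValueError("umbrella strata must be disjoint singletons")
            plan[J] = [(f"T{J[0]}", 0.5), ("C", 0.5)]
        else:
            raise ValueError(f"no allocation rule for scenario {scenario!r}")
    return plan


def _split_arms(n: int, shares) -> list[int]:
    """Split ``n`` subjects over arms by largest remainder.

    Every arm ends within one subject of its exact share; leftover units go
    to the control arm first (treatments round down when possible).
    """
    base = [int(np.floor(n * s)) for _, s in shares]
    rem = n - sum(base)
    fracs = [n * s - b for (_, s), b in zip(shares, base)]
    prio = sorted(
        range(len(shares)),
        key=lambda i: (-fracs[i], shares[i][0] != "C", i),
    )
    for i in prio[:rem]:
        base[i] += 1
    return base


def _assignment(
    structure: PopulationStructure,
    scenario: str,
    N: int,
    rng: np.random.Generator | None,
    random_membership: bool,
):
    """Stratum and arm label per subject (deterministic given counts)."""
    subsets = structure.subsets
    probs = [structure.strata[J] for J in subsets]
    if random_membership:
        if rng is None:
            raise ValueError("random membership needs an RNG")
        counts = rng.multinomial(N, probs)
    else:
        counts = largest_remainder(N, probs)
    plan = _arm_plan(structure, scenario)
    strata_lab, arm_lab = [], []
    for J, nJ in zip(subsets, counts):
        arm_counts = _split_arms(int(nJ), plan[J])
        for (arm, _), na in zip(plan[J], arm_counts):
            strata_lab.extend([J] * na)
            arm_lab.extend([arm] * na)
    return strata_lab, arm_lab


def _mean_vector(strata_lab, arm_lab, effects, intercepts) -> np.ndarray:
    effects = dict(effects or {})
    intercepts = dict(intercepts or {})
    mu = np.zeros(len(strata_lab))
    for s, (J, arm) in enumerate(zip(strata_lab, arm_lab)):
        mu[s] = intercepts.get(J, 0.0) + (effects.get(arm, 0.0) if arm != "C" else 0.0)
    return mu


def simulate_trial(
    structure: PopulationStructure,
    scenario: str,
    effects: dict | None = None,
    sigma: float = 1.0,
    N: int = 100,
    seed: int = 0,
    random_membership: bool = False,
    intercepts: dict | None = None,
) -> pd.DataFrame:
    """One simulated trial as a subject-level table.

    ``effects`` maps treatment labels (``"T"``, ``"T1"``, ...) to mean
    treatment differences; ``intercepts`` maps stratum keys to baseline
    means.  Same seed, same arguments: byte-identical output.
    """
    rng = np.random.default_rng(seed)
    strata_lab, arm_lab = _assignment(structure, scenario, N, rng, random_membership)
    if len(strata_lab) < 2:
        raise ValueError(f"infeasible N = {N} for this structure")
    mu = _mean_vector(strata_lab, arm_lab, effects, intercepts)
    outcome = mu + sigma * rng.standard_normal(len(mu))
    return pd.DataFrame(
        {
            "subject_id": np.arange(1, len(mu) + 1),
            "stratum": [format_subset(J) for J in strata_lab],
            "arm": arm_lab,
            "outcome": outcome,
        }
    )


# ---------------------------------------------------------------------------
# two-population z-statistics (known sigma) and their vectorized simulation
# ---------------------------------------------------------------------------

def _two_pop_group_index(structure, scenario, N):
    strata_lab, arm_lab = _assignment(structure, scenario, N, None, False)
    keys = sorted(set(zip(strata_lab, arm_lab)))
    index = {k: i for i, k in enumerate(keys)}
    M = np.zeros((len(strata_lab), len(keys)))
    for s, k in enumerate(zip(strata_lab, arm_lab)):
        M[s, index[k]] = 1.0
    counts = M.sum(axis=0)
    M /= counts
    mu = _mean_vector(strata_lab, arm_lab, None, None)
    return M, index, counts, len(strata_lab)


def _two_pop_z(group_means, index, counts, scenario, sigma):
    """Map group means to (Z1, Z2) for the single-study two-population designs.

    Variances use the realized integer arm counts, so the statistics have
    exactly unit variance for any feasible allocation.
    """
    gm = np.atleast_2d(group_means)
    n = lambda J, arm: counts[index[(J, arm)]]
    Z = np.empty((gm.shape[0], 2))
    if scenario == "two_pop_unequal":
        n12 = n((1, 2), "T1") + n((1, 2), "T2") + n((1, 2), "C")
        for i in (1, 2):
            ni = n((i,), f"T{i}") + n((i,), "C")
            a, b = ni / (ni + n12), n12 / (ni + n12)
            xt = a * gm[:, index[((i,), f"T{i}")]] + b * gm[:, index[((1, 2), f"T{i}")]]
            xc = a * gm[:, index[((i,), "C")]] + b * gm[:, index[((1, 2), "C")]]
            var = a**2 * (1 / n((i,), f"T{i}") + 1 / n((i,), "C")) + b**2 * (
                1 / n((1, 2), f"T{i}") + 1 / n((1, 2), "C")
            )
            Z[:, i - 1] = (xt - xc) / (sigma * np.sqrt(var))
    elif scenario == "two_pop_equal":
        for i in (1, 2):
            nt = n((i,), "T") + n((1, 2), "T")
            nc = n((i,), "C") + n((1, 2), "C")
            xt = (n((i,), "T") * gm[:, index[((i,), "T")]]
                  + n((1, 2), "T") * gm[:, index[((1, 2), "T")]]) / nt
            xc = (n((i,), "C") * gm[:, index[((i,), "C")]]
                  + n((1, 2), "C") * gm[:, index[((1, 2), "C")]]) / nc
            Z[:, i - 1] = (xt - xc) / (sigma * np.sqrt(1 / nt + 1 / nc))
    else:
        raise ValueError(f"no z-statistic mapping for scenario {scenario!r}")
    return Z


def two_pop_statistics(
    trial: pd.DataFrame, structure: PopulationStructure, scenario: str, sigma: float = 1.0
) -> np.ndarray:
    """(Z1, Z2) from one subject-level trial table (known-variance z-tests)."""
    M, index, counts, N = _two_pop_group_index(structure, scenario, len(trial))
    gm = trial["outcome"].to_numpy() @ M
    return _two_pop_z(gm, index, counts, scenario, sigma)[0]


def simulate_two_pop_statistics(
    structure: PopulationStructure,
    scenario: str,
    n_reps: int,
    N: int,
    seed: int,
    sigma: float = 1.0,
    chunk: int = 50_000,
) -> np.ndarray:
    """Vectorized replicates of (Z1, Z2) under the global null.

    Subject-level outcomes are drawn for every replicate and reduced to group
    means; this is the Monte-Carlo oracle for the closed-form correlations.
    """
    rng = np.random.default_rng(seed)
    M, index, counts, n_subj = _two_pop_group_index(structure, scenario, N)
    out = np.empty((n_reps, 2))
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        outcomes = sigma * rng.standard_normal((b, n_subj))
        gm = outcomes @ M
        out[done : done + b] = _two_pop_z(gm, index, counts, scenario, sigma)
        done += b
    return out
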