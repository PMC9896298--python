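"""Overlapping-population geometry: strata, prevalences and their estimation.

An overall patient population is the union of ``m`` possibly overlapping
target populations ``P_1, ..., P_m``.  The populations partition the overall
population into disjoint *strata* ``P_J`` indexed by non-empty subsets
``J ⊆ {1, ..., m}``: a patient is in ``P_J`` when they belong to exactly the
populations listed in ``J``.  Each stratum carries a relative prevalence
``π_J`` and the prevalences sum to one.  All error-rate computations in this
package are weighted averages over these strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationStructure",
    "StratumCounts",
    "build_structure",
    "mle_prevalences",
    "parse_subset",
    "format_subset",
    "read_prevalence_csv",
    "write_prevalence_csv",
    "read_counts_csv",
]

#: tolerance on user-supplied prevalence sums (hand-entered tables)
INPUT_SUM_TOL = 1e-6
#: internal tolerance after normalization
INTERNAL_SUM_TOL = 1e-9


class StructureError(ValueError):
    """Invalid population structure (prevalences, subsets, counts)."""


def parse_subset(key) -> tuple[int, ...]:
    """Canonicalize a stratum key to a sorted tuple of 1-based indices.

    Accepts tuples/lists/sets of ints, a single int, or the string dialect
    ``"1+2"`` used in CSV files.
    """
    if isinstance(key, str):
        parts = [p for p in key.replace(" ", "").split("+") if p]
        if not parts:
            raise StructureError(f"empty subset key {key!r}")
        try:
            idx = tuple(sorted(int(p) for p in parts))
        except ValueError as exc:
            raise StructureError(f"cannot parse subset key {key!r}") from exc
    elif isinstance(key, (int, np.integer)):
        idx = (int(key),)
    else:
        idx = tuple(sorted(int(i) for i in key))
    if len(idx) == 0:
        raise StructureError("empty subset key")
    if len(set(idx)) != len(idx):
        raise StructureError(f"repeated index in subset {key!r}")
    if idx[0] < 1:
        raise StructureError(f"population indices are 1-based, got {key!r}")
    return idx


def format_subset(subset: tuple[int, ...]) -> str:
    """Inverse of :func:`parse_subset`: ``(1, 2) -> "1+2"``."""
    return "+".join(str(i) for i in subset)


@dataclass(frozen=True)
class PopulationStructure:
    """Disjoint strata of overlapping populations with relative prevalences.

    Parameters
    ----------
    m
        Number of target populations ``P_1, ..., P_m``.
    strata
        Mapping from canonical index subset ``J`` (sorted tuple of 1-based
        indices) to its relative prevalence ``π_J``.  Prevalences are
        non-negative and sum to 1.
    min_prevalence
        Optional floor ``π_min`` that was applied during construction
        (recorded for provenance; the stored prevalences already reflect it).
    """

    m: int
    strata: dict[tuple[int, ...], float]
    min_prevalence: float | None = field(default=None)

    def __post_init__(self):
        if self.m < 1:
            raise StructureError(f"m must be >= 1, got {self.m}")
        if not self.strata:
            raise StructureError("structure needs at least one stratum")
        for J, pi in self.strata.items():
            if not J or any(i < 1 or i > self.m for i in J):
                raise StructureError(f"subset {J} not within {{1..{self.m}}}")
            if pi < 0:
                raise StructureError(f"negative prevalence {pi} for stratum {J}")
        total = float(sum(self.strata.values()))
        if abs(total - 1.0) > INTERNAL_SUM_TOL:
            raise StructureError(f"prevalences sum to {total}, not 1")

    # -- derived quantities -------------------------------------------------
    @property
    def subsets(self) -> list[tuple[int, ...]]:
        """Stratum keys ordered by cardinality, then lexicographically."""
        return sorted(self.strata, key=lambda J: (len(J), J))

    def prevalence(self, J) -> float:
        return self.strata.get(parse_subset(J), 0.0)

    def population_prevalence(self, i: int) -> float:
        """Total share ``π_i = Σ_{J ∋ i} π_J`` of population ``P_i``."""
        return float(sum(pi for J, pi in self.strata.items() if i in J))

    def is_nested(self) -> bool:
        """True when the strata form a chain ``{1} ⊂ {1,2} ⊂ ... ⊂ {1..m}``."""
        expected = {tuple(range(1, k + 1)) for k in range(1, self.m + 1)}
        return set(self.strata) <= expected

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": [format_subset(J) for J in self.subsets],
                "prevalence": [self.strata[J] for J in self.subsets],
            }
        )


@dataclass(frozen=True)
class StratumCounts:
    """Observed multinomial stratum counts ``n_J`` with total ``N``."""

    counts: dict[tuple[int, ...], int]

    def __post_init__(self):
        for J, n in self.counts.items():
            if n < 0:
                raise StructureError(f"negative count {n} for stratum {J}")
        if self.total < 1:
            raise StructureError("all stratum counts are zero")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


def _floor_and_renormalize(
    strata: dict[tuple[int, ...], float], pi_min: float
) -> dict[tuple[int, ...], float]:
    """Raise every prevalence to at least ``pi_min``.

    The mass needed to lift the floored strata is taken from the unfloored
    ones proportionally to their current prevalence, so the vector still sums
    to one.
    """
    if pi_min < 0 or pi_min * len(strata) > 1.0:
        raise StructureError(
            f"min_prevalence {pi_min} infeasible for {len(strata)} strata"
        )
    floored = {J for J, p in strata.items() if p < pi_min}
    if not floored:
        return dict(strata)
    lift = sum(pi_min - strata[J] for J in floored)
    free = sum(strata[J] for J in strata if J not in floored)
    scale = (free - lift) / free
    out = {}
    for J, p in strata.items():
        out[J] = pi_min if J in floored else p * scale
    # a proportional cut may push a previously-unfloored stratum below the
    # floor; iterate (terminates: the floored set only grows)
    if any(p < pi_min - 1e-15 for p in out.values()):
        return _floor_and_renormalize(out, pi_min)
    return out


def build_structure(
    prevalence_entries, min_prevalence: float | None = None
) -> PopulationStructure:
    """Validate and canonicalize a prevalence table into a structure.

    Parameters
    ----------
    prevalence_entries
        Iterable of ``(subset, prevalence)`` pairs or a mapping.  Subsets may
        be tuples, ints or strings like ``"1+2"``.  ``m`` is inferred as the
        largest index mentioned.
    min_prevalence
        Optional floor ``π_min``; every listed stratum is raised to at least
        this value and the vector renormalized (see
        :func:`_floor_and_renormalize`).

    Zero-prevalence strata without a floor are dropped with a logged warning:
    they contribute nothing to any population-wise error rate.
    """
    if isinstance(prevalence_entries, dict):
        items = list(prevalence_entries.items())
    else:
        items = list(prevalence_entries)
    if not items:
        raise StructureError("no prevalence entries given")
    strata: dict[tuple[int, ...], float] = {}
    for key, pi in items:
        J = parse_subset(key)
        if J in strata:
            raise StructureError(f"duplicate stratum {format_subset(J)}")
        pi = float(pi)
        if pi < 0:
            raise StructureError(f"negative prevalence {pi} for {format_subset(J)}")
        strata[J] = pi
    total = sum(strata.values())
    if abs(total - 1.0) > INPUT_SUM_TOL:
        raise StructureError(f"prevalences sum to {total:.8g}, expected 1")
    # exact renormalization of rounding slack within the input tolerance
    strata = {J: p / total for J, p in strata.items()}
    if min_prevalence is not None:
        strata = _floor_and_renormalize(strata, float(min_prevalence))
    else:
        zero = [J for J, p in strata.items() if p == 0.0]
        for J in zero:
            logger.warning(
                "dropping zero-prevalence stratum %s", format_subset(J)
            )
            del strata[J]
    m = max(i for J in strata for i in J)
    return PopulationStructure(m=m, strata=strata, min_prevalence=min_prevalence)


def mle_prevalences(
    counts: StratumCounts | dict, min_prevalence: float | None = None
) -> PopulationStructure:
    """Multinomial maximum-likelihood prevalences ``π̂_J = n_J / N``.

    With ``min_prevalence`` the estimates are floored and renormalized, which
    guards against strata that by chance recruited no patient.
    """
    if not isinstance(counts, StratumCounts):
        counts = StratumCounts({parse_subset(J): int(n) for J, n in dict(counts).items()})
    N = counts.total
    entries = [(J, n / N) for J, n in counts.counts.items()]
    return build_structure(entries, min_prevalence=min_prevalence)


# -- CSV interfaces ---------------------------------------------------------

def read_prevalence_csv(path, min_prevalence: float | None = None) -> PopulationStructure:
    """Read a ``stratum,prevalence`` table (stratum in the ``"1+2"`` dialect)."""
    df = pd.read_csv(path)
    if not {"stratum", "prevalence"} <= set(df.columns):
        raise StructureError(f"{path}: expected columns 'stratum,prevalence'")
    return build_structure(
        list(zip(df["stratum"].astype(str), df["prevalence"].astype(float))),
        min_prevalence=min_prevalence,
    )


def write_prevalence_csv(structure: PopulationStructure, path) -> None:
    structure.to_frame().to_csv(path, index=False)


def read_counts_csv(path) -> StratumCounts:
    """Read a ``stratum,count`` table."""
    df = pd.read_csv(path)
    if not {"stratum", "count"} <= set(df.columns):
        raise StructureError(f"{path}: expected columns 'stratum,count'")
    return StratumCounts(
        {parse_subset(s): int(n) for s, n in zip(df["stratum"].astype(str), df["count"])}
    )
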