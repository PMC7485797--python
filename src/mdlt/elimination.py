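"""Elimination-of-cause analysis and irreplaceable mortality.

Crude mortality D_i (the proportion of the original cohort observed dying of
cause i while all causes operate) understates what a cause would kill on its
own, because competing causes remove individuals first.  Under independence
of causes and proportionality of risks, the net probability q_i (mortality
from cause i in the absence of the others) solves the two-cause system

    q_1 / q_2 = D_1 / D_2            (proportionality)
    (1 - q_1)(1 - q_2) = 1 - D       (joint survival, D = D_1 + D_2)

which reduces to the quadratic  D_1 q_2^2 - (D_1 + D_2) q_2
+ D_2 (D_1 + D_2) = 0; the smaller root is the probability (the larger root
exceeds 1 whenever some individuals survive).  With more than two causes,
each cause is solved against the pooled remainder (focal-versus-rest).

Irreplaceable mortality of a focal cause is the part of total mortality the
other causes would not replace if the focal cause were removed: total
mortality with all causes operating minus the joint net mortality
1 - prod(1 - q_j) of the remaining causes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .life_table import MultipleDecrementTable, cause_totals
from .records import CAUSES, MortalityCause

__all__ = [
    "CauseMortalityProfile",
    "EliminationResult",
    "solve_two_cause",
    "net_probabilities",
    "joint_mortality",
    "crude_combination",
    "irreplaceable",
    "analyze",
]

Mode = Literal["totals", "per_stage"]


class NoSurvivorsError(ValueError):
    """Total crude mortality reaches 1: net probabilities are undefined."""


@dataclass(frozen=True)
class CauseMortalityProfile:
    """Crude cohort mortality proportions per cause, in fixed cause order."""

    d: tuple[float, ...]
    causes: tuple[MortalityCause, ...] = tuple(CAUSES)

    def __post_init__(self) -> None:
        if len(self.d) != len(self.causes):
            raise ValueError("one crude proportion per cause required")
        if any(di < 0 for di in self.d):
            raise ValueError("crude mortality proportions must be non-negative")
        if sum(self.d) >= 1.0:
            raise NoSurvivorsError(
                "crude mortality sums to >= 1; no survivors, net probabilities undefined"
            )

    @property
    def total(self) -> float:
        return float(sum(self.d))

    @property
    def survival(self) -> float:
        return 1.0 - self.total

    @classmethod
    def from_table(cls, table: MultipleDecrementTable) -> "CauseMortalityProfile":
        return cls(d=tuple(float(v) for v in cause_totals(table)))


def solve_two_cause(d1: float, d2: float) -> tuple[float, float]:
    """Net probabilities (q1, q2) for two competing causes with crude
    proportions (d1, d2).

    The smaller quadratic root is taken for q2 (it lies in [0, 1); the larger
    exceeds 1 whenever d1 + d2 < 1) and q1 is recovered from joint survival.
    A cause with zero crude mortality is degenerate: the competitor's net
    equals its crude.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("crude proportions must be non-negative")
    total = d1 + d2
    if total >= 1.0:
        raise NoSurvivorsError("no survivors; net probabilities undefined")
    if d1 == 0.0:
        return 0.0, d2
    if d2 == 0.0:
        return d1, 0.0
    # D1 q2^2 - (D1+D2) q2 + D2 (D1+D2) = 0, smaller root
    a, b, c = d1, -total, d2 * total
    disc = b * b - 4.0 * a * c
    if disc < 0:  # numerically impossible for valid inputs; guard anyway
        disc = 0.0
    q2 = (-b - math.sqrt(disc)) / (2.0 * a)
    q1 = 1.0 - (1.0 - total) / (1.0 - q2)
    return q1, q2


def net_probabilities(profile: CauseMortalityProfile) -> np.ndarray:
    """Net probability of death per cause in the absence of all others,
    solving each cause against the pooled remainder."""
    d = np.asarray(profile.d, dtype=float)
    out = np.empty_like(d)
    for i in range(len(d)):
        rest = float(d.sum() - d[i])
        out[i] = solve_two_cause(float(d[i]), rest)[0]
    return out


def joint_mortality(q_subset: Iterable[float]) -> float:
    """Probability of dying from at least one of a set of independent causes
    with net probabilities ``q_subset``: 1 - prod(1 - q)."""
    survival = 1.0
    for q in q_subset:
        if not 0.0 <= q < 1.0:
            raise ValueError(f"net probability out of [0, 1): {q}")
        survival *= 1.0 - q
    return 1.0 - survival


def crude_combination(
    profile: CauseMortalityProfile, subset: Sequence[MortalityCause]
) -> int:
    """Combined crude mortality of a cause subset with all causes operating,
    as an integer percentage: round(100 * sum of the subset's D_i)."""
    if not subset:
        raise ValueError("subset of causes must be non-empty")
    idx = {c: i for i, c in enumerate(profile.causes)}
    total = sum(profile.d[idx[c]] for c in set(subset))
    # half-up integer percent (report convention), not banker's rounding
    return int(math.floor(100.0 * total + 0.5))


def _stage_profiles(table: MultipleDecrementTable) -> list[np.ndarray]:
    """Conditional within-stage cause probabilities cq_ix per decremented stage."""
    return [np.asarray(row.cq_ix, dtype=float) for row in table.rows[:-1]]


def _mortality_without(
    profile: CauseMortalityProfile,
    focal: MortalityCause,
    mode: Mode,
    table: MultipleDecrementTable | None,
) -> float:
    idx = {c: i for i, c in enumerate(profile.causes)}
    f = idx[focal]
    if mode == "totals":
        q = net_probabilities(profile)
        remaining = [q[i] for i in range(len(q)) if i != f]
        return joint_mortality(remaining)
    if table is None:
        raise ValueError("per_stage elimination requires the life table")
    # eliminate the focal cause within each stage's conditional probabilities,
    # then recombine survival across stages
    survival = 1.0
    for cq in _stage_profiles(table):
        if cq.sum() >= 1.0:
            raise NoSurvivorsError(
                "a stage kills every entrant; per-stage elimination undefined"
            )
        stage_profile = CauseMortalityProfile(
            d=tuple(float(v) for v in cq), causes=profile.causes
        )
        q = net_probabilities(stage_profile)
        remaining = [q[i] for i in range(len(q)) if i != f]
        survival *= 1.0 - joint_mortality(remaining)
    return 1.0 - survival


def irreplaceable(
    profile: CauseMortalityProfile,
    focal: MortalityCause,
    mode: Mode = "totals",
    table: MultipleDecrementTable | None = None,
) -> float:
    """Irreplaceable mortality of the focal cause.

    Total mortality with all causes operating minus the joint mortality of
    the remaining causes' net probabilities, truncated to [0, D_focal]: the
    lower bound guards against floating-point negatives, the upper bound
    holds exactly under the simultaneous elimination solution but can be
    overshot by the focal-versus-pooled-rest approximation when total
    mortality is extreme and the focal cause small, and a cause cannot be
    credited with more deaths than it produced.  In ``per_stage`` mode the
    elimination is done within each stage's conditional probabilities and
    survival is recombined across stages before the subtraction.
    """
    idx = {c: i for i, c in enumerate(profile.causes)}
    d_focal = profile.d[idx[focal]]
    if d_focal == 0.0:
        return 0.0
    without = _mortality_without(profile, focal, mode, table)
    return min(max(profile.total - without, 0.0), d_focal)


@dataclass(frozen=True)
class EliminationResult:
    """Net, joint and irreplaceable mortality for one stratum."""

    causes: tuple[MortalityCause, ...]
    d: tuple[float, ...]
    q: tuple[float, ...]
    irreplaceable: tuple[float, ...]
    subset_mortality: dict[frozenset[MortalityCause], float] = field(default_factory=dict)
    mode: Mode = "totals"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cause": [c.name for c in self.causes],
                "D_i": self.d,
                "q_i": self.q,
                "irreplaceable_i": self.irreplaceable,
                "mode": self.mode,
            }
        )


def analyze(
    source: MultipleDecrementTable | CauseMortalityProfile,
    mode: Mode = "totals",
    subsets: Iterable[Iterable[MortalityCause]] = (),
) -> EliminationResult:
    """Full elimination analysis: net probabilities, irreplaceable mortality
    per cause, and joint net mortality for any requested cause subsets."""
    if isinstance(source, MultipleDecrementTable):
        table: MultipleDecrementTable | None = source
        profile = CauseMortalityProfile.from_table(source)
    else:
        table = None
        profile = source
        if mode == "per_stage":
            raise ValueError("per_stage elimination requires a life table, not totals")
    q = net_probabilities(profile)
    irr = tuple(
        irreplaceable(profile, c, mode=mode, table=table) for c in profile.causes
    )
    idx = {c: i for i, c in enumerate(profile.causes)}
    subset_mortality = {
        frozenset(s): joint_mortality(q[idx[c]] for c in frozenset(s))
        for s in (frozenset(s) for s in subsets)
    }
    return EliminationResult(
        causes=profile.causes,
        d=tuple(profile.d),
        q=tuple(float(v) for v in q),
        irreplaceable=irr,
        subset_mortality=subset_mortality,
        mode=mode,
    )
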