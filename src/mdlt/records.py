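"""Dissection-record ingestion, cause classification, and stage aggregation.

The observational unit is one dissected barley stem (summer samples, sampling
weeks 1-9) or one overwintered stub (collected before or after the adult
flight period).  Each record carries the live occupants found at dissection
(eggs, larvae) and one evidence-code set per dead occupant.  Evidence codes
map deterministically onto the five mortality causes; sampling time maps
occupants onto developmental stages; :func:`aggregate` turns a record stream
into stage-by-cause count tables ready for life-table construction.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "EvidenceCode",
    "MortalityCause",
    "Stage",
    "SampleKind",
    "StubPhase",
    "DissectionRecord",
    "StageCauseCounts",
    "RecordValidationError",
    "SchemaError",
    "POOLED",
    "classify_cause",
    "assign_stage",
    "death_stage",
    "aggregate",
    "read_records",
    "write_records",
]

#: Stratum label used when all site-years, cultivars and plots are summed
#: before table construction.
POOLED = "POOLED"


class RecordValidationError(ValueError):
    """A dissection record violates a structural invariant."""


class SchemaError(ValueError):
    """A records file is missing mandatory columns."""


class SampleKind(str, enum.Enum):
    STEM = "stem"
    STUB = "stub"


class StubPhase(str, enum.Enum):
    PRE_FLIGHT = "pre_flight"
    POST_FLIGHT = "post_flight"


class MortalityCause(enum.IntEnum):
    """The five mutually exclusive causes, in fixed column order."""

    PARASITISM = 1
    PLANT_DEFENSE = 2
    CANNIBALISM = 3
    UNKNOWN = 4
    PATHOGENS = 5


CAUSES: tuple[MortalityCause, ...] = tuple(MortalityCause)


class Stage(enum.IntEnum):
    """Developmental stages observable inside a stem, in life-cycle order.

    LARVA_I covers the pre-parasitism larval period (sampling weeks 2-4),
    LARVA_III the parasitism-vulnerable period (weeks 5-9), LARVA_IV the
    overwintered pre-flight larva and LARVA_V the post-flight larva.  The
    ordinal gap in the labels is deliberate: the field protocol never
    distinguishes an intermediate instar, so no stage is invented for it.
    """

    EGG = 0
    LARVA_I = 1
    LARVA_III = 2
    LARVA_IV = 3
    LARVA_V = 4
    ADULT = 5


STAGES: tuple[Stage, ...] = tuple(Stage)


class EvidenceCode(str, enum.Enum):
    MULTIPLE_EGGS = "MULTIPLE_EGGS"
    LARVA_PLUS_EGG = "LARVA_PLUS_EGG"
    MULTIPLE_LARVAE = "MULTIPLE_LARVAE"
    DEAD_NEONATE = "DEAD_NEONATE"
    FEEDING_SCAR_ONLY = "FEEDING_SCAR_ONLY"
    TINY_FRASS_FRAGMENT = "TINY_FRASS_FRAGMENT"
    PARASITOID_LARVA = "PARASITOID_LARVA"
    PARASITOID_COCOON = "PARASITOID_COCOON"
    PARASITOID_EXIT_HOLE = "PARASITOID_EXIT_HOLE"
    PREDATOR_LARVA = "PREDATOR_LARVA"
    WHITE_PINK_HYPHAE = "WHITE_PINK_HYPHAE"
    PINK_CADAVER = "PINK_CADAVER"
    DEAD_MULTI_INTERNODE = "DEAD_MULTI_INTERNODE"


#: Every code maps to exactly one cause.  Parasitoid and predator evidence is
#: pooled under parasitism, as is conventional when predation is negligible.
_CODE_TO_CAUSE: dict[EvidenceCode, MortalityCause] = {
    EvidenceCode.PARASITOID_LARVA: MortalityCause.PARASITISM,
    EvidenceCode.PARASITOID_COCOON: MortalityCause.PARASITISM,
    EvidenceCode.PARASITOID_EXIT_HOLE: MortalityCause.PARASITISM,
    EvidenceCode.PREDATOR_LARVA: MortalityCause.PARASITISM,
    EvidenceCode.WHITE_PINK_HYPHAE: MortalityCause.PATHOGENS,
    EvidenceCode.PINK_CADAVER: MortalityCause.PATHOGENS,
    EvidenceCode.MULTIPLE_EGGS: MortalityCause.CANNIBALISM,
    EvidenceCode.LARVA_PLUS_EGG: MortalityCause.CANNIBALISM,
    EvidenceCode.MULTIPLE_LARVAE: MortalityCause.CANNIBALISM,
    EvidenceCode.DEAD_NEONATE: MortalityCause.PLANT_DEFENSE,
    EvidenceCode.FEEDING_SCAR_ONLY: MortalityCause.PLANT_DEFENSE,
    EvidenceCode.TINY_FRASS_FRAGMENT: MortalityCause.PLANT_DEFENSE,
    EvidenceCode.DEAD_MULTI_INTERNODE: MortalityCause.UNKNOWN,
}

#: Precedence when codes for several causes co-occur on one cadaver: specific
#: physical evidence (a cocoon, hyphae) dominates circumstantial evidence
#: (multiple occupancy, feeding scars).
_PRECEDENCE: tuple[MortalityCause, ...] = (
    MortalityCause.PARASITISM,
    MortalityCause.PATHOGENS,
    MortalityCause.CANNIBALISM,
    MortalityCause.PLANT_DEFENSE,
    MortalityCause.UNKNOWN,
)

_EGG_EVIDENCE = frozenset({EvidenceCode.MULTIPLE_EGGS, EvidenceCode.LARVA_PLUS_EGG})
_NEONATE_EVIDENCE = frozenset(
    {
        EvidenceCode.DEAD_NEONATE,
        EvidenceCode.FEEDING_SCAR_ONLY,
        EvidenceCode.TINY_FRASS_FRAGMENT,
    }
)


def classify_cause(evidence: Iterable[EvidenceCode]) -> MortalityCause:
    """Map one dead occupant's evidence-code set to a mortality cause.

    Deterministic and total over non-empty code sets; when codes pointing to
    several causes co-occur, the fixed precedence
    parasitism > pathogens > cannibalism > plant defense > unknown applies.
    """
    codes = frozenset(evidence)
    if not codes:
        raise ValueError("empty evidence set: a dead occupant needs at least one code")
    causes = {_CODE_TO_CAUSE[c] for c in codes}
    for cause in _PRECEDENCE:
        if cause in causes:
            return cause
    raise AssertionError("unreachable: every code maps to a cause")


@dataclass(frozen=True)
class DissectionRecord:
    """One dissected stem or stub.

    ``dead_observations`` holds one evidence-code set per dead occupant found
    in the unit.  ``emerged`` marks a post-flight stub whose frass plug shows
    a single emergence hole and no cadaver or cocoon.
    """

    site: str
    year: int
    cultivar: str
    block: str
    plot: str
    sample_kind: SampleKind
    unit_id: str
    n_eggs: int = 0
    n_live_larvae: int = 0
    dead_observations: tuple[frozenset[EvidenceCode], ...] = ()
    week: int | None = None
    stub_phase: StubPhase | None = None
    emerged: bool = False

    def __post_init__(self) -> None:
        if self.sample_kind is SampleKind.STEM:
            if self.week is None:
                raise RecordValidationError(
                    f"unit {self.unit_id}: stem sample requires a week"
                )
            if self.stub_phase is not None:
                raise RecordValidationError(
                    f"unit {self.unit_id}: stem sample must not carry a stub phase"
                )
            if not 1 <= self.week <= 9:
                raise RecordValidationError(
                    f"unit {self.unit_id}: week must be in 1..9, got {self.week}"
                )
        else:
            if self.stub_phase is None:
                raise RecordValidationError(
                    f"unit {self.unit_id}: stub sample requires a stub phase"
                )
            if self.week is not None:
                raise RecordValidationError(
                    f"unit {self.unit_id}: stub sample must not carry a week"
                )
        if self.n_eggs < 0 or self.n_live_larvae < 0:
            raise RecordValidationError(
                f"unit {self.unit_id}: occupancy counts must be non-negative"
            )
        if self.emerged and (
            self.sample_kind is not SampleKind.STUB
            or self.stub_phase is not StubPhase.POST_FLIGHT
        ):
            raise RecordValidationError(
                f"unit {self.unit_id}: emergence is only observable in post-flight stubs"
            )
        for group in self.dead_observations:
            if not group:
                raise RecordValidationError(
                    f"unit {self.unit_id}: empty evidence set for a dead occupant"
                )


def assign_stage(record: DissectionRecord, role: str) -> Stage:
    """Developmental stage of a live occupant, from sampling time and role.

    Egg occupants are EGG regardless of timing.  Stem-sample larvae map onto
    the pre-parasitism window (weeks 2-4, LARVA_I) or the vulnerable window
    (weeks 5-9, LARVA_III); stub larvae map onto the overwintering stages by
    collection phase.  A week-1 larva is biologically anomalous (week 1
    normally contains eggs only) and is assigned LARVA_I with a warning.
    """
    if role == "egg":
        return Stage.EGG
    if role != "larva":
        raise ValueError(f"unknown occupant role {role!r}")
    if record.sample_kind is SampleKind.STEM:
        assert record.week is not None
        if record.week == 1:
            warnings.warn(
                f"unit {record.unit_id}: larva observed in week 1; assigned LARVA_I",
                stacklevel=2,
            )
            return Stage.LARVA_I
        return Stage.LARVA_I if record.week <= 4 else Stage.LARVA_III
    if record.emerged:
        return Stage.ADULT
    return (
        Stage.LARVA_IV
        if record.stub_phase is StubPhase.PRE_FLIGHT
        else Stage.LARVA_V
    )


def death_stage(record: DissectionRecord, evidence: frozenset[EvidenceCode]) -> Stage:
    """Stage at which a dead occupant died.

    Evidence is used where it is stage-diagnostic: consumed-egg codes pin the
    death to EGG; neonate evidence (dead neonate, feeding scar, frass
    fragment) and cannibalised-larva remains pin it to the pre-parasitism
    larval period; parasitoid evidence in a stem sample pins it to the
    vulnerable window (parasitism cannot act earlier).  Otherwise the death
    is binned by sampling time, as in the abridged field protocol.
    """
    cause = classify_cause(evidence)
    if evidence & _EGG_EVIDENCE and EvidenceCode.MULTIPLE_LARVAE not in evidence:
        if cause is MortalityCause.CANNIBALISM:
            return Stage.EGG
    if record.sample_kind is SampleKind.STEM:
        if cause is MortalityCause.PARASITISM:
            return Stage.LARVA_III
        if evidence & _NEONATE_EVIDENCE and cause is MortalityCause.PLANT_DEFENSE:
            return Stage.LARVA_I
        if EvidenceCode.MULTIPLE_LARVAE in evidence and cause is MortalityCause.CANNIBALISM:
            # larval cannibalism resolves among young co-occupants
            return Stage.LARVA_I
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return assign_stage(record, "larva")
    return (
        Stage.LARVA_IV
        if record.stub_phase is StubPhase.PRE_FLIGHT
        else Stage.LARVA_V
    )


@dataclass
class StageCauseCounts:
    """Stage-by-cause death counts and numbers at risk for one stratum.

    ``l`` maps each stage to the number of occupants observed to have reached
    it; ``deaths`` maps (stage, cause) to death counts.  Stages with no
    examined occupants carry l=0 and are listed in ``empty_stages``.
    """

    stratum: str = POOLED
    l: dict[Stage, int] = field(default_factory=lambda: {s: 0 for s in STAGES})
    deaths: dict[Stage, dict[MortalityCause, int]] = field(
        default_factory=lambda: {s: {c: 0 for c in CAUSES} for s in STAGES}
    )

    def d_x(self, stage: Stage) -> int:
        return sum(self.deaths[stage].values())

    @property
    def empty_stages(self) -> list[Stage]:
        return [s for s in STAGES if s is not Stage.ADULT and self.l[s] == 0]

    def validate(self) -> None:
        for s in STAGES:
            if self.l[s] < 0:
                raise ValueError(f"{self.stratum}: negative l at {s.name}")
            for c, d in self.deaths[s].items():
                if d < 0:
                    raise ValueError(f"{self.stratum}: negative deaths at {s.name}")
            if self.d_x(s) > self.l[s]:
                raise ValueError(
                    f"{self.stratum}: deaths exceed number at risk at {s.name}"
                )
        for s in (Stage.EGG, Stage.LARVA_I):
            if self.deaths[s][MortalityCause.PARASITISM] > 0:
                raise ValueError(
                    f"{self.stratum}: parasitism cannot act before the vulnerable "
                    f"window (stage {s.name})"
                )
        if self.d_x(Stage.ADULT) > 0:
            raise ValueError(f"{self.stratum}: the adult stage absorbs no decrements")

    def add(self, stage: Stage, *, alive: bool, cause: MortalityCause | None = None) -> None:
        """Register one occupant outcome: entry into every stage up to
        ``stage`` plus, for the dead, a decrement at ``stage``."""
        for s in STAGES[: stage + 1]:
            self.l[s] += 1
        if not alive:
            assert cause is not None
            self.deaths[stage][cause] += 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in STAGES:
            row = {"stage": s.name, "l_x": self.l[s]}
            for c in CAUSES:
                row[f"d_{c.name.lower()}"] = self.deaths[s][c]
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, stratum: str = POOLED) -> "StageCauseCounts":
        counts = cls(stratum=stratum)
        for _, row in frame.iterrows():
            stage = Stage[str(row["stage"]).upper()]
            counts.l[stage] = int(row["l_x"])
            for c in CAUSES:
                col = f"d_{c.name.lower()}"
                if col in row and pd.notna(row[col]) and str(row[col]) != "":
                    counts.deaths[stage][c] = int(row[col])
        counts.validate()
        return counts


def _occupant_outcomes(
    record: DissectionRecord,
) -> list[tuple[Stage, bool, MortalityCause | None]]:
    """Expand a record into per-occupant (stage, alive, cause) outcomes.

    Applies the obligate-cannibalism bookkeeping: whenever more than one live
    occupant shares a unit, a single larva eventually consumes all others, so
    all but one presumptive survivor are recorded as cannibalism decrements
    immediately — live eggs at EGG, extra live larvae at their observed stage.
    """
    outcomes: list[tuple[Stage, bool, MortalityCause | None]] = []
    for evidence in record.dead_observations:
        cause = classify_cause(evidence)
        outcomes.append((death_stage(record, evidence), False, cause))

    n_eggs, n_larvae = record.n_eggs, record.n_live_larvae
    larva_stage = (
        assign_stage(record, "larva") if n_larvae else None
    )
    if record.emerged:
        outcomes.append((Stage.ADULT, True, None))
    live = n_eggs + n_larvae
    if live > 1 or (live == 1 and n_eggs == 1 and n_larvae == 0):
        # obligate cannibalism: with >1 live occupant, keep one presumptive
        # survivor (a larva when present, else one egg) and doom the rest
        doomed_eggs = n_eggs if n_larvae >= 1 else max(n_eggs - 1, 0)
        kept_egg = n_eggs - doomed_eggs
        doomed_larvae = max(n_larvae - 1, 0) if n_larvae >= 1 else 0
        kept_larva = n_larvae - doomed_larvae
        outcomes.extend(
            [(Stage.EGG, False, MortalityCause.CANNIBALISM)] * doomed_eggs
        )
        outcomes.extend([(Stage.EGG, True, None)] * kept_egg)
        if n_larvae:
            assert larva_stage is not None
            outcomes.extend(
                [(larva_stage, False, MortalityCause.CANNIBALISM)] * doomed_larvae
            )
            outcomes.extend([(larva_stage, True, None)] * kept_larva)
    elif live == 1 and n_larvae == 1:
        assert larva_stage is not None
        outcomes.append((larva_stage, True, None))
    return outcomes


def aggregate(
    records: Iterable[DissectionRecord],
    grouping: Sequence[str] | None = None,
) -> list[StageCauseCounts]:
    """Aggregate validated records into stage-by-cause count tables.

    ``grouping`` names record fields (e.g. ``("site", "year", "cultivar")``)
    whose value combinations define strata; ``None`` pools everything into a
    single stratum.  Each occupant contributes one number-at-risk entry to
    every stage it is observed to have reached and, if dead, one decrement at
    its death stage.  Empty input yields an empty list.
    """
    strata: dict[str, StageCauseCounts] = {}
    for record in records:
        if grouping:
            key = "/".join(str(getattr(record, g)) for g in grouping)
        else:
            key = POOLED
        counts = strata.setdefault(key, StageCauseCounts(stratum=key))
        for stage, alive, cause in _occupant_outcomes(record):
            counts.add(stage, alive=alive, cause=cause)
    out = list(strata.values())
    for counts in out:
        counts.validate()
    return out


# ---------------------------------------------------------------------------
# CSV interface

_COLUMNS = [
    "site",
    "year",
    "cultivar",
    "block",
    "plot",
    "sample_kind",
    "week",
    "stub_phase",
    "unit_id",
    "n_eggs",
    "n_live_larvae",
    "dead_evidence",
    "emerged",
]


def _parse_evidence(cell: str) -> tuple[frozenset[EvidenceCode], ...]:
    cell = cell.strip()
    if not cell:
        return ()
    groups = []
    for group in cell.split(";"):
        codes = frozenset(EvidenceCode(code.strip()) for code in group.split(",") if code.strip())
        if codes:
            groups.append(codes)
    return tuple(groups)


def read_records(
    path: str | Path, *, strict: bool = False
) -> tuple[list[DissectionRecord], list[str]]:
    """Read a dissection-records CSV.

    Returns ``(records, diagnostics)``; malformed rows are rejected with a
    row-indexed diagnostic message (or raised immediately when ``strict``).
    A missing mandatory column raises :class:`SchemaError` regardless.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    records: list[DissectionRecord] = []
    diagnostics: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            week = int(row.week) if str(row.week).strip() else None
            phase = StubPhase(row.stub_phase) if str(row.stub_phase).strip() else None
            records.append(
                DissectionRecord(
                    site=row.site,
                    year=int(row.year),
                    cultivar=row.cultivar,
                    block=row.block,
                    plot=row.plot,
                    sample_kind=SampleKind(row.sample_kind),
                    week=week,
                    stub_phase=phase,
                    unit_id=row.unit_id,
                    n_eggs=int(row.n_eggs),
                    n_live_larvae=int(row.n_live_larvae),
                    dead_observations=_parse_evidence(row.dead_evidence),
                    emerged=str(row.emerged).strip().lower() in {"true", "1", "yes"},
                )
            )
        except (ValueError, RecordValidationError) as exc:
            if strict:
                raise type(exc)(f"row {i}: {exc}") from exc
            diagnostics.append(f"row {i}: {exc}")
    return records, diagnostics


def write_records(records: Iterable[DissectionRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical schema (UTF-8, comma-separated,
    semicolon-delimited per-occupant evidence groups)."""
    rows = []
    for r in records:
        rows.append(
            {
                "site": r.site,
                "year": r.year,
                "cultivar": r.cultivar,
                "block": r.block,
                "plot": r.plot,
                "sample_kind": r.sample_kind.value,
                "week": "" if r.week is None else r.week,
                "stub_phase": "" if r.stub_phase is None else r.stub_phase.value,
                "unit_id": r.unit_id,
                "n_eggs": r.n_eggs,
                "n_live_larvae": r.n_live_larvae,
                "dead_evidence": ";".join(
                    ",".join(sorted(code.value for code in group))
                    for group in r.dead_observations
                ),
                "emerged": r.emerged,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False, encoding="utf-8")
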