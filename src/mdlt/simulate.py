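"""Stochastic cohort simulator with the study's sampling design.

Generates dissection-record datasets with known ground-truth cause-specific
mortality, so the whole pipeline is testable without field data.  The
generative model follows the insect's life history in a stem:

* eggs arrive per stem from a negative binomial (multiple females oviposit
  in attractive stems, producing overdispersion), spread over the first
  three oviposition weeks;
* an egg hatches two weeks after it is laid, unless a resident larva has
  already claimed the stem, in which case it is consumed while still an egg
  (egg cannibalism);
* each hatching neonate independently survives or dies of plant defense
  (antibiosis); when several neonates hatch together, the survivors resolve
  by obligate cannibalism — exactly one resident remains, the losers are
  consumed as young larvae;
* the resident risks parasitism and unknown-factor death during the
  vulnerable window (sampling weeks 5-9), then overwinters through two stub
  stages with pathogen and unknown risks, and finally emerges as an adult.

Two sampling operators observe the simulated stand.  ``weekly`` reproduces
the field design: per plot, 3 bags x 35 stems uprooted in each of 9 weekly
samples, then 25 stubs dissected before and 25 after the adult flight
period; each stem is destroyed when sampled, so records are censored
cross-sections.  ``census`` is an idealised complete necropsy panel — every
infested stem contributes one stem record with its full summer history and,
if its larva cut the stem, one stub record with the overwinter outcome —
under which aggregation recovers the ground-truth event log exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .elimination import CauseMortalityProfile, net_probabilities
from .life_table import build_mdlt, cause_totals
from .records import (
    CAUSES,
    STAGES,
    DissectionRecord,
    EvidenceCode,
    MortalityCause,
    SampleKind,
    Stage,
    StubPhase,
    aggregate,
)

__all__ = [
    "CultivarParams",
    "SimulationConfig",
    "TruthRecord",
    "simulate_cohort",
    "recovery_report",
    "load_config",
    "STUDY_CULTIVARS",
]

#: Oviposition week offsets relative to the first sampling week (an egg laid
#: at offset a is first visible in week a+1 samples and hatches in week a+2),
#: and their relative frequencies.
_ARRIVAL_OFFSETS = np.array([0, 1, 2])
_ARRIVAL_PROBS = np.array([0.40, 0.35, 0.25])

_SITE_YEARS = [("Amsterdam", 2016), ("Amsterdam", 2017), ("BigSandy", 2017)]


class CultivarParams(BaseModel):
    """Per-cultivar generative parameters.

    ``egg_intensity`` (mean eggs per stem) models attractiveness to gravid
    females (antixenosis in reverse: attractive cultivars concentrate eggs
    and drive cannibalism); ``p_plant_defense`` models antibiosis acting on
    each hatching neonate.  The two vary independently so the
    attractiveness-versus-antibiosis tradeoff can be emulated without being
    hard-coded.
    """

    egg_intensity: float = Field(ge=0.0)
    p_plant_defense: float = Field(ge=0.0, le=1.0)
    p_parasitism: float = Field(default=0.08, ge=0.0, le=1.0)
    p_unknown_early: float = Field(default=0.10, ge=0.0, le=1.0)
    p_pathogens: float = Field(default=0.03, ge=0.0, le=1.0)
    p_unknown_late: float = Field(default=0.08, ge=0.0, le=1.0)
    #: negative binomial dispersion (smaller = more overdispersed); None
    #: gives the Poisson special case
    dispersion: float | None = Field(default=1.0, gt=0.0)
    #: probability that a co-arriving egg hatches together with the current
    #: hatcher instead of behind it (creates larval-cannibalism victims)
    p_overlap: float = Field(default=0.15, ge=0.0, le=1.0)


#: Default eight-cultivar panel spanning the attractiveness/antibiosis
#: tradeoff observed across barley cultivars.
STUDY_CULTIVARS: dict[str, CultivarParams] = {
    "Celebration": CultivarParams(egg_intensity=1.6, p_plant_defense=0.40),
    "Champion": CultivarParams(egg_intensity=1.5, p_plant_defense=0.38),
    "Craft": CultivarParams(egg_intensity=1.2, p_plant_defense=0.45),
    "Haxby": CultivarParams(egg_intensity=2.2, p_plant_defense=0.28),
    "Haybet": CultivarParams(egg_intensity=2.4, p_plant_defense=0.25),
    "Hockett": CultivarParams(egg_intensity=3.2, p_plant_defense=0.12),
    "Lavina": CultivarParams(egg_intensity=2.0, p_plant_defense=0.30),
    "Tradition": CultivarParams(egg_intensity=1.8, p_plant_defense=0.35),
}


class SimulationConfig(BaseModel):
    """Generative and sampling parameters for one simulated study.

    Defaults emulate the field design: 3 site-years x 3 blocks x 8 plots
    (one cultivar each), 3 bags x 35 stems dissected per plot in each of 9
    weekly samples, and 25 stubs per plot in each of the pre- and
    post-flight collections.
    """

    n_sites: int = Field(default=3, ge=1)
    n_blocks: int = Field(default=3, ge=1)
    n_plots_per_block: int = Field(default=8, ge=1)
    cultivar_params: dict[str, CultivarParams] = Field(
        default_factory=lambda: dict(STUDY_CULTIVARS)
    )
    stems_per_plot: int = Field(default=1100, ge=1)
    bags_per_plot: int = Field(default=3, ge=1)
    stems_per_bag: int = Field(default=35, ge=1)
    weeks: int = Field(default=9)
    stubs_per_collection: int = Field(default=25, ge=0)
    sampling: Literal["weekly", "census"] = "weekly"
    emit_uninfested: bool = False
    seed: int = 0

    @field_validator("weeks")
    @classmethod
    def _nine_weeks(cls, v: int) -> int:
        if v != 9:
            raise ValueError(
                "the stage windows are defined over a 9-week summer season"
            )
        return v

    @model_validator(mode="after")
    def _feasible_sampling(self) -> "SimulationConfig":
        if self.sampling == "weekly":
            demand = self.bags_per_plot * self.stems_per_bag * self.weeks
            if demand > self.stems_per_plot:
                raise ValueError(
                    f"requested stems exceed stand: {demand} sampled vs "
                    f"{self.stems_per_plot} per plot"
                )
        return self


def load_config(path: str | Path) -> SimulationConfig:
    """Load a simulation config from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig(**data)


# ---------------------------------------------------------------------------
# per-stem life history


@dataclass
class _Death:
    stage: Stage
    cause: MortalityCause
    week: int | None  # summer event week; None for overwinter events
    phase: StubPhase | None
    evidence: frozenset[EvidenceCode]
    # live visibility window of this occupant before death, weekly sampling
    visible_egg_week: int | None = None
    larva_weeks: tuple[int, int] | None = None  # inclusive [start, end]


@dataclass
class _StemFate:
    n_eggs: int
    deaths: list[_Death]
    resident_weeks: tuple[int, int] | None  # live larva window in stem phase
    cut: bool  # survivor entered overwintering
    overwinter: str | None  # "died_iv", "died_v", "emerged", or None
    multi_resolved: bool  # >=2 occupants alive when cannibalism resolved


def _egg_evidence(rng: np.random.Generator) -> frozenset[EvidenceCode]:
    code = (
        EvidenceCode.LARVA_PLUS_EGG
        if rng.random() < 0.5
        else EvidenceCode.MULTIPLE_EGGS
    )
    return frozenset({code})


def _pd_evidence(rng: np.random.Generator) -> frozenset[EvidenceCode]:
    r = rng.random()
    if r < 0.5:
        return frozenset({EvidenceCode.DEAD_NEONATE})
    if r < 0.8:
        return frozenset(
            {EvidenceCode.FEEDING_SCAR_ONLY, EvidenceCode.TINY_FRASS_FRAGMENT}
        )
    return frozenset({EvidenceCode.DEAD_NEONATE, EvidenceCode.FEEDING_SCAR_ONLY})


def _parasitism_evidence(rng: np.random.Generator) -> frozenset[EvidenceCode]:
    r = rng.random()
    if r < 0.45:
        return frozenset({EvidenceCode.PARASITOID_LARVA})
    if r < 0.9:
        return frozenset({EvidenceCode.PARASITOID_COCOON})
    if r < 0.98:
        return frozenset({EvidenceCode.PARASITOID_EXIT_HOLE})
    return frozenset({EvidenceCode.PREDATOR_LARVA})


def _pathogen_evidence(rng: np.random.Generator) -> frozenset[EvidenceCode]:
    code = (
        EvidenceCode.WHITE_PINK_HYPHAE
        if rng.random() < 0.7
        else EvidenceCode.PINK_CADAVER
    )
    return frozenset({code})


_UNKNOWN_EVIDENCE = frozenset({EvidenceCode.DEAD_MULTI_INTERNODE})


def _simulate_stem(rng: np.random.Generator, p: CultivarParams) -> _StemFate | None:
    """Simulate one stem's full (counterfactual) life history."""
    if p.dispersion is None or math.isinf(p.dispersion):
        n = int(rng.poisson(p.egg_intensity))
    elif p.egg_intensity == 0.0:
        n = 0
    else:
        k = p.dispersion
        n = int(rng.negative_binomial(k, k / (k + p.egg_intensity)))
    if n == 0:
        return None

    arrivals = rng.choice(_ARRIVAL_OFFSETS, size=n, p=_ARRIVAL_PROBS)
    deaths: list[_Death] = []
    resident_hatch: int | None = None
    multi_resolved = False

    def die_egg(a: int, week: int) -> None:
        deaths.append(
            _Death(
                Stage.EGG,
                MortalityCause.CANNIBALISM,
                week,
                None,
                _egg_evidence(rng),
                visible_egg_week=a + 1,
            )
        )

    for w in (2, 3, 4):
        due = np.flatnonzero(arrivals == w - 2)
        if due.size == 0:
            continue
        if resident_hatch is not None:
            # resident consumes the newly due eggs before they can hatch
            multi_resolved = True
            for i in due:
                die_egg(int(arrivals[i]), w)
            continue
        order = rng.permutation(due)
        idx = 0
        while idx < len(order) and resident_hatch is None:
            cohort = [order[idx]]
            idx += 1
            while idx < len(order) and rng.random() < p.p_overlap:
                cohort.append(order[idx])
                idx += 1
            survivors = []
            for i in cohort:
                if rng.random() < p.p_plant_defense:
                    deaths.append(
                        _Death(
                            Stage.LARVA_I,
                            MortalityCause.PLANT_DEFENSE,
                            w,
                            None,
                            _pd_evidence(rng),
                        )
                    )
                else:
                    survivors.append(i)
            if survivors:
                resident_hatch = w
                if len(survivors) > 1:
                    multi_resolved = True
                    eaten = w + 1 if w <= 3 else w
                    for _ in survivors[1:]:
                        deaths.append(
                            _Death(
                                Stage.LARVA_I,
                                MortalityCause.CANNIBALISM,
                                eaten,
                                None,
                                frozenset({EvidenceCode.MULTIPLE_LARVAE}),
                                larva_weeks=(w, eaten - 1),
                            )
                        )
        if resident_hatch is not None and idx < len(order):
            # remaining same-week eggs are consumed as the resident settles
            multi_resolved = True
            for i in order[idx:]:
                die_egg(int(arrivals[i]), w)

    if resident_hatch is None:
        return _StemFate(n, deaths, None, False, None, multi_resolved)

    # vulnerable window: parasitism and unknown-factor risks, weeks 5-9
    events = []
    if rng.random() < p.p_parasitism:
        events.append((int(rng.integers(5, 10)), 0, MortalityCause.PARASITISM))
    if rng.random() < p.p_unknown_early:
        events.append((int(rng.integers(5, 10)), 1, MortalityCause.UNKNOWN))
    if events:
        week, _, cause = min(events)  # earliest wins; tie favours parasitism
        evidence = (
            _parasitism_evidence(rng)
            if cause is MortalityCause.PARASITISM
            else _UNKNOWN_EVIDENCE
        )
        deaths.append(_Death(Stage.LARVA_III, cause, week, None, evidence))
        return _StemFate(
            n, deaths, (resident_hatch, week - 1), False, None, multi_resolved
        )

    # the survivor cuts the stem and overwinters
    resident_weeks = (resident_hatch, 9)
    for stage, phase, tag in (
        (Stage.LARVA_IV, StubPhase.PRE_FLIGHT, "died_iv"),
        (Stage.LARVA_V, StubPhase.POST_FLIGHT, "died_v"),
    ):
        if rng.random() < p.p_pathogens:
            deaths.append(
                _Death(stage, MortalityCause.PATHOGENS, None, phase, _pathogen_evidence(rng))
            )
            return _StemFate(n, deaths, resident_weeks, True, tag, multi_resolved)
        if rng.random() < p.p_unknown_late:
            deaths.append(
                _Death(stage, MortalityCause.UNKNOWN, None, phase, _UNKNOWN_EVIDENCE)
            )
            return _StemFate(n, deaths, resident_weeks, True, tag, multi_resolved)
    return _StemFate(n, deaths, resident_weeks, True, "emerged", multi_resolved)


# ---------------------------------------------------------------------------
# observation operators


def _observe_weekly(fate: _StemFate, week: int) -> tuple[int, int, list[frozenset]]:
    """Visible state of a stem uprooted at the end of sampling ``week``."""
    n_eggs = sum(
        1
        for d in fate.deaths
        if d.visible_egg_week == week
    )
    # eggs that eventually hatched are visible the week after arrival too;
    # reconstruct from larvae/resident hatch weeks (hatch = arrival + 2)
    n_live = 0
    if fate.resident_weeks is not None:
        start, end = fate.resident_weeks
        if start <= week <= end:
            n_live += 1
        if start - 1 == week:
            n_eggs += 1  # the future resident, still an egg
    for d in fate.deaths:
        if d.larva_weeks is not None:
            start, end = d.larva_weeks
            if start <= week <= end:
                n_live += 1
            if start - 1 == week:
                n_eggs += 1
        elif d.stage is Stage.LARVA_I and d.cause is MortalityCause.PLANT_DEFENSE:
            assert d.week is not None
            if d.week - 1 == week:
                n_eggs += 1  # visible as an egg the week before hatching
    dead = [
        d.evidence
        for d in fate.deaths
        if d.week is not None and d.week <= week
    ]
    return n_eggs, n_live, dead


def _stub_record_fields(fate: _StemFate, phase: StubPhase) -> dict:
    """Occupancy and evidence of a stub dissected at the given phase."""
    overwinter_deaths = [d for d in fate.deaths if d.phase is not None]
    if phase is StubPhase.PRE_FLIGHT:
        if fate.overwinter == "died_iv":
            return {"dead": [d.evidence for d in overwinter_deaths], "live": 0, "emerged": False}
        return {"dead": [], "live": 1, "emerged": False}
    if fate.overwinter == "emerged":
        return {"dead": [], "live": 0, "emerged": True}
    return {"dead": [d.evidence for d in overwinter_deaths], "live": 0, "emerged": False}


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class TruthRecord:
    """Ground truth of a simulated stand.

    ``events`` has one row per death (stratum labels, unit, stage, cause);
    ``stems`` one row per infested stem (eggs laid, emerged flag, cannibalism
    deaths, whether the stem was multiply occupied when cannibalism
    resolved).  Decrement proportions are event-log tallies divided by the
    cohort size, exactly.
    """

    events: pd.DataFrame
    stems: pd.DataFrame

    @property
    def cohort_size(self) -> int:
        return int(self.stems["n_eggs"].sum())

    @property
    def survivors(self) -> int:
        return int(self.stems["emerged"].sum())

    @property
    def final_survival(self) -> float:
        return self.survivors / self.cohort_size if self.cohort_size else 1.0

    def decrements(self) -> pd.DataFrame:
        """Stage-by-cause death counts."""
        table = pd.DataFrame(
            0,
            index=[s.name for s in STAGES],
            columns=[c.name for c in CAUSES],
        )
        if len(self.events):
            tally = self.events.groupby(["stage", "cause"]).size()
            for (stage, cause), n in tally.items():
                table.loc[stage, cause] = n
        return table

    def ad_ix(self) -> pd.DataFrame:
        """True unconditional stage-by-cause decrement proportions."""
        return self.decrements() / max(self.cohort_size, 1)

    def cause_totals(self) -> np.ndarray:
        """True crude cohort mortality aD_i per cause."""
        return self.ad_ix().sum(axis=0).to_numpy(dtype=float)

    def stage_entrants(self) -> dict[Stage, int]:
        """True number of individuals entering each stage."""
        dec = self.decrements().sum(axis=1)
        out: dict[Stage, int] = {}
        remaining = self.cohort_size
        for s in STAGES:
            out[s] = remaining
            remaining -= int(dec[s.name])
        return out


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[DissectionRecord], TruthRecord]:
    """Simulate a stand and observe it with the configured sampling design.

    Returns the dissection-record stream and the ground-truth
    :class:`TruthRecord`.  Random streams are hierarchical (site -> plot ->
    stem), so adding plots or sites does not perturb existing plots' draws;
    the same config and seed reproduce the record stream exactly.
    """
    base_seed = config.seed if seed is None else seed
    cultivar_names = list(config.cultivar_params)
    records: list[DissectionRecord] = []
    event_rows: list[tuple] = []
    stem_rows: list[tuple] = []

    n_weekly = config.bags_per_plot * config.stems_per_bag

    for si in range(config.n_sites):
        site, year = _SITE_YEARS[si % len(_SITE_YEARS)]
        if si >= len(_SITE_YEARS):
            year += si  # keep site-year labels unique beyond the study's three
        for bi in range(config.n_blocks):
            for pi in range(config.n_plots_per_block):
                cultivar = cultivar_names[pi % len(cultivar_names)]
                params = config.cultivar_params[cultivar]
                ss = np.random.SeedSequence(
                    entropy=base_seed, spawn_key=(si, bi, pi)
                )
                stem_rng, sample_rng = [
                    np.random.Generator(np.random.PCG64(child))
                    for child in ss.spawn(2)
                ]
                block, plot = f"B{bi + 1}", f"P{pi + 1}"

                # destructive sampling schedule: which stems are uprooted in
                # which week; the rest stand and may become stubs
                if config.sampling == "weekly":
                    schedule = sample_rng.permutation(config.stems_per_plot)
                    week_of = {}
                    for w in range(1, config.weeks + 1):
                        for j in schedule[(w - 1) * n_weekly : w * n_weekly]:
                            week_of[int(j)] = w
                else:
                    week_of = {}

                stub_pool: list[tuple[str, _StemFate]] = []
                for j in range(config.stems_per_plot):
                    fate = _simulate_stem(stem_rng, params)
                    unit = f"{site}{year}-{block}-{plot}-stem{j + 1}"
                    if fate is None:
                        if config.emit_uninfested and week_of.get(j):
                            records.append(
                                DissectionRecord(
                                    site=site, year=year, cultivar=cultivar,
                                    block=block, plot=plot,
                                    sample_kind=SampleKind.STEM,
                                    week=week_of[j], unit_id=unit,
                                )
                            )
                        continue

                    # --- truth, independent of observation
                    for d in fate.deaths:
                        event_rows.append(
                            (site, year, cultivar, block, plot, unit,
                             d.stage.name, d.cause.name)
                        )
                    stem_rows.append(
                        (site, year, cultivar, block, plot, unit, fate.n_eggs,
                         fate.overwinter == "emerged",
                         sum(1 for d in fate.deaths
                             if d.cause is MortalityCause.CANNIBALISM),
                         fate.multi_resolved)
                    )

                    # --- observation
                    if config.sampling == "census":
                        summer_dead = [
                            d.evidence for d in fate.deaths if d.week is not None
                        ]
                        if summer_dead:
                            records.append(
                                DissectionRecord(
                                    site=site, year=year, cultivar=cultivar,
                                    block=block, plot=plot,
                                    sample_kind=SampleKind.STEM, week=9,
                                    unit_id=unit,
                                    dead_observations=tuple(summer_dead),
                                )
                            )
                        if fate.cut:
                            phase = (
                                StubPhase.PRE_FLIGHT
                                if fate.overwinter == "died_iv"
                                else StubPhase.POST_FLIGHT
                            )
                            fields = _stub_record_fields(fate, phase)
                            records.append(
                                DissectionRecord(
                                    site=site, year=year, cultivar=cultivar,
                                    block=block, plot=plot,
                                    sample_kind=SampleKind.STUB,
                                    stub_phase=phase,
                                    unit_id=unit + "-stub",
                                    n_live_larvae=fields["live"],
                                    dead_observations=tuple(fields["dead"]),
                                    emerged=fields["emerged"],
                                )
                            )
                    else:
                        w = week_of.get(j)
                        if w is not None:
                            n_eggs, n_live, dead = _observe_weekly(fate, w)
                            if n_eggs or n_live or dead or config.emit_uninfested:
                                records.append(
                                    DissectionRecord(
                                        site=site, year=year, cultivar=cultivar,
                                        block=block, plot=plot,
                                        sample_kind=SampleKind.STEM, week=w,
                                        unit_id=unit,
                                        n_eggs=n_eggs, n_live_larvae=n_live,
                                        dead_observations=tuple(dead),
                                    )
                                )
                        elif fate.cut:
                            stub_pool.append((unit, fate))

                if config.sampling == "weekly" and stub_pool:
                    order = sample_rng.permutation(len(stub_pool))
                    k = config.stubs_per_collection
                    picks = {
                        StubPhase.PRE_FLIGHT: order[:k],
                        StubPhase.POST_FLIGHT: order[k : 2 * k],
                    }
                    for phase, chosen in picks.items():
                        for idx in chosen:
                            unit, fate = stub_pool[int(idx)]
                            fields = _stub_record_fields(fate, phase)
                            records.append(
                                DissectionRecord(
                                    site=site, year=year, cultivar=cultivar,
                                    block=block, plot=plot,
                                    sample_kind=SampleKind.STUB,
                                    stub_phase=phase,
                                    unit_id=unit + "-stub",
                                    n_live_larvae=fields["live"],
                                    dead_observations=tuple(fields["dead"]),
                                    emerged=fields["emerged"],
                                )
                            )

    events = pd.DataFrame(
        event_rows,
        columns=["site", "year", "cultivar", "block", "plot", "unit_id",
                 "stage", "cause"],
    )
    stems = pd.DataFrame(
        stem_rows,
        columns=["site", "year", "cultivar", "block", "plot", "unit_id",
                 "n_eggs", "emerged", "cannibalism_deaths", "multi_resolved"],
    )
    return records, TruthRecord(events=events, stems=stems)


def recovery_report(
    records: list[DissectionRecord] | list[list[DissectionRecord]],
    truth: TruthRecord | list[TruthRecord],
) -> pd.DataFrame:
    """Compare pipeline estimates against simulated ground truth.

    Runs the full aggregation -> life-table pipeline on the record stream(s),
    estimates crude cause totals aD_i and net probabilities q_i, and reports
    absolute errors with binomial standard errors at the simulated cohort
    size.  With several replicates, estimates and truths are averaged and the
    standard error is evaluated at the mean single-replicate cohort size.
    """
    if isinstance(truth, TruthRecord):
        records_list = [records]  # type: ignore[list-item]
        truth_list = [truth]
    else:
        records_list = records  # type: ignore[assignment]
        truth_list = truth

    est_totals, true_totals, est_q, true_q, sizes = [], [], [], [], []
    for recs, tr in zip(records_list, truth_list):
        counts = aggregate(recs)[0]
        table = build_mdlt(counts, skip_empty_stages=True)
        d_est = cause_totals(table)
        d_true = tr.cause_totals()
        est_totals.append(d_est)
        true_totals.append(d_true)
        est_q.append(net_probabilities(CauseMortalityProfile(d=tuple(d_est))))
        true_q.append(net_probabilities(CauseMortalityProfile(d=tuple(d_true))))
        sizes.append(tr.cohort_size)

    est = np.mean(est_totals, axis=0)
    true = np.mean(true_totals, axis=0)
    n = float(np.mean(sizes))
    se = np.sqrt(np.clip(true * (1.0 - true), 0.0, None) / n)
    frame = pd.DataFrame(
        {
            "cause": [c.name for c in CAUSES],
            "aD_true": true,
            "aD_est": est,
            "abs_error": np.abs(est - true),
            "binom_se": se,
            "q_true": np.mean(true_q, axis=0),
            "q_est": np.mean(est_q, axis=0),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        frame["z"] = np.where(se > 0, frame["abs_error"] / se, 0.0)
    frame.attrs["n_replicates"] = len(records_list)
    frame.attrs["mean_cohort_size"] = n
    return frame
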