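"""Record validation, cause classification, stage assignment, aggregation."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdlt.records import (
    CAUSES,
    STAGES,
    DissectionRecord,
    EvidenceCode,
    MortalityCause,
    RecordValidationError,
    SampleKind,
    SchemaError,
    Stage,
    StubPhase,
    aggregate,
    assign_stage,
    classify_cause,
    read_records,
    write_records,
)
from mdlt.simulate import SimulationConfig, simulate_cohort


def stem(week=3, n_eggs=0, n_live=0, dead=(), unit="u1", **kw):
    return DissectionRecord(
        site="A", year=2016, cultivar="Hockett", block="B1", plot="P1",
        sample_kind=SampleKind.STEM, week=week, unit_id=unit,
        n_eggs=n_eggs, n_live_larvae=n_live,
        dead_observations=tuple(frozenset(d) for d in dead), **kw,
    )


def stub(phase=StubPhase.PRE_FLIGHT, n_live=0, dead=(), emerged=False, unit="s1"):
    return DissectionRecord(
        site="A", year=2016, cultivar="Hockett", block="B1", plot="P1",
        sample_kind=SampleKind.STUB, stub_phase=phase, unit_id=unit,
        n_live_larvae=n_live,
        dead_observations=tuple(frozenset(d) for d in dead), emerged=emerged,
    )


class TestClassifyCause:
    @pytest.mark.parametrize(
        "codes, expected",
        [
            ({EvidenceCode.MULTIPLE_LARVAE}, MortalityCause.CANNIBALISM),
            (
                {EvidenceCode.DEAD_NEONATE, EvidenceCode.FEEDING_SCAR_ONLY},
                MortalityCause.PLANT_DEFENSE,
            ),
            ({EvidenceCode.PREDATOR_LARVA}, MortalityCause.PARASITISM),
            ({EvidenceCode.WHITE_PINK_HYPHAE}, MortalityCause.PATHOGENS),
            ({EvidenceCode.DEAD_MULTI_INTERNODE}, MortalityCause.UNKNOWN),
            # precedence: specific physical evidence dominates circumstantial
            (
                {EvidenceCode.MULTIPLE_LARVAE, EvidenceCode.PARASITOID_COCOON},
                MortalityCause.PARASITISM,
            ),
            (
                {EvidenceCode.DEAD_NEONATE, EvidenceCode.MULTIPLE_EGGS},
                MortalityCause.CANNIBALISM,
            ),
            (
                {EvidenceCode.DEAD_MULTI_INTERNODE, EvidenceCode.PINK_CADAVER},
                MortalityCause.PATHOGENS,
            ),
        ],
    )
    def test_mapping_and_precedence(self, codes, expected):
        assert classify_cause(codes) is expected

    def test_empty_evidence_rejected(self):
        with pytest.raises(ValueError):
            classify_cause(set())

    def test_total_and_pure_over_all_pairs(self):
        """classify_cause is defined and deterministic for every non-empty
        pair of codes (hence every singleton too)."""
        for a, b in itertools.combinations(EvidenceCode, 2):
            first = classify_cause({a, b})
            assert first is classify_cause({b, a})
            assert first in list(MortalityCause)


class TestAssignStage:
    @pytest.mark.parametrize(
        "week, expected",
        [(2, Stage.LARVA_I), (3, Stage.LARVA_I), (4, Stage.LARVA_I),
         (5, Stage.LARVA_III), (7, Stage.LARVA_III), (9, Stage.LARVA_III)],
    )
    def test_stem_larva_windows(self, week, expected):
        assert assign_stage(stem(week=week, n_live=1), "larva") is expected

    def test_egg_is_egg_any_week(self):
        for week in (1, 4, 9):
            assert assign_stage(stem(week=week, n_eggs=1), "egg") is Stage.EGG

    def test_stub_phases_and_emergence(self):
        assert assign_stage(stub(StubPhase.PRE_FLIGHT, n_live=1), "larva") is Stage.LARVA_IV
        assert assign_stage(stub(StubPhase.POST_FLIGHT, n_live=1), "larva") is Stage.LARVA_V
        assert assign_stage(
            stub(StubPhase.POST_FLIGHT, emerged=True), "larva"
        ) is Stage.ADULT

    def test_week_one_larva_warns(self):
        with pytest.warns(UserWarning, match="week 1"):
            assert assign_stage(stem(week=1, n_live=1), "larva") is Stage.LARVA_I


class TestRecordInvariants:
    def test_stem_requires_week(self):
        with pytest.raises(RecordValidationError):
            DissectionRecord(
                site="A", year=2016, cultivar="x", block="b", plot="p",
                sample_kind=SampleKind.STEM, unit_id="u",
            )

    def test_stub_rejects_week(self):
        with pytest.raises(RecordValidationError):
            DissectionRecord(
                site="A", year=2016, cultivar="x", block="b", plot="p",
                sample_kind=SampleKind.STUB, stub_phase=StubPhase.PRE_FLIGHT,
                week=3, unit_id="u",
            )

    def test_emergence_only_post_flight(self):
        with pytest.raises(RecordValidationError):
            stub(StubPhase.PRE_FLIGHT, emerged=True)

    def test_negative_counts_rejected(self):
        with pytest.raises(RecordValidationError):
            stem(n_eggs=-1)


class TestAggregate:
    def test_live_larvae_counted_at_stage(self):
        records = [stem(week=3, n_live=1, unit=f"u{i}") for i in range(10)]
        counts = aggregate(records)[0]
        assert counts.l[Stage.LARVA_I] == 10
        assert counts.d_x(Stage.LARVA_I) == 0
        assert counts.l[Stage.EGG] == 10  # every larva was once an egg

    def test_obligate_cannibalism_bookkeeping(self):
        """Four stems with two live eggs each: one egg per stem is doomed to
        cannibalism, the other is the presumptive survivor."""
        records = [stem(week=1, n_eggs=2, unit=f"u{i}") for i in range(4)]
        counts = aggregate(records)[0]
        assert counts.l[Stage.EGG] == 8
        assert counts.deaths[Stage.EGG][MortalityCause.CANNIBALISM] == 4

    def test_larva_plus_eggs_dooms_all_eggs(self):
        counts = aggregate([stem(week=4, n_eggs=2, n_live=1)])[0]
        assert counts.deaths[Stage.EGG][MortalityCause.CANNIBALISM] == 2
        assert counts.l[Stage.LARVA_I] == 1
        assert counts.d_x(Stage.LARVA_I) == 0

    def test_extra_live_larvae_doomed_at_observed_stage(self):
        counts = aggregate([stem(week=6, n_live=3)])[0]
        assert counts.deaths[Stage.LARVA_III][MortalityCause.CANNIBALISM] == 2
        assert counts.l[Stage.LARVA_III] == 3

    def test_dead_occupants_staged_by_evidence(self):
        rec = stem(
            week=7,
            dead=[
                {EvidenceCode.LARVA_PLUS_EGG},       # consumed egg -> EGG
                {EvidenceCode.DEAD_NEONATE},          # neonate -> LARVA_I
                {EvidenceCode.PARASITOID_COCOON},     # vulnerable window
            ],
        )
        counts = aggregate([rec])[0]
        assert counts.deaths[Stage.EGG][MortalityCause.CANNIBALISM] == 1
        assert counts.deaths[Stage.LARVA_I][MortalityCause.PLANT_DEFENSE] == 1
        assert counts.deaths[Stage.LARVA_III][MortalityCause.PARASITISM] == 1
        # entrant counting: the parasitised larva reached EGG, LARVA_I too
        assert counts.l[Stage.EGG] == 3
        assert counts.l[Stage.LARVA_I] == 2
        assert counts.l[Stage.LARVA_III] == 1

    def test_unknown_binned_by_sampling_time(self):
        counts = aggregate(
            [stub(StubPhase.PRE_FLIGHT, dead=[{EvidenceCode.DEAD_MULTI_INTERNODE}])]
        )[0]
        assert counts.deaths[Stage.LARVA_IV][MortalityCause.UNKNOWN] == 1

    def test_emerged_adult_counts_through_all_stages(self):
        counts = aggregate([stub(StubPhase.POST_FLIGHT, emerged=True)])[0]
        for s in STAGES:
            assert counts.l[s] == 1
        assert all(counts.d_x(s) == 0 for s in STAGES)

    def test_empty_input_empty_output(self):
        assert aggregate([]) == []

    def test_grouping_produces_strata(self):
        records = [stem(unit="a", n_live=1)]
        records.append(
            DissectionRecord(
                site="B", year=2017, cultivar="Craft", block="B1", plot="P1",
                sample_kind=SampleKind.STEM, week=3, unit_id="b", n_live_larvae=1,
            )
        )
        strata = aggregate(records, ("site", "year", "cultivar"))
        assert {c.stratum for c in strata} == {"A/2016/Hockett", "B/2017/Craft"}

    @given(
        n_eggs=st.integers(0, 5),
        n_live=st.integers(0, 3),
        week=st.integers(2, 9),
        dead=st.lists(
            st.sets(st.sampled_from(list(EvidenceCode)), min_size=1, max_size=3),
            max_size=4,
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_deaths_never_exceed_at_risk(self, n_eggs, n_live, week, dead):
        """Sum of cause deaths equals d_x and never exceeds l_x, per stage."""
        counts = aggregate([stem(week=week, n_eggs=n_eggs, n_live=n_live, dead=dead)])[0]
        for s in STAGES:
            assert 0 <= counts.d_x(s) <= counts.l[s]
            assert counts.d_x(s) == sum(counts.deaths[s][c] for c in CAUSES)

    def test_parasitism_never_in_pre_window_stages(self):
        """Even adversarial evidence cannot place parasitism before the
        vulnerable window."""
        rec = stem(week=2, dead=[{EvidenceCode.PARASITOID_LARVA, EvidenceCode.MULTIPLE_EGGS}])
        counts = aggregate([rec])[0]
        assert counts.deaths[Stage.EGG][MortalityCause.PARASITISM] == 0
        assert counts.deaths[Stage.LARVA_I][MortalityCause.PARASITISM] == 0


class TestCsvRoundTrip:
    def test_well_formed_file(self, tmp_path):
        records = [stem(unit=f"u{i}", n_eggs=1) for i in range(3)]
        path = tmp_path / "r.csv"
        write_records(records, path)
        back, diagnostics = read_records(path)
        assert len(back) == 3 and diagnostics == []

    def test_malformed_row_rejected_with_diagnostic(self, tmp_path):
        path = tmp_path / "r.csv"
        write_records([stem(unit="ok")], path)
        text = path.read_text().splitlines()
        bad = text[1].replace("stem,3", "stem,")  # stem sample without a week
        path.write_text("\n".join(text + [bad]) + "\n")
        back, diagnostics = read_records(path)
        assert len(back) == 1
        assert len(diagnostics) == 1 and "row 1" in diagnostics[0]

    def test_unknown_evidence_code_named(self, tmp_path):
        path = tmp_path / "r.csv"
        write_records([stem(dead=[{EvidenceCode.DEAD_NEONATE}])], path)
        path.write_text(path.read_text().replace("DEAD_NEONATE", "MYSTERY_CODE"))
        back, diagnostics = read_records(path)
        assert back == [] and "MYSTERY_CODE" in diagnostics[0]

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("site,year\nA,2016\n")
        with pytest.raises(SchemaError):
            read_records(path)

    def test_simulator_output_round_trips_exactly(self, tmp_path):
        """Field-by-field identity through write -> read on ~1000 records."""
        config = SimulationConfig(
            n_sites=1, n_blocks=1, n_plots_per_block=4, stems_per_plot=1000,
            sampling="weekly", seed=5,
        )
        records, _ = simulate_cohort(config)
        assert len(records) > 500
        path = tmp_path / "sim.csv"
        write_records(records, path)
        back, diagnostics = read_records(path)
        assert diagnostics == []
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.site == b.site and a.year == b.year and a.unit_id == b.unit_id
            assert a.week == b.week and a.stub_phase == b.stub_phase
            assert a.n_eggs == b.n_eggs and a.n_live_larvae == b.n_live_larvae
            assert sorted(map(sorted, a.dead_observations)) == sorted(
                map(sorted, b.dead_observations)
            )
            assert a.emerged == b.emerged
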