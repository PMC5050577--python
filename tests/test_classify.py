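"""Phase realization from ROM explorations, VAS and pain."""

import random

import pytest

from rehabkb import (
    ExplorationBand,
    JointRef,
    MovementExploration,
    MovementType,
    PhysiotherapyRecord,
    Side,
    classify_patient,
    exploration_matches_band,
    phase_condition_satisfied,
)

GJ = JointRef("glenohumeral-joint")
LEFT_GJ = JointRef("glenohumeral-joint", Side.LEFT)


def flexion_record(rom, vas=0.0, pain=False, rid="r", ts=1):
    return PhysiotherapyRecord(
        id=rid, timestamp=ts, vas=vas,
        explorations=(MovementExploration(LEFT_GJ, MovementType.FLEXION, rom, pain),),
    )


def brute_force_classify(record, protocol):
    """Independent enumerator over every (exploration, band, phase) triple."""
    satisfied = set()
    for phase in protocol.phases:
        cond = phase.membership
        if cond is None:
            continue
        if cond.vas_upper_exclusive is not None and (
            record.vas is None or record.vas >= cond.vas_upper_exclusive
        ):
            continue
        hit = False
        for e in record.explorations:
            for band in cond.bands:
                if e.type is not band.type:
                    continue
                if band.location.joint_name != e.location.joint_name:
                    continue
                if band.location.side is not Side.UNSPECIFIED and band.location.side is not e.location.side:
                    continue
                if band.lower_inclusive is not None and e.rom_value < band.lower_inclusive:
                    continue
                if band.upper_exclusive is not None and e.rom_value >= band.upper_exclusive:
                    continue
                if cond.pain_false_required and e.pain:
                    continue
                hit = True
        if hit:
            satisfied.add(phase.number)
    return satisfied


class TestBandMatching:
    def test_flexion_80_below_90(self):
        band = ExplorationBand(GJ, MovementType.FLEXION, upper_exclusive=90)
        e = MovementExploration(LEFT_GJ, MovementType.FLEXION, 80, False)
        assert exploration_matches_band(e, band)

    def test_flexion_100_in_interval_pain_free(self):
        band = ExplorationBand(GJ, MovementType.FLEXION, lower_inclusive=90, upper_exclusive=144)
        e = MovementExploration(LEFT_GJ, MovementType.FLEXION, 100, False)
        assert exploration_matches_band(e, band, pain_false_required=True)

    def test_upper_bound_is_strict(self):
        band = ExplorationBand(GJ, MovementType.FLEXION, upper_exclusive=90)
        e = MovementExploration(LEFT_GJ, MovementType.FLEXION, 90, False)
        assert not exploration_matches_band(e, band)

    def test_pain_blocks_when_pain_free_required(self):
        band = ExplorationBand(GJ, MovementType.FLEXION, lower_inclusive=90, upper_exclusive=144)
        e = MovementExploration(LEFT_GJ, MovementType.FLEXION, 100, True)
        assert exploration_matches_band(e, band)
        assert not exploration_matches_band(e, band, pain_false_required=True)


class TestPhaseCondition:
    def test_worked_example_initial_record_is_phase2(self, fixture):
        cond = fixture.protocol.phase(2).membership
        assert phase_condition_satisfied(fixture.patient2015.latest_record, cond)

    def test_no_explorations_fails(self, fixture):
        cond = fixture.protocol.phase(2).membership
        rec = PhysiotherapyRecord(id="r", timestamp=1, vas=0.0)
        assert not phase_condition_satisfied(rec, cond)

    def test_vas_bound_is_strict(self, fixture):
        cond = fixture.protocol.phase(2).membership
        assert not phase_condition_satisfied(flexion_record(80, vas=3.0), cond)
        assert phase_condition_satisfied(flexion_record(80, vas=2.9), cond)

    def test_missing_vas_fails_bounded_condition(self, fixture):
        cond = fixture.protocol.phase(2).membership
        assert not phase_condition_satisfied(flexion_record(80, vas=None), cond)


class TestClassifyPatient:
    def test_initial_record_selects_phase2(self, fixture):
        a = classify_patient(fixture.patient2015.latest_record, fixture.protocol)
        assert a.satisfied_phases == {2} and a.selected_phase == 2

    def test_updated_record_moves_to_phase3(self, fixture):
        a = classify_patient(fixture.patient2015_updated.latest_record, fixture.protocol)
        assert a.selected_phase == 3
        assert 2 not in a.satisfied_phases

    def test_multi_phase_satisfaction_selects_minimum(self, fixture):
        rec = PhysiotherapyRecord(
            id="r", timestamp=1, vas=1.0,
            explorations=(
                MovementExploration(LEFT_GJ, MovementType.FLEXION, 80, False),
                MovementExploration(LEFT_GJ, MovementType.EXTENSION, 30, False),
            ),
        )
        a = classify_patient(rec, fixture.protocol)
        assert a.satisfied_phases == {2, 3} and a.selected_phase == 2

    def test_explanation_cites_matched_band(self, fixture):
        a = classify_patient(fixture.patient2015.latest_record, fixture.protocol)
        matches = a.explanation[2]
        assert any(m.band.type is MovementType.FLEXION and m.exploration.rom_value == 80
                   for m in matches)

    def test_pure_function_of_inputs(self, fixture):
        rec = fixture.patient2015.latest_record
        assert classify_patient(rec, fixture.protocol) == classify_patient(rec, fixture.protocol)

    def test_phase_bands_disjoint_on_integer_grid(self, fixture):
        """For every movement type covered by both phases, the phase-2 and
        phase-3 intervals share no integer ROM in 0..180."""
        p2 = fixture.protocol.phase(2).membership
        p3 = fixture.protocol.phase(3).membership
        for b2 in p2.bands:
            for b3 in p3.bands:
                if b2.type is not b3.type:
                    continue
                for rom in range(181):
                    e = MovementExploration(LEFT_GJ, b2.type, rom, False)
                    assert not (
                        exploration_matches_band(e, b2) and exploration_matches_band(e, b3)
                    ), (b2.type, rom)

    def test_rom_sweep_transitions_phase2_phase3_none(self, fixture):
        """Sweeping flexion ROM 0..180 (VAS 0, no pain) walks through phase 2,
        then phase 3, then no phase, with exactly two change points."""
        selected = [
            classify_patient(flexion_record(rom), fixture.protocol).selected_phase
            for rom in range(181)
        ]
        changes = [(a, b) for a, b in zip(selected, selected[1:]) if a != b]
        assert changes == [(2, 3), (3, None)]
        assert selected[0] == 2 and selected[180] is None

    def test_oracle_equivalence_on_random_records(self, fixture):
        from rehabkb.fixtures import GeneratorParams, generate_random_record

        rng = random.Random(123)
        for i in range(500):
            rec = generate_random_record(GeneratorParams(seed=i), rng)
            a = classify_patient(rec, fixture.protocol)
            assert a.satisfied_phases == brute_force_classify(rec, fixture.protocol)
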