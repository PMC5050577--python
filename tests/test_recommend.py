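"""Recommended / contraindicated / suitable exercise sets."""

import random

import pytest

from rehabkb import (
    ContainsMovement,
    HasPastHistory,
    InPhase,
    IsPatient,
    JointRef,
    MovementType,
    NamedSet,
    PastHistoryItem,
    Patient,
    PhysiotherapyRecord,
    Rule,
    Side,
    compose_exercise,
    exercise_in_class,
    patient_satisfies,
    recommend,
)
from rehabkb.recommend import UnknownProtocolError
from conftest import make_movement, sub

LEFT_GJ = JointRef("glenohumeral-joint", Side.LEFT)


def abduction_exercise(eid, rom_max, side=Side.LEFT):
    m = make_movement(f"{eid}-m", [sub("abduction", rom_max, side=side)], "a", "b")
    return compose_exercise(eid, eid, [m])


def brute_force_recommend(patient, rules, catalog, context):
    recommended, contraindicated = set(), set()
    for rule in rules:
        if not patient_satisfies(patient, rule.patient, context):
            continue
        for e in catalog:
            if exercise_in_class(e, rule.exercises, context):
                (recommended if rule.polarity == "recommended" else contraindicated).add(e.id)
    return recommended, contraindicated, recommended - contraindicated


class TestExerciseInClass:
    def test_abduction_above_threshold(self):
        expr = ContainsMovement(MovementType.ABDUCTION, LEFT_GJ, rom_max_greater_than=80)
        assert exercise_in_class(abduction_exercise("e", 90), expr, {})

    def test_threshold_is_strict(self):
        expr = ContainsMovement(MovementType.ABDUCTION, LEFT_GJ, rom_max_greater_than=80)
        assert not exercise_in_class(abduction_exercise("e", 80), expr, {})

    def test_reference_exercise_contains_no_extension(self, fixture):
        expr = ContainsMovement(MovementType.EXTENSION)
        assert not exercise_in_class(fixture.exercises["Exer2.1.5d"], expr, {})

    def test_phase_exercise_set_membership(self, fixture):
        from rehabkb import PhaseExerciseSet

        expr = PhaseExerciseSet(fixture.protocol.name, 2)
        assert exercise_in_class(fixture.exercises["Exer2.1.5d"], expr, fixture.protocols)

    def test_unknown_protocol_reference(self, fixture):
        from rehabkb import PhaseExerciseSet

        with pytest.raises(UnknownProtocolError):
            exercise_in_class(fixture.exercises["Exer2.1.5d"],
                              PhaseExerciseSet("no-such", 2), fixture.protocols)

    def test_sided_class_ignores_other_side(self):
        expr = ContainsMovement(MovementType.ABDUCTION, LEFT_GJ, rom_max_greater_than=80)
        assert not exercise_in_class(abduction_exercise("e", 90, side=Side.RIGHT), expr, {})


class TestPatientSatisfies:
    def test_personal_past_history_matches(self, fixture):
        pred = HasPastHistory("dislocation-of-glenohumeral-joint/left", "self")
        assert patient_satisfies(fixture.patient2015, pred, fixture.protocols)

    def test_relative_history_does_not_match_self_predicate(self, fixture):
        rec = PhysiotherapyRecord(
            id="r", timestamp=1,
            past_history=(PastHistoryItem("dislocation-of-glenohumeral-joint/left", "relative"),),
        )
        pred = HasPastHistory("dislocation-of-glenohumeral-joint/left", "self")
        assert not patient_satisfies(Patient("p", (rec,)), pred, fixture.protocols)

    def test_in_phase_uses_latest_record(self, fixture):
        pred2 = InPhase(fixture.protocol.name, 2)
        pred3 = InPhase(fixture.protocol.name, 3)
        assert patient_satisfies(fixture.patient2015, pred2, fixture.protocols)
        assert not patient_satisfies(fixture.patient2015, pred3, fixture.protocols)
        assert patient_satisfies(fixture.patient2015_updated, pred3, fixture.protocols)
        assert not patient_satisfies(fixture.patient2015_updated, pred2, fixture.protocols)

    def test_is_patient(self, fixture):
        assert patient_satisfies(fixture.patient2015, IsPatient("patient2015"), {})
        assert not patient_satisfies(fixture.patient2015, IsPatient("other"), {})


class TestRecommend:
    def test_phase2_patient_gets_phase2_exercises(self, fixture):
        res = recommend(fixture.patient2015, fixture.rules.values(),
                        fixture.catalog, fixture.protocols)
        assert "Exer2.1.5d" in res.recommended

    def test_contraindication_always_wins(self, fixture):
        """A phase-2-assigned left-sided abduction exercise above 80 degrees
        is both recommended (protocol rule) and contraindicated (past
        dislocation), hence not suitable."""
        from rehabkb import assign_exercise_to_phase

        risky = abduction_exercise("ExerRisky", 90)
        catalog = fixture.catalog + [risky]
        proto = assign_exercise_to_phase("ExerRisky", fixture.protocol.phase(2),
                                         fixture.protocol, catalog)
        res = recommend(fixture.patient2015, fixture.rules.values(),
                        catalog, {proto.name: proto})
        assert "ExerRisky" in res.recommended
        assert "ExerRisky" in res.contraindicated
        assert "ExerRisky" not in res.suitable

    def test_patient_specific_extension_ban(self, fixture):
        m = make_movement("mext", [sub("extension", 20)], "a", "b")
        ext_ex = compose_exercise("ExerExt", "extension", [m])
        res = recommend(fixture.patient2015, fixture.rules.values(),
                        fixture.catalog + [ext_ex], fixture.protocols)
        assert "ExerExt" in res.contraindicated

    def test_empty_rule_set(self, fixture):
        res = recommend(fixture.patient2015, [], fixture.catalog, fixture.protocols)
        assert res.recommended == res.contraindicated == res.suitable == frozenset()

    def test_fired_rules_record_contributions(self, fixture):
        res = recommend(fixture.patient2015, fixture.rules.values(),
                        fixture.catalog, fixture.protocols)
        fired = dict(res.fired_rules)
        assert fired["phase2-protocol"] == {"Exer2.1.5d"}


def _random_world(rng):
    catalog = [abduction_exercise(f"e{i}", rng.randint(0, 180),
                                  rng.choice(list(Side))) for i in range(rng.randint(0, 30))]
    history_pool = ["dislocation-of-glenohumeral-joint/left", "rotator-cuff-tear"]
    rules = []
    for i in range(rng.randint(0, 10)):
        pred = rng.choice([
            HasPastHistory(rng.choice(history_pool), rng.choice(["self", "relative"])),
            IsPatient(rng.choice(["p", "q"])),
        ])
        expr = rng.choice([
            ContainsMovement(MovementType.ABDUCTION,
                             rom_max_greater_than=rng.randint(0, 180)),
            NamedSet(frozenset(e.id for e in rng.sample(catalog, min(len(catalog), 3)))),
        ])
        rules.append(Rule(f"r{i}", pred, rng.choice(["recommended", "contraindicated"]),
                          expr, "general-knowledge"))
    rec = PhysiotherapyRecord(
        id="r", timestamp=1,
        past_history=tuple(
            PastHistoryItem(rng.choice(history_pool), rng.choice(["self", "relative"]))
            for _ in range(rng.randint(0, 2))
        ),
    )
    return Patient("p", (rec,)), rules, catalog


class TestRecommendProperties:
    def test_suitable_invariants_on_random_worlds(self):
        rng = random.Random(42)
        for _ in range(500):
            patient, rules, catalog = _random_world(rng)
            res = recommend(patient, rules, catalog, {})
            assert res.suitable <= res.recommended
            assert not res.suitable & res.contraindicated
            assert res.suitable == res.recommended - res.contraindicated

    def test_adding_contraindication_never_grows_suitable(self):
        rng = random.Random(77)
        for _ in range(100):
            patient, rules, catalog = _random_world(rng)
            base = recommend(patient, rules, catalog, {})
            extra = Rule("extra", IsPatient("p"), "contraindicated",
                         ContainsMovement(MovementType.ABDUCTION), "general-knowledge")
            more = recommend(patient, rules + [extra], catalog, {})
            assert more.suitable <= base.suitable

    def test_oracle_equivalence_on_random_worlds(self):
        rng = random.Random(4242)
        for _ in range(200):
            patient, rules, catalog = _random_world(rng)
            res = recommend(patient, rules, catalog, {})
            rec, contra, suit = brute_force_recommend(patient, rules, catalog, {})
            assert (set(res.recommended), set(res.contraindicated), set(res.suitable)) == (
                rec, contra, suit)
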