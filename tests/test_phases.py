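"""Allowed movements, candidate exercises, cap subsumption, assignment."""

import random

import pytest

from rehabkb import (
    AllowedMovementSpec,
    DuplicateAssignmentError,
    JointRef,
    ModeMismatchError,
    MovementType,
    NotACandidateError,
    PhaseSpec,
    RomCap,
    Side,
    allowed_subsumes,
    assign_exercise_to_phase,
    candidate_exercises,
    compose_exercise,
    movement_allowed,
)
from conftest import make_movement, random_movement, sub

GJ = JointRef("glenohumeral-joint")


def brute_force_allowed(m, spec):
    """Independent evaluator enumerating every (component, cap) pair."""
    def admits(cap, s):
        same_joint = cap.location.joint_name == s.location.joint_name
        side_ok = cap.location.side is Side.UNSPECIFIED or cap.location.side is s.location.side
        return cap.type is s.type and same_joint and side_ok and s.rom_max <= cap.max_rom_inclusive

    per_component = [any(admits(c, s) for c in spec.caps) for s in m.components]
    return any(per_component) if spec.mode == "existential" else all(per_component)


def brute_force_candidates(phase, catalog):
    out = []
    for e in catalog:
        if e.movements and all(brute_force_allowed(m, phase.allowed) for m in e.movements):
            out.append(e.id)
    return sorted(out)


def random_spec(rng, mode="existential", caps_from=None):
    caps = {}
    for t in rng.sample(list(MovementType), rng.randint(1, 6)):
        loc = JointRef(rng.choice(["glenohumeral-joint", "elbow-joint"]), rng.choice(list(Side)))
        caps[(loc, t)] = RomCap(loc, t, rng.randint(0, 180))
    return AllowedMovementSpec(caps=frozenset(caps.values()), mode=mode)


def random_catalog(rng, n):
    catalog = []
    for i in range(n):
        movements = [
            random_movement(rng, f"e{i}m{k}", initial=f"e{i}p{k}", final=f"e{i}p{k + 1}")
            for k in range(rng.randint(1, 3))
        ]
        catalog.append(compose_exercise(f"e{i}", f"e{i}", movements))
    return catalog


class TestMovementAllowed:
    def test_abduction_90_passes_phase2_cap(self, fixture):
        m = fixture.movements["Mov2.1.5d"]
        assert movement_allowed(m, fixture.protocol.phase(2).allowed)

    def test_diagonal_exceeds_every_phase3_cap(self, fixture):
        m = fixture.movements["Mov2.2.1z"]
        assert not movement_allowed(m, fixture.protocol.phase(3).allowed)

    def test_empty_cap_set_allows_nothing(self):
        m = make_movement("m", [sub("flexion", 10)])
        assert not movement_allowed(m, AllowedMovementSpec(caps=frozenset()))

    def test_existential_admits_partial_diagonal_strict_does_not(self):
        """A flexion-80 + abduction-170 diagonal passes phase-2 caps in the
        existential reading but not in the strict one."""
        m = make_movement("diag", [sub("flexion", 80), sub("abduction", 170)])
        caps = frozenset({RomCap(GJ, MovementType.FLEXION, 90),
                          RomCap(GJ, MovementType.ABDUCTION, 90)})
        assert movement_allowed(m, AllowedMovementSpec(caps=caps, mode="existential"))
        assert not movement_allowed(m, AllowedMovementSpec(caps=caps, mode="strict"))

    def test_sided_cap_does_not_match_other_side(self):
        cap = frozenset({RomCap(JointRef("glenohumeral-joint", Side.LEFT),
                                MovementType.FLEXION, 90)})
        left = make_movement("l", [sub("flexion", 50, side=Side.LEFT)])
        right = make_movement("r", [sub("flexion", 50, side=Side.RIGHT)])
        assert movement_allowed(left, AllowedMovementSpec(caps=cap))
        assert not movement_allowed(right, AllowedMovementSpec(caps=cap))


class TestCandidateExercises:
    def test_reference_exercise_is_a_phase2_candidate(self, fixture):
        assert candidate_exercises(fixture.protocol.phase(2), fixture.catalog) == ["Exer2.1.5d"]

    def test_one_disallowed_movement_poisons_the_exercise(self, fixture):
        diag = fixture.movements["Mov2.2.1z"]
        ex = compose_exercise("ExDiag", "diagonal", [diag])
        ids = candidate_exercises(fixture.protocol.phase(2), fixture.catalog + [ex])
        assert "ExDiag" not in ids and "Exer2.1.5d" in ids

    def test_empty_catalog(self, fixture):
        assert candidate_exercises(fixture.protocol.phase(2), []) == []

    def test_oracle_equivalence_on_random_worlds(self):
        rng = random.Random(20240917)
        for _ in range(60):
            phase = PhaseSpec(number=1, allowed=random_spec(rng, rng.choice(["existential", "strict"])))
            catalog = random_catalog(rng, rng.randint(0, 50))
            assert candidate_exercises(phase, catalog) == brute_force_candidates(phase, catalog)

    def test_strict_candidates_subset_of_existential(self):
        rng = random.Random(7)
        for _ in range(40):
            caps = random_spec(rng).caps
            catalog = random_catalog(rng, 20)
            strict = set(candidate_exercises(
                PhaseSpec(number=1, allowed=AllowedMovementSpec(caps=caps, mode="strict")), catalog))
            existential = set(candidate_exercises(
                PhaseSpec(number=1, allowed=AllowedMovementSpec(caps=caps, mode="existential")), catalog))
            assert strict <= existential


class TestAllowedSubsumes:
    def test_phase2_subsumed_by_phase3(self, fixture):
        p2, p3 = fixture.protocol.phase(2).allowed, fixture.protocol.phase(3).allowed
        assert allowed_subsumes(p2, p3)

    def test_reflexive(self, fixture):
        spec = fixture.protocol.phase(2).allowed
        assert allowed_subsumes(spec, spec)

    def test_phase3_not_subsumed_by_phase2(self, fixture):
        p2, p3 = fixture.protocol.phase(2).allowed, fixture.protocol.phase(3).allowed
        assert not allowed_subsumes(p3, p2)

    def test_mode_mismatch_raises(self, fixture, strict_fixture):
        with pytest.raises(ModeMismatchError):
            allowed_subsumes(fixture.protocol.phase(2).allowed,
                             strict_fixture.protocol.phase(2).allowed)

    def test_subsumption_implies_candidate_monotonicity(self, fixture):
        """Whenever caps dominate, candidates are contained — 200 random
        catalogs against the reference phase-2/phase-3 pair, plus random
        dominated spec pairs."""
        rng = random.Random(99)
        p2, p3 = fixture.protocol.phase(2), fixture.protocol.phase(3)
        assert allowed_subsumes(p2.allowed, p3.allowed)
        for _ in range(200):
            catalog = random_catalog(rng, rng.randint(0, 15))
            assert set(candidate_exercises(p2, catalog)) <= set(candidate_exercises(p3, catalog))
        for _ in range(50):
            a = random_spec(rng)
            grown = frozenset(
                RomCap(c.location, c.type, c.max_rom_inclusive + rng.randint(0, 50))
                for c in a.caps
            )
            b = AllowedMovementSpec(caps=grown)
            assert allowed_subsumes(a, b)
            catalog = random_catalog(rng, 10)
            ca = candidate_exercises(PhaseSpec(number=1, allowed=a), catalog)
            cb = candidate_exercises(PhaseSpec(number=1, allowed=b), catalog)
            assert set(ca) <= set(cb)


class TestAssignment:
    def test_assign_candidate_appends(self, fixture):
        proto = fixture.protocol
        m = fixture.movements["Mov2.1.5d"]
        ex = compose_exercise("ExerNew", "new", [m])
        catalog = fixture.catalog + [ex]
        updated = assign_exercise_to_phase("ExerNew", proto.phase(2), proto, catalog)
        assert updated.phase(2).assigned_exercises[-1] == "ExerNew"
        assert proto.phase(2).assigned_exercises[-1] != "ExerNew"  # input untouched

    def test_non_candidate_rejected(self, fixture):
        proto = fixture.protocol
        ex = compose_exercise("ExDiag", "diag", [fixture.movements["Mov2.2.1z"]])
        with pytest.raises(NotACandidateError):
            assign_exercise_to_phase("ExDiag", proto.phase(2), proto, fixture.catalog + [ex])

    def test_duplicate_assignment_rejected(self, fixture):
        proto = fixture.protocol
        with pytest.raises(DuplicateAssignmentError):
            assign_exercise_to_phase("Exer2.1.5d", proto.phase(2), proto, fixture.catalog)
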