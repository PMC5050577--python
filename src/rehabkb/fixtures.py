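"""Reference fixture (the worked shoulder-rehabilitation example) and
seeded random generators.

:func:`build_reference_fixture` constructs the limited-flexion-of-the-
glenohumeral-joint treatment protocol with its published phase-2 and
phase-3 conditions, the movement/exercise examples (an abduction of the
shoulder to 90 degrees and the exercise made of that movement plus its
inverse, a three-component diagonal), the general contraindication rule
for patients with a past shoulder dislocation, and the example patient
``patient2015`` with an initial and an updated record. Phases 1, 4 and 5
of the protocol are stubs — their conditions are not part of the reference
material — and are clearly marked as such.

The random generators produce seeded, reproducible worlds (movement
catalogs with posture-chained exercises, protocols with nested ROM caps so
inter-phase subsumption is exercisable, and patient records) used as test
substrate by every other module.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .anatomy import ConceptGraph, ConceptNode
from .classify import ExplorationBand, PhaseMembershipCondition
from .model import (
    Exercise,
    JointRef,
    Movement,
    MovementExploration,
    MovementType,
    PastHistoryItem,
    Patient,
    PhysiotherapyRecord,
    Posture,
    Side,
    Submovement,
    compose_exercise,
    inverse_movement,
)
from .phases import AllowedMovementSpec, PhaseSpec, ProtocolSpec, RomCap
from .recommend import (
    ContainsMovement,
    HasPastHistory,
    InPhase,
    IsPatient,
    PhaseExerciseSet,
    Rule,
)
from .serialization import ModelBundle

__all__ = [
    "FixtureSet",
    "GeneratorParams",
    "build_reference_fixture",
    "build_paper_fixture",
    "build_anatomy_fixture",
    "generate_random_world",
    "generate_random_record",
    "PHASE2_CAPS",
    "PHASE3_CAPS",
    "PHASE2_VAS_BOUND",
    "DISLOCATION_ROM_THRESHOLD",
]

GJ = "glenohumeral-joint"

# Phase ROM caps (degrees, inclusive) of the limited-flexion protocol.
PHASE2_CAPS: dict[MovementType, float] = {
    MovementType.FLEXION: 90,
    MovementType.EXTENSION: 25,
    MovementType.ABDUCTION: 90,
    MovementType.ADDUCTION: 27,
    MovementType.INTERNAL_ROTATION: 45,
    MovementType.EXTERNAL_ROTATION: 55,
}
PHASE3_CAPS: dict[MovementType, float] = {
    MovementType.FLEXION: 144,
    MovementType.EXTENSION: 40,
    MovementType.ABDUCTION: 144,
    MovementType.ADDUCTION: 36,
    MovementType.INTERNAL_ROTATION: 72,
    MovementType.EXTERNAL_ROTATION: 88,
    MovementType.HORIZONTAL_ABDUCTION: 32,
    MovementType.HORIZONTAL_ADDUCTION: 112,
}
PHASE2_VAS_BOUND = 3.0
DISLOCATION_ROM_THRESHOLD = 80.0


@dataclass(frozen=True)
class FixtureSet:
    """The reference entities, ready for use by every module."""

    movements: dict[str, Movement]
    exercises: dict[str, Exercise]
    protocol: ProtocolSpec
    rules: dict[str, Rule]
    patient2015: Patient
    patient2015_updated: Patient
    anatomy: ConceptGraph

    @property
    def catalog(self) -> list[Exercise]:
        return list(self.exercises.values())

    @property
    def protocols(self) -> dict[str, ProtocolSpec]:
        return {self.protocol.name: self.protocol}


def _phase2_condition() -> PhaseMembershipCondition:
    gj = JointRef(GJ)
    bands = {
        ExplorationBand(gj, t, upper_exclusive=cap) for t, cap in PHASE2_CAPS.items()
    }
    return PhaseMembershipCondition(
        bands=frozenset(bands),
        vas_upper_exclusive=PHASE2_VAS_BOUND,
        pain_false_required=False,
    )


def _phase3_condition() -> PhaseMembershipCondition:
    # Intervals "between A and B" with the phase-2 cap as the lower bound and
    # the phase-3 cap as the exclusive upper bound; movement types new in
    # phase 3 get a pure upper bound. Pain-free is required; no VAS bound.
    gj = JointRef(GJ)
    bands = set()
    for t, cap3 in PHASE3_CAPS.items():
        lower = PHASE2_CAPS.get(t)
        bands.add(ExplorationBand(gj, t, lower_inclusive=lower, upper_exclusive=cap3))
    return PhaseMembershipCondition(
        bands=frozenset(bands),
        vas_upper_exclusive=None,
        pain_false_required=True,
    )


def _caps_spec(caps: dict[MovementType, float], mode: str = "existential") -> AllowedMovementSpec:
    gj = JointRef(GJ)
    return AllowedMovementSpec(
        caps=frozenset(RomCap(gj, t, v) for t, v in caps.items()), mode=mode
    )


def build_reference_fixture(mode: str = "existential") -> FixtureSet:
    """Construct the worked shoulder-rehabilitation example."""
    gj = JointRef(GJ)
    arms_on_sides = Posture("arms-on-sides", "Arms on the sides")
    arm_abducted = Posture("arm-abducted-90", "Arm remains separated 90 degrees from the trunk")

    mov_abd90 = Movement(
        id="Mov2.1.5d",
        name="Abduction of the shoulder at 90 degrees",
        initial=arms_on_sides,
        final=arm_abducted,
        components=frozenset({Submovement(gj, MovementType.ABDUCTION, 0, 90)}),
    )
    mov_abd90_inv = inverse_movement(mov_abd90)

    diag_initial = Posture("diagonal-initial", "The initial posture for the diagonal")
    diag_final = Posture("arm-flexed-adducted", "Arm flexed and adducted")
    mov_diagonal = Movement(
        id="Mov2.2.1z",
        name="Diagonal of flexion, adduction and external rotation",
        initial=diag_initial,
        final=diag_final,
        components=frozenset(
            {
                Submovement(gj, MovementType.FLEXION, 0, 180),
                Submovement(gj, MovementType.ADDUCTION, 0, 50),
                Submovement(gj, MovementType.EXTERNAL_ROTATION, 0, 90),
            }
        ),
    )

    exer_abd = compose_exercise(
        "Exer2.1.5d", "Abduction of the shoulder to 90 degrees and back",
        [mov_abd90, mov_abd90_inv],
    )

    stub = AllowedMovementSpec(caps=frozenset(), mode=mode)
    protocol = ProtocolSpec(
        name="limited-flexion-glenohumeral-joint",
        disorder="limited-flexion-of-glenohumeral-joint",
        phases=(
            PhaseSpec(number=1, allowed=stub),  # stub: conditions not defined
            PhaseSpec(
                number=2,
                allowed=_caps_spec(PHASE2_CAPS, mode),
                assigned_exercises=("Exer2.1.5d",),
                series=4,
                membership=_phase2_condition(),
            ),
            PhaseSpec(
                number=3,
                allowed=_caps_spec(PHASE3_CAPS, mode),
                membership=_phase3_condition(),
            ),
            PhaseSpec(number=4, allowed=stub),  # stub
            PhaseSpec(number=5, allowed=stub),  # stub
        ),
    )

    rules = {
        "phase2-protocol": Rule(
            id="phase2-protocol",
            patient=InPhase(protocol.name, 2),
            polarity="recommended",
            exercises=PhaseExerciseSet(protocol.name, 2),
            provenance="protocol-derived",
        ),
        "phase3-protocol": Rule(
            id="phase3-protocol",
            patient=InPhase(protocol.name, 3),
            polarity="recommended",
            exercises=PhaseExerciseSet(protocol.name, 3),
            provenance="protocol-derived",
        ),
        "past-dislocation-left-gj": Rule(
            id="past-dislocation-left-gj",
            patient=HasPastHistory("dislocation-of-glenohumeral-joint/left", "self"),
            polarity="contraindicated",
            exercises=ContainsMovement(
                MovementType.ABDUCTION,
                location=JointRef(GJ, Side.LEFT),
                rom_max_greater_than=DISLOCATION_ROM_THRESHOLD,
            ),
            provenance="general-knowledge",
        ),
        "patient2015-no-extension": Rule(
            id="patient2015-no-extension",
            patient=IsPatient("patient2015"),
            polarity="contraindicated",
            exercises=ContainsMovement(MovementType.EXTENSION),
            provenance="physiotherapist-entered",
        ),
    }

    left_gj = JointRef(GJ, Side.LEFT)
    dislocation = PastHistoryItem("dislocation-of-glenohumeral-joint/left", "self")
    record_initial = PhysiotherapyRecord(
        id="record2015",
        timestamp=1,
        vas=0.0,
        explorations=(MovementExploration(left_gj, MovementType.FLEXION, 80, False),),
        past_history=(dislocation,),
    )
    record_updated = PhysiotherapyRecord(
        id="record2015b",
        timestamp=2,
        vas=0.0,
        explorations=(MovementExploration(left_gj, MovementType.FLEXION, 100, False),),
        past_history=(dislocation,),
    )
    patient_initial = Patient("patient2015", (record_initial,))
    patient_updated = Patient("patient2015", (record_initial, record_updated))

    return FixtureSet(
        movements={m.id: m for m in (mov_abd90, mov_abd90_inv, mov_diagonal)},
        exercises={exer_abd.id: exer_abd},
        protocol=protocol,
        rules=rules,
        patient2015=patient_initial,
        patient2015_updated=patient_updated,
        anatomy=build_anatomy_fixture(),
    )


# kept as an alias used throughout the tests
build_paper_fixture = build_reference_fixture


def build_anatomy_fixture() -> ConceptGraph:
    """A synthetic anatomy taxonomy (~50 concepts) around a glenohumeral
    joint stand-in, with left/right sided duplicates, a partonomy, and
    symmetric articulates_with / continuous_with edges. It imitates the
    shape of a reference anatomy ontology, not its content."""
    g = ConceptGraph()

    def node(cid: str, label: str = "", lat: Optional[str] = None, parent: Optional[str] = None):
        g.add_node(ConceptNode(cid, label or cid.replace("-", " "), laterality=lat))
        if parent:
            g.add_is_a(cid, parent)

    node("anatomical-entity")
    node("material-anatomical-entity", parent="anatomical-entity")
    node("body", parent="material-anatomical-entity")
    node("organ-system", parent="material-anatomical-entity")
    node("skeletal-system", parent="organ-system")
    node("articular-system", parent="organ-system")
    node("nervous-system", parent="organ-system")
    node("muscular-system", parent="organ-system")
    node("limb", parent="body")
    node("upper-limb", parent="limb")
    node("shoulder-region", parent="upper-limb")
    node("joint", parent="articular-system")
    node("synovial-joint", parent="joint")
    node("bone", parent="skeletal-system")
    node("muscle", parent="muscular-system")
    node("nerve", parent="nervous-system")
    node("ligament", parent="articular-system")
    node("cartilage", parent="articular-system")
    node("joint-capsule", parent="articular-system")
    node("vertebral-column", parent="skeletal-system")

    sided = [
        ("glenohumeral-joint", "synovial-joint"),
        ("humerus", "bone"),
        ("scapula", "bone"),
        ("clavicle", "bone"),
        ("head-of-humerus", "bone"),
        ("glenoid-cavity", "bone"),
        ("capsule-of-glenohumeral-joint", "joint-capsule"),
        ("glenohumeral-ligament", "ligament"),
        ("glenoid-labrum", "cartilage"),
        ("deltoid-muscle", "muscle"),
        ("supraspinatus-muscle", "muscle"),
        ("axillary-nerve", "nerve"),
        ("suprascapular-nerve", "nerve"),
        ("acromioclavicular-joint", "synovial-joint"),
    ]
    for base, parent in sided:
        node(base, parent=parent)
        for side in ("left", "right"):
            node(f"{side}-{base}", lat=side, parent=base)

    for side in ("left", "right"):
        gj = f"{side}-glenohumeral-joint"
        for part in ("head-of-humerus", "glenoid-cavity", "capsule-of-glenohumeral-joint",
                     "glenohumeral-ligament", "glenoid-labrum"):
            g.add_edge(gj, "constitutional_part", f"{side}-{part}")
        g.add_edge(f"{side}-head-of-humerus", "constitutional_part_of", f"{side}-humerus")
        g.add_edge(f"{side}-glenoid-cavity", "constitutional_part_of", f"{side}-scapula")
        g.add_edge(f"{side}-humerus", "articulates_with", f"{side}-scapula")
        g.add_edge(f"{side}-scapula", "articulates_with", f"{side}-clavicle")
        g.add_edge(gj, "nerve_supply", f"{side}-axillary-nerve")
        g.add_edge(gj, "nerve_supply", f"{side}-suprascapular-nerve")
        g.add_edge(f"{side}-glenoid-labrum", "continuous_with", f"{side}-glenoid-cavity")
    return g


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the random-world generator; all randomness flows from seed."""

    seed: int
    n_movements: int = 20
    n_exercises: int = 10
    n_records: int = 5
    rom_grid: tuple[int, int] = (0, 180)
    p_multi_component: float = 0.3
    p_pain: float = 0.3

    def __post_init__(self) -> None:
        if min(self.n_movements, self.n_exercises, self.n_records) < 1:
            raise ValueError("counts must be positive")
        for p in (self.p_multi_component, self.p_pain):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be within [0, 1]")


_JOINTS = [GJ, "elbow-joint", "knee-joint"]


def _random_submovement(rng: random.Random, params: GeneratorParams) -> Submovement:
    lo, hi = params.rom_grid
    a, b = sorted((rng.randint(lo, hi), rng.randint(lo, hi)))
    return Submovement(
        location=JointRef(rng.choice(_JOINTS), rng.choice(list(Side))),
        type=rng.choice(list(MovementType)),
        rom_min=a,
        rom_max=b,
    )


def _random_movement(rng: random.Random, params: GeneratorParams, mid: str,
                     initial: Posture, final: Posture) -> Movement:
    n = 1 + (rng.randint(1, 3) if rng.random() < params.p_multi_component else 0)
    comps = set()
    while len(comps) < n:
        comps.add(_random_submovement(rng, params))
    return Movement(id=mid, name=f"random movement {mid}", initial=initial,
                    final=final, components=frozenset(comps))


def generate_random_record(params: GeneratorParams, rng: Optional[random.Random] = None,
                           record_id: str = "r0", timestamp: int = 1) -> PhysiotherapyRecord:
    """A seeded random record: 0-6 explorations, optional VAS on a 0.1 grid,
    optional past-history items; always passes record validation."""
    rng = rng or random.Random(params.seed)
    lo, hi = params.rom_grid
    explorations = tuple(
        MovementExploration(
            location=JointRef(rng.choice(_JOINTS), rng.choice(list(Side))),
            type=rng.choice(list(MovementType)),
            rom_value=rng.randint(lo, hi),
            pain=rng.random() < params.p_pain,
        )
        for _ in range(rng.randint(0, 6))
    )
    history = tuple(
        PastHistoryItem(rng.choice(["dislocation-of-glenohumeral-joint/left",
                                    "rotator-cuff-tear", "frozen-shoulder"]),
                        rng.choice(["self", "relative"]))
        for _ in range(rng.randint(0, 2))
    )
    return PhysiotherapyRecord(
        id=record_id,
        timestamp=timestamp,
        age=rng.randint(10, 90) if rng.random() < 0.8 else None,
        vas=round(rng.uniform(0, 10), 1) if rng.random() < 0.8 else None,
        explorations=explorations,
        past_history=history,
    )


def generate_random_world(params: GeneratorParams) -> ModelBundle:
    """A seeded random bundle: chained exercises over a movement catalog, a
    protocol whose successive phases have nested (non-shrinking) ROM caps,
    and random patients. Pure function of the seed."""
    rng = random.Random(params.seed)

    movements: dict[str, Movement] = {}
    exercises: dict[str, Exercise] = {}
    per_exercise = max(1, params.n_movements // params.n_exercises)
    mcount = 0
    for ei in range(params.n_exercises):
        length = rng.randint(1, min(4, per_exercise + 1))
        postures = [Posture(f"p{ei}-{k}") for k in range(length + 1)]
        seq = []
        for k in range(length):
            mid = f"m{mcount}"
            mcount += 1
            mv = _random_movement(rng, params, mid, postures[k], postures[k + 1])
            movements[mid] = mv
            seq.append(mv)
        ex = compose_exercise(f"e{ei}", f"random exercise {ei}", seq)
        exercises[ex.id] = ex

    # nested caps: phase k+1 caps = phase k caps grown by a random slack,
    # possibly with extra movement types, so subsumption holds by design
    gj = JointRef(GJ)
    base = {
        t: float(rng.randint(20, 90))
        for t in rng.sample(list(MovementType), rng.randint(3, 6))
    }
    phases = []
    caps = dict(base)
    n_phases = rng.randint(2, 4)
    for num in range(1, n_phases + 1):
        spec = AllowedMovementSpec(
            caps=frozenset(RomCap(gj, t, v) for t, v in caps.items())
        )
        bands = frozenset(
            ExplorationBand(gj, t, upper_exclusive=v) for t, v in caps.items()
        )
        phases.append(
            PhaseSpec(
                number=num,
                allowed=spec,
                series=rng.randint(1, 5),
                membership=PhaseMembershipCondition(
                    bands=bands,
                    vas_upper_exclusive=float(rng.randint(1, 10)),
                    pain_false_required=rng.random() < 0.5,
                ),
            )
        )
        caps = {t: v + rng.randint(0, 40) for t, v in caps.items()}
        for t in MovementType:
            if t not in caps and rng.random() < 0.2:
                caps[t] = float(rng.randint(20, 180))
    protocol = ProtocolSpec(name="random-protocol", disorder="random-disorder",
                            phases=tuple(phases))

    patients = {}
    for pi in range(params.n_records):
        rec = generate_random_record(params, rng, record_id=f"rec{pi}", timestamp=1)
        patients[f"pat{pi}"] = Patient(f"pat{pi}", (rec,))

    return ModelBundle(
        movements=movements,
        exercises=exercises,
        protocols={protocol.name: protocol},
        rules={},
        patients=patients,
        anatomy=None,
    )
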