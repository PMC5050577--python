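"""Rule-based recommended / contraindicated / suitable exercise sets.

A rule pairs a patient predicate (is the patient in phase n of a protocol?
do they have a personal past history of some condition? are they a named
patient?) with an exercise class expression (exercises containing a
movement of some type, optionally on a joint and above a ROM threshold;
the exercises assigned to a phase; an explicit id set) and a polarity.

For a patient p, the recommended set is the union of catalog exercises
falling under the class expressions of satisfied recommended-polarity
rules; contraindicated likewise; and

    suitable(p) = recommended(p) - contraindicated(p)

so a contraindication always wins — there are no rule priorities. Rules
carry a provenance tag (protocol-derived, general physiotherapy knowledge,
or entered by the physiotherapist for one patient).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

from .classify import classify_patient
from .model import Exercise, JointRef, MovementType, Patient, Side
from .phases import ProtocolSpec, _location_matches

__all__ = [
    "InPhase",
    "HasPastHistory",
    "IsPatient",
    "AllOf",
    "ContainsMovement",
    "PhaseExerciseSet",
    "NamedSet",
    "AllOfExercise",
    "Rule",
    "RecommendationResult",
    "UnknownProtocolError",
    "exercise_in_class",
    "patient_satisfies",
    "recommend",
]

ProtocolContext = Mapping[str, ProtocolSpec]


class UnknownProtocolError(KeyError):
    pass


# --------------------------------------------------------------------------
# patient predicates

@dataclass(frozen=True)
class InPhase:
    """Patient's latest record satisfies the membership condition of the
    given phase of the given protocol."""

    protocol: str
    phase_number: int


@dataclass(frozen=True)
class HasPastHistory:
    """Some record carries a personal (subject) past-history item with the
    given condition identifier."""

    condition: str
    subject: str = "self"


@dataclass(frozen=True)
class IsPatient:
    patient_id: str


@dataclass(frozen=True)
class AllOf:
    predicates: tuple["PatientPredicate", ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "predicates", tuple(self.predicates))
        if not self.predicates:
            raise ValueError("conjunction must be non-empty")


PatientPredicate = Union[InPhase, HasPastHistory, IsPatient, AllOf]


# --------------------------------------------------------------------------
# exercise class expressions

@dataclass(frozen=True)
class ContainsMovement:
    """Exercises containing a movement with a submovement of the given type
    (and joint, when given), with rom_max strictly greater than the
    threshold when one is given."""

    type: MovementType
    location: Optional[JointRef] = None
    rom_max_greater_than: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rom_max_greater_than is not None and self.rom_max_greater_than < 0:
            raise ValueError("threshold must be >= 0")


@dataclass(frozen=True)
class PhaseExerciseSet:
    """The exercises assigned to a phase of a protocol."""

    protocol: str
    phase_number: int


@dataclass(frozen=True)
class NamedSet:
    ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", frozenset(self.ids))


@dataclass(frozen=True)
class AllOfExercise:
    exprs: tuple["ExerciseClassExpr", ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exprs", tuple(self.exprs))
        if not self.exprs:
            raise ValueError("conjunction must be non-empty")


ExerciseClassExpr = Union[ContainsMovement, PhaseExerciseSet, NamedSet, AllOfExercise]


@dataclass(frozen=True)
class Rule:
    id: str
    patient: PatientPredicate
    polarity: str  # "recommended" | "contraindicated"
    exercises: ExerciseClassExpr
    provenance: str = "physiotherapist-entered"

    def __post_init__(self) -> None:
        if self.polarity not in ("recommended", "contraindicated"):
            raise ValueError(f"polarity must be recommended/contraindicated, got {self.polarity!r}")
        if self.provenance not in ("protocol-derived", "general-knowledge", "physiotherapist-entered"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass(frozen=True)
class RecommendationResult:
    recommended: frozenset[str]
    contraindicated: frozenset[str]
    suitable: frozenset[str]
    fired_rules: tuple[tuple[str, frozenset[str]], ...]  # (rule id, contributed ids)

    def __post_init__(self) -> None:
        if self.suitable != self.recommended - self.contraindicated:
            raise ValueError("suitable must equal recommended - contraindicated")


def _phase_of(context: ProtocolContext, protocol: str, number: int):
    try:
        proto = context[protocol]
    except KeyError:
        raise UnknownProtocolError(f"unknown protocol {protocol!r}")
    try:
        return proto, proto.phase(number)
    except KeyError:
        raise UnknownProtocolError(f"protocol {protocol!r} has no phase {number}")


def exercise_in_class(e: Exercise, expr: ExerciseClassExpr, context: ProtocolContext) -> bool:
    """Does exercise ``e`` fall under the class expression ``expr``?"""
    if isinstance(expr, ContainsMovement):
        for m in e.movements:
            for sub in m.components:
                if sub.type is not expr.type:
                    continue
                if expr.location is not None and not _location_matches(expr.location, sub.location):
                    continue
                if expr.rom_max_greater_than is not None and not sub.rom_max > expr.rom_max_greater_than:
                    continue
                return True
        return False
    if isinstance(expr, PhaseExerciseSet):
        _, phase = _phase_of(context, expr.protocol, expr.phase_number)
        return e.id in phase.assigned_exercises
    if isinstance(expr, NamedSet):
        return e.id in expr.ids
    if isinstance(expr, AllOfExercise):
        return all(exercise_in_class(e, sub, context) for sub in expr.exprs)
    raise TypeError(f"unknown exercise class expression {expr!r}")


def patient_satisfies(patient: Patient, pred: PatientPredicate, context: ProtocolContext) -> bool:
    """Does the patient satisfy the predicate? in-phase is evaluated on the
    latest record via the phase classifier; past history looks for a
    matching item with the stated subject in any record."""
    if isinstance(pred, InPhase):
        proto, _ = _phase_of(context, pred.protocol, pred.phase_number)
        assignment = classify_patient(patient.latest_record, proto)
        return pred.phase_number in assignment.satisfied_phases
    if isinstance(pred, HasPastHistory):
        return any(
            item.condition == pred.condition and item.subject == pred.subject
            for r in patient.records
            for item in r.past_history
        )
    if isinstance(pred, IsPatient):
        return patient.id == pred.patient_id
    if isinstance(pred, AllOf):
        return all(patient_satisfies(patient, p, context) for p in pred.predicates)
    raise TypeError(f"unknown patient predicate {pred!r}")


def recommend(
    patient: Patient,
    rules: Iterable[Rule],
    catalog: Iterable[Exercise],
    context: ProtocolContext,
) -> RecommendationResult:
    """Compute the recommended, contraindicated and suitable exercise sets
    for a patient.

    Every rule whose patient predicate the patient satisfies contributes
    all catalog exercises falling under its exercise class expression to
    the set of its polarity; suitable is the set difference. ``fired_rules``
    records, in rule-id order, what each satisfied rule contributed.
    """
    catalog = list(catalog)
    recommended: set[str] = set()
    contraindicated: set[str] = set()
    fired: list[tuple[str, frozenset[str]]] = []
    for rule in sorted(rules, key=lambda r: r.id):
        if not patient_satisfies(patient, rule.patient, context):
            continue
        contributed = frozenset(
            e.id for e in catalog if exercise_in_class(e, rule.exercises, context)
        )
        fired.append((rule.id, contributed))
        if rule.polarity == "recommended":
            recommended |= contributed
        else:
            contraindicated |= contributed
    return RecommendationResult(
        recommended=frozenset(recommended),
        contraindicated=frozenset(contraindicated),
        suitable=frozenset(recommended - contraindicated),
        fired_rules=tuple(fired),
    )
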