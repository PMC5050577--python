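"""Treatment protocols, allowed-movement caps and candidate-exercise logic.

A treatment protocol is an ordered sequence of phases. Each phase carries

* ROM caps — the maximal range of motion allowed per (joint, movement type)
  during that phase;
* an ordered list of exercises assigned to the phase;
* a membership condition deciding when a patient is *in* the phase (see
  :mod:`rehabkb.classify`).

A movement is *allowed* in a phase when it complies with the phase's caps,
and an exercise is a *candidate* for the phase when all of its movements
are allowed (and it has at least one). Because later phases relax every
cap of earlier ones, the candidate set of an earlier phase is contained in
that of a later phase — physiotherapists can always fall back on milder
exercises, e.g. to warm the joint up; :func:`allowed_subsumes` checks the
cap dominance that guarantees this containment.

Two readings of "complies with the caps" are supported. The default,
``existential``, admits a movement as soon as *some* submovement falls
under a cap, which matches the class-expression semantics the model is
drawn from. The ``strict`` mode requires *every* submovement to fall under
a cap for its own joint and type; it is stricter for multi-submovement
diagonals (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Optional

from .model import Exercise, JointRef, Movement, MovementType, Side, Submovement

if TYPE_CHECKING:  # pragma: no cover
    from .classify import PhaseMembershipCondition

__all__ = [
    "RomCap",
    "AllowedMovementSpec",
    "PhaseSpec",
    "ProtocolSpec",
    "ModeMismatchError",
    "NotACandidateError",
    "DuplicateAssignmentError",
    "movement_allowed",
    "candidate_exercises",
    "allowed_subsumes",
    "assign_exercise_to_phase",
]


@dataclass(frozen=True)
class RomCap:
    """Maximal ROM (inclusive, degrees) for one (joint, movement type)."""

    location: JointRef
    type: MovementType
    max_rom_inclusive: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "max_rom_inclusive", float(self.max_rom_inclusive))
        if self.max_rom_inclusive < 0:
            raise ValueError("max_rom_inclusive must be >= 0")


def _location_matches(cap_loc: JointRef, loc: JointRef) -> bool:
    # an unspecified side in the cap matches either side
    if cap_loc.joint_name != loc.joint_name:
        return False
    return cap_loc.side is Side.UNSPECIFIED or cap_loc.side is loc.side


def _cap_admits(cap: RomCap, sub: Submovement) -> bool:
    return (
        cap.type is sub.type
        and _location_matches(cap.location, sub.location)
        and sub.rom_max <= cap.max_rom_inclusive
    )


@dataclass(frozen=True)
class AllowedMovementSpec:
    """The set of ROM caps defining which movements a phase allows."""

    caps: frozenset[RomCap]
    mode: str = "existential"  # "existential" | "strict"

    def __post_init__(self) -> None:
        object.__setattr__(self, "caps", frozenset(self.caps))
        if self.mode not in ("existential", "strict"):
            raise ValueError(f"mode must be 'existential' or 'strict', got {self.mode!r}")
        keys = [(c.location, c.type) for c in self.caps]
        if len(keys) != len(set(keys)):
            raise ValueError("at most one cap per (location, movement type) pair")


class ModeMismatchError(ValueError):
    pass


class NotACandidateError(ValueError):
    pass


class DuplicateAssignmentError(ValueError):
    pass


@dataclass(frozen=True)
class PhaseSpec:
    """One phase: caps, assigned exercises (ordered), series count, and the
    membership condition used by the patient classifier (None for stub
    phases whose conditions are not defined)."""

    number: int
    allowed: AllowedMovementSpec
    assigned_exercises: tuple[str, ...] = ()
    series: int = 1
    membership: Optional["PhaseMembershipCondition"] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "assigned_exercises", tuple(self.assigned_exercises))
        if self.number < 1:
            raise ValueError("phase number must be >= 1")
        if self.series < 1:
            raise ValueError("series must be >= 1")


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered sequence of phases treating one disorder."""

    name: str
    disorder: str
    phases: tuple[PhaseSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        nums = [p.number for p in self.phases]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(f"phase numbers must be strictly increasing, got {nums}")

    def phase(self, number: int) -> PhaseSpec:
        for p in self.phases:
            if p.number == number:
                return p
        raise KeyError(f"protocol {self.name!r} has no phase {number}")


def movement_allowed(m: Movement, spec: AllowedMovementSpec) -> bool:
    """Is movement ``m`` allowed under ``spec``?

    existential mode: at least one submovement falls under some cap (same
    joint and type, rom_max at or below the cap). strict mode: every
    submovement falls under a cap for its own (joint, type).
    """
    if spec.mode == "existential":
        return any(_cap_admits(cap, sub) for sub in m.components for cap in spec.caps)
    return all(any(_cap_admits(cap, sub) for cap in spec.caps) for sub in m.components)


def candidate_exercises(phase: PhaseSpec, catalog: Iterable[Exercise]) -> list[str]:
    """Exercise ids from ``catalog`` that are candidates for ``phase``: at
    least one movement, and every movement allowed. Sorted by id for
    deterministic output."""
    out = [
        e.id
        for e in catalog
        if e.movements and all(movement_allowed(m, phase.allowed) for m in e.movements)
    ]
    return sorted(out)


def _dominated(cap: RomCap, caps: frozenset[RomCap]) -> bool:
    for other in caps:
        if (
            other.type is cap.type
            and other.location.joint_name == cap.location.joint_name
            and (other.location.side is Side.UNSPECIFIED or other.location.side is cap.location.side)
            and other.max_rom_inclusive >= cap.max_rom_inclusive
        ):
            return True
    return False


def allowed_subsumes(a: AllowedMovementSpec, b: AllowedMovementSpec) -> bool:
    """True when every cap of ``a`` is dominated by a cap of ``b`` (same
    joint and type, at least as large a ROM bound).

    When true, every movement allowed under ``a`` is allowed under ``b``,
    hence candidate exercises under ``a`` are a subset of those under ``b``
    for any catalog — earlier-phase candidates remain available in later
    phases.
    """
    if a.mode != b.mode:
        raise ModeMismatchError(f"cannot compare specs with modes {a.mode!r} and {b.mode!r}")
    return all(_dominated(cap, b.caps) for cap in a.caps)


def assign_exercise_to_phase(
    exercise_id: str,
    phase: PhaseSpec,
    protocol: ProtocolSpec,
    catalog: Iterable[Exercise],
) -> ProtocolSpec:
    """Assign a candidate exercise to a phase, returning the updated protocol.

    The exercise must currently be a candidate for the phase (checked
    against ``catalog``) and not already assigned; it is appended at the
    next order index. The assignment becomes an explicit axiom on export.
    """
    if exercise_id in phase.assigned_exercises:
        raise DuplicateAssignmentError(
            f"exercise {exercise_id!r} already assigned to phase {phase.number}"
        )
    if exercise_id not in candidate_exercises(phase, catalog):
        raise NotACandidateError(
            f"exercise {exercise_id!r} is not a candidate for phase {phase.number}"
        )
    new_phase = replace(phase, assigned_exercises=phase.assigned_exercises + (exercise_id,))
    new_phases = tuple(new_phase if p.number == phase.number else p for p in protocol.phases)
    return replace(protocol, phases=new_phases)
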