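"""Core domain model for physiotherapy rehabilitation knowledge.

The vocabulary mirrors how physiotherapists describe treatment elements:

* a **movement** is a transition between two postures, composed of one or
  more **submovements** that happen simultaneously (diagonals and bilateral
  movements bundle several joint/movement-type/range triplets);
* an **exercise** is an ordered sequence of movements whose postures chain
  (the final posture of each movement is the initial posture of the next);
* a **physiotherapy record** is a snapshot of answers about one patient at
  one moment: age, reported pain on the Visual Analogue Scale (VAS),
  range-of-motion (ROM) explorations per joint and movement type, past
  history items, goals and diagnosis.

Records are immutable snapshots; a patient's evolution is represented by
appending new records with later timestamps, never by mutating old ones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "MovementType",
    "Side",
    "JointRef",
    "Posture",
    "Submovement",
    "Movement",
    "Exercise",
    "MovementExploration",
    "PastHistoryItem",
    "PhysiotherapyRecord",
    "Patient",
    "Violation",
    "ChainingError",
    "validate_record",
    "inverse_movement",
    "compose_exercise",
]


class MovementType(str, enum.Enum):
    """The eight goniometric movement categories, each with an opposite."""

    FLEXION = "flexion"
    EXTENSION = "extension"
    ABDUCTION = "abduction"
    ADDUCTION = "adduction"
    INTERNAL_ROTATION = "internal-rotation"
    EXTERNAL_ROTATION = "external-rotation"
    HORIZONTAL_ABDUCTION = "horizontal-abduction"
    HORIZONTAL_ADDUCTION = "horizontal-adduction"

    @property
    def opposite(self) -> "MovementType":
        return _OPPOSITES[self]


_OPPOSITES = {
    MovementType.FLEXION: MovementType.EXTENSION,
    MovementType.EXTENSION: MovementType.FLEXION,
    MovementType.ABDUCTION: MovementType.ADDUCTION,
    MovementType.ADDUCTION: MovementType.ABDUCTION,
    MovementType.INTERNAL_ROTATION: MovementType.EXTERNAL_ROTATION,
    MovementType.EXTERNAL_ROTATION: MovementType.INTERNAL_ROTATION,
    MovementType.HORIZONTAL_ABDUCTION: MovementType.HORIZONTAL_ADDUCTION,
    MovementType.HORIZONTAL_ADDUCTION: MovementType.HORIZONTAL_ABDUCTION,
}


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class JointRef:
    """A joint with optional laterality (e.g. the left glenohumeral joint)."""

    joint_name: str
    side: Side = Side.UNSPECIFIED

    def __post_init__(self) -> None:
        if not self.joint_name:
            raise ValueError("joint_name must be non-empty")


@dataclass(frozen=True)
class Posture:
    """A body posture; identity is by id, the description is an annotation."""

    id: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("posture id must be non-empty")


@dataclass(frozen=True)
class Submovement:
    """One (joint, movement-type, ROM range) triplet, in degrees from neutral."""

    location: JointRef
    type: MovementType
    rom_min: float
    rom_max: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "rom_min", float(self.rom_min))
        object.__setattr__(self, "rom_max", float(self.rom_max))
        if not 0 <= self.rom_min <= self.rom_max <= 360:
            raise ValueError(
                f"ROM range must satisfy 0 <= min <= max <= 360, "
                f"got [{self.rom_min}, {self.rom_max}]"
            )


@dataclass(frozen=True)
class Movement:
    """A posture-to-posture transition of one or more simultaneous submovements."""

    id: str
    name: str
    initial: Posture
    final: Posture
    components: frozenset[Submovement]

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", frozenset(self.components))
        if not self.components:
            raise ValueError(f"movement {self.id!r} needs at least one submovement")


class ChainingError(ValueError):
    """Posture chaining broken: final posture of movement ``index`` (1-based)
    does not match the initial posture of the next movement."""

    def __init__(self, index: int, final_id: str, initial_id: str):
        self.index = index
        super().__init__(
            f"movement {index} ends in posture {final_id!r} but movement "
            f"{index + 1} starts in posture {initial_id!r}"
        )


@dataclass(frozen=True)
class Exercise:
    """An ordered, posture-chained sequence of movements."""

    id: str
    name: str
    movements: tuple[Movement, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "movements", tuple(self.movements))
        if not self.movements:
            raise ValueError(f"exercise {self.id!r} needs at least one movement")
        for k, (a, b) in enumerate(zip(self.movements, self.movements[1:]), start=1):
            if a.final.id != b.initial.id:
                raise ChainingError(k, a.final.id, b.initial.id)


@dataclass(frozen=True)
class MovementExploration:
    """One measured range-of-motion exploration: how far the patient moved a
    joint in one movement type, and whether it hurt.

    Out-of-range ``rom_value`` is reported by :func:`validate_record`, not
    rejected at construction, so that raw clinical input can be loaded and
    then checked.
    """

    location: JointRef
    type: MovementType
    rom_value: float
    pain: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "rom_value", float(self.rom_value))


@dataclass(frozen=True)
class PastHistoryItem:
    """A past pathological condition of the patient (subject='self') or of a
    relative; the condition id may carry laterality, e.g.
    ``dislocation-of-glenohumeral-joint/left``."""

    condition: str
    subject: str = "self"  # "self" | "relative"
    intensity: Optional[str] = None
    timespan: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.condition:
            raise ValueError("past-history condition must be non-empty")
        if self.subject not in ("self", "relative"):
            raise ValueError(f"subject must be 'self' or 'relative', got {self.subject!r}")


@dataclass(frozen=True)
class PhysiotherapyRecord:
    """Answers about one patient at one moment (an immutable snapshot)."""

    id: str
    timestamp: int
    age: Optional[int] = None
    health_issue: Optional[str] = None
    goals: tuple[str, ...] = ()
    vas: Optional[float] = None
    explorations: tuple[MovementExploration, ...] = ()
    diagnosis: Optional[str] = None
    past_history: tuple[PastHistoryItem, ...] = ()

    def __post_init__(self) -> None:
        if self.vas is not None:
            object.__setattr__(self, "vas", float(self.vas))
        object.__setattr__(self, "goals", tuple(self.goals))
        object.__setattr__(self, "explorations", tuple(self.explorations))
        object.__setattr__(self, "past_history", tuple(self.past_history))


@dataclass(frozen=True)
class Patient:
    """A patient with physiotherapy records ordered by strictly increasing
    timestamp; the latest record is the patient's current state."""

    id: str
    records: tuple[PhysiotherapyRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ts = [r.timestamp for r in self.records]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"record timestamps must be strictly increasing, got {ts}")

    @property
    def latest_record(self) -> PhysiotherapyRecord:
        if not self.records:
            raise ValueError(f"patient {self.id!r} has no records")
        return self.records[-1]


@dataclass(frozen=True)
class Violation:
    """One failed field constraint found by :func:`validate_record`."""

    field: str
    constraint: str
    value: object

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.constraint} (got {self.value!r})"


def validate_record(record: PhysiotherapyRecord) -> list[Violation]:
    """Check a record's field invariants and return the violations (empty
    list means valid).

    Checked bounds: VAS in [0.0, 10.0], age >= 0, every exploration ROM in
    [0, 360] degrees. Violations are returned rather than raised so a whole
    record can be reported at once.
    """
    out: list[Violation] = []
    if record.vas is not None and not 0.0 <= record.vas <= 10.0:
        out.append(Violation("vas", "must be within [0.0, 10.0]", record.vas))
    if record.age is not None and record.age < 0:
        out.append(Violation("age", "must be >= 0", record.age))
    for i, e in enumerate(record.explorations):
        if e.rom_value < 0:
            out.append(Violation(f"explorations[{i}].rom_value", "must be >= 0", e.rom_value))
        elif e.rom_value > 360:
            out.append(Violation(f"explorations[{i}].rom_value", "must be <= 360", e.rom_value))
    return out


def inverse_movement(m: Movement) -> Movement:
    """Return the movement performed backwards: postures swapped, the
    (joint, type, ROM range) triplets unchanged.

    ROM is measured from anatomical neutral, so the return stroke of e.g. an
    abduction stays within the abduction range rather than becoming an
    adduction; only the postures swap. Applying the inverse twice recovers
    the original movement up to the ``_inv`` id suffix.
    """
    return Movement(
        id=m.id + "_inv",
        name=m.name + " (inverse)",
        initial=m.final,
        final=m.initial,
        components=m.components,
    )


def compose_exercise(id: str, name: str, movements: Sequence[Movement]) -> Exercise:
    """Build an :class:`Exercise` from an ordered movement list.

    Raises :class:`ChainingError` at the first index k (1-based) where the
    final posture of movement k differs from the initial posture of movement
    k+1, and :class:`ValueError` on an empty list.
    """
    if not movements:
        raise ValueError("an exercise needs at least one movement")
    return Exercise(id=id, name=name, movements=tuple(movements))
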