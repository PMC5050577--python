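"""Classify patients into protocol phases from ROM explorations and pain.

Each phase of a protocol may carry a membership condition built from

* an optional VAS bound (strict ``<``): the record's reported pain on the
  0-10 Visual Analogue Scale must be below it;
* a non-empty *disjunctive* set of exploration bands — half-open ROM
  intervals per (joint, movement type): one matching exploration suffices;
* an optional pain-free requirement applied to the matched exploration.

Evaluation is closed-world over the record: a missing VAS answer fails a
VAS-bounded condition, and no exploration means no band can match. This
mirrors the inferences a description-logic reasoner draws from a fully
asserted record with closure axioms, without needing a reasoner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import JointRef, MovementExploration, MovementType, PhysiotherapyRecord, Side
from .phases import ProtocolSpec, _location_matches

__all__ = [
    "ExplorationBand",
    "PhaseMembershipCondition",
    "PhaseAssignment",
    "BandMatch",
    "exploration_matches_band",
    "phase_condition_satisfied",
    "classify_patient",
]


@dataclass(frozen=True)
class ExplorationBand:
    """A half-open ROM interval [lower_inclusive, upper_exclusive) for one
    (joint, movement type); either bound may be absent."""

    location: JointRef
    type: MovementType
    lower_inclusive: Optional[float] = None
    upper_exclusive: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lower_inclusive is not None:
            object.__setattr__(self, "lower_inclusive", float(self.lower_inclusive))
        if self.upper_exclusive is not None:
            object.__setattr__(self, "upper_exclusive", float(self.upper_exclusive))
        if (
            self.lower_inclusive is not None
            and self.upper_exclusive is not None
            and not self.lower_inclusive < self.upper_exclusive
        ):
            raise ValueError("lower_inclusive must be < upper_exclusive")


@dataclass(frozen=True)
class PhaseMembershipCondition:
    """When is a patient in a phase: VAS below a bound (optional), at least
    one exploration in one of the bands, optionally pain-free."""

    bands: frozenset[ExplorationBand]
    vas_upper_exclusive: Optional[float] = None
    pain_false_required: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", frozenset(self.bands))
        if self.vas_upper_exclusive is not None:
            object.__setattr__(self, "vas_upper_exclusive", float(self.vas_upper_exclusive))
        if not self.bands:
            raise ValueError("a membership condition needs at least one band")


@dataclass(frozen=True)
class BandMatch:
    """Explanation payload: which band a given exploration satisfied."""

    band: ExplorationBand
    exploration: MovementExploration


@dataclass(frozen=True)
class PhaseAssignment:
    """Outcome of classification: all satisfied phases, the selected one
    (minimum satisfied number — the most conservative therapy), and per-phase
    band-match explanations."""

    satisfied_phases: frozenset[int]
    selected_phase: Optional[int]
    explanation: dict[int, tuple[BandMatch, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.selected_phase is not None and self.selected_phase not in self.satisfied_phases:
            raise ValueError("selected_phase must be among satisfied_phases")


def exploration_matches_band(
    e: MovementExploration, band: ExplorationBand, pain_false_required: bool = False
) -> bool:
    """Does exploration ``e`` fall inside ``band``? Joint and movement type
    must match (a side-unspecified band matches either side), the ROM value
    must lie in [lower, upper), and when ``pain_false_required`` the
    exploration must be pain-free."""
    if e.type is not band.type or not _location_matches(band.location, e.location):
        return False
    if band.lower_inclusive is not None and e.rom_value < band.lower_inclusive:
        return False
    if band.upper_exclusive is not None and not e.rom_value < band.upper_exclusive:
        return False
    if pain_false_required and e.pain:
        return False
    return True


def _condition_matches(
    record: PhysiotherapyRecord, cond: PhaseMembershipCondition
) -> list[BandMatch]:
    if cond.vas_upper_exclusive is not None:
        if record.vas is None or not record.vas < cond.vas_upper_exclusive:
            return []
    return [
        BandMatch(band, e)
        for e in record.explorations
        for band in sorted(cond.bands, key=lambda b: (b.type.value, b.location.joint_name))
        if exploration_matches_band(e, band, cond.pain_false_required)
    ]


def phase_condition_satisfied(
    record: PhysiotherapyRecord, cond: PhaseMembershipCondition
) -> bool:
    """True iff the record passes the VAS gate (closed-world: a missing VAS
    fails a bounded condition) and some exploration matches some band."""
    return bool(_condition_matches(record, cond))


def classify_patient(record: PhysiotherapyRecord, protocol: ProtocolSpec) -> PhaseAssignment:
    """Realize a record against a protocol: which phase conditions does it
    satisfy, and which phase is selected (the minimum satisfied number)?

    Phases without a membership condition are never satisfied. An empty
    satisfied set (selected_phase None) is a valid outcome. The result is a
    pure function of (record, protocol).
    """
    satisfied: dict[int, tuple[BandMatch, ...]] = {}
    for phase in protocol.phases:
        if phase.membership is None:
            continue
        matches = _condition_matches(record, phase.membership)
        if matches:
            satisfied[phase.number] = tuple(matches)
    return PhaseAssignment(
        satisfied_phases=frozenset(satisfied),
        selected_phase=min(satisfied) if satisfied else None,
        explanation=satisfied,
    )
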