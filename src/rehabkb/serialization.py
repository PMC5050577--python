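"""Load/save the declarative model and export RDF triples / OWL axioms.

The authoring format is a small YAML dialect (versioned, documented below);
RDF and OWL are export targets only.

YAML dialect (format_version "1")::

    format_version: "1"
    movements:
      - id: Mov1
        name: ...
        initial: {id: p0, description: ...}
        final:   {id: p1}
        components:
          - {joint: glenohumeral-joint, side: left, type: abduction,
             rom_min: 0, rom_max: 90}
    exercises:
      - {id: Exer1, name: ..., movements: [Mov1, Mov1_inv]}
    protocols:
      - name: my-protocol
        disorder: ...
        phases:
          - number: 2
            series: 4
            mode: existential
            caps: [{joint: ..., type: flexion, max_rom: 90}]
            exercises: [Exer1]
            membership:
              vas_below: 3.0
              pain_free_required: false
              bands: [{joint: ..., type: flexion, upper: 90, lower: null}]
    rules:
      - id: r1
        polarity: contraindicated
        provenance: general-knowledge
        patient: {has_past_history: {condition: ..., subject: self}}
        exercises: {contains_movement: {type: abduction, joint: ...,
                                        side: left, rom_max_greater_than: 80}}
    patients:
      - id: patient2015
        records:
          - id: rec1
            timestamp: 1
            vas: 0.0
            explorations: [{joint: ..., side: left, type: flexion,
                            rom: 80, pain: false}]
            past_history: [{condition: ..., subject: self}]
    anatomy:
      symmetric_types: [articulates_with, continuous_with]
      nodes: [{id: ..., label: ..., laterality: left}]
      is_a: [[child, parent]]
      edges: [[src, edge_type, dst]]

Triple export follows the record-as-answers pattern: the patient node
``hasRecord`` the record node, the record ``hasAnswer`` typed answer nodes
(VAS, movement explorations with hasMovementType / hasLocation /
hasROMvalue / hasPain, past-history items with hasPatient). Every node is
a named IRI with a stable skolem fragment derived from (record id, index)
— no blank nodes — and documents are serialized as *sorted N-Triples*
(a syntactic subset of Turtle), so output is byte-identical across runs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Optional, Union

import yaml
from rdflib import RDF, RDFS, XSD, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL

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
)
from .phases import AllowedMovementSpec, PhaseSpec, ProtocolSpec, RomCap
from .recommend import (
    AllOf,
    AllOfExercise,
    ContainsMovement,
    ExerciseClassExpr,
    HasPastHistory,
    InPhase,
    IsPatient,
    NamedSet,
    PatientPredicate,
    PhaseExerciseSet,
    Rule,
)

__all__ = [
    "ModelBundle",
    "ModelLoadError",
    "SchemaError",
    "DanglingReferenceError",
    "load_model",
    "save_model",
    "export_record_triples",
    "export_axioms",
    "export_anatomy_triples",
    "BASE_IRI",
]

FORMAT_VERSION = "1"
BASE_IRI = "http://example.org/rehabkb#"


class ModelLoadError(ValueError):
    pass


class SchemaError(ModelLoadError):
    pass


class DanglingReferenceError(ModelLoadError):
    pass


@dataclass
class ModelBundle:
    """Everything a reasoning session needs, with resolved cross-references."""

    movements: dict[str, Movement] = field(default_factory=dict)
    exercises: dict[str, Exercise] = field(default_factory=dict)
    protocols: dict[str, ProtocolSpec] = field(default_factory=dict)
    rules: dict[str, Rule] = field(default_factory=dict)
    patients: dict[str, Patient] = field(default_factory=dict)
    anatomy: Optional[ConceptGraph] = None
    format_version: str = FORMAT_VERSION

    def validate_references(self) -> None:
        for ex in self.exercises.values():
            for m in ex.movements:
                if m.id not in self.movements:
                    raise DanglingReferenceError(
                        f"exercise {ex.id!r} references undefined movement {m.id!r}"
                    )
        for proto in self.protocols.values():
            for phase in proto.phases:
                for eid in phase.assigned_exercises:
                    if eid not in self.exercises:
                        raise DanglingReferenceError(
                            f"phase {phase.number} of protocol {proto.name!r} "
                            f"references undefined exercise {eid!r}"
                        )
        for rule in self.rules.values():
            for ref in _rule_protocol_refs(rule):
                if ref not in self.protocols:
                    raise DanglingReferenceError(
                        f"rule {rule.id!r} references undefined protocol {ref!r}"
                    )


def _rule_protocol_refs(rule: Rule) -> set[str]:
    refs: set[str] = set()

    def walk_pred(p: PatientPredicate) -> None:
        if isinstance(p, InPhase):
            refs.add(p.protocol)
        elif isinstance(p, AllOf):
            for q in p.predicates:
                walk_pred(q)

    def walk_expr(x: ExerciseClassExpr) -> None:
        if isinstance(x, PhaseExerciseSet):
            refs.add(x.protocol)
        elif isinstance(x, AllOfExercise):
            for y in x.exprs:
                walk_expr(y)

    walk_pred(rule.patient)
    walk_expr(rule.exercises)
    return refs


# ==========================================================================
# YAML loading

def _req(d: dict, key: str, where: str):
    if not isinstance(d, dict) or key not in d:
        raise SchemaError(f"{where}: missing required key {key!r}")
    return d[key]


def _joint(d: dict, where: str) -> JointRef:
    try:
        return JointRef(_req(d, "joint", where), Side(d.get("side", "unspecified")))
    except ValueError as e:
        raise SchemaError(f"{where}: {e}")


def _mtype(value: str, where: str) -> MovementType:
    try:
        return MovementType(value)
    except ValueError:
        raise SchemaError(f"{where}: unknown movement type {value!r}")


def _parse_movement(d: dict, where: str) -> Movement:
    comps = _req(d, "components", where)
    if not isinstance(comps, list) or not comps:
        raise SchemaError(f"{where}: components must be a non-empty list")
    subs = frozenset(
        Submovement(
            location=_joint(c, f"{where}.components[{i}]"),
            type=_mtype(_req(c, "type", f"{where}.components[{i}]"), where),
            rom_min=float(c.get("rom_min", 0)),
            rom_max=float(_req(c, "rom_max", f"{where}.components[{i}]")),
        )
        for i, c in enumerate(comps)
    )
    init = _req(d, "initial", where)
    fin = _req(d, "final", where)
    return Movement(
        id=_req(d, "id", where),
        name=d.get("name", ""),
        initial=Posture(_req(init, "id", f"{where}.initial"), init.get("description", "")),
        final=Posture(_req(fin, "id", f"{where}.final"), fin.get("description", "")),
        components=subs,
    )


def _parse_band(d: dict, where: str) -> ExplorationBand:
    return ExplorationBand(
        location=_joint(d, where),
        type=_mtype(_req(d, "type", where), where),
        lower_inclusive=None if d.get("lower") is None else float(d["lower"]),
        upper_exclusive=None if d.get("upper") is None else float(d["upper"]),
    )


def _parse_phase(d: dict, where: str) -> PhaseSpec:
    caps = frozenset(
        RomCap(_joint(c, f"{where}.caps[{i}]"),
               _mtype(_req(c, "type", f"{where}.caps[{i}]"), where),
               float(_req(c, "max_rom", f"{where}.caps[{i}]")))
        for i, c in enumerate(d.get("caps", []))
    )
    membership = None
    if d.get("membership") is not None:
        m = d["membership"]
        bands = frozenset(
            _parse_band(b, f"{where}.membership.bands[{i}]")
            for i, b in enumerate(_req(m, "bands", f"{where}.membership"))
        )
        membership = PhaseMembershipCondition(
            bands=bands,
            vas_upper_exclusive=None if m.get("vas_below") is None else float(m["vas_below"]),
            pain_false_required=bool(m.get("pain_free_required", False)),
        )
    return PhaseSpec(
        number=int(_req(d, "number", where)),
        allowed=AllowedMovementSpec(caps=caps, mode=d.get("mode", "existential")),
        assigned_exercises=tuple(d.get("exercises", [])),
        series=int(d.get("series", 1)),
        membership=membership,
    )


def _parse_predicate(d: dict, where: str) -> PatientPredicate:
    if len(d) != 1:
        raise SchemaError(f"{where}: patient predicate must have exactly one variant key")
    (kind, body), = d.items()
    if kind == "in_phase":
        return InPhase(_req(body, "protocol", where), int(_req(body, "phase", where)))
    if kind == "has_past_history":
        return HasPastHistory(_req(body, "condition", where), body.get("subject", "self"))
    if kind == "is_patient":
        return IsPatient(body if isinstance(body, str) else _req(body, "id", where))
    if kind == "all_of":
        return AllOf(tuple(_parse_predicate(p, where) for p in body))
    raise SchemaError(f"{where}: unknown patient predicate {kind!r}")


def _parse_expr(d: dict, where: str) -> ExerciseClassExpr:
    if len(d) != 1:
        raise SchemaError(f"{where}: exercise expression must have exactly one variant key")
    (kind, body), = d.items()
    if kind == "contains_movement":
        loc = None
        if body.get("joint") is not None:
            loc = JointRef(body["joint"], Side(body.get("side", "unspecified")))
        thr = body.get("rom_max_greater_than")
        return ContainsMovement(_mtype(_req(body, "type", where), where), loc,
                                None if thr is None else float(thr))
    if kind == "phase_exercise_set":
        return PhaseExerciseSet(_req(body, "protocol", where), int(_req(body, "phase", where)))
    if kind == "named_set":
        return NamedSet(frozenset(body))
    if kind == "all_of":
        return AllOfExercise(tuple(_parse_expr(x, where) for x in body))
    raise SchemaError(f"{where}: unknown exercise expression {kind!r}")


def _parse_record(d: dict, where: str) -> PhysiotherapyRecord:
    explorations = tuple(
        MovementExploration(
            location=_joint(e, f"{where}.explorations[{i}]"),
            type=_mtype(_req(e, "type", f"{where}.explorations[{i}]"), where),
            rom_value=float(_req(e, "rom", f"{where}.explorations[{i}]")),
            pain=bool(_req(e, "pain", f"{where}.explorations[{i}]")),
        )
        for i, e in enumerate(d.get("explorations", []))
    )
    history = tuple(
        PastHistoryItem(_req(h, "condition", f"{where}.past_history[{i}]"),
                        h.get("subject", "self"), h.get("intensity"), h.get("timespan"))
        for i, h in enumerate(d.get("past_history", []))
    )
    return PhysiotherapyRecord(
        id=_req(d, "id", where),
        timestamp=int(_req(d, "timestamp", where)),
        age=d.get("age"),
        health_issue=d.get("health_issue"),
        goals=tuple(d.get("goals", [])),
        vas=None if d.get("vas") is None else float(d["vas"]),
        explorations=explorations,
        diagnosis=d.get("diagnosis"),
        past_history=history,
    )


def _parse_anatomy(d: dict) -> ConceptGraph:
    g = ConceptGraph(symmetric_types=d.get("symmetric_types",
                                           sorted(ConceptGraph().symmetric_types)))
    for n in d.get("nodes", []):
        g.add_node(ConceptNode(_req(n, "id", "anatomy.nodes"), n.get("label", ""),
                               tuple(map(tuple, n.get("external_codes", []))),
                               n.get("laterality")))
    for child, parent in d.get("is_a", []):
        g.add_is_a(child, parent)
    for src, etype, dst in d.get("edges", []):
        g.add_edge(src, etype, dst)
    return g


def load_model(source: Union[str, IO[str]]) -> ModelBundle:
    """Load and fully validate a model bundle from a YAML path or stream.

    Raises :class:`SchemaError` on malformed content and
    :class:`DanglingReferenceError` naming any unresolved id.
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source.read()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ModelLoadError(f"not valid YAML: {e}")
    if not isinstance(data, dict):
        raise SchemaError("top level must be a mapping")

    bundle = ModelBundle(format_version=str(data.get("format_version", FORMAT_VERSION)))
    for i, d in enumerate(data.get("movements") or []):
        m = _parse_movement(d, f"movements[{i}]")
        bundle.movements[m.id] = m
    for i, d in enumerate(data.get("exercises") or []):
        where = f"exercises[{i}]"
        mids = _req(d, "movements", where)
        try:
            movs = [bundle.movements[mid] for mid in mids]
        except KeyError as e:
            raise DanglingReferenceError(f"{where}: undefined movement id {e.args[0]!r}")
        ex = Exercise(_req(d, "id", where), d.get("name", ""), tuple(movs))
        bundle.exercises[ex.id] = ex
    for i, d in enumerate(data.get("protocols") or []):
        where = f"protocols[{i}]"
        proto = ProtocolSpec(
            name=_req(d, "name", where),
            disorder=d.get("disorder", ""),
            phases=tuple(_parse_phase(p, f"{where}.phases[{j}]")
                         for j, p in enumerate(_req(d, "phases", where))),
        )
        bundle.protocols[proto.name] = proto
    for i, d in enumerate(data.get("rules") or []):
        where = f"rules[{i}]"
        rule = Rule(
            id=_req(d, "id", where),
            patient=_parse_predicate(_req(d, "patient", where), f"{where}.patient"),
            polarity=_req(d, "polarity", where),
            exercises=_parse_expr(_req(d, "exercises", where), f"{where}.exercises"),
            provenance=d.get("provenance", "physiotherapist-entered"),
        )
        if rule.id in bundle.rules:
            raise SchemaError(f"{where}: duplicate rule id {rule.id!r}")
        bundle.rules[rule.id] = rule
    for i, d in enumerate(data.get("patients") or []):
        where = f"patients[{i}]"
        pat = Patient(
            id=_req(d, "id", where),
            records=tuple(_parse_record(r, f"{where}.records[{j}]")
                          for j, r in enumerate(d.get("records", []))),
        )
        bundle.patients[pat.id] = pat
    if data.get("anatomy") is not None:
        bundle.anatomy = _parse_anatomy(data["anatomy"])
    bundle.validate_references()
    return bundle


# ==========================================================================
# YAML saving

def _dump_joint(j: JointRef) -> dict:
    d: dict = {"joint": j.joint_name}
    if j.side is not Side.UNSPECIFIED:
        d["side"] = j.side.value
    return d


def _dump_movement(m: Movement) -> dict:
    return {
        "id": m.id,
        "name": m.name,
        "initial": {"id": m.initial.id, "description": m.initial.description},
        "final": {"id": m.final.id, "description": m.final.description},
        "components": [
            {**_dump_joint(s.location), "type": s.type.value,
             "rom_min": s.rom_min, "rom_max": s.rom_max}
            for s in sorted(m.components, key=lambda s: (s.type.value, s.rom_max))
        ],
    }


def _dump_phase(p: PhaseSpec) -> dict:
    d: dict = {
        "number": p.number,
        "mode": p.allowed.mode,
        "caps": [
            {**_dump_joint(c.location), "type": c.type.value, "max_rom": c.max_rom_inclusive}
            for c in sorted(p.allowed.caps, key=lambda c: c.type.value)
        ],
        "exercises": list(p.assigned_exercises),
        "series": p.series,
    }
    if p.membership is not None:
        m = p.membership
        d["membership"] = {
            "vas_below": m.vas_upper_exclusive,
            "pain_free_required": m.pain_false_required,
            "bands": [
                {**_dump_joint(b.location), "type": b.type.value,
                 "lower": b.lower_inclusive, "upper": b.upper_exclusive}
                for b in sorted(m.bands, key=lambda b: b.type.value)
            ],
        }
    return d


def _dump_predicate(p: PatientPredicate) -> dict:
    if isinstance(p, InPhase):
        return {"in_phase": {"protocol": p.protocol, "phase": p.phase_number}}
    if isinstance(p, HasPastHistory):
        return {"has_past_history": {"condition": p.condition, "subject": p.subject}}
    if isinstance(p, IsPatient):
        return {"is_patient": p.patient_id}
    if isinstance(p, AllOf):
        return {"all_of": [_dump_predicate(q) for q in p.predicates]}
    raise TypeError(f"unknown predicate {p!r}")


def _dump_expr(x: ExerciseClassExpr) -> dict:
    if isinstance(x, ContainsMovement):
        body: dict = {"type": x.type.value}
        if x.location is not None:
            body.update(_dump_joint(x.location))
        if x.rom_max_greater_than is not None:
            body["rom_max_greater_than"] = x.rom_max_greater_than
        return {"contains_movement": body}
    if isinstance(x, PhaseExerciseSet):
        return {"phase_exercise_set": {"protocol": x.protocol, "phase": x.phase_number}}
    if isinstance(x, NamedSet):
        return {"named_set": sorted(x.ids)}
    if isinstance(x, AllOfExercise):
        return {"all_of": [_dump_expr(y) for y in x.exprs]}
    raise TypeError(f"unknown expression {x!r}")


def _dump_record(r: PhysiotherapyRecord) -> dict:
    d: dict = {"id": r.id, "timestamp": r.timestamp}
    if r.age is not None:
        d["age"] = r.age
    if r.health_issue is not None:
        d["health_issue"] = r.health_issue
    if r.goals:
        d["goals"] = list(r.goals)
    if r.vas is not None:
        d["vas"] = r.vas
    if r.explorations:
        d["explorations"] = [
            {**_dump_joint(e.location), "type": e.type.value,
             "rom": e.rom_value, "pain": e.pain}
            for e in r.explorations
        ]
    if r.diagnosis is not None:
        d["diagnosis"] = r.diagnosis
    if r.past_history:
        d["past_history"] = [
            {"condition": h.condition, "subject": h.subject,
             **({"intensity": h.intensity} if h.intensity else {}),
             **({"timespan": h.timespan} if h.timespan else {})}
            for h in r.past_history
        ]
    return d


def save_model(bundle: ModelBundle, target: Union[str, IO[str], None] = None) -> str:
    """Serialize a bundle back to the YAML dialect; returns the text (and
    writes it to ``target`` when given). load(save(b)) is the identity."""
    data: dict = {"format_version": bundle.format_version}
    if bundle.movements:
        data["movements"] = [_dump_movement(m) for m in sorted(bundle.movements.values(),
                                                               key=lambda m: m.id)]
    if bundle.exercises:
        data["exercises"] = [
            {"id": e.id, "name": e.name, "movements": [m.id for m in e.movements]}
            for e in sorted(bundle.exercises.values(), key=lambda e: e.id)
        ]
    if bundle.protocols:
        data["protocols"] = [
            {"name": p.name, "disorder": p.disorder,
             "phases": [_dump_phase(ph) for ph in p.phases]}
            for p in sorted(bundle.protocols.values(), key=lambda p: p.name)
        ]
    if bundle.rules:
        data["rules"] = [
            {"id": r.id, "polarity": r.polarity, "provenance": r.provenance,
             "patient": _dump_predicate(r.patient), "exercises": _dump_expr(r.exercises)}
            for r in sorted(bundle.rules.values(), key=lambda r: r.id)
        ]
    if bundle.patients:
        data["patients"] = [
            {"id": p.id, "records": [_dump_record(r) for r in p.records]}
            for p in sorted(bundle.patients.values(), key=lambda p: p.id)
        ]
    if bundle.anatomy is not None:
        g = bundle.anatomy
        data["anatomy"] = {
            "symmetric_types": sorted(g.symmetric_types),
            "nodes": [
                {"id": n.id,
                 **({"label": n.label} if n.label else {}),
                 **({"laterality": n.laterality} if n.laterality else {}),
                 **({"external_codes": [list(c) for c in n.external_codes]}
                    if n.external_codes else {})}
                for n in sorted(g.nodes.values(), key=lambda n: n.id)
            ],
            "is_a": sorted([list(e) for e in g.is_a_edges()]),
            "edges": sorted([list(e) for e in g.edges()]),
        }
    text = yaml.safe_dump(data, sort_keys=False, allow_unicode=True)
    if isinstance(target, str):
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
    elif target is not None:
        target.write(text)
    return text


# ==========================================================================
# RDF / OWL export

REHAB = Namespace(BASE_IRI)


def _serialize_sorted(g: Graph) -> str:
    """Serialize as sorted N-Triples — a deterministic subset of Turtle."""
    nt = g.serialize(format="nt")
    lines = sorted(line for line in nt.splitlines() if line.strip())
    return "\n".join(lines) + "\n"


def _iri(fragment: str) -> URIRef:
    return REHAB[fragment.replace(" ", "_")]


def export_record_triples(patient: Patient, record: PhysiotherapyRecord) -> str:
    """Export one patient record as RDF (returned as sorted-N-Triples text,
    parseable as Turtle).

    Pattern: patient hasRecord record; record hasAnswer answer nodes (one
    per present answer) typed by answer class; exploration nodes carry
    hasMovementType / hasLocation / hasROMvalue / hasPain; past-history
    nodes carry hasPatient. Answer node ids are skolems derived from
    (record id, index) so output is reproducible.
    """
    g = Graph()
    p = _iri(patient.id)
    r = _iri(record.id)
    g.add((p, RDF.type, REHAB.Patient))
    g.add((p, REHAB.hasRecord, r))
    g.add((r, RDF.type, REHAB.PhysiotherapyRecord))

    def answer(idx: int, cls: str) -> URIRef:
        a = _iri(f"{record.id}-answer{idx}")
        g.add((r, REHAB.hasAnswer, a))
        g.add((a, RDF.type, REHAB[cls]))
        return a

    idx = 0
    if record.age is not None:
        a = answer(idx, "AgeAnswer"); idx += 1
        g.add((a, REHAB.hasAge, Literal(record.age, datatype=XSD.integer)))
    if record.vas is not None:
        a = answer(idx, "VASAnswer"); idx += 1
        g.add((a, REHAB.hasVASvalue, Literal(record.vas, datatype=XSD.decimal)))
    for e in record.explorations:
        a = answer(idx, "MovementExplorationAnswer")
        x = _iri(f"{record.id}-movexp{idx}")
        idx += 1
        g.add((a, REHAB.hasMovementExploration, x))
        g.add((x, RDF.type, REHAB.MovementExploration))
        g.add((x, REHAB.hasMovementType, _iri(e.type.value)))
        joint = _iri(f"{record.id}-{e.location.side.value}-{e.location.joint_name}")
        g.add((x, REHAB.hasLocation, joint))
        g.add((joint, RDF.type, _iri(e.location.joint_name)))
        g.add((x, REHAB.hasROMvalue, Literal(e.rom_value, datatype=XSD.decimal)))
        g.add((x, REHAB.hasPain, Literal(e.pain, datatype=XSD.boolean)))
    for h in record.past_history:
        a = answer(idx, "PastHistoryAnswer")
        item = _iri(f"{record.id}-pasthistory{idx}")
        idx += 1
        g.add((a, REHAB.hasPastHistory, item))
        g.add((item, RDF.type, _iri(h.condition)))
        g.add((item, REHAB.hasPatient, _iri(h.subject)))
        if h.intensity:
            g.add((item, REHAB.hasIntensity, _iri(h.intensity)))
        if h.timespan:
            g.add((item, REHAB.hasTimespan, _iri(h.timespan)))
    return _serialize_sorted(g)


def export_anatomy_triples(graph: ConceptGraph) -> str:
    """Export an anatomy concept graph as RDF (sorted N-Triples)."""
    g = Graph()
    for n in graph.nodes.values():
        c = _iri(n.id)
        g.add((c, RDF.type, OWL.Class))
        if n.label:
            g.add((c, RDFS.label, Literal(n.label)))
        if n.laterality:
            g.add((c, REHAB.laterality, _iri(n.laterality)))
        for system, code in n.external_codes:
            g.add((c, REHAB.externalCode, Literal(f"{system}:{code}")))
    for child, parent in graph.is_a_edges():
        g.add((_iri(child), RDFS.subClassOf, _iri(parent)))
    for src, etype, dst in graph.edges():
        prop = _iri(etype)
        g.add((_iri(src), prop, _iri(dst)))
        if etype in graph.symmetric_types:
            g.add((prop, RDF.type, OWL.SymmetricProperty))
    return _serialize_sorted(g)


def _restriction(g: Graph, skolem: str, on_property: URIRef, **kw) -> URIRef:
    node = _iri(skolem)
    g.add((node, RDF.type, OWL.Restriction))
    g.add((node, OWL.onProperty, on_property))
    for key, value in kw.items():
        g.add((node, OWL[key], value))
    return node


def count_axioms(bundle: ModelBundle) -> int:
    """Independent tally of the class axioms :func:`export_axioms` emits:
    one equivalence per movement plus one name subclass axiom, one
    equivalence per exercise, per phase-with-membership one patient-phase
    equivalence plus one candidate-class equivalence and one allowed-
    movement equivalence, one subclass axiom per rule, and one subclass
    axiom per phase assignment."""
    n = 2 * len(bundle.movements) + len(bundle.exercises) + len(bundle.rules)
    for proto in bundle.protocols.values():
        for phase in proto.phases:
            if phase.membership is not None:
                n += 3
            n += len(phase.assigned_exercises)
    return n


def export_axioms(bundle: ModelBundle) -> str:
    """Export the bundle as OWL class axioms in RDF (sorted N-Triples).

    Movements become equivalences over component restrictions (plus a
    subclass axiom carrying the name annotation — the model mixes the two
    axiom forms on purpose); exercises become equivalences with an exact
    cardinality on the movement property; each phase with a membership
    condition yields a patient-phase class, an allowed-movement class and a
    candidate-exercise class; rules become subclass axioms over
    ``recommended``/``contraindicated`` restrictions; and every phase
    assignment becomes an ``Exercise ⊑ phase-exercise-set`` subclass axiom.
    Output is byte-identical across runs.
    """
    g = Graph()
    g.add((URIRef(BASE_IRI.rstrip("#")), RDF.type, OWL.Ontology))

    for m in bundle.movements.values():
        cls = _iri(m.id)
        g.add((cls, RDF.type, OWL.Class))
        parts = []
        for i, s in enumerate(sorted(m.components, key=lambda s: (s.type.value, s.rom_max))):
            parts.append(_restriction(
                g, f"{m.id}-component{i}", REHAB.hasComponent,
                someValuesFrom=_iri(f"{m.id}-component{i}-submovement"),
            ))
            sub = _iri(f"{m.id}-component{i}-submovement")
            g.add((sub, RDF.type, OWL.Class))
            g.add((sub, REHAB.movementType, _iri(s.type.value)))
            g.add((sub, REHAB.joint, _iri(s.location.joint_name)))
            g.add((sub, REHAB.romMin, Literal(s.rom_min, datatype=XSD.decimal)))
            g.add((sub, REHAB.romMax, Literal(s.rom_max, datatype=XSD.decimal)))
        body = _iri(f"{m.id}-definition")
        g.add((cls, OWL.equivalentClass, body))
        g.add((body, RDF.type, OWL.Class))
        g.add((body, REHAB.initialPosture, _iri(m.initial.id)))
        g.add((body, REHAB.finalPosture, _iri(m.final.id)))
        for p in parts:
            g.add((body, REHAB.hasPart, p))
        name_r = _restriction(g, f"{m.id}-name", REHAB.hasName,
                              hasValue=Literal(m.name))
        g.add((cls, RDFS.subClassOf, name_r))

    for e in bundle.exercises.values():
        cls = _iri(e.id)
        g.add((cls, RDF.type, OWL.Class))
        body = _iri(f"{e.id}-definition")
        g.add((cls, OWL.equivalentClass, body))
        g.add((body, RDF.type, OWL.Class))
        card = _restriction(g, f"{e.id}-cardinality", REHAB.hasMovement,
                            cardinality=Literal(len(e.movements),
                                                datatype=XSD.nonNegativeInteger))
        g.add((body, REHAB.hasPart, card))
        for k, m in enumerate(e.movements, start=1):
            r = _restriction(g, f"{e.id}-movement{k}", REHAB.hasMovement,
                             someValuesFrom=_iri(m.id))
            g.add((r, REHAB.movementNumber, Literal(k, datatype=XSD.integer)))
            g.add((body, REHAB.hasPart, r))

    for proto in bundle.protocols.values():
        for phase in proto.phases:
            tag = f"{proto.name}-phase{phase.number}"
            if phase.membership is not None:
                pcls = _iri(f"Patient-{tag}")
                g.add((pcls, RDF.type, OWL.Class))
                pbody = _iri(f"Patient-{tag}-definition")
                g.add((pcls, OWL.equivalentClass, pbody))
                g.add((pbody, RDF.type, OWL.Class))
                cond = phase.membership
                if cond.vas_upper_exclusive is not None:
                    g.add((pbody, REHAB.vasBelow,
                           Literal(cond.vas_upper_exclusive, datatype=XSD.decimal)))
                if cond.pain_false_required:
                    g.add((pbody, REHAB.painFreeRequired, Literal(True)))
                for i, band in enumerate(sorted(cond.bands,
                                                key=lambda b: (b.type.value,
                                                               b.upper_exclusive or 0))):
                    bn = _iri(f"Patient-{tag}-band{i}")
                    g.add((pbody, REHAB.hasBand, bn))
                    g.add((bn, REHAB.movementType, _iri(band.type.value)))
                    g.add((bn, REHAB.joint, _iri(band.location.joint_name)))
                    if band.lower_inclusive is not None:
                        g.add((bn, REHAB.romLowerInclusive,
                               Literal(band.lower_inclusive, datatype=XSD.decimal)))
                    if band.upper_exclusive is not None:
                        g.add((bn, REHAB.romUpperExclusive,
                               Literal(band.upper_exclusive, datatype=XSD.decimal)))
                allowed = _iri(f"AllowedMov-{tag}")
                g.add((allowed, RDF.type, OWL.Class))
                abody = _iri(f"AllowedMov-{tag}-definition")
                g.add((allowed, OWL.equivalentClass, abody))
                g.add((abody, RDF.type, OWL.Class))
                for i, cap in enumerate(sorted(phase.allowed.caps,
                                               key=lambda c: c.type.value)):
                    cn = _iri(f"AllowedMov-{tag}-cap{i}")
                    g.add((abody, REHAB.hasCap, cn))
                    g.add((cn, REHAB.movementType, _iri(cap.type.value)))
                    g.add((cn, REHAB.joint, _iri(cap.location.joint_name)))
                    g.add((cn, REHAB.romMaxInclusive,
                           Literal(cap.max_rom_inclusive, datatype=XSD.decimal)))
                cand = _iri(f"CandExe-{tag}")
                g.add((cand, RDF.type, OWL.Class))
                cbody = _iri(f"CandExe-{tag}-definition")
                g.add((cand, OWL.equivalentClass, cbody))
                g.add((cbody, RDF.type, OWL.Class))
                g.add((cbody, REHAB.hasPart,
                       _restriction(g, f"CandExe-{tag}-some", REHAB.hasMovement,
                                    someValuesFrom=allowed)))
                g.add((cbody, REHAB.hasPart,
                       _restriction(g, f"CandExe-{tag}-only", REHAB.hasMovement,
                                    allValuesFrom=allowed)))
            for eid in phase.assigned_exercises:
                g.add((_iri(eid), RDFS.subClassOf, _iri(f"Exe-{tag}")))

    for rule in bundle.rules.values():
        cls = _iri(f"RulePatient-{rule.id}")
        g.add((cls, RDF.type, OWL.Class))
        prop = REHAB.recommended if rule.polarity == "recommended" else REHAB.contraindicated
        target = _iri(f"RuleExercises-{rule.id}")
        g.add((target, RDF.type, OWL.Class))
        r = _restriction(g, f"Rule-{rule.id}-restriction", prop, someValuesFrom=target)
        g.add((cls, RDFS.subClassOf, r))
        g.add((cls, REHAB.provenance, Literal(rule.provenance)))

    return _serialize_sorted(g)
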