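# Methods

## The procedure and its assumptions

rehabkb re-expresses a description-logic (DL) knowledge model of
physiotherapy rehabilitation as a closed-world rule engine. The original
setting is an OWL ontology where movements, exercises, protocol phases and
patient classes are class expressions and a reasoner performs
classification and realization. Here the same semantics is evaluated
directly over explicit catalogs, which is equivalent on fully asserted
data: the DL definitions rely on closure axioms (exact cardinalities on
the movement property, enumerated exploration sets) precisely so that
universal restrictions bite; a closed-world evaluator over the explicit
lists yields the same inferences without a TBox reasoner. The engine
therefore assumes its inputs are complete — an absent VAS answer fails a
VAS-bounded condition, an unlisted movement does not exist.

Key semantic choices, each mirroring the class-expression reading:

* **Allowed movements are existential by default.** The allowed-movement
  class for a phase is a disjunction of "has SOME submovement of type t on
  joint j with ROMmax ≤ cap" classes; it says nothing about sibling
  submovements. A movement passes as soon as one component fits one cap.
  This admits clinically surprising diagonals (a flexion-80 +
  abduction-170 movement passes a phase capping both at 90), so a
  `strict` mode requiring every component to fit a cap for its own
  (joint, type) is provided; candidates under strict are always a subset
  of candidates under existential. Both modes are kept; existential is
  the default because it is the faithful reading.
* **Caps constrain only `rom_max`.** The minimum of a ROM range is
  unconstrained — ranges are measured from anatomical neutral and the
  caps bound how far a phase lets the joint travel.
* **Inverse movements keep their submovement triplets and swap only the
  postures.** The return stroke of an abduction is still an abduction
  through the same range, not an adduction; this is also the only reading
  under which the reference exercise (movement + inverse) is a phase-2
  candidate, since phase 2 caps adduction at 27°. The inverse is an
  involution up to the `_inv` id suffix.
* **Membership bands are half-open.** A "below 90" exploration class is
  [0, 90) — strict upper bound; "between A and B" classes are encoded as
  [A, B+1), which is the only convention consistent with every printed
  cap/band pair (e.g. between 90 and 143 next to a cap of 144, between
  25 and 39 next to 40). Phase 3's condition carries no VAS bound but
  requires the matched exploration to be pain-free; it is encoded exactly
  as specified rather than "repaired" to include a VAS conjunct.
* **Multi-phase satisfaction is possible** under the disjunctive band
  semantics (one record can match a phase-2 band with one exploration and
  a phase-3 band with another). The full satisfied set is always
  reported; the *selected* phase is the minimum satisfied number — the
  most conservative therapy. Patient-level helpers classify the record
  with the latest timestamp; records themselves are immutable snapshots
  and progress is modelled by appending records.
* **Recommendation quantifies extensionally.** The set formulas for
  RecommendedFor/ContraindicatedFor quantify over named classes Z ⊑ Y; on
  a concrete catalog this is realized as membership of each exercise in
  the rule's class expression (plus explicit phase assignments standing
  in for the asserted subclass axioms). "ROM greater than 80" is strict.
  A rule naming a sided joint matches only submovements on that side;
  side-unspecified rules match both. Conflicts resolve by set difference
  — contraindication wins, no priorities.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| phase-2 caps (flex/ext/abd/add/int-rot/ext-rot) | degrees | 90/25/90/27/45/55 | the reference protocol's printed phase-2 conditions |
| phase-3 caps (+ horizontal abd/add) | degrees | 144/40/144/36/72/88/32/112 | printed phase-3 conditions |
| phase-2 VAS bound | VAS score | < 3.0 | printed; strict comparison |
| dislocation contraindication threshold | degrees | > 80 | printed general-knowledge rule; strict comparison |
| VAS validity range | VAS score | [0.0, 10.0] inclusive | the record schema's datatype restriction |
| ROM sanity bound | degrees | ≤ 360 | no maximum is specified; 360 is a physical sanity cap |
| extractor `hop_limit` | hops | 1 | "logically connected" is under-specified; a bounded, configurable property-edge closure makes the choice explicit |
| allowed-movement `mode` | — | existential | see above |

Phase 2's series count is 4 (printed); phases whose series are not given
default to 1. Phases 1, 4 and 5 of the reference protocol are stubs with
no membership condition — their conditions are not part of the reference
material — and the classifier simply never selects them.

## The synthetic data

`generate_random_world` emulates the *shape* of authored content:
movement catalogs with 1–4 simultaneous submovements on an integer ROM
grid (default 0–180°), exercises whose postures are generated to chain,
protocols of 2–4 phases whose caps grow monotonically phase over phase
(so inter-phase subsumption is exercisable, as in real protocols where
later phases relax earlier limits), and records with 0–6 explorations, a
VAS on a 0.1 grid and occasional past-history items. All generators are
pure functions of their seed.

What it does **not** emulate: clinically coherent co-occurrence of
movement types within a diagonal, kinematically plausible posture
geometry, realistic correlations between VAS, pain flags and ROM, or
longitudinal recovery trajectories. Passing tests therefore show the
engine's logic is correct over the declared semantics, not that the
reference protocol's thresholds are clinically optimal or that real
records distribute like the generator's.

The synthetic anatomy graph (62 concepts around a glenohumeral-joint
stand-in, with left/right duplicates, a partonomy and symmetric
`articulates_with`/`continuous_with` edges) imitates the structure of a
reference anatomy ontology; it reproduces none of its content, and
nothing in the package downloads or embeds one. `continuous_with` and
`articulates_with` are modelled as symmetric property types (flagged, not
stored twice and not self-inverse), and queries answer in both
directions.

## Numerical and procedural choices

* All boundary comparisons are exact on floats; inputs are normalized to
  `float` at construction so YAML round-trips are byte-identical. VAS
  grids use `round(0.1*k, 1)` to stay on the intended 0.1 lattice.
* Candidate and part listings are sorted lexicographically by id;
  deterministic output is part of the contract.
* Module extraction: kept set = seeds ∪ is_a-ancestors, expanded
  breadth-first over whitelisted property types for `hop_limit` hops,
  minus the removal list, then orphan removal to fixpoint (a non-seed
  node with no edge of any type to another kept node is dropped). The
  operation is idempotent and monotone in `hop_limit`. Whether the
  original extractor's connectivity was single-hop or transitive is
  unknown; both are expressible via `hop_limit`.
* RDF/OWL export emits named skolem nodes (fragment derived from the
  parent id and an index) instead of blank nodes and serializes as
  *sorted N-Triples* — a syntactic subset of Turtle — so identical models
  produce byte-identical documents regardless of hash seeds or serializer
  internals. Movement classes are exported both as an equivalence over
  their structure and a subclass axiom carrying the name annotation,
  preserving the mixed ≡/⊑ style of the source model.
* Exercise assignment returns an updated protocol value (protocols are
  immutable); the operation takes the exercise catalog as an explicit
  argument because candidacy cannot be checked from the protocol alone.
* Degenerate inputs: an empty cap set allows no movement; a condition
  must have at least one band; an empty satisfied-phase set is a valid
  classification outcome; an empty rule set yields three empty sets.

## Problem sizes

Property tests run the engine against brute-force enumerators (every
(exercise, movement, component, cap) or (exploration, band, phase) or
(rule, exercise) combination) on 60–500 random worlds of up to 50
exercises, 4 components, 10 rules; the boundary sweeps cover all integers
0–180 and the full 0.1 VAS grid. These sizes keep the whole suite under
about ten seconds while exhausting the discrete structures involved; the
sweeps are exhaustive over their domains, not samples.

## Known limitations

* No OWL import: the YAML dialect is the only authoring format; RDF/OWL
  are export-only. No reasoner integration — by design, the engine *is*
  the evaluator, and equivalence with a DL reasoner holds only under the
  closed-world/closure assumptions above.
* Repetition counts per exercise, free-text answer parsing, clinical
  coding of diagnoses and temporal smoothing of phase transitions are out
  of scope.
* Whether intensity/timespan of past-history items should participate in
  rules is left open; the fields are carried and exported but unused by
  the predicates.
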