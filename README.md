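# rehabkb

A knowledge model and reasoning engine for physiotherapy rehabilitation
protocols, aimed at clinical-decision-support developers and researchers in
biomedical knowledge representation. It provides, as a plain Python
library, the reasoning services that a description-logic ontology plus
reasoner would provide for a telerehabilitation system: representing
movements, exercises, treatment protocols and patient records; deciding
which phase of a protocol a patient is in; proposing candidate exercises
per phase; and deriving which exercises are recommended, contraindicated
and ultimately suitable for a patient.

## The model

**Movements and exercises.** A movement is a transition between an initial
and a final posture, composed of one or more simultaneous *submovements* —
triplets (joint *j*, movement type *t*, ROM range [min, max] in degrees),
where *t* ranges over the eight goniometric categories
(flexion/extension, abduction/adduction, internal/external rotation,
horizontal abduction/adduction). An exercise is a sequence of movements
⟨m₁, …, mₙ⟩ with chained postures: final(mₖ) = initial(mₖ₊₁).

**Protocols and phases.** A treatment protocol for a disorder is a
sequence of phases. Each phase carries ROM caps — per (joint, type) an
inclusive bound capₚ(j, t) — plus assigned exercises and a membership
condition. A movement is *allowed* in phase *p* when some submovement
(j, t, [·, r]) has r ≤ capₚ(j, t) (existential reading; a strict
per-component reading is also available), and an exercise is a *candidate*
for *p* when all its movements are allowed. If capₚ(j, t) ≤ cap_q(j, t)
for every cap of *p*, phase *q*'s candidate class subsumes phase *p*'s:
candidates(p) ⊆ candidates(q) for every catalog.

**Patient classification.** A membership condition combines an optional
strict VAS bound (pain score < v), a disjunction of half-open ROM bands
[a, b) per (joint, type), and an optional pain-free requirement. A record
satisfies the condition when its VAS passes and at least one of its
explorations falls in a band; a patient's phase is the minimum satisfied
phase number of their latest record. Evaluation is closed-world: missing
answers fail.

**Recommendations.** Rules pair a patient predicate (in-phase, past
history, named patient, conjunctions) with an exercise class expression
(contains-movement with optional joint and strict ROM threshold, a phase's
exercise set, explicit id sets) and a polarity. For patient *p*:

    suitable(p) = recommended(p) \ contraindicated(p)

— a contraindication always wins.

The package also ships an anatomy concept-graph module (partonomy and
laterality queries, seeded module extraction with orphan cleanup), a YAML
authoring format with exact round-trips, and RDF/OWL export of records and
class axioms.

## Worked example

```bash
python examples/01_classify_patient.py
```

```
protocol: limited-flexion-glenohumeral-joint (5 phases)
initial record  (flexion 80°, VAS 0.0, no pain): phase 2
updated record (flexion 100°, VAS 0.0, no pain): phase 3
matched band: flexion [90.0, 144.0) at ROM 100.0
```

The patient's first record (pain-free glenohumeral flexion of 80°, VAS
0.0) satisfies the phase-2 condition (flexion below 90° with VAS < 3.0).
When flexion improves to 100° without pain, the record falls into the
phase-3 flexion band [90, 144) instead, so the patient advances to
phase 3. The other examples cover candidate selection and assignment
(`02`), recommendation with a dislocation contraindication (`03`), anatomy
queries and module extraction (`04`), and YAML/RDF/OWL serialization
(`05`). A thin CLI wraps the same operations
(`rehabkb fixtures --out model.yaml`, then `rehabkb classify model.yaml
patient2015`, `rehabkb candidates`, `rehabkb recommend`, `rehabkb export`,
`rehabkb extract-module`).

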