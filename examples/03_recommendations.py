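"""Derive recommended, contraindicated and suitable exercises for a patient.

Rules come from three sources: the protocol itself (phase-n patients get
phase-n exercises), general physiotherapy knowledge (e.g. no abduction
above 80° after a dislocation), and per-patient clinician entries. A
contraindication always wins: suitable = recommended - contraindicated.
"""

from rehabkb import (
    JointRef,
    MovementType,
    Posture,
    Side,
    Submovement,
    assign_exercise_to_phase,
    build_reference_fixture,
    compose_exercise,
    recommend,
)
from rehabkb.model import Movement

fixture = build_reference_fixture()

# A left-sided abduction exercise reaching 90° — beyond the 80° dislocation
# threshold — assigned to phase 2 alongside the reference exercise.
left_gj = JointRef("glenohumeral-joint", Side.LEFT)
risky = compose_exercise("ExerRisky", "deep abduction", [Movement(
    id="mov-risky", name="abduction to 90", initial=Posture("a"), final=Posture("b"),
    components=frozenset({Submovement(left_gj, MovementType.ABDUCTION, 0, 90)}),
)])
catalog = fixture.catalog + [risky]
protocol = assign_exercise_to_phase("ExerRisky", fixture.protocol.phase(2),
                                    fixture.protocol, catalog)

result = recommend(fixture.patient2015, fixture.rules.values(), catalog,
                   {protocol.name: protocol})
print("recommended:    ", sorted(result.recommended))
print("contraindicated:", sorted(result.contraindicated))
print("suitable:       ", sorted(result.suitable))
for rule_id, contributed in result.fired_rules:
    print(f"  fired {rule_id}: {sorted(contributed)}")

# The patient is in phase 2, so both phase-2 exercises are recommended; but
# their past dislocation contraindicates the 90° abduction, leaving only
# the reference exercise suitable.
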