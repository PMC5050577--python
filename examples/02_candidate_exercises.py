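"""Find which exercises a protocol phase admits, and assign one.

An exercise is a candidate for a phase when every one of its movements
stays within the phase's ROM caps. Later phases relax earlier caps, so
earlier candidates remain available later (subsumption).
"""

from rehabkb import (
    allowed_subsumes,
    assign_exercise_to_phase,
    build_reference_fixture,
    candidate_exercises,
    compose_exercise,
)

fixture = build_reference_fixture()
protocol = fixture.protocol

diagonal = compose_exercise("ExerDiagonal", "three-plane diagonal",
                            [fixture.movements["Mov2.2.1z"]])
catalog = fixture.catalog + [diagonal]

for phase_number in (2, 3):
    ids = candidate_exercises(protocol.phase(phase_number), catalog)
    print(f"phase {phase_number} candidates: {ids}")

print("phase-2 caps dominated by phase-3 caps:",
      allowed_subsumes(protocol.phase(2).allowed, protocol.phase(3).allowed))

# The 180° flexion component of the diagonal exceeds every cap, so it is a
# candidate for neither phase; the 90° abduction exercise fits both. An
# accepted candidate can then be assigned to the phase:
mov = fixture.movements["Mov2.1.5d"]
extra = compose_exercise("ExerWarmup", "warm-up abduction", [mov])
updated = assign_exercise_to_phase("ExerWarmup", protocol.phase(2), protocol,
                                   catalog + [extra])
print("phase-2 assigned exercises:", updated.phase(2).assigned_exercises)
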