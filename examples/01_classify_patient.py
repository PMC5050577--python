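"""Classify a patient into a treatment-protocol phase from ROM and pain.

Builds the shoulder reference model, then classifies the example patient
before and after their flexion range of motion improves.
"""

from rehabkb import build_reference_fixture, classify_patient

fixture = build_reference_fixture()
protocol = fixture.protocol

before = classify_patient(fixture.patient2015.latest_record, protocol)
after = classify_patient(fixture.patient2015_updated.latest_record, protocol)

print(f"protocol: {protocol.name} ({len(protocol.phases)} phases)")
print(f"initial record  (flexion 80°, VAS 0.0, no pain): phase {before.selected_phase}")
print(f"updated record (flexion 100°, VAS 0.0, no pain): phase {after.selected_phase}")
match = after.explanation[after.selected_phase][0]
print(f"matched band: {match.band.type.value} "
      f"[{match.band.lower_inclusive}, {match.band.upper_exclusive}) "
      f"at ROM {match.exploration.rom_value}")

# The selected phase is the stage of therapy whose ROM/pain conditions the
# latest record satisfies; improving from 80° to 100° of pain-free flexion
# moves the patient from phase 2 to phase 3.
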