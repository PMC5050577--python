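"""Save the model as YAML and export RDF triples / OWL axioms.

The YAML dialect is the authoring format (load/save round-trips exactly);
RDF and OWL are export targets: patient records become subject-predicate-
object triples, the catalog becomes class axioms with restrictions.
"""

import io

from rehabkb import (
    ModelBundle,
    build_reference_fixture,
    export_axioms,
    export_record_triples,
    load_model,
    save_model,
)

fixture = build_reference_fixture()
bundle = ModelBundle(
    movements=dict(fixture.movements),
    exercises=dict(fixture.exercises),
    protocols=dict(fixture.protocols),
    rules=dict(fixture.rules),
    patients={fixture.patient2015.id: fixture.patient2015},
    anatomy=fixture.anatomy,
)

yaml_text = save_model(bundle)
again = load_model(io.StringIO(yaml_text))
print(f"YAML model: {len(yaml_text)} bytes; round-trip exact:",
      save_model(again) == yaml_text)

triples = export_record_triples(fixture.patient2015, fixture.patient2015.records[0])
print(f"\npatient record as RDF ({len(triples.splitlines())} triples), excerpt:")
for line in triples.splitlines():
    if "hasROMvalue" in line or "hasRecord" in line or "hasPain" in line:
        print(" ", line)

axioms = export_axioms(bundle)
n_axioms = sum(1 for l in axioms.splitlines()
               if "equivalentClass" in l or "subClassOf" in l)
print(f"\nOWL export: {len(axioms.splitlines())} triples, {n_axioms} class axioms")

# The record triples follow the record-as-answers pattern (patient hasRecord
# record, record hasAnswer typed answer nodes); output is sorted N-Triples,
# so identical models always produce byte-identical documents.
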