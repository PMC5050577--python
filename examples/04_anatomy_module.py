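"""Query the anatomy concept graph and extract a reasoning-sized module.

Partonomy and laterality answer "which parts compose this joint?" and
"which side is this structure on?"; module extraction cuts a large
taxonomy down to the seeds, their upper hierarchy and connected concepts.
"""

from rehabkb import (
    ExtractionConfig,
    build_anatomy_fixture,
    extract_module,
    laterality_of,
    parts_of,
)

graph = build_anatomy_fixture()
print(f"full graph: {len(graph)} concepts")

joint = "left-glenohumeral-joint"
print(f"parts of {joint}: {parts_of(graph, joint)}")
print(f"laterality: {laterality_of(graph, joint)}")

module = extract_module(graph, ExtractionConfig(
    seeds=frozenset({joint}),
    property_types=frozenset({"constitutional_part", "articulates_with"}),
    hop_limit=1,
))
print(f"extracted module: {len(module)} concepts")
print(sorted(module.nodes))

# The module keeps the joint, its is_a ancestors up to the root, and the
# structures one property-hop away — small enough for interactive reasoning
# while every kept concept stays connected (no orphans).
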