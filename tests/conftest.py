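import random

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from rehabkb import (
    GeneratorParams,
    JointRef,
    Movement,
    MovementType,
    Posture,
    Side,
    Submovement,
    build_reference_fixture,
)


@pytest.fixture(scope="session")
def fixture():
    """The shoulder-rehabilitation reference fixture (built once)."""
    return build_reference_fixture()


@pytest.fixture(scope="session")
def strict_fixture():
    return build_reference_fixture(mode="strict")


def make_movement(mid, components, initial="p0", final="p1"):
    return Movement(
        id=mid,
        name=mid,
        initial=Posture(initial),
        final=Posture(final),
        components=frozenset(components),
    )


def sub(type_, rom_max, joint="glenohumeral-joint", side=Side.UNSPECIFIED, rom_min=0):
    return Submovement(JointRef(joint, side), MovementType(type_), rom_min, rom_max)


def random_movement(rng: random.Random, mid: str, n_components=None,
                    initial="p0", final="p1") -> Movement:
    n = n_components or rng.randint(1, 4)
    comps = set()
    while len(comps) < n:
        comps.add(
            Submovement(
                JointRef(rng.choice(["glenohumeral-joint", "elbow-joint"]),
                         rng.choice(list(Side))),
                rng.choice(list(MovementType)),
                0,
                rng.randint(0, 180),
            )
        )
    return make_movement(mid, comps, initial, final)
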