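import numpy as np
import pytest
import trimesh

from gantryclear.fixtures import SITE_PRESETS, make_phantom, _build_context, _machine_for
from gantryclear.machine import DimensionSet, build_machine


@pytest.fixture(scope="session")
def default_dims():
    return DimensionSet()


@pytest.fixture(scope="session")
def machine_civco(default_dims):
    return build_machine(default_dims, "civco", ers_attached=False)


@pytest.fixture(scope="session")
def machine_with_ers(default_dims):
    return build_machine(default_dims, "civco", ers_attached=True)


@pytest.fixture(scope="session")
def gu_phantom():
    return make_phantom("gu", 1)


@pytest.fixture(scope="session")
def gu_setup(gu_phantom):
    """Machine + phantom + plan context for a standard pelvis configuration."""
    from gantryclear.kinematics import BeamConfig

    machine = _machine_for("gu")
    beam = BeamConfig("gu1", 50.0, 0.0, (0.0, -60.0, 0.0))
    ctx = _build_context("gu", (beam,), SITE_PRESETS["gu"].jct_mean)
    return machine, gu_phantom, ctx, beam


@pytest.fixture(scope="session")
def staged_triple():
    """Breast scenarios staged at 50 / 25 / 0 mm oracle-verified clearance."""
    from gantryclear.fixtures import make_scenario
    from gantryclear.kinematics import BeamConfig

    beam = BeamConfig("stage", 35.0, 0.0, ers_required=True)
    return {
        t: make_scenario("breast_chestwall", beam, t, seed=1) for t in (50.0, 25.0, 0.0)
    }


@pytest.fixture(scope="session")
def mix12():
    from gantryclear.fixtures import collision_mix_v1

    return collision_mix_v1(seed=0)


def random_mesh_pair(rng):
    """A small random mesh pair (sphere + box), sometimes overlapping."""
    a = trimesh.creation.icosphere(subdivisions=1, radius=rng.uniform(5.0, 25.0))
    a.apply_translation(rng.uniform(-40.0, 40.0, 3))
    b = trimesh.creation.box(rng.uniform(5.0, 40.0, 3))
    b.apply_translation(rng.uniform(-40.0, 40.0, 3))
    return a, b
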