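import numpy as np
import pytest

from acuhead import generate_head_phantom
from acuhead.cli import RunConfig, reconstruct_surface
from acuhead.frames import ModelFrame, center_of_mass
from acuhead.proportional import compute_all_proportional


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def sphere_phantom(run_config):
    """Default 128^3 spherical phantom: equal semiaxes, no noise."""
    volume, landmarks = generate_head_phantom(run_config.phantom_spec())
    return volume, landmarks


@pytest.fixture(scope="session")
def sphere_pipeline(run_config, sphere_phantom):
    """Reconstructed skin surface of the spherical phantom, in both frames.

    Heavy (one marching-cubes run on 128^3); shared across the suite.
    """
    volume, landmarks = sphere_phantom
    mesh, filled = reconstruct_surface(volume, run_config.skin_threshold, run_config)
    frame = ModelFrame(tuple(center_of_mass(filled)), run_config.alpha)
    return {
        "volume": volume,
        "landmarks": landmarks,
        "filled": filled,
        "mesh": mesh,
        "frame": frame,
        "mesh_model": mesh.transformed(frame.to_model, "model"),
        "landmarks_model": landmarks.transformed(frame.to_model, "model"),
    }


@pytest.fixture(scope="session")
def sphere_proportional(run_config, sphere_pipeline):
    """The 24 proportional points on the spherical phantom (plus AUX)."""
    return compute_all_proportional(
        sphere_pipeline["mesh_model"],
        sphere_pipeline["landmarks_model"],
        config=run_config.solver_config(),
        include_aux=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
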