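"""Shared fixtures: meshes, pipelines and small cached datasets.

Session-scoped fixtures cache the expensive objects (mesh factorization,
GREIT matrix, simulated samples) so independent tests can share them.
"""

import numpy as np
import pytest

from eitsep.data import SimulationConfig, SimulationPipeline, generate_dataset
from eitsep.forward import ForwardOperator, StimulationProtocol, build_mesh
from eitsep.phantoms import PhantomSamplingConfig, sample_phantom


@pytest.fixture(scope="session")
def small_mesh():
    return build_mesh(400)


@pytest.fixture(scope="session")
def mesh():
    return build_mesh(1024)


@pytest.fixture(scope="session")
def protocol():
    return StimulationProtocol()


@pytest.fixture(scope="session")
def forward_op(mesh, protocol):
    return ForwardOperator(mesh, protocol)


@pytest.fixture(scope="session")
def small_forward_op(small_mesh, protocol):
    return ForwardOperator(small_mesh, protocol)


@pytest.fixture(scope="session")
def pipeline():
    return SimulationPipeline(SimulationConfig(), seed=0)


@pytest.fixture(scope="session")
def tiny_samples(pipeline):
    """24 simulated samples for plumbing tests."""
    return generate_dataset(24, pipeline=pipeline, seed=0, stream=0)


@pytest.fixture()
def phantom_rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def default_phantom(phantom_rng):
    return sample_phantom(PhantomSamplingConfig(), phantom_rng)
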