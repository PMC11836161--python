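import numpy as np
import pytest

from spineseg.instance_stage import OracleInstancePredictor, semantic_to_instances
from spineseg.phantom import PhantomSpec, generate_phantom
from spineseg.volume_io import AnatomicalVolume, canonical_affine


@pytest.fixture(scope="session")
def phantom5():
    """A 5-vertebra unfused phantom (shared, treat as read-only)."""
    return generate_phantom(PhantomSpec(n_vertebrae=5, seed=7))


@pytest.fixture(scope="session")
def phantom5_result(phantom5):
    """Oracle phase-2 result on the 5-vertebra phantom."""
    return semantic_to_instances(
        phantom5.semantic, OracleInstancePredictor(phantom5.instances)
    )


@pytest.fixture()
def tiny_volume():
    """A small labeled PIR volume for I/O round-trips."""
    rng = np.random.default_rng(0)
    data = rng.integers(0, 5, size=(10, 12, 8), dtype=np.uint8)
    return AnatomicalVolume(data, canonical_affine((0.8, 0.8, 3.3)))


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return AnatomicalVolume(np.asarray(data), canonical_affine(spacing))
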