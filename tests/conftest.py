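import numpy as np
import pytest

from aquapore import GeneratorSpec, LayerPartition, PoreGeometry, generate


@pytest.fixture
def small_pore() -> PoreGeometry:
    """The tight study geometry: R = 7 Å, L = 26 Å, axis along z at the origin."""
    return PoreGeometry(radius_R=7.0, length_L=26.0)


@pytest.fixture
def two_layer_partition() -> LayerPartition:
    return LayerPartition(boundaries_r=np.array([3.5]), labels=["inner", "contact"])


@pytest.fixture
def uniform_gas_run():
    """Moderate uniform-gas trajectory with its ground truth and geometry."""
    spec = GeneratorSpec(kind="uniform_gas", n_molecules=800, n_frames=10, seed=11)
    return generate(spec)
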