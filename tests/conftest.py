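import numpy as np
import pytest

from hicforecast.hic_io import ContactMatrix, SpatioTemporalStack
from hicforecast.synthetic import SyntheticConfig, generate_stack


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_config():
    """Three-TAD, 80-bin series with an establishment (ramp) schedule."""
    return SyntheticConfig(
        n_bins=80,
        n_steps=6,
        decay_exponent=1.0,
        tad_boundaries=(20, 40, 60),
        tad_strength_schedule=tuple(np.linspace(0.0, 2.0, 6)),
        depth=2e5,
        seed=7,
    )


@pytest.fixture
def small_stack(small_config):
    return generate_stack(small_config)


def random_symmetric_matrix(rng, n_bins, chrom="chrR", resolution=40000, scale=1.0):
    m = rng.random((n_bins, n_bins)) * scale
    m = 0.5 * (m + m.T)
    return ContactMatrix(chrom=chrom, resolution=resolution, values=m)


@pytest.fixture
def random_stack(rng):
    """Six random symmetric [0,1] matrices on a 60-bin grid."""
    return SpatioTemporalStack([random_symmetric_matrix(rng, 60) for _ in range(6)])
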