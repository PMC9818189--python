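import numpy as np
import pytest

from tmedeconv import AtlasSpec, make_atlas, normalize_counts


@pytest.fixture(scope="session")
def small_atlas():
    """3-type depth-normalised synthetic atlas used across modules."""
    spec = AtlasSpec(
        n_types=3,
        n_cells_per_type=60,
        n_genes=300,
        n_markers_per_type=10,
        marker_fold_change=8.0,
        seed=7,
    )
    return normalize_counts(make_atlas(spec))


@pytest.fixture(scope="session")
def five_type_atlas():
    """5-type atlas sized for exact-recovery deconvolution checks."""
    spec = AtlasSpec(
        n_types=5,
        n_cells_per_type=100,
        n_genes=800,
        n_markers_per_type=20,
        marker_fold_change=8.0,
        seed=1,
    )
    return normalize_counts(make_atlas(spec))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
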