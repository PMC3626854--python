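import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hsforest import SyntheticSpec, generate_decoy_set, generate_native


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_set():
    """207-decoy set: dominant near-native cluster, secondary cluster,
    diffuse outliers — the regime the selector targets."""
    spec = SyntheticSpec(
        n_res=30,
        cluster_sizes=(120, 60),
        cluster_center_rmsd=(2.0, 6.0),
        within_cluster_sigma=1.2,
        outlier_fraction=0.15,
        seed=11,
    )
    dset, labels = generate_decoy_set(spec)
    return dset, labels


@pytest.fixture(scope="session")
def tiny_native():
    return generate_native(10, np.random.default_rng(7))


def random_chain(n, rng, scale=5.0):
    """Random (non-protein-like) coordinates for metric property tests."""
    return rng.normal(scale=scale, size=(n, 3))
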