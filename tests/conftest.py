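import numpy as np
import pytest

from hilcell import SyntheticLatentConfig, generate_latent_dataset
from hilcell.cli import hard_cluster_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_data():
    """Small hard-cluster dataset with ground-truth strata for engine tests."""
    return hard_cluster_dataset(
        n_clusters=5, points_per_cluster=100, dim=16, hard_cluster=4, seed=0
    )


@pytest.fixture(scope="session")
def true_strata(small_data):
    """Stratum map taken from the generator's ground-truth clusters."""
    return dict(
        zip(small_data.ids.tolist(), small_data.true_cluster.tolist())
    )


@pytest.fixture(scope="session")
def separable_pair():
    """Two fully separable clusters, one per class."""
    config = SyntheticLatentConfig(
        n_clusters=2,
        dim=8,
        points_per_cluster=(80, 80),
        class_mix=(1.0, 0.0),
        separability=(0.0, 0.0),
        seed=7,
    )
    return generate_latent_dataset(config, seed=7)


@pytest.fixture(scope="session")
def study_setup():
    """Full-scale clustered study shared by the pipeline-level checks."""
    from hilcell import study

    return study.prepare_study()
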