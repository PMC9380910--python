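import numpy as np
import pytest

from microtraj import io
from microtraj.synthetic import TrajectoryDesign, make_classification_dataset, make_trajectory_dataset


@pytest.fixture(scope="session")
def classification_fixture():
    """3-class mean-shift dataset with known informative features."""
    return make_classification_dataset(seed=1)


@pytest.fixture(scope="session")
def trajectory_fixture():
    """Double-bifurcation cohort with ground truth (seed 0)."""
    return make_trajectory_dataset(TrajectoryDesign(seed=0))


@pytest.fixture(scope="session")
def trajectory_transformed(trajectory_fixture):
    table, meta, truth = trajectory_fixture
    abund = io.log10_pseudo_transform(io.to_relative(table))
    return abund, meta, truth


@pytest.fixture(scope="session")
def fitted_tree(trajectory_transformed):
    """Principal tree on the ground-truth informative features."""
    from microtraj.tree import fit_principal_tree

    abund, _meta, truth = trajectory_transformed
    X = abund.transformed.T[:, truth.informative]
    return fit_principal_tree(X, sigma=0.1, lambda_tree=150.0)


@pytest.fixture
def two_blobs():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0.0, 1.0, (30, 4)), rng.normal(20.0, 1.0, (30, 4))])
    labels = np.r_[np.zeros(30, int), np.ones(30, int)]
    return X, labels
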