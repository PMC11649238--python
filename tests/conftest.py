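import numpy as np
import pytest

from rpmaxent import (
    ChainConfig,
    Nonlinearity,
    ProjectionSet,
    RPModel,
    SpikeRaster,
    build_sparse_projections,
    make_ground_truth_model,
    mh_sample,
)


@pytest.fixture(scope="session")
def closed_form_model():
    """Two-neuron, single Heaviside projection a=(1,1), theta=1, lambda=ln 3.

    With H(0)=1 the projection fires on 3 of the 4 patterns, giving
    Z = 1 + 3 exp(-lambda) = 2 and p(0,0) = 1/2, others 1/6 each.
    """
    P = ProjectionSet(
        mask=np.array([[1, 1]]),
        weights=np.array([[1.0, 1.0]]),
        thresholds=np.array([1.0]),
        nonlinearity=Nonlinearity("heaviside"),
    )
    return RPModel(P, np.array([np.log(3.0)]))


@pytest.fixture(scope="session")
def small_sigmoid_model():
    """Seeded n=8 ground-truth sigmoid model in the sparse-firing regime."""
    return make_ground_truth_model(
        n_neurons=8, n_proj=10, indegree=3.0, target_rate_range=(0.01, 0.25), seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_sigmoid_model):
    """40k/10k train-test rasters sampled from the n=8 ground truth."""
    raster = mh_sample(small_sigmoid_model, ChainConfig(n_samples=50_000, seed=12))
    return raster[:40_000], raster[40_000:]


@pytest.fixture(scope="session")
def n6_projections():
    return build_sparse_projections(
        6, 8, 3.0, Nonlinearity("sigmoid", beta=2.0), seed=5
    )


@pytest.fixture()
def sparse_raster():
    rng = np.random.default_rng(7)
    return SpikeRaster((rng.random((3000, 6)) < 0.2).astype(int))
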