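import numpy as np
import pytest

from bayesteach import (
    GaussianFeatureSpec,
    PLDAFeatureClassifier,
    ToyImageSpec,
    fit_plda,
    make_gaussian_feature_dataset,
    make_toy_image_backend,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gaussian_data():
    """Well-separated 6-category dataset drawn from the PLDA generative model."""
    spec = GaussianFeatureSpec(
        n_categories=6,
        items_per_category=40,
        feature_dim=3,
        psi_true=np.array([4.0, 1.0, 0.25]),
        seed=7,
    )
    return make_gaussian_feature_dataset(spec)


@pytest.fixture(scope="session")
def fitted(gaussian_data):
    dataset, _ = gaussian_data
    model = fit_plda(dataset)
    return dataset, model


@pytest.fixture(scope="session")
def plda_classifier(fitted):
    dataset, model = fitted
    return PLDAFeatureClassifier(model, dataset)


@pytest.fixture(scope="session")
def toy_backend():
    spec = ToyImageSpec(height=24, width=24, images_per_category=6, noise_sd=0.02, seed=11)
    return make_toy_image_backend(spec)
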