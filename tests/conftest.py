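import numpy as np
import pytest

from mcanmf import FitConfig, fit_mca, make_ground_truth, sample_dataset


@pytest.fixture(scope="session")
def toy_ground_truth():
    """Small noise-free generative model: 4 concepts, 2 modalities, no distractors."""
    return make_ground_truth(
        n_concepts=4,
        n_distractors=0,
        dims={"mod1": 12, "mod2": 10},
        noise_level=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_dataset(toy_ground_truth):
    return sample_dataset(toy_ground_truth, 60, seed=12)


@pytest.fixture(scope="session")
def toy_model(toy_dataset):
    """Exactly factorizable toy problem: k equals the number of generative
    components, so the fit drives the I-divergence essentially to zero."""
    config = FitConfig(k=4, max_iter=400, tol=1e-12, seed=13)
    model, h = fit_mca(toy_dataset, config)
    return model, h
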