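import numpy as np
import pytest

import omegacp as o


@pytest.fixture(scope="session")
def fig1_model():
    """Symmetric tilted two-state cone: g̃ = h̃ = 0.5, s_x = 0.25, s_y = 0.1."""
    return o.first_order_two_state(0.5, 0.5, 0.25, 0.1)


@pytest.fixture(scope="session")
def fig1_dataset(fig1_model):
    coords = o.latin_hypercube(2, 600, (-0.25, 0.25), seed=3)
    return o.make_dataset(fig1_model, coords, seed=3)


@pytest.fixture(scope="session")
def raw_descriptor():
    return o.DescriptorConfig(mode="raw")


@pytest.fixture(scope="session")
def fixed_policy():
    """Fixed hyperparameters: lengthscale ≈ domain size, tiny ridge."""
    return o.HyperparamPolicy(kernel="rbf", lengthscale=0.3, regularization=1e-10)


@pytest.fixture(scope="session")
def fig1_ensembles(fig1_dataset, raw_descriptor, fixed_policy):
    """ω-CP and direct-energy surrogates fitted to the same 600-point set."""
    return {
        mode: o.fit_ensemble(fig1_dataset, raw_descriptor, mode, fixed_policy)
        for mode in ("omega_cp", "direct")
    }


def random_sorted_energies(rng, n):
    return np.sort(rng.uniform(-10.0, 10.0, size=n))
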