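import numpy as np
import pytest

import ofcnet as oc


@pytest.fixture(scope="session")
def network30():
    """Ground-truth 30-residue network with frustrated second neighbors."""
    spec = oc.SyntheticNetworkSpec(n=30, seed=7)
    return oc.generate_network(spec)


@pytest.fixture(scope="session")
def sampled_cov30(network30):
    """Scalar covariance of 500 Gaussian models drawn from the network."""
    K_true, _ = network30
    samples = oc.sample_scalar_displacements(K_true, 500, seed=11)
    return oc.empirical_scalar_covariance(samples)


@pytest.fixture(scope="session")
def fitted_K30(network30, sampled_cov30):
    """Entropy-maximization fit of the 30-residue sample covariance."""
    K_true, _ = network30
    return oc.optimize_K(sampled_cov30, K_true.constraints,
                         oc.OptimizerSettings(tolerance=0.01))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, n, cond_lift=None):
    """Random symmetric positive-definite matrix."""
    a = rng.standard_normal((n, n))
    return a @ a.T + (cond_lift if cond_lift is not None else n) * np.eye(n)


@pytest.fixture(scope="session")
def helix_ensemble():
    """Noiseless ideal α-helix, the canonical annotation fixture."""
    return oc.ideal_helix_ensemble(16, m=2)


@pytest.fixture(scope="session")
def helix_annotations(helix_ensemble):
    return oc.assign_hbonds_internal(helix_ensemble)
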