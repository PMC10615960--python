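import numpy as np
import pytest

import modmedpower as mp


@pytest.fixture(scope="session")
def simple_study():
    """Single-group simple mediation at the canonical settings."""
    return mp.simple_mediation_study()


@pytest.fixture(scope="session")
def modmed_study():
    """Single-group moderated mediation (2x2, 25 per cell)."""
    return mp.moderated_mediation_study()


@pytest.fixture(scope="session")
def simple_sample(simple_study):
    return mp.generate_sample(simple_study.population, simple_study.design,
                              seed=20240517)


@pytest.fixture(scope="session")
def simple_fit(simple_study, simple_sample):
    return mp.fit_path_model(simple_study.analysis, simple_sample)


def make_random_recursive_spec(rng: np.random.Generator, n_endo: int = 3,
                               n_cov: int = 2):
    """A random recursive standardizable spec for property tests."""
    endo = [f"y{i}" for i in range(n_endo)]
    cov = [f"x{i}" for i in range(n_cov)]
    # modest slopes keep explained variance < 1
    K = rng.uniform(-0.4, 0.4, size=(n_endo, n_cov))
    B = np.zeros((n_endo, n_endo))
    for j in range(n_endo):
        for k in range(j):
            if rng.random() < 0.7:
                B[j, k] = rng.uniform(-0.4, 0.4)
    KA = mp.make_parameter_matrix(
        "KA", [[f"k{j}{k}" for k in range(n_cov)] for j in range(n_endo)],
        K, endo, cov)
    BE = mp.make_parameter_matrix(
        "BE", [[f"b{j}{k}" if B[j, k] else 0.0 for k in range(n_endo)]
               for j in range(n_endo)], B, endo, endo)
    PS = mp.make_parameter_matrix(
        "PS", [[f"p{j}" if j == k else 0.0 for k in range(n_endo)]
               for j in range(n_endo)], np.eye(n_endo), endo, endo)
    return mp.assemble_model({"g1": {"KA": KA, "BE": BE, "PS": PS}},
                             endogenous=endo, covariates=cov)
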