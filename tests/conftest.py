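import numpy as np
import pytest

import prosplit as ps


@pytest.fixture(scope="session")
def reg_spec():
    return ps.ModelSpec("regression")


@pytest.fixture(scope="session")
def ev_spec():
    return ps.ModelSpec("regression", scorer_id="explained_variance")


@pytest.fixture(scope="session")
def clf_spec():
    return ps.ModelSpec("classification")


@pytest.fixture(scope="session")
def strong_regression():
    """Strong-signal regression data (population R^2 = 0.7)."""
    return ps.make_regression(
        ps.GeneratorConfig(n=400, p=8, task="regression", target_signal=0.7, seed=17)
    )


@pytest.fixture(scope="session")
def noise_classification():
    """Balanced two-class data with zero separation."""
    return ps.make_classification(
        ps.GeneratorConfig(
            n=120, p=5, task="classification", target_signal=0.0, seed=3
        )
    )


@pytest.fixture()
def toy_separable():
    """Linearly separable one-feature toy."""
    X = np.array([[-1.0], [-0.9], [0.9], [1.0]])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    return ps.Dataset(X, y, "classification")
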