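import numpy as np
import pytest

from tgbrt.synthetic_data import (EnvStack, VirtualSpeciesSpec, make_env_stack,
                                  make_target_group)


@pytest.fixture(scope="session")
def small_stack():
    return make_env_stack(20, 20, 5, 0.0, seed=7)


def build_study_group(seed: int = 3):
    """A 320-record, 4-species target group with the study's focal presence
    counts (73, 24, 55) plus a 168-record filler species, on distinct cells."""
    stack = make_env_stack(40, 40, 6, 0.3, seed=seed)
    specs = [
        VirtualSpeciesSpec("bufo", {"BIO1": 0.5}, n_presences=73, seed=seed + 1),
        VirtualSpeciesSpec("salamandrina", {"BIO2": 0.5}, n_presences=24, seed=seed + 2),
        VirtualSpeciesSpec("triturus", {"BIO3": 0.5}, n_presences=55, seed=seed + 3),
        VirtualSpeciesSpec("others", {"BIO1": 0.2}, n_presences=168, seed=seed + 4),
    ]
    return stack, make_target_group(stack, specs)


@pytest.fixture(scope="session")
def study_group():
    return build_study_group()


@pytest.fixture(scope="session")
def tiny_training():
    """A 60-row, 3-predictor binary problem with one informative predictor."""
    rng = np.random.default_rng(11)
    X = rng.normal(size=(60, 3))
    eta = 2.5 * X[:, 0]
    y = (rng.uniform(size=60) < 1 / (1 + np.exp(-eta))).astype(float)
    if y.min() == y.max():  # pragma: no cover - seed chosen to avoid this
        y[0] = 1 - y[0]
    return X, y
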