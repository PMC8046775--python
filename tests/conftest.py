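import numpy as np
import pytest

from openpref.dynamics import ModelParams


@pytest.fixture(scope="session")
def exp1_params() -> ModelParams:
    """Experiment-1 emulation parameter set (bundled defaults)."""
    from openpref.io import load_bundled_params
    return load_bundled_params("exp1_emulation")


@pytest.fixture(scope="session")
def exp2_params() -> ModelParams:
    from openpref.io import load_bundled_params
    return load_bundled_params("exp2_emulation")


def random_params(rng: np.random.Generator, n: int = 5,
                  alpha: float | None = None) -> ModelParams:
    """Random valid parameter set with moderate rates."""
    sigma_m = rng.uniform(0.01, 2.0)
    return ModelParams(
        mu_q=rng.uniform(0.0, 2.0),
        sigma_q=rng.uniform(0.0, 3.0),
        mu_m=sigma_m * rng.uniform(-0.9, 0.9),
        sigma_m=sigma_m,
        alpha=rng.uniform(0, 1) if alpha is None else alpha,
        lambda_decay=rng.uniform(0.0, 0.5),
        s_v=rng.uniform(0.5, (n - 1) / 2 + 0.5),
        n=n, s_max=30.0)
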