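import numpy as np
import pandas as pd
import pytest

from intergen.io import CountMatrix, SampleSheet
from intergen.simulate import SyntheticConfig, generate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced four-species experiment with planted truth (session-cached)."""
    cfg = SyntheticConfig(n_orthogroups=600)
    return cfg, generate_experiment(cfg, seed=11)


def two_group_counts(y: np.ndarray, n_a: int, n_b: int, species: str = "sp"):
    """Wrap a genes-by-samples array as CountMatrix + two-condition sheet."""
    samples = [f"s{j}" for j in range(n_a + n_b)]
    cm = CountMatrix([f"g{i}" for i in range(y.shape[0])], samples, y, species)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "species": species,
                "generation": "F1",
                "parental_condition": ["control"] * n_a + ["stress"] * n_b,
                "replicate": list(range(1, n_a + 1)) + list(range(1, n_b + 1)),
            }
        )
    )
    return cm, sheet


def nb_draw(rng, mu, alpha, size):
    """NB draws with Var = mu + alpha mu^2."""
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=size)
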