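import warnings

import numpy as np
import pandas as pd
import pytest

from trialmr.simulate import simulate_summary_pairs


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*[Cc]onverge.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_pairs():
    """Ten valid summary-level instrument pairs, true theta = 0.25."""
    pairs, _ = simulate_summary_pairs(n_variants=10, theta=0.25, seed=7)
    return pairs


def random_pairs(seed, n=None):
    rng = np.random.default_rng(seed)
    J = int(n or rng.integers(4, 15))
    g = rng.uniform(0.05, 0.5, J) * rng.choice([-1, 1], J)
    return pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(J)],
        "effect_allele": "A", "other_allele": "G",
        "beta_exp": g, "se_exp": rng.uniform(0.01, 0.05, J),
        "beta_out": rng.normal(0.2 * g, 0.05), "se_out": rng.uniform(0.02, 0.08, J),
        "eaf_exp": 0.3, "eaf_out": 0.3, "action": "kept",
    })
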