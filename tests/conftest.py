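import numpy as np
import pytest

import normstab as ns


@pytest.fixture(scope="session")
def random_panel():
    """200 seeded random stochastic C/D norms with mu in [0.01, 0.3].

    Shared by the oracle-equivalence and recursion-agreement checks.
    """
    rng = np.random.default_rng(20250917)
    panel = []
    for _ in range(200):
        norm = ns.sample_random_norm(rng)
        err = ns.ErrorModel(mu=float(rng.uniform(0.01, 0.3)))
        params = ns.GameParams(1.0, float(rng.uniform(0.1, 0.9)))
        panel.append((norm, params, err))
    return panel


@pytest.fixture(scope="session")
def leading_eight_norms():
    return {name: ns.leading_eight(name) for name in ns.LEADING_EIGHT_NAMES}
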