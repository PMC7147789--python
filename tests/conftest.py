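import pytest

from ncsim import load_oregon_bundle, run

#: Monte Carlo settings used by the full-bundle tests: the study convention
#: of 1000 iterations, under one fixed seed.
N_ITER = 1000
SEED = 7


@pytest.fixture(scope="session")
def oregon_bundle():
    return load_oregon_bundle()


@pytest.fixture(scope="session")
def oregon_runs(oregon_bundle):
    """One full simulation per implementation scenario, shared across tests."""
    return {
        name: run(oregon_bundle, name, n_iter=N_ITER, seed=SEED)
        for name in ("limited", "moderate", "ambitious")
    }
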