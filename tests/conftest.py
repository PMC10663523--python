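import numpy as np
import pytest

import memstates as ms


@pytest.fixture(scope="session")
def reference():
    return ms.make_toy_domain()


@pytest.fixture(scope="session")
def small_library(reference):
    """200-member three-state library with default truth conditions."""
    lib, labels = ms.sample_library(
        reference, ms.TruthEnsemble(seed=3), n_conformers=200
    )
    return lib, labels


def planted_measurement(lib, seed, n_members=16, noise=0.0):
    """Noise-free (or noisy) measurement generated from a known multiset."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(lib), n_members, replace=False)
    members = [lib.conformers[i] for i in idx]
    meas = ms.simulate_pre_measurement(members, noise_fraction=noise, seed=seed)
    return meas, np.sort(idx)
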