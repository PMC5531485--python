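import numpy as np
import pytest

import hexpassage as hp


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_lattice():
    return hp.LatticeConfig(10, 10, delta=24.0)


def place_cells(config: hp.LatticeConfig, sites, pp, pm=0.35, seed=0, tau=1.0 / 12.0):
    """Build a state with cells at explicit (i, j) sites (test helper)."""
    state = hp.HexLatticeState(config, pm=pm, tau=tau, seed=seed)
    flat = np.array([(j - 1) * config.I + (i - 1) for i, j in sites], dtype=np.int64)
    pp = np.full(flat.size, pp, dtype=float) if np.isscalar(pp) else np.asarray(pp, float)
    state._populate(flat, pp)
    return state
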