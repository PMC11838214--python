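import numpy as np
import pytest

import clonedeconv as cd
from clonedeconv import simulator as sim


@pytest.fixture
def tiny_cfg():
    """Small desk-scale simulation: 3 clones, 2 samples, 4 SVs, 4 SNVs."""
    return sim.SimConfig(n=3, m=2, g=4, n_svs=4, r=3, seed=11)


@pytest.fixture
def tiny_noise_free(tiny_cfg):
    bulk, rna, truth = sim.simulate_instance(tiny_cfg, noise=False)
    return bulk, rna, truth


@pytest.fixture
def tiny_noisy(tiny_cfg):
    bulk, rna, truth = sim.simulate_instance(tiny_cfg, noise=True)
    return bulk, rna, truth


def random_micro_instance(seed: int, m: int = 2):
    """Random n=3, l=2, g=2, r=2 problem for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    n, l, g, r = 3, 2, 2, 2
    K = l + g + 2 * r
    Q = np.zeros((l + g, r), dtype=int)
    for b in range(l + g):
        Q[b, rng.integers(r)] = 1
    G = np.array([[0, 1], [1, 0]])
    F = rng.uniform(0, 2, size=(m, K)).round(2)
    C_rna = rng.integers(0, 3, size=(n, 2 * r))
    U = rng.dirichlet(np.ones(n), size=m)
    bulk = cd.BulkProfile(F=F, Q=Q, G=G, l=l, g=g, r=r)
    rna = cd.RnaCloneProfile(C_rna=C_rna)
    return bulk, rna, U
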