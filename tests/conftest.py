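import numpy as np
import pytest

from popmodes.tree import TreeEmission, chow_liu_fit, floor_joint


def random_tree_emission(n_cells: int, seed: int) -> TreeEmission:
    """An arbitrary valid tree emission: random marginals, random chain."""
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.1, 0.9, size=n_cells)
    order = rng.permutation(n_cells)
    edges = [
        tuple(sorted((int(order[k]), int(order[k + 1]))))
        for k in range(n_cells - 1)
    ]
    joints = np.empty((len(edges), 2, 2))
    for e, (i, j) in enumerate(edges):
        lo = max(0.0, m[i] + m[j] - 1)
        hi = min(m[i], m[j])
        p11 = rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo))
        joints[e] = floor_joint(m[i], m[j], p11, 1e-6)
    return TreeEmission(m, edges, joints)


def random_hmm(n_cells: int, n_modes: int, seed: int):
    from popmodes.hmm import HMMParams

    rng = np.random.default_rng(seed)
    P = rng.uniform(0.05, 1.0, size=(n_modes, n_modes))
    P /= P.sum(axis=0, keepdims=True)
    init = rng.dirichlet(np.ones(n_modes))
    emissions = [
        random_tree_emission(n_cells, seed * 100 + a) for a in range(n_modes)
    ]
    return HMMParams(n_modes=n_modes, transition=P, initial=init, emissions=emissions)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def chain3_emission():
    """3-cell chain fitted from data generated as a noisy copy chain."""
    rng = np.random.default_rng(7)
    n = 50_000
    c0 = (rng.random(n) < 0.5).astype(np.uint8)
    c1 = np.where(rng.random(n) < 0.9, c0, 1 - c0).astype(np.uint8)
    c2 = np.where(rng.random(n) < 0.6, c1, 1 - c1).astype(np.uint8)
    data = np.stack([c0, c1, c2])
    return data, chow_liu_fit(data)
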