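"""Shared fixtures: small random linked blocks and noise-free structured pairs."""

import numpy as np
import pytest

from discosca.blocks import BlockMatrix, LinkedBlocks
from discosca.synthetic import SimulationSpec, simulate_blocks


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_blocks(rng):
    """Two generic random blocks (6x4 and 5x4) sharing their columns."""
    return LinkedBlocks([
        BlockMatrix(rng.standard_normal((6, 4)), "X1"),
        BlockMatrix(rng.standard_normal((5, 4)), "X2"),
    ])


def make_pair(statuses, dims=(20, 15, 10), noise=0.0, seed=0):
    """Simulated pair realizing the given component statuses exactly.

    ``statuses`` is a string per component: 'd1', 'd2' or 'c'.  Per-block
    VAF proportions are built so that common components have equal
    proportions in both blocks whenever that is feasible (it is not when
    commons are mixed with distinctives in only one block — the lone
    block's distinctive share would have to be zero).
    """
    statuses = list(statuses)
    R = len(statuses)
    idx = {s: [r for r, st in enumerate(statuses) if st == s]
           for s in ("d1", "d2", "c")}
    # distinct weights avoid singular-value ties
    weights = np.array([1.0 / (r + 2) for r in range(R)])
    imposed = np.zeros((R, 2))
    n_c, n_d1, n_d2 = len(idx["c"]), len(idx["d1"]), len(idx["d2"])
    if n_c and (n_d1 == 0) != (n_d2 == 0):
        # unbalanced: exact equal common proportions unrealizable
        for r in idx["c"]:
            imposed[r] = weights[r], weights[r]
        for r in idx["d1"]:
            imposed[r, 0] = weights[r]
        for r in idx["d2"]:
            imposed[r, 1] = weights[r]
        imposed *= ((1 - noise) if noise else 0.9) / imposed.sum(axis=0).max()
    else:
        common_share = 0.5 if (n_d1 or n_d2) else 1.0
        if n_c:
            p = weights[idx["c"]] / weights[idx["c"]].sum() * common_share
            imposed[idx["c"], 0] = imposed[idx["c"], 1] = p
        if n_d1:
            q = weights[idx["d1"]] / weights[idx["d1"]].sum() * (1 - common_share if n_c else 1.0)
            imposed[idx["d1"], 0] = q
        if n_d2:
            q = weights[idx["d2"]] / weights[idx["d2"]].sum() * (1 - common_share if n_c else 1.0)
            imposed[idx["d2"], 1] = q
        imposed *= 1 - noise if noise else 1.0
    spec = SimulationSpec(dims=dims, imposed_vaf=imposed,
                          noise_fraction=noise, seed=seed)
    return simulate_blocks(spec)


@pytest.fixture
def noise_free_221():
    """Noise-free pair with 2 block-1-distinctive, 2 block-2-distinctive and
    1 common component."""
    return make_pair(["d1", "d1", "d2", "d2", "c"], seed=11)
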