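"""Shared fixtures and independent brute-force oracles for the test suite."""
import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import beecastes as bc
from beecastes.synth import random_bifurcating_tree


@pytest.fixture(scope="session")
def study():
    return bc.build_study_fixture()


@pytest.fixture
def three_tip():
    return bc.parse_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def four_tip():
    return bc.parse_newick("((A:1.5,B:0.5):1,(C:2,D:1):0.5):0;")


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the pruning/Fitch implementations)
# ---------------------------------------------------------------------------

def enumeration_loglik(tree, tip_state_idx, Q, root_prior="equal"):
    """Likelihood by explicit summation over all internal-node state
    assignments, using expm(Q*b) transition matrices. Exponential in the
    number of internal nodes; use on tiny trees only."""
    k = Q.shape[0]
    lengths = tree.branch_lengths_floored()
    P = {v: expm(Q * lengths[v]) for v in range(tree.n_nodes) if v != tree.root}
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tip_state = {int(t): int(s) for t, s in zip(tree.tip_ids, tip_state_idx)}
    if root_prior == "equal":
        prior = np.full(k, 1.0 / k)
    else:
        prior = np.asarray(root_prior, float)
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(internals)):
        state = dict(zip(internals, combo))
        state.update(tip_state)
        p = prior[state[tree.root]]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            p *= P[v][state[tree.parent[v]], state[v]]
        total += p
    return np.log(total)


def brute_force_fitch(tree, tip_state_idx):
    """Minimum change count by exhaustive search over internal labelings."""
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tip_state = {int(t): int(s) for t, s in zip(tree.tip_ids, tip_state_idx)}
    best = None
    for combo in itertools.product((0, 1), repeat=len(internals)):
        state = dict(zip(internals, combo))
        state.update(tip_state)
        changes = sum(state[v] != state[int(tree.parent[v])]
                      for v in range(tree.n_nodes) if v != tree.root)
        best = changes if best is None else min(best, changes)
    return best


def brute_force_vcv(tree):
    """Shared path lengths via explicit root-path intersection."""
    paths = {}
    for t in tree.tip_ids:
        path = []
        v = int(t)
        while tree.parent[v] >= 0:
            path.append(v)
            v = int(tree.parent[v])
        paths[int(t)] = path
    n = tree.n_tips
    V = np.zeros((n, n))
    for i, ti in enumerate(tree.tip_ids):
        for j, tj in enumerate(tree.tip_ids):
            shared = set(paths[int(ti)]) & set(paths[int(tj)])
            V[i, j] = sum(tree.length[v] for v in shared)
    return V


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
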