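"""Discrete-character evolution on rooted, time-calibrated trees.

This module provides the tree container used throughout the package
(:class:`PhyloTree`), Newick I/O (delegating parsing to dendropy), the
Brownian-motion variance–covariance matrix, parsimony (Fitch/Sankoff)
change counts, maximum-likelihood fitting of the one-rate symmetric Markov
model for a binary character (Mk1), forward simulation of continuous-time
Markov chains on trees, and stochastic character mapping (sampling full
character histories conditional on observed tip states).

Branch lengths are in millions of years throughout; rates are expected
state changes per million years.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np
from scipy import linalg as sla
from scipy import optimize

logger = logging.getLogger("beecastes")

# Numerical policy shared by every likelihood entry point.
BRANCH_LENGTH_FLOOR = 1e-6   # my; avoids singular transition matrices
RATE_LOWER = 1e-8            # lower bound of the Mk1 rate search
RATE_UPPER = 100.0           # upper bound of the Mk1 rate search
RATE_TOL = 1e-8              # absolute tolerance of the 1-D rate search
MAP_RETRY_BUDGET = 10_000    # rejection-sampling budget per branch


class NewickError(ValueError):
    """Malformed or invalid Newick input."""


class PolytomyError(ValueError):
    """Raised by operations that require a fully bifurcating tree."""


# ---------------------------------------------------------------------------
# Tree container and Newick I/O
# ---------------------------------------------------------------------------

class PhyloTree:
    """Rooted tree with branch lengths, stored as flat parent/child arrays.

    Node ids are integers ``0..n_nodes-1`` in preorder (root first).
    ``length[i]`` is the length of the branch subtending node ``i``
    (``nan`` when absent; the root branch defaults to 0). Polytomies are
    allowed; operations that require bifurcation say so.
    """

    def __init__(self, parent: np.ndarray, lengths: np.ndarray,
                 labels: List[Optional[str]]):
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(lengths, dtype=float)
        self.label = list(labels)
        self.n_nodes = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise NewickError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children: List[List[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.tip_ids = np.array([i for i in range(self.n_nodes) if not self.children[i]],
                                dtype=int)
        self.tip_labels = [self.label[i] for i in self.tip_ids]
        if any(l is None for l in self.tip_labels):
            raise NewickError("every tip must carry a label")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dupes = sorted({l for l in self.tip_labels if self.tip_labels.count(l) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")
        self._tip_index = {l: int(i) for l, i in zip(self.tip_labels, self.tip_ids)}
        # postorder: children before parents
        post: List[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            post.append(v)
            stack.extend(self.children[v])
        self.postorder = np.array(post[::-1], dtype=int)
        self.preorder = np.array(post, dtype=int)

    # -- basic queries ----------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def is_bifurcating(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def tip_id(self, label: str) -> int:
        return self._tip_index[label]

    def require_lengths(self) -> None:
        nonroot = np.ones(self.n_nodes, bool)
        nonroot[self.root] = False
        if np.isnan(self.length[nonroot]).any():
            raise ValueError("analysis requires branch lengths on every non-root branch")

    def branch_lengths_floored(self, floor: float = BRANCH_LENGTH_FLOOR) -> np.ndarray:
        """Branch lengths with zeros (and the root branch) floored for likelihood work."""
        self.require_lengths()
        b = self.length.copy()
        b[self.root] = 0.0
        mask = np.arange(self.n_nodes) != self.root
        b[mask] = np.maximum(b[mask], floor)
        return b

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node (root branch ignored)."""
        self.require_lengths()
        depth = np.zeros(self.n_nodes)
        for v in self.preorder:
            if v == self.root:
                continue
            depth[v] = depth[self.parent[v]] + self.length[v]
        return depth

    # -- Newick -----------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if self.is_tip(v):
                s = self.label[v] or ""
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
                if self.label[v]:
                    s += self.label[v]
            b = self.length[v]
            if not math.isnan(b):
                s += f":{b:.10g}"
            return s

        return fmt(self.root) + ";"

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.length.copy(), list(self.label))

    def resolve_polytomies(self) -> "PhyloTree":
        """Arbitrarily resolve polytomies with zero-length branches.

        Children beyond the second are peeled off onto new zero-length
        internal nodes (left-ladder resolution). The resolution is logged.
        """
        parent = list(self.parent)
        length = list(self.length)
        label = list(self.label)
        children = [list(c) for c in self.children]
        resolved = 0
        i = 0
        while i < len(children):
            kids = children[i]
            while len(kids) > 2:
                new = len(parent)
                parent.append(i)
                length.append(0.0)
                label.append(None)
                a, b = kids[-2], kids[-1]
                children.append([a, b])
                parent[a] = parent[b] = new
                kids[:] = kids[:-2] + [new]
                resolved += 1
            i += 1
        if resolved:
            logger.info("resolved %d polytomies with zero-length branches", resolved)
        return PhyloTree(np.array(parent), np.array(length), label)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Unquoted labels with underscores are kept verbatim. Malformed input
    raises :class:`NewickError` carrying dendropy's position diagnostics;
    duplicate tip labels are a validation error.
    """
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer/parser types
        raise NewickError(f"malformed newick: {exc}") from exc
    ids: Dict[int, int] = {}
    parent: List[int] = []
    lengths: List[float] = []
    labels: List[Optional[str]] = []
    for nd in dt.preorder_node_iter():
        i = len(parent)
        ids[id(nd)] = i
        parent.append(ids[id(nd.parent_node)] if nd.parent_node is not None else -1)
        lengths.append(float(nd.edge.length) if nd.edge.length is not None
                       else (0.0 if nd.parent_node is None else math.nan))
        if nd.taxon is not None:
            labels.append(nd.taxon.label)
        else:
            labels.append(nd.label)
    return PhyloTree(np.array(parent), np.array(lengths), labels)


def write_newick(tree: PhyloTree, path: Optional[str] = None) -> str:
    text = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Binary state vectors
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BinaryStateVector:
    """Tip states for one binary character, with a free-text meaning for state 1."""

    states: Dict[str, int]
    meaning: str = ""

    def __post_init__(self) -> None:
        for k, v in self.states.items():
            if v not in (0, 1):
                raise ValueError(f"state for {k!r} must be 0/1, got {v!r}")

    def aligned(self, tree: PhyloTree) -> np.ndarray:
        missing = [l for l in tree.tip_labels if l not in self.states]
        if missing:
            raise ValueError(f"tips without a state: {missing}")
        return np.array([self.states[l] for l in tree.tip_labels], dtype=int)

    def is_constant(self) -> bool:
        vals = set(self.states.values())
        return len(vals) < 2

    @classmethod
    def from_csv(cls, path, meaning: str = "") -> "BinaryStateVector":
        import pandas as pd
        df = pd.read_csv(path)
        if not {"species", "state"} <= set(df.columns):
            raise ValueError("state CSV needs columns: species,state")
        return cls(dict(zip(df["species"], df["state"].astype(int))), meaning)


# ---------------------------------------------------------------------------
# Brownian-motion variance-covariance matrix
# ---------------------------------------------------------------------------

def vcv_matrix(tree: PhyloTree) -> np.ndarray:
    """Species x species shared path length from the root (Brownian VCV).

    Row/column order follows ``tree.tip_labels``. Diagonal entries are
    root-to-tip distances; off-diagonals the depth of the most recent
    common ancestor.
    """
    tree.require_lengths()
    depth = tree.node_depths()
    n = tree.n_tips
    # ancestor chains, tip -> root
    chains = []
    for t in tree.tip_ids:
        ch = []
        v = int(t)
        while v >= 0:
            ch.append(v)
            v = int(tree.parent[v]) if tree.parent[v] >= 0 else -1
        chains.append(set(ch))
    V = np.zeros((n, n))
    for i in range(n):
        V[i, i] = depth[tree.tip_ids[i]]
        for j in range(i):
            shared = chains[i] & chains[j]
            V[i, j] = V[j, i] = max(depth[v] for v in shared)
    return V


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------

def fitch_count(tree: PhyloTree, states: BinaryStateVector) -> int:
    """Minimum number of state changes (Fitch parsimony).

    Implemented as unit-cost Sankoff dynamic programming, which reduces to
    Fitch on bifurcating trees and stays exact on polytomies.
    """
    x = states.aligned(tree)
    big = tree.n_nodes + 1
    cost = np.zeros((tree.n_nodes, 2))
    for v in tree.postorder:
        if tree.is_tip(v):
            s = x[np.flatnonzero(tree.tip_ids == v)[0]]
            cost[v] = [0 if s == k else big for k in (0, 1)]
        else:
            for k in (0, 1):
                cost[v, k] = sum(min(cost[c, 0] + (k != 0), cost[c, 1] + (k != 1))
                                 for c in tree.children[v])
    return int(cost[tree.root].min())


# ---------------------------------------------------------------------------
# CTMC transition matrices and pruning likelihood (k states)
# ---------------------------------------------------------------------------

def validate_rate_matrix(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q - np.diag(np.diag(Q))
    if (off < -1e-12).any():
        raise ValueError("off-diagonal rates must be >= 0")
    if np.abs(Q.sum(axis=1)).max() > 1e-8:
        raise ValueError("Q rows must sum to 0 (conservative generator)")
    return Q


def transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """exp(Q*b) for every branch length, stacked as (n_branches, k, k).

    Uses one eigendecomposition of Q; falls back to per-branch Pade expm
    when Q is defective or poorly conditioned.
    """
    Q = np.asarray(Q, float)
    lengths = np.asarray(lengths, float)
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        E = np.exp(np.multiply.outer(lengths, w))          # (n, k)
        P = np.einsum("ij,nj,jk->nik", V, E, Vinv)
        P = P.real
        if not np.isfinite(P).all() or np.abs(P.sum(axis=2) - 1).max() > 1e-8:
            raise np.linalg.LinAlgError("eig route inaccurate")
    except np.linalg.LinAlgError:
        P = np.stack([sla.expm(Q * b) for b in lengths])
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


def _root_prior(kind, Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    if isinstance(kind, (list, tuple, np.ndarray)):
        p = np.asarray(kind, float)
        return p / p.sum()
    if kind == "equal":
        return np.full(k, 1.0 / k)
    if kind == "stationary":
        w, V = np.linalg.eig(Q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.abs(V[:, i].real)
        return pi / pi.sum()
    raise ValueError(f"unknown root prior {kind!r}")


def _tip_partials(tree: PhyloTree, tip_state_idx: np.ndarray, k: int) -> np.ndarray:
    """One-hot partial likelihoods at tips, (n_nodes, k); internals left at 1."""
    L = np.ones((tree.n_nodes, k))
    for pos, t in enumerate(tree.tip_ids):
        L[t] = 0.0
        L[t, tip_state_idx[pos]] = 1.0
    return L


def pruning_loglik(tree: PhyloTree, tip_state_idx: np.ndarray, Q: np.ndarray,
                   root_prior="equal", *, P: Optional[np.ndarray] = None,
                   lengths: Optional[np.ndarray] = None) -> float:
    """Felsenstein pruning log-likelihood of tip states under exp(Q*b).

    ``tip_state_idx`` follows ``tree.tip_labels`` order. Partial
    likelihoods are rescaled at every internal node so arbitrarily small
    likelihoods stay representable.
    """
    k = Q.shape[0]
    if lengths is None:
        lengths = tree.branch_lengths_floored()
    if P is None:
        P = transition_matrices(Q, lengths)
    L = _tip_partials(tree, tip_state_idx, k)
    logscale = 0.0
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        acc = np.ones(k)
        for c in kids:
            acc = acc * (P[c] @ L[c])
        m = acc.max()
        if m <= 0:
            return -np.inf
        L[v] = acc / m
        logscale += math.log(m)
    prior = _root_prior(root_prior, Q)
    return float(np.log(prior @ L[tree.root]) + logscale)


def pruning_loglik_batch(tree: PhyloTree, tip_state_idx: np.ndarray,
                         Qs: np.ndarray, root_prior="equal",
                         lengths: Optional[np.ndarray] = None,
                         tipL: Optional[np.ndarray] = None) -> np.ndarray:
    """Pruning log-likelihood for a stack of generators Qs (m, k, k).

    Vectorizes the per-node recursion across the batch so an objective and
    its finite-difference gradient cost one tree sweep; agrees with
    :func:`pruning_loglik` item by item. Used by the Pagel optimizer.
    """
    Qs = np.asarray(Qs, float)
    m, k, _ = Qs.shape
    if lengths is None:
        lengths = tree.branch_lengths_floored()
    try:
        w, V = np.linalg.eig(Qs)
        Vinv = np.linalg.inv(V)
        E = np.exp(w[:, None, :] * lengths[None, :, None])       # (m, n, k)
        P = np.einsum("mij,mnj,mjk->mnik", V, E, Vinv).real
        rowerr = np.abs(P.sum(axis=3) - 1.0).max()
        if not np.isfinite(P).all() or rowerr > 1e-8:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        P = np.stack([transition_matrices(Q, lengths) for Q in Qs])
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=3, keepdims=True)
    if tipL is None:
        tipL = _tip_partials(tree, tip_state_idx, k)
    L = np.repeat(tipL[None], m, axis=0)                         # (m, n, k)
    logscale = np.zeros(m)
    dead = np.zeros(m, bool)
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        acc = np.einsum("mij,mj->mi", P[:, kids[0]], L[:, kids[0]])
        for c in kids[1:]:
            acc *= np.einsum("mij,mj->mi", P[:, c], L[:, c])
        mx = acc.max(axis=1)
        bad = mx <= 0
        dead |= bad
        mx[bad] = 1.0
        L[:, v] = acc / mx[:, None]
        logscale += np.log(mx)
    prior = _root_prior(root_prior, Qs[0])
    out = np.log(np.maximum(L[:, tree.root] @ prior, 1e-300)) + logscale
    out[dead] = -np.inf
    return out


def _partials_and_scale(tree: PhyloTree, tip_state_idx: np.ndarray,
                        P: np.ndarray, k: int) -> np.ndarray:
    """Below-node partial likelihoods (rescaled), for marginals and mapping."""
    L = _tip_partials(tree, tip_state_idx, k)
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        acc = np.ones(k)
        for c in kids:
            acc = acc * (P[c] @ L[c])
        m = acc.max()
        L[v] = acc / m if m > 0 else acc
    return L


def marginal_probabilities(tree: PhyloTree, tip_state_idx: np.ndarray, Q: np.ndarray,
                           root_prior="equal") -> np.ndarray:
    """Marginal posterior state probabilities at every node (n_nodes, k).

    Standard up-down algorithm: the below-node partials from pruning are
    combined with above-node partials propagated from the root.
    """
    k = Q.shape[0]
    lengths = tree.branch_lengths_floored()
    P = transition_matrices(Q, lengths)
    below = _partials_and_scale(tree, tip_state_idx, P, k)
    prior = _root_prior(root_prior, Q)
    above = np.ones((tree.n_nodes, k))
    above[tree.root] = prior
    for v in tree.preorder:
        kids = tree.children[v]
        if not kids:
            continue
        # message each child receives: above[v] times siblings' lifted partials
        lifted = {c: P[c] @ below[c] for c in kids}
        for c in kids:
            msg = above[v].copy()
            for s in kids:
                if s != c:
                    msg = msg * lifted[s]
            above[c] = P[c].T @ msg
            m = above[c].max()
            if m > 0:
                above[c] /= m
    post = above * below
    post /= post.sum(axis=1, keepdims=True)
    return post


# ---------------------------------------------------------------------------
# Mk1 (one-rate symmetric binary model)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Mk1Fit:
    """ML fit of the equal-rates binary Markov model.

    ``rate`` is expected changes per million years; ``degenerate`` flags an
    invariant character whose rate estimate sits at the search lower bound.
    """

    rate: float
    log_likelihood: float
    marginal_node_probabilities: Dict[int, float]
    degenerate: bool = False
    root_prior: str = "equal"


def _mk1_Q(rate: float) -> np.ndarray:
    return rate * np.array([[-1.0, 1.0], [1.0, -1.0]])


def mk1_fit(tree: PhyloTree, states: BinaryStateVector,
            root_prior: str = "equal") -> Mk1Fit:
    """Maximum-likelihood Mk1 fit with marginal ancestral-state probabilities.

    The single rate is profiled by a bounded 1-D search on
    [{lo}, {hi}] (tolerance {tol}); an invariant character is reported at
    the lower bound with ``degenerate=True``.
    """
    x = states.aligned(tree)
    lengths = tree.branch_lengths_floored()
    if not (lengths[np.arange(tree.n_nodes) != tree.root] > 0).any():
        raise ValueError("at least one branch length must be > 0")

    def nll(rate: float) -> float:
        return -pruning_loglik(tree, x, _mk1_Q(rate), root_prior, lengths=lengths)

    degenerate = states.is_constant()
    if degenerate:
        rate = RATE_LOWER
    else:
        # the profile is flat for large rates, which traps a naive bounded
        # search on the plateau: bracket the optimum on a log grid first
        grid = np.geomspace(RATE_LOWER, RATE_UPPER, 41)
        vals = np.array([nll(q) for q in grid])
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                       options={"xatol": RATE_TOL})
        rate = float(res.x) if res.fun <= vals[i] else float(grid[i])
    ll = -nll(rate)
    post = marginal_probabilities(tree, x, _mk1_Q(rate), root_prior)
    marg = {int(v): float(post[v, 1]) for v in range(tree.n_nodes)}
    return Mk1Fit(rate=rate, log_likelihood=ll,
                  marginal_node_probabilities=marg,
                  degenerate=degenerate, root_prior=root_prior)


mk1_fit.__doc__ = mk1_fit.__doc__.format(lo=RATE_LOWER, hi=RATE_UPPER, tol=RATE_TOL)


# ---------------------------------------------------------------------------
# Forward simulation of a CTMC on the tree
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CharacterHistory:
    """A full character history: node states plus per-branch change events.

    ``events[v]`` lists ``(time_along_branch, new_state)`` for the branch
    subtending node ``v``, ordered by time.
    """

    node_states: np.ndarray
    events: List[List[Tuple[float, int]]]
    tree: PhyloTree

    def tip_states(self) -> Dict[str, int]:
        return {l: int(self.node_states[i])
                for l, i in zip(self.tree.tip_labels, self.tree.tip_ids)}


def _sim_branch(rng: np.random.Generator, Q: np.ndarray, s0: int,
                b: float) -> Tuple[int, List[Tuple[float, int]]]:
    s, t, ev = s0, 0.0, []
    k = Q.shape[0]
    while True:
        out = -Q[s, s]
        if out <= 0:
            return s, ev
        t += rng.exponential(1.0 / out)
        if t >= b:
            return s, ev
        probs = Q[s].copy()
        probs[s] = 0.0
        s = int(rng.choice(k, p=probs / probs.sum()))
        ev.append((t, s))


def simulate_discrete(tree: PhyloTree, Q: np.ndarray, root_prior="equal",
                      seed: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None) -> CharacterHistory:
    """Simulate one character history under generator ``Q`` (2 or 4 states).

    Exponential waiting times along every branch; the root state is drawn
    from ``root_prior``.
    """
    Q = validate_rate_matrix(Q)
    tree.require_lengths()
    if rng is None:
        rng = np.random.default_rng(seed)
    prior = _root_prior(root_prior, Q)
    node_states = np.zeros(tree.n_nodes, dtype=int)
    events: List[List[Tuple[float, int]]] = [[] for _ in range(tree.n_nodes)]
    node_states[tree.root] = int(rng.choice(Q.shape[0], p=prior))
    for v in tree.preorder:
        if v == tree.root:
            continue
        s_end, ev = _sim_branch(rng, Q, int(node_states[tree.parent[v]]),
                                float(tree.length[v]))
        node_states[v] = s_end
        events[v] = ev
    return CharacterHistory(node_states, events, tree)


def count_origins(history: CharacterHistory) -> int:
    """Number of 0 -> 1 transitions anywhere in a binary history."""
    n = 0
    for v, ev in enumerate(history.events):
        s = int(history.node_states[history.tree.parent[v]]) if history.tree.parent[v] >= 0 else None
        for _, new in ev:
            if s == 0 and new == 1:
                n += 1
            s = new
    return n


# ---------------------------------------------------------------------------
# Stochastic character mapping
# ---------------------------------------------------------------------------

class MappingError(RuntimeError):
    """Branch-path sampler exhausted its retry budget."""


@dataclasses.dataclass
class StochasticMapSummary:
    """Aggregate of simulated character histories conditional on tip data."""

    n_sim: int
    branch_state_density: Dict[int, float]
    node_posterior: Dict[int, float]
    origin_count_distribution: Dict[int, int]
    rate: float

    @property
    def modal_origin_count(self) -> int:
        return max(self.origin_count_distribution,
                   key=lambda k: (self.origin_count_distribution[k], -k))

    def to_json_dict(self) -> dict:
        return {
            "n_sim": self.n_sim,
            "rate": self.rate,
            "branch_state_density": {str(k): v for k, v in self.branch_state_density.items()},
            "node_posterior": {str(k): v for k, v in self.node_posterior.items()},
            "origin_count_distribution": {str(k): v for k, v in
                                          self.origin_count_distribution.items()},
            "modal_origin_count": self.modal_origin_count,
        }


def _sample_branch_conditional(rng: np.random.Generator, Q: np.ndarray,
                               s0: int, s1: int, b: float,
                               branch: int) -> Tuple[List[Tuple[float, int]], float]:
    """Rejection-sample a CTMC path on [0, b] from s0 conditioned to end in s1.

    When the endpoints differ at least one jump is required, so the first
    jump time is drawn from the exponential truncated to [0, b]; the path
    remains an exact draw from the endpoint-conditioned process.
    Returns the event list and the time spent in state 1 (binary chains).
    """
    k = Q.shape[0]
    for _ in range(MAP_RETRY_BUDGET):
        ev: List[Tuple[float, int]] = []
        s, t = s0, 0.0
        if s0 != s1:
            out = -Q[s0, s0]
            if out <= 0:
                break
            u = rng.uniform()
            t = -math.log1p(-u * (1 - math.exp(-out * b))) / out
            probs = Q[s0].copy()
            probs[s0] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
            ev.append((t, s))
        while True:
            out = -Q[s, s]
            if out <= 0:
                break
            t2 = t + rng.exponential(1.0 / out)
            if t2 >= b:
                break
            t = t2
            probs = Q[s].copy()
            probs[s] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
            ev.append((t, s))
        if s == s1:
            # time-weighted occupancy of state 1
            occ, prev_t, prev_s = 0.0, 0.0, s0
            for et, es in ev:
                if prev_s == 1:
                    occ += et - prev_t
                prev_t, prev_s = et, es
            if prev_s == 1:
                occ += b - prev_t
            return ev, occ
    raise MappingError(f"could not sample a consistent history on branch {branch} "
                       f"within {MAP_RETRY_BUDGET} attempts")


def stochastic_map(tree: PhyloTree, states: BinaryStateVector, n_sim: int = 1000,
                   root_prior: str = "equal", seed: Optional[int] = None,
                   rate: Optional[float] = None) -> StochasticMapSummary:
    """Stochastic character mapping of a binary trait under Mk1.

    Each history is an exact draw conditional on the tip states: node
    states are sampled root-to-tips from their joint conditional
    distribution, then branch paths are sampled conditional on their
    endpoint states. The rate is fitted by :func:`mk1_fit` unless given.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    x = states.aligned(tree)
    if rate is None:
        rate = mk1_fit(tree, states, root_prior).rate
    rng = np.random.default_rng(seed)
    Q = _mk1_Q(rate)
    lengths = tree.branch_lengths_floored()
    P = transition_matrices(Q, lengths)
    below = _partials_and_scale(tree, x, P, 2)
    prior = _root_prior(root_prior, Q)

    branch_occ = np.zeros(tree.n_nodes)
    node_one = np.zeros(tree.n_nodes)
    origin_hist: Dict[int, int] = {}
    root_p = prior * below[tree.root]
    root_p = root_p / root_p.sum()
    for _ in range(n_sim):
        node_states = np.zeros(tree.n_nodes, dtype=int)
        node_states[tree.root] = int(rng.uniform() < root_p[1])
        origins = 0
        for v in tree.preorder:
            if v == tree.root:
                continue
            sp = int(node_states[tree.parent[v]])
            w = P[v][sp] * below[v]
            p1 = w[1] / w.sum()
            sv = int(rng.uniform() < p1)
            node_states[v] = sv
            ev, occ = _sample_branch_conditional(rng, Q, sp, sv,
                                                float(lengths[v]), v)
            branch_occ[v] += occ / max(lengths[v], BRANCH_LENGTH_FLOOR)
            s = sp
            for _, new in ev:
                if s == 0 and new == 1:
                    origins += 1
                s = new
        node_one += node_states
        origin_hist[origins] = origin_hist.get(origins, 0) + 1
    nonroot = [int(v) for v in range(tree.n_nodes) if v != tree.root]
    return StochasticMapSummary(
        n_sim=n_sim,
        branch_state_density={v: float(branch_occ[v] / n_sim) for v in nonroot},
        node_posterior={int(v): float(node_one[v] / n_sim) for v in range(tree.n_nodes)},
        origin_count_distribution=dict(sorted(origin_hist.items())),
        rate=float(rate),
    )
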