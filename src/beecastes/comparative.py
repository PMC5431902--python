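"""Cross-species inference controlling for shared ancestry.

Three complementary tools, all assuming Brownian motion for continuous
traits: phylogenetically independent contrasts (PIC) with regression
through the origin, generalized least squares with the Brownian
variance-covariance matrix (PGLS), and Pagel's likelihood-ratio test of
correlated evolution for a pair of binary traits (8-rate dependent vs
4-rate independent continuous-time Markov model, 4 df).

For any bifurcating tree the PGLS slope of y on x (with intercept) equals
the PIC regression-through-origin slope; the test suite holds the two
routes to 1e-8 of each other.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import (BinaryStateVector, PhyloTree, PolytomyError, _tip_partials,
                    pruning_loglik_batch, vcv_matrix)

PAGEL_LOG_RATE_BOUNDS = (-20.0, 5.0)   # natural-log rate bounds, e^-20 .. e^5
PAGEL_DF = 4


# ---------------------------------------------------------------------------
# Independent contrasts
# ---------------------------------------------------------------------------

def pic(tree: PhyloTree, trait: Mapping[str, float]) -> np.ndarray:
    """Felsenstein's standardized independent contrasts (n_tips - 1 values).

    Requires a bifurcating tree with positive branch lengths (resolve
    polytomies first; see ``PhyloTree.resolve_polytomies``). Ancestral
    values are branch-length-weighted averages and each ancestral branch is
    inflated by b_i*b_j/(b_i+b_j).
    """
    if not tree.is_bifurcating():
        raise PolytomyError("pic requires a bifurcating tree; resolve polytomies first")
    b = tree.branch_lengths_floored()
    x = np.zeros(tree.n_nodes)
    for lab in tree.tip_labels:
        if lab not in trait:
            raise ValueError(f"no trait value for tip {lab!r}")
        x[tree.tip_id(lab)] = float(trait[lab])
    blen = b.astype(float).copy()
    contrasts = []
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        i, j = kids
        bi, bj = blen[i], blen[j]
        contrasts.append((x[i] - x[j]) / np.sqrt(bi + bj))
        x[v] = (x[i] / bi + x[j] / bj) / (1.0 / bi + 1.0 / bj)
        blen[v] = blen[v] + bi * bj / (bi + bj)
    return np.asarray(contrasts)


@dataclasses.dataclass
class OriginRegression:
    slope: float
    t_value: float
    df: int
    p_value: float
    r_squared: float
    n: int


def pic_regression_origin(contrasts_x: Sequence[float],
                          contrasts_y: Sequence[float]) -> OriginRegression:
    """No-intercept OLS of y-contrasts on x-contrasts; R^2 about zero."""
    cx = np.asarray(contrasts_x, float)
    cy = np.asarray(contrasts_y, float)
    if cx.size != cy.size or cx.size < 3:
        raise ValueError("need >= 3 paired contrasts")
    sxx = float(cx @ cx)
    if sxx == 0:
        raise ValueError("all x contrasts are zero")
    slope = float(cx @ cy) / sxx
    resid = cy - slope * cx
    dof = cx.size - 1
    s2 = float(resid @ resid) / dof
    se = np.sqrt(s2 / sxx)
    t = slope / se if se > 0 else np.inf
    syy = float(cy @ cy)
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else np.nan
    return OriginRegression(slope, float(t), dof,
                            float(2 * stats.t.sf(abs(t), dof)), float(r2), cx.size)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PGLSFit:
    """Brownian-motion GLS regression across species.

    ``r_squared`` is 1 - RSS/RSS0 in the whitened (V^{-1/2}) space, with
    RSS0 from the intercept-only GLS fit, so it lies in [0, 1].
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    df: int
    p_values: np.ndarray
    r_squared: float
    names: Tuple[str, ...]
    sigma2: float


def pgls_fit(tree: PhyloTree, y: Mapping[str, float],
             X: Mapping[str, float] | pd.DataFrame,
             add_intercept: bool = True) -> PGLSFit:
    """GLS fit of y on X with residual covariance = Brownian VCV of the tree.

    ``y`` maps species to the response; ``X`` maps species to one predictor
    or is a DataFrame (rows = species) of several. Estimator
    (X'V^-1 X)^-1 X'V^-1 y with t tests on n - p degrees of freedom.
    """
    spp = list(tree.tip_labels)
    missing = [s for s in spp if s not in y]
    if missing:
        raise ValueError(f"response missing species: {missing}")
    yv = np.array([float(y[s]) for s in spp])
    if isinstance(X, pd.DataFrame):
        Xd = X.loc[spp]
        names = list(Xd.columns)
        Xm = Xd.to_numpy(dtype=float)
    else:
        names = ["x"]
        Xm = np.array([[float(X[s])] for s in spp])
    if add_intercept:
        Xm = np.column_stack([np.ones(len(spp)), Xm])
        names = ["intercept"] + names
    n, p = Xm.shape
    if n <= p:
        raise ValueError("more parameters than species")
    V = vcv_matrix(tree)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular VCV; floor zero-length branches first") from exc
    yw = np.linalg.solve(L, yv)
    Xw = np.linalg.solve(L, Xm)
    if np.linalg.matrix_rank(Xw) < p:
        raise ValueError("design matrix is rank-deficient (constant or "
                         "collinear predictors)")
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    # intercept-only baseline for R^2 in the whitened space
    ones_w = np.linalg.solve(L, np.ones(n))
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    rss0 = float(np.sum((yw - mu * ones_w) ** 2))
    r2 = 1.0 - float(resid @ resid) / rss0 if rss0 > 0 else np.nan
    return PGLSFit(beta, se, t, dof, pvals, float(r2), tuple(names), sigma2)


# ---------------------------------------------------------------------------
# Pagel's correlated-evolution test
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PagelFit:
    """Dependent vs independent evolution of two binary traits.

    Rates are keyed ``qA01_B0`` = gain rate of A while B is 0, etc.; the
    likelihood ratio is tested against chi-square with 4 df.
    """

    logL_independent: float
    logL_dependent: float
    likelihood_ratio: float
    df: int
    p_value: float
    rates_independent: Dict[str, float]
    rates_dependent: Dict[str, float]

    @property
    def Q_dependent(self) -> np.ndarray:
        return _pagel_Q(**self.rates_dependent)


_RATE_KEYS = ("qA01_B0", "qA01_B1", "qA10_B0", "qA10_B1",
              "qB01_A0", "qB01_A1", "qB10_A0", "qB10_A1")


def _pagel_Q(qA01_B0, qA01_B1, qA10_B0, qA10_B1,
             qB01_A0, qB01_A1, qB10_A0, qB10_A1) -> np.ndarray:
    """4-state generator on (A,B) in {00, 01, 10, 11}; double changes forbidden."""
    Q = np.zeros((4, 4))
    Q[0, 2] = qA01_B0   # 00 -> 10
    Q[1, 3] = qA01_B1   # 01 -> 11
    Q[2, 0] = qA10_B0   # 10 -> 00
    Q[3, 1] = qA10_B1   # 11 -> 01
    Q[0, 1] = qB01_A0   # 00 -> 01
    Q[2, 3] = qB01_A1   # 10 -> 11
    Q[1, 0] = qB10_A0   # 01 -> 00
    Q[3, 2] = qB10_A1   # 11 -> 10
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def joint_state_index(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(A,B) tip states to 4-state index: 00->0, 01->1, 10->2, 11->3."""
    return 2 * np.asarray(a, int) + np.asarray(b, int)


_FD_EPS = 1e-6  # forward-difference step on log rates


def _batched_objective(tree, states_idx, builder, n_par, root_prior, lengths, tipL):
    """(f, grad) objective: one batched tree sweep per optimizer step."""
    eye = np.eye(n_par)

    def fun_and_grad(theta):
        thetas = np.vstack([theta, theta + _FD_EPS * eye])
        Qs = np.stack([builder(np.exp(t)) for t in thetas])
        vals = -pruning_loglik_batch(tree, states_idx, Qs, root_prior,
                                     lengths=lengths, tipL=tipL)
        return vals[0], (vals[1:] - vals[0]) / _FD_EPS

    return fun_and_grad


def _two_state_Q(rates: np.ndarray) -> np.ndarray:
    q01, q10 = rates
    return np.array([[-q01, q01], [q10, -q10]])


def _fit_two_state(tree: PhyloTree, x: np.ndarray, root_prior, lengths,
                   n_starts: int, rng: np.random.Generator) -> Tuple[float, float, float]:
    """ML asymmetric 2-state fit (gain, loss); returns (logL, q01, q10)."""
    lo, hi = PAGEL_LOG_RATE_BOUNDS
    tipL = _tip_partials(tree, x, 2)
    obj = _batched_objective(tree, x, _two_state_Q, 2, root_prior, lengths, tipL)
    best = None
    starts = [np.log([0.01, 0.01])]
    starts += [rng.uniform(-6, 0, size=2) for _ in range(max(0, n_starts - 1))]
    for s0 in starts:
        res = optimize.minimize(obj, s0, jac=True, method="L-BFGS-B",
                                bounds=[(lo, hi)] * 2)
        if best is None or res.fun < best.fun:
            best = res
    q01, q10 = np.exp(best.x)
    return -float(best.fun), float(q01), float(q10)


def pagel_fit(tree: PhyloTree, traitA: BinaryStateVector,
              traitB: BinaryStateVector, root_prior="equal",
              n_starts: int = 5, seed: int = 0) -> PagelFit:
    """Pagel's test of correlated evolution of two binary traits.

    The joint chain lives on (A,B) in {00,01,10,11} with simultaneous
    double changes forbidden. The independent model (4 free rates) makes
    each trait's gain/loss rates ignore the other's state, so its
    likelihood factorizes into two 2-state fits; the dependent model frees
    all 8 single-step rates. ML by multi-start L-BFGS-B on log rates
    (bounds e^-20..e^5), with the independent optimum embedded as one start
    so the likelihood ratio is non-negative up to optimizer tolerance.
    The LRT is referred to chi-square with 4 df.
    """
    if traitA.is_constant() or traitB.is_constant():
        raise ValueError("Pagel's test is not identifiable for a constant trait")
    a = traitA.aligned(tree)
    b = traitB.aligned(tree)
    lengths = tree.branch_lengths_floored()
    rng = np.random.default_rng(seed)

    llA, qA01, qA10 = _fit_two_state(tree, a, root_prior, lengths, n_starts, rng)
    llB, qB01, qB10 = _fit_two_state(tree, b, root_prior, lengths, n_starts, rng)
    ll_indep = llA + llB
    rates_indep = {"qA01": qA01, "qA10": qA10, "qB01": qB01, "qB10": qB10}

    joint = joint_state_index(a, b)
    lo, hi = PAGEL_LOG_RATE_BOUNDS
    tipL = _tip_partials(tree, joint, 4)
    obj = _batched_objective(tree, joint, lambda r: _pagel_Q(*r), 8,
                             root_prior, lengths, tipL)
    anchor = np.log(np.clip([qA01, qA01, qA10, qA10, qB01, qB01, qB10, qB10],
                            np.exp(lo), np.exp(hi)))
    starts = [anchor]
    starts += [rng.uniform(-6, 0, size=8) for _ in range(max(0, n_starts - 1))]
    best = None
    for s0 in starts:
        res = optimize.minimize(obj, s0, jac=True, method="L-BFGS-B",
                                bounds=[(lo, hi)] * 8)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("Pagel dependent-model optimizer failed to converge")
    ll_dep = -float(best.fun)
    rates_dep = dict(zip(_RATE_KEYS, np.exp(best.x)))
    lr = 2.0 * (ll_dep - ll_indep)
    p = float(stats.chi2.sf(max(lr, 0.0), PAGEL_DF))
    return PagelFit(ll_indep, ll_dep, float(lr), PAGEL_DF, p,
                    rates_indep, rates_dep)


# ---------------------------------------------------------------------------
# Robustness to branch-length uncertainty
# ---------------------------------------------------------------------------

def tree_robustness_compare(analysis: Callable[[PhyloTree], Mapping[str, float]],
                            tree_variant_1: PhyloTree,
                            tree_variant_2: PhyloTree) -> dict:
    """Run one analysis on two branch-length variants and report both.

    ``analysis`` must return a flat mapping of numeric results. The report
    carries both result sets, absolute differences for shared numeric
    keys, and agreement flags for any key that looks like a p-value
    (significant at 0.05 on both trees or on neither).
    """
    if set(tree_variant_1.tip_labels) != set(tree_variant_2.tip_labels):
        raise ValueError("tree variants must share the same tip set")
    r1 = dict(analysis(tree_variant_1))
    r2 = dict(analysis(tree_variant_2))
    diffs = {k: abs(float(r1[k]) - float(r2[k]))
             for k in r1 if k in r2 and np.isfinite(r1[k]) and np.isfinite(r2[k])}
    agree = {k: (float(r1[k]) <= 0.05) == (float(r2[k]) <= 0.05)
             for k in diffs if "p_value" in k or k.startswith("p_")}
    return {"tree_1": r1, "tree_2": r2, "abs_difference": diffs,
            "conclusion_agrees": agree}
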