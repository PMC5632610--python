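"""Phylogenetic regressions: PGLS with Pagel's lambda, and species-richness
independent contrasts regressed through the origin (the MacroCAIC design).

PGLS
----
Generalised least squares whose error covariance is the Brownian-motion
shared-path-length matrix of the tree, with off-diagonal entries scaled by
Pagel's lambda in [0, 1]: lambda = 0 recovers ordinary least squares,
lambda = 1 full Brownian covariance. lambda is profiled by maximum
likelihood on a 0.01 grid followed by bounded refinement. R-squared is
defined against the intercept-only model fitted under the same lambda-hat
(both evaluated in the whitened coordinates), and F is the corresponding
model-comparison statistic with (1, n-2) degrees of freedom.

MacroCAIC
---------
Felsenstein's independent-contrasts recursion is applied to the predictor
trait (weighted-average nodal values, branch-length standardisation). At
each internal node the response is not a trait contrast but the log ratio
of daughter-clade species richness, ln(N1/N2), oriented so that daughter 1
is the one with the larger reconstructed trait value; the trait contrast is
then non-negative by construction. The richness contrasts are regressed on
the trait contrasts through the origin (no intercept: under the null of no
effect a contrast's expected response is zero), reporting the slope, F,
adjusted R-squared and df = n_contrasts - 1. Polytomies are refused by
default; ``polytomies="resolve"`` expands each into a pectinate series of
zero-length edges with a warning.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats

from .errors import DegenerateDataError, InputError
from .treeio import PhyloTree

logger = logging.getLogger(__name__)

__all__ = ["PGLSFit", "CAICFit", "pgls_fit", "macrocaic", "model_report",
           "phylo_covariance"]

_EPS_LEN = 1e-12


@dataclass(frozen=True)
class PGLSFit:
    """PGLS regression summary (single predictor)."""

    beta: float
    intercept: float
    se_beta: float
    f_stat: float
    df_num: int
    df_den: int
    r_squared: float
    lambda_hat: float
    loglik: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "intercept": self.intercept,
            "se_beta": self.se_beta,
            "f_stat": self.f_stat,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "r_squared": self.r_squared,
            "lambda_hat": self.lambda_hat,
            "loglik": self.loglik,
            "p_value": self.p_value,
        }


@dataclass
class CAICFit:
    """Through-origin regression of richness contrasts on trait contrasts."""

    contrasts: list[tuple[int, float, float]]  # (node id, trait, richness)
    slope_through_origin: float
    f_stat: float
    adj_r_squared: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "contrasts": [list(c) for c in self.contrasts],
            "slope_through_origin": self.slope_through_origin,
            "f_stat": self.f_stat,
            "adj_r_squared": self.adj_r_squared,
            "df": self.df,
            "p_value": self.p_value,
        }


def phylo_covariance(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """Brownian covariance: C[i, j] = shared root-to-MRCA path length.

    Returns the matrix in a fixed tip order together with that order.
    """
    depths = tree.node_depths()
    tips = tree.tip_ids
    pos = {tid: i for i, tid in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    clade: dict[int, list[int]] = {}
    for v in range(tree.n_nodes):
        kids = tree.children[v]
        if not kids:
            clade[v] = [pos[v]]
            C[pos[v], pos[v]] = depths[v]
            continue
        members: list[int] = []
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ia = clade[kids[a]]
                ib = clade[kids[b]]
                C[np.ix_(ia, ib)] = depths[v]
                C[np.ix_(ib, ia)] = depths[v]
        for c in kids:
            members.extend(clade[c])
            del clade[c]
        clade[v] = members
    return C, [tree.label[t] for t in tips]  # type: ignore[list-item]


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _chol(V: np.ndarray) -> np.ndarray:
    try:
        return scipy.linalg.cholesky(V, lower=True)
    except scipy.linalg.LinAlgError:
        warnings.warn(
            "singular phylogenetic covariance; adding 1e-10 ridge",
            stacklevel=3,
        )
        return scipy.linalg.cholesky(
            V + 1e-10 * np.mean(np.diag(V)) * np.eye(len(V)), lower=True
        )


def _gls(L: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Whitened OLS given the Cholesky factor of the covariance."""
    Xw = scipy.linalg.solve_triangular(L, X, lower=True)
    yw = scipy.linalg.solve_triangular(L, y, lower=True)
    coef, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ coef
    rss = float(resid @ resid)
    return coef, rss, Xw


def _profile_loglik(C, X, y, lam) -> float:
    n = len(y)
    L = _chol(_lambda_cov(C, lam))
    _, rss, _ = _gls(L, X, y)
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)


def pgls_fit(
    tree: PhyloTree,
    x: Mapping[str, float],
    y: Mapping[str, float],
    lambda_mode: float | str = "ML",
) -> PGLSFit:
    """Fit ``y ~ x`` by PGLS with Pagel's lambda.

    ``lambda_mode`` is either a fixed value in [0, 1] or ``"ML"`` to profile
    lambda by maximum likelihood. Both variable maps must cover every tip.
    Any transformation (the comparative analyses here log both host
    diversity and richness) is applied by the caller.
    """
    C, order = phylo_covariance(tree)
    missing = [t for t in order if t not in x or t not in y]
    if missing:
        raise InputError(f"tips without data: {missing}")
    xv = np.array([float(x[t]) for t in order])
    yv = np.array([float(y[t]) for t in order])
    n = len(order)
    if n < 4:
        raise InputError("PGLS needs at least 4 tips")
    if float(np.std(xv)) == 0:
        raise DegenerateDataError("predictor has zero variance")
    X = np.column_stack([np.ones(n), xv])
    X0 = np.ones((n, 1))

    if lambda_mode == "ML":
        grid = np.linspace(0.0, 1.0, 101)
        lls = np.array([_profile_loglik(C, X, yv, g) for g in grid])
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if hi > lo:
            res = scipy.optimize.minimize_scalar(
                lambda g: -_profile_loglik(C, X, yv, g),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-6},
            )
            lam = float(res.x)
            if _profile_loglik(C, X, yv, lam) < lls[i]:
                lam = float(grid[i])
        else:
            lam = float(grid[i])
    else:
        lam = float(lambda_mode)
        if not 0.0 <= lam <= 1.0:
            raise InputError("lambda must lie in [0, 1]")

    L = _chol(_lambda_cov(C, lam))
    coef, rss, Xw = _gls(L, X, yv)
    _, rss0, _ = _gls(L, X0, yv)
    df_den = n - 2
    sigma2 = rss / df_den
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    se_beta = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    f_stat = float((rss0 - rss) / (rss / df_den))
    r2 = float(1.0 - rss / rss0) if rss0 > 0 else 0.0
    p = float(scipy.stats.f.sf(f_stat, 1, df_den))
    return PGLSFit(
        beta=float(coef[1]),
        intercept=float(coef[0]),
        se_beta=se_beta,
        f_stat=f_stat,
        df_num=1,
        df_den=df_den,
        r_squared=r2,
        lambda_hat=lam,
        loglik=float(_profile_loglik(C, X, yv, lam)),
        p_value=p,
    )


def _resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Pectinate zero-length resolution of every polytomy (order-preserving)."""
    parent = list(tree.parent)
    children = [list(c) for c in tree.children]
    length = list(tree.length)
    label = list(tree.label)
    changed = False
    v = 0
    while v < len(children):
        kids = children[v]
        if len(kids) > 2:
            changed = True
            first_two, rest = kids[:2], kids[2:]
            new = len(children)
            parent.append(v)
            children.append(first_two)
            length.append(0.0)
            label.append(None)
            for c in first_two:
                parent[c] = new
            children[v] = [new] + rest
        v += 1
    if not changed:
        return tree
    warnings.warn("polytomies resolved pectinately with zero-length edges",
                  stacklevel=3)
    # renumber to postorder
    order: list[int] = []
    root = parent.index(-1)
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
        else:
            stack.append((node, True))
            for c in children[node]:
                stack.append((c, False))
    newid = {old: i for i, old in enumerate(order)}
    n = len(order)
    return PhyloTree(
        np.array([newid[parent[o]] if parent[o] >= 0 else -1 for o in order]),
        [[newid[c] for c in children[o]] for o in order],
        np.array([length[o] for o in order]),
        [label[o] for o in order],
    )


def macrocaic(
    tree: PhyloTree,
    trait: Mapping[str, float],
    richness: Mapping[str, int],
    polytomies: str = "error",
) -> CAICFit:
    """Species-richness contrasts regressed through the origin on trait contrasts.

    The predictor trait is propagated up the tree by Felsenstein's
    weighted-average recursion with branch-length standardisation; at each
    internal node the trait contrast is the standardised daughter difference
    oriented non-negative, and the response is ln(N1/N2) with N summed over
    each daughter clade's richness. Trait contrasts are invariant to adding
    a constant to the trait; richness contrasts to a common positive
    rescaling of richness.
    """
    if polytomies not in ("error", "resolve"):
        raise InputError("polytomies must be 'error' or 'resolve'")
    if any(len(k) > 2 for k in tree.children if k):
        if polytomies == "error":
            raise InputError(
                "tree contains polytomies; pass polytomies='resolve' to "
                "expand them with zero-length edges"
            )
        tree = _resolve_polytomies(tree)
    missing = [t for t in tree.tip_labels if t not in trait or t not in richness]
    if missing:
        raise InputError(f"tips without data: {missing}")
    if any(int(richness[t]) < 1 for t in tree.tip_labels):
        raise InputError("richness must be >= 1 for every tip")

    n = tree.n_nodes
    xval = np.zeros(n)
    vlen = np.zeros(n)  # branch length + pruning correction
    nsum = np.zeros(n)
    rows: list[tuple[int, float, float]] = []
    for v in range(n):
        kids = tree.children[v]
        if not kids:
            lab = tree.label[v]
            xval[v] = float(trait[lab])
            nsum[v] = int(richness[lab])
            vlen[v] = float(tree.length[v])
            continue
        c1, c2 = kids
        x1, x2 = xval[c1], xval[c2]
        v1, v2 = vlen[c1], vlen[c2]
        n1, n2 = nsum[c1], nsum[c2]
        if x2 > x1:
            x1, x2, v1, v2, n1, n2 = x2, x1, v2, v1, n2, n1
        denom = math.sqrt(max(v1 + v2, _EPS_LEN))
        rows.append((v, (x1 - x2) / denom, math.log(n1 / n2)))
        w1 = 1.0 / max(v1, _EPS_LEN)
        w2 = 1.0 / max(v2, _EPS_LEN)
        xval[v] = (w1 * x1 + w2 * x2) / (w1 + w2)
        vlen[v] = float(tree.length[v]) + (v1 * v2) / max(v1 + v2, _EPS_LEN)
        nsum[v] = n1 + n2

    xs = np.array([r[1] for r in rows])
    ys = np.array([r[2] for r in rows])
    m = len(rows)
    if m < 2:
        raise InputError("need at least 2 internal nodes for the regression")
    sxx = float(xs @ xs)
    if sxx == 0:
        raise DegenerateDataError("all trait contrasts are zero")
    slope = float(xs @ ys) / sxx
    rss = float(np.sum((ys - slope * xs) ** 2))
    tss = float(ys @ ys)
    df = m - 1
    if tss == 0:
        return CAICFit(rows, 0.0, 0.0, 0.0, df, 1.0)
    f_stat = (tss - rss) / (rss / df) if rss > 0 else math.inf
    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * m / df
    p = float(scipy.stats.f.sf(f_stat, 1, df))
    return CAICFit(rows, slope, float(f_stat), float(adj_r2), df, p)


def model_report(fit: PGLSFit | CAICFit) -> str:
    """One-line summary in the conventional reporting shape."""
    if isinstance(fit, PGLSFit):
        return (
            f"β = {fit.beta:.2f}, SE = {fit.se_beta:.2f}, "
            f"F_{fit.df_den} = {fit.f_stat:.2f}, p = {fit.p_value:.3g}, "
            f"R² = {fit.r_squared:.2f}, λ = {fit.lambda_hat:.2f}"
        )
    if isinstance(fit, CAICFit):
        return (
            f"df = {fit.df}; adjusted R-square = {fit.adj_r_squared:.3f}; "
            f"F = {fit.f_stat:.3g}; p = {fit.p_value:.3g}"
        )
    raise InputError(f"unsupported fit type {type(fit).__name__}")


def fit_to_json(fit: PGLSFit | CAICFit) -> str:
    """Lossless JSON serialisation of a fit object."""
    payload = fit.to_dict()
    payload["type"] = type(fit).__name__
    return json.dumps(payload, indent=2)
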