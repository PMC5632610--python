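"""Phylogenetic signal of binary traits via Mk transition rates.

Signal is measured inversely by the maximum-likelihood transition rate of a
two-state equal-rates Markov (Mk/ER) model: a trait that is clustered on the
tree needs few transitions to explain, hence a low fitted rate, whereas a
trait scattered over the tips needs a high rate. Significance is calibrated
by permutation: tip states are shuffled over the tips (preserving the state
counts), the rate refitted, and the p-value is the fraction of permuted
rates at or below the observed rate — a low-tail test, since low rates mean
strong signal.

Model conventions
-----------------
The ER chain is symmetric with a single rate ``q`` per unit branch length;
along a branch of length ``t`` the transition probabilities are

    P_stay(t)   = (1 + exp(-2 q t)) / 2
    P_switch(t) = (1 - exp(-2 q t)) / 2

Likelihoods are computed by Felsenstein's pruning algorithm with a flat
(1/2, 1/2) root prior (flat equals the ER stationary distribution, so the
choice is inert). Missing tip states contribute a partial likelihood of
(1, 1) rather than being deleted, so permutations act on a fixed tip set.

Rates are optimised on a copy of the tree rescaled to unit depth (bounds
``q`` in [1e-8, 1e3] there, for conditioning) and reported on the original
branch-length scale. Rates are therefore only interpretable relative to the
depth of the tree at hand; rates fitted on trees with different length units
are not comparable.

The permutation p-value is reported as the raw fraction k/n (so a rate lower
than every permuted rate prints as p = 0); the (k+1)/(n+1) upper bound is
available as :attr:`SignalTestResult.p_value_plus_one` for reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputError
from .treeio import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "MkFit",
    "SignalTestResult",
    "mk_loglik",
    "mk_fit_rate",
    "permutation_signal_test",
    "batch_signal",
]

Q_MIN = 1e-8  # bounds on the unit-depth scale
Q_MAX = 1e3
_N_GRID = 25
_N_GOLDEN = 32
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class MkFit:
    """ML fit of the single ER transition rate."""

    q: float
    loglik: float
    converged: bool = True
    bounds_hit: str | None = None  # None | "lower" | "upper"


@dataclass
class SignalTestResult:
    """Permutation-calibrated phylogenetic-signal test for one binary trait."""

    observed_q: float
    permuted_q: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    @property
    def p_value_plus_one(self) -> float:
        """(k+1)/(n+1) bound: a valid p-value even when the raw fraction is 0."""
        k = round(self.p_value * self.n_perm)
        return (k + 1) / (self.n_perm + 1)


# ---------------------------------------------------------------------------
# pruning machinery (vectorised across B datasets with per-dataset rates)
# ---------------------------------------------------------------------------


def _states_matrix(
    tree: PhyloTree, states: Mapping[str, int]
) -> np.ndarray:
    """Column vector of tip states in tip-id order; -1 encodes missing."""
    unknown = [lab for lab in states if lab not in tree._tip_index]
    if unknown:
        raise InputError(f"tip(s) in states absent from tree: {sorted(unknown)}")
    col = np.full(tree.n_tips, -1, dtype=np.int64)
    for k, tid in enumerate(tree.tip_ids):
        lab = tree.label[tid]
        if lab in states and states[lab] is not None:
            s = int(states[lab])
            if s not in (0, 1):
                raise InputError(f"state for {lab!r} must be 0 or 1, got {s}")
            col[k] = s
    return col[:, None]


def _loglik_batch(tree: PhyloTree, state_cols: np.ndarray, q: np.ndarray,
                  lengths: np.ndarray | None = None) -> np.ndarray:
    """Pruning log-likelihood for B datasets, each with its own rate.

    ``state_cols``: (n_tips, B) int array of 0/1/-1 in ``tree.tip_ids`` order.
    ``q``: (B,) rates. Returns (B,) natural-log likelihoods; impossible data
    (q = 0 with discordant tips) yield -inf, never an exception.
    """
    n_nodes = tree.n_nodes
    B = state_cols.shape[1]
    t = tree.length if lengths is None else lengths
    # per-edge stay/switch probabilities, all edges at once: (n_nodes, B)
    decay = np.exp(np.outer(-2.0 * t, q))
    ps = 0.5 * (1.0 + decay)
    pw = 0.5 * (1.0 - decay)

    L = np.empty((n_nodes, B, 2))
    for k, tid in enumerate(tree.tip_ids):
        s = state_cols[k]
        L[tid, :, 0] = np.where(s == -1, 1.0, s == 0)
        L[tid, :, 1] = np.where(s == -1, 1.0, s == 1)

    logscale = np.zeros(B)
    with np.errstate(divide="ignore", invalid="ignore"):
        for v in range(n_nodes):
            kids = tree.children[v]
            if not kids:
                continue
            acc0 = acc1 = None
            for c in kids:
                m0 = ps[c] * L[c, :, 0] + pw[c] * L[c, :, 1]
                m1 = pw[c] * L[c, :, 0] + ps[c] * L[c, :, 1]
                if acc0 is None:
                    acc0, acc1 = m0, m1
                else:
                    acc0 = acc0 * m0
                    acc1 = acc1 * m1
            mx = np.maximum(acc0, acc1)
            ok = mx > 0
            inv = np.where(ok, 1.0 / np.where(ok, mx, 1.0), 0.0)
            L[v, :, 0] = acc0 * inv
            L[v, :, 1] = acc1 * inv
            logscale += np.where(ok, np.log(np.where(ok, mx, 1.0)), -np.inf)
        root = tree.root
        lik = 0.5 * (L[root, :, 0] + L[root, :, 1])
        return logscale + np.where(lik > 0, np.log(np.where(lik > 0, lik, 1.0)),
                                   -np.inf)


def mk_loglik(tree: PhyloTree, states: Mapping[str, int], q: float) -> float:
    """ER log-likelihood of binary tip states at rate ``q`` (flat root prior)."""
    if q < 0:
        raise InputError("rate q must be >= 0")
    col = _states_matrix(tree, states)
    return float(_loglik_batch(tree, col, np.array([float(q)]))[0])


def _fit_rate_batch(
    tree: PhyloTree, state_cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximise the ER likelihood over the rate, per dataset column.

    Works in log-rate space on the unit-depth-rescaled tree: a coarse grid
    brackets the optimum, golden-section search refines it. Returns
    (q_hat on the original scale, loglik, boundary code 0/-1/+1).
    """
    depth = tree.depth()
    if depth <= 0:
        raise InputError("tree must have positive depth")
    unit_lengths = tree.length / depth
    B = state_cols.shape[1]

    grid = np.linspace(np.log(Q_MIN), np.log(Q_MAX), _N_GRID)
    ll = np.empty((_N_GRID, B))
    for i, x in enumerate(grid):
        ll[i] = _loglik_batch(tree, state_cols, np.full(B, np.exp(x)),
                              lengths=unit_lengths)
    best = np.argmax(ll, axis=0)
    a = grid[np.maximum(best - 1, 0)]
    b = grid[np.minimum(best + 1, _N_GRID - 1)]
    for _ in range(_N_GOLDEN):
        x1 = b - _GOLDEN * (b - a)
        x2 = a + _GOLDEN * (b - a)
        f1 = _loglik_batch(tree, state_cols, np.exp(x1), lengths=unit_lengths)
        f2 = _loglik_batch(tree, state_cols, np.exp(x2), lengths=unit_lengths)
        take_left = f1 >= f2
        b = np.where(take_left, x2, b)
        a = np.where(take_left, a, x1)
    x_hat = 0.5 * (a + b)
    ll_hat = _loglik_batch(tree, state_cols, np.exp(x_hat), lengths=unit_lengths)
    q_unit = np.exp(x_hat)
    bounds = np.zeros(B, dtype=np.int64)
    bounds[q_unit <= Q_MIN * 3.0] = -1
    bounds[q_unit >= Q_MAX / 3.0] = 1
    return q_unit / depth, ll_hat, bounds


def mk_fit_rate(tree: PhyloTree, states: Mapping[str, int]) -> MkFit:
    """ML estimate of the single ER transition rate for one binary trait.

    At least two tips must carry observed states. A constant trait pins the
    rate at the lower search bound (the likelihood is monotone decreasing in
    ``q``), reported via ``bounds_hit="lower"``.
    """
    col = _states_matrix(tree, states)
    if int((col >= 0).sum()) < 2:
        raise InputError("need at least 2 tips with observed states")
    q, ll, bounds = _fit_rate_batch(tree, col)
    code = {-1: "lower", 0: None, 1: "upper"}[int(bounds[0])]
    return MkFit(q=float(q[0]), loglik=float(ll[0]), converged=True,
                 bounds_hit=code)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def permutation_signal_test(
    tree: PhyloTree,
    states: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> SignalTestResult:
    """Permutation test of phylogenetic signal for one binary trait.

    Tip states are shuffled over the observed tips ``n_perm`` times (state
    counts preserved; missing tips stay missing) and the ER rate refitted
    with the same estimator used for the observed data. The p-value is the
    raw fraction of permuted rates <= the observed rate; ties count as <=
    (conservative for a low-tail test). A constant trait short-circuits to
    p = 1 with a warning: every permutation is identical.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    col = _states_matrix(tree, states)[:, 0]
    obs_mask = col >= 0
    if int(obs_mask.sum()) < 2:
        raise InputError("need at least 2 tips with observed states")
    values = col[obs_mask]
    if len(np.unique(values)) == 1:
        warnings.warn(
            "trait is constant across observed tips; permutation test is "
            "uninformative (p = 1)",
            stacklevel=2,
        )
        observed = {
            tree.label[tid]: int(col[k])
            for k, tid in enumerate(tree.tip_ids)
            if col[k] >= 0
        }
        fit = mk_fit_rate(tree, observed)
        return SignalTestResult(
            observed_q=fit.q,
            permuted_q=np.full(n_perm, fit.q),
            p_value=1.0,
            n_perm=n_perm,
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    cols = np.tile(col[:, None], (1, n_perm + 1))
    for j in range(1, n_perm + 1):
        cols[obs_mask, j] = rng.permutation(values)
    q, _, _ = _fit_rate_batch(tree, cols)
    q_obs = q[0]
    q_perm = q[1:]
    tol = 1e-9 * max(q_obs, Q_MIN)
    k = int(np.sum(q_perm <= q_obs + tol))
    return SignalTestResult(
        observed_q=float(q_obs),
        permuted_q=q_perm,
        p_value=k / n_perm,
        n_perm=n_perm,
        seed=seed,
    )


def batch_signal(
    tree: PhyloTree,
    trait_matrix: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, SignalTestResult]]:
    """Signal tests for every column of a taxon x trait 0/1 matrix.

    Each column gets its own sub-seed derived deterministically from the
    master seed, so adding or reordering columns does not perturb other
    columns' permutations. Returns a tidy (trait, t_rate, p) table — the
    shape of a transition-rate summary table — plus the per-trait results.
    """
    col_seeds = np.random.default_rng(seed).integers(
        0, 2**31 - 1, size=trait_matrix.shape[1]
    )
    rows = []
    results: dict[str, SignalTestResult] = {}
    for j, trait in enumerate(trait_matrix.columns):
        states = {
            str(taxon): (int(v) if not pd.isna(v) else None)
            for taxon, v in trait_matrix[trait].items()
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = permutation_signal_test(
                tree, states, n_perm=n_perm, seed=int(col_seeds[j])
            )
        results[str(trait)] = res
        constant = bool(np.all(res.permuted_q == res.observed_q))
        if constant:
            logger.warning("trait %r is constant; p fixed at 1", trait)
        rows.append(
            {"trait": str(trait), "t_rate": res.observed_q, "p": res.p_value,
             "constant": constant}
        )
    return pd.DataFrame(rows), results
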