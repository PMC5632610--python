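"""Parsimony tracing of host-use characters on the tree.

Two tracers, both length-free by default, matching their role as descriptive
reconstructions rather than model fits:

* :func:`fitch_trace` — minimum-change count and ancestral state sets for a
  binary character (e.g. the "3+ orders" / "7+ orders" polyphagy codings).
  Implemented as unit-cost Sankoff dynamic programming with a rerooting
  uppass, which on binary trees reproduces Fitch's algorithm exactly and on
  polytomies still yields the exact minimum and the full set of
  MPR-compatible states per node.
* :func:`squared_change_trace` — squared-change parsimony for a continuous
  character (host diversity traced across the tree): internal values
  minimise the sum of squared changes over edges, found by solving the
  sparse linear stationarity system (each internal node sits at the mean of
  its neighbours). A branch-length-weighted variant (changes penalised by
  1/length) is available via ``weighted=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .errors import InputError
from .treeio import PhyloTree

__all__ = ["ParsimonyTrace", "ContinuousTrace", "fitch_trace",
           "squared_change_trace"]

_INF = np.inf


@dataclass
class ParsimonyTrace:
    """Minimum-change reconstruction of a binary character."""

    min_changes: int
    node_state_sets: dict[int, frozenset[int]]


@dataclass
class ContinuousTrace:
    """Squared-change parsimony reconstruction of a continuous character."""

    node_values: dict[int, float]
    objective: float


def _tip_states_array(tree: PhyloTree, states: Mapping[str, int]) -> np.ndarray:
    out = np.full(tree.n_nodes, -1, dtype=np.int64)
    for lab, s in states.items():
        tid = tree.tip_id(lab)
        if s is None:
            continue
        if s not in (0, 1):
            raise InputError(f"state for {lab!r} must be 0 or 1, got {s}")
        out[tid] = int(s)
    return out


def fitch_trace(tree: PhyloTree, states: Mapping[str, int]) -> ParsimonyTrace:
    """Minimum number of binary-state changes and per-node MPR state sets.

    Tips absent from ``states`` (or mapped to ``None``) are treated as
    unknown and may take either state. ``min_changes`` is 0 iff all observed
    tips share one state; each observed tip's set is exactly its state.
    """
    obs = _tip_states_array(tree, states)
    n = tree.n_nodes

    down = np.zeros((n, 2))
    for tid in tree.tip_ids:
        if obs[tid] == 0:
            down[tid] = (0.0, _INF)
        elif obs[tid] == 1:
            down[tid] = (_INF, 0.0)
    # contrib[c][s] = cost of child c's subtree given its parent is in state s
    contrib = np.zeros((n, 2))
    for v in range(n):
        kids = tree.children[v]
        if kids:
            down[v] = sum(contrib[c] for c in kids)
        if v != tree.root:
            contrib[v, 0] = min(down[v, 0], down[v, 1] + 1)
            contrib[v, 1] = min(down[v, 1], down[v, 0] + 1)

    up = np.zeros((n, 2))
    for v in range(n - 1, -1, -1):
        kids = tree.children[v]
        if not kids:
            continue
        total_contrib = sum(contrib[c] for c in kids)
        for c in kids:
            # cost outside c's subtree, given c's state: reroot through v
            outside = up[v] + total_contrib - contrib[c]
            up[c, 0] = min(outside[0], outside[1] + 1)
            up[c, 1] = min(outside[1], outside[0] + 1)

    total = down + up
    best = float(total.min(axis=1).min())
    sets = {
        v: frozenset(s for s in (0, 1) if total[v, s] <= best)
        for v in range(n)
    }
    return ParsimonyTrace(min_changes=int(round(best)), node_state_sets=sets)


def squared_change_trace(
    tree: PhyloTree, values: Mapping[str, float], weighted: bool = False
) -> ContinuousTrace:
    """Ancestral values minimising the (optionally 1/length-weighted) sum of
    squared changes along edges; tip values are fixed to the input.

    The stationarity conditions form a symmetric positive-definite sparse
    system (a graph Laplacian restricted to internal nodes), solved exactly.
    Reconstructed internal values always lie within [min(tips), max(tips)].
    """
    missing = [lab for lab in tree.tip_labels if lab not in values]
    if missing:
        raise InputError(f"tip(s) without values: {missing}")
    n = tree.n_nodes
    tipval = np.zeros(n)
    is_tip = np.zeros(n, dtype=bool)
    for lab, x in values.items():
        tid = tree.tip_id(lab)
        tipval[tid] = float(x)
        is_tip[tid] = True

    internal = [v for v in range(n) if not is_tip[v]]
    idx = {v: i for i, v in enumerate(internal)}
    m = len(internal)

    def edge_weight(child: int) -> float:
        if not weighted:
            return 1.0
        t = float(tree.length[child])
        return 1.0 / max(t, 1e-12)

    A = scipy.sparse.lil_matrix((m, m))
    b = np.zeros(m)
    for v in internal:
        i = idx[v]
        neighbours = list(tree.children[v])
        if v != tree.root:
            neighbours.append(int(tree.parent[v]))
        for u in neighbours:
            w = edge_weight(v if u == tree.parent[v] else u)
            A[i, i] += w
            if is_tip[u]:
                b[i] += w * tipval[u]
            else:
                A[i, idx[u]] -= w
    x_int = scipy.sparse.linalg.spsolve(A.tocsr(), b) if m else np.empty(0)

    node_values = {v: float(tipval[v]) for v in range(n) if is_tip[v]}
    for v, i in idx.items():
        node_values[v] = float(x_int[i])
    objective = 0.0
    for v in range(n - 1):  # every non-root node has an edge to its parent
        diff = node_values[v] - node_values[int(tree.parent[v])]
        objective += edge_weight(v) * diff * diff
    return ContinuousTrace(node_values=node_values, objective=float(objective))
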