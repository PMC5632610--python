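import itertools

import numpy as np
import pytest

from oscillate import parse_newick, simulate_yule_tree


@pytest.fixture
def cherry():
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def quartet():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def yule50():
    return simulate_yule_tree(50, 1.0, seed=101)


def enumerate_topologies(labels):
    """All rooted binary labeled tree shapes over ``labels`` as nested tuples.

    Counted by the double factorial (2n-3)!!: 1, 3, 15, 105, 945 for
    n = 2..6 leaves.
    """
    labels = tuple(labels)
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    # unordered root split: the subset containing the first label
    for r in range(len(rest) + 1):
        for picked in itertools.combinations(rest, r):
            left = (first,) + picked
            right = tuple(x for x in rest if x not in picked)
            if not right:
                continue
            for lt in enumerate_topologies(left):
                for rt in enumerate_topologies(right):
                    yield (lt, rt)


def topology_to_newick(top, lengths):
    """Serialise a nested-tuple topology with branch lengths drawn from ``lengths``."""
    it = iter(lengths)

    def rec(node, is_root):
        if isinstance(node, tuple):
            inner = "(" + ",".join(rec(c, False) for c in node) + ")"
        else:
            inner = str(node)
        return inner if is_root else f"{inner}:{next(it):.6f}"

    return rec(top, True) + ";"


def _edge_same_indicators(tree):
    """For every non-root edge and every (tip assignment, internal assignment)
    pair, whether child and parent share a state.

    Tip assignment b encodes tip k's state as bit k of b (B = 2^n_tips
    columns); internal assignment m likewise over internal nodes. Returns a
    list of (edge length, same (B, M) boolean array).
    """
    tips = tree.tip_ids
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    B = 1 << len(tips)
    M = 1 << len(internal)
    tip_pos = {v: k for k, v in enumerate(tips)}
    int_pos = {v: k for k, v in enumerate(internal)}

    def state_of(v):
        if v in tip_pos:
            s = (np.arange(B) >> tip_pos[v]) & 1
            return s[:, None]  # (B, 1)
        s = (np.arange(M) >> int_pos[v]) & 1
        return s[None, :]  # (1, M)

    out = []
    for v in range(tree.n_nodes - 1):
        p = int(tree.parent[v])
        same = state_of(v) == state_of(p)
        out.append((float(tree.length[v]), same))
    return out


def enumeration_loglik_all(tree, q):
    """Mk/ER log-likelihood for *every* full tip-state assignment by explicit
    summation over all internal-state assignments — the brute-force oracle
    for the pruning algorithm. Returns (2^n_tips,) array; tip k's state is
    bit k of the index."""
    edges = _edge_same_indicators(tree)
    B = 1 << len(tree.tip_ids)
    M = edges[0][1].shape[1] if edges else 1
    prob = np.full((B, M), 0.5)  # flat root prior
    for t_len, same in edges:
        stay = 0.5 * (1.0 + np.exp(-2.0 * q * t_len))
        prob *= np.where(same, stay, 1.0 - stay)
    total = prob.sum(axis=1)
    with np.errstate(divide="ignore"):
        return np.log(total)


def enumeration_loglik(tree, states, q):
    """Scalar brute-force log-likelihood for one (possibly partial) state map.

    Missing tips are summed over both states, mirroring the (1, 1) partial
    likelihood convention.
    """
    all_ll = enumeration_loglik_all(tree, q)
    tips = tree.tip_ids
    idx_fixed = 0
    missing = []
    for k, tid in enumerate(tips):
        s = states.get(tree.label[tid])
        if s is None:
            missing.append(k)
        elif s:
            idx_fixed |= 1 << k
    if not missing:
        return float(all_ll[idx_fixed])
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(missing)):
        idx = idx_fixed
        for k, bit in zip(missing, combo):
            idx |= bit << k
        total += np.exp(all_ll[idx])
    return float(np.log(total)) if total > 0 else -np.inf


def bruteforce_fitch_all(tree):
    """Minimum change count for every full tip assignment, by exhaustive
    minimisation over internal labelings. Returns (2^n_tips,) int array."""
    edges = _edge_same_indicators(tree)
    B = 1 << len(tree.tip_ids)
    M = edges[0][1].shape[1] if edges else 1
    changes = np.zeros((B, M), dtype=np.int64)
    for _, same in edges:
        changes += ~same
    return changes.min(axis=1)
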