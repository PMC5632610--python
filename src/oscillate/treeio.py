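"""Rooted phylogeny container and Newick round-tripping.

:class:`PhyloTree` is a small array-backed rooted tree: node ids are assigned
in postorder (every child id is smaller than its parent's id, the root is the
last id), which lets every downstream likelihood/parsimony pass iterate over
``range(n_nodes)`` without an explicit stack. Newick reading and writing are
delegated to dendropy; this module adds the validation the comparative
analyses rely on (unique non-empty tip labels, non-negative branch lengths,
exactly one root) and the clade queries used when building sister-clade
contrasts.

Polytomies are preserved as-is; an unrooted basal trifurcation is accepted
and treated as a rooted polytomy (logged). Missing branch lengths default to
1.0 with a warning: parsimony tracing is length-free but the Mk and PGLS
machinery requires lengths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import InputError, NewickError

logger = logging.getLogger(__name__)

__all__ = ["PhyloTree", "parse_newick", "write_newick"]

DEFAULT_BRANCH_LENGTH = 1.0


@dataclass
class PhyloTree:
    """Rooted tree with labeled tips and non-negative branch lengths.

    Attributes
    ----------
    parent
        ``parent[i]`` is the parent id of node ``i``; ``-1`` for the root.
    children
        ``children[i]`` lists the child ids of node ``i`` (empty for tips).
    length
        Branch length from node ``i`` to its parent; 0.0 for the root.
    label
        Tip label for leaf nodes, ``None`` for internal nodes.

    Node ids are postorder: children always precede their parent.
    """

    parent: np.ndarray
    children: list[list[int]]
    length: np.ndarray
    label: list[str | None]
    _tip_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=np.float64)
        self._validate()
        self._tip_index = {
            lab: i for i, lab in enumerate(self.label) if lab is not None
        }

    # -- invariants -------------------------------------------------------
    def _validate(self) -> None:
        n = len(self.parent)
        if n == 0:
            raise NewickError("empty tree")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise NewickError(f"tree must have exactly one root, found {len(roots)}")
        if roots[0] != n - 1:
            raise NewickError("node ids must be postorder (root last)")
        if np.any(self.parent[:-1] <= np.arange(n - 1)):
            raise NewickError("node ids must be postorder (child < parent)")
        if np.any(self.length < 0):
            bad = int(np.flatnonzero(self.length < 0)[0])
            raise NewickError(
                f"negative branch length {self.length[bad]} on node {bad}"
            )
        tips = [lab for i, lab in enumerate(self.label) if not self.children[i]]
        if any(lab is None or lab == "" for lab in tips):
            raise NewickError("every tip must carry a non-empty label")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    @property
    def tip_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def n_tips(self) -> int:
        return len(self._tip_index)

    @property
    def tip_labels(self) -> list[str]:
        return [self.label[i] for i in self.tip_ids]  # type: ignore[misc]

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise InputError(f"unknown tip label {label!r}") from None

    def _check_node(self, node: int) -> None:
        if not 0 <= node < self.n_nodes:
            raise InputError(f"unknown node id {node}")

    def clade_tips(self, node: int) -> set[str]:
        """Tip labels descended from ``node`` (the node itself if a tip)."""
        self._check_node(node)
        out: set[str] = set()
        stack = [node]
        while stack:
            v = stack.pop()
            if self.children[v]:
                stack.extend(self.children[v])
            else:
                out.add(self.label[v])  # type: ignore[arg-type]
        return out

    def sister_of(self, node: int) -> int | frozenset[int]:
        """The sister node, or the set of co-children under a polytomy.

        For a child of a binary node this is the unique other child; under a
        polytomy the full tie-set of co-children is returned and the caller
        decides how to treat it.
        """
        self._check_node(node)
        p = int(self.parent[node])
        if p < 0:
            raise InputError("the root has no sister")
        sibs = [c for c in self.children[p] if c != node]
        if len(sibs) == 1:
            return sibs[0]
        return frozenset(sibs)

    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths for every node."""
        depth = np.zeros(self.n_nodes)
        for v in range(self.n_nodes - 2, -1, -1):
            depth[v] = depth[self.parent[v]] + self.length[v]
        return depth

    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        d = self.node_depths()
        return float(max(d[i] for i in self.tip_ids))

    def total_length(self) -> float:
        return float(self.length.sum())

    def rescaled(self, factor: float) -> "PhyloTree":
        """Copy of the tree with all branch lengths multiplied by ``factor``."""
        if factor <= 0:
            raise InputError("rescale factor must be positive")
        return PhyloTree(
            self.parent.copy(),
            [list(c) for c in self.children],
            self.length * factor,
            list(self.label),
        )

    # -- newick -----------------------------------------------------------
    def to_newick(self, include_lengths: bool = True) -> str:
        def rec(v: int) -> str:
            if self.is_tip(v):
                s = _quote(self.label[v])  # type: ignore[arg-type]
            else:
                s = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if include_lengths and v != self.root:
                s += f":{self.length[v]:.10g}"
            return s

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)


def _quote(label: str) -> str:
    if any(ch in label for ch in "():,; \t'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Branch lengths are optional and default to 1.0 (with a warning) when
    absent. Malformed syntax, duplicate tip labels and negative branch
    lengths raise :class:`~oscillate.errors.NewickError` naming the problem.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise NewickError(f"malformed Newick: {exc}") from exc

    ids: dict[int, int] = {}
    parent: list[int] = []
    children: list[list[int]] = []
    length: list[float] = []
    label: list[str | None] = []
    missing_lengths = 0
    for i, nd in enumerate(dtree.postorder_node_iter()):
        ids[id(nd)] = i
        parent.append(-1)
        children.append([ids[id(c)] for c in nd.child_nodes()])
        for c in nd.child_nodes():
            parent[ids[id(c)]] = i
        if nd.parent_node is None:
            bl = 0.0
        elif nd.edge.length is None:
            bl = DEFAULT_BRANCH_LENGTH
            missing_lengths += 1
        else:
            bl = float(nd.edge.length)
        length.append(bl)
        if nd.is_leaf():
            label.append(nd.taxon.label if nd.taxon is not None else None)
        else:
            label.append(None)
    if missing_lengths:
        warnings.warn(
            f"{missing_lengths} branch length(s) missing; defaulting to "
            f"{DEFAULT_BRANCH_LENGTH}",
            stacklevel=2,
        )
    tree = PhyloTree(np.array(parent), children, np.array(length), label)
    if len(tree.children[tree.root]) > 2:
        logger.info(
            "root has %d children; treating unrooted/basal polytomy as a "
            "rooted polytomy",
            len(tree.children[tree.root]),
        )
    return tree


def write_newick(tree: PhyloTree, include_lengths: bool = True) -> str:
    """Serialize a tree; ``parse_newick(write_newick(t))`` is isomorphic to ``t``."""
    return tree.to_newick(include_lengths=include_lengths)
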