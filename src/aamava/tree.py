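"""Rooted time trees.

A :class:`TimeTree` is a rooted binary tree over N labelled tips with a
height (age before the present) for every node; branch lengths are parent
height minus child height, in expected substitutions per site once
multiplied by a clock rate.  The flat array layout (parent pointers,
children pairs, heights) keeps MCMC moves cheap; Newick/NEXUS conversion
goes through dendropy.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

__all__ = ["TimeTree", "read_newick", "write_newick"]


class TimeTree:
    """Rooted binary ultrametric-capable tree with node heights.

    Nodes ``0..n_tips-1`` are tips (height 0 unless dated), nodes
    ``n_tips..2*n_tips-2`` are internal.  ``parent[root] == -1``.
    """

    def __init__(self, labels: list[str], parent: np.ndarray, children: np.ndarray,
                 heights: np.ndarray):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        self.children = np.asarray(children, dtype=np.int64).copy()
        self.heights = np.asarray(heights, dtype=float).copy()
        self.n_tips = len(labels)
        if len(set(self.labels)) != self.n_tips:
            raise ValueError("tip labels must be unique")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    def validate(self) -> None:
        n = self.n_tips
        if self.parent.shape != (2 * n - 1,):
            raise ValueError("parent array has wrong size")
        if self.children.shape != (2 * n - 1, 2):
            raise ValueError("children array has wrong size")
        for node in range(2 * n - 1):
            p = self.parent[node]
            if p >= 0 and self.heights[p] <= self.heights[node]:
                raise ValueError(
                    f"parent height must exceed child height at node {node}"
                )
        if np.any(self.children[:n] != -1):
            raise ValueError("tips cannot have children")

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        if p < 0:
            raise ValueError("root has no branch")
        return float(self.heights[p] - self.heights[node])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 slot for root)."""
        out = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        out[mask] = self.heights[self.parent[mask]] - self.heights[mask]
        return out

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            if node >= self.n_tips:
                stack.extend(self.children[node])
        order.reverse()
        return order

    def root_height(self) -> float:
        return float(self.heights[self.root])

    def copy(self) -> "TimeTree":
        return TimeTree(self.labels, self.parent, self.children, self.heights)

    def clade_bitsets(self) -> dict[int, frozenset[str]]:
        """Tip-label set below each internal node."""
        sets: dict[int, frozenset[str]] = {}
        below: dict[int, set[str]] = {i: {self.labels[i]} for i in range(self.n_tips)}
        for node in self.postorder():
            if node >= self.n_tips:
                l, r = self.children[node]
                below[node] = below[l] | below[r]
                sets[node] = frozenset(below[node])
        return sets

    # -- Newick ------------------------------------------------------------

    def to_newick(self, precision: int = 12) -> str:
        def rec(node: int) -> str:
            if node < self.n_tips:
                core = self.labels[node]
            else:
                l, r = self.children[node]
                core = f"({rec(l)},{rec(r)})"
            if node == self.root:
                return core
            return f"{core}:{self.branch_length(node):.{precision}g}"
        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=True)
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "TimeTree":
        leaves = [lf for lf in dt.leaf_node_iter()]
        labels = [lf.taxon.label for lf in leaves]
        n = len(labels)
        index = {id(lf): i for i, lf in enumerate(leaves)}
        nxt = n
        for node in dt.postorder_node_iter():
            if node.is_leaf():
                continue
            if len(node.child_nodes()) != 2:
                raise ValueError("tree must be strictly bifurcating")
            index[id(node)] = nxt
            nxt += 1
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
        depth: dict[int, float] = {}
        for node in dt.preorder_node_iter():
            i = index[id(node)]
            if node.parent_node is None:
                depth[i] = 0.0
            else:
                p = index[id(node.parent_node)]
                parent[i] = p
                depth[i] = depth[p] + (node.edge.length or 0.0)
            for slot, ch in enumerate(node.child_nodes()):
                children[i, slot] = index[id(ch)]
        span = max(depth.values())
        heights = np.array([span - depth[i] for i in range(2 * n - 1)])
        heights[np.abs(heights) < 1e-12] = 0.0
        return cls(labels, parent, children, heights)

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None
                    ) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(), schema="newick",
            taxon_namespace=taxon_namespace or dendropy.TaxonNamespace(self.labels),
        )


def read_newick(path_or_text) -> TimeTree:
    """Read a tree from a Newick file path or a raw Newick string."""
    text = path_or_text
    if not str(text).lstrip().startswith("("):
        with open(path_or_text) as fh:
            text = fh.read()
    return TimeTree.from_newick(text)


def write_newick(tree: TimeTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
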