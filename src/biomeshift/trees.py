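"""Rooted binary time-trees: newick I/O and flat postorder arrays.

Trees are parsed with dendropy and converted to a flat representation that
the pruning and simulation kernels consume: nodes are numbered with tips
first (``0 .. n_tips - 1``, in the order of ``tip_labels``), internal nodes
follow in postorder, and the root is the last node.  Every non-root node
carries the length of the branch above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

__all__ = ["Phylogeny", "read_tree", "parse_newick"]


class TreeFormatError(ValueError):
    """Malformed tree input (polytomy, missing branch lengths, ...)."""


@dataclass
class Phylogeny:
    """Rooted binary phylogeny in flat postorder form.

    Attributes
    ----------
    tip_labels:
        Tip names; tip node ids are their positions in this list.
    left, right:
        For each internal node (postorder over internal nodes), the node
        ids of its two children.  The last entry is the root.
    branch_lengths:
        Length of the branch above every node (0.0 stored for the root).
    """

    tip_labels: tuple[str, ...]
    left: np.ndarray
    right: np.ndarray
    internal_ids: np.ndarray
    branch_lengths: np.ndarray
    _dendropy: Optional[dendropy.Tree] = field(default=None, repr=False)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root_id(self) -> int:
        return self.n_nodes - 1

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length."""
        depth = np.zeros(self.n_nodes)
        for k in range(len(self.internal_ids) - 1, -1, -1):
            v = self.internal_ids[k]
            for c in (self.left[k], self.right[k]):
                depth[c] = depth[v] + self.branch_lengths[c]
        return float(depth[: self.n_tips].max())

    def rescaled(self, height: float = 1.0) -> "Phylogeny":
        """Copy with all branch lengths scaled so the root height matches.

        Rates are defined per unit tree height, so analyses normally run on
        a unit-height tree.
        """
        h = self.height
        if h <= 0:
            raise TreeFormatError("tree has zero height; cannot rescale")
        bl = self.branch_lengths * (height / h)
        t = Phylogeny(
            tip_labels=self.tip_labels,
            left=self.left.copy(),
            right=self.right.copy(),
            internal_ids=self.internal_ids.copy(),
            branch_lengths=bl,
            _dendropy=None,
        )
        return t

    def newick(self) -> str:
        """Serialize to a newick string (12 significant digits)."""

        def fmt(node: int) -> str:
            if self.is_tip(node):
                base = self.tip_labels[node]
            else:
                k = int(np.flatnonzero(self.internal_ids == node)[0])
                base = f"({fmt(self.left[k])},{fmt(self.right[k])})"
            if node == self.root_id:
                return base
            return f"{base}:{self.branch_lengths[node]:.12g}"

        return fmt(self.root_id) + ";"

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        root = tree.seed_node
        # suppress a unifurcation at the root (common in newick output)
        while len(root.child_nodes()) == 1:
            root = root.child_nodes()[0]
        tips = []
        internals = []
        for nd in root.postorder_iter():
            kids = nd.child_nodes()
            if not kids:
                tips.append(nd)
            elif len(kids) == 2:
                internals.append(nd)
            else:
                raise TreeFormatError(
                    f"node {nd.taxon.label if nd.taxon else nd} has "
                    f"{len(kids)} children; the tree must be strictly binary"
                )
        labels = []
        for nd in tips:
            if nd.taxon is None or not nd.taxon.label:
                raise TreeFormatError("unlabeled tip in tree")
            labels.append(nd.taxon.label)
        if len(set(labels)) != len(labels):
            raise TreeFormatError("duplicate tip labels in tree")
        ids = {nd: i for i, nd in enumerate(tips)}
        for j, nd in enumerate(internals):
            ids[nd] = len(tips) + j
        n_nodes = len(tips) + len(internals)
        left = np.zeros(len(internals), dtype=np.int64)
        right = np.zeros(len(internals), dtype=np.int64)
        internal_ids = np.zeros(len(internals), dtype=np.int64)
        bl = np.zeros(n_nodes)
        for j, nd in enumerate(internals):
            a, b = nd.child_nodes()
            left[j], right[j] = ids[a], ids[b]
            internal_ids[j] = ids[nd]
        for nd in tips + internals:
            if nd is root:
                continue
            if nd.edge.length is None:
                who = nd.taxon.label if nd.taxon else "an internal node"
                raise TreeFormatError(f"missing branch length above {who}")
            if nd.edge.length < 0 or not np.isfinite(nd.edge.length):
                raise TreeFormatError("branch lengths must be finite and >= 0")
            bl[ids[nd]] = float(nd.edge.length)
        return cls(
            tip_labels=tuple(labels),
            left=left,
            right=right,
            internal_ids=internal_ids,
            branch_lengths=bl,
            _dendropy=tree,
        )


def parse_newick(newick: str) -> Phylogeny:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return Phylogeny.from_dendropy(tree)


def read_tree(path: str) -> Phylogeny:
    """Read a rooted binary newick tree with branch lengths from a file."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return Phylogeny.from_dendropy(tree)
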