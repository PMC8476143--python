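"""Rooted species tree container.

The reconstruction conditions on a fixed, rooted species tree.  Internally
the tree is stored as flat preorder arrays (parent pointers, child lists,
branch lengths) so that the pruning recursions can be vectorized over sites.
Newick parsing is delegated to dendropy; this module only converts between
dendropy's node objects and the array representation.

Branch lengths are kept for the independent-contrasts analysis only; the
gain/loss model is parameterized directly by per-branch intensities
(rate x time) and ignores them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "NewickFormatError",
    "TreeValidationError",
    "read_newick",
    "write_newick",
]


class NewickFormatError(ValueError):
    """Raised when a newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


@dataclass
class PhyloTree:
    """Rooted tree in preorder arrays.

    Node 0 is the root.  ``parent[i]`` is the preorder index of the parent
    (-1 for the root), ``children[i]`` lists child indices in input order,
    and ``lengths[i]`` is the length of the branch above node ``i``
    (0.0 for the root, 1.0 where the newick gave none).
    """

    names: list[str]
    parent: np.ndarray
    lengths: np.ndarray
    children: list[list[int]] = field(repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.sum(self.parent < 0) != 1 or self.parent[0] != -1:
            raise TreeValidationError("exactly one root expected at index 0")
        leaves = self.leaf_names
        if len(set(leaves)) != len(leaves):
            raise TreeValidationError("duplicate leaf labels")
        if any(not n for n in leaves):
            raise TreeValidationError("empty leaf label")
        if np.any(self.lengths[1:] < 0):
            raise TreeValidationError("negative branch length")

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return 0

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaf_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if self.is_leaf(i)])

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaf_indices]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        # preorder reversed is a valid postorder for this layout
        return np.arange(self.n_nodes)[::-1]

    def preorder(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no node named {name!r}") from None

    def path_to_root(self, i: int) -> list[int]:
        """Nodes from ``i`` up to and including the root."""
        path = [i]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def mrca(self, indices) -> int:
        """Most recent common ancestor of a set of node indices."""
        indices = list(indices)
        if not indices:
            raise ValueError("mrca of empty set")
        common = set(self.path_to_root(indices[0]))
        for i in indices[1:]:
            common &= set(self.path_to_root(i))
        # deepest common ancestor = max preorder index among common ancestors
        # that is an ancestor of all; preorder index ordering works because
        # ancestors of a node appear earlier in preorder.
        return max(common, key=lambda v: len(self.path_to_root(v)))

    def subtree(self, i: int) -> list[int]:
        """All nodes in the clade rooted at ``i`` (preorder)."""
        out = []
        stack = [i]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(reversed(self.children[v]))
        return out

    def leaves_below(self, i: int) -> list[int]:
        return [v for v in self.subtree(i) if self.is_leaf(v)]

    # -- io ----------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return read_newick(text)

    def to_newick(self) -> str:
        return write_newick(self)


def _subtree_newick(tree: PhyloTree, i: int) -> str:
    if tree.is_leaf(i):
        body = tree.names[i]
    else:
        inner = ",".join(_subtree_newick(tree, c) for c in tree.children[i])
        body = f"({inner}){tree.names[i]}"
    if i == tree.root:
        return body
    return f"{body}:{tree.lengths[i]:.12g}"


def write_newick(tree: PhyloTree) -> str:
    """Serialize a :class:`PhyloTree` to a rooted newick string."""
    return _subtree_newick(tree, tree.root) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse a rooted newick string into a :class:`PhyloTree`.

    The outermost clade is taken as the root.  Missing branch lengths
    default to 1.0.  Unlabelled internal nodes are named deterministically
    by their preorder index (``n<k>``).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        offset = getattr(exc, "col_num", None)
        where = f" near character {offset}" if offset is not None else ""
        raise NewickFormatError(f"newick parse failure{where}: {exc}") from exc

    # flatten to preorder arrays
    dnodes = list(dtree.preorder_node_iter())
    index = {id(n): k for k, n in enumerate(dnodes)}
    names: list[str] = []
    parent = np.full(len(dnodes), -1, dtype=np.int64)
    lengths = np.zeros(len(dnodes))
    children: list[list[int]] = [[] for _ in dnodes]
    for k, node in enumerate(dnodes):
        if node.taxon is not None and node.taxon.label:
            label = node.taxon.label
        elif node.label:
            label = node.label
        else:
            label = f"n{k}"
        names.append(label)
        if node.parent_node is not None:
            p = index[id(node.parent_node)]
            parent[k] = p
            children[p].append(k)
            lengths[k] = node.edge.length if node.edge.length is not None else 1.0
    try:
        return PhyloTree(names=names, parent=parent, lengths=lengths, children=children)
    except TreeValidationError:
        raise


def trees_isomorphic(a: PhyloTree, b: PhyloTree) -> bool:
    """True when two rooted trees have the same labelled topology.

    Compares canonical forms where children are ordered by their smallest
    descendant leaf label; branch lengths are compared to 1e-6.
    """

    def canon(tree: PhyloTree, i: int):
        if tree.is_leaf(i):
            return (tree.names[i], round(float(tree.lengths[i]), 6))
        kids = sorted((canon(tree, c) for c in tree.children[i]), key=repr)
        return (tuple(kids), round(float(tree.lengths[i]), 6))

    return canon(a, a.root) == canon(b, b.root)
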