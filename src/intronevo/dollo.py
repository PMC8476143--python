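"""Dollo parsimony reconstruction of intron site histories.

Dollo parsimony allows each intron site a single origination (gain) with
an unlimited number of subsequent losses.  The most parsimonious single
gain is placed at the most recent common ancestor of the unambiguously
present leaves; the site is present on the minimal subtree spanning those
leaves and absent elsewhere, with one loss charged per maximal absent
clade hanging off the spanning subtree.  Ambiguous leaves carry no
constraint: a clade containing only ambiguous leaves is reconstructed
absent but charged no loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import PhyloTree

__all__ = ["DolloHistory", "dollo_reconstruct"]


@dataclass
class DolloHistory:
    """Single-gain reconstruction of one site."""

    gain_node: int            # node under whose parent branch the gain occurred
    loss_branches: list[int]  # nodes whose parent branch carries a loss
    node_states: np.ndarray   # 0/1 per tree node

    @property
    def n_losses(self) -> int:
        return len(self.loss_branches)


def dollo_reconstruct(tree: PhyloTree, leaf_states: np.ndarray) -> DolloHistory:
    """Reconstruct one site under Dollo parsimony.

    ``leaf_states`` holds one code per leaf (0, 1 or 2 for '?') in the
    tree's leaf order.  At least one leaf must be unambiguously present.
    """
    leaf_states = np.asarray(leaf_states)
    leaf_idx = tree.leaf_indices
    present_nodes = leaf_idx[leaf_states == 1]
    if len(present_nodes) == 0:
        raise ValueError("Dollo reconstruction needs >= 1 present leaf")

    gain = tree.mrca(present_nodes)

    # has_present[v]: any unambiguously present leaf in subtree(v);
    # has_absent[v]: any unambiguously absent leaf in subtree(v)
    n = tree.n_nodes
    has_present = np.zeros(n, dtype=bool)
    has_absent = np.zeros(n, dtype=bool)
    state_of = dict(zip(leaf_idx.tolist(), leaf_states.tolist()))
    for v in tree.postorder():
        if tree.is_leaf(v):
            has_present[v] = state_of[v] == 1
            has_absent[v] = state_of[v] == 0
        else:
            for c in tree.children[v]:
                has_present[v] |= has_present[c]
                has_absent[v] |= has_absent[c]

    in_gain_subtree = np.zeros(n, dtype=bool)
    for v in tree.subtree(gain):
        in_gain_subtree[v] = True

    node_states = np.zeros(n, dtype=np.int8)
    losses: list[int] = []
    for v in tree.subtree(gain):
        if has_present[v]:
            node_states[v] = 1
            for c in tree.children[v]:
                if not has_present[c] and has_absent[c]:
                    losses.append(c)
        # clades without present leaves stay absent; only those containing
        # an unambiguous absence are charged (at their root branch, merged
        # maximally by construction)
    return DolloHistory(gain_node=gain, loss_branches=sorted(losses),
                        node_states=node_states)


def dollo_node_counts(tree: PhyloTree, states_matrix: np.ndarray) -> np.ndarray:
    """Per-node count of Dollo-present sites over a site x leaf matrix.

    Sites with no unambiguous present leaf are skipped (they cannot be
    reconstructed and are removed by the table filter anyway).
    """
    counts = np.zeros(tree.n_nodes)
    for row in states_matrix:
        if not np.any(row == 1):
            continue
        counts += dollo_reconstruct(tree, row).node_states
    return counts
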