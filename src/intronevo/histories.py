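"""Posterior decoding of per-site gain/loss histories and event calling.

For every site and branch the up-down algorithm yields posterior gain and
loss probabilities; only events with posterior probability at or above a
cutoff (default 0.99, boundary inclusive) are called.  Sites with no
called event anywhere and at least one extant intron are labelled
"presence" — their intron is reconstructed as retained along the tree
rather than recently moved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import PruningEngine
from .model import GainLossModel
from .sites import IntronSiteTable
from .tree import PhyloTree

__all__ = [
    "SiteHistorySet",
    "compute_histories",
    "classify_histories",
    "lineage_site_labels",
    "false_positive_rate",
]

DEFAULT_PP_CUTOFF = 0.99


@dataclass
class SiteHistorySet:
    """Posterior event probabilities for every site and branch.

    ``p_gain``/``p_loss`` have shape (n_sites, n_nodes) with zeros at the
    root column; ``node_presence`` holds per-node posterior presence
    probabilities.
    """

    tree: PhyloTree
    site_ids: list[str]
    p_gain: np.ndarray
    p_loss: np.ndarray
    node_presence: np.ndarray
    calls: pd.DataFrame | None = None
    cutoff: float | None = None
    extant_present: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for a in (self.p_gain, self.p_loss, self.node_presence):
            if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
                raise ValueError("posterior probabilities outside [0, 1]")
        if np.any(self.p_gain + self.p_loss > 1 + 1e-9):
            raise ValueError("gain + loss posterior exceeds 1 on some branch")

    def calls_frame(self) -> pd.DataFrame:
        if self.calls is None:
            raise ValueError("run classify_histories first")
        return self.calls


def compute_histories(
    tree: PhyloTree, model: GainLossModel, table: IntronSiteTable
) -> SiteHistorySet:
    """Posterior gain/loss/presence probabilities for every table site."""
    table = table.reorder_species(tree.leaf_names)
    engine = PruningEngine(tree, model)
    p_gain, p_loss = engine.branch_event_posteriors(table.states)
    presence = engine.node_posteriors(table.states)
    return SiteHistorySet(
        tree=tree,
        site_ids=[str(s) for s in table.meta["site_id"]],
        p_gain=p_gain,
        p_loss=p_loss,
        node_presence=presence,
        extant_present=np.any(table.states == 1, axis=1),
    )


def classify_histories(
    histories: SiteHistorySet, cutoff: float = DEFAULT_PP_CUTOFF
) -> SiteHistorySet:
    """Threshold posterior events into called gains and losses.

    Every (site, branch) posterior >= cutoff becomes a call; everything
    else stays uncalled.  Adds a per-site "presence" record for sites with
    no called events and at least one extant intron.  Returns the same
    history set with its ``calls`` frame populated.
    """
    if not 0.5 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0.5, 1]")
    tree = histories.tree
    rows = []
    called_any = np.zeros(len(histories.site_ids), dtype=bool)
    for event, p in (("gain", histories.p_gain), ("loss", histories.p_loss)):
        s_idx, b_idx = np.nonzero(p >= cutoff)
        called_any[s_idx] = True
        for s, b in zip(s_idx.tolist(), b_idx.tolist()):
            rows.append(
                {
                    "site_id": histories.site_ids[s],
                    "branch": tree.names[b],
                    "event": event,
                    "posterior": float(p[s, b]),
                }
            )
    if histories.extant_present is not None:
        for s in np.nonzero(~called_any & histories.extant_present)[0]:
            rows.append(
                {
                    "site_id": histories.site_ids[s],
                    "branch": "",
                    "event": "presence",
                    "posterior": float("nan"),
                }
            )
    histories.calls = pd.DataFrame(
        rows, columns=["site_id", "branch", "event", "posterior"]
    ).sort_values(["site_id", "branch", "event"], kind="stable").reset_index(drop=True)
    histories.cutoff = cutoff
    return histories


def lineage_site_labels(
    histories: SiteHistorySet,
    species: str,
    table: IntronSiteTable,
    cutoff: float = DEFAULT_PP_CUTOFF,
) -> pd.Series:
    """History label of each site on the root-to-leaf path of one species.

    Walking the path from the root to the species' leaf, the most recent
    (closest to the leaf) called event determines the label: "gain" or
    "loss".  Sites with no called event on the path are "presence" when
    the extant state is present and "uncalled" otherwise.  Ambiguous
    extant states yield "uncalled".
    """
    tree = histories.tree
    table = table.reorder_species(tree.leaf_names)
    leaf = tree.index_of(species)
    col = list(tree.leaf_names).index(species)
    path = tree.path_to_root(leaf)  # leaf first
    labels = []
    for s in range(len(histories.site_ids)):
        label = None
        for b in path:  # leaf-to-root: first called event is the most recent
            if b == tree.root:
                break
            if histories.p_gain[s, b] >= cutoff:
                label = "gain"
                break
            if histories.p_loss[s, b] >= cutoff:
                label = "loss"
                break
        if label is None:
            label = "presence" if table.states[s, col] == 1 else "uncalled"
        labels.append(label)
    return pd.Series(labels, index=histories.site_ids, name=species)


def false_positive_rate(candidates: int, flagged: int) -> float:
    """Percentage of candidate events flagged as false positives."""
    if candidates <= 0:
        raise ValueError("candidates must be > 0")
    if not 0 <= flagged <= candidates:
        raise ValueError("flagged must lie in [0, candidates]")
    return 100.0 * flagged / candidates
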