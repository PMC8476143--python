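"""Ground-truth-labelled synthetic data for every pipeline stage.

The generator mirrors the assumptions of the inference model exactly: a
root state drawn from Bernoulli(pi_root), one of K equally probable
loss-rate categories per site, and per-branch interval transition matrices
(at most one net event per branch per site — multiple hits within a branch
are unidentifiable and are not simulated).  Sites absent in every leaf are
rejected and redrawn, matching the observability conditioning of the
likelihood; the number of rejected draws is recorded.

Default parameters are a desk-scale stand-in for a fungal-style data set:
a 16-leaf tree, loss-biased intensities (gain 0.1, loss 0.3 per branch),
a moderately intron-rich root (pi = 0.6), strong loss-rate heterogeneity
(alpha = 1, K = 2), 5% alignment-ambiguity masking, ~150 nt mean exon
segments, and negative-binomial expression counts in which introns double
translation efficiency (tau = 2).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genestruct import GeneModel, GeneStructure, IntronSiteInfo
from .likelihood import PruningEngine
from .model import GainLossModel
from .sites import MISSING, IntronSiteTable
from .tree import PhyloTree

__all__ = [
    "TrueHistory",
    "MaskResult",
    "ExpressionParams",
    "SyntheticBundle",
    "random_bifurcating_tree",
    "rate_time_model",
    "simulate_sites",
    "mask_ambiguity",
    "simulate_gene_structures",
    "extant_structure",
    "true_lineage_labels",
    "simulate_expression",
    "simulate_bundle",
    "write_bundle",
]


def _require_seed(seed) -> int:
    if seed is None:
        raise ValueError("a seed is required; simulations must be reproducible")
    return int(seed)


def random_bifurcating_tree(
    n_leaves: int, seed: int, mean_branch: float = 1.0
) -> PhyloTree:
    """Random rooted bifurcating tree with exponential branch lengths.

    Topology by sequential random attachment (leaves named sp01, sp02,
    ...); deterministic under ``seed``.
    """
    if n_leaves < 2:
        raise ValueError("need >= 2 leaves")
    rng = np.random.default_rng(_require_seed(seed))
    # grow the topology by replacing a random extant leaf with a cherry;
    # child lists keyed by node id, root id = -1
    topo: dict[int, list[int]] = {-1: [0, 1]}
    next_id = 2
    leaf_ids = [0, 1]
    while len(leaf_ids) < n_leaves:
        pick = int(rng.integers(0, len(leaf_ids)))
        old = leaf_ids[pick]
        internal = next_id
        new_leaf = next_id + 1
        next_id += 2
        # replace `old` by a cherry (old, new_leaf) under `internal`
        for node, kids in topo.items():
            if old in kids:
                kids[kids.index(old)] = internal
                break
        topo[internal] = [old, new_leaf]
        leaf_ids.append(new_leaf)

    # flatten to preorder arrays
    names: list[str] = []
    parent: list[int] = []
    lengths: list[float] = []
    children: list[list[int]] = []
    leaf_counter = [0]

    def visit(node_id: int, parent_idx: int) -> None:
        idx = len(names)
        if node_id in topo:
            names.append(f"n{idx}")
        else:
            leaf_counter[0] += 1
            names.append(f"sp{leaf_counter[0]:02d}")
        parent.append(parent_idx)
        lengths.append(0.0 if parent_idx < 0 else
                       float(rng.exponential(mean_branch)) + 1e-3)
        children.append([])
        if parent_idx >= 0:
            children[parent_idx].append(idx)
        for kid in topo.get(node_id, []):
            visit(kid, idx)

    visit(-1, -1)
    return PhyloTree(names=names, parent=np.array(parent),
                     lengths=np.array(lengths), children=children)


def rate_time_model(
    tree: PhyloTree,
    gain_rate: float,
    loss_rate: float,
    pi_root: float,
    alpha: float = np.inf,
    K: int = 1,
) -> GainLossModel:
    """Gain/loss model with intensities proportional to branch lengths.

    Per-branch intensity = rate x branch duration, the regime of a real
    time-calibrated tree.  Branch-length heterogeneity is what makes
    high-confidence event calling possible: an event on a long branch
    flanked by short ones leaves little room for competing multi-event
    explanations, whereas on a uniform-intensity tree the "event one
    branch earlier plus a compensating second event" alternative always
    retains posterior weight comparable to the per-branch intensity.
    """
    gain = gain_rate * tree.lengths
    loss = loss_rate * tree.lengths
    gain[tree.root] = loss[tree.root] = 0.0
    return GainLossModel(gain=gain, loss=loss, pi_root=pi_root,
                         alpha=alpha, K=K)


@dataclass
class TrueHistory:
    """Ground truth behind a simulated site table."""

    node_states: np.ndarray   # (n_sites, n_nodes) 0/1
    categories: np.ndarray    # (n_sites,) category index per site
    events: list[list[tuple[int, str]]]  # per site: (node, "gain"|"loss")
    n_rejected: int = 0       # all-absent draws discarded

    def subset(self, indices) -> "TrueHistory":
        indices = np.asarray(indices)
        return TrueHistory(
            node_states=self.node_states[indices],
            categories=self.categories[indices],
            events=[self.events[i] for i in indices.tolist()],
            n_rejected=self.n_rejected,
        )


def _default_meta(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [f"s{i:06d}" for i in range(n)],
            "gene_id": ["unassigned"] * n,
            "ordinal": np.ones(n, dtype=int),
            "cds_offset": np.ones(n, dtype=int),
        }
    )


def simulate_sites(
    tree: PhyloTree, model: GainLossModel, n_sites: int, seed: int
) -> tuple[IntronSiteTable, TrueHistory]:
    """Simulate observed intron sites under the gain/loss model.

    Sites invisible at every leaf are rejected and redrawn until
    ``n_sites`` observed sites exist; the rejection count is reported on
    the returned :class:`TrueHistory`.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(_require_seed(seed))
    P = PruningEngine(tree, model).P  # (K, N, 2, 2)
    K = P.shape[0]
    N = tree.n_nodes
    leaf_idx = tree.leaf_indices
    preorder = [v for v in tree.preorder() if v != tree.root]

    kept_states: list[np.ndarray] = []
    kept_cats: list[np.ndarray] = []
    n_rejected = 0
    remaining = n_sites
    while remaining > 0:
        m = max(remaining, 128)
        cats = rng.integers(0, K, size=m)
        states = np.empty((m, N), dtype=np.int8)
        states[:, tree.root] = rng.random(m) < model.pi_root
        for v in preorder:
            p1 = P[cats, v, states[:, tree.parent[v]], 1]
            states[:, v] = rng.random(m) < p1
        observed = np.any(states[:, leaf_idx] == 1, axis=1)
        n_rejected += int(m - observed.sum())
        take = np.nonzero(observed)[0][:remaining]
        kept_states.append(states[take])
        kept_cats.append(cats[take])
        remaining -= len(take)

    node_states = np.concatenate(kept_states)
    categories = np.concatenate(kept_cats)
    events = [
        [
            (int(v), "gain" if node_states[s, v] else "loss")
            for v in preorder
            if node_states[s, v] != node_states[s, tree.parent[v]]
        ]
        for s in range(n_sites)
    ]
    table = IntronSiteTable(
        species=tree.leaf_names,
        states=node_states[:, leaf_idx],
        meta=_default_meta(n_sites),
    )
    history = TrueHistory(node_states, categories, events, n_rejected)
    return table, history


@dataclass
class MaskResult:
    """Masked table plus bookkeeping for ground-truth alignment."""

    table: IntronSiteTable
    kept_indices: np.ndarray
    n_dropped: int


def mask_ambiguity(
    table: IntronSiteTable, mask_prob: float, seed: int
) -> MaskResult:
    """Replace cells by '?' independently with probability ``mask_prob``.

    Sites left without any unambiguous present state are dropped (they
    could never have been observed); the drop count and the surviving
    row indices are reported.
    """
    if not 0.0 <= mask_prob < 1.0:
        raise ValueError("mask_prob must lie in [0, 1)")
    rng = np.random.default_rng(_require_seed(seed))
    states = table.states.copy()
    if mask_prob > 0:
        mask = rng.random(states.shape) < mask_prob
        states[mask] = MISSING
    keep = np.nonzero(np.any(states == 1, axis=1))[0]
    masked = IntronSiteTable(table.species, states[keep], table.meta.iloc[keep])
    return MaskResult(masked, keep, table.n_sites - len(keep))


def simulate_gene_structures(
    table: IntronSiteTable,
    n_genes: int,
    exon_length_mean: float = 150.0,
    seed: int = 0,
) -> tuple[list[GeneModel], IntronSiteTable]:
    """Partition sites into genes and draw ancestral exon segment lengths.

    Sites are assigned to genes in contiguous blocks (preserving per-gene
    ordinal order).  Ancestral exon segments are i.i.d. shifted-geometric
    with the stated mean and a 3 nt minimum; CDS offsets are their
    cumulative sums.  Returns the gene models and a copy of the table with
    gene_id / ordinal / cds_offset metadata filled in.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if table.n_sites < n_genes:
        raise ValueError("fewer sites than genes")
    if exon_length_mean <= 3:
        raise ValueError("exon_length_mean must exceed the 3 nt minimum")
    rng = np.random.default_rng(_require_seed(seed))
    p = 1.0 / (exon_length_mean - 2.0)  # length = 2 + Geometric(p), mean as stated

    blocks = np.array_split(np.arange(table.n_sites), n_genes)
    meta = table.meta.copy()
    genes: list[GeneModel] = []
    for g, idx in enumerate(blocks):
        gene_id = f"g{g:05d}"
        k = len(idx)
        exon_lengths = 2 + rng.geometric(p, size=k + 1)
        gene = GeneModel(
            gene_id=gene_id,
            site_ids=[str(meta.at[i, "site_id"]) for i in idx],
            exon_lengths=exon_lengths,
        )
        genes.append(gene)
        offsets = gene.offsets
        for rank, i in enumerate(idx):
            meta.at[i, "gene_id"] = gene_id
            meta.at[i, "ordinal"] = rank + 1
            meta.at[i, "cds_offset"] = int(offsets[rank])
    return genes, IntronSiteTable(table.species, table.states, meta)


def extant_structure(
    gene: GeneModel,
    table: IntronSiteTable,
    species: str,
    labels: dict[str, str] | None = None,
) -> GeneStructure:
    """Extant gene structure of one gene in one species.

    Ambiguous states count as absent for structure purposes.  ``labels``
    optionally maps site_id to a history label (gain/loss/presence/
    uncalled).
    """
    col = table.species.index(species)
    row_of = {str(sid): i for i, sid in enumerate(table.meta["site_id"])}
    offsets = np.asarray(gene.offsets)
    sites = []
    for rank, sid in enumerate(gene.site_ids):
        i = row_of[sid]
        sites.append(
            IntronSiteInfo(
                site_id=sid,
                ordinal=rank + 1,
                offset=int(offsets[rank]),
                present=bool(table.states[i, col] == 1),
                label=(labels or {}).get(sid, "uncalled"),
            )
        )
    return GeneStructure(
        gene_id=gene.gene_id, species=species,
        cds_length=gene.cds_length, sites=sites,
    )


def true_lineage_labels(
    tree: PhyloTree, history: TrueHistory, table: IntronSiteTable, species: str
) -> dict[str, str]:
    """Ground-truth history label per site on the path to one species.

    Mirrors the posterior-based labelling: the most recent true event on
    the root-to-leaf path wins; otherwise "presence" for extant-present
    sites and "uncalled" for the rest.
    """
    leaf = tree.index_of(species)
    col = tree.leaf_names.index(species)
    path = tree.path_to_root(leaf)  # leaf first
    labels: dict[str, str] = {}
    for s in range(len(history.events)):
        on_path = {v: kind for v, kind in history.events[s] if v in path}
        label = None
        for v in path:
            if v in on_path:
                label = on_path[v]
                break
        if label is None:
            label = "presence" if table.states[s, col] == 1 else "uncalled"
        labels[str(table.meta.at[s, "site_id"])] = label
    return labels


@dataclass
class ExpressionParams:
    """Negative-binomial expression model with an intron TE effect.

    ``dispersion`` is the NB size parameter (variance mu + mu^2/size);
    ``tau`` multiplies the footprint mean of intron-containing genes, and
    ``translation_multiplier`` that of genes in the "translation" GO
    class, so tau > 1 yields higher translation efficiency for
    intron-containing genes at equal mRNA levels.
    """

    baseline_mean: float = 200.0
    dispersion: float = 5.0
    tau: float = 2.0
    translation_multiplier: float = 3.0
    p_translation: float = 0.2


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float):
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_expression(
    genes: pd.DataFrame, params: ExpressionParams, seed: int
) -> pd.DataFrame:
    """Simulate RNA and ribosome-footprint counts per gene.

    ``genes`` needs columns gene_id, length, has_intron.  Returns a table
    with go_class and nonnegative integer rna_count / fp_count columns.
    """
    if params.tau <= 0:
        raise ValueError("tau must be > 0")
    if params.baseline_mean <= 0 or params.dispersion <= 0:
        raise ValueError("baseline mean and dispersion must be > 0")
    rng = np.random.default_rng(_require_seed(seed))
    n = len(genes)
    go_class = np.where(
        rng.random(n) < params.p_translation, "translation", "other"
    )
    has_intron = genes["has_intron"].to_numpy(dtype=bool)
    rna_mean = np.full(n, params.baseline_mean)
    fp_mean = (
        params.baseline_mean
        * np.where(has_intron, params.tau, 1.0)
        * np.where(go_class == "translation", params.translation_multiplier, 1.0)
    )
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "length": genes["length"].to_numpy(),
            "has_intron": has_intron,
            "go_class": go_class,
            "rna_count": _nb_draw(rng, rna_mean, params.dispersion),
            "fp_count": _nb_draw(rng, fp_mean, params.dispersion),
        }
    )


@dataclass
class SyntheticBundle:
    """Complete ground-truth-labelled input set for the pipeline."""

    tree: PhyloTree
    model: GainLossModel
    table: IntronSiteTable
    history: TrueHistory
    genes: list[GeneModel]
    expression: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def simulate_bundle(
    seed: int,
    n_leaves: int = 16,
    n_sites: int = 2000,
    n_genes: int = 300,
    gain: float = 0.1,
    loss: float = 0.3,
    pi_root: float = 0.6,
    alpha: float = 1.0,
    K: int = 2,
    mask_prob: float = 0.05,
    exon_length_mean: float = 150.0,
    expression_params: ExpressionParams | None = None,
    reference_species: str | None = None,
) -> SyntheticBundle:
    """Simulate a full bundle: tree, sites, gene structures, expression."""
    seed = _require_seed(seed)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(5)]
    tree = random_bifurcating_tree(n_leaves, seeds[0])
    if K > 1:
        model = GainLossModel.rate_variation(tree, gain, loss, pi_root, alpha, K)
    else:
        model = GainLossModel.constant(tree, gain, loss, pi_root)
    table, history = simulate_sites(tree, model, n_sites, seeds[1])
    masked = mask_ambiguity(table, mask_prob, seeds[2])
    history = history.subset(masked.kept_indices)
    genes, table2 = simulate_gene_structures(
        masked.table, min(n_genes, masked.table.n_sites), exon_length_mean, seeds[3]
    )
    ref = reference_species or tree.leaf_names[0]
    ref_col = table2.species.index(ref)
    gene_rows = []
    site_rows = {str(s): i for i, s in enumerate(table2.meta["site_id"])}
    for g in genes:
        rows = [site_rows[s] for s in g.site_ids]
        gene_rows.append(
            {
                "gene_id": g.gene_id,
                "length": g.cds_length,
                "has_intron": bool(np.any(table2.states[rows, ref_col] == 1)),
            }
        )
    params = expression_params or ExpressionParams()
    expression = simulate_expression(pd.DataFrame(gene_rows), params, seeds[4])
    manifest = {
        "seed": seed,
        "n_leaves": n_leaves,
        "n_sites": n_sites,
        "n_genes": len(genes),
        "gain": gain,
        "loss": loss,
        "pi_root": pi_root,
        "alpha": alpha,
        "K": K,
        "mask_prob": mask_prob,
        "exon_length_mean": exon_length_mean,
        "expression": asdict(params),
        "reference_species": ref,
        "n_rejected_draws": history.n_rejected,
        "n_sites_dropped_by_masking": masked.n_dropped,
    }
    return SyntheticBundle(tree, model, table2, history, genes, expression, manifest)


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write a bundle to a directory in the formats the readers accept."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(bundle.tree.to_newick() + "\n")
    bundle.table.write_tsv(out / "sites.tsv")
    bundle.model.write_json(out / "model.json", bundle.tree)
    genes = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "cds_length": g.cds_length,
                "site_ids": ";".join(g.site_ids),
                "exon_lengths": ";".join(str(int(x)) for x in g.exon_lengths),
            }
            for g in bundle.genes
        ]
    )
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    bundle.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    truth = pd.DataFrame(bundle.history.node_states, columns=bundle.tree.names)
    truth.insert(0, "site_id", bundle.table.meta["site_id"].to_numpy())
    truth.insert(1, "category", bundle.history.categories)
    truth.to_csv(out / "true_states.tsv", sep="\t", index=False)
    events = pd.DataFrame(
        [
            {
                "site_id": bundle.table.meta.at[s, "site_id"],
                "branch": bundle.tree.names[v],
                "event": kind,
            }
            for s, evs in enumerate(bundle.history.events)
            for v, kind in evs
        ],
        columns=["site_id", "branch", "event"],
    )
    events.to_csv(out / "true_events.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)
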