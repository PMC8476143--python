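import numpy as np
import pandas as pd
import pytest
from scipy import stats

import intronevo as ie
from intronevo.model import branch_transition
from intronevo.simulate import (
    extant_structure,
    mask_ambiguity,
    simulate_gene_structures,
    true_lineage_labels,
)


def test_seed_is_mandatory():
    tree = ie.random_bifurcating_tree(4, seed=1)
    model = ie.GainLossModel.constant(tree, 0.1, 0.3, 0.5)
    with pytest.raises(ValueError, match="seed"):
        ie.simulate_sites(tree, model, 10, seed=None)


def test_simulation_deterministic_under_seed():
    tree = ie.random_bifurcating_tree(6, seed=2)
    model = ie.GainLossModel.rate_variation(tree, 0.2, 0.5, 0.5, 1.0)
    t1, h1 = ie.simulate_sites(tree, model, 100, seed=3)
    t2, h2 = ie.simulate_sites(tree, model, 100, seed=3)
    assert np.array_equal(t1.states, t2.states)
    assert np.array_equal(h1.node_states, h2.node_states)
    assert h1.events == h2.events


def test_loss_free_root_present_limit():
    tree = ie.random_bifurcating_tree(6, seed=4)
    model = ie.GainLossModel.constant(tree, gain=0.2, loss=0.0, pi_root=1.0)
    table, hist = ie.simulate_sites(tree, model, 100, seed=5)
    assert np.all(table.states == 1)
    assert all(kind != "loss" for evs in hist.events for _, kind in evs)


def test_gain_free_presence_is_single_connected_clade():
    tree = ie.random_bifurcating_tree(8, seed=6)
    model = ie.GainLossModel.constant(tree, gain=0.0, loss=0.5, pi_root=1.0)
    table, hist = ie.simulate_sites(tree, model, 200, seed=7)
    for s in range(200):
        present = set(np.nonzero(hist.node_states[s])[0])
        assert tree.root in present  # single origination at the root
        for v in present:
            assert v == tree.root or tree.parent[v] in present


def test_event_replay_reproduces_node_states():
    tree = ie.random_bifurcating_tree(7, seed=8)
    model = ie.GainLossModel.rate_variation(tree, 0.3, 0.6, 0.5, 0.8)
    _, hist = ie.simulate_sites(tree, model, 150, seed=9)
    for s in range(150):
        events = dict(hist.events[s])
        state = np.zeros(tree.n_nodes, dtype=np.int8)
        state[tree.root] = hist.node_states[s, tree.root]
        for v in tree.preorder():
            if v == tree.root:
                continue
            state[v] = state[tree.parent[v]]
            if v in events:
                state[v] = 1 if events[v] == "gain" else 0
        assert np.array_equal(state, hist.node_states[s])


def test_two_leaf_pattern_frequencies_match_analytic():
    tree = ie.read_newick("(A,B);")
    G, M, pi = 0.4, 0.6, 0.5
    model = ie.GainLossModel.constant(tree, G, M, pi)
    n = 50000
    table, _ = ie.simulate_sites(tree, model, n, seed=10)
    iA, iB = tree.index_of("A"), tree.index_of("B")
    PA = branch_transition(model.gain[iA], model.loss[iA])
    PB = branch_transition(model.gain[iB], model.loss[iB])
    prior = np.array([1 - pi, pi])
    joint = {
        (a, b): sum(prior[r] * PA[r, a] * PB[r, b] for r in (0, 1))
        for a in (0, 1) for b in (0, 1)
    }
    z = 1 - joint[(0, 0)]
    for (a, b), p in joint.items():
        if (a, b) == (0, 0):
            continue
        p_cond = p / z
        freq = np.mean((table.states[:, 0] == a) & (table.states[:, 1] == b))
        se = np.sqrt(p_cond * (1 - p_cond) / n)
        assert abs(freq - p_cond) < 3 * se + 1e-12


def test_degenerate_two_category_model_indistinguishable_from_constant():
    tree = ie.random_bifurcating_tree(5, seed=11)
    const = ie.GainLossModel.constant(tree, 0.2, 0.5, 0.5)
    degen = ie.GainLossModel.rate_variation(tree, 0.2, 0.5, 0.5, 1e10, K=2)
    for seed in (12, 13, 14):
        t1, _ = ie.simulate_sites(tree, const, 1500, seed=seed)
        t2, _ = ie.simulate_sites(tree, degen, 1500, seed=seed + 100)
        pats = np.vstack([t1.states, t2.states])
        uniq, inv = np.unique(pats, axis=0, return_inverse=True)
        c1 = np.bincount(inv[:1500], minlength=len(uniq))
        c2 = np.bincount(inv[1500:], minlength=len(uniq))
        keep = (c1 + c2) >= 5  # chi-square validity
        obs = np.vstack(
            [np.append(c1[keep], c1[~keep].sum()),
             np.append(c2[keep], c2[~keep].sum())]
        )
        obs = obs[:, obs.sum(axis=0) > 0]
        _, p, _, _ = stats.chi2_contingency(obs)
        assert p > 0.01


class TestMasking:
    def test_zero_probability_is_identity(self, small_bundle):
        table = small_bundle.table
        res = mask_ambiguity(table, 0.0, seed=1)
        assert np.array_equal(res.table.states, table.states)
        assert res.n_dropped == 0

    def test_heavy_masking_keeps_observable_sites_only(self):
        tree = ie.random_bifurcating_tree(5, seed=20)
        model = ie.GainLossModel.constant(tree, 0.2, 0.4, 0.5)
        table, _ = ie.simulate_sites(tree, model, 200, seed=21)
        res = mask_ambiguity(table, 0.9, seed=22)
        assert res.n_dropped > 0
        assert np.all((res.table.states == 1).any(axis=1))

    def test_masking_deterministic(self):
        tree = ie.random_bifurcating_tree(5, seed=23)
        model = ie.GainLossModel.constant(tree, 0.2, 0.4, 0.5)
        table, _ = ie.simulate_sites(tree, model, 100, seed=24)
        r1 = mask_ambiguity(table, 0.3, seed=25)
        r2 = mask_ambiguity(table, 0.3, seed=25)
        assert np.array_equal(r1.table.states, r2.table.states)
        assert np.array_equal(r1.kept_indices, r2.kept_indices)


class TestGeneStructures:
    def test_partition_identity(self, small_bundle):
        # extant exon lengths of any species always sum to the CDS length
        table = small_bundle.table
        for gene in small_bundle.genes[:20]:
            for sp in table.species[:3]:
                gs = extant_structure(gene, table, sp)
                exons = ie.extant_exons(gs)
                assert sum(e.length for e in exons) == gs.cds_length
                assert len(exons) == len(gs.present_sites) + 1

    def test_intronless_gene_is_single_exon(self):
        gene = ie.GeneModel("g", [], np.array([300]))
        table = ie.IntronSiteTable(
            ["A"], np.zeros((0, 1), dtype=np.int8),
            pd.DataFrame(columns=["site_id", "gene_id", "ordinal", "cds_offset"]),
        )
        gs = extant_structure(gene, table, "A")
        exons = ie.extant_exons(gs)
        assert len(exons) == 1 and exons[0].length == 300

    def test_mean_extant_exon_length(self):
        tree = ie.read_newick("(A,B);")
        model = ie.GainLossModel.constant(tree, 0.2, 0.0, 1.0)  # all present
        table, _ = ie.simulate_sites(tree, model, 3000, seed=30)
        genes, table2 = simulate_gene_structures(
            table, n_genes=1000, exon_length_mean=150.0, seed=31
        )
        lengths = []
        for g in genes:
            gs = extant_structure(g, table2, "A")
            lengths.extend(e.length for e in ie.extant_exons(gs))
        assert np.mean(lengths) == pytest.approx(150.0, rel=0.05)

    def test_fewer_sites_than_genes_rejected(self):
        tree = ie.read_newick("(A,B);")
        model = ie.GainLossModel.constant(tree, 0.2, 0.1, 0.9)
        table, _ = ie.simulate_sites(tree, model, 5, seed=32)
        with pytest.raises(ValueError):
            simulate_gene_structures(table, n_genes=10, seed=33)

    def test_true_labels_consistent_with_leaf_states(self, small_bundle):
        b = small_bundle
        sp = b.table.species[0]
        labels = true_lineage_labels(b.tree, b.history, b.table, sp)
        col = b.table.species.index(sp)
        for i in range(b.table.n_sites):
            lab = labels[str(b.table.meta.at[i, "site_id"])]
            state = b.table.states[i, col]
            if lab == "presence":
                assert state == 1
            if lab == "uncalled":
                assert state != 1


class TestExpression:
    def _genes(self, n, rng):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "length": rng.integers(300, 3000, n),
                "has_intron": rng.random(n) < 0.5,
            }
        )

    def test_counts_are_nonnegative_integers(self):
        rng = np.random.default_rng(40)
        params = ie.ExpressionParams()
        df = ie.simulate_expression(self._genes(500, rng), params, seed=41)
        for col in ("rna_count", "fp_count"):
            assert (df[col] >= 0).all()
            assert np.issubdtype(df[col].dtype, np.integer)

    def test_null_case_shows_no_te_effect(self):
        rng = np.random.default_rng(42)
        params = ie.ExpressionParams(tau=1.0, translation_multiplier=1.0)
        df = ie.simulate_expression(self._genes(2000, rng), params, seed=43)
        res = ie.expression_compare(df)
        te_tests = res["tests"].query("metric == 'te' and not skipped")
        assert (te_tests["p"] > 1e-3).all()

    def test_tau_two_detected_by_welch_test(self):
        rng = np.random.default_rng(44)
        params = ie.ExpressionParams(tau=2.0)
        df = ie.simulate_expression(self._genes(2000, rng), params, seed=45)
        res = ie.expression_compare(df)
        te_tests = res["tests"].query("metric == 'te' and not skipped")
        assert (te_tests["p"] < 0.01).all()
        assert (te_tests["t"] > 0).all()  # intron-containing genes higher

    def test_invalid_parameters_rejected(self):
        rng = np.random.default_rng(46)
        with pytest.raises(ValueError):
            ie.simulate_expression(
                self._genes(10, rng), ie.ExpressionParams(tau=0.0), seed=47
            )


def test_bundle_site_to_gene_mapping(small_bundle):
    b = small_bundle
    by_gene = b.table.meta.groupby("gene_id")
    assert set(g.gene_id for g in b.genes) == set(by_gene.groups)
    for g in b.genes:
        rows = b.table.meta[b.table.meta["gene_id"] == g.gene_id]
        assert list(rows["ordinal"]) == list(range(1, len(rows) + 1))
        assert list(rows["site_id"]) == g.site_ids
        assert (rows["cds_offset"] < g.cds_length).all()
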