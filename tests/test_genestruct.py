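import numpy as np
import pandas as pd
import pytest
from scipy import stats

import intronevo as ie
from intronevo.genestruct import (
    GeneStructure,
    IntronSiteInfo,
    classify_reshaped,
    distance_to_start_test,
    extant_exons,
    interval_overlap_bootstrap,
    length_comparison,
    positional_heterogeneity_test,
    positional_profile,
)


def gene(cds, sites):
    """GeneStructure from (offset, present, label) triples."""
    return GeneStructure(
        gene_id="g",
        species="sp",
        cds_length=cds,
        sites=[
            IntronSiteInfo(f"s{i}", i + 1, off, pres, lab)
            for i, (off, pres, lab) in enumerate(sites)
        ],
    )


class TestExonTiling:
    def test_no_present_sites_single_exon(self):
        exons = extant_exons(gene(500, [(100, False, "loss")]))
        assert [(e.start, e.end) for e in exons] == [(0, 500)]

    def test_two_present_sites_three_exons(self):
        exons = extant_exons(gene(300, [(100, True, "presence"),
                                        (220, True, "presence")]))
        assert [(e.start, e.end) for e in exons] == [(0, 100), (100, 220), (220, 300)]
        assert sum(e.length for e in exons) == 300

    @pytest.mark.parametrize("seed", range(20))
    def test_tiling_identity_randomized(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            n = int(rng.integers(0, 8))
            offsets = np.sort(rng.choice(np.arange(1, 999), size=n, replace=False))
            g = gene(1000, [(int(o), bool(rng.random() < 0.6), "uncalled")
                            for o in offsets])
            exons = extant_exons(g)
            assert sum(e.length for e in exons) == 1000
            assert all(e.length > 0 for e in exons)
            assert exons[0].start == 0 and exons[-1].end == 1000


class TestReshapingClasses:
    def test_two_internal_losses_fuse_three_exons(self):
        # ancestral exons 100+120+80 fused into one 300 nt extant exon
        g = gene(300, [(100, False, "loss"), (220, False, "loss")])
        exons = classify_reshaped(g)
        assert len(exons) == 1
        assert exons[0].cls == "3-into-1"
        assert exons[0].length == 300

    def test_single_gain_splits_one_exon_in_two(self):
        g = gene(300, [(120, True, "gain")])
        exons = classify_reshaped(g)
        assert [e.cls for e in exons] == ["1-into-2", "1-into-2"]

    def test_two_consecutive_gains_yield_one_into_three(self):
        g = gene(300, [(100, True, "gain"), (200, True, "gain")])
        assert [e.cls for e in classify_reshaped(g)] == ["1-into-3"] * 3

    def test_three_consecutive_gains_excluded(self):
        g = gene(400, [(100, True, "gain"), (200, True, "gain"),
                       (300, True, "gain")])
        assert [e.cls for e in classify_reshaped(g)] == ["excluded"] * 4

    def test_mixed_gain_and_loss_excluded(self):
        g = gene(300, [(100, True, "gain"), (200, False, "loss")])
        exons = classify_reshaped(g)
        assert exons[1].cls == "excluded"

    def test_untouched_exons_are_controls(self):
        g = gene(300, [(150, True, "presence")])
        assert [e.cls for e in classify_reshaped(g)] == ["control", "control"]

    def test_loss_only_labels_never_produce_split_classes(self, small_bundle):
        # ground-truth labels from a simulation; sanity: a species' split
        # classes can only come from gain labels
        from intronevo.simulate import extant_structure, true_lineage_labels

        b = small_bundle
        for sp in b.table.species[:4]:
            labels = true_lineage_labels(b.tree, b.history, b.table, sp)
            loss_only = {k: ("uncalled" if v == "gain" else v)
                         for k, v in labels.items()}
            for g in b.genes:
                gs = extant_structure(g, b.table, sp, labels=loss_only)
                for e in classify_reshaped(gs):
                    assert not e.cls.startswith("1-into")

    def test_ground_truth_classes_recovered(self, small_bundle):
        # with perfect (true) labels, a gene whose absent sites are all
        # called losses and k<=2 must class as (k+1)-into-1
        from intronevo.simulate import extant_structure, true_lineage_labels

        b = small_bundle
        sp = b.table.species[0]
        labels = true_lineage_labels(b.tree, b.history, b.table, sp)
        seen = 0
        for g in b.genes:
            gs = extant_structure(g, b.table, sp, labels=labels)
            exons = classify_reshaped(gs)
            for j, e in enumerate(exons):
                if e.cls in ("2-into-1", "3-into-1"):
                    seen += 1
                    k = int(e.cls[0]) - 1
                    interior = [s for s in gs.sites
                                if not s.present and e.start < s.offset < e.end]
                    assert sum(s.label == "loss" for s in interior) == k
        assert seen > 0


class TestLengthComparison:
    def test_identical_groups_give_null_test(self):
        exons = [ie.ExonRecord("g", "s", 0, 100, "2-into-1") for _ in range(5)]
        exons += [ie.ExonRecord("g", "s", 0, 100, "control") for _ in range(5)]
        stats_df, tests_df = length_comparison(exons)
        assert tests_df.loc[0, "t"] == 0.0 and tests_df.loc[0, "p"] == 1.0

    def test_welch_matches_independent_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.normal(120, 30, 10)
        b = rng.normal(90, 10, 10)
        exons = [ie.ExonRecord("g", "s", 0, int(x), "3-into-1") for x in a]
        exons += [ie.ExonRecord("g", "s", 0, int(x), "control") for x in b]
        _, tests_df = length_comparison(exons)
        import statsmodels.stats.weightstats as ws

        la = np.array([int(x) for x in a], dtype=float)
        lb = np.array([int(x) for x in b], dtype=float)
        t_ref, p_ref, _ = ws.ttest_ind(la, lb, usevar="unequal")
        assert tests_df.loc[0, "t"] == pytest.approx(t_ref, abs=1e-9)
        assert tests_df.loc[0, "p"] == pytest.approx(p_ref, abs=1e-9)

    def test_fused_exons_stochastically_larger(self):
        # sums of 3 vs 2 vs 1 iid ancestral segments
        rng = np.random.default_rng(2)
        wins = 0
        for _ in range(100):
            seg = lambda k, n: rng.exponential(150, (n, k)).sum(axis=1) + 3 * k
            m3 = np.median(seg(3, 60))
            m2 = np.median(seg(2, 60))
            m1 = np.median(seg(1, 60))
            if m3 > m2 > m1:
                wins += 1
        assert wins >= 95


class TestPositional:
    def test_normalized_position(self):
        g = gene(200, [(100, True, "presence")])
        prof = positional_profile([g])
        assert prof["normalized"]["presence"][0] == pytest.approx(0.5)

    def test_single_intron_is_first_from_both_ends(self):
        g = gene(200, [(50, True, "gain")])
        prof = positional_profile([g])
        assert prof["ordinal_5p"].loc["gain", 1] == 1
        assert prof["ordinal_3p"].loc["gain", 1] == 1

    def test_uniform_positions_average_half(self):
        rng = np.random.default_rng(3)
        genes = []
        for i in range(400):
            off = int(rng.integers(1, 1000))
            genes.append(gene(1000, [(off, True, "presence")]))
        prof = positional_profile(genes)
        vals = prof["normalized"]["presence"]
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.5) < 3 * se

    def test_proportional_rows_no_heterogeneity(self):
        counts = pd.DataFrame([[10, 20, 30], [20, 40, 60], [1, 2, 3]],
                              index=["gain", "loss", "presence"],
                              columns=[1, 2, 3])
        res = positional_heterogeneity_test(counts)
        assert np.allclose(res["chi2"], 0.0, atol=1e-12)
        assert np.allclose(res["p"], 1.0)

    def test_chi2_matches_hand_calculation(self):
        # rows [10,20,30] vs [30,20,10]: expected [20,20,20] each,
        # chi2 = 2 * ((100+0+100)/20) = 20
        counts = pd.DataFrame([[10, 20, 30], [30, 20, 10]],
                              index=["gain", "loss"], columns=[1, 2, 3])
        res = positional_heterogeneity_test(counts)
        assert res.loc[0, "chi2"] == pytest.approx(20.0, abs=1e-9)
        assert res.loc[0, "p"] == pytest.approx(stats.chi2.sf(20.0, 2), abs=1e-12)

    def test_zero_total_label_excluded(self):
        counts = pd.DataFrame([[5, 5, 5], [0, 0, 0]],
                              index=["gain", "loss"], columns=[1, 2, 3])
        res = positional_heterogeneity_test(counts)
        assert bool(res.loc[0, "excluded"])


class TestDistanceToStart:
    def test_extreme_shift_detected(self):
        genes = [gene(1000, [(1, True, "presence")]) for _ in range(1000)]
        res = distance_to_start_test(genes, n_null=5, seed=1)
        assert res["p"] < 1e-6
        assert 0 <= res["statistic"] <= 1

    def test_uniform_placement_not_rejected(self):
        rng = np.random.default_rng(2)
        fails = 0
        for rep in range(40):
            genes = [
                gene(1000, [(int(rng.integers(1, 1000)), True, "presence")])
                for _ in range(150)
            ]
            if distance_to_start_test(genes, n_null=10, seed=rep)["p"] <= 0.01:
                fails += 1
        assert fails <= 3


class TestIntervalOverlap:
    def test_full_and_zero_coverage(self):
        feats = pd.DataFrame({"chrom": ["c1"], "start": [100], "end": [200]})
        lengths = {"c1": 10000}
        full = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [10000]})
        none = pd.DataFrame({"chrom": ["c1"], "start": [5000], "end": [6000]})
        assert interval_overlap_bootstrap(feats, full, lengths, B=10,
                                          seed=1)["percent"] == 100.0
        assert interval_overlap_bootstrap(feats, none, lengths, B=10,
                                          seed=1)["percent"] == 0.0

    def test_half_covered_bootstrap_median(self):
        # mask covers exactly half of the sequence in alternating blocks,
        # so random length-matched placement is ~50% covered
        blocks = [(i * 200, i * 200 + 100) for i in range(50)]
        mask = pd.DataFrame(
            {"chrom": "c1", "start": [b[0] for b in blocks],
             "end": [b[1] for b in blocks]}
        )
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 9900, 200)
        feats = pd.DataFrame({"chrom": "c1", "start": starts, "end": starts + 10})
        res = interval_overlap_bootstrap(feats, mask, {"c1": 10000}, B=200, seed=4)
        assert res["bootstrap_median"] == pytest.approx(50.0, abs=5.0)

    def test_malformed_interval_rejected(self):
        feats = pd.DataFrame({"chrom": ["c1"], "start": [100], "end": [100]})
        mask = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [10]})
        with pytest.raises(ValueError, match="malformed"):
            interval_overlap_bootstrap(feats, mask, {"c1": 1000}, B=2, seed=1)
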