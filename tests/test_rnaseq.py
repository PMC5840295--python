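"""RPKM, NB differential test, BH, filter cascade, endogenous estimator,
concordance."""

import numpy as np
import pandas as pd
import pytest

import baitcall as bc


def _gene_table(counts: dict, lengths: dict, conditions: dict,
                library_sizes: dict | None = None) -> bc.GeneCountTable:
    return bc.GeneCountTable(
        counts=pd.DataFrame(counts),
        gene_lengths=pd.Series(lengths, dtype=float),
        conditions=pd.Series(conditions),
        library_sizes=None if library_sizes is None
        else pd.Series(library_sizes, dtype=float),
    )


class TestRpkm:
    def test_unit_definition(self):
        t = _gene_table({"s1": [1000, 0]}, {0: 1000, 1: 500}, {"s1": "a"},
                        {"s1": 1_000_000})
        r = bc.rpkm(t)
        assert r.loc[0, "s1"] == 1000.0
        assert r.loc[1, "s1"] == 0.0

    def test_doubling_library_halves_rpkm(self):
        t1 = _gene_table({"s1": [100]}, {0: 2000}, {"s1": "a"}, {"s1": 1e6})
        t2 = _gene_table({"s1": [100]}, {0: 2000}, {"s1": "a"}, {"s1": 2e6})
        assert bc.rpkm(t1).loc[0, "s1"] == 2 * bc.rpkm(t2).loc[0, "s1"]

    def test_zero_library_rejected(self):
        t = _gene_table({"s1": [1]}, {0: 100}, {"s1": "a"}, {"s1": 0.0})
        with pytest.raises(ValueError, match="library"):
            bc.rpkm(t)


class TestNbDeTest:
    def test_duplicated_columns_give_zero_log2fc(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=40)
        counts = {f"a{i}": base for i in range(2)} | {
            f"b{i}": base for i in range(2)
        }
        t = _gene_table(counts, {i: 1000 for i in range(40)},
                        {"a0": "A", "a1": "A", "b0": "B", "b1": "B"})
        de = bc.nb_de_test(t, "A", "B")
        assert np.allclose(de["log2FC"], 0.0)

    def test_planted_effect_recovered(self, rnaseq_sim):
        _, gene_table, _, truth_table = rnaseq_sim
        de = bc.nb_de_test(gene_table, "WT", "YFP")
        planted = truth_table[truth_table["label"] == "bait_specific"]
        err = (de.loc[planted.index, "log2FC"] - planted["bait_log2fc"]).abs()
        assert err.max() < 0.2

    def test_null_type_one_error_controlled(self):
        truth = bc.default_rnaseq_truth(n_tag_genes=0, n_bait_genes=0, seed=11)
        truth.tag_effects.clear()
        truth.bait_effects.clear()
        truth.transgene = None
        gt, _, _ = bc.simulate_rnaseq(truth, bc.default_groups())
        de = bc.nb_de_test(gt, "WT", "YFP")
        assert (de["adj_p"] <= 0.05).mean() <= 0.05

    def test_too_few_replicates_rejected(self):
        t = _gene_table({"a0": [1], "b0": [2], "b1": [3]}, {0: 100},
                        {"a0": "A", "b0": "B", "b1": "B"})
        with pytest.raises(ValueError, match="replicates"):
            bc.nb_de_test(t, "A", "B")


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bc.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_unchanged(self):
        assert np.allclose(bc.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_step_up_hand_example(self):
        # hand evaluation of the step-up rule on (.01,.02,.03,.04):
        # min over j>=i of p_(j)*n/j = 0.04 for every rank
        assert np.allclose(bc.bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        adj = bc.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p).all() and (adj <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bc.bh_adjust([0.5, 1.5])


class TestSpecificFilter:
    def _de(self, rows):
        return pd.DataFrame(rows).set_index("gene_id")

    def _toy(self):
        # one bait-specific responder, one tag artifact, one low-expression
        # responder, two nulls
        de_bait = self._de([
            {"gene_id": "G1", "log2FC": np.log2(1.8), "adj_p": 0.01},
            {"gene_id": "G2", "log2FC": 1.5, "adj_p": 0.001},
            {"gene_id": "G3", "log2FC": -1.0, "adj_p": 0.02},
            {"gene_id": "G4", "log2FC": 0.05, "adj_p": 0.9},
            {"gene_id": "G5", "log2FC": 0.1, "adj_p": 0.8},
        ])
        de_tag = self._de([
            {"gene_id": "G1", "log2FC": 0.0, "adj_p": 1.0},
            {"gene_id": "G2", "log2FC": 2.0, "adj_p": 0.001},
            {"gene_id": "G3", "log2FC": 0.1, "adj_p": 0.6},
            {"gene_id": "G4", "log2FC": 0.0, "adj_p": 1.0},
            {"gene_id": "G5", "log2FC": 0.0, "adj_p": 1.0},
        ])
        rpkm_means = pd.DataFrame(
            {"WT": [150, 300, 20, 500, 50], "YFP": [90, 80, 15, 480, 60]},
            index=de_bait.index,
        )
        return de_bait, de_tag, rpkm_means

    def test_cascade_keeps_only_the_specific_gene(self):
        de_bait, de_tag, rpkm_means = self._toy()
        got = bc.matr3_specific_filter(de_bait, de_tag, rpkm_means)
        assert list(got) == ["G1"]

    def test_tag_responsive_gene_excluded_even_if_bait_responsive(self):
        de_bait, de_tag, rpkm_means = self._toy()
        got = bc.matr3_specific_filter(de_bait, de_tag, rpkm_means)
        assert "G2" not in got  # significant in the tag-alone comparison

    def test_infinite_fold_threshold_empties_the_set(self):
        de_bait, de_tag, rpkm_means = self._toy()
        cfg = bc.FilterConfig(specific_fold=1e9)
        assert len(bc.matr3_specific_filter(de_bait, de_tag, rpkm_means, cfg)) == 0

    def test_universe_mismatch_rejected(self):
        de_bait, de_tag, rpkm_means = self._toy()
        with pytest.raises(ValueError, match="universe"):
            bc.matr3_specific_filter(de_bait.drop(index="G5"), de_tag,
                                     rpkm_means)

    def test_planted_genes_recovered_from_simulation(self, rnaseq_sim):
        _, gene_table, _, truth_table = rnaseq_sim
        de_bait = bc.nb_de_test(gene_table, "WT", "YFP")
        de_tag = bc.nb_de_test(gene_table, "YFP", "untransfected")
        got = set(
            bc.matr3_specific_filter(
                de_bait, de_tag, gene_table.condition_mean_rpkm()
            )
        )
        planted = set(truth_table.index[truth_table["label"] == "bait_specific"])
        assert planted <= got
        assert len(got - planted) <= 3


class TestEndogenousExpression:
    SHARED = ["G00000_E0", "G00000_E1", "G00000_E2"]

    def test_transgene_free_exons_recover_planted_level(self, rnaseq_sim):
        truth, gene_table, exon_table, _ = rnaseq_sim
        est = bc.endogenous_expression(exon_table, "G00000", self.SHARED)
        bait_samples = (gene_table.samples_for("WT")
                        + gene_table.samples_for("F115C"))
        planted = 800.0 * 2 ** truth.tag_effects[0]
        got = est[bait_samples].mean()
        assert abs(got - planted) / planted < 0.10
        naive = bc.rpkm(gene_table).loc["G00000", bait_samples].mean()
        assert naive / planted > 10

    def test_suppression_ratio_recovered(self, rnaseq_sim):
        # planted 1.4-fold endogenous suppression upon transfection
        _, gene_table, exon_table, _ = rnaseq_sim
        est = bc.endogenous_expression(exon_table, "G00000", self.SHARED)
        ratio = (est[gene_table.samples_for("untransfected")].mean()
                 / est[gene_table.samples_for("YFP")].mean())
        assert ratio == pytest.approx(1.4, abs=0.1)

    def test_without_transgene_matches_whole_gene_rpkm(self, rnaseq_sim):
        _, gene_table, exon_table, _ = rnaseq_sim
        # a background gene has no transgene reads: restricting to a subset
        # of exons estimates the same RPKM up to counting noise
        gid = "G01500"
        exons = list(exon_table.exons_of(gid))
        est = bc.endogenous_expression(exon_table, gid, exons[:1])
        whole = bc.rpkm(gene_table).loc[gid]
        assert np.allclose(est, whole, rtol=0.35)

    def test_all_exons_shared_rejected(self, rnaseq_sim):
        _, _, exon_table, _ = rnaseq_sim
        all_exons = list(exon_table.exons_of("G00000"))
        with pytest.raises(ValueError, match="shared"):
            bc.endogenous_expression(exon_table, "G00000", all_exons)


class TestFoldReduction:
    @pytest.mark.parametrize("a,b,expected",
                             [(817, 568, 1.4), (5, 5, 1.0), (480, 568, 0.8)])
    def test_rounded_ratios(self, a, b, expected):
        assert bc.fold_reduction(a, b) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            bc.fold_reduction(1.0, 0.0)


class TestPairwisePearson:
    def test_duplicated_sample_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=50)
        df = pd.DataFrame({"s1": x, "s2": x, "s3": rng.lognormal(size=50)})
        corr, order, _ = bc.pairwise_pearson(df)
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_replicates_cluster_adjacently(self):
        # untransfected and tag-only triplicates each form contiguous leaf
        # blocks; the two bait conditions are transcriptionally near-identical
        # and must form one contiguous block of six
        hits = 0
        for seed in range(1, 11):
            truth = bc.default_rnaseq_truth(n_genes=500, seed=seed)
            gt, _, _ = bc.simulate_rnaseq(truth, bc.default_groups())
            _, order, _ = bc.pairwise_pearson(bc.rpkm(gt))
            cond = [gt.conditions[s] for s in order]
            merged = ["bait" if c in ("WT", "F115C") else c for c in cond]
            blocks = [
                len([1 for a, b in zip(merged, merged[1:]) if a != b])
            ]
            hits += blocks[0] == 2  # exactly three contiguous blocks
        assert hits >= 9

    def test_zero_variance_sample_rejected(self):
        df = pd.DataFrame({"s1": [1.0, 1.0, 1.0], "s2": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            bc.pairwise_pearson(df)
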