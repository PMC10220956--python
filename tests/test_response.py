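"""Response analytics: direction tests, partitions, strata, maintenance,
ortholog compensation, overlap, correlation, clustering."""

import numpy as np
import pandas as pd
import pytest

from maalseq.quantify import compute_tpm
from maalseq.response import (
    add_chisq_q,
    assign_strata,
    classify_maintenance,
    cluster_samples,
    correlate_trans_gene_number,
    cross_classify_orthologs,
    direction_chisq,
    overlap_coregulated,
    partition_cis_trans,
    stratify_by_expression,
    summarize_comparison,
)
from maalseq.simulate import EffectConfig, build_genome_pair, simulate_experiment


def degs_frame(statuses, log2fc=None, index=None):
    idx = index or [f"g{i}" for i in range(len(statuses))]
    return pd.DataFrame({
        "status": statuses,
        "log2fc": log2fc or [0.0] * len(statuses),
    }, index=idx)


class TestSummarizeComparison:
    def test_direction_chisq_formula(self):
        stat, p = direction_chisq(861, 1213)
        assert stat == pytest.approx(59.74, abs=0.01)
        assert p < 0.01  # the published significance flag

    def test_balanced_counts_give_zero_statistic(self):
        stat, p = direction_chisq(50, 50)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_statistic_invariant_to_label_swap(self):
        assert direction_chisq(861, 1213)[0] == \
            pytest.approx(direction_chisq(1213, 861)[0])

    def test_ratios_recompute_from_counts(self):
        degs = degs_frame(["up"] * 861 + ["down"] * 1213)
        s = summarize_comparison(degs, universe_size=66516)
        assert s.n_total == 2074
        assert s.ratio_up == 41.51
        assert s.ratio_down == 58.49
        assert s.ratio_up + s.ratio_down == pytest.approx(100.0, abs=0.01)

    def test_empty_comparison_undefined_chisq(self):
        s = summarize_comparison(degs_frame(["unchanged"] * 5), 100)
        assert np.isnan(s.chisq_stat)

    def test_q_values_bh_across_run(self):
        degs_a = degs_frame(["up"] * 90 + ["down"] * 10)
        degs_b = degs_frame(["up"] * 51 + ["down"] * 49)
        out = add_chisq_q([summarize_comparison(degs_a, 1000),
                           summarize_comparison(degs_b, 1000)])
        ps = np.array([s.chisq_p for s in out])
        from maalseq.diffexpr import adjust_bh
        assert np.allclose([s.chisq_q for s in out], adjust_bh(ps))


class TestPartitionCisTrans:
    def test_partition_on_simulation(self, experiment):
        catalog, counts, truth, _ = experiment
        from maalseq.diffexpr import compare_groups, support_average_factors
        tpm = compute_tpm(counts, catalog, added_chrom="B1")
        recip = catalog.genes_of("recipient")
        degs_cc = compare_groups(counts, tpm, "CC", "MAAL", genes=recip)
        f = support_average_factors(counts, catalog, "B1")
        degs_bb = compare_groups(counts, tpm, "BB", "MAAL",
                                 genes=catalog.genes_on("B1"), factors=f)
        part = partition_cis_trans(degs_cc, degs_bb, catalog, "B1")
        assert set(part.cis.index).isdisjoint(part.trans.index)
        assert set(catalog.table.loc[part.trans.index, "subgenome"]) <= \
            {"recipient"}
        assert set(catalog.table.loc[part.cis.index, "chromosome"]) <= {"B1"}
        assert part.trans_per_chromosome["total"].sum() == len(part.trans)

    def test_trans_recall_precision_vs_truth(self, experiment):
        """Planted 5% trans at |log2fc| 2: recall >= 0.8, precision >= 0.9."""
        catalog, counts, truth, _ = experiment
        from maalseq.diffexpr import compare_groups
        tpm = compute_tpm(counts, catalog, added_chrom="B1")
        recip = catalog.genes_of("recipient")
        degs_cc = compare_groups(counts, tpm, "CC", "MAAL", genes=recip)
        called = set(degs_cc.index[degs_cc["status"].isin(["up", "down"])])
        planted = set(truth.index[truth["planted_trans_direction"] != "none"])
        assert len(called & planted) / len(planted) >= 0.8
        assert len(called & planted) / len(called) >= 0.9

    def test_missing_added_chromosome_rejected(self, experiment):
        catalog = experiment[0]
        empty = degs_frame([])
        with pytest.raises(ValueError):
            partition_cis_trans(empty, empty, catalog, "B99")


class TestStratification:
    @pytest.mark.parametrize("tpm,stratum", [
        (5.0, "low"), (50.0, "medium"), (500.0, "high"),
        (10.0, "medium"), (100.0, "high"), (1.0, "low"),
    ])
    def test_stratum_boundaries(self, tpm, stratum):
        out = assign_strata(pd.Series({"g": tpm}))
        assert out["g"] == stratum

    def test_below_one_unassigned(self):
        assert assign_strata(pd.Series({"g": 0.5})).isna().all()

    def test_every_expressed_gene_in_exactly_one_stratum(self, experiment):
        catalog, counts, _, _ = experiment
        tpm = compute_tpm(counts, catalog, added_chrom="B1")
        cc_mean = tpm.loc[:, counts.samples_of("CC")].mean(axis=1)
        strata = assign_strata(cc_mean)
        expressed = cc_mean[cc_mean >= 1.0]
        assert strata[expressed.index].notna().all()
        assert strata[cc_mean[cc_mean < 1.0].index].isna().all()

    def test_counts_and_shares_recompute(self):
        mean_tpm = pd.Series([5.0] * 6 + [50.0] * 3 + [500.0] * 1,
                             index=[f"g{i}" for i in range(10)])
        degs = degs_frame(["up", "down", "unchanged"] * 3 + ["down"],
                          index=[f"g{i}" for i in range(10)])
        table = stratify_by_expression(mean_tpm, degs)
        assert table.loc["low", "n_genes"] == 6
        assert table["n_genes"].sum() == 10
        assert table.loc["low", "total"] == \
            table.loc["low", "up"] + table.loc["low", "down"]
        assert table["share_of_expressed"].sum() == pytest.approx(100.0,
                                                                  abs=0.05)


class TestMaintenance:
    def test_same_direction_is_maintained(self):
        maal = degs_frame(["down"], index=["g"])
        non = degs_frame(["down"], index=["g"])
        out = classify_maintenance(maal, non)
        assert out.loc["down", "maintained"] == 1

    def test_opposite_direction_detected(self):
        maal = degs_frame(["down"], index=["g"])
        non = degs_frame(["up"], index=["g"])
        out = classify_maintenance(maal, non)
        assert out.loc["down", "opposite"] == 1

    def test_rows_sum_to_total_and_100_percent(self):
        maal = degs_frame(["down", "down", "down", "up", "up"])
        non = degs_frame(["down", "up", "unchanged", "up", "unexpressed"])
        out = classify_maintenance(maal, non)
        for d in ("up", "down"):
            row = out.loc[d]
            assert row["opposite"] + row["maintained"] + row["unchanged"] == \
                row["total"]
            assert row["pct_opposite"] + row["pct_maintained"] + \
                row["pct_unchanged"] == pytest.approx(100.0, abs=0.05)

    def test_maintenance_fraction_recovery(self):
        """Planted 50% maintenance is recovered within +-10 points.

        ~270 planted trans genes keep the binomial planting noise (sd ~3
        points) well inside the tolerance, so the check reflects recovery
        accuracy rather than planting variance.
        """
        cfg = EffectConfig(genes_per_chrom=300, trans_fraction=0.1,
                           maintenance_fraction=0.5, reversal_fraction=0.01,
                           seed=31)
        catalog = build_genome_pair(cfg)
        counts, truth, _ = simulate_experiment(catalog, cfg)
        from maalseq.diffexpr import compare_groups
        tpm = compute_tpm(counts, catalog, added_chrom="B1")
        recip = catalog.genes_of("recipient")
        maal = compare_groups(counts, tpm, "CC", "MAAL", genes=recip)
        non = compare_groups(counts, tpm, "CC", "nonMAAL", genes=recip)
        out = classify_maintenance(maal, non)
        maintained_share = 100.0 * out["maintained"].sum() / out["total"].sum()
        assert maintained_share == pytest.approx(50.0, abs=10.0)


class TestOrthologCross:
    def test_published_style_percentages_recompute(self):
        # 58 pairs up-in-recipient splitting 13/24/6/15 across partner status
        pairs = pd.DataFrame({
            "recipient_id": [f"r{i}" for i in range(58)],
            "donor_id": [f"d{i}" for i in range(58)],
        })
        cc = degs_frame(["up"] * 58, index=list(pairs["recipient_id"]))
        partner_status = (["unexpressed"] * 13 + ["down"] * 24 +
                          ["up"] * 6 + ["unchanged"] * 15)
        bb = degs_frame(partner_status, index=list(pairs["donor_id"]))
        tpm_cc = pd.Series(10.0, index=pairs["recipient_id"].to_list())
        tpm_bb = pd.Series(10.0, index=pairs["donor_id"].to_list())
        out = cross_classify_orthologs(cc, bb, pairs, tpm_cc, tpm_bb)
        row = out.loc["up"]
        assert (row[["unexpressed", "down", "up", "unchanged"]].to_list() ==
                [13, 24, 6, 15])
        assert row["total"] == 58
        assert row["pct_unexpressed"] == 22.41
        assert row["pct_down"] == 41.38
        assert row["pct_up"] == 10.34
        assert row["pct_unchanged"] == 25.86

    def test_unexpressed_pairs_filtered_without_error(self):
        pairs = pd.DataFrame({"recipient_id": ["r0"], "donor_id": ["d0"]})
        cc = degs_frame(["up"], index=["r0"])
        bb = degs_frame(["down"], index=["d0"])
        out = cross_classify_orthologs(cc, bb, pairs,
                                       pd.Series({"r0": 0.5}),
                                       pd.Series({"d0": 10.0}))
        assert out["total"].sum() == 0

    def test_duplicated_pairs_rejected(self):
        pairs = pd.DataFrame({"recipient_id": ["r0", "r0"],
                              "donor_id": ["d0", "d1"]})
        cc = degs_frame(["up"], index=["r0"])
        bb = degs_frame(["down", "down"], index=["d0", "d1"])
        with pytest.raises(ValueError):
            cross_classify_orthologs(cc, bb, pairs, pd.Series(dtype=float),
                                     pd.Series(dtype=float))

    def test_maal_side_threshold_marks_unexpressed(self):
        pairs = pd.DataFrame({"recipient_id": ["r0"], "donor_id": ["d0"]})
        cc = degs_frame(["up"], index=["r0"])
        bb = degs_frame(["down"], index=["d0"])
        out = cross_classify_orthologs(
            cc, bb, pairs, pd.Series({"r0": 10.0}), pd.Series({"d0": 10.0}),
            donor_maal_tpm=pd.Series({"d0": 0.2}))
        assert out.loc["up", "unexpressed"] == 1


class TestOverlapAndCorrelation:
    def test_disjoint_sets_share_nothing(self):
        out = overlap_coregulated(degs_frame(["up"], index=["a"]),
                                  degs_frame(["up"], index=["b"]))
        assert out["n_shared"] == 0

    def test_identical_sets_fully_concordant(self):
        d = degs_frame(["up", "down"], index=["a", "b"])
        out = overlap_coregulated(d, d)
        assert out["pct_of_set1"] == 100.0
        assert out["n_same_direction"] == 2

    def test_published_share_recomputes(self):
        # 2797 shared of 10599 trans DEGs -> 26.39%
        set1 = degs_frame(["up"] * 10599)
        set2 = degs_frame(["up"] * 2797 + ["unchanged"] * 7802)
        out = overlap_coregulated(set1, set2)
        assert out["n_shared"] == 2797
        assert out["pct_of_set1"] == 26.39

    def test_perfect_and_anti_correlation(self):
        assert correlate_trans_gene_number([1, 2, 3], [2, 4, 6])["r"] == \
            pytest.approx(1.0)
        assert correlate_trans_gene_number([1, 2, 3], [-1, -2, -3])["r"] == \
            pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # cov = 10, var_x = 10, var_y = 14.8 -> r = 10 / sqrt(148)
        out = correlate_trans_gene_number([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert out["r"] == pytest.approx(10 / np.sqrt(148), abs=1e-6)
        assert out["r"] == pytest.approx(0.8220, abs=1e-4)

    def test_zero_variance_reported_missing(self):
        out = correlate_trans_gene_number([1, 1, 1], [2, 3, 4])
        assert np.isnan(out["r"])


class TestClusterSamples:
    def make_tpm(self, cols):
        rng = np.random.default_rng(5)
        base = rng.lognormal(3, 1, size=200)
        data = {}
        for name, noise in cols:
            data[name] = base * rng.lognormal(0, noise, size=200)
        return pd.DataFrame(data)

    def test_duplicated_sample_merges_first(self):
        tpm = self.make_tpm([("a", 0.3), ("c", 0.3)])
        tpm["b"] = tpm["a"]
        link, order = cluster_samples(tpm)
        first = sorted(int(i) for i in link[0, :2])
        assert [order[i] for i in first] == ["a", "b"]
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_divergent_sample_joins_last(self):
        """A sample with much stronger perturbation joins the tree last."""
        cfg = EffectConfig(genes_per_chrom=60, trans_fraction=0.3,
                           trans_effect_log2=3.0, seed=13)
        catalog = build_genome_pair(cfg)
        counts, _, _ = simulate_experiment(catalog, cfg)
        tpm = compute_tpm(counts, catalog, added_chrom="B1")
        recip = catalog.genes_of("recipient")
        cols = list(counts.samples_of("CC")) + list(counts.samples_of("MAAL"))
        link, order = cluster_samples(tpm.loc[recip, cols])
        # the last merge separates the MAAL block from the euploids
        n = len(order)
        cc = {i for i, s in enumerate(order) if s.startswith("CC")}

        members = {i: {i} for i in range(n)}
        for j, row in enumerate(link):
            members[n + j] = members[int(row[0])] | members[int(row[1])]
        left = members[int(link[-1, 0])]
        right = members[int(link[-1, 1])]
        assert cc in (left, right)

    def test_constant_profile_rejected_by_name(self):
        tpm = self.make_tpm([("a", 0.3), ("b", 0.3)])
        tpm["flat"] = 5.0
        with pytest.raises(ValueError, match="flat"):
            cluster_samples(tpm)
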