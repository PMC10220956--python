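"""Aneuploidy-response tables: direction summaries, cis/trans partition,
strata, maintenance, ortholog compensation, overlap, clustering.

Reproduces the study's summary-table suite on the synthetic experiment
and scores trans-effect recovery against the simulator's truth table.
"""

import pandas as pd
from _config import ADDED, RESULTS

from maalseq import io, response
from maalseq.diffexpr import STATUS_UNEXPRESSED


def main() -> None:
    counts = io.read_counts(RESULTS / "counts.tsv")
    catalog = io.read_catalog(RESULTS / "catalog.tsv")
    truth = io.read_truth(RESULTS / "truth.tsv")
    tpm = pd.read_csv(RESULTS / "tpm.tsv", sep="\t", index_col="gene_id")
    degs_maal = pd.read_csv(RESULTS / "degs_MAAL_vs_CC.tsv", sep="\t",
                            index_col="gene_id")
    degs_non = pd.read_csv(RESULTS / "degs_nonMAAL_vs_CC.tsv", sep="\t",
                           index_col="gene_id")
    degs_cis = pd.read_csv(RESULTS / "degs_MAAL_vs_BB.tsv", sep="\t",
                           index_col="gene_id")

    universe = int((degs_maal["status"] != STATUS_UNEXPRESSED).sum())
    summaries = response.add_chisq_q([
        response.summarize_comparison(degs_maal, universe, "MAAL vs CC"),
        response.summarize_comparison(degs_non, universe, "nonMAAL vs CC"),
        response.summarize_comparison(
            degs_cis, int((degs_cis["status"] != STATUS_UNEXPRESSED).sum()),
            "MAAL vs BB"),
    ])
    table1 = response.summary_table(summaries)
    table1.to_csv(RESULTS / "table_direction_summary.tsv", sep="\t")
    print(table1[["n_up", "n_down", "ratio_down", "chisq_q"]])

    part = response.partition_cis_trans(degs_maal, degs_cis, catalog, ADDED)
    part.trans_per_chromosome.to_csv(
        RESULTS / "table_trans_per_chromosome.tsv", sep="\t")
    planted = set(truth.index[truth["planted_trans_direction"] != "none"])
    called = set(part.trans.index)
    gedd = set(truth.index[truth["in_gedd"]])
    print(f"trans DEGs {len(called)}: recall "
          f"{len(called & planted) / len(planted):.3f}, precision "
          f"{len(called & (planted | gedd)) / len(called):.3f} vs truth")

    cc_mean = tpm.loc[:, counts.samples_of("CC")].mean(axis=1)
    strata = response.stratify_by_expression(
        cc_mean[catalog.genes_of("recipient")], degs_maal)
    strata.to_csv(RESULTS / "table_strata.tsv", sep="\t")

    maint = response.classify_maintenance(degs_maal, degs_non)
    maint.to_csv(RESULTS / "table_maintenance.tsv", sep="\t")
    print("maintained share:",
          round(100 * maint["maintained"].sum() / maint["total"].sum(), 2),
          "percent of MAAL trans DEGs (GEDD window included)")

    pairs = io.read_orthologs(RESULTS / "ortholog_pairs.tsv")
    pairs = pairs[pairs["donor_id"].isin(catalog.genes_on(ADDED))]
    bb_mean = tpm.loc[:, counts.samples_of("BB")].mean(axis=1)
    maal_mean = tpm.loc[:, counts.samples_of("MAAL")].mean(axis=1)
    cross = response.cross_classify_orthologs(
        degs_maal, degs_cis, pairs, tpm_cc=cc_mean, tpm_bb=bb_mean,
        donor_maal_tpm=maal_mean)
    cross.to_csv(RESULTS / "table_ortholog_cross.tsv", sep="\t")

    overlap = response.overlap_coregulated(degs_maal, degs_non)
    print(f"co-regulated DEGs: {overlap['n_shared']} shared "
          f"({overlap['pct_of_set1']}% of the MAAL trans set), "
          f"{overlap['n_opposite_direction']} reversed")

    link, order = response.cluster_samples(tpm)
    pd.DataFrame(link, columns=["left", "right", "distance", "size"]) \
        .to_csv(RESULTS / "sample_clustering.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
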