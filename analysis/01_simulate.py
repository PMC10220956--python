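"""Simulate the MAAL experiment and write counts, catalog and truth.

Outputs (results/analysis/): catalog.tsv, counts.tsv, truth.tsv,
ortholog_pairs.tsv.
"""

from _config import CONFIG, RESULTS

from maalseq import io
from maalseq.simulate import build_genome_pair, simulate_experiment


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    catalog = build_genome_pair(CONFIG)
    counts, truth, _ = simulate_experiment(catalog, CONFIG)
    io.write_catalog(catalog, RESULTS / "catalog.tsv")
    io.write_counts(counts, RESULTS / "counts.tsv")
    io.write_truth(truth, RESULTS / "truth.tsv")
    io.write_orthologs(catalog, RESULTS / "ortholog_pairs.tsv")
    n_trans = int((truth["planted_trans_direction"] != "none").sum())
    print(f"simulated {len(catalog.table)} genes x {counts.counts.shape[1]} "
          f"samples; planted {n_trans} trans effects, "
          f"{int(truth['in_gedd'].sum())} GEDD genes, "
          f"{int(truth['planted_cis'].sum())} dosage-shifted donor genes")


if __name__ == "__main__":
    main()
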