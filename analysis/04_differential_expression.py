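"""The three DE comparisons: MAAL vs CC, nonMAAL vs CC, MAAL vs BB.

Trans effects are read off recipient genes in MAAL vs CC; cis effects off
the added chromosome in MAAL vs BB, with support-anchored normalization
(the dosage shift is genome-wide on the shared genes).  Writes one
DEG table per comparison and prints the DEG counts.
"""

import pandas as pd
from _config import ADDED, RESULTS

from maalseq import io
from maalseq.diffexpr import compare_groups, support_average_factors


def main() -> None:
    counts = io.read_counts(RESULTS / "counts.tsv")
    catalog = io.read_catalog(RESULTS / "catalog.tsv")
    tpm = pd.read_csv(RESULTS / "tpm.tsv", sep="\t", index_col="gene_id")
    recip = catalog.genes_of("recipient")
    on_added = catalog.genes_on(ADDED)
    cis_factors = support_average_factors(counts, catalog, ADDED)
    jobs = {
        "degs_MAAL_vs_CC": ("CC", "MAAL", recip, None),
        "degs_nonMAAL_vs_CC": ("CC", "nonMAAL", recip, None),
        "degs_MAAL_vs_BB": ("BB", "MAAL", on_added, cis_factors),
    }
    for name, (a, b, genes, factors) in jobs.items():
        degs = compare_groups(counts, tpm, a, b, genes=genes, factors=factors)
        degs.to_csv(RESULTS / f"{name}.tsv", sep="\t", index_label="gene_id")
        n_up = int((degs["status"] == "up").sum())
        n_down = int((degs["status"] == "down").sum())
        print(f"{name}: {n_up} up, {n_down} down "
              f"of {len(degs)} genes tested")


if __name__ == "__main__":
    main()
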