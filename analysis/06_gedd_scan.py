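"""Scan recipient chromosomes for gene-expression dysregulation domains.

Smooths MAAL-vs-CC log2 fold changes along gene order per chromosome
(robust lowess) and calls contiguous shifted runs; compares the calls
with the planted window from the truth table.
"""

import pandas as pd
from _config import CONFIG, RESULTS

from maalseq import io
from maalseq.gedd import scan_genome


def main() -> None:
    catalog = io.read_catalog(RESULTS / "catalog.tsv")
    degs = pd.read_csv(RESULTS / "degs_MAAL_vs_CC.tsv", sep="\t",
                       index_col="gene_id")
    tested = degs[degs["status"] != "unexpressed"]
    domains = scan_genome(tested, catalog)
    domains.to_csv(RESULTS / "domains.tsv", sep="\t", index=False)
    print(domains.to_string(index=False) if len(domains)
          else "no domains called")
    for chrom, start, length, shift in CONFIG.gedd_specs:
        print(f"planted window: {chrom}[{start}:{start + length}) "
              f"shift {shift:+.1f} log2")


if __name__ == "__main__":
    main()
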