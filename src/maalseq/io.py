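"""Plain-text table readers/writers for the pipeline's interchange files.

All interchange formats are TSV: a counts table (gene_id + one column per
sample, with a second header line of group labels handled separately), the
gene catalog, ortholog pairs and the truth table.
"""

from __future__ import annotations

import pandas as pd

from maalseq.simulate import CountMatrix, GeneCatalog


def write_counts(counts: CountMatrix, path) -> None:
    df = counts.counts.copy()
    df.columns = [f"{s}:{g}" for s, g in counts.groups.items()]
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    samples, groups = zip(*(c.split(":", 1) for c in df.columns))
    df.columns = list(samples)
    return CountMatrix(counts=df,
                       groups=pd.Series(groups, index=list(samples),
                                        name="group"))


def write_catalog(catalog: GeneCatalog, path) -> None:
    catalog.table.to_csv(path, sep="\t", index_label="gene_id")


def read_catalog(path) -> GeneCatalog:
    t = pd.read_csv(path, sep="\t", index_col="gene_id",
                    dtype={"ortholog_partner": "object"})
    t["ortholog_partner"] = t["ortholog_partner"].where(
        t["ortholog_partner"].notna(), pd.NA)
    return GeneCatalog(table=t)


def write_orthologs(catalog: GeneCatalog, path) -> None:
    catalog.ortholog_pairs().to_csv(path, sep="\t", index=False)


def read_orthologs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene_id")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
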