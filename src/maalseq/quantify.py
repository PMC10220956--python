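"""TPM normalization and per-chromosome expression summaries.

TPM (transcripts per kilobase per million mapped reads) is computed per
sample as ``(count/length) / sum(count/length) * 1e6``.  The denominator is
taken over the genes a sample's genome actually carries (its *support*):
donor genes are excluded for euploid recipient samples and vice versa, so
TPM columns are comparable between euploid and aneuploid samples even
though the aneuploid carries extra genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from maalseq.simulate import CountMatrix, GeneCatalog, support_for


def compute_tpm(counts: CountMatrix, catalog: GeneCatalog,
                added_chrom: str | None = None) -> pd.DataFrame:
    """Genes x samples TPM matrix; each column sums to 1e6 over its support.

    An all-zero sample yields an all-zero column with a warning rather
    than a division error.
    """
    lengths = catalog.table["tx_length"].reindex(counts.genes)
    if lengths.isna().any():
        raise ValueError("counts contain genes absent from the catalog")
    if (lengths <= 0).any():
        raise ValueError("non-positive transcript length")
    rate = counts.counts.div(lengths, axis=0)
    tpm = pd.DataFrame(0.0, index=counts.genes, columns=counts.samples)
    for sample in counts.samples:
        group = counts.groups[sample]
        sup = support_for(catalog, group, added_chrom).intersection(counts.genes)
        denom = rate.loc[sup, sample].sum()
        if denom == 0:
            warnings.warn(f"sample {sample} has zero mapped reads; TPM set to 0")
            continue
        tpm.loc[sup, sample] = rate.loc[sup, sample] / denom * 1e6
    return tpm


def group_mean_tpm(tpm: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Arithmetic mean TPM per group (genes x groups)."""
    return tpm.T.groupby(groups).mean().T


def expressed_genes(tpm: pd.DataFrame, groups: pd.Series, group: str,
                    threshold: float = 1.0) -> pd.Index:
    """Genes whose group-mean TPM exceeds ``threshold`` (strict)."""
    if group not in set(groups):
        raise ValueError(f"unknown group {group!r}")
    mean = tpm.loc[:, groups.index[groups == group]].mean(axis=1)
    return tpm.index[mean > threshold]


def per_chromosome_profile(tpm: pd.DataFrame, catalog: GeneCatalog,
                           groups: pd.Series, group: str,
                           threshold: float = 1.0) -> pd.DataFrame:
    """Distribution summary of log2(TPM+1) over expressed genes, per chromosome.

    One row per chromosome with median and quartiles; chromosomes with no
    expressed gene yield missing values.
    """
    expr = expressed_genes(tpm, groups, group, threshold)
    mean = tpm.loc[:, groups.index[groups == group]].mean(axis=1)
    log_expr = np.log2(mean + 1.0)
    rows = []
    for chrom in catalog.table["chromosome"].unique():
        on = catalog.genes_on(chrom).intersection(expr)
        if len(on) == 0:
            rows.append((chrom, 0, np.nan, np.nan, np.nan))
            continue
        v = log_expr[on]
        rows.append((chrom, len(on), v.quantile(0.25), v.median(),
                     v.quantile(0.75)))
    return pd.DataFrame(rows, columns=["chromosome", "n_expressed", "q25",
                                       "median", "q75"]).set_index("chromosome")
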