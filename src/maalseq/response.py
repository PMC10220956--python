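"""Aneuploidy-response analytics.

Everything downstream of the DEG calls: direction-bias summaries with
chi-square tests, cis/trans partitioning of DEGs by subgenome, expression
strata, maintenance of DEGs in the derived euploid, ortholog-pair
compensation cross-tables, co-regulation overlap, the trans-effect vs
gene-number correlation, and hierarchical sample clustering.

Percentages in every emitted table recompute exactly (round-half-even to
2 dp) from the table's own counts; that property is what reproduces the
published-style summary tables from first principles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from maalseq.diffexpr import (
    STATUS_DOWN,
    STATUS_UNCHANGED,
    STATUS_UNEXPRESSED,
    STATUS_UP,
    adjust_bh,
)
from maalseq.simulate import GeneCatalog


def round2(x: float) -> float:
    """Round-half-even to 2 decimals, the convention for printed ratios."""
    return float(np.round(x, 2))


@dataclass(frozen=True)
class ComparisonSummary:
    """Up/down DEG counts for one comparison plus the 1:1 direction test."""

    comparison: str
    n_up: int
    n_down: int
    n_total: int
    ratio_up: float
    ratio_down: float
    ratio_total: float
    universe_size: int
    chisq_stat: float
    chisq_p: float
    chisq_q: float = float("nan")


def direction_chisq(n_up: int, n_down: int) -> tuple[float, float]:
    """Chi-square goodness of fit of (up, down) against 1:1, 1 df.

    No continuity correction.  Undefined (NaN) when both counts are zero.
    """
    total = n_up + n_down
    if total == 0:
        return float("nan"), float("nan")
    e = total / 2.0
    stat = (n_up - e) ** 2 / e + (n_down - e) ** 2 / e
    return float(stat), float(stats.chi2.sf(stat, df=1))


def summarize_comparison(degs: pd.DataFrame, universe_size: int,
                         comparison: str | None = None) -> ComparisonSummary:
    """Count up/down DEGs and test the direction balance against 1:1."""
    n_up = int((degs["status"] == STATUS_UP).sum())
    n_down = int((degs["status"] == STATUS_DOWN).sum())
    n_total = n_up + n_down
    stat, p = direction_chisq(n_up, n_down)
    label = comparison or (degs["comparison"].iloc[0] if "comparison" in degs
                           and len(degs) else "")
    return ComparisonSummary(
        comparison=label,
        n_up=n_up, n_down=n_down, n_total=n_total,
        ratio_up=round2(100.0 * n_up / n_total) if n_total else float("nan"),
        ratio_down=round2(100.0 * n_down / n_total) if n_total else float("nan"),
        ratio_total=round2(100.0 * n_total / universe_size) if universe_size
        else float("nan"),
        universe_size=int(universe_size),
        chisq_stat=stat, chisq_p=p,
    )


def add_chisq_q(summaries: list[ComparisonSummary]) -> list[ComparisonSummary]:
    """BH-adjust the chi-square p-values across a run's comparisons."""
    ps = np.array([s.chisq_p for s in summaries])
    ok = ~np.isnan(ps)
    qs = np.full(len(ps), np.nan)
    if ok.any():
        qs[ok] = adjust_bh(ps[ok])
    out = []
    for s, q in zip(summaries, qs):
        d = asdict(s)
        d["chisq_q"] = float(q)
        out.append(ComparisonSummary(**d))
    return out


def summary_table(summaries: list[ComparisonSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries]).set_index("comparison")


@dataclass(frozen=True)
class CisTransPartition:
    """DEGs split into cis (added-chromosome, vs donor parent) and trans
    (recipient genome, vs recipient parent)."""

    cis: pd.DataFrame
    trans: pd.DataFrame
    trans_per_chromosome: pd.DataFrame


def partition_cis_trans(degs_vs_cc: pd.DataFrame, degs_vs_bb: pd.DataFrame,
                        catalog: GeneCatalog, added_chrom: str
                        ) -> CisTransPartition:
    """Partition MAAL DEGs into cis and trans effects.

    Trans DEGs: recipient-genome genes differentially expressed in MAAL vs
    the recipient parent.  Cis DEGs: genes on the added donor chromosome
    differentially expressed in MAAL vs the donor parent.
    """
    t = catalog.table
    if added_chrom not in set(t["chromosome"]):
        raise ValueError(f"added chromosome {added_chrom!r} not in catalog")
    is_deg = lambda df: df["status"].isin([STATUS_UP, STATUS_DOWN])

    recip = t.index[t["subgenome"] == "recipient"]
    trans = degs_vs_cc[is_deg(degs_vs_cc) &
                       degs_vs_cc.index.isin(recip)].copy()
    on_added = t.index[t["chromosome"] == added_chrom]
    cis = degs_vs_bb[is_deg(degs_vs_bb) & degs_vs_bb.index.isin(on_added)].copy()

    chrom = t.loc[trans.index, "chromosome"]
    per_chrom = (pd.crosstab(chrom, trans["status"])
                 .reindex(columns=[STATUS_UP, STATUS_DOWN], fill_value=0))
    per_chrom["total"] = per_chrom.sum(axis=1)
    return CisTransPartition(cis=cis, trans=trans,
                             trans_per_chromosome=per_chrom)


STRATA = (("low", 1.0, 10.0), ("medium", 10.0, 100.0), ("high", 100.0, np.inf))


def assign_strata(mean_tpm: pd.Series) -> pd.Series:
    """Expression stratum from parental mean TPM: [1,10) low, [10,100)
    medium, [100,inf) high; genes below 1 are unassigned (NaN)."""
    out = pd.Series(pd.NA, index=mean_tpm.index, dtype="object")
    for name, lo, hi in STRATA:
        out[(mean_tpm >= lo) & (mean_tpm < hi)] = name
    return out


def stratify_by_expression(mean_tpm_cc: pd.Series,
                           degs: pd.DataFrame) -> pd.DataFrame:
    """Up/down/total DEG counts and within-stratum ratios per stratum.

    Strata are defined on the recipient parent's group-mean TPM; the ratio
    is DEG total over the number of stratum genes, as a percentage.
    """
    strata = assign_strata(mean_tpm_cc)
    rows = []
    for name, _lo, _hi in STRATA:
        genes = strata.index[strata == name]
        sub = degs[degs.index.isin(genes)]
        n_up = int((sub["status"] == STATUS_UP).sum())
        n_down = int((sub["status"] == STATUS_DOWN).sum())
        n_genes = len(genes)
        total = n_up + n_down
        rows.append({
            "stratum": name, "n_genes": n_genes, "up": n_up, "down": n_down,
            "total": total,
            "ratio": round2(100.0 * total / n_genes) if n_genes else float("nan"),
            "share_of_expressed": float("nan"),
        })
    table = pd.DataFrame(rows).set_index("stratum")
    n_expr = table["n_genes"].sum()
    if n_expr:
        table["share_of_expressed"] = [
            round2(100.0 * n / n_expr) for n in table["n_genes"]]
    return table


MAINT_MAINTAINED = "maintained"
MAINT_OPPOSITE = "opposite"
MAINT_UNCHANGED = "unchanged"


def classify_maintenance(degs_maal: pd.DataFrame,
                         degs_nonmaal: pd.DataFrame) -> pd.DataFrame:
    """Fate of each MAAL DEG in the derived euploid comparison.

    'maintained' = still a DEG in the same direction, 'opposite' = a DEG in
    the other direction, 'unchanged' = no longer a DEG.  Rows are the MAAL
    DEG direction; counts sum to the row total (=100%).
    """
    is_deg = degs_maal["status"].isin([STATUS_UP, STATUS_DOWN])
    rows = []
    for direction in (STATUS_DOWN, STATUS_UP):
        genes = degs_maal.index[is_deg & (degs_maal["status"] == direction)]
        n_opp = n_maint = n_unch = 0
        for g in genes:
            if g in degs_nonmaal.index:
                s = degs_nonmaal.at[g, "status"]
            else:
                warnings.warn(f"gene {g} absent from the euploid comparison; "
                              "counted as unchanged")
                s = STATUS_UNCHANGED
            if s == direction:
                n_maint += 1
            elif s in (STATUS_UP, STATUS_DOWN):
                n_opp += 1
            else:
                n_unch += 1
        total = len(genes)
        pct = (lambda n: round2(100.0 * n / total) if total else float("nan"))
        rows.append({
            "maal_direction": direction, "opposite": n_opp,
            "maintained": n_maint, "unchanged": n_unch, "total": total,
            "pct_opposite": pct(n_opp), "pct_maintained": pct(n_maint),
            "pct_unchanged": pct(n_unch),
        })
    return pd.DataFrame(rows).set_index("maal_direction")


def cross_classify_orthologs(degs_cc_side: pd.DataFrame,
                             degs_bb_side: pd.DataFrame,
                             pairs: pd.DataFrame,
                             tpm_cc: pd.Series, tpm_bb: pd.Series,
                             donor_maal_tpm: pd.Series | None = None,
                             tpm_cut: float = 1.0) -> pd.DataFrame:
    """Cross-classify ortholog pairs: recipient DEG direction x donor status.

    ``pairs`` has columns recipient_id / donor_id (added-chromosome donor
    genes).  Pairs unexpressed (< tpm_cut) in either parental genome
    (``tpm_cc``, ``tpm_bb``) are removed first.  When ``donor_maal_tpm``
    is given, the 'unexpressed' column means the donor partner is
    expressed in the diploid donor parent but falls below the threshold on
    the MAAL's single chromosome (the default MAAL-side reading); without
    it, partners absent from the donor-side DEG table count as unexpressed.
    """
    if pairs.duplicated("recipient_id").any() or \
            pairs.duplicated("donor_id").any():
        raise ValueError("ortholog pair table is not one-to-one")
    keep = pairs[
        pairs["recipient_id"].map(tpm_cc).fillna(0.0).ge(tpm_cut)
        & pairs["donor_id"].map(tpm_bb).fillna(0.0).ge(tpm_cut)
    ]
    col_order = ["unexpressed", "down", "up", "unchanged"]
    rows = []
    for direction in (STATUS_UP, STATUS_DOWN):
        cc_genes = degs_cc_side.index[degs_cc_side["status"] == direction]
        sub = keep[keep["recipient_id"].isin(cc_genes)]
        partner_status = sub["donor_id"].map(
            degs_bb_side["status"]).fillna(STATUS_UNEXPRESSED)
        if donor_maal_tpm is not None:
            low = sub["donor_id"].map(donor_maal_tpm).fillna(0.0) < tpm_cut
            partner_status = partner_status.mask(low.to_numpy(),
                                                 STATUS_UNEXPRESSED)
        counts = {c: int((partner_status == c).sum()) for c in col_order}
        total = sum(counts.values())
        row = {"cc_direction": direction, **counts, "total": total}
        for c in col_order:
            row[f"pct_{c}"] = round2(100.0 * counts[c] / total) if total \
                else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("cc_direction")


def overlap_coregulated(degs_1: pd.DataFrame,
                        degs_2: pd.DataFrame) -> dict:
    """Shared DEGs between two comparisons with direction concordance.

    Returns shared ids, same- vs opposite-direction counts and the shared
    share of the first comparison's DEG set (percent).
    """
    def deg_dirs(df):
        m = df["status"].isin([STATUS_UP, STATUS_DOWN])
        return df.loc[m, "status"]

    d1, d2 = deg_dirs(degs_1), deg_dirs(degs_2)
    shared = d1.index.intersection(d2.index)
    same = int((d1[shared] == d2[shared]).sum())
    return {
        "shared_genes": list(shared),
        "n_shared": len(shared),
        "n_set1": len(d1),
        "n_set2": len(d2),
        "n_same_direction": same,
        "n_opposite_direction": len(shared) - same,
        "pct_of_set1": round2(100.0 * len(shared) / len(d1)) if len(d1)
        else float("nan"),
    }


def correlate_trans_gene_number(trans_counts, gene_numbers,
                                extra_pvalues=()) -> dict:
    """Pearson correlation of per-MAAL trans-DEG counts with the gene
    number of the added chromosome, BH-adjusted when run alongside other
    correlations."""
    x = np.asarray(trans_counts, dtype=float)
    y = np.asarray(gene_numbers, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 MAALs")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "padj": float("nan")}
    r, p = stats.pearsonr(x, y)
    ps = np.concatenate([[p], np.asarray(extra_pvalues, dtype=float)])
    padj = adjust_bh(ps)[0]
    return {"r": float(r), "p": float(p), "padj": float(padj)}


def cluster_samples(tpm: pd.DataFrame):
    """Average-linkage tree over samples, 1 - Pearson correlation distance.

    Profiles are log2(TPM+1) over genes expressed (TPM > 1 in some sample);
    samples are ordered by id for deterministic tie-breaking.  A constant
    profile has undefined correlation and raises, naming the sample.
    """
    if tpm.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    cols = sorted(tpm.columns)
    shared = tpm.index[(tpm > 1.0).any(axis=1)]
    prof = np.log2(tpm.loc[shared, cols] + 1.0)
    sd = prof.std(axis=0)
    flat = sd.index[sd < 1e-12]
    if len(flat):
        raise ValueError(f"constant expression profile: {list(flat)}")
    corr = np.corrcoef(prof.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return link, cols
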