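"""Negative-binomial Wald differential-expression test.

A deliberately closed-form NB test for small replicate numbers (n = 3 is
the design here):

* size factors by DESeq-style median-of-ratios,
* per-gene dispersion by pooled method of moments,
  ``alpha = max(0, (s^2 - m) / m^2)`` per group, precision-weighted, then
  moderated toward the across-genes median with a fixed prior weight
  (``DISPERSION_PRIOR_DF`` pseudo-replicates, limma-style) — the raw
  per-gene estimate is far too noisy at n = 3 to test against,
* Wald statistic on the log of pseudo-counted normalized group means with
  the delta-method variance ``Var(log m) ~ (1/n) (1/m + alpha)``,
* two-sided p-values against a t reference whose degrees of freedom sum
  the residual df and the prior df (normal quantiles are anticonservative
  with plug-in dispersion at n = 3), then Benjamini-Hochberg adjustment,
* the DEG filter: |log2FC| >= 1, Padj < 0.05 and group-mean TPM >= 1 in
  either group (genes failing the TPM filter are 'unexpressed' and are
  excluded from the testing universe).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

PSEUDOCOUNT = 0.5
ALPHA_FLOOR = 1e-8
DISPERSION_PRIOR_DF = 6.0

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_UNCHANGED = "unchanged"
STATUS_UNEXPRESSED = "unexpressed"


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios scaling factors, one per sample (column).

    Computed over genes with nonzero counts in every sample; if no such
    gene exists, falls back to total-count factors with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        warnings.warn("no gene covered in all samples; using total-count factors")
        totals = mat.sum(axis=0)
        f = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(f, index=counts.columns, name="size_factor")
    sub = mat[all_nonzero]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    f = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    return pd.Series(f, index=counts.columns, name="size_factor")


def support_average_factors(counts, catalog, added_chrom: str | None) -> pd.Series:
    """Per-sample factors from the average count per genome-support gene.

    For comparisons whose shared gene set carries a genome-wide dosage
    shift (MAAL vs donor parent on the single added chromosome),
    median-of-ratios over the shared genes would absorb the shift entirely.
    These factors instead anchor each sample on its full genome support:
    factor_s = (total support counts / number of support genes), scaled to
    geometric mean 1.  Valid under the assumption that average per-gene
    output per genome copy is constant across samples.
    """
    from maalseq.simulate import support_for

    vals = {}
    for sample in counts.samples:
        sup = support_for(catalog, counts.groups[sample], added_chrom) \
            .intersection(counts.genes)
        vals[sample] = counts.counts.loc[sup, sample].sum() / len(sup)
    f = pd.Series(vals, name="size_factor")
    return f / np.exp(np.mean(np.log(f)))


def _moments_dispersion(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    """Moderated method-of-moments NB dispersion per gene (vectorized).

    Per group: alpha_g = max(0, (s^2 - m) / m^2); the two estimates are
    combined weighted by group mean (a precision proxy), then shrunk
    toward the across-genes median with prior weight DISPERSION_PRIOR_DF
    against the residual df, and floored at 1e-8.
    """
    def one(group: np.ndarray):
        m = group.mean(axis=1)
        s2 = group.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        return np.maximum(a, 0.0), m

    a_a, m_a = one(norm_a)
    a_b, m_b = one(norm_b)
    w = m_a + m_b
    with np.errstate(invalid="ignore"):
        alpha = np.where(w > 0, (a_a * m_a + a_b * m_b) / np.maximum(w, 1e-300), 0.0)
    d_res = norm_a.shape[1] + norm_b.shape[1] - 2
    expressed = w > 0
    common = float(np.median(alpha[expressed])) if expressed.any() else 0.0
    alpha = (DISPERSION_PRIOR_DF * common + d_res * alpha) / \
        (DISPERSION_PRIOR_DF + d_res)
    return np.maximum(alpha, ALPHA_FLOOR)


def test_genes(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
               factors_a: pd.Series, factors_b: pd.Series) -> pd.DataFrame:
    """Wald NB test for every gene; groups are the columns of each frame.

    Returns a frame with ``base_mean_A``, ``base_mean_B``, ``log2fc``,
    ``p``.  The fold change is B over A. Genes at zero in both groups get
    log2fc = 0, p = 1.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    norm_a = counts_a.to_numpy(dtype=float) / factors_a.to_numpy()
    norm_b = counts_b.to_numpy(dtype=float) / factors_b.to_numpy()
    m_a = norm_a.mean(axis=1)
    m_b = norm_b.mean(axis=1)
    c = PSEUDOCOUNT
    log2fc = np.log2((m_b + c) / (m_a + c))
    alpha = _moments_dispersion(norm_a, norm_b)
    n_a, n_b = norm_a.shape[1], norm_b.shape[1]
    var = (1.0 / n_a) * (1.0 / (m_a + c) + alpha) + \
          (1.0 / n_b) * (1.0 / (m_b + c) + alpha)
    wald = (np.log(m_b + c) - np.log(m_a + c)) / np.sqrt(var)
    # t reference with df = prior + residual: a normal reference is
    # anticonservative with plug-in dispersion at n = 3 (type-I ~0.11)
    p = 2.0 * stats.t.sf(np.abs(wald),
                         df=DISPERSION_PRIOR_DF + n_a + n_b - 2)
    both_zero = (m_a == 0) & (m_b == 0)
    log2fc[both_zero] = 0.0
    p[both_zero] = 1.0
    return pd.DataFrame({
        "base_mean_A": m_a, "base_mean_B": m_b,
        "log2fc": log2fc, "p": p,
    }, index=counts_a.index)


def test_gene(counts_a, counts_b, factors_a, factors_b) -> tuple[float, float]:
    """Single-gene convenience wrapper around :func:`test_genes`."""
    a = pd.DataFrame([np.asarray(counts_a, dtype=float)])
    b = pd.DataFrame([np.asarray(counts_b, dtype=float)])
    res = test_genes(a, b, pd.Series(np.asarray(factors_a, dtype=float)),
                     pd.Series(np.asarray(factors_b, dtype=float)))
    return float(res["log2fc"].iloc[0]), float(res["p"].iloc[0])


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_degs(records: pd.DataFrame, lfc_cut: float = 1.0,
              padj_cut: float = 0.05, tpm_cut: float = 1.0) -> pd.DataFrame:
    """Assign DEG status given test results plus group-mean TPM columns.

    ``records`` needs ``log2fc``, ``p``, ``mean_tpm_A``, ``mean_tpm_B``.
    Genes with both group means below ``tpm_cut`` are 'unexpressed' and are
    excluded from the BH universe; among the rest, 'up' means log2fc >=
    lfc_cut with padj < padj_cut, 'down' symmetric, else 'unchanged'.
    """
    out = records.copy()
    expressed = (out["mean_tpm_A"] >= tpm_cut) | (out["mean_tpm_B"] >= tpm_cut)
    out["padj"] = np.nan
    if expressed.any():
        out.loc[expressed, "padj"] = adjust_bh(out.loc[expressed, "p"].to_numpy())
    status = np.full(len(out), STATUS_UNCHANGED, dtype=object)
    status[~expressed.to_numpy()] = STATUS_UNEXPRESSED
    with np.errstate(invalid="ignore"):
        sig = expressed.to_numpy() & (out["padj"].to_numpy() < padj_cut)
    lfc = out["log2fc"].to_numpy()
    status[sig & (lfc >= lfc_cut)] = STATUS_UP
    status[sig & (lfc <= -lfc_cut)] = STATUS_DOWN
    out["status"] = status
    return out


def compare_groups(counts, tpm: pd.DataFrame, group_a: str, group_b: str,
                   genes: pd.Index | None = None,
                   factors: pd.Series | None = None,
                   lfc_cut: float = 1.0, padj_cut: float = 0.05,
                   tpm_cut: float = 1.0) -> pd.DataFrame:
    """Full two-group DE comparison on a CountMatrix.

    Size factors default to median-of-ratios jointly over the two groups'
    samples (restricted to ``genes`` when given, e.g. the shared genome
    support of the two groups); pass precomputed ``factors`` (e.g. from
    :func:`support_average_factors`) when the shared gene set itself
    carries a genome-wide dosage shift.  Returns one DEGRecord row per
    gene; fold change is B over A.
    """
    sa = counts.samples_of(group_a)
    sb = counts.samples_of(group_b)
    if len(sa) == 0 or len(sb) == 0:
        raise ValueError(f"no samples for {group_a!r} or {group_b!r}")
    sub = counts.counts
    if genes is not None:
        sub = sub.loc[genes]
    both = sub[list(sa) + list(sb)]
    factors = size_factors(both) if factors is None else factors
    res = test_genes(sub[list(sa)], sub[list(sb)], factors[sa], factors[sb])
    res["mean_tpm_A"] = tpm.loc[sub.index, sa].mean(axis=1)
    res["mean_tpm_B"] = tpm.loc[sub.index, sb].mean(axis=1)
    res = call_degs(res, lfc_cut=lfc_cut, padj_cut=padj_cut, tpm_cut=tpm_cut)
    res.insert(0, "comparison", f"{group_b} vs {group_a}")
    return res
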