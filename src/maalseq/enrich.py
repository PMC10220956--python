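"""Generic over-representation analysis against user-supplied term maps.

One-sided hypergeometric test of a gene set against each term of an
annotation map (e.g. a GMT file), with BH correction across terms.  No
ontology structure and no live database access: annotations come in as a
plain term -> gene-set mapping.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from maalseq.diffexpr import adjust_bh


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT file: term <tab> description <tab> gene1 <tab> gene2..."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def ora_test(gene_set, annotation: dict, universe, padj_cut: float = 0.05
             ) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` per term.

    p = P(X >= k) for k overlap genes given term size K, set size n and
    universe size N; enrich factor = (k/n)/(K/N).  Terms are intersected
    with the universe first, and the gene set must be a subset of it.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(gene_set)
    if not genes <= universe:
        raise ValueError("gene set not contained in universe")
    N, n = len(universe), len(genes)
    rows = []
    for term, members in annotation.items():
        members = set(members) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        ef = (k / n) / (K / N) if n else float("nan")
        rows.append({"term": term, "overlap": k, "term_size": K,
                     "set_size": n, "universe_size": N, "p": p,
                     "enrich_factor": ef})
    table = pd.DataFrame(rows, columns=["term", "overlap", "term_size",
                                        "set_size", "universe_size", "p",
                                        "enrich_factor"])
    if len(table):
        table["padj"] = adjust_bh(table["p"].to_numpy())
        table["significant"] = table["padj"] < padj_cut
        table = table.sort_values(["p", "term"]).reset_index(drop=True)
    else:
        table["padj"] = []
        table["significant"] = []
    return table
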