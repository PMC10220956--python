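"""Synthetic MAAL experiment generator.

Emulates the study design of a monosomic alien addition line (MAAL)
experiment: a recipient parent (``CC``, euploid), a donor parent (``BB``,
euploid), a MAAL (full CC complement plus one monosomic donor chromosome)
and a derived euploid sibling (``nonMAAL``) that has lost the alien
chromosome again.  Each group has ``n_replicates`` biological replicates.

The generative model:

* baseline per-gene expression drawn log-normal(``mean_log_expr``),
* counts negative-binomial around length- and library-size-scaled means
  with a common dispersion ``alpha`` (var = m + alpha * m**2),
* the monosomic donor chromosome expressed at ``2**cis_dosage_log2`` of the
  diploid BB level (cis dosage effect),
* a fraction of recipient genes shifted in trans by ``+-trans_effect_log2``,
* optional contiguous dysregulation domains (GEDDs) adding a shared log2
  shift to a window of genes,
* in the derived euploid each planted trans effect is maintained, reversed
  or reverted according to ``maintenance_fraction`` / ``reversal_fraction``.

Everything planted is recorded in a truth table so downstream stages can be
scored for parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("CC", "BB", "MAAL", "nonMAAL")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    """Raised when an EffectConfig is internally inconsistent."""


@dataclass(frozen=True)
class GeneCatalog:
    """Per-gene metadata anchoring every downstream classification.

    ``table`` is indexed by ``gene_id`` with columns ``subgenome``
    (``recipient``/``donor``), ``chromosome``, ``position_index`` (ordinal
    along the chromosome, 0..n-1 without gaps), ``tx_length`` (bp) and
    ``ortholog_partner`` (partner gene_id or NA).  Ortholog pairing is
    symmetric and always links one recipient gene to one donor gene.
    """

    table: pd.DataFrame
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        t = self.table
        required = {"subgenome", "chromosome", "position_index", "tx_length",
                    "ortholog_partner"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        if not t.index.is_unique:
            raise ValueError("gene_ids are not unique")
        if (t["tx_length"] <= 0).any():
            raise ValueError("tx_length must be positive")
        for chrom, sub in t.groupby("chromosome", observed=True):
            pos = np.sort(sub["position_index"].to_numpy())
            if not np.array_equal(pos, np.arange(len(sub))):
                raise ValueError(
                    f"position_index on {chrom} is not 0..n-1 without gaps")
        paired = t["ortholog_partner"].dropna()
        for gid, partner in paired.items():
            if partner not in t.index:
                raise ValueError(f"ortholog partner {partner} not in catalog")
            if t.at[partner, "ortholog_partner"] != gid:
                raise ValueError(f"ortholog pairing not symmetric at {gid}")
            if t.at[gid, "subgenome"] == t.at[partner, "subgenome"]:
                raise ValueError(
                    f"ortholog pair {gid}/{partner} links one subgenome")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def genes_of(self, subgenome: str) -> pd.Index:
        return self.table.index[self.table["subgenome"] == subgenome]

    def genes_on(self, chromosome: str) -> pd.Index:
        sub = self.table[self.table["chromosome"] == chromosome]
        return sub.sort_values("position_index").index

    def ortholog_pairs(self) -> pd.DataFrame:
        """(recipient_id, donor_id) rows, one per pair."""
        t = self.table
        rec = t[(t["subgenome"] == "recipient") & t["ortholog_partner"].notna()]
        return pd.DataFrame({
            "recipient_id": rec.index,
            "donor_id": rec["ortholog_partner"].to_numpy(),
        }).reset_index(drop=True)

def support_for(catalog: GeneCatalog, group: str, added_chrom: str | None) -> pd.Index:
    """Gene universe with nonzero possible counts for one sample group.

    CC and nonMAAL samples carry only the recipient genome; BB only the
    donor genome; a MAAL carries the recipient genome plus the added donor
    chromosome.
    """
    t = catalog.table
    if group in ("CC", "nonMAAL"):
        return t.index[t["subgenome"] == "recipient"]
    if group == "BB":
        return t.index[t["subgenome"] == "donor"]
    if group == "MAAL":
        if added_chrom is None:
            raise ValueError("MAAL support requires added_chrom")
        keep = (t["subgenome"] == "recipient") | (t["chromosome"] == added_chrom)
        return t.index[keep]
    raise ValueError(f"unknown group {group!r}")


@dataclass(frozen=True)
class EffectConfig:
    """Parameters of the synthetic MAAL experiment.

    ``cis_dosage_log2`` defaults to -1.0: the single (monosomic) donor
    chromosome is expressed at half of the diploid donor-parent level.
    ``gedd_specs`` is a list of ``(chromosome, start_index, length,
    shift_log2)`` windows over gene ordinals.
    """

    n_recip_chrom: int = 9
    n_donor_chrom: int = 8
    genes_per_chrom: int = 100
    added_chrom: str = "B1"
    cis_dosage_log2: float = -1.0
    trans_fraction: float = 0.05
    trans_up_prob: float = 0.5
    trans_effect_log2: float = 2.0
    gedd_specs: tuple = ()
    maintenance_fraction: float = 0.5
    reversal_fraction: float = 0.01
    n_replicates: int = 3
    dispersion: float = 0.05
    mean_log_expr: tuple = (3.0, 1.5)
    ortholog_fraction: float = 0.8
    divergence_rate: float = 0.05
    tx_length_range: tuple = (300, 2000)
    library_size: float = 2.0e6
    library_size_jitter: tuple = (0.8, 1.2)
    seed: int = 0

    def validate(self) -> None:
        if self.genes_per_chrom <= 0:
            raise ConfigError("genes_per_chrom must be positive")
        if self.n_recip_chrom <= 0 or self.n_donor_chrom <= 0:
            raise ConfigError("need at least one chromosome per subgenome")
        for name in ("trans_fraction", "trans_up_prob", "maintenance_fraction",
                     "reversal_fraction", "ortholog_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} not in [0, 1]")
        if self.maintenance_fraction + self.reversal_fraction > 1.0:
            raise ConfigError("maintenance_fraction + reversal_fraction > 1")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.trans_effect_log2 <= 0:
            raise ConfigError("trans_effect_log2 must be positive")
        n_donor = self.n_donor_chrom
        donor_names = [f"B{i + 1}" for i in range(n_donor)]
        if self.added_chrom not in donor_names:
            raise ConfigError(
                f"added_chrom {self.added_chrom!r} is not a donor chromosome")
        for chrom, start, length, _shift in self.gedd_specs:
            if start < 0 or length <= 0 or start + length > self.genes_per_chrom:
                raise ConfigError(
                    f"GEDD window ({chrom},{start},{length}) outside chromosome")

    @property
    def recip_chroms(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_recip_chrom)]

    @property
    def donor_chroms(self) -> list[str]:
        return [f"B{i + 1}" for i in range(self.n_donor_chrom)]


@dataclass(frozen=True)
class CountMatrix:
    """Integer read counts, genes x samples, with per-sample group labels."""

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.groups.index):
            raise ValueError("counts columns and group labels disagree")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, group: str) -> pd.Index:
        return self.groups.index[self.groups == group]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases at ``rate``; every hit changes the base."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hits):
        # shift by 1..3 in base space so a mutation never reproduces the base
        idx = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(idx + rng.integers(1, 4, size=len(hits))) % 4]
    return out


def build_genome_pair(config: EffectConfig,
                      with_sequences: bool = False) -> GeneCatalog:
    """Construct the recipient + donor gene catalog (optionally transcripts).

    A configurable fraction of gene pairs (same chromosome ordinal i on
    recipient chromosome Ci / donor chromosome Bi) are linked as orthologs.
    When sequences are requested, donor transcripts are derived from their
    recipient orthologs by point substitution at ``divergence_rate``,
    re-drawn until each pair differs by >= 3 substitutions so the
    <=1-mismatch attribution rule can separate the subgenomes.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0xC0DE])

    rows = []
    for chroms, subg in ((config.recip_chroms, "recipient"),
                         (config.donor_chroms, "donor")):
        for chrom in chroms:
            for i in range(config.genes_per_chrom):
                rows.append((f"{chrom}g{i:04d}", subg, chrom, i))
    table = pd.DataFrame(rows, columns=["gene_id", "subgenome", "chromosome",
                                        "position_index"]).set_index("gene_id")
    lo, hi = config.tx_length_range
    table["tx_length"] = rng.integers(lo, hi + 1, size=len(table))
    table["ortholog_partner"] = pd.Series(pd.NA, index=table.index, dtype="object")

    # pair ordinal i on Ck with ordinal i on Bk for the shared chromosomes
    n_shared = min(config.n_recip_chrom, config.n_donor_chrom)
    for k in range(n_shared):
        rc, dc = f"C{k + 1}", f"B{k + 1}"
        paired = rng.random(config.genes_per_chrom) < config.ortholog_fraction
        for i in np.flatnonzero(paired):
            rid, did = f"{rc}g{i:04d}", f"{dc}g{i:04d}"
            table.at[rid, "ortholog_partner"] = did
            table.at[did, "ortholog_partner"] = rid
            table.at[did, "tx_length"] = table.at[rid, "tx_length"]

    sequences = None
    if with_sequences:
        sequences = {}
        for gid in table.index[table["subgenome"] == "recipient"]:
            seq = rng.choice(_BASES, size=int(table.at[gid, "tx_length"]))
            sequences[gid] = seq.tobytes().decode()
        for gid in table.index[table["subgenome"] == "donor"]:
            partner = table.at[gid, "ortholog_partner"]
            if pd.isna(partner):
                seq = rng.choice(_BASES, size=int(table.at[gid, "tx_length"]))
                sequences[gid] = seq.tobytes().decode()
            else:
                src = np.frombuffer(sequences[partner].encode(), dtype="S1")
                while True:
                    mut = _mutate(rng, src, config.divergence_rate)
                    if int((mut != src).sum()) >= 3:
                        break
                sequences[gid] = mut.tobytes().decode()

    return GeneCatalog(table=table, sequences=sequences)


def _gedd_mask(catalog: GeneCatalog, config: EffectConfig) -> pd.Series:
    """Boolean gene mask plus log2 shift for GEDD windows."""
    shift = pd.Series(0.0, index=catalog.gene_ids)
    t = catalog.table
    for chrom, start, length, s in config.gedd_specs:
        on = (t["chromosome"] == chrom) & \
             (t["position_index"] >= start) & (t["position_index"] < start + length)
        shift[on] += s
    return shift


def simulate_experiment(catalog: GeneCatalog, config: EffectConfig
                        ) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw counts for the four-group MAAL design.

    Returns ``(counts, truth, expected_tpm)`` where ``truth`` has per-gene
    columns ``planted_cis``, ``planted_trans_direction``, ``in_gedd``,
    ``maintained_in_nonmaal`` and ``expected_tpm`` holds the noise-free TPM
    of each group. Identical (catalog, config, seed) give identical output.
    """
    config.validate()
    genes = catalog.gene_ids
    t = catalog.table
    rng = np.random.default_rng([config.seed, 0x5EED])

    mu, sigma = config.mean_log_expr
    base = rng.lognormal(mean=mu, sigma=sigma, size=len(genes))
    base = pd.Series(base, index=genes)

    gedd_shift = _gedd_mask(catalog, config)

    # choose trans-affected recipient genes outside GEDD windows
    recip = catalog.genes_of("recipient")
    eligible = recip[gedd_shift[recip] == 0.0]
    for chrom in config.recip_chroms:
        on_chrom = t.index[t["chromosome"] == chrom]
        gedd_frac = float((gedd_shift[on_chrom] != 0).mean()) if len(on_chrom) else 0
        if config.trans_fraction + gedd_frac > 1.0:
            raise ConfigError(
                f"trans_fraction + GEDD coverage exceeds 1 on {chrom}")
    is_trans = rng.random(len(eligible)) < config.trans_fraction
    trans_genes = eligible[is_trans]
    trans_up = rng.random(len(trans_genes)) < config.trans_up_prob
    trans_dir = pd.Series("none", index=genes, dtype="object")
    trans_dir[trans_genes[trans_up]] = "up"
    trans_dir[trans_genes[~trans_up]] = "down"
    trans_log2 = pd.Series(0.0, index=genes)
    trans_log2[trans_genes[trans_up]] = config.trans_effect_log2
    trans_log2[trans_genes[~trans_up]] = -config.trans_effect_log2

    # nonMAAL fate of each planted trans effect
    u = rng.random(len(trans_genes))
    maintained = u < config.maintenance_fraction
    reversed_ = (~maintained) & \
        (u < config.maintenance_fraction + config.reversal_fraction)
    maint = pd.Series(False, index=genes)
    maint[trans_genes[maintained]] = True
    nonmaal_log2 = pd.Series(0.0, index=genes)
    nonmaal_log2[trans_genes[maintained]] = trans_log2[trans_genes[maintained]]
    nonmaal_log2[trans_genes[reversed_]] = -trans_log2[trans_genes[reversed_]]

    donor = catalog.genes_of("donor")
    on_added = t.index[t["chromosome"] == config.added_chrom]

    # group-wise expected expression (relative transcript abundance)
    expr = pd.DataFrame(0.0, index=genes, columns=list(GROUPS))
    expr.loc[recip, "CC"] = base[recip]
    expr.loc[donor, "BB"] = base[donor]
    expr.loc[recip, "MAAL"] = base[recip] * 2.0 ** (trans_log2[recip] +
                                                    gedd_shift[recip])
    expr.loc[on_added, "MAAL"] = base[on_added] * 2.0 ** config.cis_dosage_log2
    expr.loc[recip, "nonMAAL"] = base[recip] * 2.0 ** nonmaal_log2[recip]

    lengths = t["tx_length"].astype(float)
    cols, groups = [], []
    counts = np.zeros((len(genes), 4 * config.n_replicates), dtype=np.int64)
    j = 0
    for group in GROUPS:
        rel = expr[group] * lengths  # read mass ~ abundance x length
        total = rel.sum()
        for r in range(config.n_replicates):
            lib = config.library_size * rng.uniform(*config.library_size_jitter)
            mean = (rel / total * lib).to_numpy()
            alpha = config.dispersion
            # NB via gamma-Poisson mixture: var = m + alpha m^2
            lam = np.where(mean > 0,
                           rng.gamma(1.0 / alpha, alpha * np.maximum(mean, 1e-300)),
                           0.0)
            counts[:, j] = rng.poisson(lam)
            cols.append(f"{group}_{r + 1}")
            groups.append(group)
            j += 1
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=cols),
        groups=pd.Series(groups, index=cols, name="group"),
    )

    truth = pd.DataFrame({
        "planted_cis": pd.Series(False, index=genes),
        "planted_trans_direction": trans_dir,
        "in_gedd": gedd_shift != 0.0,
        "maintained_in_nonmaal": maint,
    })
    if config.cis_dosage_log2 != 0.0:
        truth.loc[on_added, "planted_cis"] = True

    # noise-free TPM per group over each group's genome support
    etpm = pd.DataFrame(0.0, index=genes, columns=list(GROUPS))
    for group in GROUPS:
        sup = support_for(catalog, group, config.added_chrom)
        rate = expr.loc[sup, group]  # abundance is already per-transcript
        tot = rate.sum()
        if tot > 0:
            etpm.loc[sup, group] = rate / tot * 1e6
    return cm, truth, etpm


def simulate_reads(catalog: GeneCatalog, expression: pd.Series,
                   read_length: int, n_reads: int, error_rate: float,
                   seed: int) -> list[tuple[str, str]]:
    """Sample error-bearing reads from transcript sequences.

    Reads are drawn from transcripts proportional to expression x usable
    length, with uniform start positions and per-base substitution errors.
    Returns ``(read_id, sequence)`` pairs; the read id encodes the true
    source transcript and offset (``<gene>|<offset>|<n>``) so attribution
    can be scored against ground truth.  Transcripts shorter than
    ``read_length`` are skipped with a warning.
    """
    if catalog.sequences is None:
        raise ValueError("catalog has no sequences; build with with_sequences=True")
    rng = np.random.default_rng([seed, 0xFA57])
    gids, weights, seqs = [], [], []
    for gid, x in expression.items():
        seq = catalog.sequences.get(gid)
        if x <= 0 or seq is None:
            continue
        if len(seq) < read_length:
            warnings.warn(f"transcript {gid} shorter than read length; skipped")
            continue
        gids.append(gid)
        weights.append(x * len(seq))
        seqs.append(np.frombuffer(seq.encode(), dtype="S1"))
    if not gids:
        return []
    p = np.asarray(weights, dtype=float)
    p /= p.sum()
    src = rng.choice(len(gids), size=n_reads, p=p)
    reads = []
    for n, i in enumerate(src):
        seq = seqs[i]
        start = int(rng.integers(0, len(seq) - read_length + 1))
        frag = seq[start:start + read_length]
        if error_rate > 0:
            frag = _mutate(rng, frag, error_rate)
        reads.append((f"{gids[i]}|{start}|{n}", frag.tobytes().decode()))
    return reads


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write reads as Phred+33 FASTQ (constant quality 'I')."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
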