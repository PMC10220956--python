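"""End-to-end pipeline orchestration.

``run_pipeline`` drives simulate -> (attribute) -> quantify -> differential
expression -> response analytics -> GEDD scan -> enrichment from a single
config, writes the summary-table suite (direction summary, cis/trans,
ortholog cross-table, strata, maintenance, domains, enrichment) as TSVs
plus a machine-readable ``summary.json``, and is deterministic given the
seed.  In ``counts-in`` mode the simulation stage is replaced by reading a
counts table, catalog and ortholog pairs from disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from maalseq import attribution, diffexpr, enrich, gedd, io, quantify, response
from maalseq.simulate import (
    EffectConfig,
    GeneCatalog,
    build_genome_pair,
    simulate_experiment,
    simulate_reads,
    write_fasta,
    write_fastq,
)

log = logging.getLogger("maalseq")

_EFFECT_FIELDS = {f.name for f in dataclasses.fields(EffectConfig)}


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``mode`` is 'synthetic' (simulate everything; seed mandatory) or
    'counts-in' (counts/catalog/orthologs read from files).  ``simulate``
    holds EffectConfig overrides; ``attribution``, ``de``, ``gedd`` and
    ``enrich`` hold per-stage parameters.
    """

    mode: str = "synthetic"
    outdir: str = "maalseq_run"
    seed: int | None = 0
    counts: str | None = None
    catalog: str | None = None
    orthologs: str | None = None
    simulate: dict = dataclasses.field(default_factory=dict)
    attribution: dict = dataclasses.field(default_factory=dict)
    de: dict = dataclasses.field(default_factory=dict)
    gedd: dict = dataclasses.field(default_factory=dict)
    enrich: dict = dataclasses.field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        errors = []
        known = {f.name for f in dataclasses.fields(cls)}
        for key in d:
            if key not in known:
                errors.append(f"unknown config key {key!r}")
        mode = d.get("mode", "synthetic")
        if mode not in ("synthetic", "counts-in"):
            errors.append(f"mode must be synthetic or counts-in, got {mode!r}")
        if mode == "synthetic" and d.get("seed") is None:
            errors.append("seed is mandatory in synthetic mode")
        if mode == "counts-in":
            for key in ("counts", "catalog"):
                path = d.get(key)
                if path is None:
                    errors.append(f"counts-in mode requires {key!r}")
                elif not Path(path).exists():
                    errors.append(f"{key} file {path!r} does not exist")
        for key in ("simulate", "attribution", "de", "gedd", "enrich"):
            block = d.get(key, {})
            if not isinstance(block, dict):
                errors.append(f"config block {key!r} must be a mapping")
            elif key == "simulate":
                for p in block:
                    if p not in _EFFECT_FIELDS:
                        errors.append(f"unknown simulate parameter {p!r}")
        if errors:
            raise ValueError("invalid config:\n  " + "\n  ".join(errors))
        return cls(**{k: v for k, v in d.items() if k in known})


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    return obj


def _synthetic_annotation(catalog: GeneCatalog, seed: int,
                          n_terms: int = 30, term_size: int = 40) -> dict:
    """Deterministic random term map over recipient genes (null annotation)."""
    rng = np.random.default_rng([seed, 0xE7])
    genes = np.asarray(catalog.genes_of("recipient"))
    return {f"TERM{i:03d}": set(rng.choice(genes, size=min(term_size, len(genes)),
                                           replace=False))
            for i in range(n_terms)}


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write the run directory; returns its path."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    summary: dict = {"mode": config.mode, "seed": config.seed}

    if config.mode == "synthetic":
        eff = EffectConfig(**{**config.simulate, "seed": int(config.seed)})
        do_reads = bool(config.attribution.get("enabled", False))
        catalog = build_genome_pair(eff, with_sequences=do_reads)
        counts, truth, etpm = simulate_experiment(catalog, eff)
        added = eff.added_chrom
        io.write_catalog(catalog, outdir / "catalog.tsv")
        io.write_counts(counts, outdir / "counts.tsv")
        io.write_truth(truth, outdir / "truth.tsv")
        io.write_orthologs(catalog, outdir / "ortholog_pairs.tsv")
        with open(outdir / "config.json", "w") as fh:
            json.dump(_jsonable(dataclasses.asdict(config)), fh, indent=2,
                      default=str)
        if do_reads:
            write_fasta(catalog.sequences, outdir / "transcripts.fasta")
            n_reads = int(config.attribution.get("n_reads", 5000))
            read_len = int(config.attribution.get("read_length", 100))
            err = float(config.attribution.get("error_rate", 0.002))
            expr = etpm["MAAL"]
            reads = simulate_reads(catalog, expr, read_len, n_reads, err,
                                   seed=int(config.seed))
            write_fastq(reads, outdir / "reads.fastq")
            k = attribution.default_k(read_len)
            rec_idx = attribution.build_index(
                {g: catalog.sequences[g] for g in catalog.genes_of("recipient")}, k)
            don_idx = attribution.build_index(
                {g: catalog.sequences[g] for g in catalog.genes_of("donor")}, k)
            _, att_summary = attribution.attribute_reads(
                reads, rec_idx, don_idx,
                max_mismatch=int(config.attribution.get("max_mismatch", 1)))
            summary["attribution"] = att_summary
    else:
        counts = io.read_counts(config.counts)
        catalog = io.read_catalog(config.catalog)
        truth = None
        added = config.simulate.get("added_chrom", "B1")

    tpm = quantify.compute_tpm(counts, catalog, added_chrom=added)
    tpm.to_csv(outdir / "tpm.tsv", sep="\t", index_label="gene_id")

    de_kwargs = {k: config.de[k] for k in ("lfc_cut", "padj_cut", "tpm_cut")
                 if k in config.de}
    recip = catalog.genes_of("recipient")
    on_added = catalog.genes_on(added)
    degs_maal = diffexpr.compare_groups(counts, tpm, "CC", "MAAL",
                                        genes=recip, **de_kwargs)
    degs_nonmaal = diffexpr.compare_groups(counts, tpm, "CC", "nonMAAL",
                                           genes=recip, **de_kwargs)
    # the cis comparison's shared genes all carry the monosomic dosage
    # shift, so anchor its normalization on each sample's full support
    cis_factors = diffexpr.support_average_factors(counts, catalog, added)
    degs_cis = diffexpr.compare_groups(counts, tpm, "BB", "MAAL",
                                       genes=on_added, factors=cis_factors,
                                       **de_kwargs)
    for name, df in (("degs_MAAL_vs_CC", degs_maal),
                     ("degs_nonMAAL_vs_CC", degs_nonmaal),
                     ("degs_MAAL_vs_BB", degs_cis)):
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index_label="gene_id")

    groups = counts.groups
    universe = int((degs_maal["status"] != diffexpr.STATUS_UNEXPRESSED).sum())
    summaries = response.add_chisq_q([
        response.summarize_comparison(degs_maal, universe, "MAAL vs CC"),
        response.summarize_comparison(degs_nonmaal, universe, "nonMAAL vs CC"),
        response.summarize_comparison(
            degs_cis,
            int((degs_cis["status"] != diffexpr.STATUS_UNEXPRESSED).sum()),
            "MAAL vs BB"),
    ])
    table1 = response.summary_table(summaries)
    table1.to_csv(outdir / "table_direction_summary.tsv", sep="\t")
    summary["comparisons"] = _jsonable(table1.reset_index().to_dict("records"))

    part = response.partition_cis_trans(degs_maal, degs_cis, catalog, added)
    part.trans_per_chromosome.to_csv(outdir / "table_trans_per_chromosome.tsv",
                                     sep="\t")
    summary["n_trans_degs"] = int(len(part.trans))
    summary["n_cis_degs"] = int(len(part.cis))

    mean_tpm_cc = tpm.loc[recip, counts.samples_of("CC")].mean(axis=1)
    strata = response.stratify_by_expression(mean_tpm_cc, degs_maal)
    strata.to_csv(outdir / "table_strata.tsv", sep="\t")
    summary["strata"] = _jsonable(strata.reset_index().to_dict("records"))

    maint = response.classify_maintenance(degs_maal, degs_nonmaal)
    maint.to_csv(outdir / "table_maintenance.tsv", sep="\t")
    summary["maintenance"] = _jsonable(maint.reset_index().to_dict("records"))

    pairs = catalog.ortholog_pairs()
    pairs = pairs[pairs["donor_id"].isin(on_added)]
    tpm_bb_diploid = tpm.loc[:, counts.samples_of("BB")].mean(axis=1)
    tpm_maal = tpm.loc[:, counts.samples_of("MAAL")].mean(axis=1)
    cross = response.cross_classify_orthologs(
        degs_maal, degs_cis, pairs,
        tpm_cc=mean_tpm_cc, tpm_bb=tpm_bb_diploid,
        donor_maal_tpm=tpm_maal)
    cross.to_csv(outdir / "table_ortholog_cross.tsv", sep="\t")
    summary["ortholog_cross"] = _jsonable(cross.reset_index().to_dict("records"))

    overlap = response.overlap_coregulated(degs_maal, degs_nonmaal)
    summary["coregulated_overlap"] = _jsonable(
        {k: v for k, v in overlap.items() if k != "shared_genes"})

    gedd_kwargs = {k: config.gedd[k] for k in
                   ("span", "iterations", "shift_threshold", "min_genes")
                   if k in config.gedd}
    domains = gedd.scan_genome(degs_maal, catalog, **gedd_kwargs)
    domains.to_csv(outdir / "domains.tsv", sep="\t", index=False)
    summary["n_gedd_domains"] = int(len(domains))

    if config.mode == "synthetic":
        annot = _synthetic_annotation(catalog, int(config.seed))
    else:
        gmt = config.enrich.get("gmt")
        annot = enrich.read_gmt(gmt) if gmt else {}
    trans_degs = set(part.trans.index)
    expressed = set(
        degs_maal.index[degs_maal["status"] != diffexpr.STATUS_UNEXPRESSED])
    if annot and trans_degs:
        ora = enrich.ora_test(trans_degs & expressed, annot, expressed)
        ora.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        summary["n_enriched_terms"] = int(ora["significant"].sum()) \
            if len(ora) else 0

    link, order = response.cluster_samples(tpm)
    summary["cluster_merge_order"] = _jsonable(link[:, :2].astype(int).tolist())
    summary["cluster_samples"] = order

    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", outdir)
    return outdir
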