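"""Shared fixtures: small synthetic experiments generated at test time."""

import pytest

from maalseq.simulate import EffectConfig, build_genome_pair, simulate_experiment


@pytest.fixture(scope="session")
def small_config():
    """Compact study design: 9+8 chromosomes, 60 genes each, 3 replicates."""
    return EffectConfig(genes_per_chrom=60, trans_fraction=0.05,
                        trans_effect_log2=2.0, seed=11)


@pytest.fixture(scope="session")
def experiment(small_config):
    """(catalog, counts, truth, expected_tpm) for the small design."""
    catalog = build_genome_pair(small_config)
    counts, truth, etpm = simulate_experiment(catalog, small_config)
    return catalog, counts, truth, etpm


@pytest.fixture(scope="session")
def seq_experiment():
    """Tiny genome pair with transcript sequences, for attribution tests."""
    cfg = EffectConfig(n_recip_chrom=2, n_donor_chrom=2, genes_per_chrom=10,
                       ortholog_fraction=1.0, divergence_rate=0.05,
                       tx_length_range=(300, 500), seed=7)
    catalog = build_genome_pair(cfg, with_sequences=True)
    return cfg, catalog
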