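"""Shared configuration for the analysis scripts.

One synthetic MAAL experiment emulating the study design: recipient
parent CC (3 reps), donor parent BB (3 reps), one MAAL carrying donor
chromosome B1 (3 reps) and its derived euploid sibling (3 reps); 9 + 8
chromosomes at 300 genes each, 5% trans effects of |log2FC| = 2, the
monosomic chromosome at half the diploid donor dose, one planted
80-gene dysregulation domain, and 50% maintenance in the derived euploid.
"""

from pathlib import Path

from maalseq.simulate import EffectConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

SEED = 1

CONFIG = EffectConfig(
    genes_per_chrom=300,
    trans_fraction=0.05,
    trans_effect_log2=2.0,
    cis_dosage_log2=-1.0,
    maintenance_fraction=0.5,
    reversal_fraction=0.01,
    gedd_specs=(("C2", 60, 80, 1.0),),
    seed=SEED,
)

ADDED = CONFIG.added_chrom
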