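# Methods

## The experimental design being modeled

A monosomic alien addition line (MAAL) carries a recipient species'
complete diploid genome plus one chromosome from a donor species. Four
sample groups with three biological replicates each anchor every
comparison: the recipient parent (`CC`), the donor parent (`BB`), the
MAAL, and a derived euploid sibling (`nonMAAL`) that has lost the alien
chromosome again. *Trans* effects are expression changes of recipient
genes induced by the alien chromosome (MAAL vs CC); *cis* effects are
changes of the alien chromosome's own genes relative to their diploid
context (MAAL vs BB); *maintenance* is the persistence of a MAAL-induced
change after the chromosome is lost (nonMAAL vs CC).

## Synthetic data generator

`simulate.build_genome_pair` lays out `n_recip_chrom` (default 9) and
`n_donor_chrom` (default 8) chromosomes with `genes_per_chrom` genes
each, transcript lengths uniform on 300–2000 bp, and a configurable
fraction (default 0.8) of recipient/donor gene pairs linked as
one-to-one orthologs. When sequences are requested, donor transcripts
are derived from their recipient orthologs by point substitution at
`divergence_rate` (default 0.05 per base, redrawn until ≥ 3
substitutions per pair so a 1-mismatch budget can in principle separate
the subgenomes).

`simulate.simulate_experiment` draws baseline expression
log-normal(μ=3, σ=1.5) per gene and counts from a gamma–Poisson
(negative-binomial) mixture with common dispersion α (default 0.05,
var = m + αm²), around means proportional to expression × length,
scaled to a library of 2×10⁶ ± 20 % reads. Planted effects:

* the added chromosome's genes in the MAAL at `2^cis_dosage_log2` of
  the diploid BB level (default −1 log2, the monosomic halving — the
  study only states the direction qualitatively, so the magnitude is a
  modeling choice and is configurable);
* a `trans_fraction` (default 0.05) of recipient genes outside GEDD
  windows shifted by ±`trans_effect_log2` (default 2), direction
  Bernoulli(`trans_up_prob`);
* GEDD windows adding a shared log2 shift to a contiguous run of genes
  (MAAL only);
* in the derived euploid each planted trans effect is maintained with
  probability `maintenance_fraction`, direction-reversed with
  probability `reversal_fraction`, and reverted otherwise (mutually
  exclusive draws).

Everything planted is recorded in a per-gene truth table. The generator
emulates group structure, dosage, overdispersion and library-size
variation; it does **not** model isoforms, paired-end reads, indels,
GC/length biases, batch effects, or correlated co-expression — so
passing recovery tests demonstrates correctness of the analytics under
the stated model, not robustness to every artifact of real libraries.

## Read attribution

A read is labeled `donor` iff it has ≥ 1 donor placement within the
mismatch budget (default 1), exactly one donor transcript attains the
best placement, and no recipient placement exists within the budget;
`recipient` symmetrically; `ambiguous` when both subgenomes accept it or
the best placement ties across transcripts of one subgenome; `unmapped`
otherwise. Candidates come from exact k-mer seeds (k = ⌊L/2⌋ capped at
31): with budget 1, two disjoint seeds guarantee at least one exact seed
at any true placement (pigeonhole), so seeding plus full Hamming
verification at the implied offset is exhaustive. No indels are
modeled; reverse-complement lookup is optional (`both_strands`). A
brute-force scanner over every offset of every transcript provides the
independent oracle in tests (100 % label agreement required).

Two accuracy caveats follow from the model rather than the code: a read
carrying ≥ 2 sequencing errors exceeds the budget and is unmappable by
construction (≈ 3.7 % of 150-bp reads at error rate 0.002), and at
divergence 0.05 about 3.7 % of 100-bp windows — but only ≈ 0.4 % of
150-bp windows — contain ≤ 1 diagnostic substitution and are correctly
ambiguous. Attribution accuracy is therefore assessed on 150-bp reads
(the study design's read length), with recall measured over
budget-attributable reads.

## TPM and the expressed universe

TPM is computed per sample with the denominator restricted to the
sample's genome support (recipient genes for CC/nonMAAL, donor genes for
BB, recipient + added chromosome for the MAAL), so columns are
comparable across ploidies; each column sums to 10⁶ over its support. A
gene is *expressed* in a group when the group's arithmetic-mean TPM
exceeds 1 (strict). The DEG expression filter passes when **either**
group's mean is ≥ 1, keeping genes expressed in only one condition.

## Differential expression

Size factors are DESeq-style median-of-ratios over genes covered in all
samples (total-count fallback with a warning). Per gene, dispersion is
the precision-weighted method-of-moments estimate per group,
α̂ = max(0, (s²−m)/m²), **moderated** toward the across-genes median with
a fixed prior weight of 6 pseudo-replicates against the residual df —
the raw estimate at n = 3 is far too noisy to test against. The Wald
statistic is the difference of log pseudo-counted (c = 0.5) normalized
group means over the delta-method standard error
√(Σ_groups (1/n)(1/(m+c) + α̂)), referred to a t distribution with
prior + residual df (10 at 3 vs 3). The t reference replaces a normal
one deliberately: with plug-in dispersion the normal reference rejects
~11 % of null genes at the 5 % level, while the moderated-t combination
is calibrated (empirical type-I ≈ 0.04 across dispersions 0.05–0.3)
with essentially full power for |log2FC| = 2 at m = 100, n = 3. BH
adjustment is applied within the expressed universe only; status
boundaries are inclusive for |log2FC| ≥ 1 and strict for Padj < 0.05.

**Cis-comparison normalization.** The genes shared between a MAAL and
the donor parent are exactly the genes carrying the genome-wide
monosomic dosage shift, so median-of-ratios over them absorbs the shift
completely — the dosage is unidentifiable without an external anchor.
`support_average_factors` supplies that anchor: each sample is scaled by
its average count per support gene, which is valid under the assumption
that the average per-gene output per genome copy is constant across
samples. Within the simulator this recovers the planted dosage in
expectation; the estimate carries a small attenuation (≈ 0.1 log2 at
dosage −1.5) because the added chromosome's own reduced mass enters the
MAAL denominator. The same assumption is what licenses any absolute
dosage statement about real MAAL data.

## Response analytics

Every emitted table's percentages recompute exactly (round-half-even to
2 dp) from its own counts. Direction bias per comparison is a 1-df χ²
goodness-of-fit of (up, down) against 1:1 without continuity correction,
with BH q-values across a run's comparisons. Expression strata on the
recipient parent's mean TPM are half-open — [1,10), [10,100), [100,∞) —
because the verbal "1 < TPM < 10 / 10 < TPM < 100 / TPM > 100"
convention leaves the boundaries unassigned. Maintenance requires the
nonMAAL comparison to pass the full DEG filter in the same direction;
`opposite` is a DEG in the other direction; everything else is
`unchanged` (three mutually exclusive states). Ortholog cross-tables
first drop pairs below TPM 1 in either parental genome; the
"unexpressed" partner column then means below threshold on the MAAL's
single chromosome (the dosage-relevant reading; a parent-side reading is
available by omitting `donor_maal_tpm`). Sample clustering uses
1 − Pearson r of log2(TPM+1) profiles over genes expressed anywhere,
average linkage, samples pre-sorted by id for deterministic ties.

## GEDD scanning

Fold-change tracks are ordered by catalog gene ordinal (not base pairs),
smoothed by robust lowess — tricube-weighted local linear fits over the
nearest ⌈span·n⌉ neighbours with 3 bisquare robustifying iterations
(statsmodels' implementation of the same estimator family as R's
`lowess`) — with untested genes interpolated linearly. Domains are
maximal constant-sign runs with |smoothed| ≥ 0.5 spanning ≥ 20 genes.
The smoother's span (0.2), the shift threshold and the minimum size are
the operative tunables, chosen for planted-window recovery (boundary
Jaccard ≥ 0.7 for an 80-gene +1.0-log2 window under σ = 0.5 noise) with
≤ 0.5 false domains per null genome, and all three are CLI-exposed. A
span below 2/n on a sparsely tested chromosome is widened to keep the
local window at two fit points.

## Enrichment

One-sided over-representation only: p = P(X ≥ k) from the
hypergeometric law for overlap k, term size K, set size n, universe N,
enrich factor (k/n)/(K/N), BH across terms. The universe defaults to
the expressed genes of the comparison. No ontology structure, no live
databases.

## Problem sizes and determinism

Default analysis scale is 9 + 8 chromosomes × 300 genes (5 100 genes,
12 samples), which runs end-to-end in seconds; tests use 60–300 genes
per chromosome, 10 000 null genes for calibration checks, 3 000 reads
for oracle-equivalence, and 50 seeds for null-specificity — sizes chosen
so Monte-Carlo noise sits well inside each criterion's tolerance.
Statistical recovery checks that compare a recovered fraction with a
planted one (e.g. maintenance 50 % ± 10 points) plant enough genes
(≈ 270) that binomial planting noise (sd ≈ 3 points) cannot dominate
the comparison. All randomness flows from explicit integer seeds;
identical (catalog, config, seed) give byte-identical counts, truth
tables, reads and summary JSON.

## Known limitations

* The NB test has no GLM covariates, no outlier handling, and no
  trended dispersion; it is adequate for the two-group n = 3 design it
  serves, not a general DE framework.
* Support-average normalization's constant-output assumption is
  untestable from expression data alone; absolute dosage claims on real
  data inherit it.
* The attribution index is exhaustive only for mismatch budgets below
  the number of disjoint seeds per read (guaranteed for the default
  budget 1).
* GEDD calling operationalizes a visual judgment; boundary placement
  depends on the span and threshold, and only the defaults are tuned.
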