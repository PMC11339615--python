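# Methods

This note documents the statistical procedures, the synthetic-cohort
generator, the numerical conventions, and the design choices made where a
convention was genuinely open.

## Misexpression as outlier analysis

Bulk RNA-seq of a large cohort yields a gene × sample TPM matrix. Most
genes are either robustly expressed or essentially silent, giving a
bimodal distribution of per-gene "percentage of samples with TPM > 0.1".
The pipeline focuses on the silent mode: a gene is **inactive** when it
has TPM > 0.1 in strictly fewer than 5% of samples. A **misexpression
event** is an (inactive gene, sample) pair with TPM > 0.5 and per-gene
Z-score > 2. The Z-score gate makes events comparable across genes with
different baseline leakiness; the TPM gate removes events that are
extreme only relative to a near-zero baseline. All four inequalities are
strict, exactly as the thresholds are written.

Z-scores use the sample standard deviation (ddof = 1). Genes with zero
variance carry an undefined flag and can never be called. Whether the
covariate filter runs before or after Z-scoring does not change per-gene
Z values; the pipeline filters first and scores the retained genes.

### Sample and gene QC

*Global expression outliers.* For every gene with any non-zero TPM, each
sample attaining the per-gene maximum contributes one "top expression
event" to its count; ties credit every tied sample. Samples with
≥ 5 × (non-zero genes / samples) such events are removed. At the scale of
57,555 non-zero genes and 4,731 samples this cutoff is 60.8 events, so
retained samples can have at most 60.

*Covariate-correlated genes.* Each inactive gene is Spearman-correlated
with every covariate (average ranks for ties; large-sample t
approximation for p — exact permutation adds nothing at cohort n).
Benjamini–Hochberg FDR is applied jointly across all gene × covariate
tests, a single decision family. A gene is removed when any pair has
|ρ| > 0.2 and adjusted p < 0.05. Categorical covariates are rank-encoded;
constant covariates are skipped with a warning.

## Rare-variant enrichment

For a given Z threshold the **misexpression group** contains all
qualifying events and the **control group** all remaining (gene, sample)
pairs restricted to the same genes, so both arms share an identical gene
set and the contrast reflects genotype, not gene composition. An event
"has a variant" when its sample carries ≥ 1 variant of the tested
class/MAF bin within the tested region (binary per event; this matches
the proportion definition of the risk ratio).

The risk ratio is RR = (a/n₁)/(c/n₂) with a two-sided Fisher exact
p-value (sum of table probabilities not exceeding the observed table's)
and Wald CI `exp(ln RR ± 1.96·√(1/a − 1/n₁ + 1/c − 1/n₂))`. When a or c
is zero, 0.5 is added to all four table cells for the CI only; the
Fisher p is untouched. An independent enumeration oracle
(`fisher_exact_oracle`, direct log-hypergeometric summation) backs the
test suite.

*Distance windows.* Variants are assigned to the gene body (any overlap)
or to one of five 200 kb windows per side up to 1 Mb, measured from the
variant's gene-nearest edge with gap distance (overlap ⇒ 0; "within X kb"
means gap ≤ X). Windows are strand-aware — upstream means 5′ of the TSS —
because enrichment is asymmetric around genes. A variant spanning a
window boundary belongs to the gene-nearest window, making the assignment
a partition. MAF bins are half-open with rare = [0, 1%).

*Consequences.* Each SV carries optional per-gene VEP consequence terms.
The most severe consequence on the tested gene is used; a variant with no
consequence on that gene falls back to its overall most severe term only
if that term is regulatory or intergenic (TFBS/regulatory-region
ablation, amplification or variant, intergenic), otherwise it is labelled
"no predicted effect". The severity ranking ships as the published
Ensembl VEP consequence ordering.

*Logistic feature enrichment.* Gene-level or SV-level features are
Z-transformed over the analysis set and modelled one at a time:
logit(P(outcome)) = β₀ + β₁·feature (+ covariates, e.g. log₁₀ SV length).
CIs are β ± 1.96·SE; Bonferroni spans the features tested. Perfect
separation and non-convergence are flagged, never silently reported.
Feature standardisation for the SV comparisons uses the pooled
associated + control distribution.

## SV association and mechanisms

A rare (MAF < 1%) SV within ±200 kb of an ever-misexpressed inactive gene
is **associated** when carrier median TPM > 0.5, carrier median Z > 2,
and no carrier has TPM < 0.1 (the floor is `exclude iff TPM < 0.1`,
mirroring the wording of the rule). One association row is emitted per
qualifying (gene, SV) pair. **Control** SVs show maximum TPM = 0 at every
inactive gene in their window; the sample scope of that maximum is a
config switch (`carriers`, the default — the samples the SV could act
in — or `all`). SVs with no inactive gene in the window are neither.
Inversions and MEIs flow through association but are excluded from
group-wise length/score comparisons when their numbers are small.

*Position classes.* contains_gene / internal / partial_5′ / partial_3′ /
upstream / downstream, strand-aware, exhaustive and mutually exclusive
for same-chromosome pairs.

*Readthrough.* Deletion candidates must (1) lie strand-aware upstream of
(and not overlap) the misexpressed gene, (2) cover the TTS but not the
TSS of a same-strand donor gene with median TPM > 0.5 while overlapping a
terminal-exon polyA site, and (3) leave no expressed same-strand gene in
the predicted readthrough region; with several associated genes the
closest is kept. Duplication candidates must contain the entire
misexpressed gene and cover the 5′ (not 3′) terminus of a downstream
same-strand expressed donor, with the same intervening-region rule; the
gene with the shortest expected region is kept. "Partially overlaps a
gene's 3′ end" is operationalised as covering the TTS but not the TSS
(mirrored for 5′). The readthrough region runs from the misexpressed
gene's 5′ boundary to the SV breakpoint nearest that boundary — the same
rule for DEL and DUP, measured in reference coordinates.

Over that region, per sample: FPKM = count / (kb × depth/10⁶) and FBNC =
covered bases / region length, counting only fragments on the region's
strand. Both are Z-scored across all samples per region; a sample is
called a readthrough carrier when both Z > 2 (strict). FPKM measures
depth, FBNC breadth; requiring both guards against a few high-coverage
fragments or diffuse background.

*3D-architecture candidates.* Associated SVs without another mechanism
qualify when they overlap a shared TAD boundary and a CTCF-only cCRE;
duplications must additionally contain the misexpressed gene and overlap
an Enh/EnhG chromatin state, deletions must not overlap the gene.

*Mechanism summary.* One primary mechanism per (gene, SV) with precedence
readthrough > fusion > inversion > 3D candidate > unknown. Fusion calls
are input-only (an external fusion-transcript table); the package does
not re-implement fusion discovery.

## Synthetic cohort generator

The generator emulates the features of a real cohort the pipeline relies
on, with full ground truth. Defaults: 300 samples, 2,000 genes on 4
chromosomes of 10 Mb, 60% inactive.

- **Active genes** draw a per-gene baseline from LogNormal(log-mean 2.0,
  log-SD 1.0) on the TPM scale with log-SD 0.3 sample noise — a bimodal
  active/inactive expression landscape.
- **Leak expression**: each inactive gene-sample pair has probability
  0.02 of TPM ~ U(0, 0.1), below both the activity and event gates.
- **Background (non-genetic) misexpression** has marginal rate 5 × 10⁻⁴
  per inactive pair with TPM ~ U(0.6, 50), generated as gene-level bursts
  (1 + Poisson(2) samples per affected gene, capped below the 5%
  inactivity boundary). The burst structure matters: with exact-zero
  baselines an isolated outlier always attains Z ≈ √n regardless of
  magnitude, so only recurrence across samples produces the spectrum of
  event Z-scores seen in real cohorts, where low Z thresholds admit many
  more non-genetic events than high ones.
- **SV-driven events** (30): a rare SV (MAF < 1%, 1–3 carriers, length
  5–50 kb, gap ≤ 150 kb from its target inactive gene, class mixed over
  DEL/DUP/INV/MEI) whose carriers express the target at TPM ~ U(1, 100).
- **Null rare SVs** (500) are placed uniformly; their carriers are forced
  silent at every inactive gene within ±200 kb, making them *bona fide*
  control SVs.
- **Covariate-driven genes** (5) follow a rank-scaled covariate plus
  uniform noise mixed to a target Spearman ρ ≈ 0.5, mapped below TPM 0.1
  so they stay inactive yet removable by the covariate filter.
- **Global-outlier samples** (3) are set to the strict per-gene maximum
  in twice the removal-cutoff number of active genes.
- **Readthrough loci** (4, alternating DEL/DUP and strand) are built in
  reserved chromosome tails with the exact geometry the selection
  criteria test, carrier-specific same-strand fragment tiling over the
  readthrough region, and sparse random background fragments elsewhere.

Gene placement is uniform with a minimum 15 kb inter-gene gap (2,000
genes of ≤ 2 kb on 40 Mb cannot honour a larger gap; the layout is
validated and an infeasible configuration raises before sampling).
Determinism: one `numpy` Generator seeded from the config drives every
draw in fixed order, so identical configs give byte-identical bundles.

What the generator does **not** emulate: read-level sequences, linkage
between variants, count noise (TPM is simulated directly; counts are
derived only where the TPM conversion itself is under test), multi-tissue
structure, and continuous low-grade expression of inactive genes beyond
the uniform leak. Passing tests therefore demonstrate correctness of the
decision rules and statistics under these conditions, not performance on
the full noise structure of real cohorts.

## Scales and numerical choices

- The enrichment-scan Z grid on synthetic cohorts is {2, 10, 15}: the
  largest attainable Z for a single-sample outlier is √n (1 − 1/n) ≈ 17.3
  at n = 300, so 15 plays the role that a threshold of 40 plays in a
  cohort of thousands — the regime where only the most extreme events
  survive.
- Fisher p-values come from `scipy.stats.fisher_exact`; the test suite
  checks them against an independent enumeration oracle exhaustively for
  small tables and on random tables with margins up to 40.
- Simulation-backed tests use 10 seeded cohorts (300 × 2,000); logistic
  calibration uses 20 seeds at n = 2,000. These sizes give stable
  averages for every asserted quantity while keeping the full suite
  under a minute of simulation time.
- Carrier = any sample with ≥ 1 alternate allele; MAF is folded to ≤ 0.5.
- Internal coordinates are 0-based half-open everywhere; GTF and VCF are
  converted on read and write. Interval distance is the gap in bp, zero
  on overlap or abutment.

## Known limitations

- Control-SV scope, readthrough measurement on the reference allele for
  duplications, and tie handling in top-expression events are documented
  conventions, not uniquely determined by the problem.
- The logistic enrichment flags separation rather than switching to a
  penalised fit; fully separated features are reported unconverged.
- The readthrough caller assumes fragment tables already restricted to
  candidate regions; genome-wide fragment extraction from BAM/CRAM is
  out of scope (inputs are BED).
- Fusion discovery, VEP execution, SV calling and external score
  computation (CADD-SV, PhyloP, gnomAD constraint, gwRVIS) are consumed
  as inputs, never re-implemented.
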