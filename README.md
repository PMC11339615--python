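# misexpression

Genome-wide detection of **gene misexpression** — the aberrant transcription
of a gene in a tissue where it is normally inactive — from cohort bulk
RNA-seq, and quantification of its association with nearby **rare structural
variants** (SVs).

The package is aimed at statistical geneticists and transcriptomics analysts
working with paired RNA-seq / WGS cohorts. It treats misexpression as a type
of transcriptomic outlier analysis: instead of flagging outliers in highly
expressed genes, it asks when genes that are essentially silent across a
cohort suddenly show clear expression in a handful of samples, and whether a
rare deletion, duplication, inversion or mobile element insertion nearby can
explain it.

## Method

1. **Quantification & QC.** Gene counts are converted to TPM using
   merged-exon lengths (`TPM_g = (c_g / L_g) / Σ_j (c_j / L_j) × 10⁶`).
   Samples with ≥ 5× the expected number of per-gene maximum-expression
   events (expected = genes/samples) are removed as global expression
   outliers.
2. **Inactive genes.** A gene is *inactive* when it has TPM > 0.1 in fewer
   than 5% of samples (both comparisons strict). Genes whose expression
   tracks any measured covariate (|Spearman ρ| > 0.2, BH-FDR p < 0.05,
   jointly across all gene × covariate tests) are removed.
3. **Misexpression events.** TPM values of each inactive gene are Z-scored
   across samples (sample SD, ddof = 1); an (inactive gene, sample) pair is
   a misexpression event when TPM > 0.5 **and** Z > 2.
4. **Rare-variant enrichment.** For a Z threshold, the misexpression group
   holds all qualifying events and the control group all remaining pairs of
   the *same* genes. Enrichment is the risk ratio
   RR = (a/n₁)/(c/n₂) of carrying a qualifying variant near the gene
   (gene ± flank, or strand-aware 200 kb distance windows up to ±1 Mb),
   with a two-sided Fisher exact p, Wald CI on the log scale, and
   Bonferroni correction over the scan. MAF bins: rare [0, 1%),
   low [1%, 5%), common [5%, 10%) and [10%, 50%].
5. **SV association & properties.** A rare (MAF < 1%) SV within ±200 kb of
   an ever-misexpressed inactive gene is *misexpression-associated* when
   its carriers' median TPM > 0.5, median Z > 2 and no carrier has
   TPM < 0.1; *control* SVs have zero TPM at every inactive gene in their
   window. Groups are compared by length (one-sided Mann-Whitney) and by
   genomic-score / regulatory-overlap enrichment in length-adjusted
   logistic regressions.
6. **Mechanisms.** Transcriptional readthrough candidates are deletions
   that remove an expressed gene's termination site (and polyA site)
   upstream of the misexpressed gene, or tandem duplications that place an
   entire inactive gene downstream of an expressed promoter. Readthrough
   is verified from strand-aware fragment coverage over the predicted
   region via FPKM (depth) and FBNC (fraction of bases with non-zero
   coverage, breadth), both Z-scored across the cohort; a sample is called
   when FPKM Z > 2 and FBNC Z > 2. Remaining associated SVs can qualify as
   3D-chromatin-architecture candidates via TAD-boundary and CTCF-only
   cCRE overlap rules.

A fully seeded synthetic-cohort generator (`misexpression.simulate`)
produces annotation, TPM matrix, covariates, SV callset, readthrough loci
with strand-aware fragment coverage, and a ground-truth table, so every
stage is testable without access to restricted cohort data.

## Worked example

```python
from misexpression import MisexpressionModel, SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(seed=1))
results = MisexpressionModel(cohort.tpm, cohort.covariates, cohort.genes).fit()
print(results.summary())
scan = results.enrichment_scan({"SV": cohort.svs}, z_grid=(2, 10, 15),
                               flank_bp=200_000)
print(scan[["z_thr", "a", "n1", "c", "n2", "rr", "p_adj"]])
```

Output:

```
Misexpression cohort summary
============================
samples (post-QC):          297  (removed 3 global outliers)
inactive genes:             1199  (removed 5 covariate-correlated)
misexpression events:       246  (Z > 2.0, TPM > 0.5)
gene-sample pairs:          356103
% pairs misexpressed:       0.0691
% genes misexpressed:       8.3
% samples with an event:    54.5
median events per sample:   1.0
   z_thr   a   n1     c     n2         rr             p         p_adj
0      2  63  246  1082  29157   6.901143  1.182952e-33  3.548856e-33
1     10  38  124  1092  28685   8.049968  9.108941e-24  2.732682e-23
2     15  25   40   500  11840  14.800000  1.687321e-24  5.061964e-24
```

The three samples injected as global outliers are removed, all five
covariate-driven genes are filtered, the fraction of misexpressed
gene-sample pairs is sparse (0.07%), and rare SVs near misexpressed genes
show a strong risk-ratio enrichment that grows with the misexpression
Z-score threshold.

The same pipeline is available from the shell:

```bash
misexpression simulate --seed 1 --out workdir
misexpression all --workdir workdir
```

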