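# pantemap

Population-scale transposable-element (TE) analysis for pangenome
projects: build a pan-TE presence/absence map from per-assembly TE
annotations and structural-variant (SV) bubbles, date LTR
retrotransposon insertions, classify TE effects on nearby gene
expression, run TE-based GWAS/eQTL scans with LD clumping, and
summarize haplotype combinations — plus synthetic-data generators with
a ground-truth channel so every stage is testable without external
data.

It is written for researchers working with TE insertion polymorphisms
(TIPs) in crop or plant panels — the motivating system is a rapeseed
(*Brassica napus*) accession panel genotyped against a multi-assembly
pangenome — who want the population-genetic bookkeeping around TIPs as
a tested, importable library rather than a chain of one-off scripts.

## What it computes

- **Pan-TE map** (`pantemap.pante`): SV alleles are typed by REF/ALT
  length (DEL: REF ≥ 50 bp & ALT = 1 bp; INS: the converse; MNP:
  otherwise ≥ 50 bp); a TE is linked to the SV allele whose segment
  covers strictly more than half of the TE, and a TE linked to several
  SVs gets the minimum carrier-allele dosage per accession. Filters:
  missing ≤ 0.5, MAF > 0.05, het < 0.5.
- **LTR clock** (`pantemap.ltr`): terminal-repeat divergence
  K = −(3/4)·ln(1 − 4p/3) (Jukes–Cantor) and insertion age
  T = K/(2r) at r = 1.5×10⁻⁸ substitutions/site/year; burst profiles
  per superfamily with a young-fraction summary.
- **Expression effects** (`pantemap.expression`): TPM filter
  (< 0.01 in > 80% of samples), TMM normalization factors, nearest-gene
  assignment, and the 1.5× rule — carriers ≥ 1.5× non-carriers is
  promotive, ≤ 1/1.5 suppressive — with cross-stage consistency sets.
- **Association engine** (`pantemap.association`): per-variant OLS with
  PC covariates, the 1/n significance rule (−log₁₀ p* = log₁₀ n),
  cis/trans partitioning at an inclusive 1 Mb window, greedy LD
  clumping (p1 = 10⁻⁵, 100 kb, r² ≥ 0.1) and locus merging.
- **Haplotype combinations** (`pantemap.haplotypes`): joint
  presence/absence states of focal variants, frequency-thresholded
  combinations (> 0.05), phenotype/ecotype summaries with
  integer-truncated percentages.
- **Pangenome occupancy** (`pantemap.pangene`): core / softcore /
  dispensable / private gene-cluster classes and random-subsampling
  pan/core growth curves; a Wilcoxon rank-sum utility.
- **Synthetic data** (`pantemap.synthetic`): genotypes
  (Hardy–Weinberg with optional inbreeding F, configurable fixed
  fraction and MAF law), expression with planted multiplicative
  effects, phenotypes with planted QTLs at a target heritability,
  interval layouts with known TE↔SV links, and LTR pairs diverged for
  known times.

## Worked example

Classify planted expression effects (from `examples/03_expression_effects.py`):

```python
from pantemap import (classify_effects, effect_summary,
                      simulate_expression, simulate_genotypes)

gm, _ = simulate_genotypes(n_accessions=300, n_tes=200,
                           fixed_fraction=0.0,
                           maf_law=("constant", 0.3), seed=5)
planted = {t: 2.0 for t in list(gm.variants)[:100]}   # fold-2 effects
mats, truth = simulate_expression(gm, planted, noise_cv=0.2, stages=2,
                                  seed=5)
calls = {s: classify_effects(gm, em, truth.te_target_gene, stage=s)
         for s, em in mats.items()}
summary = effect_summary(calls)
```

This prints:

```
stage1: 100 promotive, 0 suppressive, 100 none -> 100.00% promotive among regulatory TEs
stage2: 100 promotive, 0 suppressive, 100 none -> 100.00% promotive among regulatory TEs
consistently promotive across both stages: 100 (planted: 100)
```

All 100 planted fold-2 TEs are recovered as promotive at both
developmental stages and none of the 100 null TEs is miscalled — the
sensitivity/specificity the 1.5× rule achieves under multiplicative
noise with CV 0.2 at n = 300.

The other scripts in `examples/` demonstrate the pan-TE map
(`01_pante_map.py`), LTR dating (`02_ltr_dating.py`), GWAS with
clumping (`04_gwas_clumping.py`), haplotype combinations
(`05_haplotype_combos.py`) and pangenome occupancy/growth
(`06_pangenome.py`). A thin CLI chains the stages end to end:

```bash
pantemap run --seed 1 --outdir run1        # all stages + manifest
pantemap simulate --seed 1 --outdir run1   # or stage by stage
pantemap pante build --seed 1 --outdir run1
```

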