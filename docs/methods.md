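# Methods

This note documents the models and procedures implemented in `pantemap`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Problem setting

Transposable-element insertion polymorphisms (TIPs) are presence/absence
variants of mobile elements segregating in a population — in the
motivating setting, a panel of *Brassica napus* (rapeseed) accessions
genotyped against a multi-assembly pangenome. TEs are not called from
reads directly; they are annotated per assembly and then tied to the
structural-variant (SV) bubbles of the pangenome graph, inheriting the
bubbles' population genotypes. Downstream, TIP genotypes behave like any
biallelic marker: they can be tested against expression (TE-eQTL),
against phenotypes (TE-GWAS), and combined into haplotypes.

## Pan-TE map construction

**SV typing.** An allele is a deletion if REF ≥ 50 bp and ALT = 1 bp, an
insertion if REF = 1 bp and ALT ≥ 50 bp, complex (MNP) if any side is
≥ 50 bp otherwise, and `small` (excluded) when both sides are < 50 bp.

**TE ↔ SV association.** A TE annotated on genome *g* is linked to an SV
when an allele segment of that SV — the reference anchor for the REF
allele, or genome *g*'s alternative placement for the ALT allele —
covers *strictly more than half* of the TE's length. The overlap
denominator is always the TE length; the bound is strict, so a TE
exactly half-covered is not linked. The carrier allele records which
allele hosts the TE (ALT for insertion-borne, REF for deletion-borne
TEs); the TE dosage of an accession is the dosage of that carrier
allele. Coordinates are 0-based half-open internally; GFF3/VCF-style I/O
converts at the boundary.

**Genotype merging.** When one TE is linked to several SVs, the merged
TE dosage per accession is the *minimum* carrier-allele dosage over the
linked SVs, with any missing linked call making the merged call missing.
Rationale: a TE spanning several hosting segments requires all of them,
so the conservative intersection is the default; the union alternative
(`rule="any"`, maximum) is available because the upstream description of
"merging" does not pin the semantics down.

**Filters.** Variants are kept with missing fraction ≤ 0.5, MAF
strictly > 0.05 (when requested), and heterozygote fraction strictly
< 0.5 (when requested). MAF is computed over non-missing calls as the
dosage sum divided by 2N, folded to [0, 0.5]. A locus is *fixed* when a
single allele is observed among its non-missing calls; fixed and
polymorphic fractions are reported over loci with at least one call.

## LTR insertion-time clock

At insertion the 5′ and 3′ terminal repeats of an intact LTR element are
identical; each accumulates substitutions independently afterwards. With
per-site mismatch fraction *p* between the two repeats, the
Jukes–Cantor-corrected divergence is K = −(3/4)·ln(1 − 4p/3)
(substitutions/site; saturation error at p ≥ 0.75), and the insertion
age is T = K / (2r) with r = 1.5×10⁻⁸ substitutions/site/year, the
synonymous-site rate conventionally used in Brassica (so K = 0.03 dates
an element to exactly 1 Myr, and K = 2.25×10⁻⁴ to the ≈7,500-year
allopolyploidy age scale of rapeseed). The upstream tooling that
produces pass-list divergences applies a correction it does not restate,
so both `jc` (default) and `raw` modes are exposed; raw mode
underestimates older ages. Ambiguity codes are skipped in the mismatch
count. Burst profiles bin ages per superfamily (Copia, Gypsy) with
unclassified elements counted in the "Total" group only, and report the
fraction younger than a cutoff (default 1 Myr).

## Expression effects

Genes expressed below 0.01 TPM in more than 80% of samples are removed
before any expression analysis. TMM normalization factors follow the
trimmed-mean-of-M-values scheme: reference library by upper-quartile
proximity to the mean upper quartile, M/A values over genes positive in
both libraries, 30%/5% two-sided trimming of M and A, inverse-variance
(delta-method) weights, geometric-mean-1 rescaling. Trimming uses
quantile bands rather than rank counts; agreement with edgeR's
`calcNormFactors` is within 0.2% relative on realistic instances and is
enforced at 2% in a cross-check test.

Each TE is assigned its nearest gene on the same contig: distance 0 when
overlapping the gene body, otherwise the gap to the nearest gene
boundary, signed negative upstream / positive downstream relative to
gene strand. Ties on gap break by smaller distance to the transcription
start, then lexicographic gene id — a deterministic convention, not a
biological claim.

The effect classifier compares carrier accessions (any non-zero dosage;
dominant coding, since presence/absence is the unit of interest) with
non-carriers on raw TPM means: ratio (mean_with + ε)/(mean_without + ε)
with ε = 0.01 TPM guarding empty denominators. Ratio ≥ 1.5 is
*promotive* (inclusive "at least"), ≤ 1/1.5 *suppressive*, otherwise
*none*. Calls with fewer than 5 accessions in either group are
*unevaluable* and reported, not dropped. The promotive percentage is
reported among regulatory (promotive + suppressive) TEs, with fractions
over all evaluable TEs alongside, because the "no detectable effect"
denominator is ambiguous in published summaries. Cross-stage consistency
is the intersection of per-stage class sets.

## Association engine

Per-variant ordinary least squares replaces a mixed model: dosage is
regressed on the response with an intercept and optional covariates
(top-10 expression PCs by default), using a shared QR projection for
variants with complete data and per-variant complete cases otherwise.
The t-test has n − k − 2 degrees of freedom (intercept, k covariates,
dosage); betas, SEs and p-values match `statsmodels` OLS to machine
precision (enforced in tests). This is the package's one deliberate
methodological substitution: at the scale the package targets there is
no kinship machinery, and population structure is absorbed by PC
covariates only. Null calibration (KS uniformity, 5% rejection at
α = 0.05) is enforced on permuted responses.

Significance uses the 1/n rule: p* = 1/#variants, i.e. a −log₁₀
threshold of log₁₀ n (5.1712 at n = 148,323). No FDR layer is added on
top. cis/trans classification is by gap between variant anchor and gene
body on the same contig, inclusive at exactly 1 Mb (overlap ⇒ distance
0 ⇒ cis); different contigs are trans.

Clumping is the standard greedy procedure: repeatedly take the
unassigned variant with smallest p ≤ 1×10⁻⁵ as index, absorb unassigned
variants within 100 kb with r² ≥ 0.1 against the index (r² = squared
Pearson correlation over pairwise-complete accessions; undefined r²
counts as 0). Ties on p break by position then id for reproducibility.
Clump spans are merged into per-contig locus intervals by sweep-line
union.

## Haplotype combinations

Accessions are classified by the joint state of K focal variants,
present = dosage 2, absent = dosage 0; heterozygous or missing calls
exclude an accession from the partition (counted separately), because
the analysis treats insertions as present/absent line attributes.
Combination frequencies are over classifiable accessions; combinations
with frequency strictly above 0.05 are flagged retained. Summaries
report per-combination trait mean/SD and ecotype counts, and
per-accession carriage (number of focal variants carried) with integer
percentages *truncated* toward zero — the convention that turns 104/132
into 78%.

## Pangenome module

Occupancy classes generalize the 14-genome convention: private = 1,
dispensable = [2, n−3], softcore = [n−2, n−1], core = n; the bands must
partition [1, n] and are configurable. Growth curves use "totally
random" resampling: at each subset size k, 500 × 30 independent random
genome subsets (without replacement within a subset), with pan(k) =
clusters present in ≥ 1 member and core(k) = clusters present in all;
means and 5/95% quantiles are reported. The rank-sum utility
(`compare_groups`) wraps the two-sided Mann–Whitney U test, exact for
small tie-free samples, tie-corrected normal approximation otherwise;
fully tied inputs return p = 1 with a warning.

## Synthetic-data generators

The generators exist so that every stage can be exercised against known
truth; each returns a `SimTruth` sidecar.

- **Genotypes.** Diploid, biallelic, independent loci. A configurable
  fraction (default 0.8514, matching the observed share of fixed TEs) is
  fixed at dosage 2; polymorphic loci draw a TE-allele frequency from a
  configurable law — default uniform(0.005, 0.5), a choice made once
  because the empirical TIP spectrum is only described qualitatively as
  low-frequency-dominated — and sample dosages under Hardy–Weinberg.
  An optional Wright's F (`inbreeding`) mixes in autozygous draws;
  rapeseed panels are near-homozygous inbred lines, so the pipeline
  config defaults to F = 0.9 while the function default stays 0.
  Missingness is i.i.d. per call.
- **Expression.** One target gene per TE; a planted TE with fold f
  multiplies carrier expression by f; noise is multiplicative log-normal
  with unit mean and configurable CV (TPM is positive and
  right-skewed), so the carrier/non-carrier expectation ratio is exactly
  f. Stages share baselines and effects, differing only in noise.
- **Phenotypes.** Additive genetic value Σβ·dosage plus Gaussian noise
  scaled to a target heritability; ecotype labels follow the first
  planted variant's dosage (0 → spring, 1 → semi_winter, 2 → winter),
  a stated deterministic rule so haplotype summaries have structure.
- **Interval layouts.** SV alternative placements are laid out
  non-overlapping with ≥ 400 bp padding; linked TEs are placed with
  overlap fraction drawn in (0.55, 1]; decoys overlap at most half their
  length by construction, so brute-force scanning recovers the planted
  link set exactly.
- **LTR pairs.** A random ancestral repeat is mutated at per-site
  probability p = (3/4)(1 − e^(−4K/3)) with K = 2rT, i.e. the
  Jukes–Cantor forward process at total divergence K.

What the generators deliberately do not emulate: linkage
disequilibrium beyond the block-correlated genotypes constructed ad hoc
in clumping tests, shared-ancestry population structure and kinship,
read-level noise, multi-allelic SVs, and nested/fragmented TE
annotations. Passing tests therefore demonstrate correctness of the
procedures under the stated generative model, not robustness to
confounding in real panels — in particular the OLS engine's clean null
calibration relies on the generator's exchangeable accessions.

## Problem sizes and determinism

Default test and acceptance problem sizes (hundreds of accessions,
hundreds of variants, 100-instance oracle sweeps, 200 × 500 null scans,
2-kb LTR repeats) were chosen so the whole suite runs in seconds on one
CPU while keeping Monte-Carlo tolerances meaningful; they are stated in
each test. All randomness flows from explicit seeds; the pipeline
derives per-stage seeds from a master seed by hashing, and a rerun with
the same config is bit-identical (checksummed in the manifest).

## Known limitations

- No mixed model / kinship: association p-values are anti-conservative
  under real population structure (PC covariates mitigate, not cure).
- The min-rule merge is a convention; with the `any` rule, multi-SV TEs
  can genotype differently. Both are exposed, neither is claimed as the
  upstream pipeline's exact behaviour.
- The JC clock assumes equal rates across sites and no gene conversion
  between LTRs; ages of old elements are noisier and raw-p mode biases
  them young.
- TMM quantile-band trimming can differ from edgeR's rank trimming on
  very small gene sets.
- Nearest-gene assignment is per-contig brute force over candidate
  genes; adequate at package scale, not indexed for whole-genome use.
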