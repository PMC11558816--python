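# Methods

## Model

`drivecross` models a single autosomal locus with five allele classes:
`drive` (the cassette; *cardinal* loss-of-function, CFP-marked), `wt`
(canonical target site), `wt_snp` (target site carrying a defined silent
SNP — by default the A→T transversion at protospacer position 17), `nhej_r1`
(functional end-joining repair) and `nhej_r2` (loss-of-function end-joining
repair). Genotypes track parent of origin, because the maternal-effect
mechanism acts specifically on the paternally contributed allele, and three
paternal-slot states per individual:

- **zygotic** — the allele the father's gamete carried; together with the
  somatic mosaic category it determines the screened phenotype;
- **somatic** — the allele carcass sequencing reports (an embryonic NHEJ
  event replaces it);
- **germline** — the allele the individual transmits.

### Gametogenesis

In a drive/wild-type hemizygote the cleavable partner allele is cut with
probability *c*; a cut resolves to homology-directed repair (drive copy)
with probability *h*, otherwise to NHEJ, loss-of-function with probability
*β*. Gamete fractions: drive (1 + *ch*)/2, NHEJ *c*(1 − *h*)/2 (split
*β* : 1 − *β*), unmodified wild type (1 − *c*)/2. Pre-existing NHEJ alleles
are never re-cut; `wt_snp` escapes cutting entirely when `snp_cleavable` is
false. Parents without a drive allele have no Cas9 source and segregate
Mendelian.

### Maternal deposition

Embryos of drive-carrying mothers whose paternal allele is cleavable are cut
with probability *m*. The embryonic repair outcome is loss-of-function with
probability *β*: it then produces a visible somatic mosaic category —
small tear, big tear, or fully cardinal eyes — drawn from `dep_outcome`,
and reaches the germ line with the per-category probability `g_germ` (a
fully mutated soma always transmits the lesion). With probability 1 − *β*
the repair is functional: the eye stays black, carcass sequencing detects a
functional NHEJ allele, and the germ line carries it with probability
`g_germ_func`. Splitting the repair outcome *before* assigning a mosaic
category is a deliberate design choice: it is the only arrangement that
produces the observed class of black-eyed F1 carrying functional NHEJ
alleles, which a model that assigns a tear/cardinal category to every
deposition event cannot represent. Paternal-lineage "leaky" somatic Cas9
produces small tears at rate `lam` with no heritable consequence.

### Phenotype map

CFP is strictly a function of drive presence. Eye colour: cardinal when
both zygotic alleles are loss-of-function or the soma is fully mutated, big
tear for mosaic loss above the 25%-pigment screening boundary, small tear
below it, black otherwise. Tear categories are simulated as categorical
outcomes, not continuous cell fractions, because screening is categorical.
The SNP haplotype is phenotypically silent.

### Cage design

The simulator reproduces the reference design: three replicate cages of 75
homozygous drive adults × 75 wild types (reciprocal lineages), ~150 random
F1 intercrossed per replicate, and 15–20 phenotype-selected F1 males
backcrossed to wild-type females. Scored progeny totals are Poisson around
`mean_progeny` (default 1500 per cage, matching the scale of the reference
cage counts); phenotypes are effectively multinomial given the totals. Sex
is assigned 1:1 and used only for mating and sterility logic. A cross
flagged `hybrid_male_sterile` (Haldane's rule, as for the *An. arabiensis*
introgression) yields F1 but no F2; the empty table is a result, not an
error. Replicate *r* uses RNG substream `seed + r`, so runs are reproducible
cage by cage.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `c` | 0.995 | germline cut probability per cleavable allele |
| `h` | 0.995 | HDR fraction given a cut (*e* = *ch* ≈ 0.990) |
| `beta` | 0.93 | loss-of-function fraction of NHEJ repairs |
| `m` | 0.84 | maternal-deposition cleavage probability |
| `dep_outcome` | (0.36, 0.54, 0.10) | small / big / full somatic categories |
| `g_germ` | (0.10, 0.15, 1.0) | germline carriage per category |
| `g_germ_func` | 1.0 | germline carriage of functional embryonic repairs |
| `lam` | 0.004 | paternal-lineage leaky mosaicism rate |

Phenotype data cannot identify *c* and *h* separately (only composite
outcomes are observable), so these defaults are fitted by eye — chosen once
so that simulated F1/F2 phenotype spectra fall inside the ranges the
reference cage experiments produced (~22–34% black-eye F1 in female
lineages, ~7–12% exceptional cardinal-eye F1, ~0.6–1.6% CFP− F2, ~0.4%
male-lineage tears, backcross drive inheritance of tear classes ≈ 85–100%) —
and are not calibrated further. They are conditions of the synthetic
experiments, not estimates.

## Estimators

- **Drive inheritance** — CFP+ fraction, pooled or per replicate; the
  chi-square test is the uncorrected two-cell Pearson statistic on CFP+/CFP−
  counts against the 3:1 expectation (df = 1); no Yates correction, which is
  what reproduces the published statistic on the pooled reference counts.
- **F1 maternal-effect NHEJ allele frequency** — the weighted composite
  (black-eye/CFP+ fraction × NHEJ carrier fraction among sequenced
  black-eye/CFP+) + (cardinal-eye/CFP+ fraction × NHEJ carrier fraction
  among sequenced cardinal-eye/CFP+), multiplied by 0.5: every F1 carries
  one maternal drive allele, so NHEJ can occupy at most the paternal slot.
  The halving is required to reproduce the published totals and is
  documented here because the published formula leaves it implicit. Tear-eye
  classes are excluded by construction — the estimator replicates the
  published one rather than improving on it, and therefore underestimates
  total heritable NHEJ by the (small) germline carriage of tear classes.
- **F2 allele frequencies** — sum over phenotype classes of (class
  population fraction × allele-level target fraction among sequenced
  individuals of the class), where a homozygote contributes 1.0 and a
  hemizygous carrier 0.5. With full class coverage, drive + NHEJ + wild-type
  estimates sum to 1 exactly, and the estimator equals a brute-force allele
  count when the subset is the whole population.
- **Replicate CIs** — mean ± t(0.975, n−1)·sd/√n across replicate cages,
  clamped to [0.0001%, 99.999%]; the t interval is chosen for validity at
  n = 3, and the clamps replicate the reporting convention of the reference
  tables. Pooled and replicate-mean estimates can differ in the first
  decimal; both are available.
- **Pairwise background comparisons** — two-sided two-sample t-tests on
  per-replicate rates, Bonferroni-multiplied by the number of pairs; a
  zero-variance degenerate comparison reports the limiting p (1 for equal
  means, 0 otherwise) instead of NaN.
- **SNP tracking** — SNP fraction among wild-type-class alleles in parents
  vs. F2, with a pooled two-proportion z-test. A cleavable SNP confers no
  transmission advantage, so stable frequency is the no-resistance
  expectation; an uncleavable SNP approaches fixation among surviving
  wild-type alleles as *ch* → 1.

## Amplicon calling

The caller compares each amplicon with the reference target region: exact
match → wild type; one substitution matching a defined SNP → SNP haplotype;
a length difference explicable by a single contiguous indel (longest common
prefix/suffix test, equivalent to an optimal single-gap global alignment)
whose left-aligned span intersects ±`window` (default 10 bp) of the cut site
→ NHEJ indel; everything else → UNKNOWN, never a forced call. In-frame
indels are annotated informationally; functional vs. non-functional NHEJ
status is always taken from phenotype context, not inferred from frame.
Drive presence comes from the two cassette-junction amplicons: both present
→ drive; one → flagged inconsistent. Junction-positive individuals with one
(zero) cardinal-locus amplicons are called drive hemizygotes (homozygotes).
The synthetic default reference (`DEFAULT_TARGET_SITE`) has invented flank
sequence; only its geometry — 20-nt protospacer with an A at position 17,
NGG PAM, cut at the 17/18 boundary — carries meaning.

## DIS ancestry

Ancestry is allele-weighted over all called genotypes (CC = 2 coluzzii
alleles, CG = 1 + 1, ND excluded), pooled across individuals of a strain;
allele weighting is the convention that yields ancestry values that are not
multiples of 1/14. A per-individual-then-average variant is provided.
Hardy–Weinberg uses the exact conditional test by default (strain samples
are ~45–50 individuals), with a chi-square option above a configurable
total; the heterozygote excess/deficit direction is reported alongside. The
28S marker is treated as an ordinary X-group marker; sex-aware X dosage is
out of scope.

## What the generator does and does not emulate

The simulator reproduces the statistical structure the estimators assume:
multinomial phenotype sampling within Poisson cage totals, hemizygote
gametogenesis with conversion, maternal-effect deposition with somatic/
germline decoupling, phenotype-stratified subsampling, and single-indel
amplicon lesions. It does not model fitness costs, density-dependent larval
ecology, overlapping generations, multi-locus drives, brood structure
within cages, strain-specific pigmentation modifiers, sex linkage,
heterozygous Sanger-trace deconvolution, or deposition-induced HDR (off by
default; a flag exists because rare embryonic HDR cannot be excluded in
real data). Passing calibration tests therefore demonstrates estimator
correctness under these idealised conditions, not robustness to the
unmodelled features of real cage data.

## Numerical choices and degenerate inputs

Probabilities are validated to [0, 1]; `dep_outcome` must sum to 1 within
1e-9. Chi-square requires a non-zero total; p-values below float resolution
are reported as 0.0 and displayed as "< 2.2e-16". The CI clamp floor/ceiling
are applied after the t interval. Amplicon ties between equal-scoring indel
placements are broken leftmost. Monomorphic Hardy–Weinberg samples return
p = 1 by convention. Backcrosses of an empty male selection return an empty
table; mixed-phenotype male selections are rejected. The reference-count
loader warns (and proceeds with the count sum) when a printed denominator
disagrees with its row total — one such cell exists in the shipped F1 table
and is treated as a typographical inconsistency of the source, never
silently corrected.

## Problem sizes

The test suite and acceptance script use the design sizes above: cage
simulations at `mean_progeny` = 1500 × 3 replicates, the Mendelian-limit
check at ≥100,000 F2 in a single cage, calibration over 100 seeded runs,
and 10,000 synthetic amplicons for the round-trip check. These sizes give
binomial standard errors comfortably below the tolerances being asserted.
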