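# Methods

## Scope and data model

binqtl analyses an F2 cross between two inbred parents genotyped by
low-coverage whole-genome resequencing.  Only *parent-informative*
SNPs are used: bi-allelic sites where both parents are homozygous for
different alleles, with site QUAL ≥ 20 and INFO/MQ ≥ 20 (records
without MQ are dropped; the filter is applied at site level).  Every
progeny observation is then a pair of read counts `(n_A, n_B)` oriented
to the female/male parental alleles; zero depth means missing.
Coordinates are 1-based inclusive internally; BED/BedGraph exports are
0-based half-open.  Genotypes are coded AA/AB/BB/unknown (letters
A/H/B/U in text exports), where A is the female-parent allele.

## Hidden Markov imputation and bins

Each individual × chromosome is decoded with a three-state HMM.
Emissions are binomial read models with per-read error ε (default
0.01): a heterozygote emits B-reads at rate ½, homozygotes at ε or
1−ε; zero-depth markers are uninformative (uniform).  Transitions
convert the physical gap to a Haldane per-gamete switch probability at
a background rate ρ (default 3.0 cM/Mb — the order of a ~900 cM map on
a ~310 Mb genome; configurable), and the diploid chain is the product
of two independent gametes.  Decoding is hard Viterbi (the pipeline
reports discrete blocks and crossovers, so a single best path is the
natural output) with a uniform ¼/½/¼ start, log-space arithmetic and
ties broken toward staying in the current state.  A chromosome with no
sequenced marker at all becomes a single `unknown` block, excluded
from crossover counting and from χ²/QTL codes.

A crossover is the interval between the last marker of one block and
the first marker of the next; its point estimate is the interval
midpoint (unbiased absent further information; the interval is kept in
the output).  Midpoints pooled over the population partition each
chromosome's marker-covered span into candidate bins.  Candidates
shorter than `min_bin_bp` (default 30 kb) — the scale at which
apparent double recombination is more plausibly genotyping error or
gene conversion — are merged into the flanking bin sharing the larger
number of identical individual genotypes (tie → left), and bin
genotypes are re-derived from the block structure by largest overlap.

## Linkage map

De novo marker ordering is **not** re-implemented: bins are scaffolded
in reference physical order, which resequencing-derived maps are
themselves validated against; a diagnostic flags adjacent bins with
r̂ > 0.3 as potential ordering conflicts.  Bins with more than 20 %
unknown genotypes are excluded.  Adjacent-bin recombination fractions
are maximum-likelihood estimates for codominant F2 markers: the 3×3
genotype table's only ambiguous class is the double heterozygote
(parental vs double-recombinant gamete pairs), resolved by EM on the
expected recombinant-gamete count (r₀ = 0.25, |Δr| < 1e−8 or 200
iterations, clamped to [0, 0.5]).  Distances use Kosambi,
`d = 25 ln((1+2r)/(1−2r))` cM, whose inverse `r = ½ tanh(0.02 d)`
round-trips to ≤1e−12.  Because pairwise Kosambi on physical order is
not the same objective as a multipoint ML ordering, map totals are
validated on simulations (estimated chromosome length within 15 % of
truth at n=200, 7×) and on re-tabulated published summaries, not
against any multipoint software output.

## Segregation distortion

Per bin, unknowns excluded: zygotic test = Pearson χ² of (AA, AB, BB)
against 1:2:1 (df 2); gametic test = χ² of allele counts
(2n_AA+n_AB : 2n_BB+n_AB) against 1:1 on 2n alleles (df 1).  No
continuity or multiple-testing correction (a raw P = 0.01 display
line; a Bonferroni column is emitted for reference).  The gametic test
treats the 2n alleles as independent and therefore overstates
significance under true zygotic selection — a deliberate, documented
construction; the stages remain distinguishable because a pure
heterozygote deficit leaves alleles balanced.  SDRs are maximal runs
of consecutive bins significant at α = 0.01 on either stage, with zero
gap tolerance; single-bin regions are allowed; the region direction is
the modal bin direction (female/male = over-represented parental
allele).

## QTL scan

Bins are the scan grid (within-bin position is unidentifiable on a bin
map), so the scan is a Haley–Knott-style regression of the phenotype
on F2 codes x = +1/0/−1 (AA/AB/BB) and z = [het], with
`LOD = (n/2) log10(RSS0/RSS1)` against the covariate-only null on the
same individuals.  Missing bin genotypes drop the individual at that
bin only.  Rank-deficient designs are handled by SVD projection; a
degenerate null fit (constant phenotype) yields LOD 0.  Composite
scans forward-select up to 3 covariate bins (config key) by repeated
peak picking; covariates within 10 cM (config key) of the tested bin
are excluded from its model.  Genome-wide thresholds come from 1000
phenotype permutations against intact genotype rows (preserving
marker correlation), using the type-7 empirical (1−α) quantile;
n_perm < 20 is refused.  Declared peaks (one per chromosome above
threshold) are jointly re-fitted: overall PVE = 100·(1 −
RSS_full/RSS_null), per-QTL effects from the joint coefficients and
per-QTL PVE by drop-one comparison.  The support interval is the peak
bin plus both flanking bins; overlapping same-trait intervals merge.

## Graded-pool mapping

Phenotyped individuals are ranked (ties by stable ID) and split into
k = 4 contiguous pools of size ⌊n/k⌋/⌈n/k⌉.  Pool allele counts are
merged in silico, in one of two units:

* **reads** — sum member allele depths, emulating sequencing of a
  physical pool.  At multi-read depth the reads of one individual are
  clustered (a homozygote's reads all carry the same allele;
  within-individual allele correlation ≈ 0.5), so the mid-rank
  variance underestimates the truth by roughly 1 + (λ̄−1)/2 and the
  Ridit p-values are **anti-conservative** (measured null z sd ≈ 2.25
  at 7×).  These p-values are usable for ranking and peak calling, not
  as nominal significance.
* **alleles** — each member contributes a diploid allele-dosage call
  once ((2,0)/(1,1)/(0,2) from read presence).  The two alleles of an
  F2 individual are independent Mendelian draws, so these tokens meet
  the rank test's exchangeability assumption and the null p-values are
  uniform (measured z sd ≈ 1.0; KS p ≈ 0.4).  This is the pipeline
  default for in-silico pooling from individual data.

The Ridit statistic itself is the Bross-style ordered-category
mid-rank test with tie correction, algebraically identical to the
two-sided normal-approximation Mann–Whitney test on grouped
observations (pinned to 1e−9 against that oracle).  Variants with
total depth < 10 or an empty pool are filtered.  Windows of 400 kb
slide in 100 kb steps ("sliding" is given, the step is a config key);
a window's score is the mean −log10(p) of its ≥5 unfiltered variants
(Fisher combination available behind a config switch), and the
candidate region is the genome-wide peak window ±200 kb, clipped to
the chromosome.

## Synthetic populations

The simulator emulates the target study design: F2 individuals as two
independent gametes per chromosome; Poisson crossovers with mean
L/100 per gamete (L in cM; **no interference** — the analysis model
assumes none either), uniform positions; markers placed uniformly at
random (1-based) to exercise variable gaps; Poisson(λ) depths with
binomial ε miscalls and optional extra dropout; distortion by
rejection sampling (gametic: allele survival weights w_A/w_B;
zygotic: genotype weight w_A^(2−g)·w_B^g), keeping population size
exact; phenotypes y = μ + Σ(a·x + δ·z) + N(0, σ²) through the marker
nearest each QTL, so truth stays discrete.  A lone additive QTL
contributes variance a²/2 (dominance δ²/4) in an infinite F2, which is
how target-PVE effects are derived.  All randomness flows through one
seeded generator; identical seeds are bit-identical.

What the generator does **not** emulate: read-level artefacts (mapping
bias, indels, gene conversion), marker-density heterogeneity of real
genomes, interference, epistasis, and environment structure in
phenotypes.  Passing recovery tests therefore demonstrate correctness
of the inference machinery under the stated stochastic model, not
robustness to alignment-level artefacts.

## Study problem sizes

Simulation studies run on a scaled genome — typically two or three
30 Mb chromosomes at 3 cM/Mb (≈90 cM each) with 60–600 markers —
while keeping the design-point parameters n = 200 individuals, 7×
depth, ε = 0.01.  This preserves per-chromosome genetic structure
(crossover counts per chromosome, marker-level LD, pool sizes) at a
fraction of the full 12-chromosome cost; per-chromosome quantities
(accuracy, power, calibration) are unaffected by chromosome count.
Null-calibration studies that need approximately independent tests
(distortion type-I rate, Ridit uniformity) instead use many small or
single-marker chromosomes so the tested loci are unlinked.

## Known limitations

* Physical-order scaffolding cannot detect reference mis-assemblies;
  the r̂ > 0.3 diagnostic only flags them.
* ε and ρ are fixed, not re-estimated (no Baum–Welch); grossly wrong ε
  degrades imputation gracefully but silently.
* The graded-pool candidate region (peak 400 kb window ±200 kb) is an
  ~800 kb interval, while at n = 200 the window-score profile around a
  QTL is nearly flat over ±1 Mb; the peak window therefore jitters on
  the Mb scale and the candidate region misses the causal position in
  a substantial minority of replicates (measured coverage ≈ 0.55–0.7
  for a PVE-30 % QTL).  Larger populations, not deeper sequencing,
  are what sharpen this localisation.
* Read-unit Ridit p-values are anti-conservative (see above); the
  allele unit or the permutation-free window ranking should be used
  for inference.
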