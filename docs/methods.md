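# Methods

`immunediv` implements the statistical core of a population-genomic
comparison of immune-gene divergence among three sympatric mosquito taxa
(*Anopheles coluzzii* and the Bamako and Savanna chromosomal forms of
*A. gambiae s.s.*): per-SNP population statistics, gene-set resampling
tests, linkage disequilibrium from unphased genotypes, and a coalescent
F_ST outlier scan, together with synthetic-data generators that realize
the statistical structure those analyses assume.

## Data model and conventions

Genotypes are biallelic alternate-allele dosages in {0, 1, 2} with a
distinguished missing sentinel (−1), never a dosage. SNP positions are
1-based (VCF); gene and inversion intervals are 0-based half-open (BED).
The single point where the conventions meet is SNP-to-gene assignment: a
1-based position *p* lies in BED interval [start, end) iff
start < *p* ≤ end. SNPs inside overlapping genes are assigned to all of
them, and per-gene statistics count such a SNP once per gene.
Multi-allelic VCF rows are skipped by default (the analysis is defined
for biallelic SNPs); an opt-in splits them into one biallelic row per
alternate allele. Missing data are handled per locus by complete-case
analysis within each population; for LD, per pair of loci.

## Functional SNP classification

A coding SNP is *potentially functional* if it is non-synonymous
(stop gain/loss included), or synonymous but exchanging codons whose
relative usage frequencies differ at least 2-fold
(max(f_ref/f_alt, f_alt/f_ref) ≥ 2). The threshold is inclusive at
exactly 2.0 and symmetric in ref/alt; both properties are tested. Codon
context (ref codon, alt codon, position within codon) is supplied by the
caller — the package does not derive it from a transcript model — and
the usage table is a genome-wide input file. The bundled
`synthetic_usage_table` is a log-uniform synthetic fixture, not a claim
about any real genome.

## Population statistics

* **Allele frequency / heterozygosity.** Complete-case within taxon;
  H_obs is the heterozygote fraction, with mean and SD over loci that
  have at least one call.
* **Association.** Pearson chi-square (no continuity correction) on the
  taxa × genotype-class table, empty rows/columns dropped,
  df = (r−1)(c−1); an allelic 2-column variant is available behind a
  flag. The genotypic test is the default because the data of interest
  are genotype distributions. Monomorphic tables give NaN with df 0.
* **Multiple testing.** Bonferroni, significant iff p < α/m with
  α = 0.05 and m defaulting to the number of SNPs tested; m is exposed
  so a panel-wide denominator (e.g. 333) can be used when only a subset
  is examined.
* **Power.** Chi-square power from the noncentral chi-square with
  noncentrality n·w²; w = 0 reduces exactly to α.
* **F_ST.** Weir & Cockerham (1984) variance components a (among
  populations), b (among individuals within populations), c (within
  individuals), θ = a/(a+b+c), NaN when a+b+c = 0. Multilocus sets use
  the ratio-of-sums ("weighted") estimator Σa/Σ(a+b+c), matching the
  VCFtools weighted convention; negative per-locus estimates are never
  clamped, so they average properly in the set estimator. Monomorphic
  loci are excluded from the sums and their count reported.

## EM linkage disequilibrium

Two-locus haplotype frequencies are maximum-likelihood estimates from
unphased genotypes: only the double-heterozygote class is
phase-ambiguous, and the E-step splits it between coupling and repulsion
by relative haplotype-product probabilities. Defaults: tolerance 1e-8 on
the log-likelihood gain, 1000 iterations, 5 restarts (first at linkage
equilibrium, the rest random Dirichlet). Additional deterministic
*boundary starts* zero each haplotype that no unambiguous genotype
requires: maxima on simplex faces are common in small samples and
interior EM approaches them only sublinearly, while EM started on the
face converges there quickly. The monotonicity of the log-likelihood is
asserted at every iteration. Near-ties between distinct maxima (the
all-double-heterozygote degeneracy has symmetric coupling/repulsion
maxima with identical r²) are flagged multimodal and resolved toward
the higher-|D| solution. r² = D²/(p_A(1−p_A)p_B(1−p_B)) is computed
from the EM haplotype frequencies, not from the composite (Burrows)
estimator. Pairs with fewer than 5 complete-case individuals, or with a
monomorphic member, are NaN with a flag.

The LD summary partitions pairs of gene-assigned SNPs into within-gene
(sharing a gene id) and between-gene, and reports the proportion
exceeding r² thresholds {0.5, 0.8, 0.95} among pairs with *defined* r²;
NaN pairs are counted separately rather than pooled into the
denominator. Between-gene pairs can be capped by seeded subsampling to
keep large panels tractable (the full pairwise set is quadratic).

## Gene-set resampling and inversion permutation

Genes, not SNPs, are the resampling unit, preserving within-gene LD.
Observed statistics: the weighted set F_ST over all SNPs in immune genes
(per taxon contrast), or the SNP count in the set. Null replicates draw
equal-sized gene sets from the non-immune pool without replacement
(independently across replicates); genes overlapping configured
exclusion regions (speciation islands) are removed from both the immune
set and the pool first. Empirical p-values use the add-one convention
(1 + #{null ≥ observed})/(B + 1) and can never be 0. The
inversion-overlap test counts immune genes lying within an inversion or
within 1 Mb of a breakpoint (interval overlap with the inversion
expanded by `near_distance`), permuting gene labels over *all* genes;
a flag restricts the analysis to one chromosome arm. Each test also has
an exhaustive mode enumerating every equal-sized subset of the full pool
(observed set included) and reporting the exact upper-tail fraction —
the quantity the sampled p-value converges to.

## Hierarchical-island outlier scan

The neutral null is a structured coalescent on `n_groups` × 
`demes_per_group` demes: within-deme pairwise coalescence at rate 1 per
pair, migration at total rate (M_w + M_b)/2 per lineage with destination
uniform in the same group w.p. M_w/(M_w+M_b) and uniform in another
group otherwise (M_w > M_b). Per locus one mutation is placed on the
genealogy proportionally to branch length, so every locus is polymorphic
in the pooled sample; lineages are paired into diploids within demes
(exchangeable, so consecutive pairing is random pairing). Each null
point is (mean within-deme unbiased expected heterozygosity, W&C θ
across sampled demes). Defaults: 10 groups × 100 demes, M_w = 20,
M_b = 2, three sampled demes in three distinct groups (mimicking three
partially isolated taxa), 12 diploids per deme, 20,000 simulations. The
simulator is a numba-compiled event loop; it is validated against
closed-form coalescent limits (mean pairwise coalescence time of 1 in a
single deme; θ → 0 in the fast-migration panmixia limit) and migration
monotonicity.

Observed loci are ranked against null points in the same heterozygosity
quantile bin (default 20 bins, bins with < 20 points merged), one-sided
toward high θ: p = (1 + #{null θ ≥ observed})/(n_bin + 1). Outliers are
flagged by Bonferroni (p < α/m).

**Known limitation — conservativeness on discrete nulls.** A single
biallelic SNP from ~36 diploids yields a heavily atomic joint (het, θ)
distribution: singleton configurations alone carry roughly a sixth of
the null mass and are exactly tied. A tie-inclusive exact rank p-value
can never reject a configuration whose within-bin mass exceeds the
nominal level, so the realized rejection rate under the null is ~0.027
at nominal 0.05 with the default binning (and lower under finer
conditioning). This is the standard conservativeness of exact
conditional rank tests on discrete data; it makes the scan conservative
(fewer false positives), not anti-conservative.

## Synthetic data

Balding–Nichols is the divergence model: ancestral frequency p ~
Uniform(0.05, 0.95) (avoiding near-fixed ancestral SNPs; exposed in
config), taxon frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes
Binomial(2, freq) — Hardy–Weinberg within taxon. The generator's F is
the estimand of W&C θ, so the parameter-recovery suite (F ∈ {0.02,
0.05, 0.10, 0.15} recovered within ±0.015 from 2000 loci × 3×50
diploids) closes the loop between simulation and inference. Monomorphic
draws are retained deliberately to exercise the NaN paths downstream.

The study-mimic bundle defaults are the emulated study conditions: a
12,519-gene genome (stylized chromosome lengths for arms 2L/2R/3L/3R/X),
231 immune genes at F = 0.13 versus an F = 0.035 background, taxa of
12/11/13 diploids (the genotyping-scale alternative is 194/167/87), one
SNP per gene, and five stylized 2R paracentric inversions (2Rj, 2Rb,
2Rc, 2Rd, 2Ru — synthetic coordinates, not real breakpoints). With
multiple SNPs per gene, within-gene loci share one frequency draw per
gene and taxon and are coupled into an LD block at a target r² via a
haplotype Markov chain (adjacent pairs exact, longer range decaying);
equal frequencies make any target feasible, mirroring SNPs on a shared
haplotype background. Immune genes can be placed with a bias toward
inversions to emulate positional enrichment.

What the generator does **not** emulate: demography (bottlenecks,
admixture, sweeps), mutation-rate or recombination-rate variation along
the genome, genotyping error and allelic dropout, and real gene/inversion
coordinates. Passing tests therefore demonstrate estimator correctness
and pipeline calibration under the assumed model, not robustness to
those real-data features.

## Numerical and design choices

* Seeds: every stochastic component takes an explicit seed; the pipeline
  derives per-stage seeds from one master seed via `SeedSequence`, so
  reruns are byte-identical.
* The Bamako/Savanna/coluzzii labels are conventions of the bundled
  configurations; taxon labels are free strings throughout.
* The full-pipeline LD stage computes all within-gene pairs but caps
  between-gene pairs (default 500 per taxon, seeded subsample).
* Problem sizes in the test suite: the heavy checks use 20,000 null
  simulations + 2,000 test loci for the outlier scan, 2,000 loci for
  parameter recovery, B = 1000 with the full 12,519-gene genome for the
  gene-set tests, and 50 seeded study-scale runs for null calibration.
* The command-line interface is a thin layer over the library; every
  subcommand is also available as a plain function call.
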