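# Methods

`paleoweave` re-implements, as a tested library, the analysis layer used in
haplotype-based studies of ancient population structure: genotype handling
for low-coverage ancient genomes, D/f-statistics with block-jackknife
errors, Li–Stephens chromosome painting with donation-vector statistics,
polygenic trait scores, extended haplotype homozygosity, and the
authentication estimators (sex, contamination, damage). Because the real
archaeological datasets such analyses are run on are large external
downloads, the package ships a synthetic-cohort generator that reproduces
the *statistical structure* those methods assume, so every method can be
validated end-to-end against known truth at desk scale.

## The synthetic cohort generator (`simdata`)

**Sources.** Each site draws an ancestral frequency p ~ U(0.05, 0.95).
Population k draws q_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k) — the
Balding–Nichols model, whose drift parameter F_k is approximately the
population's FST to the ancestor. Founder haplotypes are iid Bernoulli(q_k);
sampled haplotypes are *founder mosaics*: switch points fall as a Poisson
process (default 30 per Morgan) along a uniform genetic map and each segment
copies one uniformly chosen founder. The mosaic construction is a deliberate
shortcut past coalescent simulation: it produces the within-population
haplotype sharing and LD that chromosome painting needs, at a cost linear in
sites, while leaving the site-frequency spectrum and recombination
clock unrealistic (see Limitations). A Monte-Carlo evaluation of the
generative model (2×10⁶ sites) puts the Hudson-type FST between two F = 0.1
sources at 0.100; the simulator's sampled cohorts match it within the test
tolerance.

**Admixture.** An admixed population is built haplotype by haplotype from a
two-state Markov ancestry process: potential switch points fall as a Poisson
process of intensity g per Morgan, each drawing a fresh ancestry state from
the stationary law (α, 1−α); runs of equal state are merged into truth
tracts, and each tract copies alleles contiguously from one uniformly chosen
source haplotype. Truth tracts (0-based, half-open, tiling the chromosome)
are recorded and are exactly consistent with a rescan of the copied
segments. The copying pool can be restricted to a subset of source
individuals; the bundled scenario uses this to hold the F4-ratio reference
individuals out of the admixture donors, since sharing sampling noise
between the admixed target and its reference individuals biases the ratio
estimator.

**Reads.** Depth per individual-site is Poisson(λ); coverage defaults follow
the sub-1x regime typical of ancient shotgun data. Each read picks a
chromosome uniformly, flips its allele with the sequencing error ε, and — at
transition sites where the read's true base is the deamination-susceptible
allele (C of a C/T pair, G of a G/A pair) — converts to the damage product
with probability δ·2^(−d/d_half), d ~ U{0..59} the distance from the 5′
end (d_half = 2 by default). Reads are site-level records, not sequences;
that is sufficient for pseudo-haploid calling and damage profiling.

**Imputed-like calls.** Rather than reimplementing a phasing/imputation
engine, its output is emulated: each truth genotype survives with a per
MAF-bin × genotype-class accuracy (bins of 0.005, mirroring how imputation
accuracy is reported), else is replaced with the adjacent genotype twice as
likely as the opposite homozygote; the GP posterior triplet puts
u ~ U(0.90, 1.0) on the emitted call. Only the *evaluation* of imputation is
in scope, and the emulator gives it a configurable truth.

**Trait.** n_causal sites get effects β ~ N(0, h²/n_causal); the true
genetic value is Σβ·dosage. Null SNPs with near-zero effects and
p ~ U(0.1, 1) support p-value-threshold filtering exercises.

**Reproducibility.** All stages derive generators as
`default_rng([root_seed, STREAM_ID, ...])` with fixed stream constants (and
a CRC32 of the population name for admixture events, so the stream is
stable across processes); identical configs reproduce identical cohorts.

## Genotype handling (`calls`)

Pseudo-haploid calls take one uniformly sampled read per individual-site
(zero reads → missing). Filters run in the order GP-mask → transversion →
completeness → MAF: the GP filter (default threshold 0.99) masks individual
genotypes whose posterior maximum is too low, and site-level filters then
act on the masked matrix, with MAF recomputed on retained calls. The GP
filter is per-genotype, not per-site — the order "mask, then drop
incompletely genotyped sites" reproduces the usual pipeline. "Removing
potential deamination calls" is operationalized as the transversions-only
filter. Allele frequencies are complete-case per population; haploid calls
contribute one allele, diploid two.

The imputation evaluation stratifies truth/call concordance by truth
genotype class and MAF bin, reporting missingness separately. The
reference-bias harness treats the two call sets of one individual as two
single-sample "populations" and computes D(outgroup, R; truth, variant) for
every panel population R: calls biased toward R give excess R–variant
sharing and a positive Z.

## D/f-statistics (`fstats`)

D = Σ(p1−p2)(p3−p4) / Σ(p1+p2−2p1p2)(p3+p4−2p3p4);
f4 = mean (p1−p2)(p3−p4);
outgroup f3(C; A, B) = mean [(pC−pA)(pC−pB) − pC(1−pC)/(nC−1)], the
finite-sample correction on by default (skipped with a note when nC ≤ 1 —
whether to apply it to pseudo-haploid data is exposed as a flag);
F4-ratio α = f4(O, A1; X, Out2)/f4(O, A1; A2, Out2) on the common
complete-case site set, flagged unreliable when the denominator has |Z| < 2.

Sign convention, stated prominently because directionality is usually
reported verbally: **D > 0 means excess sharing between P1–P3 and between
P2–P4** (ABBA > BABA with the formula as written).

Standard errors use the weighted delete-one-block jackknife for ratio
statistics (Busing, Meijer & van der Leeden 1999), block weights
proportional to per-block used-site counts; blocks default to 5 Mb of
physical position (no canonical size exists; 5 Mb comfortably exceeds the
simulator's LD scale). For equal weights the formula reduces to the
textbook jackknife, which the tests check. Null calibration: on
no-gene-flow quartets, |Z| > 3 occurs in ≤ 2% of replicates.

## Chromosome painting (`painting`)

The Li–Stephens copying model over K donor haplotypes: across an interval of
g cM the chain keeps its donor with probability e^(−ρg), otherwise jumps to
a uniform donor (1/K, self-return allowed); emissions match the copied donor
with probability 1−θ. Scaled forward–backward gives per-donor posteriors;
**expected copied length** integrates posterior mass against site weights
(midpoint boundaries plus chromosome ends, so lengths conserve total map
length per haplotype to 1e−6), and **expected chunk count** sums posterior
switch-in events P(d_s ≠ j, d_{s+1} = j) plus the first site's donor
probability. The implementation is validated against exhaustive donor-path
enumeration on small fixtures (agreement ~1e−13) and is stable to hundreds
of donors and tens of thousands of sites.

Defaults when unset: ρ = K/100 per cM (about one expected switch per cM per
100 donors) and θ = t/(2(K+t)) with t = 1/Σ_{k<K} 1/k, the Watterson-style
mutation parameter. EM re-estimation of ρ and θ is out of scope; both are
plain config values.

Cohort painting is all-vs-all with leave-self-out (both haplotypes of the
recipient individual excluded from its donor set), or restricted to
explicit recipient/donor panels — the latter supports both painting
directions (ancients as donors to moderns, or the reverse) for the
modern-reference comparison. Donor haplotype results aggregate to donor
individuals.

Donation statistics: the per-recipient differential d_r = c_{r,X} − c_{r,ref}
uses expected chunk counts ("number of haplotypes donated"); expected
lengths are also emitted since either could underlie a published figure.
Group contrasts use a two-sided Mann–Whitney U (exact when n_A + n_B ≤ 20
without ties). TVD between two groups' per-target median donation vectors is
computed after normalizing each vector to sum 1 (the natural reading of a
distance between donation *profiles*); raw signed differences are kept for
absolute-shift displays. PCA column-centers the chunk matrix and uses SVD
with a deterministic sign fix. Clustering is a greedy agglomeration on the
gain in multinomial-Dirichlet marginal likelihood of pooled chunk-count rows
(symmetric prior, concentration 1 split across donors, ties broken by the
smallest index pair) — a deterministic stand-in for a full MCMC cluster
search, adequate for well-separated groups (tests recover two F = 0.15
populations exactly) but without any posterior uncertainty.

## Polygenic scores (`traits`)

Scores are average per-allele effects, Σβ_j·dosage_j / (2·n_used), with the
effect allele aligned per SNP (effect = ref uses ploidy − dosage); a sum
mode exists. Missing genotypes are skipped by default or mean-imputed from
the cohort. Odds ratios convert to effects as β = ln(OR)/1.81 — the
liability-scale convention; the phrase "logarithm of OR/1.81" also parses as
ln(OR/1.81), which is available behind a flag. Group comparisons use a
permutation test of the mean difference (10,000 label permutations,
add-one correction) with a Mann–Whitney p alongside; the test behind the
published group p-values is not documented, so a distribution-free default
was chosen. The ancestry–score regression is OLS of population mean score on
an admixture proportion (typically an F4-ratio α), reporting slope, Pearson
r and its t-test p, flagged when ancestry has no variance.

## EHH (`ehh`)

EHH at a target is the probability that two random carriers of the core
allele are identical over the closed core–target interval:
Σ_h C(n_h,2)/C(n_c,2) over identity classes. No carrier-frequency floor is
applied (low-frequency cores kept, as with a keep-low-freq analysis);
windows default to 5 Mb of physical distance; haplotype input must be
complete and phased, as imputed data is. Decay curves are monotone
non-increasing by construction (identity partitions refine outward), which
the property tests assert. Furcation trees split carriers at each successive
site; singleton branches are pruned from the rendered structure but retained
in node counts.

## QC (`qc`)

Sex: Ry = nY/(nX+nY) with a normal-approximation binomial CI; XX if the CI
upper bound < 0.016, XY if the lower bound > 0.075 (the shotgun-data
convention of the originating method; both configurable). mtDNA
contamination is the mismatch fraction at haplogroup-defining sites with a
binomial CI. X contamination in males uses a closed-form moment estimator,
c = (r_snp − r_adj)/(f̄ − r_adj), clamped to [0,1] and flagged when
f̄ ≤ r_adj — a deliberate simplification with the same inputs as the
likelihood methods (SNP mismatch rate, adjacent-site error baseline, mean
minor-allele frequency); the adjacent-site window is ±5 bp by convention
and configurable. The damage profile reports the conversion rate by
5′-distance among reads carrying the susceptible allele and fits
δ·2^(−d/d_half) by weighted least squares; on simulated pileups it recovers
δ = 0.25 within ±0.01 at ~2×10⁵ reads.

## The bundled scenario

`pipeline.iberia_analog_config()` wires five sources (WHG-, CHG-,
Anatolian-, Steppe- and outgroup-analogs; F between 0.15 and 0.3, 30
founders each), a Neolithic-analog (75% Anatolian + 25% WHG), a
BronzeAge-analog adding 15% Steppe ancestry on the Neolithic background,
and a CordedWare-analog control with 50%. On 8,000 sites over a 1-Morgan
chromosome this recovers, in one run of a few seconds: a significantly
positive D(Outgroup, Steppe; Neolithic, BronzeAge); F4-ratio α̂ within 2 SE
of 0.15 (and ≈0.5 for the control); and a Neolithic→BronzeAge donation-TVD
shift smaller than the control's — the qualitative shape of a modest Steppe
introgression detected against a 50%-turnover comparison. These parameter
values are synthetic-scenario choices that make the contrast recoverable at
desk scale, not estimates of any real population.

## Problem sizes and numerical choices

Test and scenario sizes were fixed once as the package's study conditions:
1k-site fixtures for oracle equivalence, 10k sites × 100 replicates for null
calibration, 50k sites × 20 replicates for F4-ratio recovery, 20k sites ×
20 seeds for painting tract recovery, 8k sites for the end-to-end scenario.
Forward–backward runs in scaled (not log) space with per-site normalizers,
raising an error with the site index on a non-finite likelihood. Filters are
idempotent; PCA signs are fixed by the largest-magnitude loading;
clustering ties break on the smallest index pair; jackknife blocks with no
data are dropped (≥2 required). Internal coordinates are 0-based half-open
everywhere, converted only at VCF/EIGENSTRAT boundaries; alleles are taken
verbatim, never strand-complemented.

## Limitations

The founder-mosaic simulator has no coalescent genealogy: allele-frequency
spectra, tract-length distributions at old admixture times, and
recombination-map heterogeneity are not realistic, so passing tests show
method correctness under the stated generative model, not robustness to
real-data pathologies (reference bias from alignment, imputation error
correlated along haplotypes, phasing switch errors). The greedy clusterer
has no posterior and can undersplit weakly separated groups. The moment
estimator for X contamination assumes a single contaminant with known mean
allele frequency. Multi-chromosome data are handled as independent
replicates with per-chromosome seeds rather than a genome-wide map.
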