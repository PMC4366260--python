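# Methods

## Scope and data model

The package operates on a sites × samples genotype matrix with three-valued
calls: a variant genotype, a confident homozygous-reference call (`0/0`), or
missing (`./.`). The distinction between the last two is load-bearing for
every downstream statistic (call-count distributions, group call-rate
filters, modal group sizes), so it is preserved through every read/write
path. Internally coordinates are 0-based half-open; VCF emission and parsing
are 1-based via pysam.

## Merge conventions

Per-individual VCFs are merged over the union of variant positions. A
genotype is kept only if raw depth ≥ 5, high-quality depth ≥ 5, depth ≤
2·(sample mean depth)+1, and genotype quality ≥ 20 (when present). The mean
depth is estimated from all of the sample's records. "Confidently callable
non-variant" cannot be observed directly in a variant-only VCF, so the
convention is: a reference record (`ALT=.`) passing the same filters codes
`0/0`; anything else is missing. Sites where no passing call carries an
alternative allele are removed (they are not variants); alternative alleles
never observed in a passing call are pruned, with genotypes remapped.
Multiallelic records are stored un-split so the allele-class census (AA /
RA / A1A2 / triallelic / quadallelic, classified by the set of alleles
observed among non-missing genotypes plus whether the reference was ever
observed) matches single-position accounting. Union alt alleles are ordered
lexicographically for determinism.

## Ancestral-allele rules

Eligible sites are mono- or biallelic with the reference among their
alleles; AA sites (reference never observed) are treated as biallelic with
the reference as second allele. Rule A assigns an allele homozygous in at
least two *Sus* outgroup species; heterozygous outgroup calls withdraw that
species' support without disqualifying the site; two species homozygous for
different alleles make rule A undecidable, and the site falls through to
rule B (flagged `conflict`). Rule B assigns the warthog's allele when its
call is homozygous. An assigned allele that is neither the site's reference
nor its alternative (a third allele in the outgroups) renders the site
unknown rather than falling through — the outgroups then positively
contradict both candidate states. Polarization excludes unknown sites and
counts derived copies over non-missing genotypes per group.

## Windowed features and variance decomposition

Features are computed on fixed tiles (default 1 Mb; any partitioning can be
supplied as a start/end table). Ts/Tv uses biallelic SNPs only (transitions
= A↔G, C↔T); multiallelic sites still count toward SNP density. Gene
density is the fraction of window bp inside genes, with genes overlapping a
window boundary discarded from all windows — a deliberate reproduction of
the source convention that slightly underestimates density near boundaries.
CpG dinucleotides are counted within the window slice (a CG spanning a
boundary counts in neither window; at most one dinucleotide per boundary is
affected). Windows that are entirely N are flagged and carry undefined
composition features. Zero-transversion windows have undefined Ts/Tv and
drop out of the regression as incomplete cases.

The two regression models are ordinary least squares on z-scored response
and predictors — except the missing rate, which enters on its raw scale —
with the recombination rate log-transformed (its raw distribution is
strongly right-skewed). Each predictor's contribution is the increase in R²
upon sequential addition. Sequential increments telescope, so they sum to
the full-model R² for any ordering; the default ordering is greedy (largest
marginal gain first), which makes the first increment the single best
univariate predictor. The design-matrix condition number is reported and a
collinearity flag raised above 1e8.

## Group sharing and spectra

A site enters the sharing analyses when it is a biallelic
reference/alternative site and every group has at least `min_called_frac`
(default 0.5) of its members genotyped. "Segregating in a group" means ≥ 1
derived copy among called genotypes (a fixed-derived group is also
segregating in this sense; exclusive *fixed* status — every called
chromosome derived, derived absent elsewhere — is reported separately). The
Venn partition assigns each eligible site with ≥ 1 derived copy to the exact
subset of groups carrying the derived allele; the 15 cells are disjoint and
sum to that site total.

Joint spectra are computed at the modal group size: the called-sample count
n at which the largest number of SNPs was genotyped in exactly n
individuals (ties broken toward larger n, maximizing frequency resolution).
Only sites genotyped in exactly the modal count in both groups enter —
"exactly" rather than "at least" keeps every site's frequency denominator
identical. Axes run 0..2n including the fixed class; the (0,0) cell is
excluded. Marginal sums equal the corresponding 1D spectra as integer
identities on the same site set.

The extreme-frequency contrast classifies a site as extreme when one
group's derived frequency exceeds 0.8 while the other's is below 0.2, and
tests the 2×2 association with annotation class (non-synonymous vs
synonymous) by Fisher's exact test; the odds ratio uses a Haldane 0.5
correction when a cell is empty (flagged).

## Neutral expectations

For N diploids, a = Σ_{i=1}^{2N−1} 1/i. The package exposes a, 1/a and
1 − 1/a under separate names because the literature overloads one symbol for
all three. The expected fraction of SNPs whose reference allele is ancestral
is 1 − 1/a: under the neutral frequency spectrum a site has i derived
copies with probability ∝ 1/i and a designated reference haplotype carries
the derived allele with probability i/2N, so the exact value is
1 − (2N−1)/(2N·a), within O(1/N) of the reported form. E[S] = a·θ·L
(Watterson).

## Pipeline-accuracy simulation

**Demography.** Four populations — EUWB (18 haplotypes), EUDM (110), ASWB
(82), ASDM (46) — with relative sizes 0.2/0.5/2.5/3.0, a migration pulse
EUDM→ASDM (rate 5) between t = 0.049 and 0.06, wild/domestic joins at
t = 0.07 (Europe) and 0.08 (Asia), ancestral size changes at 0.09/0.2/0.21,
and a deep continental join at t = 10, with θ = ρ = 0.0005/bp over 100 kb
(all in ms units: time in 4·N0 generations). msprime reproduces this scaling
with deme sizes `relative/4`, making event times and scaled rates carry over
numerically. Mutations use a binary model, so every site is biallelic with
known ancestral state. One European-domestic haplotype (the first, under
the seed) is designated the reference assembly; genotypes are evaluated in
reference space, where a site whose reference haplotype carries the derived
allele has its coding flipped — reference and ancestral intentionally do
not always coincide.

**Calling model.** Read simulation and mapping are abstracted to a per-site,
per-sample model: depth ~ Poisson(sample mean), means drawn once per panel
uniformly in [3, 22]× and held fixed across replicates; reads sample the two
true alleles (fair for heterozygotes) and are misread with probability 0.01
(the Q20 bound), landing uniformly on the three other bases, so only
same-base error pileups can imitate an alternative allele; reads showing
neither candidate allele are discarded from the likelihood. Genotypes are
called by binomial maximum likelihood over {0/0, 0/1, 1/1} with a variant
prior of 1e-3 (the magnitude a bcftools-style caller uses): posterior odds
≥ 100 (phred 20) against 0/0 emit the best variant genotype, odds ≤ 1 emit
a confident 0/0, anything between is missing, as is any call outside the
[5, 2·mean+1] depth window. At invariant positions only error pileups of ≥ 3
same-base reads can clear the odds threshold, which is what the spurious-SNP
scan exploits for speed. With error 0 and fixed depth 5 the model reduces
exactly to the textbook case: a heterozygote is miscalled iff all five reads
sample one allele, rate 2·(1/2)⁵ = 1/16.

**Metrics.** Genotype-level recovery divides correct calls by all true
genotypes; sensitivity by non-missing calls; FDR is the fraction of emitted
calls of a class whose truth differs. These are computed over truly
segregating sites. SNP-level recovery is the fraction of truly segregating
sites with a variant call in ≥ 1 sample; SNP-level FDR counts variant-called
sites that are not truly segregating, including error-pileup sites at
invariant positions. Per-group SNP recovery restricts both the site set
(≥ 1 non-hom-ref truth genotype within the group) and the detection events
to that group's samples.

**Problem sizes.** The evaluation defaults to 20 replicates of 100 kb —
about 3.6 k segregating sites per replicate under this demography — which
stabilizes the mean recovery to ±0.1 pp while keeping a full run around ten
seconds. Under these conditions the simulation detects ≈ 98% of segregating
sites at ≈ 0.26% SNP-level FDR. A read-level pipeline on real genomes loses
additional sites to mapping failure in repetitive or structurally variable
regions; this model deliberately excludes those mechanisms, so its recovery
should be read as the no-mapping-loss ceiling of the calling conventions,
a few points above what a full read-level evaluation reports.

## Synthetic data

The fixture generator reuses the same coalescent and demography, then adds
nucleotide identities: the ancestral base is the background-sequence base;
the derived base is drawn with transition bias κ (default 4, giving Ts/Tv
≈ 2, matching the genome-wide values reported for mammalian panels).
The background sequence is a first-order Markov chain whose stationary
composition equals the GC target (default 42%) while P(G|C) is scaled by a
CpG-enrichment factor (default 0.25 — vertebrate genomes are CpG-depleted),
constructed so every base keeps its marginal frequency exactly; the
realized CpG count is therefore `enrichment · f(C) · f(G) · (L−1)` in
expectation. Gene tracks are non-overlapping intervals covering roughly a
third of the sequence; recombination rates are lognormal (right-skewed, as
real maps are). Outgroup genotypes are generated directly — homozygous
ancestral, flipped to homozygous derived with a configurable discordance
probability and dropped with a missingness probability — rather than
simulated coalescently; the fixtures only need to exercise rules A/B, and
outgroup depths/missingness are free parameters the source data do not pin
down. Per-sample VCFs contain, at each truth site, a variant record, a
confident-reference record, or nothing (depth dropout); no genotype errors
are introduced in this path, so merging a bundle reproduces the truth
exactly under the dropout mask — calling errors belong to the pipeline
simulation, not the fixture generator.

All randomness in a bundle flows from one integer seed, split into fixed
named substreams (reference, coalescent, bases, outgroups, depths, dropout)
via numpy `SeedSequence` spawn keys, so any subset of artifacts is
reproducible independently.

### What the synthetic data does not emulate

Alignment artifacts (repeats, CNVs, indels — indels are excluded from scope
entirely), GC-coverage bias, correlated (non-Poisson) depth along the
genome, CpG-elevated mutation rates (the generator's Ts bias is
site-independent, so window-level Ts/Tv–CpG correlations of real genomes do
not arise spontaneously in fixtures), and linked selection. Tests passing on
these fixtures validate the bookkeeping and the statistical conventions,
not robustness to mapping pathologies of real data.

## Numerical and degenerate-input conventions

Undefined ratios (Ts/Tv without transversions, FDR without calls, group
recovery without true sites) are NaN or 0-with-flag rather than raising;
empty eligible site sets yield empty/zero outputs with a warning where the
result object allows it. Allele-order ties at merged sites resolve
lexicographically; modal-size ties resolve toward larger n; genotype
likelihood ties at k = n/2 resolve toward the heterozygote. All seeds
derived for msprime are kept below 2³¹.
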