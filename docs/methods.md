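# Methods

## The sex-determination model

Three sex chromosome types co-segregate: W, Z and Y. Sex is a pure function
of the unordered pair an individual carries, under a dominance hierarchy —
Y over W over Z: {WY, ZY, ZZ} → male, {WW, WZ} → female. YY is classified
male by the same rule but is never produced by a valid cross (mothers never
carry Y) and the simulator refuses YY parents. Gametes are drawn with equal
probability from a heterozygous parent; a transmission-distortion parameter
exists for sensitivity analyses and defaults to fair segregation (0.5).

All cross-level expectations are computed on the *parent-of-origin resolved*
offspring distribution (maternal allele, paternal allele). Complete paternal
Y linkage holds when the father carries exactly one Y and the paternal Y is
transmitted to every son and no daughter; complete maternal W linkage is the
mirror condition on the maternal W. These definitions reproduce the known
sets: {WZ×WY, WW×ZY, WW×WY} paternally Y-linked, {WW×ZZ, WZ×ZZ} maternally
W-linked, and WZ×ZY as the single cross with a skewed (1:3) sex ratio.

## What the synthetic data emulate — and what they do not

The family generator produces diploid genotypes at RAD-style markers
(restriction-site tags carrying 0–2 SNPs) for two parents and their F1
offspring. Study-condition defaults: ~40 offspring; marker density
2 tags/Mb; a four-chromosome genome (Chr1 217 Mb, Chr3 154 Mb, Chr7 134 Mb,
Chr10 52 Mb — a scaled-down karyotype retaining a full-length sex
chromosome); the sex-linked (SL) region Chr7:1–10,300,000 with the
sex-determining locus at 9,940,000; offspring depth mean 30× and parents
120× (gamma–Poisson with shape 6); genotype quality a deterministic ramp of
depth with Gaussian jitter; het→hom error rate 0.02 applied before 3%
random missingness.

**Recombination.** Crossover counts per chromosome are Poisson with mean
equal to the map length in Morgans — *no crossover interference*, the
simplest model compatible with Kosambi-based mapping downstream (a known
mismatch: Kosambi assumes partial interference, so estimated map lengths
are mildly compressed). Sex-specific rates default to 0.63 cM/Mb (female)
and 0.25 cM/Mb (male), i.e. a ~2.5-fold female:male map-length ratio.
Female crossover positions are uniform; male positions follow a symmetric
Beta(a, a) with a = 0.4 mapped onto the chromosome, concentrating events at
the tips (the qualitative pattern reported for male meiosis; no functional
form is published, so the shape parameter is exposed). Recombination is
suppressed across the whole SL region in any parent carrying a W there;
Z–Y recombination is allowed, so a ZY father can transmit recombinant sex
chromosomes whose type at the sex-determining locus decides offspring sex.

**Gametolog divergence.** SL-region markers are type-diagnostic with
probability 0.8; a diagnostic marker's derived allele is assigned to the W,
Z or Y branch with probability proportional to additive branch lengths
derived from the pairwise divergences (defaults d_WZ = d_WY = 0.01,
d_ZY = 0.002, so branch weights ≈ 9:1:1 and the Y is Z-derived by
construction). Non-diagnostic markers are ordinary shared polymorphisms.
This marker-level model realizes the divergence structure without per-bp
sequence simulation; it does *not* model within-type polymorphism at
diagnostic sites, reference-mapping bias, or restriction-site dropout.

**Unrelated cohorts.** For population-scale scans a separate generator
draws each individual's two chromosome types from population frequencies
(rejection-sampled to match phenotypic sex) and assigns independent
per-site allele frequencies outside the diagnostic SL markers — no linkage
disequilibrium except that created by the sex chromosomes, which is what a
between-sex FST scan on wild samples assumes. Within a single family, by
contrast, chromosome-scale LD makes sex-linkage signals (and FST) shade
beyond the SL boundary; this shoulder is real family-genetics behavior, not
an artifact, and the tests account for it.

**Expression.** Counts are negative binomial (dispersion 0.2) around
log-normal gene baselines; sex effects are assigned at gene level and
shared by a gene's transcripts. By default 12% of SL-region genes are
male-biased with |logFC| = 2 + Exp(1.5), 60% of those male-specific (zero
female mean); 0.8% of background genes are biased in each direction.
Fourteen offspring (9 daughters, 5 sons) are profiled, with ~800 SL and
4,000 background transcripts at ~50 callable bp each — the scale of the
motivating dataset. Per-transcript heterozygous-site counts are
Binomial(callable bp, π) with π the divergence of the individual's true
chromosome pair (θ = 5×10⁻⁴ within-type). What passing tests show is that
the *inference machinery* recovers truth under this generative model; they
do not validate count-model assumptions (e.g. edgeR-style dispersion
estimation) against real libraries.

## Analysis stages and numerical choices

**QC cascade order** (the source filters are listed unordered; this order is
fixed and logged): quality mask (DP < 15 or GQ < 20 → missing) →
site offspring-missingness (> 20%, strict) → exact Hardy–Weinberg among
offspring (Levene/Haldane conditional distribution, two-sided by summing
probabilities ≤ observed; α = 0.01 default — unspecified at source and
statistically odd in an F1, hence configurable) → Mendelian impossibility
(> 10% of called offspring, evaluated only when both parents are called) →
one random SNP per RADtag (seeded) → individual missingness (> 20%,
offspring only; a toggle disables it for small families). The cascade is
idempotent.

**Sex-linkage scan.** Informative sites are those heterozygous in the focal
parent and homozygous in the other; offspring are recoded to the inherited
focal allele, with impossible genotypes set missing. Adjacent markers are
phased greedily to minimize implied recombinants (ties keep the current
phase). Masking: per offspring, any maximal run of equal states flanked on
both sides by the opposite state, whose flank-to-flank physical span is
≤ 10 Mb, is set to missing, iterating to a fixed point; runs at chromosome
ends are never masked. The association statistic is a two-sided Fisher
exact test on the 2×2 (inherited allele × sex) table — exact at family
sample sizes; χ² is available. BH-FDR is applied within a (family, parent)
scan and can be disabled for small families. Under the generator's
independent-error model, masking removes error genotypes and thereby
*sharpens* true signals while reducing error-driven false positives off the
sex chromosome; the false-positive property is therefore assessed on
off-sex-chromosome sites at small family size.

**FST.** Weir & Cockerham (1984) two-deme θ per biallelic site (Hudson
optional), computed from genotype counts with missing data handled per
site; monomorphic or under-covered sites are undefined and excluded before
windowing. Negative per-site θ is retained (standard practice). Windows are
means of 50 consecutive usable SNPs, step 1, never spanning chromosomes;
the window coordinate is the lower-median SNP position (first/last
positions are also emitted). The null band resamples autosomal window
values — both a bootstrap CI of the mean and a plain envelope are offered
because the published genome-wide interval is ambiguous between the two.

**Expression bias.** TPM with per-kb rates scaled to 10⁶ per individual;
logFC = log2((male mean + 0.125)/(female mean + 0.125)). The canonical path
consumes an external differential-expression table (logFC, FDR); the
internal fallback is a Welch t test on log2(TPM + prior) with BH-FDR — a
documented approximation, not a count model. Significance requires
q < 0.05 and |logFC| > 2; "specific" additionally requires zero raw counts
in every individual of the minor sex. Transcripts are assigned to regions
by start coordinate; densities are per Mb at full precision (rounded to one
decimal only in reports); enrichment is the exact upper-tail binomial
probability of the male share inside the region given the rest-of-genome
share.

**π-based genotype inference.** Within-individual π for a diploid is
heterozygous/callable sites after DP ≥ 4, GQ ≥ 20, MQ ≥ 20 filters;
the per-individual SL summary is site-weighted (Σhet/Σcallable over region
transcripts), with the unweighted per-transcript mean emitted alongside.
Two-level detection uses the largest gap in the sorted per-sex values,
accepted only if it exceeds 3× the larger of (a) the spread of background π
across individuals and (b) the median binomial sampling SE of the π values
— the second floor prevents counting noise at elevated π from faking a
split. Cross resolution treats observed level counts as lower bounds on the
cross's per-sex genotype counts (five sons are all one genotype in ~6% of
WZ×WY draws) and requires a unique consistent cross; with a resolved cross,
groups ordered by mean π map to genotypes ordered by expected divergence
(WW/ZZ < ZY < WZ/WY), a sex whose level count falls short abstains, and a
call whose genotype contradicts the phenotypic sex is never emitted.
Y-origin: from_Z iff the pooled π of the ZY class is below both W-involving
classes with ≥ 0.95 support from 1,000 bootstrap resamples of transcripts
within class (from_W symmetric; otherwise undetermined).

**Maps.** Markers keep their physical (assembly) order; LOD-based grouping
and de-novo ordering are out of scope. Adjacent-interval recombination
fractions are recombinant/informative offspring, accumulating intervals
until ≥ 5 informative offspring; Kosambi is the default mapping function
(Haldane optional) — a convention choice, not a claim about the original
pipeline. Crossovers are one event per state flip between consecutive
non-missing markers (midpoint = mean of the flanking positions); quartile
densities pool events into four equal physical bins per chromosome, with
tip bias = (Q1+Q4)/total. The map-length model is OLS with the design
`maplength ~ sex*family + sex:family:bpcovered`; per-(sex, family) slopes
and t-based 95% CIs are extracted via design-matrix contrasts, and a
residual-normality diagnostic is reported. Crossovers beyond the terminal
markers of a chromosome are invisible to any map; because male events
concentrate at the tips this truncation depresses male map lengths and tip
bias at low marker density, so density-sensitive checks use ≥ 5 tags/Mb.

## Problem sizes in the test and acceptance runs

Seeded replicate tests use a two-chromosome genome (Chr1 150 Mb + the full
Chr7) and the defaults above: 100-seed loops for FST peak localization
(unrelated cohorts of 12 females / 26 males at 10 tags/Mb), masking
false-positive pairing (12-offspring WZ×ZY families), genotype
classification and Y origin (14-offspring expression datasets), slope-CI
coverage (40 synthetic maps per fit) and male tip bias (60-offspring
families on two 150 Mb autosomes). The acceptance script reports the same
quantities at 25 seeds per rate plus the analytic and worked numbers.

## Known limitations

- No crossover interference; no reference-mapping or allele-dropout bias;
  RADtag positions are uniform rather than restriction-site driven.
- The internal DE test is a normal-theory approximation on transformed TPM.
- The largest-gap split assumes at most two diversity levels per sex (true
  for any single cross, not for pooled families).
- Coordinates are single-assembly; dual-assembly (lift-over) reporting is
  out of scope.
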