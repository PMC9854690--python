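# Methods

## Study design being emulated

`ewescan` reproduces, as reusable code, a selection-signature scan for
fecundity in a single flock of Katahdin ewes genotyped on a ~50k SNP
array: covariate-adjust the fecundity phenotype, split the flock into
high/low subpopulations, QC the markers, then look for two kinds of
footprints — shared runs of homozygosity (ROH) per group and per-SNP
allele-frequency differentiation between groups — and annotate candidate
regions with genes. The original genotypes are available only on request,
so the package ships a synthetic-cohort generator whose defaults encode
the study conditions (23 high- and 25 low-fecundity ewes, group fecundity
means 1.3 and 1.1, 25 autosomes) with planted, recoverable signals.

## Phenotype model and group formation

Fecundity (0/1/2 lambs per mating per year, three years of records) is
modelled as a Gaussian identity-link linear function of the candidate
covariates; per-coefficient Wald statistics are (estimate/SE)² referred
to χ²(1), and covariates with p < 0.05 are retained. With the default
generator only body condition carries signal, so the final model is
`y = β₀ + β₁·bc`. "Accuracy" is the fraction of ewes whose fitted value,
rounded to the nearest category (clamped to [0,2]), equals the observed
category — the most natural reading of a single-number prediction
accuracy for a rounded Gaussian fit; other classification rules would
give slightly different numbers.

Groups come from agglomerative hierarchical clustering on the Euclidean
distance matrix of the adjusted (fitted) phenotypes, cut at k = 2.
Linkage defaults to *complete* (the default of the classic `hclust`
routine this step mirrors); it is configurable because the choice is not
dictated by the method. The higher-mean cluster is labelled "high". The
group contrast is Welch's t (Satterthwaite df), computed on the adjusted
values — the quantity that was clustered; the raw 0/1/2 outcome differs
between groups by only ~0.2 lambs and could never show the extreme
p-values the adjusted contrast does.

Aggregation: by default one record per ewe (mean fecundity across years,
covariates from the latest year). Per-year records remain available in
the phenotype table for callers who want a repeated-measures treatment,
which this package deliberately does not implement (no mixed models).

## Marker QC

Three filters, evaluated on the full input matrix and removed as a
union: MAF < 0.05; exact Hardy–Weinberg test p < 10⁻⁶; call rate < 90%.
Per-filter counts therefore may overlap; the report records every reason
per marker. The HWE test is the conditional exact test on heterozygote
counts: configurations no more probable than the observed one are summed,
with the "no more probable" comparison decided in exact integer
arithmetic so probability ties are handled exactly; only the final
summation is floating point. The exclusion direction is the standard one
(small p = disequilibrium = excluded); a flag flips it for auditing
because published descriptions of this step are sometimes printed with
the opposite sign. Markers with no calls at all fall to the call-rate
rule; their MAF/HWE statistics are undefined and reported as NaN.

## ROH scan

Sliding-window detection in the style of the classic SNP-array ROH
callers: every contiguous window of `windowSize` SNPs on a chromosome is
homozygous iff it has ≤ `maxOppWindow` heterozygous and ≤ `maxMissWindow`
missing calls; a SNP's score is the fraction of covering windows that are
homozygous; SNPs scoring strictly above `threshold` are in-state; maximal
in-state stretches with ≥ `minSNP` SNPs are runs. Defaults: 15 / 0.05 /
20 / 1 / 1. Length, gap and density constraints found in some callers
exist as options but are disabled by default. Note the strict ">" rule
makes `threshold = 1` vacuous (no score exceeds 1); the "reduce to
maximal homozygous stretches" closed form is obtained with
`windowSize = 1, maxOpp = maxMiss = 0, minSNP = 1` and any threshold in
(0, 1).

Per group, a SNP's in-ROH frequency is the fraction of the group's ewes
with at least one run covering it. Consensus candidate haplotypes are
maximal stretches of ≥ 3 consecutive SNPs with frequency ≥ 0.75
(inclusive boundary: the cutoff is a minimum requirement). Stretches
never cross chromosome boundaries. Published tables of this scan report
3–11-SNP entries that cannot be individual runs under minSNP = 20; they
are consistent with these consensus haplotypes, which is how this package
interprets and reports them.

## F_ST scan

Two statistics per marker. Within each group, F = 1 − H_o/H_e with
H_e = 2p(1−p) from the group allele frequency (F ≡ 0 where the group is
monomorphic), and the differential Δ = |F_high − F_low|. Alongside, the
two-population per-locus Weir–Cockerham θ = a/(a+b+c) from the standard
variance components (sample sizes, allele frequencies, heterozygote
fractions; r = 2). Candidates are markers at or above the top-20%
empirical quantile of the ranking statistic, ties included, deterministic
(chromosome, bp) order.

The default ranking statistic is θ, not Δ. The choice is forced by the
statistics, not convenience: when each subpopulation is internally in
Hardy–Weinberg proportions, E[F] ≈ 0 in both groups *regardless of the
frequency gap between them*, so Δ is pure sampling noise and ranks a
0.9-vs-0.1 fixed-effect locus no better than chance (verified by
simulation during development: Δ recovers ~17% of planted loci where θ
recovers 100%). Δ remains available (`--stat delta`) as the literal
reading of "difference between the fixation values per SNP".

## Annotation

A candidate SNP at position p becomes the closed 1-based region
[max(1, p−50000), p+50000]; a candidate haplotype is flanked from its bp
span. Overlapping regions of the same (method, group) are merged so a
gene between two adjacent candidate SNPs is reported once; an unmerged
mode exists for auditing. A gene is reported iff its interval overlaps a
region by ≥ 1 bp (closed-interval overlap; `--min-overlap-bp` tightens
it). Regions export as BED (converted to 0-based half-open at the file
boundary; everything internal is 1-based inclusive). The package bundles
a transcription of the published Katahdin candidate-gene table as the
reference shape for the report and as input to the count summarizer.

## Synthetic cohort generator

What it emulates: two subpopulations drawn SNP-by-SNP under
Hardy–Weinberg proportions from shared base frequencies
(MAF ~ U(0.10, 0.50)); planted frequency-differentiated loci
(group-specific frequencies, default 0.8 vs 0.2); planted shared ROH — a
span of SNPs overwritten with one homozygous haplotype in a carrier
fraction (default 0.9 / 0.85) of one group, the footprint of a selected
IBD segment; planted QC failures (loci with ≤ 3 minor alleles, loci with
all-homozygous genotypes, loci with 15% forced missingness) plus uniform
2% missingness applied last, so planted tracts are het-free pre-masking.
Default marker density is 80 SNPs per 4 Mb chromosome (~50 kb spacing,
the chip's density) over 25 autosomes — 2000 markers, a desk-scale stand-in
for the ~50k chip that keeps every test and the acceptance script fast;
all sizes are configurable.

Two deliberate structural choices:

* **Planted-ROH spans draw base frequencies near 0.5** and the shared
  haplotype is one of the common alleles. A shared IBD segment of a rare
  haplotype would drag span SNPs across the MAF and pooled-HWE filters
  and silently delete the planted signal in QC — which is a property of
  whole-sample QC, not of the scan.
* **Default differentiated-locus frequencies are 0.8/0.2, not more
  extreme.** Pooling two groups fixed near 0.9/0.1 produces a Wahlund
  heterozygote deficit whose exact-HWE p straddles the 10⁻⁶ exclusion
  threshold at n = 48, i.e. whole-sample QC can remove exactly the loci
  the scan is meant to find. At 0.8/0.2 the pooled deficit is far from
  the threshold while θ ≈ 0.35 still ranks deep inside the top 20%. The
  recovery experiments that specifically stress 0.9 vs 0.1 run on the
  scan stage directly (true groups, no QC), matching what they measure.

Phenotypes follow a liability y = β₀ + β₁·bc + offset_group + ε,
ε ~ N(0, 0.35), rounded to {0,1,2} and clamped. Body-condition
distributions differ by group (high-fecundity ewes in better condition):
the pipeline clusters the model-*fitted* values, which are functions of
body condition only, so group structure must be visible through the
retained covariate to be recoverable at all. Group offsets are solved
numerically (Brent's method on the exact discretized-mean expression) so
the realized group means converge to the configured 1.3/1.1. Because the
fitted values take at most five distinct levels (one per body-condition
score), the k = 2 cut lands on a body-condition boundary; depending on
where sampling puts the gap, truth-group agreement ranges roughly 85–98%
across seeds. A
`calibrate_means=False` mode gives the bare model (offsets 0), used for
limit checks such as accuracy → 1 as noise → 0 (under calibration that
limit cannot hold, because hitting a fractional target mean parks one
body-condition class on a category boundary).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium and recombination-scaled
haplotype structure (SNPs are independent given the planted tracts),
pedigree relatedness, genotyping-error patterns, informative missingness,
X-chromosome dosage, and selection acting on standing variation rather
than planted blocks. Recovery rates here are upper bounds on what
LD-structured real data would give.

## Numerical and convention notes

* Genotypes are alt-allele counts {0,1,2} with −1 as the missing
  sentinel; PED import maps the first-seen allele to reference by default
  (an explicit reference map makes round trips exact); every downstream
  statistic is invariant to allele relabeling (tested).
* All internal coordinates are 1-based inclusive; run length is
  end − start + 1; BED conversion happens only at file boundaries.
* PCA mean-imputes missing calls, centers, unit-scales by default
  (drift scaling 2p(1−p) available), drops zero-variance markers, and
  orients each component so its largest-magnitude loading is positive.
* θ is undefined (NaN) for loci monomorphic across both groups or with a
  group entirely missing; such loci are excluded from quantile selection.
* Welch's test returns t = 0, p = 1 for two zero-variance equal-mean
  groups, and ±∞, p = 0 for zero-variance unequal means.
* Determinism: one `numpy` Generator seeded from the config drives the
  whole simulation; identical config + seed gives byte-identical output
  files, and the pipeline stamps every result table with a hash of the
  science-relevant config fields (output paths excluded).

## Problem sizes used in the test and acceptance runs

Defaults everywhere: 48 ewes × 2000 markers. The differential-recovery
experiment uses 20 planted loci among 2000 (4 × 500-SNP chromosomes) over
200 seeds; null calibration uses 25–40 seeds of the default shape; the
ROH end-to-end check runs 6–8 full cohorts; the exact-HWE cross-check
enumerates every genotype triple with n ≤ 50; the ROH brute-force
cross-check runs 100 random 20-ewe × 200-SNP instances with randomized
window parameters. These sizes were chosen so the whole suite documents
the method's behavior in about half a minute while keeping every
statistical claim testable at its stated confidence.

## Known limitations

Two-group design only (r = 2 variance components); no window-averaged
F_ST, XP-EHH, hapFLK or Tajima's D; no ROH-based inbreeding coefficients
or length-class analyses; no per-individual QC (heterozygosity outliers,
relatedness); no mixed-model phenotype adjustment; no ortholog mapping or
enrichment on the candidate genes. The published study's
genotype-dependent headline numbers (post-QC marker count, total ROH
counts, candidate-marker counts on the real chip) cannot be reproduced
without the restricted genotypes and are not targets of this package's
checks.
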