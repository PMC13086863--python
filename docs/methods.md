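# Methods

This note documents the models and procedures implemented in `loxpop`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions adopted where the
design was genuinely open.

## Cohort representation

The in-memory substrate is a samples × sites matrix of diploid genotype
codes in {0, 1, 2, MISSING}, counting non-reference alleles (or derived
alleles after polarization), with per-site metadata (chromosome, 1-based
position, REF/ALT, ancestral allele, functional impact) and optional
per-genotype DP and AD fields. Only biallelic SNVs are retained on read;
indels and multiallelic records are dropped, not split. VCF positions are
1-based; BED intervals are 0-based half-open, and all internal interval
arithmetic uses the BED convention (1-based position p lies in [s, e) iff
s ≤ p−1 < e). The ancestral allele comes from the AA INFO tag or a
sidecar table; sites lacking it are excluded from derived-allele
operations only. Functional impact is parsed from ANN annotations with
ties across transcripts resolved by severity (HIGH > MODERATE > LOW >
SYNONYMOUS); a `synonymous_variant` effect is tabulated as its own
category because it serves as the load-normalization baseline.

## Site and genotype filters

**Global depth.** Per-site total depth is summed over samples; a site is
kept iff 0.5·m ≤ d ≤ 1.5·m, where m is the median total depth over all
sites before any filtering and both bounds are inclusive. The median is
genome-wide, not per-chromosome.

**Excess heterozygosity.** The per-site inbreeding coefficient is
F = 1 − H_obs/H_exp with H_exp = 2p̂(1−p̂); F is undefined (NaN) at
monomorphic sites and reaches −1 when every call is heterozygous. The
Hardy–Weinberg test is the exact conditional test: given the observed
allele counts, the p-value sums the probabilities of all attainable
heterozygote counts whose probability does not exceed that of the
observed count (plain minimum-likelihood two-sided tail; no mid-p).
A site is flagged when F < −0.90 **and** p < 10⁻⁶, and every site within
±5 kb (a 10 kb window centered on the offending site, boundaries
inclusive) is excluded as well; overlapping windows merge. F is computed
from hard genotype counts rather than genotype likelihoods — at high
coverage these target the same quantity; the divergence matters only for
low-coverage data, which this stack does not model.

**Genotype masks.** A genotype becomes MISSING when DP < 10, DP exceeds
2× the global mean depth, or it is heterozygous with fewer than 2 reads
supporting either allele (a heterozygote lacking AD is masked with a
warning). Site-level MAF ≥ 0.05 and missingness ≤ 0.05 filters are
applied before ROH calling.

## Differentiation and structure

**Hudson F_ST.** The corrected estimator in ratio-of-averages form:
per-site numerator (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) and
denominator p₁(1−p₂) + p₂(1−p₁), summed over sites before dividing.
Ratio-of-averages was chosen over averaging per-site ratios because the
latter is dominated by low-information sites; this matches how the
estimator is defined in the f-statistics literature. Sites with fewer
than two allele copies in either population are skipped with a warning;
sites monomorphic in both contribute 0/0 and drop out. The same estimator
marginalized from the joint 2D-SFS is implemented independently and
agrees exactly on complete-data sites (a tested invariant).

**PCA.** Genotype columns are centered by 2p̂ and scaled by √(2p̂(1−p̂))
(variance scaling is the default, matching common PLINK practice; a flag
disables it); monomorphic columns are dropped; missing genotypes are
mean-imputed; scores come from an SVD. Sign convention: each component's
largest-magnitude loading is positive.

**Hybrid index.** h = 1 − (x − x_sav)/(x_for − x_sav) over PC1 scores,
anchored on one savanna and one forest individual. As printed, the
formula maps the savanna anchor to 1 and the forest anchor to 0 even
though it measures forest ancestry; because the sign of PC1 is itself a
convention, the implementation follows the formula verbatim and exposes
`orient="forest"` to flip the orientation. Values outside [0, 1]
(samples beyond the anchors) are reported as-is. The index is invariant
to affine rescaling of the PC axis.

## Introgression statistics

f4 and D are computed from population allele frequencies (the
frequency-based estimators; identical in expectation to single-sequence
sampling with lower variance). D uses the normalization
Σ(p₁+p₂−2p₁p₂)(p₃+p₄−2p₃p₄), so a single site with (1,0,1,0) gives
exactly D = 1. Swapping H1 and H2 negates D and Z exactly.

**Block jackknife.** Sites are tiled greedily into contiguous blocks of
at most 5 Mb (never crossing chromosomes); both printed block-size
conventions ("5 Mb", "5 × 10⁶ SNP block size") are exposed as the single
`block_bp` parameter defaulting to 5,000,000 bp — the SNP-count reading
is noted but not implemented. Standard errors use the weighted
delete-one jackknife of Busing et al. (1999) with block weights equal to
informative-site counts, the convention of the ADMIXTOOLS ecosystem; at
equal weights it reduces exactly to the plain delete-one formula (tested).
With a single non-empty block the point estimate is returned with SE and
Z undefined (NaN) rather than raising, so degenerate micro-examples
remain computable.

**F4 ratio.** α = f4(A,O;X,B)/f4(A,O;C,B), with both terms restricted to
the common site set and jackknifed on the same partition so the SE
reflects their covariance. The denominator must be significantly nonzero
(default |Z| ≥ 3), otherwise an unstable-ratio error carrying both f4
estimates is raised.

**Mantel test.** Spearman correlation of the strictly-lower-triangle
entries, with a one-sided permutation p-value
(1 + #{ρ_perm ≥ ρ_obs})/(n_perm + 1), permuting the row/column labels of
the second matrix jointly. One-sided matches the directional hypothesis
(ancestry declining with distance); the caller chooses the orientation of
the similarity/distance matrices. The permutation core is vectorized and
driven by a mandatory seed. Distances to a habitat boundary are minimum
haversine distances (Earth radius 6371 km) to the vertices of the
boundary polylines after spherical densification to ≤ 1 km spacing.

## Runs of homozygosity and diversity

The ROH caller reproduces the PLINK 1.9 `--homozyg` sliding-window
algorithm with the PLINK defaults for every parameter not explicitly
overridden: 50-SNP windows, window hit-fraction threshold 0.05, minimum
100 SNPs and 1,000 kb per segment, density ≤ 50 kb/SNP, maximum interior
gap 1,000 kb; the per-window allowances are opened to 3 heterozygous and
20 missing calls. Windows that would extend past a chromosome end are
truncated rather than dropped — PLINK's own edge behavior has
undocumented corners, so byte-equality with `.hom` output at chromosome
edges is not promised; planted-tract recovery tests bound the boundary
error at about one window instead. Chromosomes with fewer SNPs than one
window are skipped with a warning. The missing-call allowance is
implemented and tested even though imputed inputs have no missingness.

F_ROH divides summed segment lengths by a configurable autosomal span
(for simulated cohorts, the summed chromosome lengths; 2.6 Gb is the
real-genome analogue). ROH size classes are left-closed/right-open with
default breaks at 2 and 5 Mb, so a segment of exactly 2 Mb falls in the
2–5 Mb class. Heterozygosity is the proportion of heterozygous genotypes
among callable sites (variant plus invariant, supplied as a span by the
caller after masking); heterozygosity outside ROH masks each sample's own
segments and its span accordingly.

## Kinship

R0 = O/S, R1 = S/Σ(discordant cells) and KING = (S − 2O)/(H_i + H_j) are
computed from the pair's 3×3 joint genotype-count table. Published R1
denominators vary; the all-discordant-cells denominator is adopted, and
classification relies on KING and R0 only (R1 is reported descriptively).
Thresholds follow the standard KING powers-of-two convention: ≥ 0.354
duplicate, ≥ 0.177 first degree. Undefined denominators yield NaN, not
exceptions. Pruning is greedy by descending KING, removing the
lower-coverage member of each still-intact flagged pair (later id on
ties). These are hard-genotype analogues of genotype-likelihood
estimators and target the same statistics at high coverage.

## Genetic load

Per sample, derived-allele counts are tabulated by impact class and
zygosity after polarization; sites with unknown ancestral state are
excluded from all load counts (logged). Heterozygous load =
n(het HIGH or MODERATE derived)/n(het SYNONYMOUS derived), and the
homozygous analogue; LOW-impact counts are tabulated but carry no ratio.
Ratios are undefined (NaN), never zero, when the synonymous denominator
is empty, and are scale-free under site duplication.

The two-group comparison runs Shapiro–Wilk per group and uses Welch's
two-sided t-test when both groups look normal at α = 0.05 (with
Welch–Satterthwaite df, a Welch-df CI of the mean difference, and
pooled-SD Cohen's d — pooled SD despite the unpooled test, matching
common reporting practice), otherwise a Wilcoxon rank-sum test with the
Hodges–Lehmann shift (median of pairwise differences) and its
order-statistic 95% CI from the normal approximation of the Mann–Whitney
null. Constant groups make normality undefined and fall through to
Wilcoxon; `force_test` overrides the gate (used for calibration studies,
where the test choice must not vary across replicates).

## Synthetic cohorts

Frequencies follow a hierarchical Balding–Nichols model: ancestral
p₀ ~ Uniform(0.05, 0.95) per site; each species draws
Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with species drift F; each population
draws analogously around its species frequency with its own drift. An
admixture pulse replaces the recipient's frequency with
(1−α)·own + α·donor before genotypes are drawn, which makes the F4-ratio
expectation exactly α (f4 is linear in frequencies) — the property the
recovery tests exploit. Genotypes are two Bernoulli allele draws per
diploid; planted autozygous tracts overwrite genotypes with a doubled
single haplotype; DP ~ Poisson(mean), AD ~ Binomial(DP, ½) for
heterozygotes. Frequency-level simulation was chosen over a coalescent
because every target statistic then has an analytically known
expectation; the trade-off is that sites are unlinked, so linkage
disequilibrium, recombination maps and selection are *not* emulated —
the block jackknife is exercised positionally but its robustness to LD
is not tested here, and passing tests say nothing about LD-driven
artifacts in real data. Sequencing error beyond depth sampling is also
not modelled.

Preset study conditions (used by the acceptance suite and
`scripts/acceptance.py`):

- `trace-introgression` — outgroup + two forest + two savanna populations,
  25 diploids each, 100k sites over 20 × 25 Mb chromosomes (100 jackknife
  blocks), species drift 0.3, population drift 0.02, forest→savanna pulse
  with default α = 0.005 (the trace-ancestry regime);
- `inbred-isolate` — one panmictic population of 10 diploids, 220k sites
  over 4 × 20 Mb chromosomes, giving a background per-bp heterozygosity of
  ≈ 10⁻³; per sample, planted tracts of 1.5 and 2.5 Mb totaling 5% of the
  genome;
- `load-contrast` — two drift-free species labels of 25 diploids (so the
  two groups are exchangeable under the null and test calibration is
  meaningful), 20k sites, impact classes HIGH 5% / MODERATE 15% / LOW 10% /
  SYNONYMOUS 30%, deleterious frequencies scaled ×0.2; the alternative
  multiplies species A's deleterious frequencies by a further 1.5;
- `pedigree` — one panmictic population at 50k sites for Mendelian
  offspring, clones, and unrelated pairs;
- `two-species` — a five-population, two-species cohort with depth fields,
  impact annotations, polarization noise and one 5% pulse; the pipeline
  smoke-test substrate.

Problem sizes were chosen so each recovery check has comfortable
statistical power while the full suite runs in a couple of minutes on one
CPU.

## Numerical conventions and degenerate inputs

- Exact-HWE probabilities are computed in log space with a 1 + 10⁻¹²
  relative slack when comparing against the observed configuration, so
  the observed outcome always counts itself despite rounding.
- Monomorphic sites: F undefined (NaN), HWE p = 1 (single attainable
  configuration).
- Jackknife z is +∞/0 conventionally when SE = 0 (all block ratios
  identical) and NaN with fewer than two non-empty blocks.
- The greedy block partition starts a new block when the positional span
  would reach the block size, and always at chromosome boundaries.
- Interval sets are merged on load; empty intervals are rejected.
- The simulator requires a seed; identical (config, seed) produce
  byte-identical VCFs (single integer-state generator, fixed draw order).

## Known limitations

- No linkage disequilibrium in synthetic data (see above).
- F and kinship from hard genotypes, not genotype likelihoods: unsuitable
  for low-coverage cohorts without prior imputation.
- ROH calling is not guaranteed byte-identical to PLINK at chromosome
  edges (truncated-window policy).
- The Mantel test's one-sided orientation is the caller's responsibility.
- Model-based ancestry (ADMIXTURE-style), graph fitting, phasing,
  imputation and variant-effect annotation are out of scope; annotations
  and masks are consumed, not produced.
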