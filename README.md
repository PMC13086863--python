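# loxpop

Population-genomic inference for cohorts of two deeply diverged, partially
admixing species — the analysis stack used in continent-wide studies of
African savanna and forest elephants, reimplemented as a tested, reusable
Python library with a command-line front end.

## Who this is for

Conservation and population genomicists working with multi-sample VCFs of
diploid genotype calls who need, in one coherent stack:

- **reliable-site filtering** — global-depth bounds around the cohort
  median, excess-heterozygosity (paralog) screening via per-site inbreeding
  coefficients and an exact Hardy–Weinberg test with 10 kb exclusion
  windows, genotype-level depth/allele-support masks, MAF/missingness
  filters;
- **differentiation and structure** — the corrected Hudson F<sub>ST</sub>
  (Bhatia–Patterson ratio-of-averages) from per-population frequencies or
  marginalized exactly from the 2D site-frequency spectrum; PCA with a
  PC1-anchored hybrid index;
- **introgression statistics** — ABBA-BABA D, f4, and the F4-ratio
  admixture proportion α = f4(A,O;X,B) / f4(A,O;C,B), all with weighted
  block-jackknife standard errors (default 5 Mb blocks), plus a seeded
  Mantel test and great-circle distances to a habitat boundary;
- **inbreeding and diversity** — PLINK 1.9 `--homozyg`-style runs of
  homozygosity, F<sub>ROH</sub>, ROH size classes, and heterozygosity
  inside/outside ROH;
- **sample QC** — R0, R1 and KING-robust kinship from pairwise joint
  genotype counts, with greedy relative/duplicate pruning;
- **genetic load** — heterozygous (masked) and homozygous (realized)
  derived-allele load by functional-impact class, normalized by the
  synonymous category, with a normality-gated Welch / Wilcoxon group
  comparison (Cohen's d, Hodges–Lehmann shift).

A synthetic cohort generator (`loxpop.simdata`) emulates the full
statistical structure these methods assume — hierarchical Balding–Nichols
drift, frequency-level admixture pulses down to trace proportions
(α ≈ 0.005), planted autozygous tracts, impact annotations, ancestral
polarization, per-genotype depths — and returns the ground truth alongside
the cohort, so every stage has parameter-recovery tests.

## The statistics at the core

For population allele frequencies p measured at site *i*:

- **Hudson F<sub>ST</sub>** (corrected, ratio of averages):
  N<sub>i</sub> = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
  D<sub>i</sub> = p₁(1−p₂) + p₂(1−p₁), F̂<sub>ST</sub> = ΣN<sub>i</sub>/ΣD<sub>i</sub>.
- **D statistic**: D = Σ(p₁−p₂)(p₃−p₄) / Σ(p₁+p₂−2p₁p₂)(p₃+p₄−2p₃p₄);
  D = 0 under tree-like evolution.
- **f4 / F4-ratio**: f4(A,O;X,B) = mean (p_A−p_O)(p_X−p_B); the ratio of
  two f4 terms sharing A, O, B estimates the admixture proportion α of
  donor lineage C in target X. Standard errors use the weighted delete-one
  block jackknife (Busing et al. 1999), weights = informative sites per
  block; Z = estimate/SE.
- **KING-robust**: (S − 2·O)/(H_i + H_j) from shared-het (S) and
  opposing-homozygote (O) counts — ≈0.5 duplicates, ≈0.25 first degree.
- **Load ratios**: n(het deleterious derived) / n(het synonymous derived)
  per sample, per impact class (and the homozygous analogue).

## Worked example

Simulate a five-population cohort (outgroup, two forest reference
populations, an unadmixed savanna reference, and a savanna target that
received a 5 % forest pulse; 25 diploids each at 100 000 unlinked sites),
then recover differentiation, gene flow and the admixture proportion:

```python
import loxpop as lp
from loxpop import simdata

cfg = simdata.preset("trace-introgression", seed=42)
cfg.admixture_pulses = [simdata.AdmixturePulse("forest_C", "savanna_X", 0.05)]
gm, meta, truth = lp.simulate_cohort(cfg)

pf = lp.population_frequencies(gm, meta)
part = lp.block_partition(pf.sites, block_size_bp=5_000_000)

fst = lp.hudson_fst(pf, "savanna_B", "forest_A")
d = lp.d_statistic(pf, "savanna_B", "savanna_X", "forest_C", "outgroup", part)
a = lp.f4_ratio(pf, "forest_A", "outgroup", "savanna_X", "savanna_B",
                "forest_C", part)

print(f"FST(savanna_B, forest_A)   = {fst:.3f}")
print(f"D(B, X; forest, outgroup)  = {d.estimate:.4f}  Z = {d.z:.1f}")
print(f"F4-ratio alpha(savanna_X)  = {a.alpha:.4f} +/- {a.se:.4f}  (truth 0.05)")
```

Output:

```
FST(savanna_B, forest_A)   = 0.313
D(B, X; forest, outgroup)  = -0.0272  Z = -25.0
F4-ratio alpha(savanna_X)  = 0.0502 +/- 0.0020  (truth 0.05)
```

Between-species differentiation is strong (F<sub>ST</sub> ≈ 0.31 under
species drift 0.3); D is negative at |Z| ≫ 3 because the test population
X shares excess alleles with the forest lineage; and the F4-ratio
recovers the planted admixture proportion within one jackknife SE.

The same flows are available from the shell:

```bash
loxpop simulate --preset two-species --seed 42 --out-prefix cohort
loxpop fst cohort.vcf --samples cohort.samples.tsv --out fst.tsv
loxpop roh cohort.vcf --out-prefix cohort_roh
loxpop run pipeline.yaml      # filters → FST → PCA → ROH → kinship → load
```

## Layout

- `src/loxpop/vcfio.py` — VCF 4.2 / BED3 / sample-table I/O, `GenotypeMatrix`
- `src/loxpop/sitefilter.py` — depth, excess-het (F + exact HWE), genotype masks
- `src/loxpop/structure.py` — frequencies, 2D-SFS, Hudson FST, PCA, hybrid index
- `src/loxpop/introgression.py` — f4 / D / F4-ratio, block jackknife, Mantel, geography
- `src/loxpop/diversity.py` — ROH calling, F_ROH, size classes, heterozygosity
- `src/loxpop/kinship.py` — R0 / R1 / KING-robust, relative pruning
- `src/loxpop/load.py` — load counting and group comparison
- `src/loxpop/simdata.py` — synthetic cohorts with ground truth, presets
- `src/loxpop/pipeline.py`, `src/loxpop/cli.py` — orchestration and the `loxpop` CLI

See `docs/methods.md` for the models, parameter choices and limitations.
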