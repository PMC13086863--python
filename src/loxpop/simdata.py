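"""Synthetic cohort generator with ground truth.

Emulates the statistical structure the pipeline assumes — two deeply
diverged species with within-species substructure, frequency-level
admixture pulses (down to trace proportions), planted autozygous tracts,
per-site impact annotations, ancestral-allele polarization and
per-genotype depth fields — using a hierarchical Balding–Nichols model:

* ancestral frequency ``p0 ~ Uniform(freq_low, freq_high)`` per site;
* each species' frequency ``~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F)`` with
  species drift ``F`` (F = 0 copies p0);
* each population's frequency drawn the same way around its species
  frequency with its own drift;
* an admixture pulse of proportion α replaces the recipient's frequency
  with ``(1-α)·own + α·donor`` before genotypes are drawn, so f4-ratio
  expectations are exactly α;
* genotypes are Binomial(2, p) per diploid; planted ROH tracts overwrite
  genotypes with a doubled single haplotype (homozygous-by-descent).

Sites are unlinked by construction; the block jackknife is still
exercised because blocks are positional.  Everything is reproducible from
the mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .vcfio import SITE_COLUMNS, UNKNOWN_ANCESTRAL, GenotypeMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class PopulationSpec:
    name: str
    species: str
    n_diploids: int
    drift: float = 0.0  # Balding–Nichols F around the species frequency


@dataclass
class AdmixturePulse:
    donor: str  # population or species name
    recipient: str  # population name
    alpha: float


@dataclass
class RohPlant:
    """Plant tracts of ``tract_length_bp`` until ``fraction_of_genome``
    of the genome is covered (per sample)."""

    fraction_of_genome: float
    tract_length_bp: int


@dataclass
class SimulationConfig:
    seed: int
    n_chromosomes: int = 4
    chromosome_length_bp: int = 25_000_000
    n_sites: int = 20_000
    populations: list[PopulationSpec] = field(default_factory=list)
    species_drift: float = 0.2
    admixture_pulses: list[AdmixturePulse] = field(default_factory=list)
    roh_plant: dict[str, list[RohPlant]] = field(default_factory=dict)
    impact_fractions: dict[str, float] = field(default_factory=dict)
    deleterious_frequency_scaler: dict[str, float] = field(default_factory=dict)
    species_load_scaler: dict[str, dict[str, float]] = field(default_factory=dict)
    depth_mean: Optional[float] = None
    missing_rate: float = 0.0
    freq_low: float = 0.05
    freq_high: float = 0.95
    ancestral_flip_fraction: float = 0.0
    ancestral_unknown_fraction: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if sum(self.impact_fractions.values()) > 1 + 1e-9:
            raise ValueError("impact fractions must sum to <= 1")
        for p in self.populations:
            if not (0 <= p.drift < 1):
                raise ValueError(f"drift out of range for {p.name}")
        if not (0 <= self.species_drift < 1):
            raise ValueError("species drift out of range")
        for pulse in self.admixture_pulses:
            if not (0 <= pulse.alpha <= 1):
                raise ValueError("pulse alpha out of range")

    @property
    def genome_span_bp(self) -> int:
        return self.n_chromosomes * self.chromosome_length_bp


@dataclass
class SyntheticTruth:
    """Generator ground truth used by parameter-recovery tests."""

    config: SimulationConfig
    alpha: dict[str, float]  # recipient population -> pulse proportion
    expected_fst: dict[tuple[str, str], float]
    planted_tracts: dict[str, list[tuple[str, int, int]]]  # 1-based inclusive
    pedigree: list[tuple[str, str, str]]  # (child, parent1, parent2)
    population_frequencies: dict[str, np.ndarray]
    het_probability: dict[str, np.ndarray]  # per population, per site: 2p(1-p)

    def to_json(self, path, include_frequencies: bool = False) -> None:
        obj = {
            "seed": self.config.seed,
            "genome_span_bp": self.config.genome_span_bp,
            "alpha": self.alpha,
            "expected_fst": {f"{a}|{b}": v for (a, b), v in self.expected_fst.items()},
            "planted_tracts": {
                s: [[c, int(a), int(b)] for c, a, b in tr]
                for s, tr in self.planted_tracts.items()
            },
            "pedigree": [list(t) for t in self.pedigree],
        }
        if include_frequencies:
            obj["population_frequencies"] = {
                k: v.tolist() for k, v in self.population_frequencies.items()
            }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Beta-distributed daughter frequencies with drift parameter F."""
    if F <= 0:
        return p.copy()
    ratio = (1 - F) / F
    return rng.beta(np.maximum(p * ratio, 1e-12), np.maximum((1 - p) * ratio, 1e-12))


def _positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n sorted distinct 1-based positions on a chromosome of given length."""
    if n > length:
        raise ValueError("more sites than base pairs")
    draw = rng.integers(1, length + 1, size=int(n * 1.2) + 16)
    uniq = np.unique(draw)
    while len(uniq) < n:
        extra = rng.integers(1, length + 1, size=n)
        uniq = np.unique(np.concatenate([uniq, extra]))
    return np.sort(rng.choice(uniq, size=n, replace=False))


def _expected_fst(cfg: SimulationConfig) -> dict[tuple[str, str], float]:
    """Model-implied Hudson FST for every population pair.

    Within a species, two populations with drifts F1 and F2 around the
    shared species frequency have FST = (F1 + F2) / 2 at the estimator's
    estimand (heterozygosity deficit relative to between-pop diversity).
    """
    out = {}
    pops = cfg.populations
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a, b = pops[i], pops[j]
            if a.species == b.species:
                out[(a.name, b.name)] = (a.drift + b.drift) / 2.0
    return out


def simulate_cohort(cfg: SimulationConfig):
    """Generate a cohort under the configured hierarchical model.

    Returns ``(GenotypeMatrix, sample_table, SyntheticTruth)``.  Identical
    config and seed give identical output (single Generator, fixed draw
    order).
    """
    if not cfg.populations:
        raise ValueError("config defines no populations")
    rng = np.random.default_rng(cfg.seed)
    n_sites = cfg.n_sites
    # -- site coordinates: sites spread over chromosomes proportionally
    per_chrom = np.full(cfg.n_chromosomes, n_sites // cfg.n_chromosomes)
    per_chrom[: n_sites % cfg.n_chromosomes] += 1
    width = len(str(cfg.n_chromosomes))
    chroms, positions = [], []
    for k in range(cfg.n_chromosomes):
        if per_chrom[k] == 0:
            continue
        chroms.append(np.full(per_chrom[k], f"chr{k + 1:0{width}d}", dtype=object))
        positions.append(_positions(rng, per_chrom[k], cfg.chromosome_length_bp))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions).astype(np.int64)

    # -- impact annotation
    classes = list(cfg.impact_fractions)
    fracs = [cfg.impact_fractions[c] for c in classes]
    probs = fracs + [max(0.0, 1.0 - sum(fracs))]
    impact = rng.choice(np.array(classes + ["NONE"], dtype=object), size=n_sites,
                        p=np.array(probs) / sum(probs))

    # -- hierarchical frequencies
    p0 = rng.uniform(cfg.freq_low, cfg.freq_high, size=n_sites)
    species = sorted({p.species for p in cfg.populations})
    sp_freq = {s: _balding_nichols(rng, p0, cfg.species_drift) for s in species}
    pop_freq: dict[str, np.ndarray] = {}
    for p in cfg.populations:
        pop_freq[p.name] = _balding_nichols(rng, sp_freq[p.species], p.drift)
    # admixture pulses (donor may be a population or a species lineage)
    alpha_truth: dict[str, float] = {}
    for pulse in cfg.admixture_pulses:
        donor = pop_freq.get(pulse.donor, sp_freq.get(pulse.donor))
        if donor is None:
            raise ValueError(f"unknown pulse donor {pulse.donor!r}")
        pop_freq[pulse.recipient] = (
            (1 - pulse.alpha) * pop_freq[pulse.recipient] + pulse.alpha * donor
        )
        alpha_truth[pulse.recipient] = pulse.alpha
    # deleterious-frequency scaling by impact class (global, then per species)
    species_of = {p.name: p.species for p in cfg.populations}
    for imp, scale in cfg.deleterious_frequency_scaler.items():
        sel = impact == imp
        for name in pop_freq:
            pop_freq[name][sel] = np.clip(pop_freq[name][sel] * scale, 0, 1)
    for sp, scalers in cfg.species_load_scaler.items():
        for imp, scale in scalers.items():
            sel = impact == imp
            for name, sp_name in species_of.items():
                if sp_name == sp:
                    pop_freq[name][sel] = np.clip(pop_freq[name][sel] * scale, 0, 1)

    # -- genotypes
    sample_ids: list[str] = []
    sample_pop: list[str] = []
    blocks = []
    for p in cfg.populations:
        freq = pop_freq[p.name]
        # two Bernoulli allele draws per diploid (fast equivalent of Binomial(2, p))
        g = (
            (rng.random((p.n_diploids, n_sites)) < freq).view(np.int8)
            + (rng.random((p.n_diploids, n_sites)) < freq).view(np.int8)
        )
        blocks.append(g)
        sample_ids += [f"{p.name}_{i:03d}" for i in range(p.n_diploids)]
        sample_pop += [p.name] * p.n_diploids
    genotypes = np.vstack(blocks)

    # -- planted autozygous tracts (doubled single haplotype)
    planted: dict[str, list[tuple[str, int, int]]] = {}
    chrom_names = [f"chr{k + 1:0{width}d}" for k in range(cfg.n_chromosomes)]
    for sample_id, plants in cfg.roh_plant.items():
        if sample_id not in sample_ids:
            raise ValueError(f"roh_plant sample {sample_id!r} not in cohort")
        i = sample_ids.index(sample_id)
        freq = pop_freq[sample_pop[i]]
        tracts = []
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
        for plant in plants:
            if plant.tract_length_bp > cfg.chromosome_length_bp:
                raise ValueError("tract longer than chromosome")
            target = plant.fraction_of_genome * cfg.genome_span_bp
            total = 0
            attempts = 0
            while total < target - plant.tract_length_bp / 2:
                attempts += 1
                if attempts > 1000:
                    raise ValueError("cannot place planted tracts (genome too full)")
                c = chrom_names[rng.integers(cfg.n_chromosomes)]
                start = int(rng.integers(1, cfg.chromosome_length_bp - plant.tract_length_bp + 2))
                end = start + plant.tract_length_bp - 1
                if any(s <= end and start <= e for s, e in occupied[c]):
                    continue
                occupied[c].append((start, end))
                tracts.append((c, start, end))
                total += plant.tract_length_bp
        for c, start, end in tracts:
            sel = (chrom == c) & (pos >= start) & (pos <= end)
            hap = rng.binomial(1, freq[sel])
            genotypes[i, sel] = (2 * hap).astype(np.int8)
        planted[sample_id] = tracts

    # -- missingness
    if cfg.missing_rate > 0:
        miss = rng.random(genotypes.shape) < cfg.missing_rate
        genotypes[miss] = -1

    # -- alleles, ancestral polarization
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ref = _BASES[ref_idx]
    alt = _BASES[alt_idx]
    u = rng.random(n_sites)
    ancestral = ref.astype(object).copy()
    flip = u < cfg.ancestral_flip_fraction
    ancestral[flip] = alt[flip]
    unknown = (u >= cfg.ancestral_flip_fraction) & (
        u < cfg.ancestral_flip_fraction + cfg.ancestral_unknown_fraction
    )
    ancestral[unknown] = UNKNOWN_ANCESTRAL

    sites = pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "ancestral": ancestral, "impact": impact,
    })[SITE_COLUMNS]

    # -- depth fields
    depth = allelic_depth = None
    if cfg.depth_mean is not None:
        depth = rng.poisson(cfg.depth_mean, size=genotypes.shape).astype(np.int32)
        alt_reads = np.zeros_like(depth)
        het = genotypes == 1
        alt_reads[het] = rng.binomial(depth[het], 0.5)
        hom_alt = genotypes == 2
        alt_reads[hom_alt] = depth[hom_alt]
        allelic_depth = np.stack([depth - alt_reads, alt_reads], axis=-1)

    gm = GenotypeMatrix(
        sample_ids=sample_ids, sites=sites, genotypes=genotypes,
        depth=depth, allelic_depth=allelic_depth,
    )
    meta = pd.DataFrame({
        "sample": sample_ids,
        "species": [species_of[p] for p in sample_pop],
        "population": sample_pop,
        "lat": np.nan, "lon": np.nan,
    })
    truth = SyntheticTruth(
        config=cfg,
        alpha=alpha_truth,
        expected_fst=_expected_fst(cfg),
        planted_tracts=planted,
        pedigree=[],
        population_frequencies=pop_freq,
        het_probability={k: 2 * v * (1 - v) for k, v in pop_freq.items()},
    )
    return gm, meta, truth


def simulate_pedigree(
    gm: GenotypeMatrix, parent_pairs: list[tuple[str, str]], seed: int,
    prefix: str = "offspring",
):
    """Extend a cohort with Mendelian offspring of the given parent pairs.

    Each offspring draws one allele uniformly from each parent's two at
    every site; a site where either parent is missing is missing in the
    offspring.  Returns ``(extended GenotypeMatrix, pedigree links)``.
    """
    rng = np.random.default_rng(seed)
    new_rows = []
    links = []
    for k, (pa, pb) in enumerate(parent_pairs):
        ga = gm.genotypes[gm.sample_index(pa)].astype(np.int16)
        gb = gm.genotypes[gm.sample_index(pb)].astype(np.int16)
        # P(transmit alt) = g/2 for g in {0,1,2}
        child = (
            rng.binomial(1, np.clip(ga, 0, 2) / 2.0)
            + rng.binomial(1, np.clip(gb, 0, 2) / 2.0)
        ).astype(np.int8)
        child[(ga < 0) | (gb < 0)] = -1
        name = f"{prefix}_{k:02d}"
        new_rows.append(child)
        links.append((name, pa, pb))
    ext = GenotypeMatrix(
        sample_ids=list(gm.sample_ids) + [l[0] for l in links],
        sites=gm.sites.copy(),
        genotypes=np.vstack([gm.genotypes] + new_rows),
    )
    return ext, links


def clone_sample(gm: GenotypeMatrix, sample_id: str, new_id: str) -> GenotypeMatrix:
    """Append an exact genotype duplicate (KING = 0.5 against its source)."""
    g = gm.genotypes[gm.sample_index(sample_id)]
    return GenotypeMatrix(
        sample_ids=list(gm.sample_ids) + [new_id],
        sites=gm.sites.copy(),
        genotypes=np.vstack([gm.genotypes, g[None, :]]),
    )


# ---------------------------------------------------------------------------
# Presets: the study conditions exercised by the acceptance suite.


def preset(name: str, seed: int, **overrides) -> SimulationConfig:
    """Named study-condition presets.

    two-species
        Two species (three + two populations, 10 diploids each), species
        drift 0.2, within-species drift 0.02, 5% forest→savanna pulse,
        impact annotations, 0.2 ancestral flips / 0.05 unknown, DP/AD at
        mean depth 20.
    trace-introgression
        Five roles for f4-ratio recovery — outgroup, two forest reference
        populations, an unadmixed savanna reference and a savanna target
        carrying a forest pulse (default α = 0.005); 25 diploids/pop,
        100k sites.
    inbred-isolate
        One panmictic population of 10 diploids, 220k sites over 80 Mb
        (background per-bp heterozygosity ≈ 1e-3); planted autozygous
        tracts of 1.5 and 2.5 Mb totaling 5% of the genome in every
        sample.
    load-contrast
        Two species with no drift (exchangeable under the null), 20k
        sites, impact classes HIGH 5% / MODERATE 15% / LOW 10% /
        SYNONYMOUS 30%, deleterious frequencies scaled ×0.2; pass
        ``species_load_scaler={"speciesA": {"HIGH": 1.5, "MODERATE": 1.5}}``
        for the elevated-load alternative.
    pedigree
        One panmictic population of 8 diploids at 50k sites, no drift —
        substrate for Mendelian offspring and clone fixtures.
    """
    if name == "two-species":
        cfg = SimulationConfig(
            seed=seed, n_chromosomes=4, chromosome_length_bp=25_000_000,
            n_sites=20_000,
            populations=[
                PopulationSpec("sav_east", "savanna", 10, 0.02),
                PopulationSpec("sav_south", "savanna", 10, 0.02),
                PopulationSpec("sav_west", "savanna", 10, 0.02),
                PopulationSpec("for_central", "forest", 10, 0.02),
                PopulationSpec("for_west", "forest", 10, 0.02),
            ],
            species_drift=0.2,
            admixture_pulses=[AdmixturePulse("for_central", "sav_west", 0.05)],
            impact_fractions={"HIGH": 0.02, "MODERATE": 0.08, "LOW": 0.1,
                              "SYNONYMOUS": 0.2},
            deleterious_frequency_scaler={"HIGH": 0.3, "MODERATE": 0.5},
            depth_mean=20.0,
            ancestral_flip_fraction=0.2,
            ancestral_unknown_fraction=0.05,
        )
    elif name == "trace-introgression":
        cfg = SimulationConfig(
            seed=seed, n_chromosomes=20, chromosome_length_bp=25_000_000,
            n_sites=100_000,
            populations=[
                PopulationSpec("outgroup", "outgroup", 25, 0.0),
                PopulationSpec("forest_A", "forest", 25, 0.02),
                PopulationSpec("forest_C", "forest", 25, 0.02),
                PopulationSpec("savanna_B", "savanna", 25, 0.02),
                PopulationSpec("savanna_X", "savanna", 25, 0.02),
            ],
            species_drift=0.3,
            admixture_pulses=[AdmixturePulse("forest_C", "savanna_X", 0.005)],
        )
    elif name == "inbred-isolate":
        cfg = SimulationConfig(
            seed=seed, n_chromosomes=4, chromosome_length_bp=20_000_000,
            n_sites=220_000,
            populations=[PopulationSpec("isolate", "savanna", 10, 0.0)],
            species_drift=0.0,
            roh_plant={
                f"isolate_{i:03d}": [RohPlant(0.01875, 1_500_000),
                                     RohPlant(0.03125, 2_500_000)]
                for i in range(10)
            },
        )
    elif name == "load-contrast":
        cfg = SimulationConfig(
            seed=seed, n_chromosomes=4, chromosome_length_bp=25_000_000,
            n_sites=20_000,
            populations=[
                PopulationSpec("popA", "speciesA", 25, 0.0),
                PopulationSpec("popB", "speciesB", 25, 0.0),
            ],
            species_drift=0.0,
            impact_fractions={"HIGH": 0.05, "MODERATE": 0.15, "LOW": 0.1,
                              "SYNONYMOUS": 0.3},
            deleterious_frequency_scaler={"HIGH": 0.2, "MODERATE": 0.2},
        )
    elif name == "pedigree":
        cfg = SimulationConfig(
            seed=seed, n_chromosomes=4, chromosome_length_bp=25_000_000,
            n_sites=50_000,
            populations=[PopulationSpec("herd", "savanna", 8, 0.0)],
            species_drift=0.0,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.__post_init__()
    return cfg
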