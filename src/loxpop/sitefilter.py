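"""Reliable-site and genotype-level filters.

Three layers of quality control operate on a called cohort:

* a **global depth** filter keeping sites whose summed read depth lies
  within [0.5, 1.5] × the cohort-wide median (bounds inclusive) — extreme
  total depth marks collapsed repeats or dropout;
* an **excess heterozygosity** filter flagging putative paralog-collapse
  sites (per-site inbreeding coefficient F < -0.90 together with an exact
  Hardy–Weinberg test p < 1e-6) and excluding a 10 kb window (±5 kb)
  around each flagged site;
* **genotype masks**: per-genotype depth bounds and a minor-allele read
  support rule for heterozygotes, plus cohort-level MAF/missingness site
  filters used before ROH calling.

F here is computed from hard genotype counts; at high coverage this targets
the same quantity as a genotype-likelihood estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .vcfio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

FLAG_LOW_DEPTH = "LOW_DEPTH"
FLAG_HIGH_DEPTH = "HIGH_DEPTH"
FLAG_EXCESS_HET = "EXCESS_HET"
FLAG_WINDOW_EXCLUDED = "WINDOW_EXCLUDED"
FLAG_LOW_MAF = "LOW_MAF"
FLAG_HIGH_MISSING = "HIGH_MISSING"


class ConfigurationError(ValueError):
    """A filter was asked to run without the fields it needs."""


@dataclass
class SiteFilterReport:
    """Per-site QC quantities and flags.

    ``flags`` holds one set of flag strings per site; a site with an empty
    set passed the filter that produced the report.
    """

    total_depth: np.ndarray | None = None
    inbreeding_F: np.ndarray | None = None
    hwe_p: np.ndarray | None = None
    flags: list[set[str]] = field(default_factory=list)

    def keep_mask(self) -> np.ndarray:
        return np.array([len(f) == 0 for f in self.flags], dtype=bool)

    def to_frame(self, sites: pd.DataFrame) -> pd.DataFrame:
        df = sites[["chrom", "pos"]].copy()
        df["total_depth"] = (
            self.total_depth if self.total_depth is not None else np.nan
        )
        df["F"] = self.inbreeding_F if self.inbreeding_F is not None else np.nan
        df["hwe_p"] = self.hwe_p if self.hwe_p is not None else np.nan
        df["flags"] = [",".join(sorted(f)) or "." for f in self.flags]
        return df


def global_depth_filter(
    gm: GenotypeMatrix,
    min_depth_factor: float = 0.5,
    max_depth_factor: float = 1.5,
) -> SiteFilterReport:
    """Flag sites with extreme summed depth relative to the cohort median.

    The median is computed over all sites before any filtering; a site is
    kept iff ``min_factor * median <= total <= max_factor * median`` with
    both bounds inclusive.
    """
    if gm.depth is None:
        raise ConfigurationError("global depth filter requires per-genotype DP")
    total = gm.depth.sum(axis=0).astype(np.int64)
    m = float(np.median(total))
    lo, hi = min_depth_factor * m, max_depth_factor * m
    flags = []
    for d in total:
        f: set[str] = set()
        if d < lo:
            f.add(FLAG_LOW_DEPTH)
        if d > hi:
            f.add(FLAG_HIGH_DEPTH)
        flags.append(f)
    return SiteFilterReport(total_depth=total, flags=flags)


def site_inbreeding_F(nAA: int, nAa: int, naa: int) -> float:
    """Per-site inbreeding coefficient from genotype counts.

    ``F = 1 - H_obs / H_exp`` with ``H_exp = 2 p (1 - p)`` at the sample
    allele frequency ``p``.  Returns NaN (undefined) for monomorphic counts.
    Negative F marks heterozygote excess; F = -1 when every call is het.
    """
    if min(nAA, nAa, naa) < 0:
        raise ValueError("negative genotype counts")
    n = nAA + nAa + naa
    if n < 1:
        raise ValueError("empty genotype counts")
    p = (2 * nAA + nAa) / (2 * n)
    if p in (0.0, 1.0):
        return float("nan")
    return 1.0 - (nAa / n) / (2.0 * p * (1.0 - p))


def hwe_exact_test(nAA: int, nAa: int, naa: int) -> float:
    """Two-sided exact Hardy–Weinberg test (conditional on allele counts).

    The p-value sums, over every heterozygote count attainable with the
    observed allele totals, the probabilities that do not exceed the
    probability of the observed count (minimum-likelihood two-sided tail;
    no mid-p correction).  Monomorphic input has a single attainable
    configuration, so p = 1.
    """
    if min(nAA, nAa, naa) < 0:
        raise ValueError("negative genotype counts")
    n = nAA + nAa + naa
    if n < 1:
        raise ValueError("empty genotype counts")
    na = 2 * nAA + nAa  # copies of allele A
    nb = 2 * n - na
    rare = min(na, nb)
    if rare == 0:
        return 1.0
    # attainable het counts share the parity of the rare-allele total
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts) up to a shared constant:
    # P = n! na! nb! 2^h / ( (2n)! ((na-h)/2)! h! ((nb-h)/2)! )
    logp = (
        hets * np.log(2.0)
        - gammaln((na - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((nb - hets) / 2 + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, nAa)]
    # small relative slack so the observed configuration always counts itself
    p = float(prob[prob <= obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def genotype_counts(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site (n_hom_ref, n_het, n_hom_alt) counts, shape (n_sites, 3)."""
    g = gm.genotypes
    return np.stack([(g == k).sum(axis=0) for k in (0, 1, 2)], axis=1)


def excess_het_filter(
    gm: GenotypeMatrix,
    window_bp: int = 10_000,
    f_threshold: float = -0.90,
    hwe_threshold: float = 1e-6,
) -> SiteFilterReport:
    """Flag paralog-like excess-heterozygosity sites and their neighborhoods.

    A site is EXCESS_HET iff its inbreeding coefficient is below
    ``f_threshold`` *and* its exact HWE p-value is below ``hwe_threshold``.
    Every other site within ±``window_bp``/2 of a flagged site (same
    chromosome, boundaries inclusive) is WINDOW_EXCLUDED; overlapping
    windows merge naturally.
    """
    counts = genotype_counts(gm)
    F = np.array([site_inbreeding_F(*c) for c in counts])
    hwe = np.array([hwe_exact_test(*c) for c in counts])
    with np.errstate(invalid="ignore"):
        excess = (F < f_threshold) & (hwe < hwe_threshold)
    flags: list[set[str]] = [set() for _ in range(gm.n_sites)]
    chrom = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy(np.int64)
    half = window_bp / 2.0
    for j in np.flatnonzero(excess):
        flags[j].add(FLAG_EXCESS_HET)
        near = (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= half)
        for k in np.flatnonzero(near):
            if not excess[k]:
                flags[k].add(FLAG_WINDOW_EXCLUDED)
    return SiteFilterReport(inbreeding_F=F, hwe_p=hwe, flags=flags)


def genotype_mask(
    gm: GenotypeMatrix,
    min_dp: int = 10,
    max_dp_factor: float = 2.0,
    min_minor_reads: int = 2,
) -> GenotypeMatrix:
    """Mask unreliable genotypes to MISSING.

    A genotype is masked when its DP is below ``min_dp``, above
    ``max_dp_factor`` × the global mean depth, or it is heterozygous with
    fewer than ``min_minor_reads`` reads supporting either allele.  A
    heterozygote lacking an AD record is masked with a logged warning.
    """
    if gm.depth is None or gm.allelic_depth is None:
        raise ConfigurationError("genotype mask requires DP and AD fields")
    g = gm.genotypes.copy()
    dp = gm.depth
    mean_dp = float(dp[g != MISSING].mean()) if (g != MISSING).any() else 0.0
    bad = (dp < min_dp) | (dp > max_dp_factor * mean_dp)
    het = g == 1
    ad = gm.allelic_depth
    ad_absent = ad[..., 0] < 0
    n_no_ad = int((het & ad_absent).sum())
    if n_no_ad:
        logger.warning("masked %d heterozygotes lacking AD", n_no_ad)
    low_minor = np.minimum(ad[..., 0], ad[..., 1]) < min_minor_reads
    bad |= het & (low_minor | ad_absent)
    g[bad] = MISSING
    out = GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        sites=gm.sites.copy(),
        genotypes=g,
        depth=gm.depth,
        allelic_depth=gm.allelic_depth,
    )
    return out


def maf_missingness_filter(
    gm: GenotypeMatrix, min_maf: float = 0.05, max_missing: float = 0.05
) -> GenotypeMatrix:
    """Keep variable sites with MAF ≥ ``min_maf`` (over non-missing calls)
    and missing-call fraction ≤ ``max_missing``."""
    g = gm.genotypes
    miss = g == MISSING
    n_called = (~miss).sum(axis=0)
    alt = np.where(miss, 0, g).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        maf = np.minimum(p, 1.0 - p)
    miss_frac = miss.mean(axis=0)
    keep = (n_called > 0) & (maf >= min_maf) & (miss_frac <= max_missing)
    return gm.take_sites(keep)
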