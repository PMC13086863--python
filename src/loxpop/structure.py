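"""Allele frequencies, joint SFS, Hudson FST, PCA, and the PC1 hybrid index.

The differentiation estimator is the corrected Hudson FST in its
Bhatia–Patterson ratio-of-averages form: per-site numerators carry a
finite-sample correction, and the genome-wide estimate is the ratio of the
summed numerators to the summed denominators (never a mean of per-site
ratios, which is badly behaved at low-information sites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .vcfio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PopulationFrequencies:
    """Per-population alternate/derived allele frequencies.

    ``p[k]`` and ``n[k]`` are per-site arrays for population ``k``: the
    allele frequency and the number of non-missing allele copies (2 × the
    genotyped diploids).  ``p`` is NaN where ``n`` is zero.
    """

    populations: list[str]
    p: dict[str, np.ndarray]
    n: dict[str, np.ndarray]
    sites: pd.DataFrame

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def population_frequencies(
    gm: GenotypeMatrix,
    sample_table: pd.DataFrame,
    polarize: bool = False,
    group_by: str = "population",
) -> PopulationFrequencies:
    """Per-population allele frequencies and allele sample sizes.

    With ``polarize=True`` genotypes are flipped to derived-allele counts
    first and sites with unknown ancestral state are excluded.
    """
    if polarize:
        keep = gm.derived_known_mask()
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("polarization: excluding %d sites with unknown ancestral", n_drop)
        gm = gm.take_sites(keep).polarized()
    meta = sample_table.set_index("sample")
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(gm.sample_ids):
        if s in meta.index:
            groups.setdefault(str(meta.at[s, group_by]), []).append(i)
    p: dict[str, np.ndarray] = {}
    n: dict[str, np.ndarray] = {}
    for name, idx in groups.items():
        g = gm.genotypes[idx]
        called = g != MISSING
        copies = 2 * called.sum(axis=0)
        if copies.max(initial=0) == 0:
            raise ValueError(f"population {name!r} has no genotyped sample at any site")
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[name] = np.where(copies > 0, alt / copies, np.nan)
        n[name] = copies.astype(np.int64)
    return PopulationFrequencies(
        populations=list(groups), p=p, n=n, sites=gm.sites.copy()
    )


@dataclass
class Sfs2D:
    """Joint site-frequency spectrum of two populations.

    ``counts[i, j]`` is the number of sites with ``i`` alternate/derived
    copies in population A (of ``2 nA`` total) and ``j`` in population B.
    """

    counts: np.ndarray
    pop_a: str
    pop_b: str

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


def joint_sfs(
    gm: GenotypeMatrix, sample_table: pd.DataFrame, pop_a: str, pop_b: str,
    group_by: str = "population",
) -> Sfs2D:
    """2D SFS over sites with complete data in both populations; incomplete
    sites are excluded with a logged count."""
    meta = sample_table.set_index("sample")
    idx_a = [i for i, s in enumerate(gm.sample_ids)
             if s in meta.index and str(meta.at[s, group_by]) == pop_a]
    idx_b = [i for i, s in enumerate(gm.sample_ids)
             if s in meta.index and str(meta.at[s, group_by]) == pop_b]
    if not idx_a or not idx_b:
        raise ValueError("both populations must contain samples")
    ga, gb = gm.genotypes[idx_a], gm.genotypes[idx_b]
    complete = (ga != MISSING).all(axis=0) & (gb != MISSING).all(axis=0)
    n_excl = int((~complete).sum())
    if n_excl:
        logger.info("joint SFS: excluded %d sites with missingness", n_excl)
    da = ga[:, complete].sum(axis=0)
    db = gb[:, complete].sum(axis=0)
    shape = (2 * len(idx_a) + 1, 2 * len(idx_b) + 1)
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, (da, db), 1)
    return Sfs2D(counts=counts, pop_a=pop_a, pop_b=pop_b)


def _hudson_terms(pa, pb, na, nb):
    """Per-site Hudson numerator and denominator with finite-sample correction."""
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    return num, den


def hudson_fst(
    pf: PopulationFrequencies, pop_a: str, pop_b: str,
    return_terms: bool = False,
):
    """Corrected Hudson FST between two populations, ratio-of-averages.

    Sites with fewer than two allele copies in either population are
    skipped (warned); sites monomorphic in both contribute 0/0 and drop
    out of both sums.  A fixed difference gives FST = 1 at any sample size.
    """
    pa, pb = pf.p[pop_a], pf.p[pop_b]
    na, nb = pf.n[pop_a], pf.n[pop_b]
    usable = (na >= 2) & (nb >= 2) & np.isfinite(pa) & np.isfinite(pb)
    n_skip = int((~usable).sum())
    if n_skip:
        logger.warning("Hudson FST: skipped %d sites with n<2 copies", n_skip)
    num, den = _hudson_terms(pa[usable], pb[usable], na[usable], nb[usable])
    informative = den != 0
    fst = float(num[informative].sum() / den[informative].sum())
    if return_terms:
        return fst, num[informative], den[informative]
    return fst


def hudson_fst_from_sfs(sfs: Sfs2D) -> float:
    """Hudson FST marginalized directly from a complete-data 2D SFS.

    Exactly equals :func:`hudson_fst` computed from the per-site
    frequencies of the same complete-data sites.
    """
    na = sfs.counts.shape[0] - 1
    nb = sfs.counts.shape[1] - 1
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 allele copies per population")
    i = np.arange(na + 1)[:, None] / na
    j = np.arange(nb + 1)[None, :] / nb
    num, den = _hudson_terms(i, j, na, nb)
    w = sfs.counts
    mask = den != 0
    return float((w * np.where(mask, num, 0.0)).sum() /
                 (w * np.where(mask, den, 0.0)).sum())


def fst_matrix(
    pf: PopulationFrequencies, populations: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    pops = list(populations or pf.populations)
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            v = hudson_fst(pf, pops[a], pops[b])
            out.iloc[a, b] = out.iloc[b, a] = v
    return out


@dataclass
class PcaResult:
    """Sample scores and per-component explained-variance fractions."""

    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    loadings: np.ndarray
    sample_ids: list[str]

    def score_of(self, sample_id: str, component: int = 0) -> float:
        return float(self.scores[self.sample_ids.index(sample_id), component])


def pca(gm: GenotypeMatrix, scale: bool = True, n_components: Optional[int] = None) -> PcaResult:
    """PCA of the genotype matrix.

    Columns are centered by twice the allele frequency and (by default)
    scaled by ``sqrt(2 p (1-p))``; monomorphic columns are dropped; missing
    genotypes are mean-imputed.  Each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    g = gm.genotypes.astype(float)
    g[gm.genotypes == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    g = g[:, keep]
    p = p[keep]
    g = np.where(np.isnan(g), 2 * p, g) - 2 * p
    if scale:
        g /= np.sqrt(2 * p * (1 - p))
    u, s, vt = np.linalg.svd(g, full_matrices=False)
    k = min(n_components or gm.n_samples, len(s))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    # sign convention: largest-|loading| positive
    for c in range(k):
        jmax = np.argmax(np.abs(loadings[:, c]))
        if loadings[jmax, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    total_var = float((g ** 2).sum())
    evf = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PcaResult(
        scores=scores,
        explained_variance_fraction=evf,
        loadings=loadings,
        sample_ids=list(gm.sample_ids),
    )


@dataclass
class AncestryEstimate:
    """Per-sample hybrid index / admixture proportion.

    ``method`` is ``"PC1"`` (linear rescaling of the leading PC between two
    anchor individuals) or ``"F4RATIO"`` (f4-ratio α with jackknife SE).
    """

    hybrid_index: pd.Series
    method: str
    alpha: Optional[float] = None
    se: Optional[float] = None
    z: Optional[float] = None
    n_blocks: Optional[int] = None


def pc1_hybrid_index(
    pca_result: PcaResult,
    anchor_savanna_id: str,
    anchor_forest_id: str,
    orient: str = "printed",
) -> AncestryEstimate:
    """Hybrid index from PC1 scores between two anchor individuals.

    The printed formula ``h = 1 - (x - x_sav) / (x_for - x_sav)`` maps the
    savanna anchor to 1 and the forest anchor to 0; ``orient="forest"``
    flips it (``1 - h``) so the forest anchor scores 1.  Values outside
    [0, 1] are reported as-is (samples beyond the anchors).  The index is
    invariant to any affine rescaling of the PC1 axis.
    """
    x = pd.Series(pca_result.scores[:, 0], index=pca_result.sample_ids)
    x_sav = x[anchor_savanna_id]
    x_for = x[anchor_forest_id]
    if x_for == x_sav:
        raise ValueError("anchor samples have identical PC1 scores")
    h = 1.0 - (x - x_sav) / (x_for - x_sav)
    if orient == "forest":
        h = 1.0 - h
    elif orient != "printed":
        raise ValueError("orient must be 'printed' or 'forest'")
    return AncestryEstimate(hybrid_index=h, method="PC1")
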