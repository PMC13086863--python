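"""f4 / D statistics with block jackknife, F4-ratio ancestry proportions,
and the ancestry–geography Mantel test.

All statistics are computed from population allele frequencies (the
frequency-based estimators — identical in expectation to single-sequence
sampling, lower variance).  Standard errors come from a weighted
delete-one block jackknife over contiguous genomic blocks (default 5 Mb),
with block weights equal to the informative-site counts, following the
weighted-jackknife formulation of Busing et al. (1999) used throughout the
f-statistics ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .structure import PopulationFrequencies

EARTH_RADIUS_KM = 6371.0


class UnstableRatioError(ValueError):
    """F4-ratio denominator indistinguishable from zero."""

    def __init__(self, msg, f4_num=None, f4_den=None):
        super().__init__(msg)
        self.f4_num = f4_num
        self.f4_den = f4_den


@dataclass
class JackknifeEstimate:
    """Ratio statistic with weighted block-jackknife uncertainty."""

    estimate: float
    se: float
    z: float
    n_blocks: int
    block_values: np.ndarray  # leave-one-block-out estimates
    block_weights: np.ndarray  # informative-site counts per block
    n_sites: int = 0


@dataclass
class BlockPartition:
    """Dense block ids for sorted sites; blocks never cross chromosomes."""

    block_ids: np.ndarray
    n_blocks: int
    block_size_bp: int


def block_partition(sites: pd.DataFrame, block_size_bp: int = 5_000_000) -> BlockPartition:
    """Greedy tiling of sorted sites into contiguous blocks.

    A new block starts at each chromosome start and whenever including the
    next site would stretch the block's positional span beyond
    ``block_size_bp``.
    """
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy(np.int64)
    ids = np.zeros(len(sites), dtype=np.int64)
    cur = 0
    start_pos = pos[0] if len(pos) else 0
    for i in range(1, len(pos)):
        if chrom[i] != chrom[i - 1] or pos[i] - start_pos >= block_size_bp:
            cur += 1
            start_pos = pos[i]
        ids[i] = cur
    return BlockPartition(block_ids=ids, n_blocks=cur + 1 if len(pos) else 0,
                          block_size_bp=block_size_bp)


def block_jackknife(
    num_by_block: np.ndarray,
    den_by_block: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> JackknifeEstimate:
    """Weighted delete-one jackknife of the ratio Σnum / Σden.

    ``weights`` are per-block informative-site counts (defaults to
    ``den_by_block`` when integer counts are the denominator).  With equal
    weights the standard error reduces exactly to the plain delete-one
    jackknife formula.
    """
    num = np.asarray(num_by_block, dtype=float)
    den = np.asarray(den_by_block, dtype=float)
    if weights is None:
        weights = den.copy()
    w = np.asarray(weights, dtype=float)
    nz = w > 0
    num, den, w = num[nz], den[nz], w[nz]
    B = len(w)
    if B < 2:
        raise ValueError("block jackknife needs >= 2 non-empty blocks")
    theta = num.sum() / den.sum()
    loo = (num.sum() - num) / (den.sum() - den)
    n_tot = w.sum()
    h = n_tot / w
    theta_J = B * theta - ((1 - w / n_tot) * loo).sum()
    tau = h * theta - (h - 1) * loo
    var = ((tau - theta_J) ** 2 / (h - 1)).sum() / B
    se = float(np.sqrt(var))
    return JackknifeEstimate(
        estimate=float(theta), se=se,
        z=float(theta / se) if se > 0 else float("inf") if theta != 0 else 0.0,
        n_blocks=B, block_values=loo, block_weights=w,
        n_sites=int(n_tot),
    )


def _freqs(pf: PopulationFrequencies, names):
    ps = [pf.p[n] for n in names]
    ok = np.ones(pf.n_sites, dtype=bool)
    for p in ps:
        ok &= np.isfinite(p)
    return [p[ok] for p in ps], ok


def _block_sums(values: np.ndarray, blocks: np.ndarray, n_blocks: int) -> np.ndarray:
    return np.bincount(blocks, weights=values, minlength=n_blocks)


def _ratio_jackknife(num_sums, den_sums, weights) -> JackknifeEstimate:
    """Jackknife the ratio; with a single non-empty block the point estimate
    is still returned, with SE (and Z) undefined (NaN)."""
    w = np.asarray(weights, dtype=float)
    if int((w > 0).sum()) >= 2:
        return block_jackknife(num_sums, den_sums, weights=w)
    est = float(np.sum(num_sums) / np.sum(den_sums))
    return JackknifeEstimate(
        estimate=est, se=float("nan"), z=float("nan"),
        n_blocks=int((w > 0).sum()),
        block_values=np.array([est]), block_weights=w[w > 0],
        n_sites=int(w.sum()),
    )


def f4(
    pf: PopulationFrequencies, a: str, o: str, x: str, b: str,
    partition: BlockPartition,
) -> JackknifeEstimate:
    """f4(A, O; X, B) = mean over sites of (pA − pO)(pX − pB).

    Jackknifed over the block partition with weights equal to the number
    of sites per block at which all four populations have data.
    """
    (pa, po, px, pb), ok = _freqs(pf, (a, o, x, b))
    if not ok.any():
        raise ValueError("no site with data in all four populations")
    vals = (pa - po) * (px - pb)
    blocks = partition.block_ids[ok]
    counts = np.bincount(blocks, minlength=partition.n_blocks).astype(float)
    sums = _block_sums(vals, blocks, partition.n_blocks)
    return _ratio_jackknife(sums, counts, counts)


def d_statistic(
    pf: PopulationFrequencies, h1: str, h2: str, h3: str, h4: str,
    partition: BlockPartition,
) -> JackknifeEstimate:
    """ABBA-BABA D statistic with block-jackknife SE and Z.

    ``D = Σ (p1−p2)(p3−p4) / Σ (p1+p2−2p1p2)(p3+p4−2p3p4)``; swapping H1
    and H2 negates D and Z exactly; D = 0 in expectation without gene flow.
    """
    (p1, p2, p3, p4), ok = _freqs(pf, (h1, h2, h3, h4))
    if not ok.any():
        raise ValueError("no site with data in all four populations")
    num = (p1 - p2) * (p3 - p4)
    den = (p1 + p2 - 2 * p1 * p2) * (p3 + p4 - 2 * p3 * p4)
    if not (den != 0).any():
        raise ValueError("D statistic undefined: all-zero denominator")
    blocks = partition.block_ids[ok]
    informative = (den != 0).astype(float)
    return _ratio_jackknife(
        _block_sums(num, blocks, partition.n_blocks),
        _block_sums(den, blocks, partition.n_blocks),
        _block_sums(informative, blocks, partition.n_blocks),
    )


def f4_ratio(
    pf: PopulationFrequencies, a: str, o: str, x: str, b: str, c: str,
    partition: BlockPartition, min_denominator_z: float = 3.0,
):
    """Admixture proportion α = f4(A,O;X,B) / f4(A,O;C,B).

    Both f4 terms are restricted to the common site set (data in all six
    roles) and jackknifed on the same partition, so the SE reflects the
    ratio's covariance structure.  Raises :class:`UnstableRatioError` when
    the denominator f4 is not significantly nonzero.
    """
    from .structure import AncestryEstimate

    (pa, po, px, pb, pc), ok = _freqs(pf, (a, o, x, b, c))
    if not ok.any():
        raise ValueError("no site with data in all five populations")
    num_vals = (pa - po) * (px - pb)
    den_vals = (pa - po) * (pc - pb)
    blocks = partition.block_ids[ok]
    counts = np.bincount(blocks, minlength=partition.n_blocks).astype(float)
    num_sums = _block_sums(num_vals, blocks, partition.n_blocks)
    den_sums = _block_sums(den_vals, blocks, partition.n_blocks)
    den_jk = _ratio_jackknife(den_sums, counts, counts)
    import math
    if not math.isnan(den_jk.z) and abs(den_jk.z) < min_denominator_z:
        num_jk = _ratio_jackknife(num_sums, counts, counts)
        raise UnstableRatioError(
            f"denominator f4 not significantly nonzero (|Z|={abs(den_jk.z):.2f})",
            f4_num=num_jk, f4_den=den_jk,
        )
    jk = _ratio_jackknife(num_sums, den_sums, counts)
    return AncestryEstimate(
        hybrid_index=pd.Series({x: jk.estimate}),
        method="F4RATIO",
        alpha=jk.estimate, se=jk.se, z=jk.z, n_blocks=jk.n_blocks,
    )


# ---------------------------------------------------------------------------
# Mantel test and geography


@dataclass
class MantelResult:
    rho: float
    p: float
    n_perm: int
    seed: int


def _lower_triangle(mat: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j]


def mantel_test(
    mat_a: np.ndarray, mat_b: np.ndarray, n_perm: int = 9999, seed: int = 0
) -> MantelResult:
    """One-sided Mantel test with Spearman correlation.

    rho is the Spearman correlation of the strictly-lower-triangle entries;
    the p-value permutes the row/column labels of ``mat_b`` jointly:
    ``p = (1 + #{rho_perm >= rho_obs}) / (n_perm + 1)``.
    """
    a = np.asarray(mat_a, dtype=float)
    b = np.asarray(mat_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square with equal dimension")
    m = a.shape[0]
    if m < 3:
        raise ValueError("need dimension >= 3")
    for mat in (a, b):
        if not np.allclose(mat, mat.T):
            raise ValueError("matrices must be symmetric")
        if not np.allclose(np.diag(mat), 0):
            raise ValueError("matrices must have zero diagonal")
    va = _lower_triangle(a)
    vb = _lower_triangle(b)
    if np.all(va == va[0]) or np.all(vb == vb[0]):
        raise ValueError("constant matrix: Spearman rho undefined")
    ra = rankdata(va)
    ra = (ra - ra.mean()) / np.sqrt(((ra - ra.mean()) ** 2).sum())

    def rho_of(bm: np.ndarray) -> float:
        rb = rankdata(_lower_triangle(bm))
        rb = (rb - rb.mean()) / np.sqrt(((rb - rb.mean()) ** 2).sum())
        return float(ra @ rb)

    rho_obs = rho_of(b)
    rng = np.random.default_rng(seed)
    # vectorized label permutations: gather permuted lower triangles at once
    perms = np.stack([rng.permutation(m) for _ in range(n_perm)])
    i, j = np.tril_indices(m, k=-1)
    tri = b[perms[:, i], perms[:, j]]  # (n_perm, n_pairs)
    rb = rankdata(tri, axis=1).astype(float)
    rb -= rb.mean(axis=1, keepdims=True)
    norms = np.sqrt((rb ** 2).sum(axis=1))
    rho_perm = (rb @ ra) / np.where(norms > 0, norms, np.inf)
    p = (1 + int((rho_perm >= rho_obs - 1e-12).sum())) / (n_perm + 1)
    return MantelResult(rho=rho_obs, p=float(p), n_perm=n_perm, seed=seed)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance (km) between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _densify(boundary: np.ndarray, max_spacing_km: float) -> np.ndarray:
    """Insert vertices along each polyline edge so consecutive spacing is
    at most ``max_spacing_km`` (spherical linear interpolation)."""
    pts = [boundary[0]]
    for k in range(1, len(boundary)):
        p0, p1 = boundary[k - 1], boundary[k]
        d = float(haversine_km(p0[0], p0[1], p1[0], p1[1]))
        n_seg = max(1, int(np.ceil(d / max_spacing_km)))
        if n_seg > 1:
            v0 = _to_unit(p0)
            v1 = _to_unit(p1)
            omega = np.arccos(np.clip(v0 @ v1, -1, 1))
            for t in np.linspace(0, 1, n_seg + 1)[1:-1]:
                v = (np.sin((1 - t) * omega) * v0 + np.sin(t * omega) * v1) / np.sin(omega)
                pts.append(_from_unit(v))
        pts.append(p1)
    return np.array(pts)


def _to_unit(latlon):
    lat, lon = np.radians(latlon)
    return np.array([np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)])


def _from_unit(v):
    return np.degrees([np.arcsin(np.clip(v[2], -1, 1)), np.arctan2(v[1], v[0])])


def distance_to_forest(
    points: np.ndarray, forest_boundary: list[np.ndarray],
    max_spacing_km: float = 1.0,
) -> np.ndarray:
    """Minimum great-circle distance (km) from each point to any vertex of
    the densified forest-boundary polylines.

    ``points`` is (n, 2) lat/lon in decimal degrees; ``forest_boundary`` a
    list of (m_k, 2) polylines.  Vertices are inserted so that consecutive
    boundary vertices are at most ``max_spacing_km`` apart.
    """
    if not forest_boundary or all(len(b) == 0 for b in forest_boundary):
        raise ValueError("empty forest boundary")
    verts = np.vstack([
        _densify(np.asarray(b, dtype=float), max_spacing_km)
        for b in forest_boundary if len(b)
    ])
    pts = np.asarray(points, dtype=float)
    out = np.empty(len(pts))
    for i, (lat, lon) in enumerate(pts):
        out[i] = haversine_km(lat, lon, verts[:, 0], verts[:, 1]).min()
    return out
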