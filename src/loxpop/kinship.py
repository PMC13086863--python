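"""Pairwise relatedness screening: R0, R1, KING-robust, and relative pruning.

Statistics come from the 3×3 joint genotype-count table of a sample pair
(equivalently its 2D SFS), not from allele frequencies, so they are robust
to population structure:

* ``KING = (S − 2·O) / (H_i + H_j)`` with S the shared-heterozygote count,
  O the opposing-homozygote count and H the per-sample het totals;
  ≈ 0.5 for duplicates, ≈ 0.25 for first-degree pairs, ≈ 0 for unrelated.
* ``R0 = O / S`` — exactly 0 for parent–offspring pairs (opposing
  homozygotes are Mendelian-impossible without genotyping error).
* ``R1 = S / Σ(discordant cells)`` — reported descriptively; published
  denominators vary, so classification relies on KING and R0 only.

These are hard-genotype analogues of the genotype-likelihood statistics;
at high coverage they target the same quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .vcfio import MISSING, GenotypeMatrix

KING_DUPLICATE = 0.354  # 1 / 2^{3/2}
KING_FIRST_DEGREE = 0.177  # 1 / 2^{5/2}

CLASS_DUPLICATE = "DUPLICATE"
CLASS_FIRST_DEGREE = "FIRST_DEGREE"
CLASS_UNRELATED = "UNRELATED"
CLASS_OTHER = "OTHER"


@dataclass
class JointGenotypeCounts:
    """3×3 site-count table for a sample pair over jointly called sites."""

    counts: np.ndarray  # counts[g1][g2]
    sample_a: str
    sample_b: str

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


@dataclass
class KinshipResult:
    sample_a: str
    sample_b: str
    n_sites: int
    r0: float
    r1: float
    king: float
    classification: str


def joint_counts(gm: GenotypeMatrix, sample_a: str, sample_b: str) -> JointGenotypeCounts:
    """Tabulate joint genotypes over sites where both samples are called."""
    if sample_a == sample_b:
        raise ValueError("samples must be distinct")
    ga = gm.genotypes[gm.sample_index(sample_a)]
    gb = gm.genotypes[gm.sample_index(sample_b)]
    ok = (ga != MISSING) & (gb != MISSING)
    if not ok.any():
        raise ValueError("zero jointly called sites")
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (ga[ok], gb[ok]), 1)
    return JointGenotypeCounts(counts=counts, sample_a=sample_a, sample_b=sample_b)


def kinship_stats(
    jc: JointGenotypeCounts,
    king_dup: float = KING_DUPLICATE,
    king_first: float = KING_FIRST_DEGREE,
) -> KinshipResult:
    """R0, R1 and KING-robust from joint genotype counts.

    Undefined denominators yield NaN statistics rather than an exception.
    Classification: KING ≥ ``king_dup`` and R0 ≈ 0 → DUPLICATE;
    KING ≥ ``king_first`` → FIRST_DEGREE; |KING| small → UNRELATED;
    anything else → OTHER.
    """
    n = jc.counts
    O = int(n[0, 2] + n[2, 0])
    S = int(n[1, 1])
    h_i = int(n[1, :].sum())
    h_j = int(n[:, 1].sum())
    discordant = int(jc.n_sites - np.trace(n))
    king = (S - 2 * O) / (h_i + h_j) if h_i + h_j > 0 else float("nan")
    r0 = O / S if S > 0 else float("nan")
    r1 = S / discordant if discordant > 0 else float("nan")
    if np.isnan(king):
        klass = CLASS_OTHER
    elif king >= king_dup:
        klass = CLASS_DUPLICATE
    elif king >= king_first:
        klass = CLASS_FIRST_DEGREE
    elif abs(king) < king_first / 2:
        klass = CLASS_UNRELATED
    else:
        klass = CLASS_OTHER
    return KinshipResult(
        sample_a=jc.sample_a, sample_b=jc.sample_b, n_sites=jc.n_sites,
        r0=r0, r1=r1, king=king, classification=klass,
    )


def pairwise_kinship(gm: GenotypeMatrix) -> list[KinshipResult]:
    return [
        kinship_stats(joint_counts(gm, a, b))
        for a, b in combinations(gm.sample_ids, 2)
    ]


def kinship_table(results: list[KinshipResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_a, r.sample_b, r.n_sites, r.r0, r.r1, r.king, r.classification)
         for r in results],
        columns=["sampleA", "sampleB", "n_sites", "R0", "R1", "KING", "class"],
    )


def prune_relatives(
    results: list[KinshipResult],
    coverage: Optional[Mapping[str, float]] = None,
    king_first: float = KING_FIRST_DEGREE,
) -> set[str]:
    """Greedy removal of one member of each duplicate/first-degree pair.

    Pairs at or above ``king_first`` are processed in order of descending
    KING; from each still-intact pair the lower-coverage member is removed
    (the later id on a coverage tie or when no coverage is given).
    Returns the kept sample set.
    """
    samples = {r.sample_a for r in results} | {r.sample_b for r in results}
    removed: set[str] = set()
    flagged = sorted(
        (r for r in results if not np.isnan(r.king) and r.king >= king_first),
        key=lambda r: -r.king,
    )
    for r in flagged:
        if r.sample_a in removed or r.sample_b in removed:
            continue
        ca = coverage.get(r.sample_a, 0.0) if coverage else 0.0
        cb = coverage.get(r.sample_b, 0.0) if coverage else 0.0
        if ca < cb:
            removed.add(r.sample_a)
        elif cb < ca:
            removed.add(r.sample_b)
        else:
            removed.add(max(r.sample_a, r.sample_b))
    return samples - removed
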