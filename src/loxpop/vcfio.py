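"""Read/write the standard formats of the stack and build the in-memory cohort.

The substrate of every downstream stage is a :class:`GenotypeMatrix`:
a samples × sites array of diploid genotype codes counting non-reference
(or, after polarization, derived) alleles, plus per-site metadata and the
optional per-genotype depth fields that the genotype-level filters need.

Conventions
-----------
* VCF positions are 1-based; BED intervals are 0-based half-open.  All
  internal interval arithmetic uses the BED convention: position ``p`` lies
  inside ``[s, e)`` iff ``s <= p - 1 < e``.
* Only biallelic SNVs are retained; indels and multiallelic records are
  dropped on read with a logged count (they are not split).
* Missing genotypes are coded as :data:`MISSING` (= -1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1
UNKNOWN_ANCESTRAL: str = "."

#: severity order used to resolve multi-transcript annotations
IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "SYNONYMOUS", "NONE")
_IMPACT_RANK = {imp: i for i, imp in enumerate(IMPACT_LEVELS)}

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "ancestral", "impact"]


class VcfFormatError(ValueError):
    """Malformed VCF header or records."""


class EmptyInputError(ValueError):
    """No biallelic SNVs retained from the input."""


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for a cohort at biallelic SNVs.

    Attributes
    ----------
    sample_ids:
        Sample identifiers, one per row of ``genotypes``.
    sites:
        DataFrame with columns ``chrom, pos, ref, alt, ancestral, impact``;
        strictly sorted by (chrom, pos).
    genotypes:
        ``(n_samples, n_sites)`` int8 array with values in {0, 1, 2, MISSING}.
    depth:
        Optional ``(n_samples, n_sites)`` int32 per-genotype total read depth.
    allelic_depth:
        Optional ``(n_samples, n_sites, 2)`` int32 (ref_reads, alt_reads);
        -1 marks an absent AD field.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    depth: Optional[np.ndarray] = None
    allelic_depth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, s = len(self.sample_ids), len(self.sites)
        if self.genotypes.shape != (n, s):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} != ({n}, {s})"
            )
        g = self.genotypes
        if ((g < MISSING) | (g > 2)).any():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")
        for name in ("depth", "allelic_depth"):
            arr = getattr(self, name)
            if arr is not None and arr.shape[:2] != (n, s):
                raise ValueError(f"{name} shape {arr.shape} != ({n}, {s}, ...)")
        if s > 1:
            key = list(zip(self.sites["chrom"], self.sites["pos"]))
            if any(key[i] >= key[i + 1] for i in range(s - 1)):
                raise ValueError("sites must be strictly sorted by (chrom, pos)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site index (bool mask or ints)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[:, index],
            depth=None if self.depth is None else self.depth[:, index],
            allelic_depth=(
                None if self.allelic_depth is None else self.allelic_depth[:, index]
            ),
        )

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            sites=self.sites.copy(),
            genotypes=self.genotypes[idx],
            depth=None if self.depth is None else self.depth[idx],
            allelic_depth=(
                None if self.allelic_depth is None else self.allelic_depth[idx]
            ),
        )

    def polarized(self) -> "GenotypeMatrix":
        """Flip genotype codes to count derived alleles.

        Where the ancestral allele equals ALT, codes flip ``g -> 2 - g``;
        where it equals REF they are already derived counts.  Sites with
        UNKNOWN ancestral state are retained unchanged — derived-allele
        operations must exclude them via :meth:`derived_known_mask`.
        """
        flip = (self.sites["ancestral"] == self.sites["alt"]).to_numpy()
        g = self.genotypes.copy()
        cols = np.flatnonzero(flip)
        sub = g[:, cols]
        sub[sub >= 0] = 2 - sub[sub >= 0]
        g[:, cols] = sub
        return replace(self, genotypes=g, sites=self.sites.copy())

    def derived_known_mask(self) -> np.ndarray:
        """Boolean mask of sites whose ancestral allele is REF or ALT."""
        anc = self.sites["ancestral"]
        return ((anc == self.sites["ref"]) | (anc == self.sites["alt"])).to_numpy()


@dataclass
class GenomicIntervalSet:
    """Per-chromosome sorted, merged 0-based half-open intervals."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_tuples(
        cls, tuples: Iterable[tuple[str, int, int]]
    ) -> "GenomicIntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        return cls({c: _merge(np.array(sorted(iv))) for c, iv in by_chrom.items()})

    def total_span(self) -> int:
        return sum(int((iv[:, 1] - iv[:, 0]).sum()) for iv in self.intervals.values())

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Membership of 1-based positions, vectorized per chromosome."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        out = np.zeros(len(pos), dtype=bool)
        for c in np.unique(chrom):
            iv = self.intervals.get(str(c))
            if iv is None or len(iv) == 0:
                continue
            sel = chrom == c
            p0 = pos[sel] - 1  # to 0-based
            k = np.searchsorted(iv[:, 0], p0, side="right") - 1
            ok = k >= 0
            ok[ok] &= p0[ok] < iv[k[ok], 1]
            out[sel] = ok
        return out


def _merge(iv: np.ndarray) -> np.ndarray:
    if len(iv) == 0:
        return iv.reshape(0, 2)
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged)


def read_bed(path) -> GenomicIntervalSet:
    """Load a BED3 file; overlapping intervals are merged."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return GenomicIntervalSet.from_tuples(df.itertuples(index=False, name=None))


def write_bed(ivs: GenomicIntervalSet, path) -> None:
    with open(path, "w") as fh:
        for chrom in ivs.intervals:
            for s, e in ivs.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_sample_table(path) -> pd.DataFrame:
    """TSV with header ``sample species population lat lon`` (lat/lon optional)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "species", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    for col, bound in (("lat", 90.0), ("lon", 180.0)):
        if col in df.columns:
            vals = df[col].dropna()
            if (vals.abs() > bound).any():
                raise ValueError(f"|{col}| exceeds {bound}")
    return df


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF


def apply_interval_mask(
    gm: GenotypeMatrix, mask: GenomicIntervalSet, mode: str = "keep"
) -> GenotypeMatrix:
    """Subset sites by a BED interval set; the sample set is unchanged.

    ``mode='keep'`` retains sites inside the intervals, ``'remove'`` drops
    them.  An empty result is allowed.
    """
    if mode not in ("keep", "remove"):
        raise ValueError("mode must be 'keep' or 'remove'")
    inside = mask.contains(
        gm.sites["chrom"].to_numpy(), gm.sites["pos"].to_numpy(np.int64)
    )
    return gm.take_sites(inside if mode == "keep" else ~inside)


def _parse_ann_impact(ann: Optional[str]) -> str:
    """Impact from an ANN INFO value; multiple transcripts resolve by severity.

    Per SnpEff convention annotation effect is field 2 (|-separated) and the
    impact class field 3; a ``synonymous_variant`` effect is tabulated as its
    own SYNONYMOUS category.
    """
    if not ann:
        return "NONE"
    best = "NONE"
    for entry in str(ann).split(","):
        parts = entry.split("|")
        if len(parts) < 3:
            continue
        effect, impact = parts[1], parts[2].upper()
        if "synonymous_variant" in effect:
            impact = "SYNONYMOUS"
        if impact not in _IMPACT_RANK:
            continue
        if _IMPACT_RANK[impact] < _IMPACT_RANK[best]:
            best = impact
    return best


def read_vcf(
    path,
    region_filter: Optional[GenomicIntervalSet] = None,
    ancestral_table: Optional[pd.DataFrame] = None,
) -> GenotypeMatrix:
    """Read a diploid VCF into a :class:`GenotypeMatrix`.

    Indels and multiallelic records are dropped (count logged).  ``./.``
    genotypes become MISSING.  DP and AD FORMAT fields and the AA INFO tag
    are captured when present.  ``ancestral_table`` is an optional two-column
    sidecar (chrom:pos key via columns ``chrom, pos, ancestral``) overriding
    the AA tag.

    Raises
    ------
    VcfFormatError
        On an unreadable/malformed file.
    EmptyInputError
        When no biallelic SNV is retained.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VcfFormatError(f"cannot read VCF {path}: {exc}") from exc

    rows = []
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    ads: list[np.ndarray] = []
    any_dp = any_ad = False
    n_dropped = 0
    n = len(samples)
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        g = np.asarray(var.gt_types, dtype=np.int8)  # gts012: 3 == unknown
        g[g == 3] = MISSING
        gts.append(g)
        fmts = var.FORMAT
        if "DP" in fmts:
            any_dp = True
            dp = var.format("DP")
            dp = np.where(dp < 0, 0, dp).astype(np.int32).reshape(n)
        else:
            dp = np.zeros(n, dtype=np.int32)
        dps.append(dp)
        if "AD" in fmts:
            any_ad = True
            ad = var.format("AD").astype(np.int64).reshape(n, -1)[:, :2]
            ad = np.where(ad < 0, -1, ad).astype(np.int32)
        else:
            ad = np.full((n, 2), -1, dtype=np.int32)
        ads.append(ad)
        aa = var.INFO.get("AA")
        impact = _parse_ann_impact(var.INFO.get("ANN"))
        rows.append(
            (var.CHROM, var.POS, var.REF, var.ALT[0],
             aa if aa in ("A", "C", "G", "T") else UNKNOWN_ANCESTRAL, impact)
        )
    if n_dropped:
        logger.info("dropped %d non-biallelic-SNV records", n_dropped)
    if not rows:
        raise EmptyInputError(f"no biallelic SNVs retained from {path}")

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if ancestral_table is not None:
        key = sites["chrom"].astype(str) + ":" + sites["pos"].astype(str)
        lut = dict(
            zip(
                ancestral_table["chrom"].astype(str)
                + ":"
                + ancestral_table["pos"].astype(str),
                ancestral_table["ancestral"],
            )
        )
        sites["ancestral"] = [lut.get(k, a) for k, a in zip(key, sites["ancestral"])]

    gm = GenotypeMatrix(
        sample_ids=samples,
        sites=sites,
        genotypes=np.vstack(gts).T.astype(np.int8) if gts else
        np.zeros((n, 0), np.int8),
        depth=np.vstack(dps).T if any_dp else None,
        allelic_depth=np.stack(ads, axis=1) if any_ad else None,
    )
    if region_filter is not None:
        gm = apply_interval_mask(gm, region_filter, mode="keep")
    return gm


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=loxpop
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotation: Allele|Annotation|Impact">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""

_IMPACT_EFFECT = {
    "HIGH": ("stop_gained", "HIGH"),
    "MODERATE": ("missense_variant", "MODERATE"),
    "LOW": ("splice_region_variant", "LOW"),
    "SYNONYMOUS": ("synonymous_variant", "LOW"),
}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write VCF 4.2 with GT (and DP/AD/AA/ANN when present); lossless for
    the retained fields, so ``read_vcf(write_vcf(gm))`` round-trips."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        contigs = dict.fromkeys(gm.sites["chrom"].astype(str))
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        if not contigs:
            fh.write("##contig=<ID=chr1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        fmt = "GT"
        if gm.depth is not None:
            fmt += ":DP"
        if gm.allelic_depth is not None:
            fmt += ":AD"
        sites = gm.sites
        # vectorized per-cell strings (transposed to sites × samples)
        gt_lut = np.array(["./.", "0/0", "0/1", "1/1"], dtype=object)
        cells = gt_lut[gm.genotypes.T.astype(np.int16) + 1]
        if gm.depth is not None:
            cells = cells + ":" + gm.depth.T.astype(str).astype(object)
        if gm.allelic_depth is not None:
            ref_r = gm.allelic_depth[..., 0].T
            alt_r = gm.allelic_depth[..., 1].T
            ad = np.where(
                ref_r < 0, ".",
                np.char.add(np.char.add(ref_r.astype(str), ","),
                            alt_r.astype(str)),
            ).astype(object)
            cells = cells + ":" + ad
        info = np.full(gm.n_sites, "", dtype=object)
        anc = sites["ancestral"].to_numpy()
        has_aa = anc != UNKNOWN_ANCESTRAL
        info[has_aa] = "AA=" + anc[has_aa].astype(object)
        impact = sites["impact"].to_numpy()
        alt_al = sites["alt"].to_numpy(dtype=object)
        for imp, (effect, klass) in _IMPACT_EFFECT.items():
            sel = impact == imp
            ann = alt_al[sel] + f"|{effect}|{klass}"
            info[sel] = np.where(info[sel] == "", "ANN=" + ann,
                                 info[sel] + ";ANN=" + ann)
        info[info == ""] = "."
        left = (
            sites["chrom"].astype(str) + "\t" + sites["pos"].astype(str)
            + "\t.\t" + sites["ref"].astype(str) + "\t"
            + sites["alt"].astype(str) + "\t.\tPASS\t" + info + "\t" + fmt
        ).to_numpy(dtype=object)
        for j in range(gm.n_sites):
            fh.write(left[j] + "\t" + "\t".join(cells[j]) + "\n")
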