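"""Heterozygosity, PLINK-style ROH detection, F_ROH and size classes.

The ROH caller reproduces the PLINK 1.9 ``--homozyg`` sliding-window
algorithm: a fixed-size SNP window slides along each chromosome, a window
is called homozygous when it contains at most ``window_het`` heterozygous
and ``window_missing`` missing calls, each SNP's *hit fraction* is the
proportion of windows containing it that are homozygous, and maximal runs
of SNPs with hit fraction ≥ ``window_threshold`` become segments subject
to minimum SNP count, minimum length, maximum kb-per-SNP density, and a
maximum inter-SNP gap (a larger gap splits the run).  Windows that would
extend past a chromosome end are truncated, so byte-equality with PLINK at
chromosome edges is not promised.

Defaults are the PLINK 1.9 defaults (window 50 SNPs, threshold 0.05,
min 100 SNPs, min 1000 kb, density 50 kb/SNP, gap 1000 kb) with the het
and missing allowances opened to 3 and 20 calls per window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vcfio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["sample", "chrom", "start_pos", "end_pos", "n_snps", "length_bp"]


@dataclass
class RohParams:
    """Sliding-window ROH parameters (PLINK 1.9 ``--homozyg`` family)."""

    window_snps: int = 50
    window_het: int = 3
    window_missing: int = 20
    window_threshold: float = 0.05
    min_snps: int = 100
    min_length_bp: int = 1_000_000
    max_kb_per_snp: float = 50.0
    max_gap_bp: int = 1_000_000


@dataclass
class ROHSegmentSet:
    """Per-sample homozygous segments with the parameters that produced them."""

    segments: pd.DataFrame  # columns SEGMENT_COLUMNS
    params: RohParams = field(default_factory=RohParams)

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.segments[self.segments["sample"] == sample_id]

    def total_length(self, sample_id: str) -> int:
        return int(self.for_sample(sample_id)["length_bp"].sum())

    def to_plink_hom(self) -> pd.DataFrame:
        """PLINK ``.hom``-style table (FID IID CHR POS1 POS2 KB NSNP)."""
        s = self.segments
        return pd.DataFrame({
            "FID": s["sample"], "IID": s["sample"], "CHR": s["chrom"],
            "POS1": s["start_pos"], "POS2": s["end_pos"],
            "KB": s["length_bp"] / 1000.0, "NSNP": s["n_snps"],
        })


def _call_chromosome(g: np.ndarray, pos: np.ndarray, params: RohParams):
    """Eligible-run segments for one sample on one chromosome.

    Returns a list of (start_idx, end_idx) site-index runs that satisfy
    every segment-level rule.
    """
    L = len(g)
    W = params.window_snps
    if L < W:
        return []
    het = (g == 1).astype(np.int32)
    mis = (g == MISSING).astype(np.int32)
    kern = np.ones(W, dtype=np.int32)
    het_w = np.convolve(het, kern, mode="valid")  # per window start
    mis_w = np.convolve(mis, kern, mode="valid")
    hom_w = ((het_w <= params.window_het) & (mis_w <= params.window_missing)) \
        .astype(np.int32)
    # windows containing SNP i start in [i-W+1, i] clipped to [0, L-W]
    n_start = L - W + 1
    chom = np.concatenate([[0], np.cumsum(hom_w)])
    lo = np.clip(np.arange(L) - W + 1, 0, n_start - 1)
    hi = np.minimum(np.arange(L), n_start - 1)
    n_windows = hi - lo + 1
    n_hom = chom[hi + 1] - chom[lo]
    frac = n_hom / n_windows
    eligible = frac >= params.window_threshold
    # maximal runs of eligible SNPs, split at gaps > max_gap_bp
    runs = []
    i = 0
    while i < L:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < L and eligible[j + 1] and pos[j + 1] - pos[j] <= params.max_gap_bp:
            j += 1
        runs.append((i, j))
        i = j + 1
    out = []
    for i, j in runs:
        n_snps = j - i + 1
        length = int(pos[j] - pos[i] + 1)
        if n_snps < params.min_snps:
            continue
        if length < params.min_length_bp:
            continue
        if length / 1000.0 / n_snps > params.max_kb_per_snp:
            continue
        out.append((i, j, n_snps, length))
    return out


def roh_call(gm: GenotypeMatrix, params: RohParams | None = None) -> ROHSegmentSet:
    """Call runs of homozygosity for every sample.

    Chromosomes with fewer SNPs than the window size are skipped with a
    warning.  Segment boundaries are the positions of the first and last
    SNP of the qualifying run (1-based, inclusive).
    """
    params = params or RohParams()
    chrom_arr = gm.sites["chrom"].to_numpy()
    pos_arr = gm.sites["pos"].to_numpy(np.int64)
    rows = []
    for chrom in pd.unique(gm.sites["chrom"]):
        sel = np.flatnonzero(chrom_arr == chrom)
        if len(sel) < params.window_snps:
            logger.warning(
                "chromosome %s has %d < %d SNPs; skipped",
                chrom, len(sel), params.window_snps,
            )
            continue
        pos = pos_arr[sel]
        for i, sample in enumerate(gm.sample_ids):
            g = gm.genotypes[i, sel]
            for a, b, n_snps, length in _call_chromosome(g, pos, params):
                rows.append((sample, chrom, int(pos[a]), int(pos[b]), n_snps, length))
    segments = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return ROHSegmentSet(segments=segments, params=params)


def froh(roh: ROHSegmentSet, autosomal_span_bp: int,
         sample_ids: list[str] | None = None) -> pd.Series:
    """Genomic inbreeding coefficient F_ROH = Σ segment length / span."""
    if autosomal_span_bp <= 0:
        raise ValueError("autosomal span must be positive")
    totals = roh.segments.groupby("sample")["length_bp"].sum()
    if sample_ids is not None:
        totals = totals.reindex(sample_ids, fill_value=0)
    return totals / float(autosomal_span_bp)


def roh_size_classes(
    roh: ROHSegmentSet, breaks: tuple[int, ...] = (2_000_000, 5_000_000),
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Total ROH length per sample per size class.

    Classes are left-closed, right-open intervals over segment length:
    with the default breaks a 2 Mb segment falls in the 2–5 Mb class.
    """
    if list(breaks) != sorted(breaks):
        raise ValueError("breaks must be increasing")
    edges = [0, *breaks, np.inf]
    labels = []
    for k in range(len(edges) - 1):
        lo = edges[k] / 1e6
        hi = edges[k + 1]
        labels.append(f"lt{hi/1e6:g}Mb" if k == 0 else
                      (f"ge{lo:g}Mb" if np.isinf(hi) else f"{lo:g}to{hi/1e6:g}Mb"))
    s = roh.segments
    klass = np.searchsorted(np.array(breaks), s["length_bp"].to_numpy(), side="right")
    df = pd.DataFrame({"sample": s["sample"], "class": [labels[k] for k in klass],
                       "length_bp": s["length_bp"]})
    out = df.pivot_table(index="sample", columns="class", values="length_bp",
                         aggfunc="sum", fill_value=0)
    for lab in labels:
        if lab not in out.columns:
            out[lab] = 0
    out = out[labels]
    if sample_ids is not None:
        out = out.reindex(sample_ids, fill_value=0)
    return out


def heterozygosity(gm: GenotypeMatrix, callable_span: int | pd.Series) -> pd.Series:
    """Per-sample H_O: heterozygous genotypes / callable sites.

    ``callable_span`` counts callable positions (variant and invariant)
    after masking; masked (MISSING) genotypes never count as heterozygous,
    and the caller is responsible for excluding them from the span.
    """
    het = pd.Series((gm.genotypes == 1).sum(axis=1), index=gm.sample_ids, dtype=float)
    span = pd.Series(callable_span, index=gm.sample_ids) \
        if np.ndim(callable_span) else float(callable_span)
    if np.any(np.asarray(span) <= 0):
        raise ValueError("callable span must be positive")
    return het / span


def het_outside_roh(
    gm: GenotypeMatrix, roh: ROHSegmentSet,
    callable_span_outside: int | pd.Series,
) -> pd.Series:
    """H_O restricted to sites outside each sample's own ROH segments.

    A sample with no ROH reproduces :func:`heterozygosity` exactly.  Raises
    when a sample's ROH covers every variant site.
    """
    chrom = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy(np.int64)
    out = {}
    span = pd.Series(callable_span_outside, index=gm.sample_ids) \
        if np.ndim(callable_span_outside) else None
    for i, sample in enumerate(gm.sample_ids):
        inside = np.zeros(gm.n_sites, dtype=bool)
        for _, seg in roh.for_sample(sample).iterrows():
            inside |= (chrom == seg["chrom"]) & \
                (pos >= seg["start_pos"]) & (pos <= seg["end_pos"])
        if inside.all() and gm.n_sites:
            raise ValueError(f"all sites of sample {sample!r} fall inside ROH")
        het = int((gm.genotypes[i, ~inside] == 1).sum())
        sp = float(span[sample]) if span is not None else float(callable_span_outside)
        if sp <= 0:
            raise ValueError("callable span outside ROH must be positive")
        out[sample] = het / sp
    return pd.Series(out)


def diversity_summary(
    gm: GenotypeMatrix, roh: ROHSegmentSet, autosomal_span_bp: int,
) -> pd.DataFrame:
    """Per-sample table: H_O, H_O outside ROH, F_ROH, and size-class totals.

    Callable spans are the autosomal span (and the span minus each
    sample's ROH total) — appropriate when masking has already been
    applied upstream.
    """
    h_o = heterozygosity(gm, autosomal_span_bp)
    f = froh(roh, autosomal_span_bp, gm.sample_ids)
    span_out = pd.Series(
        {s: autosomal_span_bp - roh.total_length(s) for s in gm.sample_ids}
    )
    h_out = het_outside_roh(gm, roh, span_out)
    classes = roh_size_classes(roh, sample_ids=gm.sample_ids)
    df = pd.DataFrame({
        "sample": gm.sample_ids,
        "H_O": h_o.values,
        "H_O_outside": h_out[gm.sample_ids].values,
        "F_ROH": f[gm.sample_ids].values,
    })
    for col in classes.columns:
        df[f"kb_{col}"] = (classes[col].values / 1000.0)
    return df
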