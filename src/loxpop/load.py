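"""Derived-allele genetic-load counting and the two-species comparison.

Load is measured per sample as counts of derived alleles at annotated
sites, split by functional impact and zygosity, then normalized by the
synonymous category:

* heterozygous ("masked") load: # het deleterious derived sites /
  # het synonymous derived sites;
* homozygous ("realized") load: the same ratio over homozygous-derived
  sites.

The normalization cancels per-sample callability and polarization
artifacts, so the ratio is comparable across samples and scale-free
(duplicating every site leaves it unchanged).  Sites with unknown
ancestral state are excluded from all counts.  The species comparison
follows a normality-gated protocol: Shapiro–Wilk per group, Welch's
two-sided t (with pooled-SD Cohen's d and a Welch-df CI of the mean
difference) when both groups look normal, otherwise a Wilcoxon rank-sum
test with the Hodges–Lehmann shift estimator and its distribution-based
95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .vcfio import GenotypeMatrix, MISSING

logger = logging.getLogger(__name__)

LOAD_IMPACTS = ("HIGH", "MODERATE", "LOW", "SYNONYMOUS")
TEST_WELCH = "WELCH_T"
TEST_WILCOXON = "WILCOXON"


def count_load(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample derived-allele counts and load ratios by impact class.

    Requires impact annotations and ancestral alleles on the sites;
    genotypes are polarized to derived counts internally.  A sample's
    HET_DERIVED count for a class increments where its derived count is 1,
    HOM_DERIVED where it is 2.  Ratios for HIGH and MODERATE are
    normalized by the SYNONYMOUS counts and are NaN (undefined, never
    zero) when the synonymous denominator is zero.  LOW counts are
    tabulated but carry no ratio.
    """
    known = gm.derived_known_mask()
    n_excluded = int((~known).sum())
    if n_excluded:
        logger.info("load: excluding %d sites with unknown ancestral allele",
                    n_excluded)
    sub = gm.take_sites(known).polarized()
    impact = sub.sites["impact"].to_numpy()
    rows = []
    for i, sample in enumerate(sub.sample_ids):
        g = sub.genotypes[i]
        rec: dict[str, object] = {"sample": sample}
        for imp in LOAD_IMPACTS:
            sel = impact == imp
            rec[f"n_het_{imp.lower()}"] = int(((g == 1) & sel).sum())
            rec[f"n_hom_{imp.lower()}"] = int(((g == 2) & sel).sum())
        rows.append(rec)
    df = pd.DataFrame(rows)
    syn_het = df["n_het_synonymous"].to_numpy(float)
    syn_hom = df["n_hom_synonymous"].to_numpy(float)
    if (syn_het == 0).all() and (syn_hom == 0).all():
        logger.warning("no synonymous derived sites: all load ratios undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        for imp in ("high", "moderate"):
            df[f"het_load_{imp}"] = np.where(
                syn_het > 0, df[f"n_het_{imp}"] / syn_het, np.nan)
            df[f"hom_load_{imp}"] = np.where(
                syn_hom > 0, df[f"n_hom_{imp}"] / syn_hom, np.nan)
    return df


def exclude_admixed(
    load_table: pd.DataFrame,
    sample_table: pd.DataFrame,
    excluded_populations: Sequence[str],
) -> pd.DataFrame:
    """Drop samples from the listed (admixed) populations.

    Raises on an unknown population name; an empty list is the identity.
    """
    known = set(sample_table["population"].astype(str))
    unknown = [p for p in excluded_populations if p not in known]
    if unknown:
        raise ValueError(f"unknown population(s): {unknown}")
    meta = sample_table.set_index("sample")
    pops = load_table["sample"].map(meta["population"].astype(str))
    keep = ~pops.isin(set(map(str, excluded_populations)))
    out = load_table[keep].reset_index(drop=True)
    logger.info("load comparison: %d of %d samples retained", len(out), len(load_table))
    return out


@dataclass
class GroupComparisonResult:
    """Two-group comparison with normality-gated test choice."""

    test_name: str
    statistic: float
    p_value: float
    effect_size: float  # Cohen's d (Welch) or Hodges–Lehmann shift (Wilcoxon)
    ci95: tuple[float, float]
    df: Optional[float] = None
    normality_p: tuple[float, float] = (float("nan"), float("nan"))
    n: tuple[int, int] = (0, 0)


def _hodges_lehmann(a: np.ndarray, b: np.ndarray) -> tuple[float, tuple[float, float]]:
    """HL shift estimate (median of pairwise A−B differences) and its 95% CI
    from the normal approximation of the Mann–Whitney null distribution."""
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    hl = float(np.median(diffs))
    n1, n2 = len(a), len(b)
    N = n1 * n2
    mu = N / 2.0
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    k = int(np.floor(mu - 1.959963984540054 * sigma))
    k = max(k, 0)
    lo = diffs[k] if k < N else diffs[0]
    hi = diffs[N - 1 - k] if k < N else diffs[-1]
    return hl, (float(lo), float(hi))


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha_normality: float = 0.05,
    force_test: Optional[str] = None,
) -> GroupComparisonResult:
    """Compare two groups of per-sample load values.

    Shapiro–Wilk is run per group; when both p-values are at least
    ``alpha_normality`` a two-sided Welch t-test is used, otherwise a
    Wilcoxon rank-sum test.  Constant groups make normality undefined and
    fall through to Wilcoxon.  ``force_test`` ("welch" or "wilcoxon")
    overrides the gate.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 finite values")
    norm_p = []
    for grp in (a, b):
        if np.ptp(grp) == 0:
            norm_p.append(float("nan"))
        else:
            norm_p.append(float(stats.shapiro(grp).pvalue))
    use_welch = all(np.isfinite(p) and p >= alpha_normality for p in norm_p)
    if force_test is not None:
        use_welch = force_test.lower() in ("welch", "welch_t", "t")

    if use_welch:
        res = stats.ttest_ind(a, b, equal_var=False)
        n1, n2 = len(a), len(b)
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        pooled_sd = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
        d = (a.mean() - b.mean()) / pooled_sd if pooled_sd > 0 else float("nan")
        se = np.sqrt(v1 / n1 + v2 / n2)
        tcrit = stats.t.ppf(0.975, df)
        diff = a.mean() - b.mean()
        return GroupComparisonResult(
            test_name=TEST_WELCH,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            effect_size=float(d),
            ci95=(float(diff - tcrit * se), float(diff + tcrit * se)),
            df=float(df),
            normality_p=(norm_p[0], norm_p[1]),
            n=(n1, n2),
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    hl, ci = _hodges_lehmann(a, b)
    return GroupComparisonResult(
        test_name=TEST_WILCOXON,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size=hl,
        ci95=ci,
        df=None,
        normality_p=(norm_p[0], norm_p[1]),
        n=(len(a), len(b)),
    )
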