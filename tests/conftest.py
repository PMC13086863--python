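import numpy as np
import pandas as pd
import pytest

from loxpop.vcfio import SITE_COLUMNS, GenotypeMatrix


def make_sites(positions, chrom="chr1", ref="A", alt="G",
               ancestral=None, impact="NONE"):
    n = len(positions)
    return pd.DataFrame({
        "chrom": [chrom] * n if isinstance(chrom, str) else list(chrom),
        "pos": list(positions),
        "ref": [ref] * n if isinstance(ref, str) else list(ref),
        "alt": [alt] * n if isinstance(alt, str) else list(alt),
        "ancestral": ([ref] * n if isinstance(ref, str) else list(ref))
        if ancestral is None else
        ([ancestral] * n if isinstance(ancestral, str) else list(ancestral)),
        "impact": [impact] * n if isinstance(impact, str) else list(impact),
    })[SITE_COLUMNS]


def make_gm(genotypes, positions=None, sample_ids=None, **site_kwargs):
    """GenotypeMatrix from a plain (n_samples, n_sites) array of codes."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, s = g.shape
    if positions is None:
        positions = np.arange(1, s + 1) * 1000
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        sites=make_sites(positions, **site_kwargs),
        genotypes=g,
    )


def make_meta(gm, populations, species=None):
    pops = list(populations)
    return pd.DataFrame({
        "sample": gm.sample_ids,
        "species": species if species is not None else pops,
        "population": pops,
        "lat": np.nan, "lon": np.nan,
    })


@pytest.fixture
def tiny_vcf(tmp_path):
    """3 samples, 2 SNVs plus one indel and one multiallelic record."""
    text = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
chr1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0
chr1\t300\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t0/1\t0/0
chr1\t400\t.\tG\tA,C\t.\tPASS\t.\tGT\t0/0\t1/2\t0/0
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path
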