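"""End-to-end orchestration: filters → structure → diversity → kinship → load.

``run_pipeline`` executes the stages in dependency order from a flat
YAML/dict config, writing one TSV/JSON per stage with a provenance header
(tool version, seed, parameters).  A stage is skipped on rerun when all
of its outputs exist and are newer than the input VCF (idempotence); a
stage failure aborts everything downstream.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from . import __version__
from . import diversity, kinship, load, simdata, sitefilter, structure, vcfio

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "fst", "pca", "roh", "kinship", "load")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    output_dir: Path
    seed: int = 0
    vcf: Optional[Path] = None
    sample_table: Optional[Path] = None
    mask_bed: Optional[Path] = None
    simulate_preset: Optional[str] = None
    stages: tuple[str, ...] = STAGES
    params: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        core = {k: v for k, v in d.items() if k in known and k != "params"}
        params = dict(d.get("params", {}))
        cfg = cls(**{**core, "params": params})
        cfg.output_dir = Path(cfg.output_dir)
        for name in ("vcf", "sample_table", "mask_bed"):
            v = getattr(cfg, name)
            if v is not None:
                p = Path(v)
                if cfg.simulate_preset is None and not p.exists():
                    raise FileNotFoundError(f"{name}: {p}")
                setattr(cfg, name, p)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _provenance(cfg: RunConfig, stage: str, **params) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return (f"# loxpop {__version__} stage={stage} seed={cfg.seed} "
            f"time={time.strftime('%Y-%m-%dT%H:%M:%S')} {kv}\n")


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def _fresh(outputs: list[Path], inputs: list[Path]) -> bool:
    if not all(p.exists() for p in outputs):
        return False
    newest_in = max((p.stat().st_mtime for p in inputs if p.exists()), default=0.0)
    return all(p.stat().st_mtime >= newest_in for p in outputs)


def run_pipeline(cfg: RunConfig) -> dict[str, list[Path]]:
    """Run the configured stages; returns the per-stage output files."""
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    produced: dict[str, list[Path]] = {}
    params = cfg.params

    vcf_path = cfg.vcf
    sample_path = cfg.sample_table
    if "simulate" in cfg.stages and cfg.simulate_preset:
        vcf_path = vcf_path or out / "cohort.vcf"
        sample_path = sample_path or out / "samples.tsv"
        truth_path = out / "truth.json"
        outputs = [vcf_path, sample_path, truth_path]
        if _fresh(outputs, []):
            logger.info("simulate: outputs up to date, skipped")
        else:
            gm, meta, truth = simdata.simulate_cohort(
                simdata.preset(cfg.simulate_preset, cfg.seed)
            )
            vcfio.write_vcf(gm, vcf_path)
            vcfio.write_sample_table(meta, sample_path)
            truth.to_json(truth_path)
        produced["simulate"] = outputs
    if vcf_path is None or sample_path is None:
        raise ValueError("pipeline needs a VCF and sample table (or a simulate preset)")

    gm = None

    def cohort() -> vcfio.GenotypeMatrix:
        nonlocal gm
        if gm is None:
            mask = vcfio.read_bed(cfg.mask_bed) if cfg.mask_bed else None
            gm = vcfio.read_vcf(vcf_path, region_filter=mask)
        return gm

    meta = vcfio.read_sample_table(sample_path)
    inputs = [vcf_path, sample_path]

    if "filter" in cfg.stages:
        path = out / "site_filters.tsv"
        if _fresh([path], inputs):
            logger.info("filter: outputs up to date, skipped")
        else:
            g = cohort()
            rep = sitefilter.excess_het_filter(
                g,
                window_bp=params.get("window_bp", 10_000),
                f_threshold=params.get("het_F", -0.90),
                hwe_threshold=params.get("hwe_p", 1e-6),
            )
            df = rep.to_frame(g.sites)
            if g.depth is not None:
                drep = sitefilter.global_depth_filter(
                    g,
                    params.get("min_depth_factor", 0.5),
                    params.get("max_depth_factor", 1.5),
                )
                df["total_depth"] = drep.total_depth
                df["flags"] = [
                    ",".join(sorted(a | b)) or "."
                    for a, b in zip(rep.flags, drep.flags)
                ]
            _write_tsv(df, path, _provenance(cfg, "filter"))
        produced["filter"] = [path]

    if "fst" in cfg.stages:
        path = out / "fst_matrix.tsv"
        if _fresh([path], inputs):
            logger.info("fst: outputs up to date, skipped")
        else:
            pf = structure.population_frequencies(cohort(), meta)
            mat = structure.fst_matrix(pf)
            with open(path, "w") as fh:
                fh.write(_provenance(cfg, "fst"))
                mat.to_csv(fh, sep="\t")
        produced["fst"] = [path]

    if "pca" in cfg.stages:
        path = out / "pca_scores.tsv"
        if _fresh([path], inputs):
            logger.info("pca: outputs up to date, skipped")
        else:
            res = structure.pca(cohort())
            df = pd.DataFrame(
                res.scores[:, :10],
                columns=[f"PC{k + 1}" for k in range(min(10, res.scores.shape[1]))],
            )
            df.insert(0, "sample", res.sample_ids)
            anchors = params.get("hybrid_anchors")
            if anchors:
                est = structure.pc1_hybrid_index(res, anchors[0], anchors[1])
                df["hybrid_index"] = est.hybrid_index.values
            _write_tsv(df, path, _provenance(cfg, "pca"))
        produced["pca"] = [path]

    if "roh" in cfg.stages:
        seg_path = out / "roh_segments.tsv"
        sum_path = out / "diversity_summary.tsv"
        if _fresh([seg_path, sum_path], inputs):
            logger.info("roh: outputs up to date, skipped")
        else:
            g = cohort()
            g2 = sitefilter.maf_missingness_filter(
                g, params.get("min_maf", 0.05), params.get("max_missing", 0.05)
            )
            roh_params = diversity.RohParams(
                window_het=params.get("window_het", 3),
                window_missing=params.get("window_missing", 20),
            )
            roh = diversity.roh_call(g2, roh_params)
            span = params.get("autosomal_span_bp")
            if span is None:
                span = int(
                    g.sites.groupby("chrom")["pos"].max().sum()
                )
            summary = diversity.diversity_summary(g, roh, span)
            _write_tsv(roh.to_plink_hom(), seg_path, _provenance(cfg, "roh"))
            _write_tsv(summary, sum_path, _provenance(cfg, "roh"))
        produced["roh"] = [seg_path, sum_path]

    if "kinship" in cfg.stages:
        path = out / "kinship_pairs.tsv"
        if _fresh([path], inputs):
            logger.info("kinship: outputs up to date, skipped")
        else:
            results = kinship.pairwise_kinship(cohort())
            _write_tsv(kinship.kinship_table(results), path,
                       _provenance(cfg, "kinship"))
        produced["kinship"] = [path]

    if "load" in cfg.stages:
        tsv_path = out / "load_per_sample.tsv"
        json_path = out / "load_comparison.json"
        if _fresh([tsv_path, json_path], inputs):
            logger.info("load: outputs up to date, skipped")
        else:
            g = cohort()
            table = load.count_load(g)
            lut = meta.set_index("sample")
            table.insert(1, "population", table["sample"].map(lut["population"]))
            table.insert(2, "species", table["sample"].map(lut["species"]))
            _write_tsv(table, tsv_path, _provenance(cfg, "load"))
            report: dict[str, Any] = {"seed": cfg.seed, "version": __version__}
            species = table["species"].dropna().unique()
            if len(species) == 2:
                for metric in ("het_load_high", "het_load_moderate"):
                    a = table.loc[table["species"] == species[0], metric]
                    b = table.loc[table["species"] == species[1], metric]
                    try:
                        r = load.compare_groups(a, b)
                        report[metric] = {
                            "groups": [str(species[0]), str(species[1])],
                            "test": r.test_name, "statistic": r.statistic,
                            "p_value": r.p_value, "effect_size": r.effect_size,
                            "ci95": list(r.ci95), "df": r.df,
                        }
                    except ValueError as exc:
                        report[metric] = {"error": str(exc)}
            with open(json_path, "w") as fh:
                json.dump(report, fh, indent=1)
        produced["load"] = [tsv_path, json_path]

    return produced
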