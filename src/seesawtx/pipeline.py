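"""End-to-end pipeline: seesaw calling, overlap nulls, genome landscape,
operons and QC from a single structured config, with seed bookkeeping and a
consolidated report.

Stage order mirrors the analysis: seesaw calls -> overlap enrichment ->
chromosomal landscape (bias, windows, clusters, operons) -> QC. Mandatory
stages (the two DE tables) abort on failure; optional stages (attribute
clustering, operons, counts QC) are skipped with a warning when their inputs
are absent. The master seed touches only the simulation-based stages, so
significant seesaw sets are identical across seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression_qc, genome_landscape, io_tables, overlap_null, seesaw_core

logger = logging.getLogger(__name__)

_STAGE_ORDER = ("overlap_up", "overlap_down", "cluster_null")


class ConfigError(ValueError):
    """Invalid pipeline configuration (missing path / bad parameter)."""


@dataclass
class PipelineConfig:
    de_phe: str
    de_stv: str
    out_dir: str
    annotation: str | None = None
    attribute: str | None = None
    operons: str | None = None
    counts: str | None = None
    fpkm: str | None = None
    germline_reference: str | None = None
    alpha: float = 0.05
    min_fold: float = 2.0
    window: int = 2_500_000
    step: int = 500_000
    min_genes: int = 10
    min_size: int = 3
    max_gap: int = 2
    sims: int = 10_000
    ratio_threshold: float = 0.5
    pseudocount: float = 0.1
    seed: int = 0
    chrom_lengths: dict | None = None  # chromosome name -> bp; inferred if absent

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("de_phe", "de_stv"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise ConfigError(f"required input {name!r} missing: {p}")
        for name in ("annotation", "attribute", "operons", "counts", "fpkm",
                     "germline_reference"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured path {name!r} does not exist: {p}")
        if not 0 <= self.alpha <= 1:
            raise ConfigError("alpha must lie in [0, 1]")
        if self.min_fold <= 1:
            raise ConfigError("min_fold must exceed 1")
        if self.window <= 0 or self.step <= 0:
            raise ConfigError("window and step must be positive")
        if self.sims < 1:
            raise ConfigError("sims must be >= 1")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds derived from the master seed."""
    rng = np.random.default_rng(master_seed)
    return {name: int(rng.integers(2**31)) for name in _STAGE_ORDER}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage and write the consolidated report."""
    config.validate()
    seeds = stage_seeds(config.seed)
    tables: dict[str, pd.DataFrame] = {}
    report: dict = {"parameters": {k: v for k, v in asdict(config).items()
                                   if not isinstance(v, dict)},
                    "stage_seeds": seeds}

    de_phe = io_tables.read_de_table(config.de_phe, condition="Phe")
    de_stv = io_tables.read_de_table(config.de_stv, condition="Stv")

    # --- seesaw calling (mandatory) ------------------------------------
    quad = seesaw_core.quadrant_labels(de_phe, de_stv)
    calls = seesaw_core.call_significant_seesaw(de_phe, de_stv, alpha=config.alpha)
    trend = seesaw_core.trend_seesaw(de_phe, de_stv, min_fold=config.min_fold)
    tally = quad.value_counts().reindex(seesaw_core.QUADRANTS, fill_value=0)
    n_universe = len(quad)
    q13 = int(tally["Q1"] + tally["Q3"])
    report["seesaw"] = {
        "alpha": config.alpha,
        "n_universe": n_universe,
        "up_down": len(calls.up_down),
        "down_up": len(calls.down_up),
        "seesaw_total": len(calls.seesaw),
        "shared_up": len(calls.shared_up),
        "shared_down": len(calls.shared_down),
        "quadrant_tally": tally.to_dict(),
        "inverse_quadrant_percent": seesaw_core.percentage_report(q13, n_universe, 1),
        "trend_up_down": len(trend.up_down),
        "trend_down_up": len(trend.down_up),
    }
    tables["quadrants"] = quad.rename_axis("gene_id").reset_index()
    tables["seesaw_calls"] = pd.DataFrame(
        [{"gene_id": g, "direction": d}
         for d, s in (("up_down", calls.up_down), ("down_up", calls.down_up))
         for g in sorted(s)])

    # --- overlap nulls --------------------------------------------------
    m = de_phe.merge(de_stv, on="gene_id", suffixes=("_phe", "_stv"))
    universe = set(m["gene_id"])
    phe_up = set(m.loc[(m["fdr_phe"] < config.alpha) & (m["log2fc_phe"] > 0), "gene_id"])
    phe_down = set(m.loc[(m["fdr_phe"] < config.alpha) & (m["log2fc_phe"] < 0), "gene_id"])
    stv_up = set(m.loc[(m["fdr_stv"] < config.alpha) & (m["log2fc_stv"] > 0), "gene_id"])
    stv_down = set(m.loc[(m["fdr_stv"] < config.alpha) & (m["log2fc_stv"] < 0), "gene_id"])
    report["overlap"] = {}
    for name, a, b, seed_name in (("phe_up_stv_down", phe_up, stv_down, "overlap_up"),
                                  ("phe_down_stv_up", phe_down, stv_up, "overlap_down")):
        if not a or not b:
            logger.warning("overlap %s skipped: an input set is empty", name)
            report["overlap"][name] = None
            continue
        enr = overlap_null.overlap_enrichment(a, b, universe, S=config.sims,
                                              seed=seeds[seed_name])
        report["overlap"][name] = {
            "n1": enr.n1, "n2": enr.n2, "N": enr.N, "k_obs": enr.k_obs,
            "null_mean": enr.null_mean, "null_sd": enr.null_sd,
            "fold": enr.fold, "p": enr.p_str, "S": enr.S,
        }

    # --- genome landscape (needs annotation) ----------------------------
    annotation = None
    if config.annotation:
        annotation = io_tables.read_annotation(config.annotation)
        chrom_lengths = config.chrom_lengths or (
            annotation.groupby("chrom", sort=False)["end"].max().to_dict())
        for cls_name, genes in (("trend_up_down", trend.up_down),
                                ("trend_down_up", trend.down_up)):
            genes = genes & set(annotation["gene_id"])
            if not genes:
                continue
            bias = genome_landscape.chrom_bias_chi2(genes, annotation)
            tables[f"chrom_bias_{cls_name}"] = bias
            track = genome_landscape.sliding_window_enrichment(
                genes, annotation, chrom_lengths,
                window=config.window, step=config.step, min_genes=config.min_genes)
            tables[f"windows_{cls_name}"] = track
        if config.attribute:
            attr_ids = io_tables.read_gene_list(config.attribute)
            missing = attr_ids - set(annotation["gene_id"])
            if missing:
                logger.warning("%d attribute id(s) absent from annotation", len(missing))
            flags = annotation["gene_id"].isin(attr_ids).to_numpy()
            cs = genome_landscape.cluster_null(
                flags, annotation, min_size=config.min_size, max_gap=config.max_gap,
                S=config.sims, seed=seeds["cluster_null"])
            sizes = [c.size for c in cs.clusters]
            band = sum(1 for s in sizes if 3 <= s <= 10)
            report["clusters"] = {
                "min_size": cs.min_size, "max_gap": cs.max_gap,
                "n_clusters": cs.n_clusters,
                "n_clustered_genes": cs.n_clustered_genes,
                "n_attribute": cs.n_attribute,
                "percent_attribute_clustered": seesaw_core.percentage_report(
                    cs.n_clustered_genes, cs.n_attribute, 0) if cs.n_attribute else None,
                "size_range": [min(sizes), max(sizes)] if sizes else None,
                "percent_size_3_to_10": seesaw_core.percentage_report(band, len(sizes), 0)
                if sizes else None,
                "fold_n_clusters": cs.fold_n_clusters,
                "fold_n_clustered": cs.fold_n_clustered,
                "p_n_clusters": cs.p_n_clusters,
                "p_n_clustered": cs.p_n_clustered,
                "S": cs.S,
            }
            tables["clusters"] = pd.DataFrame(
                [{"chrom": c.chrom, "start": c.start, "end": c.end,
                  "size": c.size, "span": c.span,
                  "gene_ids": ",".join(c.gene_ids)} for c in cs.clusters])
            bias = genome_landscape.chrom_bias_chi2(
                attr_ids & set(annotation["gene_id"]), annotation)
            tables["chrom_bias_attribute"] = bias
    elif config.attribute:
        logger.warning("attribute list given without annotation; cluster stage skipped")

    # --- operons ---------------------------------------------------------
    if config.operons:
        operons = io_tables.read_operon_table(config.operons)
        count, pct = genome_landscape.operon_membership(calls.seesaw, operons) \
            if calls.seesaw else (0, None)
        op_table, op_tally, skipped = genome_landscape.operon_quadrant_classify(
            operons, de_phe, de_stv)
        report["operons"] = {
            "n_operons": len(operons),
            "seesaw_genes_in_operons": count,
            "percent_seesaw_in_operons": pct,
            "quadrant_tally": op_tally,
            "n_skipped": len(skipped),
        }
        tables["operon_quadrants"] = op_table
    else:
        logger.warning("no operon table configured; operon stage skipped")

    # --- QC ---------------------------------------------------------------
    if config.counts:
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        pearson = {}
        cols = list(counts.columns)
        strains = sorted({c.rsplit("_", 1)[0] for c in cols})
        for strain in strains:
            reps = [c for c in cols if c.rsplit("_", 1)[0] == strain]
            for c1, c2 in zip(reps[:-1], reps[1:]):
                r, p = expression_qc.replicate_pearson(counts[c1], counts[c2])
                pearson[f"{c1}~{c2}"] = {"r": r, "p": p}
        pca = expression_qc.pc_significance(counts.to_numpy())
        report["qc"] = {
            "replicate_pearson": pearson,
            "pca_eigenvalues": pca.eigenvalues.tolist(),
            "pca_variance_shares": pca.variance_shares.tolist(),
            "broken_stick_shares": pca.broken_stick_shares.tolist(),
            "kaiser_significant": pca.kaiser_significant.tolist(),
            "broken_stick_significant": pca.broken_stick_significant.tolist(),
            "n_genes_dropped": pca.n_genes_dropped,
        }
    else:
        logger.warning("no count matrix configured; QC stage skipped")

    if config.fpkm:
        fpkm = pd.read_csv(config.fpkm, sep="\t", index_col=0)
        ref = (io_tables.read_gene_list(config.germline_reference)
               if config.germline_reference else None)
        germ = expression_qc.germline_enrichment_classify(
            fpkm["wildtype"], fpkm["ablated"], gene_ids=fpkm.index,
            ratio_threshold=config.ratio_threshold, pseudocount=config.pseudocount,
            reference_list=ref)
        report["germline"] = {
            "median_ratio": germ.median_ratio,
            "n_enriched": germ.n_enriched,
            "fraction_enriched": germ.fraction_enriched,
            "fisher_p": germ.fisher_p,
        }
        tables["germline_calls"] = germ.calls

    summary_path = io_tables.write_results(tables, report, config.out_dir)
    _write_text_report(report, Path(config.out_dir) / "report.txt")
    logger.info("report written to %s", summary_path)
    return report


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["seesawtx pipeline report", "=" * 24, ""]
    for section, content in report.items():
        lines.append(f"[{section}]")
        if isinstance(content, dict):
            for k, v in content.items():
                if isinstance(v, dict):
                    lines.append(f"  {k}:")
                    for kk, vv in v.items():
                        lines.append(f"    {kk}: {_fmt(vv)}")
                else:
                    lines.append(f"  {k}: {_fmt(v)}")
        else:
            lines.append(f"  {content}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def make_report(report: dict, out_dir) -> Path:
    """Re-serialize an in-memory report bundle (JSON + text)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "summary.json"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(io_tables._jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_text_report(report, out_dir / "report.txt")
    return path
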