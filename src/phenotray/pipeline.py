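"""End-to-end orchestration: images -> areas -> growth -> scan -> candidates.

Each stage logs its inputs, parameters and row counts; failures stop the
run with the stage name attached.  Every output table carries a header
comment with the tool version and a hash of the configuration, and a
machine-readable JSON report summarizes the run.
"""

from __future__ import annotations

import json
import logging
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .association import call_candidates, emmax_scan, kinship_matrix, lr_scan, maf_filter
from .config import RunConfig
from .fileio import read_annotations, read_genotypes
from .imaging import PipelineError, TrayPipelineConfig, process_tray
from .stats import ecotype_growth_rate, log_transform

__all__ = ["run_pipeline"]

logger = logging.getLogger("phenotray")


def _write_table(df: pd.DataFrame, path, cfg_hash: str, sep: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(f"# phenotray {__version__} config_hash={cfg_hash}\n")
        df.to_csv(fh, sep=sep, index=False, lineterminator="\n")


def _tray_config(cfg: RunConfig) -> TrayPipelineConfig:
    return TrayPipelineConfig(
        tray_filter=cfg.tray_filter,
        plant_filter=cfg.plant_filter,
        rows=cfg.rows,
        cols=cfg.cols,
        cell_px=cfg.cell_px,
        min_blob_px=cfg.min_blob_px,
        calibration=cfg.calibration,
        manual_crop=cfg.manual_crop,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return the JSON-serializable report.

    Stages: per-image tray measurement; join to the accession map; growth
    rates per accession over the configured time course; optional
    association scan on the log-transformed growth phenotype; candidate
    calling against the gene annotations.  Outputs land in
    ``config.output_dir``.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    cfg_hash = config.config_hash()
    report = {
        "tool": "phenotray",
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "stages": {},
    }

    # stage: imaging
    if not config.images:
        raise PipelineError("images", "config lists no images")
    tray_cfg = _tray_config(config)
    tables = []
    logs = []
    for entry in config.images:
        image_id = entry.get("image_id") or os.path.basename(entry["path"])
        img = iio.imread(entry["path"])
        tab, log = process_tray(img, tray_cfg, image_id=image_id)
        tab["timepoint"] = entry.get("timepoint", 0)
        tab["treatment"] = entry.get("treatment", "cold")
        tables.append(tab)
        logs.append(log)
        logger.info("measured %s: %d cells", image_id, len(tab))
    cells = pd.concat(tables, ignore_index=True)
    cells_path = os.path.join(config.output_dir, "cells.csv")
    _write_table(cells, cells_path, cfg_hash)
    report["stages"]["imaging"] = {
        "n_images": len(tables),
        "n_cells": int(len(cells)),
        "logs": logs,
        "out": cells_path,
    }

    # stage: join to accession map
    if not config.genotype_map:
        report["stages"]["growth"] = {"skipped": "no genotype_map configured"}
        return _finish(report, config)
    gmap = pd.read_csv(config.genotype_map, sep="\t", comment="#")
    for col in ("image_id", "row", "col", "accession"):
        if col not in gmap.columns:
            raise PipelineError("map", f"genotype map lacks column {col!r}")
    joined = cells.merge(gmap, on=["image_id", "row", "col"], how="inner")
    if joined.empty:
        raise PipelineError("map", "no cells matched the genotype map")

    # stage: growth rates over the time course
    sub = joined
    if config.growth_treatment is not None and "treatment_y" in sub.columns:
        sub = sub[sub["treatment_y"] == config.growth_treatment]
    mean_areas = (
        sub.groupby(["accession", "timepoint"])["area_px"].mean().unstack("timepoint")
    )
    t0, t1 = config.growth_initial, config.growth_final
    for tp in (t0, t1):
        if tp not in mean_areas.columns:
            raise PipelineError("growth", f"no measurements at timepoint {tp}")
    rates = pd.DataFrame(
        {
            "accession": mean_areas.index,
            "area_initial": mean_areas[t0].to_numpy(),
            "area_final": mean_areas[t1].to_numpy(),
        }
    )
    rates["growth_rate"] = [
        ecotype_growth_rate(a0, a1)
        for a0, a1 in zip(rates["area_initial"], rates["area_final"])
    ]
    growth_path = os.path.join(config.output_dir, "growth.csv")
    _write_table(rates, growth_path, cfg_hash)
    report["stages"]["growth"] = {
        "n_accessions": int(len(rates)),
        "initial_timepoint": t0,
        "final_timepoint": t1,
        "out": growth_path,
    }

    # stage: association scan
    if not config.genotypes_path:
        report["stages"]["scan"] = {"skipped": "no genotypes configured"}
        return _finish(report, config)
    G = read_genotypes(config.genotypes_path, format=config.genotypes_format)
    common = [s for s in G.samples if s in set(rates["accession"])]
    if len(common) < 3:
        raise PipelineError("scan", "fewer than 3 accessions shared between genotypes and phenotypes")
    keep = [G.samples.index(s) for s in common]
    G = _subset_samples(G, keep)
    y_map = dict(zip(rates["accession"], rates["growth_rate"]))
    y = log_transform([y_map[s] for s in common], offset=config.log_offset)
    G = maf_filter(G, config.scan_maf)
    if config.scan_model == "emmax":
        K = kinship_matrix(G)
        result = emmax_scan(G, y, K)
    elif config.scan_model == "lr":
        result = lr_scan(G, y)
    else:
        raise PipelineError("scan", f"unknown scan model {config.scan_model!r}")
    assoc_path = os.path.join(config.output_dir, "association.tsv")
    _write_table(result.to_frame(), assoc_path, cfg_hash, sep="\t")
    report["stages"]["scan"] = {
        "model": result.model,
        "n_accessions": len(common),
        "n_snps": int(G.n_snps),
        "maf": config.scan_maf,
        "lambda_gc": None if np.isnan(result.lambda_gc) else float(result.lambda_gc),
        "out": assoc_path,
    }

    # stage: candidate-gene calling
    if not config.annotations_path:
        report["stages"]["candidates"] = {"skipped": "no annotations configured"}
        return _finish(report, config)
    genes = read_annotations(config.annotations_path, format=config.annotations_format)
    cand = call_candidates(
        result,
        genes,
        threshold_nlp=config.scan_threshold_nlp,
        promoter_bp=config.scan_promoter_bp,
    )
    cand_path = os.path.join(config.output_dir, "candidates.tsv")
    _write_table(cand, cand_path, cfg_hash, sep="\t")
    report["stages"]["candidates"] = {
        "n_genes_annotated": len(genes),
        "n_candidates": int(len(cand)),
        "threshold_nlp": config.scan_threshold_nlp,
        "promoter_bp": config.scan_promoter_bp,
        "out": cand_path,
        "gene_ids": cand["gene_id"].tolist(),
    }
    return _finish(report, config)


def _subset_samples(G, idx):
    from .association import GenotypeMatrix

    return GenotypeMatrix(
        samples=[G.samples[i] for i in idx],
        chrom=G.chrom,
        pos=G.pos,
        ref=G.ref,
        alt=G.alt,
        dosage=G.dosage[idx, :],
    )


def _finish(report: dict, config: RunConfig) -> dict:
    path = os.path.join(config.output_dir, "report.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    report["report_path"] = path
    return report
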