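"""Run configuration: YAML schema for the end-to-end pipeline.

Every threshold of the workflow is surfaced here; nothing numerical is
hard-coded in the pipeline itself.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .imaging import ColorFilterParams

__all__ = ["RunConfig", "ConfigError", "filter_from_dict"]


class ConfigError(ValueError):
    pass


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ConfigError(f"missing config key: {where}.{key}" if where else f"missing config key: {key}")
    return d[key]


def filter_from_dict(d: dict, where: str) -> ColorFilterParams:
    return ColorFilterParams(
        space=_require(d, "space", where),
        lower=tuple(_require(d, "lower", where)),
        upper=tuple(_require(d, "upper", where)),
        opening_radius=d.get("opening_radius"),
    )


@dataclass
class RunConfig:
    """Parsed pipeline configuration."""

    output_dir: str
    seed: int
    rows: int
    cols: int
    cell_px: int | None
    tray_filter: ColorFilterParams
    plant_filter: ColorFilterParams
    min_blob_px: int = 10
    calibration: float | None = None
    manual_crop: tuple | None = None
    images: list = field(default_factory=list)  # {path, image_id, timepoint, treatment}
    genotype_map: str | None = None
    genotypes_path: str | None = None
    genotypes_format: str = "vcf"
    annotations_path: str | None = None
    annotations_format: str = "bed"
    growth_initial: float = 0
    growth_final: float = 30
    growth_treatment: str | None = None
    log_offset: float = 0.0
    scan_model: str = "emmax"
    scan_maf: float = 0.05
    scan_threshold_nlp: float = 4.5
    scan_promoter_bp: int = 2000
    alpha: float = 0.05
    m_comparisons: int | None = None
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        grid = _require(d, "grid", "")
        filters = _require(d, "filters", "")
        growth = d.get("growth", {})
        scan = d.get("scan", {})
        tests = d.get("tests", {})
        genotypes = d.get("genotypes") or {}
        annotations = d.get("annotations") or {}
        return cls(
            output_dir=_require(d, "output_dir", ""),
            seed=int(d.get("seed", 0)),
            rows=int(_require(grid, "rows", "grid")),
            cols=int(_require(grid, "cols", "grid")),
            cell_px=grid.get("cell_px"),
            tray_filter=filter_from_dict(_require(filters, "tray", "filters"), "filters.tray"),
            plant_filter=filter_from_dict(_require(filters, "plant", "filters"), "filters.plant"),
            min_blob_px=int(d.get("min_blob_px", 10)),
            calibration=d.get("calibration"),
            manual_crop=tuple(d["manual_crop"]) if d.get("manual_crop") else None,
            images=list(d.get("images", [])),
            genotype_map=d.get("genotype_map"),
            genotypes_path=genotypes.get("path"),
            genotypes_format=genotypes.get("format", "vcf"),
            annotations_path=annotations.get("path"),
            annotations_format=annotations.get("format", "bed"),
            growth_initial=growth.get("initial_timepoint", 0),
            growth_final=growth.get("final_timepoint", 30),
            growth_treatment=growth.get("treatment"),
            log_offset=float(growth.get("log_offset", 0.0)),
            scan_model=scan.get("model", "emmax"),
            scan_maf=float(scan.get("maf", 0.05)),
            scan_threshold_nlp=float(scan.get("threshold_nlp", 4.5)),
            scan_promoter_bp=int(scan.get("promoter_bp", 2000)),
            alpha=float(tests.get("alpha", 0.05)),
            m_comparisons=tests.get("m"),
            raw=d,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(d)

    def config_hash(self) -> str:
        """Short stable digest of the raw configuration."""
        blob = json.dumps(self.raw or asdict_safe(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def asdict_safe(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d.pop("raw", None)
    return d
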