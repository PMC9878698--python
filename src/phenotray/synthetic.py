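"""Synthetic study generators: tray images with exact ground truth, phenotype
panels with known variance components, and genotype/phenotype pairs with
planted causal variants.

Every downstream stage of the package (imaging, heritability, association
scans) is validated against data produced here, because the originating
platform's raw photographs and resequencing data are not redistributable.
The tray renderer therefore keeps an *exact* per-cell pixel-count manifest:
rosettes are painted as unions of disks at a known color, and the manifest
records, per cell, the number of painted pixels in the unwarped frame.

All randomness flows from an explicit integer seed; no global random state
is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import ProjectiveTransform, warp

__all__ = [
    "TraySpec",
    "RosetteGroundTruth",
    "PanelSimSpec",
    "GenoSimSpec",
    "render_tray",
    "random_rosettes",
    "simulate_phenotype_panel",
    "simulate_genotypes",
    "write_manifest",
    "reference_tray_filter",
    "reference_plant_filter",
]

# Default palette: well separated tray (dark soil/plastic), background (bench),
# cell ridges (light plastic) and plant (green).  Filter thresholds derived by
# reference_*_filter() sit at channel midpoints between the plant and tray
# colors so that blended edge pixels (bilinear interpolation under warp) are
# classified by nearest color, keeping area estimates unbiased.
TRAY_COLOR = (42, 40, 38)
BACKGROUND_COLOR = (204, 202, 200)
LINE_COLOR = (168, 168, 168)
PLANT_COLOR = (50, 180, 60)


@dataclass(frozen=True)
class TraySpec:
    """Geometry and palette of one half-tray frame (12 x 12 wells)."""

    rows: int = 12
    cols: int = 12
    cell_px: int = 40
    margin_px: int = 30
    tray_color: tuple = TRAY_COLOR
    background_color: tuple = BACKGROUND_COLOR
    line_color: tuple = LINE_COLOR
    warp: np.ndarray | None = None  # (4, 2) displaced corners, (x, y), TL TR BR BL
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.rows < 2 or self.cols < 2:
            raise ValueError("tray must have at least 2 rows and 2 cols")
        if self.cell_px < 8:
            raise ValueError("cell_px must be >= 8")
        if self.warp is not None:
            corners = np.asarray(self.warp, dtype=float)
            if corners.shape != (4, 2):
                raise ValueError("warp must be 4 corner points (x, y)")
            if not _is_convex_quad(corners):
                raise ValueError("warp corner quadrilateral is not convex")
            object.__setattr__(self, "warp", corners)

    @property
    def image_shape(self) -> tuple:
        h = self.rows * self.cell_px + 2 * self.margin_px + 1
        w = self.cols * self.cell_px + 2 * self.margin_px + 1
        return (h, w)

    def ideal_corners(self) -> np.ndarray:
        """(rows+1, cols+1, 2) array of grid-line intersections, (x, y)."""
        xs = self.margin_px + self.cell_px * np.arange(self.cols + 1)
        ys = self.margin_px + self.cell_px * np.arange(self.rows + 1)
        return np.stack(np.meshgrid(xs, ys), axis=-1).astype(float)


@dataclass
class RosetteGroundTruth:
    """One cell's rosette: a union of disks plus its exact rasterized area."""

    cell_row: int
    cell_col: int
    pixel_count: int = 0
    color: tuple = PLANT_COLOR
    # disks in cell-local coordinates: list of (cx, cy, radius), x right y down
    shape_params: list = field(default_factory=list)


@dataclass(frozen=True)
class PanelSimSpec:
    """Accession x replicate panel with additive genetic and residual variance."""

    n_accessions: int
    n_replicates: int
    var_genetic: float
    var_residual: float
    mean: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.var_genetic < 0 or self.var_residual < 0:
            raise ValueError("variances must be non-negative")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates for heritability estimation")


@dataclass(frozen=True)
class GenoSimSpec:
    """Biallelic genotype panel with optional causal SNPs and population structure."""

    n_accessions: int
    n_snps: int
    maf_range: tuple = (0.05, 0.5)
    causal_snps: tuple = ()  # ((snp_index, effect_size), ...)
    structure_groups: int | None = None
    group_shift: float = 0.0
    fst: float = 0.1
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        for idx, _ in self.causal_snps:
            if not (0 <= idx < self.n_snps):
                raise ValueError(f"causal SNP index {idx} out of range")
        if self.structure_groups is not None and self.structure_groups < 2:
            raise ValueError("structure_groups must be >= 2 when given")


def _is_convex_quad(corners: np.ndarray) -> bool:
    """True when the 4 points in order form a convex, consistently wound quad."""
    cross = []
    for i in range(4):
        a, b, c = corners[i], corners[(i + 1) % 4], corners[(i + 2) % 4]
        v1, v2 = b - a, c - b
        cross.append(v1[0] * v2[1] - v1[1] * v2[0])
    cross = np.asarray(cross)
    return bool(np.all(cross > 0) or np.all(cross < 0))


def _rasterize_disks(disks, cell_px: int) -> np.ndarray:
    """Boolean mask (cell interior, cell_px-1 square) of a union of disks.

    Pixel (x, y) covered when its center lies inside some disk.
    """
    n = cell_px - 1  # interior pixels; boundary ridge lines excluded
    yy, xx = np.mgrid[0:n, 0:n]
    mask = np.zeros((n, n), dtype=bool)
    for cx, cy, r in disks:
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return mask


def render_tray(spec: TraySpec, rosettes: list) -> tuple:
    """Render one tray image and its exact ground-truth manifest.

    Returns ``(image, manifest)`` where ``image`` is an (H, W, 3) uint8 raster
    and ``manifest`` a DataFrame with one row per cell (``row``, ``col``,
    ``pixel_count``, ``color``).  ``pixel_count`` is the exact number of
    plant-colored pixels painted in that cell in the *unwarped* frame.  When
    ``spec.warp`` is set the returned image is the projective re-render and
    the manifest's ``attrs`` carry the warp corners.
    """
    h, w = spec.image_shape
    m, cp = spec.margin_px, spec.cell_px
    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.background_color
    y1 = m + spec.rows * cp
    x1 = m + spec.cols * cp
    img[m : y1 + 1, m : x1 + 1] = spec.tray_color
    for i in range(spec.rows + 1):
        img[m + i * cp, m : x1 + 1] = spec.line_color
    for j in range(spec.cols + 1):
        img[m : y1 + 1, m + j * cp] = spec.line_color

    counts = np.zeros((spec.rows, spec.cols), dtype=int)
    colors = np.empty((spec.rows, spec.cols), dtype=object)
    for r in range(spec.rows):
        for c in range(spec.cols):
            colors[r, c] = None
    seen = set()
    for ros in rosettes:
        r, c = ros.cell_row, ros.cell_col
        if not (0 <= r < spec.rows and 0 <= c < spec.cols):
            raise ValueError(f"rosette cell ({r}, {c}) outside grid")
        if (r, c) in seen:
            raise ValueError(f"multiple rosettes assigned to cell ({r}, {c})")
        seen.add((r, c))
        for cx, cy, rad in ros.shape_params:
            if cx - rad < -0.5 or cy - rad < -0.5 or cx + rad > cp - 1.5 or cy + rad > cp - 1.5:
                raise ValueError(
                    f"disk in cell ({r}, {c}) bleeds across the cell boundary"
                )
        mask = _rasterize_disks(ros.shape_params, cp)
        n_px = int(mask.sum())
        ros.pixel_count = n_px
        counts[r, c] = n_px
        colors[r, c] = tuple(ros.color)
        top, left = m + r * cp + 1, m + c * cp + 1
        region = img[top : top + cp - 1, left : left + cp - 1]
        region[mask] = ros.color

    if spec.warp is not None:
        src = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
        tform = ProjectiveTransform.from_estimate(src, spec.warp)
        if not tform:
            raise ValueError("degenerate warp quadrilateral")
        img = warp(
            img,
            inverse_map=ProjectiveTransform(matrix=np.linalg.inv(tform.params)),
            output_shape=(h, w),
            order=1,
            mode="constant",
            cval=0.0,
            preserve_range=True,
        )
        # fill the out-of-quad area with background so crop detection behaves
        filled = warp(
            np.ones((h, w)),
            inverse_map=ProjectiveTransform(matrix=np.linalg.inv(tform.params)),
            output_shape=(h, w),
            order=0,
            mode="constant",
            cval=0.0,
        )
        img[filled < 0.5] = spec.background_color

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    rows_idx, cols_idx = np.meshgrid(
        np.arange(spec.rows), np.arange(spec.cols), indexing="ij"
    )
    manifest = pd.DataFrame(
        {
            "row": rows_idx.ravel(),
            "col": cols_idx.ravel(),
            "pixel_count": counts.ravel(),
            "color": colors.ravel(),
        }
    )
    manifest.attrs["warp"] = None if spec.warp is None else spec.warp.tolist()
    manifest.attrs["seed"] = spec.rng_seed
    manifest.attrs["cell_px"] = cp
    return img, manifest


def random_rosettes(
    spec: TraySpec,
    rng: np.random.Generator,
    n_cells: int | None = None,
    area_range: tuple = (50, 4000),
    color: tuple = PLANT_COLOR,
) -> list:
    """Draw rosettes for ``n_cells`` distinct cells (default: every cell).

    Each rosette is a union of 3-9 overlapping disks mimicking leaf lobes,
    scaled so rasterized areas span ``area_range`` (log-uniform targets).
    Disks are kept strictly inside the cell interior.
    """
    cp = spec.cell_px
    cells = [(r, c) for r in range(spec.rows) for c in range(spec.cols)]
    if n_cells is not None:
        idx = rng.choice(len(cells), size=n_cells, replace=False)
        cells = [cells[i] for i in sorted(idx)]
    lo, hi = area_range
    max_half = (cp - 2) / 2.0 - 1.0  # max offset+radius from cell center
    rosettes = []
    for r, c in cells:
        target = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        rosettes.append(
            rosette_for_area(target, cp, rng, cell_row=r, cell_col=c, color=color)
        )
    # guard: targets near (cp/2)^2*pi may exceed the cell; rosette_for_area caps
    del max_half
    return rosettes


def rosette_for_area(
    target_px: float,
    cell_px: int,
    rng: np.random.Generator,
    cell_row: int = 0,
    cell_col: int = 0,
    color: tuple = PLANT_COLOR,
) -> RosetteGroundTruth:
    """A multi-disk rosette whose union area roughly matches ``target_px``."""
    center = (cell_px - 2) / 2.0
    max_r = center - 1.5
    r0 = min(np.sqrt(target_px / np.pi), max_r)
    n_disks = int(rng.integers(3, 10))
    disks = [(center, center, r0 * 0.9)]
    for _ in range(n_disks - 1):
        ang = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0.1, 0.45) * r0
        rad = rng.uniform(0.4, 0.75) * r0
        cx = center + off * np.cos(ang)
        cy = center + off * np.sin(ang)
        rad = min(rad, max_r - off)  # stay inside the cell
        if rad > 0.8:
            disks.append((cx, cy, rad))
    ros = RosetteGroundTruth(cell_row, cell_col, color=tuple(color), shape_params=disks)
    ros.pixel_count = int(_rasterize_disks(disks, cell_px).sum())
    return ros


def corner_warp(spec: TraySpec, rng: np.random.Generator, max_frac: float = 0.05) -> np.ndarray:
    """Random projective warp: displace image corners by <= max_frac of size."""
    h, w = spec.image_shape
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    for _ in range(100):
        d = rng.uniform(-max_frac, max_frac, size=(4, 2)) * np.array([w, h])
        # pull displacements inward so the warped tray stays inside the frame
        inward = np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]], dtype=float)
        cand = corners + np.abs(d) * inward
        if _is_convex_quad(cand):
            return cand
    raise RuntimeError("failed to draw a convex warp quadrilateral")


def write_manifest(path, manifest: pd.DataFrame) -> None:
    """Serialize a ground-truth manifest to JSON."""
    payload = {
        "cells": [
            {
                "row": int(r.row),
                "col": int(r.col),
                "pixel_count": int(r.pixel_count),
                "color": list(r.color) if r.color is not None else None,
            }
            for r in manifest.itertuples()
        ],
        "warp": manifest.attrs.get("warp"),
        "seed": manifest.attrs.get("seed"),
        "cell_px": manifest.attrs.get("cell_px"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def reference_tray_filter(spec: TraySpec | None = None):
    """RGB box filter selecting the tray (well soil) color of a spec's palette.

    Each competing color (ridge lines, background, plant green) is excluded
    through the channel where it differs most from the tray color, with the
    bound placed at the midpoint between the two.  Midpoint bounds make the
    classification of blended boundary pixels (bilinear interpolation under
    warp, additive noise) unbiased while keeping wide margins on the other
    channels.
    """
    from .imaging import ColorFilterParams

    spec = spec or TraySpec()
    tray = np.asarray(spec.tray_color, dtype=float)
    lower = np.zeros(3)
    upper = np.full(3, 255.0)
    for comp in (spec.line_color, spec.background_color, PLANT_COLOR):
        comp = np.asarray(comp, dtype=float)
        ch = int(np.argmax(np.abs(comp - tray)))
        mid = (comp[ch] + tray[ch]) / 2.0
        if comp[ch] > tray[ch]:
            upper[ch] = min(upper[ch], mid)
        else:
            lower[ch] = max(lower[ch], mid)
    return ColorFilterParams(space="rgb", lower=tuple(lower), upper=tuple(upper))


def reference_plant_filter(spec: TraySpec | None = None, color=PLANT_COLOR):
    """HSV filter selecting healthy-rosette green for a spec's palette.

    The value (brightness) threshold sits at the midpoint between the plant
    and tray colors, which localizes the mask boundary at the 50% blend and
    keeps warped-image area estimates unbiased; the saturation floor rejects
    gray ridge and background pixels and their blends.
    """
    from .imaging import ColorFilterParams

    spec = spec or TraySpec()
    v_mid = (max(color) + max(spec.tray_color)) / 2.0 / 255.0
    return ColorFilterParams(
        space="hsv",
        lower=(0.20, 0.40, v_mid),
        upper=(0.45, 1.0, 1.0),
    )


def simulate_phenotype_panel(spec: PanelSimSpec) -> pd.DataFrame:
    """Long-format accession x replicate panel.

    value(a, r) = mean + g_a + e_ar with g_a ~ N(0, var_genetic) and
    e_ar ~ N(0, var_residual).  Broad-sense heritability of the generating
    model is var_genetic / (var_genetic + var_residual).
    """
    rng = np.random.default_rng(spec.rng_seed)
    g = rng.normal(0.0, np.sqrt(spec.var_genetic), size=spec.n_accessions)
    e = rng.normal(
        0.0, np.sqrt(spec.var_residual), size=(spec.n_accessions, spec.n_replicates)
    )
    values = spec.mean + g[:, None] + e
    acc = np.repeat(np.arange(spec.n_accessions), spec.n_replicates)
    rep = np.tile(np.arange(spec.n_replicates), spec.n_accessions)
    return pd.DataFrame(
        {
            "accession": [f"acc{i:04d}" for i in acc],
            "replicate": rep,
            "value": values.ravel(),
        }
    )


def simulate_genotypes(spec: GenoSimSpec):
    """Simulate a dosage matrix, phenotype vector and truth record.

    Genotypes are Binomial(2, p_snp) draws (Hardy-Weinberg); with
    ``structure_groups`` set, per-group allele frequencies are drawn from a
    Balding-Nichols model at the given Fst and accessions inherit a
    group-level phenotype shift, creating the confounding that a
    kinship-corrected scan is meant to absorb.

    Returns ``(G, y, truth)`` where ``G`` is an association.GenotypeMatrix,
    ``y`` the phenotype vector, and ``truth`` a dict with causal indices,
    effects and group labels.
    """
    from .association import GenotypeMatrix

    rng = np.random.default_rng(spec.rng_seed)
    lo, hi = spec.maf_range
    p = rng.uniform(lo, hi, size=spec.n_snps)

    groups = None
    if spec.structure_groups:
        k = spec.structure_groups
        groups = rng.integers(0, k, size=spec.n_accessions)
        a = p * (1 - spec.fst) / spec.fst
        b = (1 - p) * (1 - spec.fst) / spec.fst
        p_groups = rng.beta(a, b, size=(k, spec.n_snps))
        dosage = rng.binomial(2, p_groups[groups, :]).astype(float)
    else:
        dosage = rng.binomial(2, p[None, :].repeat(spec.n_accessions, 0)).astype(float)

    y = rng.normal(0.0, spec.noise_sd, size=spec.n_accessions)
    for idx, eff in spec.causal_snps:
        y = y + eff * dosage[:, idx]
    if groups is not None and spec.group_shift:
        y = y + spec.group_shift * groups

    pos = 1 + 1000 * np.arange(spec.n_snps)
    G = GenotypeMatrix(
        samples=[f"acc{i:04d}" for i in range(spec.n_accessions)],
        chrom=np.array(["1"] * spec.n_snps),
        pos=pos.astype(int),
        ref=np.array(["A"] * spec.n_snps),
        alt=np.array(["T"] * spec.n_snps),
        dosage=dosage,
    )
    truth = {
        "causal": [int(i) for i, _ in spec.causal_snps],
        "effects": {int(i): float(e) for i, e in spec.causal_snps},
        "groups": None if groups is None else groups.tolist(),
        "allele_freq": p.tolist(),
    }
    return G, y, truth
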