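"""Six-step tray-image workflow: crop, grid-line detection, intersection
geometry, perspective rectification, cell segmentation and rosette
measurement.

The workflow mirrors a fixed-camera phenotyping rig photographing half
plug-trays of 12 x 12 wells: the tray surface is isolated with a color
filter, cell ridge boundaries are found as linear features with a Hough
transform, the tray plane is recovered from the line intersections, the
*original unfiltered* image is registered to an orthographic view, and each
cell sub-image is measured with a second color filter tuned to healthy
rosette leaves.  Rosette area is the pixel count over all retained
8-connected components, so a cell holding a group of seedlings is measured
as the aggregate.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.morphology import closing, dilation, disk, footprint_rectangle, opening
from skimage.transform import ProjectiveTransform, hough_line, hough_line_peaks, warp

__all__ = [
    "ColorFilterParams",
    "LineSet",
    "GridModel",
    "RosetteMeasurement",
    "CropResult",
    "TrayPipelineConfig",
    "PipelineError",
    "GridDetectionError",
    "filter_color",
    "crop_tray",
    "detect_grid_lines",
    "compute_grid",
    "rectify",
    "segment_cells",
    "measure_rosette",
    "process_tray",
]


class PipelineError(RuntimeError):
    """Stage failure carrying the name of the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class GridDetectionError(PipelineError):
    def __init__(self, message: str):
        super().__init__("grid_lines", message)


@dataclass(frozen=True)
class ColorFilterParams:
    """Per-channel box filter in RGB (0-255) or HSV (0-1) space."""

    space: str = "hsv"
    lower: tuple = (0.0, 0.0, 0.0)
    upper: tuple = (1.0, 1.0, 1.0)
    opening_radius: int | None = None

    def __post_init__(self):
        if self.space not in ("rgb", "hsv"):
            raise ValueError("space must be 'rgb' or 'hsv'")
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("lower/upper must be 3-channel")
        if np.any(lo > hi):
            raise ValueError("lower bound exceeds upper bound")


@dataclass
class LineSet:
    """Detected grid lines as (rho, theta) with theta in [0, pi).

    A point (x, y) lies on the line when x*cos(theta) + y*sin(theta) = rho.
    ``horizontal`` lines run left-right (normal near vertical), ``vertical``
    lines run top-bottom.  Both arrays are sorted by position across the
    image.
    """

    horizontal: np.ndarray  # (n_h, 2) of (rho, theta)
    vertical: np.ndarray  # (n_v, 2)


@dataclass
class GridModel:
    """Recovered cell-boundary geometry of one tray image."""

    corners: np.ndarray  # (rows+1, cols+1, 2) of (x, y) image coordinates
    homography: np.ndarray  # 3x3, image plane -> orthographic tray plane
    cell_px: int  # rectified cell side length
    rows: int
    cols: int

    def __post_init__(self):
        det = np.linalg.det(self.homography)
        if abs(det) < 1e-12:
            raise ValueError("homography is not invertible")


@dataclass
class RosetteMeasurement:
    """Per-cell rosette area and color summary - the pipeline's atomic output."""

    cell_row: int
    cell_col: int
    area_px: int
    n_components: int
    mean_color: tuple | None  # None when area_px == 0
    area_mm2: float | None = None


@dataclass
class CropResult:
    ok: bool
    image: np.ndarray | None = None
    bbox: np.ndarray | None = None  # (4, 2) quadrilateral, (x, y)
    offset: tuple = (0, 0)  # (x0, y0) of crop in the original frame
    region_mask: np.ndarray | None = None  # filled tray region in crop frame
    message: str = ""


def _as_rgb(image: np.ndarray) -> np.ndarray:
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected a 3-channel RGB image, got shape {image.shape}"
        )
    return image


def filter_color(image: np.ndarray, params: ColorFilterParams) -> np.ndarray:
    """Binary mask of pixels whose channels all fall within the filter bounds.

    RGB bounds are on raw 0-255 values; HSV bounds on scikit-image's 0-1
    scale.  An optional morphological opening removes speckle.
    """
    image = _as_rgb(image)
    if params.space == "hsv":
        chans = rgb2hsv(image)
    else:
        chans = np.asarray(image, dtype=float)
    lo = np.asarray(params.lower, float)
    hi = np.asarray(params.upper, float)
    mask = np.all((chans >= lo) & (chans <= hi), axis=-1)
    if params.opening_radius:
        mask = opening(mask, disk(params.opening_radius))
    return mask


def crop_tray(
    image: np.ndarray,
    tray_filter: ColorFilterParams,
    min_area_frac: float = 0.2,
    close_radius: int = 3,
    pad: int = 1,
) -> CropResult:
    """Locate the tray as the largest tray-colored region and crop to it.

    Cell faces are disconnected by ridge lines, so the tray mask is closed
    morphologically before the largest connected component is taken.  The
    bounding box is padded by ``pad`` pixels so the outermost ridge lines
    survive the crop.  When no region covering ``min_area_frac`` of the
    frame is found the result carries ``ok=False``, signalling that a
    manual crop is required; the tray is never silently passed through.
    """
    image = _as_rgb(image)
    mask = filter_color(image, tray_filter)
    closed = closing(mask, disk(close_radius))
    labels, n = ndimage.label(closed)
    if n == 0:
        return CropResult(ok=False, message="no tray-colored region found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area_frac * mask.size:
        return CropResult(
            ok=False,
            message=(
                f"largest tray-colored region covers "
                f"{sizes[best - 1] / mask.size:.1%} of the frame "
                f"(< {min_area_frac:.0%}); manual crop required"
            ),
        )
    comp = labels == best
    rows = np.any(comp, axis=1)
    cols = np.any(comp, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    r0 = max(r0 - pad, 0)
    c0 = max(c0 - pad, 0)
    r1 = min(r1 + pad, image.shape[0] - 1)
    c1 = min(c1 + pad, image.shape[1] - 1)
    region = ndimage.binary_fill_holes(comp[r0 : r1 + 1, c0 : c1 + 1])
    region = dilation(region, footprint_rectangle((2 * pad + 1, 2 * pad + 1)))
    quad = np.array([[c0, r0], [c1, r0], [c1, r1], [c0, r1]], dtype=float)
    return CropResult(
        ok=True,
        image=image[r0 : r1 + 1, c0 : c1 + 1],
        bbox=quad,
        offset=(int(c0), int(r0)),
        region_mask=region,
    )


def _normalize_line(rho: float, theta: float) -> tuple:
    """Map (rho, theta) to the theta in [0, pi) convention."""
    theta = float(theta)
    rho = float(rho)
    while theta < 0:
        theta += np.pi
        rho = -rho
    while theta >= np.pi:
        theta -= np.pi
        rho = -rho
    return rho, theta


def _line_position(rho: float, theta: float, orientation: str) -> float:
    """Signed coordinate of the line along its sweep axis, for sorting."""
    if orientation == "vertical":
        s = np.cos(theta)
    else:
        s = np.sin(theta)
    return rho / s if abs(s) > 1e-9 else np.inf


def _refine_line(mask: np.ndarray, rho: float, theta: float, band: float = 2.0):
    """Total-least-squares refit of a line to mask pixels within ``band`` px."""
    ys, xs = np.nonzero(mask)
    d = xs * np.cos(theta) + ys * np.sin(theta) - rho
    sel = np.abs(d) <= band
    if sel.sum() < 10:
        return rho, theta
    x, y = xs[sel].astype(float), ys[sel].astype(float)
    cx, cy = x.mean(), y.mean()
    cov = np.cov(np.stack([x - cx, y - cy]))
    evals, evecs = np.linalg.eigh(cov)
    normal = evecs[:, 0]  # eigenvector of the smaller eigenvalue
    theta_new = np.arctan2(normal[1], normal[0])
    rho_new = cx * normal[0] + cy * normal[1]
    return _normalize_line(rho_new, theta_new)


def detect_grid_lines(
    mask: np.ndarray,
    expected_per_axis: int | tuple,
    theta_window_deg: float = 20.0,
    theta_step_deg: float = 0.25,
    min_vote_frac: float = 0.25,
    refine: bool = True,
) -> LineSet:
    """Detect the cell-boundary lines of the tray grid by Hough voting.

    ``mask`` is a binary image in which the ridge boundaries are the
    dominant linear features (e.g. the complement of the tray-color mask
    within the tray region).  ``expected_per_axis`` is rows+1 horizontal and
    cols+1 vertical lines, as an int (square grids) or an
    ``(n_horizontal, n_vertical)`` tuple.  The top-voted accumulator peaks
    per orientation class are returned after non-maximum suppression with a
    radius of half the expected line spacing; finding fewer than expected is
    an error naming the axis.  Each Hough line is optionally refined by a
    total-least-squares fit to nearby mask pixels, which removes the
    accumulator's quantization error.
    """
    if mask.ndim != 2:
        raise ValueError("mask must be a 2D binary image")
    if not np.any(mask):
        raise GridDetectionError("empty mask: no line features to detect")
    if np.isscalar(expected_per_axis):
        n_h = n_v = int(expected_per_axis)
    else:
        n_h, n_v = map(int, expected_per_axis)

    h_img, w_img = mask.shape
    step = np.deg2rad(theta_step_deg)
    win = np.deg2rad(theta_window_deg)
    # vertical lines: normal near theta = 0; horizontal: normal near +-pi/2
    theta_v = np.arange(-win, win + step / 2, step)
    theta_h = np.concatenate(
        [
            np.arange(-np.pi / 2, -np.pi / 2 + win + step / 2, step),
            np.arange(np.pi / 2 - win, np.pi / 2, step),
        ]
    )

    out = {}
    for orientation, thetas, n_expect, extent in (
        ("vertical", theta_v, n_v, w_img),
        ("horizontal", theta_h, n_h, h_img),
    ):
        acc, angles, dists = hough_line(mask, theta=thetas)
        min_dist = max(1, int(round(extent / max(n_expect, 2) / 2)))
        peaks = hough_line_peaks(
            acc,
            angles,
            dists,
            min_distance=min_dist,
            min_angle=max(1, int(round(len(thetas) / 6))),
            threshold=min_vote_frac * acc.max(),
            num_peaks=n_expect,
        )
        lines = []
        for _votes, ang, dist in zip(*peaks):
            rho, theta = _normalize_line(dist, ang)
            if refine:
                rho, theta = _refine_line(mask, rho, theta)
            lines.append((rho, theta))
        if len(lines) < n_expect:
            raise GridDetectionError(
                f"found {len(lines)} {orientation} lines, expected {n_expect}"
            )
        lines.sort(key=lambda rt: _line_position(rt[0], rt[1], orientation))
        out[orientation] = np.asarray(lines, dtype=float)

    return LineSet(horizontal=out["horizontal"], vertical=out["vertical"])


def _intersect(l1, l2):
    rho1, th1 = l1
    rho2, th2 = l2
    a = np.array([[np.cos(th1), np.sin(th1)], [np.cos(th2), np.sin(th2)]])
    det = np.linalg.det(a)
    if abs(det) < 1e-12:
        return None
    return np.linalg.solve(a, np.array([rho1, rho2]))


def compute_grid(
    lines: LineSet,
    image_shape: tuple,
    cell_px: int | None = None,
) -> GridModel:
    """Corner mesh and homography from the detected boundary lines.

    ``corners[i, j]`` is the intersection of the i-th horizontal with the
    j-th vertical line.  The homography maps the four outer corners onto an
    axis-aligned square grid of side ``cell_px`` per cell (least-squares
    projective fit); interior corners serve only as diagnostics.
    """
    n_h, n_v = len(lines.horizontal), len(lines.vertical)
    if n_h < 2 or n_v < 2:
        raise ValueError("need at least 2 lines per orientation")
    h_img, w_img = image_shape[:2]

    for cls_lines, name in ((lines.horizontal, "horizontal"), (lines.vertical, "vertical")):
        for i in range(len(cls_lines)):
            for j in range(i + 1, len(cls_lines)):
                pt = _intersect(cls_lines[i], cls_lines[j])
                if pt is None:
                    if abs(cls_lines[i][0] - cls_lines[j][0]) < 1e-6 and (
                        abs(cls_lines[i][1] - cls_lines[j][1]) < 1e-9
                    ):
                        raise ValueError(f"coincident {name} lines")
                    continue
                if 0 <= pt[0] < w_img and 0 <= pt[1] < h_img:
                    raise ValueError(
                        f"degenerate grid: {name} lines intersect inside the image"
                    )

    corners = np.empty((n_h, n_v, 2), dtype=float)
    for i, hl in enumerate(lines.horizontal):
        for j, vl in enumerate(lines.vertical):
            pt = _intersect(hl, vl)
            if pt is None:
                raise ValueError("horizontal and vertical line are parallel")
            corners[i, j] = pt

    if np.any(np.diff(corners[..., 0], axis=1) <= 0) or np.any(
        np.diff(corners[..., 1], axis=0) <= 0
    ):
        raise ValueError("corner mesh is not monotone; grid detection failed")

    rows, cols = n_h - 1, n_v - 1
    if cell_px is None:
        w_mean = (
            np.linalg.norm(corners[0, -1] - corners[0, 0])
            + np.linalg.norm(corners[-1, -1] - corners[-1, 0])
        ) / (2 * cols)
        h_mean = (
            np.linalg.norm(corners[-1, 0] - corners[0, 0])
            + np.linalg.norm(corners[-1, -1] - corners[0, -1])
        ) / (2 * rows)
        cell_px = int(round((w_mean + h_mean) / 2))

    src = np.array(
        [corners[0, 0], corners[0, -1], corners[-1, -1], corners[-1, 0]], dtype=float
    )
    dst = np.array(
        [
            [0, 0],
            [cols * cell_px, 0],
            [cols * cell_px, rows * cell_px],
            [0, rows * cell_px],
        ],
        dtype=float,
    )
    tform = ProjectiveTransform.from_estimate(src, dst)
    if not tform:
        raise ValueError("homography estimation failed")
    return GridModel(
        corners=corners,
        homography=tform.params,
        cell_px=int(cell_px),
        rows=rows,
        cols=cols,
    )


def grid_residuals(grid: GridModel) -> np.ndarray:
    """Distance of each interior corner from its ideal rectified position."""
    pts = grid.corners.reshape(-1, 2)
    mapped = ProjectiveTransform(matrix=grid.homography)(pts)
    xs = grid.cell_px * np.arange(grid.cols + 1)
    ys = grid.cell_px * np.arange(grid.rows + 1)
    ideal = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)
    return np.linalg.norm(mapped - ideal, axis=1).reshape(grid.rows + 1, grid.cols + 1)


def rectify(image: np.ndarray, grid: GridModel) -> np.ndarray:
    """Register the original unfiltered image to the orthographic tray plane.

    Inverse-mapped with bilinear interpolation; output is
    rows*cell_px x cols*cell_px.  Plant masks should be recomputed on the
    rectified image.
    """
    image = _as_rgb(image)
    h_inv = np.linalg.inv(grid.homography)
    out_shape = (grid.rows * grid.cell_px, grid.cols * grid.cell_px)
    out = warp(
        image,
        inverse_map=ProjectiveTransform(matrix=h_inv),
        output_shape=out_shape,
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(image.dtype)
    return out


def segment_cells(
    image: np.ndarray,
    rows: int,
    cols: int,
    cell_px: int,
    margin: int = 0,
) -> list:
    """Row-major list of cell sub-images cut from a rectified image.

    With ``margin`` 0 the sub-images exactly partition the grid area; a
    positive margin shaves the cell ridges off each side.
    """
    if margin < 0 or 2 * margin >= cell_px:
        raise ValueError("margin must satisfy 0 <= 2*margin < cell_px")
    cells = []
    for r in range(rows):
        for c in range(cols):
            y0, x0 = r * cell_px + margin, c * cell_px + margin
            cells.append(
                image[y0 : y0 + cell_px - 2 * margin, x0 : x0 + cell_px - 2 * margin]
            )
    return cells


def measure_rosette(
    cell_image: np.ndarray,
    plant_filter: ColorFilterParams,
    min_blob_px: int = 10,
    calibration: float | None = None,
    cell_row: int = 0,
    cell_col: int = 0,
) -> RosetteMeasurement:
    """Aggregate rosette area of one cell.

    The plant mask is split into 8-connected components; components smaller
    than ``min_blob_px`` are despeckled away and the remaining pixels are
    summed (a cell may hold a group of seedlings, so all retained components
    count).  ``calibration`` converts px to mm^2 when supplied.
    """
    mask = filter_color(cell_image, plant_filter)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    area = 0
    kept = 0
    keep_mask = np.zeros_like(mask)
    if n:
        sizes = np.bincount(labels.ravel())[1:]
        for comp_id, size in enumerate(sizes, start=1):
            if size >= min_blob_px:
                area += int(size)
                kept += 1
                keep_mask |= labels == comp_id
    mean_color = None
    if area > 0:
        px = np.asarray(cell_image, dtype=float)[keep_mask]
        mean_color = tuple(px.mean(axis=0))
    return RosetteMeasurement(
        cell_row=cell_row,
        cell_col=cell_col,
        area_px=area,
        n_components=kept,
        mean_color=mean_color,
        area_mm2=None if calibration is None else area * calibration,
    )


@dataclass
class TrayPipelineConfig:
    """Everything the end-to-end tray workflow needs."""

    tray_filter: ColorFilterParams
    plant_filter: ColorFilterParams
    rows: int = 12
    cols: int = 12
    cell_px: int | None = None  # rectified cell side; None = infer from grid
    min_blob_px: int = 10
    calibration: float | None = None  # mm^2 per pixel
    cell_margin: int = 0
    manual_crop: tuple | None = None  # (x0, y0, x1, y1) in image coordinates
    crop_min_frac: float = 0.2
    close_radius: int = 3
    refine_lines: bool = True


def process_tray(image: np.ndarray, config: TrayPipelineConfig, image_id: str = "tray"):
    """Run crop -> filter -> lines -> grid -> rectify -> segment -> measure.

    Returns ``(table, log)``: one row per cell (grid indices, areas, mean
    color, component count) and a per-stage diagnostics dict.  Stage errors
    are re-raised as :class:`PipelineError` with the stage name; if the
    automatic crop fails and ``config.manual_crop`` is provided, the manual
    coordinates are honored instead.
    """
    log = {"image_id": image_id, "stages": {}}
    image = _as_rgb(image)

    crop = crop_tray(
        image,
        config.tray_filter,
        min_area_frac=config.crop_min_frac,
        close_radius=config.close_radius,
    )
    if not crop.ok:
        if config.manual_crop is not None:
            x0, y0, x1, y1 = map(int, config.manual_crop)
            crop = CropResult(
                ok=True,
                image=image[y0 : y1 + 1, x0 : x1 + 1],
                bbox=np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float),
                offset=(x0, y0),
                region_mask=None,
            )
            log["stages"]["crop"] = {"mode": "manual", "bbox": crop.bbox.tolist()}
        else:
            raise PipelineError("crop", crop.message)
    else:
        log["stages"]["crop"] = {"mode": "auto", "bbox": crop.bbox.tolist()}

    sub = crop.image
    tray_mask = filter_color(sub, config.tray_filter)
    plant_mask = filter_color(sub, config.plant_filter)
    line_mask = ~tray_mask & ~plant_mask
    if crop.region_mask is not None:
        line_mask &= crop.region_mask
    log["stages"]["filters"] = {
        "tray_px": int(tray_mask.sum()),
        "plant_px": int(plant_mask.sum()),
        "line_px": int(line_mask.sum()),
    }

    lines = detect_grid_lines(
        line_mask,
        (config.rows + 1, config.cols + 1),
        refine=config.refine_lines,
    )
    log["stages"]["grid_lines"] = {
        "n_horizontal": len(lines.horizontal),
        "n_vertical": len(lines.vertical),
    }

    try:
        grid = compute_grid(lines, sub.shape, cell_px=config.cell_px)
    except ValueError as exc:
        raise PipelineError("grid", str(exc)) from exc
    res = grid_residuals(grid)
    log["stages"]["grid"] = {
        "cell_px": grid.cell_px,
        "corner_residual_mean": float(res.mean()),
        "corner_residual_max": float(res.max()),
    }

    try:
        registered = rectify(sub, grid)
    except ValueError as exc:
        raise PipelineError("rectify", str(exc)) from exc

    cells = segment_cells(
        registered, grid.rows, grid.cols, grid.cell_px, margin=config.cell_margin
    )
    records = []
    for idx, cell in enumerate(cells):
        r, c = divmod(idx, grid.cols)
        m = measure_rosette(
            cell,
            config.plant_filter,
            min_blob_px=config.min_blob_px,
            calibration=config.calibration,
            cell_row=r,
            cell_col=c,
        )
        mc = m.mean_color or (np.nan, np.nan, np.nan)
        records.append(
            {
                "image_id": image_id,
                "row": r,
                "col": c,
                "area_px": m.area_px,
                "area_mm2": np.nan if m.area_mm2 is None else m.area_mm2,
                "mean_r": mc[0],
                "mean_g": mc[1],
                "mean_b": mc[2],
                "n_components": m.n_components,
            }
        )
    table = pd.DataFrame.from_records(records)
    log["stages"]["measure"] = {
        "n_cells": len(records),
        "total_area_px": int(table["area_px"].sum()),
    }
    return table, log
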