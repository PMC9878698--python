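"""Image workflow: color filtering, grid recovery, rectification, measurement."""

import numpy as np
import pytest
from skimage.transform import ProjectiveTransform

from phenotray import synthetic as syn
from phenotray.imaging import (
    ColorFilterParams,
    GridDetectionError,
    LineSet,
    PipelineError,
    compute_grid,
    crop_tray,
    detect_grid_lines,
    filter_color,
    measure_rosette,
    process_tray,
    rectify,
    segment_cells,
)

from conftest import tray_pipeline_config


def uniform_image(color, shape=(24, 24)):
    img = np.empty(shape + (3,), dtype=np.uint8)
    img[:] = color
    return img


def line_color_mask(image, spec):
    """Ridge-line mask: everything that is neither tray, plant nor background."""
    tray = filter_color(image, syn.reference_tray_filter(spec))
    plant = filter_color(image, syn.reference_plant_filter(spec))
    bg_cut = (np.asarray(spec.line_color, float) + np.asarray(spec.background_color)) / 2
    bg = np.all(image.astype(float) >= bg_cut, axis=-1)
    return ~(tray | plant | bg)


class TestFilterColor:
    def test_uniform_plant_passes_plant_filter(self):
        spec = syn.TraySpec()
        mask = filter_color(uniform_image(syn.PLANT_COLOR), syn.reference_plant_filter(spec))
        assert mask.all()

    def test_uniform_tray_fails_plant_filter(self):
        spec = syn.TraySpec()
        mask = filter_color(uniform_image(spec.tray_color), syn.reference_plant_filter(spec))
        assert not mask.any()

    def test_grayscale_rejected(self):
        with pytest.raises(ValueError, match="3-channel"):
            filter_color(np.zeros((10, 10), dtype=np.uint8), ColorFilterParams())

    def test_disk_mask_count_matches_manifest(self):
        spec = syn.TraySpec()
        ros = syn.RosetteGroundTruth(2, 3, shape_params=[(19.0, 19.0, 8.0)])
        img, manifest = syn.render_tray(spec, [ros])
        mask = filter_color(img, syn.reference_plant_filter(spec))
        assert int(mask.sum()) == manifest.set_index(["row", "col"])["pixel_count"][(2, 3)]

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="lower bound"):
            ColorFilterParams(space="rgb", lower=(10, 0, 0), upper=(5, 255, 255))


class TestCropTray:
    def test_full_frame_tray(self):
        spec = syn.TraySpec()
        img = uniform_image(spec.tray_color, shape=(100, 120))
        res = crop_tray(img, syn.reference_tray_filter(spec))
        assert res.ok
        assert res.image.shape == img.shape

    def test_inset_tray_bounds(self, small_tray):
        spec, _, image, _ = small_tray
        res = crop_tray(image, syn.reference_tray_filter(spec))
        assert res.ok
        # generator places the tray at margin_px from each edge
        assert abs(res.offset[0] - spec.margin_px) <= 2
        assert abs(res.offset[1] - spec.margin_px) <= 2
        w = res.image.shape[1]
        assert abs(w - (spec.cols * spec.cell_px + 1)) <= 4

    def test_blank_background_fails_with_flag(self):
        spec = syn.TraySpec()
        img = uniform_image(spec.background_color, shape=(120, 120))
        res = crop_tray(img, syn.reference_tray_filter(spec))
        assert not res.ok
        assert res.message


class TestDetectGridLines:
    def test_axis_aligned_lines_recovered(self, small_tray):
        spec, _, image, _ = small_tray
        mask = line_color_mask(image, spec)
        lines = detect_grid_lines(mask, (spec.rows + 1, spec.cols + 1))
        assert len(lines.horizontal) == 13 and len(lines.vertical) == 13
        truth = spec.margin_px + spec.cell_px * np.arange(13)
        for (rho, theta), x in zip(lines.vertical, truth):
            pos = rho / np.cos(theta) if theta < np.pi / 2 else -rho / np.cos(np.pi - theta)
            assert abs(pos - x) <= 1.0
            assert min(theta, np.pi - theta) <= np.deg2rad(0.5)
        for (rho, theta), y in zip(lines.horizontal, truth):
            assert abs(rho / np.sin(theta) - y) <= 1.0
            assert abs(theta - np.pi / 2) <= np.deg2rad(0.5)

    def test_rotated_tray_thetas(self):
        rng = np.random.default_rng(0)
        base = syn.TraySpec(cell_px=40)
        h, w = base.image_shape
        ang = np.deg2rad(5.0)
        c, s = np.cos(ang), np.sin(ang)
        center = np.array([w / 2, h / 2])
        rot = np.array([[c, -s], [s, c]])
        corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
        warped_corners = (corners - center) @ rot.T * 0.9 + center
        spec = syn.TraySpec(cell_px=40, warp=warped_corners)
        ros = syn.random_rosettes(spec, rng, n_cells=20, area_range=(50, 400))
        img, _ = syn.render_tray(spec, ros)
        mask = line_color_mask(img, spec)
        lines = detect_grid_lines(mask, 13)
        v_theta = np.array([min(t, np.pi - t) for _, t in lines.vertical])
        h_theta = np.array([abs(t - np.pi / 2) for _, t in lines.horizontal])
        assert np.all(np.abs(np.rad2deg(v_theta) - 5.0) <= 0.5)
        assert np.all(np.abs(np.rad2deg(h_theta) - 5.0) <= 0.5)

    def test_empty_mask_is_error(self):
        with pytest.raises(GridDetectionError, match="empty mask"):
            detect_grid_lines(np.zeros((50, 50), dtype=bool), 13)

    def test_missing_lines_error_names_axis(self):
        mask = np.zeros((200, 200), dtype=bool)
        for x in (20, 60, 100):
            mask[:, x] = True
        mask[100, :] = True
        with pytest.raises(GridDetectionError, match="horizontal"):
            detect_grid_lines(mask, (4, 3))


def ideal_lineset(positions_y, positions_x):
    h = np.array([[y, np.pi / 2] for y in positions_y], float)
    v = np.array([[x, 0.0] for x in positions_x], float)
    return LineSet(horizontal=h, vertical=v)


class TestComputeGrid:
    def test_axis_aligned_corners_exact(self):
        pos = 40.0 * np.arange(13)
        grid = compute_grid(ideal_lineset(pos, pos), (500, 500))
        xs, ys = np.meshgrid(pos, pos)
        assert np.allclose(grid.corners[..., 0], xs, atol=1e-9)
        assert np.allclose(grid.corners[..., 1], ys, atol=1e-9)
        H = grid.homography / grid.homography[2, 2]
        assert np.allclose(H, np.eye(3), atol=1e-9)

    def test_warped_corners_match_forward_model(self, warped_tray):
        spec, _, image, _ = warped_tray
        h, w = spec.image_shape
        src = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
        fwd = ProjectiveTransform.from_estimate(src, spec.warp)
        ideal = fwd(spec.ideal_corners().reshape(-1, 2)).reshape(13, 13, 2)
        mask = line_color_mask(image, spec)
        lines = detect_grid_lines(mask, 13)
        grid = compute_grid(lines, image.shape)
        err = np.linalg.norm(grid.corners - ideal, axis=-1)
        assert err.max() <= 1.0

    def test_coincident_lines_error(self):
        pos = 40.0 * np.arange(13)
        v = np.array([[x, 0.0] for x in pos], float)
        v[1] = v[0]
        with pytest.raises(ValueError, match="coincident"):
            compute_grid(LineSet(horizontal=np.array([[y, np.pi / 2] for y in pos]), vertical=v), (500, 500))

    def test_in_image_class_intersection_error(self):
        v = np.array([[100.0, 0.0], [150.0, np.deg2rad(15.0)]])
        h = np.array([[100.0, np.pi / 2], [200.0, np.pi / 2]])
        with pytest.raises(ValueError, match="degenerate"):
            compute_grid(LineSet(horizontal=h, vertical=v), (400, 400))


class TestRectify:
    def test_identity_homography_is_lossless(self, small_tray):
        spec, _, image, _ = small_tray
        m = spec.margin_px
        sub = image[m : m + 480, m : m + 480]
        pos = 40.0 * np.arange(13)
        grid = compute_grid(ideal_lineset(pos, pos), sub.shape, cell_px=40)
        out = rectify(sub, grid)
        assert np.array_equal(out, sub)

    def test_warped_blob_centroids_recovered(self, warped_tray):
        spec, rosettes, image, _ = warped_tray
        mask = line_color_mask(image, spec)
        lines = detect_grid_lines(mask, 13)
        grid = compute_grid(lines, image.shape, cell_px=spec.cell_px)
        reg = rectify(image, grid)
        plant = filter_color(reg, syn.reference_plant_filter(spec))
        cp, m = spec.cell_px, spec.margin_px
        clean, _ = syn.render_tray(syn.TraySpec(cell_px=cp), rosettes)
        truth_mask = filter_color(clean, syn.reference_plant_filter(spec))
        ys, xs = np.nonzero(truth_mask)
        for ros in rosettes[:20]:
            r, c = ros.cell_row, ros.cell_col
            sel = (
                (ys >= m + r * cp) & (ys < m + (r + 1) * cp)
                & (xs >= m + c * cp) & (xs < m + (c + 1) * cp)
            )
            truth_cy, truth_cx = ys[sel].mean() - m, xs[sel].mean() - m
            cell = plant[r * cp : (r + 1) * cp, c * cp : (c + 1) * cp]
            cys, cxs = np.nonzero(cell)
            got_cy, got_cx = cys.mean() + r * cp, cxs.mean() + c * cp
            assert np.hypot(got_cy - truth_cy, got_cx - truth_cx) <= 1.5


class TestSegmentAndMeasure:
    def test_cell_count_and_partition(self, small_tray):
        spec, _, image, manifest = small_tray
        m = spec.margin_px
        sub = image[m : m + 480, m : m + 480]
        cells = segment_cells(sub, 12, 12, 40)
        assert len(cells) == 144
        assert sum(c.size for c in cells) == sub.size

    def test_cell_contains_its_manifest_blob(self, small_tray):
        spec, _, image, manifest = small_tray
        m = spec.margin_px
        sub = image[m : m + 480, m : m + 480]
        cells = segment_cells(sub, 12, 12, 40)
        lut = manifest.set_index(["row", "col"])["pixel_count"]
        plant = syn.reference_plant_filter(spec)
        cell = cells[3 * 12 + 7]
        assert int(filter_color(cell, plant).sum()) == lut[(3, 7)]

    def test_empty_cell_measures_zero(self):
        spec = syn.TraySpec()
        img = uniform_image(spec.tray_color, shape=(39, 39))
        m = measure_rosette(img, syn.reference_plant_filter(spec))
        assert m.area_px == 0 and m.n_components == 0 and m.mean_color is None

    def test_min_blob_despeckle_rule(self):
        spec = syn.TraySpec()
        img = uniform_image(spec.tray_color, shape=(40, 40))
        img[2:12, 2:12] = syn.PLANT_COLOR  # 100 px blob
        img[25:30, 25:28] = syn.PLANT_COLOR  # 15 px blob
        m = measure_rosette(img, syn.reference_plant_filter(spec), min_blob_px=20)
        assert m.area_px == 100 and m.n_components == 1

    def test_calibration_converts_area(self):
        spec = syn.TraySpec()
        img = uniform_image(spec.tray_color, shape=(40, 40))
        img[0:10, 0:10] = syn.PLANT_COLOR
        m = measure_rosette(img, syn.reference_plant_filter(spec), calibration=0.25)
        assert m.area_mm2 == pytest.approx(25.0)


class TestProcessTray:
    def test_unwarped_exact_equality(self, small_tray):
        spec, _, image, manifest = small_tray
        table, _ = process_tray(image, tray_pipeline_config(spec))
        truth = manifest.sort_values(["row", "col"])["pixel_count"].to_numpy()
        got = table.sort_values(["row", "col"])["area_px"].to_numpy()
        assert np.array_equal(got, truth)

    def test_warped_relative_error_and_correlation(self, warped_tray):
        from scipy.stats import pearsonr

        spec, _, image, manifest = warped_tray
        table, _ = process_tray(image, tray_pipeline_config(spec))
        truth = manifest.sort_values(["row", "col"])["pixel_count"].to_numpy().astype(float)
        got = table.sort_values(["row", "col"])["area_px"].to_numpy().astype(float)
        err = np.abs(got - truth)
        # 2% relative per cell, with a small absolute floor for tiny blobs
        # where bilinear interpolation bounds accuracy to a couple of pixels
        assert np.all((err <= 0.02 * truth) | (err <= 3))
        assert pearsonr(got, truth)[0] >= 0.99

    def test_monotone_in_blob_growth(self):
        spec = syn.TraySpec()
        disks = [(19.0, 19.0, 6.0)]
        ros = syn.RosetteGroundTruth(5, 5, shape_params=list(disks))
        img, _ = syn.render_tray(spec, [ros])
        t1, _ = process_tray(img, tray_pipeline_config(spec))
        grown = syn.RosetteGroundTruth(5, 5, shape_params=disks + [(22.0, 19.0, 5.0)])
        img2, _ = syn.render_tray(spec, [grown])
        t2, _ = process_tray(img2, tray_pipeline_config(spec))
        assert t2["area_px"].sum() >= t1["area_px"].sum()

    def test_crop_failure_raises_with_stage(self):
        spec = syn.TraySpec()
        img = uniform_image(spec.background_color, shape=(300, 300))
        with pytest.raises(PipelineError, match=r"\[crop\]"):
            process_tray(img, tray_pipeline_config(spec))

    def test_manual_crop_fallback(self, small_tray):
        spec, _, image, manifest = small_tray
        # break the auto-crop by demanding an impossible tray fraction
        m = spec.margin_px
        cfg = tray_pipeline_config(
            spec,
            crop_min_frac=0.999,
            manual_crop=(m, m, m + 480, m + 480),
        )
        table, log = process_tray(image, cfg)
        assert log["stages"]["crop"]["mode"] == "manual"
        truth = manifest.sort_values(["row", "col"])["pixel_count"].to_numpy()
        got = table.sort_values(["row", "col"])["area_px"].to_numpy()
        assert np.array_equal(got, truth)
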