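"""Mask morphometry: area, outline, landmarks, midline, thickness."""

import numpy as np
import pytest
from scipy import ndimage

from callothick.morphometry import (
    BinaryMask,
    Contour,
    LandmarkError,
    Landmarks,
    MaskError,
    Orientation,
    border_pixels,
    clean_mask,
    compute_area,
    compute_midline,
    detect_landmarks,
    extract_outline,
    measure_thickness,
    profile_pipeline,
    resample_contour,
    split_contour,
)
from callothick.simulate import PhantomParams, generate_mask, half_annulus_mask

FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)


class TestArea:
    def test_pixel_count_times_pixel_area(self):
        grid = np.zeros((6, 6), int)
        grid[2:4, 1:6] = 1  # 10 pixels
        area = compute_area(BinaryMask(grid, spacing=(0.7, 0.7)))
        assert area.voxel_count == 10
        assert area.pixel_area_mm2 == pytest.approx(0.49)
        assert area.area_mm2 == pytest.approx(4.9)
        # exactness invariant
        assert area.area_mm2 / area.pixel_area_mm2 == pytest.approx(10)

    def test_rasterized_disc_matches_analytic(self):
        h = 0.1
        n = 240
        c = n * h / 2
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        grid = (np.hypot((xx + 0.5) * h - c, (yy + 0.5) * h - c) <= 10.0).astype(int)
        area = compute_area(BinaryMask(grid, spacing=(h, h)))
        assert area.area_mm2 == pytest.approx(np.pi * 100, rel=0.01)

    def test_empty_mask_is_extraction_failure(self):
        with pytest.raises(MaskError, match="extraction failed"):
            compute_area(BinaryMask(np.zeros((4, 4), int)))


class TestCleanup:
    def test_keeps_largest_component_and_fills_holes(self):
        grid = np.zeros((12, 12), int)
        grid[1:8, 1:8] = 1
        grid[3:5, 3:5] = 0  # hole
        grid[10, 10] = 1  # stray component
        cleaned, report = clean_mask(BinaryMask(grid))
        assert report["components_removed"] == 1
        assert report["pixels_removed"] == 1
        assert report["holes_filled_pixels"] == 4
        assert cleaned.grid.sum() == 49


class TestOutline:
    def test_square_has_eight_border_pixels(self):
        grid = np.zeros((5, 5), int)
        grid[1:4, 1:4] = 1
        contour = extract_outline(BinaryMask(grid), boundary_offset=0.0)
        assert contour.closed
        assert len(contour) == 8

    def test_thin_strip_is_all_border(self):
        grid = np.zeros((6, 10), int)
        grid[2:4, 1:9] = 1
        assert border_pixels(grid).sum() == grid.sum()
        contour = extract_outline(BinaryMask(grid))
        assert set(map(tuple, contour.pixels)) == set(zip(*np.nonzero(grid)))

    def test_random_blob_matches_erosion_oracle(self):
        rng = np.random.default_rng(42)
        raw = ndimage.gaussian_filter(rng.standard_normal((60, 60)), 4) > 0.02
        mask, _ = clean_mask(BinaryMask(raw.astype(int)))
        contour = extract_outline(mask)
        eroded = ndimage.binary_erosion(mask.grid, structure=FOUR, border_value=0)
        oracle = set(zip(*np.nonzero(mask.grid & ~eroded)))
        assert set(map(tuple, contour.pixels)) == oracle

    def test_fragmented_mask_rejected(self):
        grid = np.zeros((8, 8), int)
        grid[1, 1] = grid[6, 6] = 1
        with pytest.raises(MaskError, match="components"):
            extract_outline(BinaryMask(grid))


class TestLandmarks:
    def test_phantom_landmarks_within_one_pixel(self, phantom_run):
        _, truth, result = phantom_run
        found = result.contour.points[
            [result.landmarks.rostrum_tip, result.landmarks.splenium_base]
        ]
        assert np.hypot(*(found[0] - truth.rostrum_tip)) <= 0.7
        assert np.hypot(*(found[1] - truth.splenium_base)) <= 0.7

    def test_mirrored_mask_gives_identical_canonical_result(self, phantom_run):
        mask, _, result = phantom_run
        flipped = BinaryMask(
            mask.grid[:, ::-1].copy(),
            spacing=mask.spacing,
            orientation=Orientation(anterior_low_col=False),
        )
        res2 = profile_pipeline(flipped)
        assert res2.area.area_mm2 == result.area.area_mm2
        np.testing.assert_array_equal(res2.profile.thickness, result.profile.thickness)

    def test_rotated_mask_with_updated_orientation(self, phantom_run):
        mask, _, result = phantom_run
        rotated = BinaryMask(
            np.ascontiguousarray(np.rot90(mask.grid, k=-1)),
            spacing=mask.spacing,
            orientation=Orientation(
                transpose=True, anterior_low_col=True, dorsal_low_row=False
            ),
        )
        res2 = profile_pipeline(rotated)
        assert res2.area.area_mm2 == result.area.area_mm2
        np.testing.assert_allclose(
            res2.profile.thickness, result.profile.thickness, atol=1e-9
        )

    def test_rectangle_has_no_inbend(self):
        grid = np.zeros((30, 60), int)
        grid[5:25, 5:55] = 1
        contour = extract_outline(BinaryMask(grid))
        with pytest.raises(LandmarkError):
            detect_landmarks(contour)

    def test_manual_override_maps_to_nearest_vertex(self, phantom_run):
        _, truth, result = phantom_run
        lm = detect_landmarks(
            result.contour, override=(truth.rostrum_tip, truth.splenium_base)
        )
        found = result.contour.points[lm.rostrum_tip]
        assert np.hypot(*(found - truth.rostrum_tip)) <= 0.7


class TestSplit:
    def test_partition_identity(self, phantom_run):
        _, _, result = phantom_run
        dorsal, ventral = split_contour(result.contour, result.landmarks)
        assert len(dorsal) + len(ventral) == len(result.contour) + 2

    def test_landmark_order_does_not_change_assignment(self, phantom_run):
        _, _, result = phantom_run
        lm = result.landmarks
        d1, v1 = split_contour(result.contour, lm)
        d2, v2 = split_contour(
            result.contour,
            Landmarks(rostrum_tip=lm.splenium_base, splenium_base=lm.rostrum_tip),
        )
        assert set(map(tuple, d1.points)) == set(map(tuple, d2.points))
        assert set(map(tuple, v1.points)) == set(map(tuple, v2.points))

    def test_arcs_share_only_landmarks(self, phantom_run):
        _, _, result = phantom_run
        dorsal, ventral = split_contour(result.contour, result.landmarks)
        shared = set(map(tuple, dorsal.points)) & set(map(tuple, ventral.points))
        assert len(shared) == 2


class TestResample:
    def test_straight_segment(self):
        pts = resample_contour(np.array([[0.0, 0.0], [10.0, 0.0]]), 5)
        np.testing.assert_allclose(pts[:, 0], [0, 2.5, 5, 7.5, 10])

    def test_equal_arclength_spacing(self):
        rng = np.random.default_rng(0)
        poly = np.cumsum(rng.random((50, 2)), axis=0)
        out = resample_contour(poly, 33)
        # arc position of every output point along the source polyline
        seg = np.hypot(*np.diff(poly, axis=0).T)
        cum = np.concatenate([[0], np.cumsum(seg)])
        pos = []
        for p in out:
            d = poly[:-1] - p
            e = np.diff(poly, axis=0)
            u = np.clip(np.einsum("ij,ij->i", -d, e) / np.einsum("ij,ij->i", e, e), 0, 1)
            proj = poly[:-1] + u[:, None] * e
            j = np.argmin(np.hypot(*(proj - p).T))
            pos.append(cum[j] + u[j] * seg[j])
        np.testing.assert_allclose(np.diff(pos), cum[-1] / 32, atol=1e-9)

    def test_semicircle_chords_and_length(self):
        theta = np.linspace(0, np.pi, 5000)
        arc = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta)])
        out = resample_contour(arc, 101)
        chords = np.hypot(*np.diff(out, axis=0).T)
        np.testing.assert_allclose(chords, chords[0], rtol=1e-6)
        assert chords.sum() == pytest.approx(np.pi * 10, rel=1e-3)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            resample_contour(np.array([[1.0, 1.0], [1.0, 1.0]]), 5)
        with pytest.raises(ValueError):
            resample_contour(np.array([[0.0, 0.0], [1.0, 0.0]]), 1)


class TestMidline:
    def test_parallel_lines(self):
        x = np.linspace(0, 10, 20)
        d = np.column_stack([x, np.zeros_like(x)])
        v = np.column_stack([x, np.full_like(x, 4.0)])
        mid = compute_midline(d, v)
        np.testing.assert_allclose(mid[:, 1], 2.0)

    def test_identical_sequences_degenerate(self):
        x = np.linspace(0, 10, 20)
        d = np.column_stack([x, x])
        mid = compute_midline(d, d.copy())
        np.testing.assert_allclose(mid, d)

    def test_concentric_arcs(self):
        theta = np.linspace(0.2, np.pi - 0.2, 100)
        inner = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta)])
        outer = np.column_stack([14 * np.cos(theta), 14 * np.sin(theta)])
        mid = compute_midline(outer, inner)
        np.testing.assert_allclose(np.hypot(*mid.T), 12.0, atol=0.05)

    def test_reversed_arc_detected(self):
        x = np.linspace(0, 10, 20)
        d = np.column_stack([x, np.zeros_like(x)])
        v = np.column_stack([x[::-1], np.full_like(x, 4.0)])
        with pytest.raises(ValueError, match="reverse"):
            compute_midline(d, v)


class TestThickness:
    def test_parallel_strip_is_exact(self):
        x = np.linspace(0, 50, 200)
        h = 3.7
        dorsal = np.column_stack([x, np.zeros_like(x)])
        ventral = np.column_stack([x, np.full_like(x, h)])
        mid = compute_midline(dorsal, ventral)
        thickness, _, _, fallback = measure_thickness(mid, dorsal, ventral)
        assert not fallback.any()
        np.testing.assert_allclose(thickness, h, atol=1e-9)

    def test_half_annulus_constant_thickness(self, half_annulus_run):
        _, truth, result = half_annulus_run
        prof = result.profile
        ok = ~(prof.fallback | prof.terminal)
        assert ok.sum() >= 70  # cap-degenerate segments are flagged, not many
        assert np.abs(prof.thickness[ok] - truth["thickness_mm"]).max() <= 0.7

    def test_varying_thickness_recovered(self):
        mask, truth = generate_mask(PhantomParams(spacing=(0.35, 0.35)))
        result = profile_pipeline(mask)
        prof = result.profile
        expected = truth.thickness_at_points(prof.midline)
        ok = ~(prof.fallback | prof.terminal)
        err = np.abs(prof.thickness - expected)
        # 5% of the local truth, floored at one pixel of discretization
        assert np.all(err[ok] <= np.maximum(0.05 * expected[ok], 0.35))

    def test_resolution_convergence(self):
        errs = []
        for h in (1.4, 0.7, 0.35):
            mask, truth = generate_mask(PhantomParams(thickness=6.0, spacing=(h, h)))
            result = profile_pipeline(mask)
            prof = result.profile
            ok = ~(prof.fallback | prof.terminal)
            errs.append(np.abs(prof.thickness[ok] - 6.0).max())
        assert errs[0] > errs[1] > errs[2]


class TestPipeline:
    def test_deterministic(self, phantom_run):
        mask, _, result = phantom_run
        again = profile_pipeline(mask)
        np.testing.assert_array_equal(
            again.profile.thickness, result.profile.thickness
        )
        assert again.area.area_mm2 == result.area.area_mm2

    def test_profile_has_100_points_and_metadata(self, phantom_run):
        _, _, result = phantom_run
        prof = result.profile
        assert prof.n_points == 100
        np.testing.assert_allclose(
            prof.midline, 0.5 * (prof.dorsal_pts + prof.ventral_pts)
        )
        assert np.all(np.isfinite(prof.thickness)) and np.all(prof.thickness >= 0)
        assert result.provenance["fallback_segments"] == list(
            np.nonzero(prof.fallback)[0]
        )

    def test_stage_errors_carry_diagnostics(self):
        grid = np.zeros((30, 60), int)
        grid[5:25, 5:55] = 1
        with pytest.raises(LandmarkError):
            profile_pipeline(BinaryMask(grid))
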