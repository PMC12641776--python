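"""Filtering cascade, grid summarization, profiles, heatmaps, matching."""

import numpy as np
import pandas as pd
import pytest

from retimosaic import (
    EyeMeta,
    ImageRecord,
    MaskSet,
    density_heatmap,
    eccentricity_profile,
    exclude_overmasked,
    grid_summaries,
    match_rpe_pr_rectangles,
    pr_central_exclusion,
    voronoi_morphometry,
)


def masks_with_fraction(n, masked_fraction):
    ones = np.ones((n, n), dtype=bool)
    mosaic = ones.copy().ravel()
    k = int(round(masked_fraction * n * n))
    mosaic[:k] = False
    return MaskSet(ones, np.zeros_like(ones), mosaic.reshape(n, n))


class TestImageExclusion:
    @pytest.mark.parametrize(
        "fraction,excluded", [(0.91, True), (0.90, False), (0.0, False)]
    )
    def test_strict_ninety_percent_rule(self, fraction, excluded):
        masks = masks_with_fraction(100, fraction)
        assert masks.masked_fraction == pytest.approx(fraction)
        assert exclude_overmasked(masks) is excluded


def small_image(eye, n=512, center=(0.0, 0.0), modality="RPE"):
    return ImageRecord(
        eye=eye,
        modality=modality,
        pixels=np.zeros((n, n), dtype=np.uint16),
        center_deg=center,
        image_id="img0",
    )


def cells_at(positions, boundary=False):
    pos = np.asarray(positions, dtype=float)
    return pd.DataFrame(
        {
            "row_px": pos[:, 0],
            "col_px": pos[:, 1],
            "area_um2": 100.0,
            "perimeter_um": 40.0,
            "n_neighbors": 6,
            "boundary_flag": boundary,
        }
    )


class TestGridSummaries:
    def test_cell_count_filter_boundary(self, eye):
        img = small_image(eye, n=512)
        ones = np.ones((512, 512), dtype=bool)
        full = MaskSet(ones, np.zeros_like(ones), ones.copy())
        rng = np.random.default_rng(0)
        pos199 = rng.uniform(0, 255, size=(199, 2))
        pos200 = rng.uniform([0, 256], [255, 511], size=(200, 2))
        cells = cells_at(np.vstack([pos199, pos200]))
        out = grid_summaries(cells, full, img, grid_px=256, min_cells=200)
        assert len(out) == 1
        assert (out.grid_i.iloc[0], out.grid_j.iloc[0]) == (0, 1)
        assert out.n_cells.iloc[0] == 200

    def test_local_density_uses_visible_area(self, eye):
        n = 512
        img = small_image(eye, n=n)
        ones = np.ones((n, n), dtype=bool)
        mosaic = ones.copy()
        mosaic[0:256, 0:128] = False  # half of square (0,0) masked
        masks = MaskSet(ones, np.zeros_like(ones), mosaic)
        rng = np.random.default_rng(1)
        cells = cells_at(rng.uniform([0, 128], [255, 255], size=(300, 2)))
        out = grid_summaries(cells, masks, img, grid_px=256, min_cells=200)
        px_mm = img.pixel_size_um / 1000
        expected_area = 256 * 128 * px_mm**2
        assert out.visible_area_mm2.iloc[0] == pytest.approx(expected_area)
        assert out.local_density.iloc[0] == pytest.approx(300 / expected_area)

    def test_density_area_duality_on_tessellation(self, eye):
        n = 512
        img = small_image(eye, n=n)
        ones = np.ones((n, n), dtype=bool)
        full = MaskSet(ones, np.zeros_like(ones), ones.copy())
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, n - 1, size=(1200, 2))
        cells = voronoi_morphometry(pts, full, img.pixel_size_um, img)
        out = grid_summaries(cells, full, img, grid_px=256, min_cells=200)
        # density (cells per visible mm^2) x mean interior area (um^2) ~ 1
        prod = out.local_density * out.mean_area * 1e-6
        assert prod.to_numpy() == pytest.approx(1.0, abs=0.05)

    def test_partition_no_cell_counted_twice(self, eye):
        img = small_image(eye, n=512)
        ones = np.ones((512, 512), dtype=bool)
        full = MaskSet(ones, np.zeros_like(ones), ones.copy())
        rng = np.random.default_rng(3)
        cells = cells_at(rng.uniform(0, 511, size=(2000, 2)))
        out = grid_summaries(cells, full, img, grid_px=256, min_cells=0)
        assert out.n_cells.sum() == 2000

    def test_filter_monotonicity(self, eye):
        img = small_image(eye, n=512)
        ones = np.ones((512, 512), dtype=bool)
        full = MaskSet(ones, np.zeros_like(ones), ones.copy())
        rng = np.random.default_rng(4)
        cells = cells_at(rng.uniform(0, 511, size=(900, 2)))
        n_hi = len(grid_summaries(cells, full, img, min_cells=250))
        n_lo = len(grid_summaries(cells, full, img, min_cells=100))
        assert n_lo >= n_hi


class TestPrCentralExclusion:
    def _records(self):
        return pd.DataFrame({"ecc_deg": [-3.0, -2.5, -1.0, 0.0, 2.4999, 2.5, 4.0]})

    def test_open_interval_band(self):
        out = pr_central_exclusion(self._records(), "PR")
        assert sorted(out.ecc_deg) == [-3.0, -2.5, 2.5, 4.0]

    def test_rpe_untouched(self):
        out = pr_central_exclusion(self._records(), "RPE")
        assert len(out) == 7

    def test_idempotent(self):
        once = pr_central_exclusion(self._records(), "PR")
        twice = pr_central_exclusion(once, "PR")
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )


class TestEccentricityProfile:
    def _summaries(self, eccs, dens):
        return pd.DataFrame(
            {
                "ecc_deg": eccs,
                "local_density": dens,
                "mean_area": 1.0,
                "mean_perimeter": 1.0,
                "mean_neighbors": 6.0,
            }
        )

    def test_single_location_single_bin(self):
        prof = eccentricity_profile(self._summaries([3.1] * 5, [10, 20, 30, 40, 50]))
        populated = prof[prof["count"] > 0]
        assert len(populated) == 1
        assert populated.local_density_mean.iloc[0] == pytest.approx(30.0)

    def test_hand_computed_bin_means(self):
        # range [-10, 10], 25 bins of width 0.8: bin 13 = [0.4, 1.2),
        # bin 18 = [4.4, 5.2), bin 0 = [-10, -9.2)
        s = self._summaries([1.0, 1.1, 4.5, 4.7, 5.1, -9.9], [10, 20, 30, 40, 50, 60])
        prof = eccentricity_profile(s)
        b13 = prof[prof.bin == 13].iloc[0]
        b18 = prof[prof.bin == 18].iloc[0]
        b0 = prof[prof.bin == 0].iloc[0]
        assert b13["count"] == 2 and b13.local_density_mean == pytest.approx(15.0)
        assert b18["count"] == 3 and b18.local_density_mean == pytest.approx(40.0)
        assert b0["count"] == 1 and b0.local_density_mean == pytest.approx(60.0)

    def test_binning_conservation(self):
        rng = np.random.default_rng(5)
        s = self._summaries(rng.uniform(-10, 10, 200), rng.uniform(5, 6, 200))
        prof = eccentricity_profile(s)
        assert prof["count"].sum() == 200
        assert len(prof) == 25

    def test_negative_slope_recovered(self):
        eccs = np.linspace(2.6, 9.4, 40)
        dens = 12000 - 400 * eccs
        prof = eccentricity_profile(self._summaries(eccs, dens))
        pop = prof[prof["count"] > 0]
        slope = np.polyfit(pop.ecc_center, pop.local_density_mean, 1)[0]
        assert slope < 0


class TestDensityHeatmap:
    def test_single_location_delta_without_smoothing(self):
        s = pd.DataFrame({"x_deg": [0.1], "y_deg": [0.1], "local_density": [42.0]})
        grid, xe, ye = density_heatmap(s, smoothing_sigma_bins=0)
        assert np.nansum(grid) == pytest.approx(42.0)
        assert np.sum(~np.isnan(grid)) == 1

    def test_smoothing_preserves_values_on_support(self):
        rng = np.random.default_rng(6)
        s = pd.DataFrame(
            {
                "x_deg": rng.uniform(-5, 5, 400),
                "y_deg": rng.uniform(-5, 5, 400),
                "local_density": np.full(400, 7.0),
            }
        )
        grid, _, _ = density_heatmap(s)
        vals = grid[~np.isnan(grid)]
        assert vals == pytest.approx(7.0, rel=0.01)

    def test_symmetric_input_symmetric_heatmap(self):
        s = pd.DataFrame(
            {
                "x_deg": [-3.0, 3.0, -3.0, 3.0],
                "y_deg": [-3.0, -3.0, 3.0, 3.0],
                "local_density": [5.0, 5.0, 5.0, 5.0],
            }
        )
        grid, _, _ = density_heatmap(s)
        assert np.allclose(grid, grid[::-1], equal_nan=True)
        assert np.allclose(grid, grid[:, ::-1], equal_nan=True)


class TestRectangleMatching:
    def _grid(self, dens, offset=0.0):
        xs, ys = np.meshgrid(np.arange(4) * 0.8375, np.arange(4) * 0.8375)
        df = pd.DataFrame(
            {
                "x_deg": xs.ravel() + offset,
                "y_deg": ys.ravel(),
                "local_density": dens,
                "mean_area": 1.0,
                "mean_perimeter": 1.0,
                "mean_neighbors": 6.0,
            }
        )
        df["ecc_deg"] = np.hypot(df.x_deg, df.y_deg)
        df["image_id"] = "x"
        return df

    def test_identical_grids_all_matched_elementwise_ratio(self):
        rpe = self._grid(np.full(16, 5000.0))
        pr = self._grid(np.full(16, 8000.0))
        out = match_rpe_pr_rectangles(rpe, pr, tol_deg=0.42)
        assert len(out) == 16
        assert out.local_density_ratio.to_numpy() == pytest.approx(1.6)

    def test_offset_beyond_tolerance_no_matches(self):
        rpe = self._grid(np.full(16, 5000.0))
        pr = self._grid(np.full(16, 8000.0), offset=0.3)
        with pytest.warns(UserWarning):
            out = match_rpe_pr_rectangles(rpe, pr, tol_deg=0.15)
        assert len(out) == 0

    def test_one_to_one_matching(self):
        rpe = self._grid(np.full(16, 5000.0))
        pr = pd.concat([self._grid(np.full(16, 8000.0))] * 1, ignore_index=True)
        out = match_rpe_pr_rectangles(rpe, pr, tol_deg=0.42)
        assert out.pr_image_id.size == len(out)
        assert len(out) == len(set(zip(out.ecc_deg, out.distance_deg))) or len(out) == 16
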