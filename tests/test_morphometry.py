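"""Morphometry analytics: roundness, SDOM, distribution features, catalogue."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from ctcmorph import (
    CHANNELS,
    FEATURE_CATALOG,
    FrameBackground,
    compute_features,
    frame_background,
    roundness,
    sdom,
)


def _cell_fixture(radius_nuc=6, radius_cell=10, size=32, value=100.0):
    nuc = np.zeros((size, size), bool)
    cell = np.zeros((size, size), bool)
    c = size // 2
    nuc[draw_disk((c, c), radius_nuc)] = True
    cell[draw_disk((c, c), radius_cell)] = True
    channels = {ch: np.full((size, size), value) for ch in CHANNELS}
    return nuc, cell, channels


class TestRoundness:
    def test_continuous_circle_identity(self):
        r = 7.3
        assert roundness(2 * math.pi * r, math.pi * r**2) == pytest.approx(1.0)

    def test_rectangle_formula_value(self):
        assert roundness(100.0, 400.0) == pytest.approx(1.9894, abs=1e-4)

    @given(k=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, k):
        assert roundness(k * 40.0, k**2 * 60.0) == pytest.approx(
            roundness(40.0, 60.0), rel=1e-9
        )

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            roundness(0.0, 10.0)
        with pytest.raises(ValueError):
            roundness(10.0, -1.0)

    @pytest.mark.parametrize("radius", [10, 15, 25, 40])
    def test_rasterized_disk_roundness_near_one(self, radius):
        mask = np.zeros((2 * radius + 8, 2 * radius + 8), bool)
        mask[draw_disk((radius + 4, radius + 4), radius)] = True
        from ctcmorph import mask_perimeter

        value = roundness(mask_perimeter(mask), mask.sum())
        assert value == pytest.approx(1.0, abs=0.02)

    def test_ellipse_roundness_increases_with_axis_ratio(self):
        """Fixed-area ellipses: roundness grows with elongation (polygon oracle)."""

        def polygon_roundness(a, b, n=20000):
            t = np.linspace(0, 2 * math.pi, n)
            x, y = a * np.cos(t), b * np.sin(t)
            perim = np.hypot(np.diff(x), np.diff(y)).sum()
            return roundness(perim, math.pi * a * b)

        area_axis = 12.0
        values = [
            polygon_roundness(area_axis * q, area_axis / q) for q in (1.0, 1.3, 1.8, 2.5)
        ]
        assert all(v2 > v1 for v1, v2 in zip(values, values[1:]))
        # and the rasterized measurement agrees with the oracle to a few %
        mask = np.zeros((80, 80), bool)
        mask[draw_ellipse(40, 40, 12, 24)] = True
        from ctcmorph import mask_perimeter

        measured = roundness(mask_perimeter(mask), mask.sum())
        assert measured == pytest.approx(polygon_roundness(12, 24), rel=0.05)


class TestSdom:
    def _bg(self, mu=10.0, sigma=2.0, n=5):
        return FrameBackground(stats={"ck": (mu, sigma, n)}, source={"ck": "wbc"})

    def test_cell_at_background_mean_is_zero(self):
        assert sdom(10.0, self._bg(), "ck") == 0.0

    def test_guide_value_five_sigma(self):
        assert sdom(10.0 + 5 * 2.0, self._bg(), "ck") == pytest.approx(5.0)

    @given(k=st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_affine_linearity(self, k):
        base = sdom(12.0, self._bg(), "ck")
        assert sdom(12.0 + k * 2.0, self._bg(), "ck") == pytest.approx(base + k, abs=1e-9)

    def test_degenerate_background_flagged_missing(self):
        assert math.isnan(sdom(5.0, FrameBackground(stats={"ck": (10.0, 0.0, 3)}), "ck"))
        assert math.isnan(sdom(5.0, FrameBackground(), "ck"))


class TestFrameBackground:
    def test_hand_computed_mu_sigma(self):
        cells = [{"mean_ck_cell": 8.0}, {"mean_ck_cell": 10.0}, {"mean_ck_cell": 12.0}]
        bg = frame_background(cells, channels=["ck"])
        mu, sigma, n = bg.stats["ck"]
        assert (mu, sigma, n) == (10.0, 2.0, 3)
        assert bg.available("ck")

    def test_identical_means_degenerate(self):
        cells = [{"mean_ck_cell": 10.0}] * 3
        bg = frame_background(cells, channels=["ck"])
        assert bg.stats["ck"][0] == 10.0
        assert not bg.available("ck")

    def test_single_wbc_unavailable(self):
        bg = frame_background([{"mean_ck_cell": 10.0}], channels=["ck"])
        assert not bg.available("ck")


class TestComputeFeatures:
    def test_uniform_field_distribution_features(self):
        nuc, cell, channels = _cell_fixture()
        f = compute_features(nuc, cell, channels)
        for ch in CHANNELS:
            assert f[f"heterogeneity_{ch}"] == pytest.approx(0.0, abs=1e-12)
            assert f[f"margination_{ch}"] == pytest.approx(1.0, abs=1e-12)
            assert f[f"clumpiness_{ch}"] == 0.0

    def test_disk_nucleus_area_close_to_analytic(self):
        # rasterize with centre-inclusion (x^2 + y^2 <= r^2)
        yy, xx = np.mgrid[:40, :40]
        nuc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 10**2
        cell = (yy - 20) ** 2 + (xx - 20) ** 2 <= 14**2
        f = compute_features(nuc, cell, {ch: np.ones((40, 40)) for ch in CHANNELS})
        assert f["nuclear_area"] == pytest.approx(100 * math.pi, rel=0.02)
        assert f["cytoplasm_area"] == f["cell_area"] - f["nuclear_area"]
        assert f["nc_ratio"] == pytest.approx(
            f["nuclear_area"] / (f["cell_area"] - f["nuclear_area"])
        )

    def test_interior_blob_clumpiness_and_margination(self):
        """10% of the mask carries all signal -> clumpiness ~0.10, margination < 1."""
        size = 61
        cell = np.zeros((size, size), bool)
        cell[draw_disk((30, 30), 25)] = True
        area = cell.sum()
        blob = np.zeros_like(cell)
        r_blob = int(round(math.sqrt(0.10 * area / math.pi)))
        blob[draw_disk((30, 30), r_blob)] = True
        img = np.where(blob, 100.0, 0.0)
        nuc = np.zeros_like(cell)
        nuc[draw_disk((30, 30), 5)] = True
        f = compute_features(nuc, cell, {ch: img for ch in CHANNELS})
        assert f["clumpiness_ck"] == pytest.approx(blob.sum() / area, abs=0.02)
        assert f["margination_ck"] < 1.0

    def test_catalogue_complete_and_snapshot(self):
        nuc, cell, channels = _cell_fixture()
        f = compute_features(nuc, cell, channels)
        assert set(f) == set(FEATURE_CATALOG)
        assert len(FEATURE_CATALOG) == 87
        # spot-check the documented naming scheme
        for name in ("mean_cdx2_nucleus", "cv_cd45_cell", "integrated_dapi_cytoplasm",
                     "heterogeneity_ck", "sdom_cdx2", "nuclear_solidity"):
            assert name in f

    def test_translation_invariance(self):
        nuc, cell, channels = _cell_fixture()
        rng = np.random.default_rng(0)
        noise = rng.normal(100, 10, nuc.shape)
        ch0 = {ch: noise for ch in CHANNELS}
        f0 = compute_features(nuc, cell, ch0)
        shift = 4  # keeps the cell away from the wrap-around border
        f1 = compute_features(
            np.roll(nuc, shift, axis=1),
            np.roll(cell, shift, axis=1),
            {ch: np.roll(noise, shift, axis=1) for ch in CHANNELS},
        )
        for key in FEATURE_CATALOG:
            if math.isnan(f0[key]):
                assert math.isnan(f1[key])
            else:
                assert f1[key] == pytest.approx(f0[key], rel=1e-9)

    def test_empty_mask_rejected(self):
        _, cell, channels = _cell_fixture()
        with pytest.raises(ValueError):
            compute_features(np.zeros_like(cell), cell, channels)

    def test_pixel_size_scales_areas_and_perimeters(self):
        nuc, cell, channels = _cell_fixture()
        f_px = compute_features(nuc, cell, channels)
        f_um = compute_features(nuc, cell, channels, pixel_size=0.5)
        assert f_um["nuclear_area"] == pytest.approx(0.25 * f_px["nuclear_area"])
        assert f_um["cell_perimeter"] == pytest.approx(0.5 * f_px["cell_perimeter"])
        assert f_um["nuclear_roundness"] == pytest.approx(f_px["nuclear_roundness"])
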