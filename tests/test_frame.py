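"""Subpleural-band geometry against analytic disk/annulus oracles."""

import numpy as np
import pytest

from fibroframe import (
    BinaryMask,
    FrameParams,
    build_frame,
    depth_map,
    pleural_boundary,
)

from conftest import disk_mask


def _polyline_length(xy: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))


class TestPleuralBoundary:
    def test_disk_contour_length(self):
        tissue = disk_mask(500.0, pixel_size_um=1.0)
        contours = pleural_boundary(tissue)
        assert len(contours) == 1
        length = _polyline_length(contours[0])
        assert length == pytest.approx(np.pi * 1000.0, rel=0.02)

    def test_two_lobes_two_contours(self):
        pix = np.zeros((600, 1200), bool)
        yy, xx = np.ogrid[:600, :600]
        lobe = (yy - 300) ** 2 + (xx - 300) ** 2 <= 250**2
        pix[:, :600] |= lobe
        pix[:, 600:] |= lobe
        tissue = BinaryMask(pix, pixel_size_um=1.0)
        assert len(pleural_boundary(tissue)) == 2

    def test_internal_hole_ignored(self):
        tissue = disk_mask(400.0)
        pix = tissue.pixels.copy()
        c = pix.shape[0] // 2
        yy, xx = np.ogrid[: pix.shape[0], : pix.shape[1]]
        pix &= ~((yy - c) ** 2 + (xx - c) ** 2 <= 100**2)
        assert len(pleural_boundary(BinaryMask(pix, 1.0))) == 1

    def test_empty_mask(self):
        assert pleural_boundary(BinaryMask(np.zeros((50, 50), bool), 1.0)) == []


class TestBuildFrame:
    @pytest.mark.parametrize(
        ("radius_um", "px"),
        [
            (300.0, 0.5), (300.0, 1.0), (300.0, 2.0),
            (500.0, 0.5), (500.0, 1.0), (500.0, 2.0),
            (1000.0, 1.0), (1000.0, 2.0),
            (2000.0, 2.0),
        ],
    )
    def test_annulus_oracle(self, radius_um, px):
        """Band area matches π(R² − (R−d)²) within 1% whenever R > d.

        Radii are exercised at pixel sizes keeping rasters a few megapixels;
        the largest radii are covered at the coarser resolutions.
        """
        depth = 250.0
        tissue = disk_mask(radius_um, pixel_size_um=px)
        result = build_frame(tissue, FrameParams(depth_um=depth))
        expected = np.pi * (radius_um**2 - (radius_um - depth) ** 2)
        assert result.frame_area_um2 == pytest.approx(expected, rel=0.01)

    def test_band_saturates_on_thin_tissue(self):
        tissue = disk_mask(200.0, pixel_size_um=1.0)
        result = build_frame(
            tissue, FrameParams(depth_um=250.0, min_component_um2=1e4)
        )
        assert np.array_equal(result.frame.pixels, tissue.pixels)

    def test_one_pixel_depth_is_boundary_layer(self):
        tissue = disk_mask(300.0, pixel_size_um=1.0)
        result = build_frame(tissue, FrameParams(depth_um=1.0))
        from scipy import ndimage

        eroded = ndimage.binary_erosion(tissue.pixels)
        boundary = tissue.pixels & ~eroded
        assert np.array_equal(result.frame.pixels, boundary)

    def test_max_depth_bounded(self):
        tissue = disk_mask(800.0, pixel_size_um=1.0)
        result = build_frame(tissue, FrameParams(depth_um=250.0))
        dm = depth_map(tissue)
        inside = dm[result.frame.pixels]
        assert inside.max() <= 250.0 + tissue.pixel_size_um  # +1 px tolerance
        assert inside.min() > 0

    def test_depth_monotonicity_and_saturation(self):
        tissue = disk_mask(400.0, pixel_size_um=1.0)
        areas = [
            build_frame(tissue, FrameParams(depth_um=d)).frame_area_um2
            for d in (50, 150, 300, 500, 1000)
        ]
        assert areas == sorted(areas)
        filled_area = tissue.area_um2()
        assert areas[-1] == filled_area  # saturates at the filled tissue

    def test_hole_independence(self):
        """An internal hole leaves the band unchanged (holes filled first)."""
        tissue = disk_mask(500.0, pixel_size_um=1.0)
        base = build_frame(tissue)
        pix = tissue.pixels.copy()
        c = pix.shape[0] // 2
        yy, xx = np.ogrid[: pix.shape[0], : pix.shape[1]]
        pix &= ~((yy - c) ** 2 + (xx - c) ** 2 <= 150**2)
        holed = build_frame(BinaryMask(pix, 1.0))
        assert np.array_equal(base.frame.pixels, holed.frame.pixels)

    def test_idempotence(self):
        tissue = disk_mask(400.0, pixel_size_um=1.0)
        first = build_frame(tissue)
        again = build_frame(
            BinaryMask(first.frame.pixels | tissue.pixels, 1.0)
        )
        assert np.array_equal(first.frame.pixels, again.frame.pixels)

    def test_empty_tissue(self):
        result = build_frame(BinaryMask(np.zeros((64, 64), bool), 1.0))
        assert result.frame_area_um2 == 0.0
        assert result.lung_area_um2 == 0.0
        assert result.pleura == []

    def test_exclude_boundary_flag(self):
        tissue = disk_mask(300.0, pixel_size_um=1.0)
        with_b = build_frame(tissue, FrameParams(depth_um=100.0))
        without = build_frame(
            tissue, FrameParams(depth_um=100.0, include_boundary=False)
        )
        assert without.frame_area_um2 < with_b.frame_area_um2
        assert not (without.frame.pixels & ~with_b.frame.pixels).any()

    def test_small_fragment_excluded(self):
        pix = disk_mask(400.0, pixel_size_um=1.0).pixels.copy()
        pix[2:10, 2:10] = True  # 64 µm² debris
        result = build_frame(BinaryMask(pix, 1.0))
        assert not result.frame.pixels[2:10, 2:10].any()
        assert result.lung_area_um2 == pytest.approx(
            disk_mask(400.0).area_um2(), rel=1e-6
        )


class TestDepthMap:
    def test_disk_center_depth(self):
        tissue = disk_mask(300.0, pixel_size_um=1.0)
        dm = depth_map(tissue)
        c = tissue.shape[0] // 2
        assert dm[c, c] == pytest.approx(300.0, abs=1.5)

    def test_background_zero(self):
        tissue = disk_mask(100.0, pixel_size_um=1.0)
        dm = depth_map(tissue)
        assert dm[0, 0] == 0.0

    def test_translation_invariance(self):
        pix = np.zeros((200, 200), bool)
        yy, xx = np.ogrid[:200, :200]
        pix |= (yy - 60) ** 2 + (xx - 60) ** 2 <= 40**2
        dm1 = depth_map(BinaryMask(pix, 1.0))
        shifted = np.roll(np.roll(pix, 30, axis=0), 25, axis=1)
        dm2 = depth_map(BinaryMask(shifted, 1.0))
        assert np.allclose(dm2, np.roll(np.roll(dm1, 30, axis=0), 25, axis=1))
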