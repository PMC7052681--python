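"""Focus detection against planted ground truth and metric arithmetic."""

import numpy as np
import pytest

from fibroframe import (
    FociParams,
    FrameParams,
    build_frame,
    classify_focus_size,
    compute_foci_metrics,
    detect_foci,
    generate_lung_image,
    tissue_mask,
)
from fibroframe.foci import AOI, FociMetrics

from conftest import paint_image, small_lung_params


def _slab_image(rects, slab=(800, 1100), px=1.0, rounded=False):
    """Rectangular tissue slab with collagen rectangles at given pixel boxes.

    ``rounded`` drops the four corner pixels of each rectangle, making the
    shape invariant under the detection pipeline's radius-1 opening (a
    sharp rectangle corner is clipped by a disk opening), so planted areas
    are recovered exactly.
    """
    canvas = (slab[0] + 200, slab[1] + 200)
    tissue = np.zeros(canvas, bool)
    tissue[100 : 100 + slab[0], 100 : 100 + slab[1]] = True
    collagen = np.zeros(canvas, bool)
    for r0, c0, h, w in rects:
        collagen[100 + r0 : 100 + r0 + h, 100 + c0 : 100 + c0 + w] = True
        if rounded:
            for r, c in ((r0, c0), (r0, c0 + w - 1), (r0 + h - 1, c0),
                         (r0 + h - 1, c0 + w - 1)):
                collagen[100 + r, 100 + c] = False
    img = paint_image(
        {"collagen": collagen, "cytoplasm": tissue & ~collagen}, pixel_size_um=px
    )
    return img


class TestClassify:
    def test_threshold_inclusive_exclusive(self):
        assert classify_focus_size(7_500.0) == "small"
        assert classify_focus_size(7_501.0) == "large"
        assert classify_focus_size(1.0) == "small"

    def test_one_pixel_flips_class_at_native_resolution(self):
        # at 1 µm²/px, adding a single pixel crosses the boundary
        assert classify_focus_size(7_500.0 + 1.0) == "large"

    def test_invalid_area(self):
        with pytest.raises(ValueError):
            classify_focus_size(0.0)


class TestDetect:
    def test_planted_foci_recovered(self, lung_section):
        img, manifest = lung_section
        frame = build_frame(tissue_mask(img))
        aois = detect_foci(img, frame)
        assert len(aois) == len(manifest.foci) == 3
        detected = sorted(a.area_um2 for a in aois)
        planted = sorted(f.area_um2 for f in manifest.foci)
        for d, p in zip(detected, planted):
            assert d == pytest.approx(p, rel=0.02)
        classes = [a.size_class for a in sorted(aois, key=lambda a: a.area_um2)]
        assert classes == ["small", "large", "large"]

    def test_no_green_no_foci(self):
        img = _slab_image([])
        frame = build_frame(tissue_mask(img))
        assert detect_foci(img, frame) == []

    def test_deep_focus_excluded_by_band(self):
        """A focus planted entirely deeper than the band depth yields no AOI."""
        img, manifest = generate_lung_image(
            small_lung_params(
                focus_count=2, focus_depth_range_um=(400.0, 470.0), seed=21
            )
        )
        assert all(f.min_depth_um > 250.0 for f in manifest.foci)
        frame = build_frame(tissue_mask(img), FrameParams(depth_um=250.0))
        assert detect_foci(img, frame) == []

    def test_size_class_edge_end_to_end(self):
        """Rasterized 7,500 µm² focus is small; a 7,501 µm² one is large.

        Shapes: 56×134 − 4 corners = 7,500 px and 95×79 − 4 = 7,501 px,
        both stable under the pipeline's morphological opening.
        """
        img = _slab_image(
            [(40, 200, 56, 134), (40, 450, 95, 79)], rounded=True
        )
        frame = build_frame(tissue_mask(img))
        aois = sorted(detect_foci(img, frame), key=lambda a: a.area_um2)
        assert [a.area_um2 for a in aois] == [7_500.0, 7_501.0]
        assert [a.size_class for a in aois] == ["small", "large"]

    def test_aoi_pixels_inside_frame(self, lung_section):
        img, _ = lung_section
        frame = build_frame(tissue_mask(img))
        for aoi in detect_foci(img, frame):
            rows, cols = aoi.pixel_region.T
            assert frame.frame.pixels[rows, cols].all()

    def test_depth_annotation(self, lung_section):
        img, manifest = lung_section
        frame = build_frame(tissue_mask(img))
        aois = sorted(detect_foci(img, frame), key=lambda a: a.area_um2)
        planted = sorted(manifest.foci, key=lambda f: f.area_um2)
        for a, f in zip(aois, planted):
            assert a.min_depth_um == pytest.approx(f.min_depth_um, abs=2 * img.pixel_size_um)
            assert a.max_depth_um == pytest.approx(f.max_depth_um, abs=2 * img.pixel_size_um)

    def test_calibration_mismatch_rejected(self, lung_section):
        img, _ = lung_section
        frame = build_frame(tissue_mask(img))
        frame.frame.pixel_size_um = img.pixel_size_um * 2
        with pytest.raises(ValueError, match="pixel size"):
            detect_foci(img, frame)


class TestMetrics:
    def _frame_stub(self, frame_um2, lung_um2):
        from fibroframe import BinaryMask, FrameResult

        return FrameResult(
            frame=BinaryMask(np.ones((2, 2), bool), 1.0, kind="frame"),
            pleura=[],
            frame_area_um2=frame_um2,
            lung_area_um2=lung_um2,
        )

    def _aoi(self, i, area):
        return AOI(
            id=i, pixel_region=np.zeros((1, 2), int), area_um2=area,
            centroid_um=(0, 0), size_class=classify_focus_size(area),
            min_depth_um=0, max_depth_um=0,
        )

    def test_density_arithmetic(self):
        aois = [self._aoi(i, 1000.0) for i in range(5)]
        m = compute_foci_metrics(aois, self._frame_stub(1e6, 10e6))
        assert m.foci_per_mm2_lung == pytest.approx(0.5)

    def test_frame_fraction_arithmetic(self):
        aois = [self._aoi(1, 1e5)]
        m = compute_foci_metrics(aois, self._frame_stub(1e6, 2e6))
        assert m.aoi_frame_fraction == pytest.approx(0.10)
        assert m.aoi_lung_fraction == pytest.approx(0.05)

    def test_empty_list_all_zero(self):
        m = compute_foci_metrics([], self._frame_stub(0.0, 0.0))
        assert m == FociMetrics(0, 0.0, 0.0, 0.0, 0.0, 0, 0)

    def test_class_tally_consistent(self, lung_section):
        img, _ = lung_section
        frame = build_frame(tissue_mask(img))
        aois = detect_foci(img, frame)
        m = compute_foci_metrics(aois, frame)
        assert m.n_small + m.n_large == m.n_foci
        assert 0.0 <= m.aoi_frame_fraction <= 1.0

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_foci_metrics([self._aoi(1, 10.0)], self._frame_stub(0.0, 0.0))
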