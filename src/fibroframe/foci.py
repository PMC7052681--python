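"""Fibrotic-focus (AOI) detection inside the subpleural band and the
derived morphometric readouts.

A focus is a connected collagen-dense region inside the band: the
Light-Green stain loading is thresholded, restricted to the band, lightly
opened to break hairline bridges, and connected components above a noise
floor become AOIs.  A focus straddling the inner band edge is clipped and
its clipped area is what gets measured.  Foci are split into small
(area ≤ 7,500 µm²) and large (> 7,500 µm²) classes.

Reported per section: focus count, foci per mm² of lung tissue, the summed
focus area normalized on the band area (ΣAOI/Frame — the headline fibrosis
fraction) and on the whole lung area, and the small/large tally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .frame import FrameResult, depth_map as _depth_map
from .imgio import BinaryMask, CalibratedImage
from .stainseg import SegParams, StainModel, _collagen_signal
from skimage.filters import threshold_otsu

__all__ = [
    "AOI",
    "FociParams",
    "FociMetrics",
    "detect_foci",
    "classify_focus_size",
    "compute_foci_metrics",
]

SIZE_SMALL = "small"
SIZE_LARGE = "large"


@dataclass
class FociParams:
    """Detection and classification parameters.

    size_threshold_um2 : small/large class boundary (≤ is small).
    min_aoi_um2 : noise floor (~a few cells); smaller components dropped.
    connectivity : 4 or 8 pixel connectivity for component labeling.
    fibrosis_threshold : Light-Green OD loading cut, or "otsu" computed on
        loadings within the band.
    opening_radius_px : disk radius of the morphological opening that
        breaks hairline bridges between adjacent foci (0 disables).
    """

    size_threshold_um2: float = 7_500.0
    min_aoi_um2: float = 100.0
    connectivity: int = 8
    fibrosis_threshold: float | str = 0.30
    opening_radius_px: int = 1

    def __post_init__(self) -> None:
        if not (self.size_threshold_um2 > self.min_aoi_um2 > 0):
            raise ValueError("require size_threshold_um2 > min_aoi_um2 > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if isinstance(self.fibrosis_threshold, str) and self.fibrosis_threshold != "otsu":
            raise ValueError("fibrosis_threshold must be a number or 'otsu'")
        if self.opening_radius_px < 0:
            raise ValueError("opening_radius_px must be >= 0")


@dataclass
class AOI:
    """One detected fibrotic focus.

    ``pixel_region`` holds (row, col) pixel coordinates; ``polygon_um`` is
    the closed outer contour in µm for GeoJSON export; depths are distances
    from the pleural edge spanned by the focus.
    """

    id: int
    pixel_region: np.ndarray
    area_um2: float
    centroid_um: tuple[float, float]
    size_class: str
    min_depth_um: float
    max_depth_um: float
    polygon_um: np.ndarray | None = None

    def geojson_properties(self) -> dict:
        return {
            "id": self.id,
            "area_um2": self.area_um2,
            "size_class": self.size_class,
            "min_depth_um": self.min_depth_um,
            "max_depth_um": self.max_depth_um,
        }


@dataclass
class FociMetrics:
    n_foci: int
    foci_per_mm2_lung: float
    sum_aoi_um2: float
    aoi_frame_fraction: float
    aoi_lung_fraction: float
    n_small: int
    n_large: int


def classify_focus_size(area_um2: float, threshold_um2: float = 7_500.0) -> str:
    """Small iff area ≤ threshold (inclusive); large for strictly greater."""
    if not (area_um2 > 0):
        raise ValueError(f"focus area must be positive, got {area_um2}")
    if not (threshold_um2 > 0):
        raise ValueError("threshold must be positive")
    return SIZE_SMALL if area_um2 <= threshold_um2 else SIZE_LARGE


def _focus_polygon_um(component: np.ndarray, bbox: tuple, px: float) -> np.ndarray:
    """Outer contour of one focus in µm (x, y), from a padded crop."""
    r0, c0 = bbox[0], bbox[1]
    padded = np.pad(component, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    outer = max(contours, key=len)
    rows = outer[:, 0] - 1 + r0
    cols = outer[:, 1] - 1 + c0
    return np.stack([cols * px, rows * px], axis=1)


def detect_foci(
    image: CalibratedImage,
    frame: FrameResult,
    model: StainModel | None = None,
    params: FociParams | None = None,
    seg_params: SegParams | None = None,
) -> list[AOI]:
    """Detect fibrotic foci within the subpleural band.

    The fibrosis mask is the thresholded collagen (Light-Green) loading
    intersected with the band, opened with a small disk, and labeled at the
    configured connectivity; components under ``min_aoi_um2`` are dropped.
    An empty band yields an empty list; a calibration mismatch between
    image and band is an error.
    """
    model = model or StainModel()
    params = params or FociParams()
    seg_params = seg_params or SegParams()
    frame.frame.check_aligned(image)
    px = image.pixel_size_um
    band = frame.frame.pixels
    if not band.any():
        return []

    signal = _collagen_signal(image, model, seg_params)
    thr = params.fibrosis_threshold
    if thr == "otsu":
        values = signal[band]
        thr = float(threshold_otsu(values)) if values.size > 1 else np.inf
    fibrosis = (signal > float(thr)) & band
    if params.opening_radius_px > 0:
        fibrosis = morphology.opening(
            fibrosis, morphology.disk(params.opening_radius_px)
        )

    connectivity = 2 if params.connectivity == 8 else 1
    labels = measure.label(fibrosis, connectivity=connectivity)
    if frame.depth_map_um is not None:
        dmap = frame.depth_map_um
    else:
        dmap = _depth_map(BinaryMask(band, px, kind="frame"))

    min_px = params.min_aoi_um2 / px**2
    aois: list[AOI] = []
    for prop in measure.regionprops(labels):
        if prop.area < min_px:
            continue
        area_um2 = float(prop.area) * px**2
        rows, cols = np.nonzero(labels == prop.label)
        depths = dmap[rows, cols]
        cy, cx = prop.centroid
        aois.append(
            AOI(
                id=len(aois) + 1,
                pixel_region=np.stack([rows, cols], axis=1),
                area_um2=area_um2,
                centroid_um=(float(cx) * px, float(cy) * px),
                size_class=classify_focus_size(area_um2, params.size_threshold_um2),
                min_depth_um=float(depths.min()),
                max_depth_um=float(depths.max()),
                polygon_um=_focus_polygon_um(prop.image, prop.bbox, px),
            )
        )
    return aois


def compute_foci_metrics(aois: list[AOI], frame: FrameResult) -> FociMetrics:
    """Per-section focus metrics.

    Density is normalized on lung tissue area (per mm²); the summed focus
    area is normalized on the band (ΣAOI/Frame) and on the lung area.
    All metrics are zero for an empty focus list; a non-empty list with a
    zero-area band is inconsistent input.
    """
    n = len(aois)
    if n == 0:
        return FociMetrics(0, 0.0, 0.0, 0.0, 0.0, 0, 0)
    if frame.frame_area_um2 <= 0 or frame.lung_area_um2 <= 0:
        raise ValueError("non-empty AOI list with zero frame/lung area")
    sum_area = float(sum(a.area_um2 for a in aois))
    n_small = sum(1 for a in aois if a.size_class == SIZE_SMALL)
    return FociMetrics(
        n_foci=n,
        foci_per_mm2_lung=n / (frame.lung_area_um2 / 1e6),
        sum_aoi_um2=sum_area,
        aoi_frame_fraction=sum_area / frame.frame_area_um2,
        aoi_lung_fraction=sum_area / frame.lung_area_um2,
        n_small=n_small,
        n_large=n - n_small,
    )
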