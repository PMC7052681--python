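"""Tissue segmentation and Masson-trichrome stain separation.

Masson's trichrome renders collagen green (Light Green SF), cytoplasm and
muscle red, and nuclei dark.  Collagen is isolated by Beer–Lambert color
deconvolution (Ruifrok & Johnston style): per-pixel optical density
OD = -log10(I / I0) is decomposed onto three unit stain-absorbance
vectors, and the Light-Green loading is thresholded.  An HSV-hue fallback
mode is available for images whose stain vectors are unknown.

Tissue is discriminated from background and air spaces by HSV saturation
(stained tissue is chromatic, background and lumens are near-white),
followed by small-object removal and bounded hole filling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import morphology
from skimage.filters import threshold_otsu

from .imgio import BinaryMask, CalibratedImage

__all__ = [
    "StainModel",
    "SegParams",
    "StainChannels",
    "REFERENCE_STAIN_OD",
    "separate_stains",
    "tissue_mask",
    "collagen_mask",
    "rgb_to_od",
    "od_to_rgb",
]

# Reference stain absorbance directions (rows: Light-Green collagen,
# red cytoplasm, hematoxylin nuclei), shared with the synthetic generator
# so that the default pipeline is self-consistent on synthetic sections.
# A green dye absorbs red and blue light, a red dye absorbs green and
# blue, and iron hematoxylin absorbs broadly.
REFERENCE_STAIN_OD: np.ndarray = np.array(
    [
        [0.65, 0.10, 0.75],  # Light Green (collagen)
        [0.07, 0.72, 0.65],  # Biebrich scarlet / fuchsin (cytoplasm, muscle)
        [0.60, 0.60, 0.55],  # hematoxylin (nuclei)
    ],
    dtype=float,
)


class StainChannels(NamedTuple):
    """Per-stain optical-density loadings (each a 2-D float raster)."""

    collagen: np.ndarray
    cytoplasm: np.ndarray
    nuclei: np.ndarray


@dataclass
class StainModel:
    """Three unit optical-density stain vectors plus the reference white.

    ``stain_vectors`` rows are (collagen/Light-Green, cytoplasm/red,
    nuclei/hematoxylin) absorbance directions in (R, G, B) order; each row
    is normalized to unit Euclidean norm on construction.  The matrix must
    be invertible.
    """

    stain_vectors: np.ndarray = field(
        default_factory=lambda: REFERENCE_STAIN_OD.copy()
    )
    background_intensity: tuple[float, float, float] = (255.0, 255.0, 255.0)

    def __post_init__(self) -> None:
        m = np.asarray(self.stain_vectors, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"stain_vectors must be 3×3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain vectors must be non-zero")
        m = m / norms[:, None]
        if np.linalg.cond(m) > 1e8:
            raise ValueError("stain matrix is singular (condition number too large)")
        self.stain_vectors = m
        bg = np.asarray(self.background_intensity, dtype=float)
        if bg.shape != (3,) or np.any(bg <= 0):
            raise ValueError("background_intensity must be 3 positive values")
        self.background_intensity = tuple(float(v) for v in bg)

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.stain_vectors)


@dataclass
class SegParams:
    """Segmentation thresholds.

    tissue_saturation_min : HSV saturation above which a pixel counts as
        stained tissue (background and air are near-white).
    tissue_min_object_um2 : stained specks below this area are dropped.
    hole_fill_max_um2 : tissue-internal holes up to this area are filled;
        ``inf`` fills all lumens (used for pleural-band construction),
        a finite cap keeps large airways out of area denominators.
    collagen_channel_threshold : OD loading cut on the Light-Green channel,
        or "otsu" to derive it from tissue-pixel loadings.
    collagen_min_object_um2 : collagen specks below this area are dropped.
    collagen_method : "deconvolution" (default) or "hsv" hue-band fallback.
    """

    tissue_saturation_min: float = 0.10
    tissue_min_object_um2: float = 1_000.0
    hole_fill_max_um2: float = float("inf")
    collagen_channel_threshold: float | str = 0.30
    collagen_min_object_um2: float = 50.0
    collagen_method: str = "deconvolution"
    # HSV fallback: hue band (degrees) counted as Light Green
    hsv_hue_range_deg: tuple[float, float] = (70.0, 180.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tissue_saturation_min <= 1.0:
            raise ValueError("tissue_saturation_min must be in [0, 1]")
        if self.tissue_min_object_um2 <= 0 or self.collagen_min_object_um2 <= 0:
            raise ValueError("minimum object areas must be positive")
        if not (self.hole_fill_max_um2 >= 0):
            raise ValueError("hole_fill_max_um2 must be non-negative or inf")
        if isinstance(self.collagen_channel_threshold, str):
            if self.collagen_channel_threshold != "otsu":
                raise ValueError("collagen_channel_threshold must be a number or 'otsu'")
        if self.collagen_method not in ("deconvolution", "hsv"):
            raise ValueError("collagen_method must be 'deconvolution' or 'hsv'")


# ---------------------------------------------------------------------------
# Beer–Lambert transforms
# ---------------------------------------------------------------------------

# Intensity floor avoiding log(0) on saturated dark pixels while keeping
# dense stain mixtures (channel OD up to ~5) representable.
_MIN_INTENSITY = 1.0 / 512.0


def rgb_to_od(
    pixels: np.ndarray, background: tuple[float, float, float] = (255.0, 255.0, 255.0)
) -> np.ndarray:
    """Per-channel optical density OD = -log10(I / I0)."""
    arr = np.maximum(np.asarray(pixels, dtype=float), _MIN_INTENSITY)
    return -np.log10(arr / np.asarray(background, dtype=float))


def od_to_rgb(
    od: np.ndarray, background: tuple[float, float, float] = (255.0, 255.0, 255.0)
) -> np.ndarray:
    """Invert :func:`rgb_to_od` (float output, not clipped to uint8)."""
    return np.asarray(background, dtype=float) * np.power(10.0, -np.asarray(od, float))


def separate_stains(image: CalibratedImage, model: StainModel) -> StainChannels:
    """Decompose an RGB trichrome image into per-stain OD loadings.

    Solves OD = loadings · M for the 3×3 unit-vector stain matrix M and
    clips negative projections to zero.  For a pixel synthesized as a
    non-negative stain mixture the round-trip is exact to numerical
    precision.
    """
    od = rgb_to_od(image.pixels, model.background_intensity)
    loadings = od @ model.inverse()
    loadings = np.clip(loadings, 0.0, None)
    return StainChannels(
        collagen=loadings[..., 0],
        cytoplasm=loadings[..., 1],
        nuclei=loadings[..., 2],
    )


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def _um2_to_px(area_um2: float, pixel_size_um: float) -> int:
    return int(np.ceil(area_um2 / pixel_size_um**2))


def _drop_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Remove connected objects of area strictly below min_px pixels."""
    if min_px <= 1:
        return mask
    return morphology.remove_small_objects(mask, max_size=min_px - 1)


def fill_holes_bounded(mask: np.ndarray, max_hole_px: float) -> np.ndarray:
    """Fill interior holes with area ≤ max_hole_px pixels (inf = all).

    A hole is a background component not touching the image border;
    border-connected background is never filled.
    """
    if max_hole_px <= 0:
        return mask.copy()
    labels, n = ndimage.label(~mask)
    if n == 0:
        return mask.copy()
    border_ids = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    sizes = ndimage.sum_labels(
        np.ones_like(labels, dtype=np.int64), labels, index=np.arange(1, n + 1)
    )
    fill = np.flatnonzero(sizes <= max_hole_px) + 1
    fill = np.setdiff1d(fill, border_ids)
    if len(fill) == 0:
        return mask.copy()
    return mask | np.isin(labels, fill)


def tissue_mask(image: CalibratedImage, params: SegParams | None = None) -> BinaryMask:
    """Segment stained tissue from white background and air spaces.

    Pipeline: HSV saturation threshold → small-object removal → bounded
    hole filling.  An all-background image yields an empty mask.
    """
    params = params or SegParams()
    hsv = skcolor.rgb2hsv(image.pixels)
    raw = hsv[..., 1] > params.tissue_saturation_min
    min_px = _um2_to_px(params.tissue_min_object_um2, image.pixel_size_um)
    cleaned = _drop_small(raw, min_px)
    max_hole_px = params.hole_fill_max_um2 / image.pixel_size_um**2
    filled = fill_holes_bounded(cleaned, max_hole_px)
    return BinaryMask(pixels=filled, pixel_size_um=image.pixel_size_um, kind="tissue")


def _collagen_signal(
    image: CalibratedImage, model: StainModel, params: SegParams
) -> np.ndarray:
    """Scalar raster whose thresholding yields the collagen mask."""
    if params.collagen_method == "deconvolution":
        return separate_stains(image, model).collagen
    # HSV fallback: 1 inside the green hue band (weighted by saturation), else 0
    hsv = skcolor.rgb2hsv(image.pixels)
    hue_deg = hsv[..., 0] * 360.0
    lo, hi = params.hsv_hue_range_deg
    in_band = (hue_deg >= lo) & (hue_deg <= hi)
    return np.where(in_band, hsv[..., 1], 0.0)


def collagen_mask(
    image: CalibratedImage,
    tissue: BinaryMask,
    model: StainModel | None = None,
    params: SegParams | None = None,
) -> BinaryMask:
    """Binary collagen (Light Green) mask restricted to tissue.

    With ``collagen_channel_threshold="otsu"`` the cut is computed by
    Otsu's method on collagen-channel values over tissue pixels only.
    The result is always a subset of the tissue mask; an empty tissue
    mask yields an empty collagen mask.
    """
    model = model or StainModel()
    params = params or SegParams()
    tissue.check_aligned(image)
    signal = _collagen_signal(image, model, params)
    tpix = tissue.pixels
    if not tpix.any():
        return BinaryMask(
            pixels=np.zeros_like(tpix),
            pixel_size_um=image.pixel_size_um,
            kind="collagen",
        )
    thr = params.collagen_channel_threshold
    if thr == "otsu":
        values = signal[tpix]
        thr = float(threshold_otsu(values)) if values.size > 1 else np.inf
    raw = (signal > float(thr)) & tpix
    min_px = _um2_to_px(params.collagen_min_object_um2, image.pixel_size_um)
    cleaned = _drop_small(raw, min_px)
    return BinaryMask(
        pixels=cleaned, pixel_size_um=image.pixel_size_um, kind="collagen"
    )
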