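"""Calibrated image and mask I/O.

Every raster in this package carries an isotropic physical pixel size in
micrometers per pixel.  All downstream quantities are areas (µm²) or
distances (µm), so a missing or anisotropic calibration corrupts every
metric; readers therefore fail loudly rather than assume a default.

Conventions
-----------
* pixel coordinates are 0-based, row-major; rectangles are half-open
* polygon exports are in physical µm with x = col × pixel_size_um and
  y = row × pixel_size_um, so area thresholds are resolution-independent

Supported inputs are plain or pyramidal/tiled TIFF and PNG.  Vendor WSI
containers (NDPI, SVS) are out of scope; export to TIFF first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import tifffile
from PIL import Image
from shapely.geometry import LineString, Polygon

__all__ = [
    "CalibratedImage",
    "BinaryMask",
    "read_image",
    "read_mask",
    "write_mask",
    "export_polygons",
    "import_polygons",
    "PixelSizeError",
]

MASK_KINDS = ("tissue", "frame", "collagen", "fibrosis", "layer")

#: relative x/y pixel-size mismatch above which an input is rejected as anisotropic
ANISOTROPY_TOL = 0.01


class PixelSizeError(ValueError):
    """Raised when no usable (isotropic) pixel size can be determined."""


@dataclass
class CalibratedImage:
    """RGB raster plus physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols, 3), uint8
    pixel_size_um : float
        Isotropic pixel size, µm per pixel, > 0.
    source_id : str
        Label identifying the originating file or generator.
    level : int
        Pyramid level the raster was read from (0 = full resolution).
    """

    pixels: np.ndarray
    pixel_size_um: float
    source_id: str = ""
    level: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected (rows, cols, 3) RGB raster, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("raster must have at least one row and one column")
        if not (self.pixel_size_um > 0):
            raise PixelSizeError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.level < 0:
            raise ValueError("pyramid level must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def pixel_area_um2(self) -> float:
        return float(self.pixel_size_um) ** 2


@dataclass
class BinaryMask:
    """Boolean raster aligned to a CalibratedImage."""

    pixels: np.ndarray
    pixel_size_um: float
    kind: str = "tissue"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.pixels.shape}")
        if not (self.pixel_size_um > 0):
            raise PixelSizeError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.kind not in MASK_KINDS:
            raise ValueError(f"kind must be one of {MASK_KINDS}, got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_um2(self) -> float:
        """Physical area of the true pixels (count × pixel_size_um²)."""
        return float(self.pixels.sum()) * self.pixel_size_um**2

    def check_aligned(self, other: "CalibratedImage | BinaryMask") -> None:
        oshape = other.shape if not isinstance(other, CalibratedImage) else other.shape
        if self.shape != oshape:
            raise ValueError(f"shape mismatch: mask {self.shape} vs {oshape}")
        if not np.isclose(self.pixel_size_um, other.pixel_size_um, rtol=1e-9):
            raise ValueError(
                f"pixel size mismatch: {self.pixel_size_um} vs {other.pixel_size_um}"
            )


# ---------------------------------------------------------------------------
# pixel-size resolution
# ---------------------------------------------------------------------------


def _sidecar_pixel_size(path: Path) -> float | None:
    """Look for `<file>.json` next to the image with a `pixel_size_um` key."""
    for candidate in (path.with_suffix(path.suffix + ".json"),):
        if candidate.exists():
            meta = json.loads(candidate.read_text())
            if "pixel_size_um" in meta:
                return float(meta["pixel_size_um"])
    return None


def _tiff_pixel_size(page: "tifffile.TiffPage") -> float | None:
    """Pixel size in µm from TIFF resolution tags, rejecting anisotropy."""
    tags = page.tags
    if "XResolution" not in tags or "YResolution" not in tags:
        return None
    unit = tags.get("ResolutionUnit")
    unit_val = getattr(unit, "value", unit)
    unit_val = getattr(unit_val, "value", unit_val)  # enum -> int
    # 2 = inch, 3 = centimeter (TIFF 6.0); 1/None = unitless -> unusable
    if unit_val == 2:
        um_per_unit = 25_400.0
    elif unit_val == 3:
        um_per_unit = 10_000.0
    else:
        return None

    def _ratio(tag: Any) -> float:
        v = tag.value
        if isinstance(v, tuple):
            return v[0] / v[1]
        return float(v)

    xres = _ratio(tags["XResolution"])
    yres = _ratio(tags["YResolution"])
    if xres <= 0 or yres <= 0:
        return None
    px_x = um_per_unit / xres
    px_y = um_per_unit / yres
    if abs(px_x - px_y) > ANISOTROPY_TOL * max(px_x, px_y):
        raise PixelSizeError(
            f"anisotropic pixel size ({px_x:.4g} × {px_y:.4g} µm) is not supported"
        )
    return px_x


def _png_pixel_size(img: Image.Image) -> float | None:
    dpi = img.info.get("dpi")
    if dpi:
        dx, dy = float(dpi[0]), float(dpi[1])
        if dx <= 0 or dy <= 0:
            return None
        px_x, px_y = 25_400.0 / dx, 25_400.0 / dy
        if abs(px_x - px_y) > ANISOTROPY_TOL * max(px_x, px_y):
            raise PixelSizeError(
                f"anisotropic pixel size ({px_x:.4g} × {px_y:.4g} µm) is not supported"
            )
        return px_x
    return None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _to_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"cannot interpret array of shape {arr.shape} as RGB")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def read_image(
    path: str | Path,
    pixel_size_um: float | None = None,
    level: int = 0,
) -> CalibratedImage:
    """Read a calibrated RGB image from TIFF (incl. pyramidal) or PNG.

    The pixel size is resolved in priority order: explicit ``pixel_size_um``
    argument (interpreted as the level-0 size), then a ``<file>.json``
    sidecar with a ``pixel_size_um`` key, then embedded metadata (TIFF
    resolution tags / PNG dpi).  For pyramidal TIFFs the returned
    ``pixel_size_um`` is the base size multiplied by the requested level's
    downsample factor.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    PixelSizeError
        If no pixel size can be determined from any source ("pixel size
        unknown"), or the calibration is anisotropic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()

    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            levels = getattr(series, "levels", [series])
            if level >= len(levels):
                raise ValueError(
                    f"level {level} not available ({len(levels)} level(s) present)"
                )
            base_shape = levels[0].shape
            lvl = levels[level]
            arr = _to_rgb(lvl.asarray())
            downsample = base_shape[1] / lvl.shape[1]
            base_px = pixel_size_um
            if base_px is None:
                base_px = _sidecar_pixel_size(path)
            if base_px is None:
                base_px = _tiff_pixel_size(series.pages[0])
            if base_px is None:
                raise PixelSizeError(
                    f"pixel size unknown for {path}: pass pixel_size_um, add a "
                    f"'{path.name}.json' sidecar, or embed TIFF resolution tags"
                )
            return CalibratedImage(
                pixels=arr,
                pixel_size_um=float(base_px) * downsample,
                source_id=path.name,
                level=level,
            )

    if suffix == ".png":
        if level != 0:
            raise ValueError("PNG images have a single resolution level")
        with Image.open(path) as img:
            px = pixel_size_um
            if px is None:
                px = _sidecar_pixel_size(path)
            if px is None:
                px = _png_pixel_size(img)
            arr = _to_rgb(np.asarray(img.convert("RGB")))
        if px is None:
            raise PixelSizeError(
                f"pixel size unknown for {path}: pass pixel_size_um or add a "
                f"'{path.name}.json' sidecar"
            )
        return CalibratedImage(pixels=arr, pixel_size_um=float(px), source_id=path.name)

    raise ValueError(f"unreadable format {suffix!r}; expected TIFF or PNG")


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as a lossless 8-bit PNG or TIFF (0 / 255).

    A ``<file>.json`` sidecar records ``pixel_size_um`` and ``kind`` so the
    mask round-trips through :func:`read_mask` without extra arguments.
    """
    path = Path(path)
    arr = (mask.pixels.astype(np.uint8)) * 255
    suffix = path.suffix.lower()
    if suffix == ".png":
        Image.fromarray(arr, mode="L").save(path)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr, photometric="minisblack")
    else:
        raise ValueError(f"mask format {suffix!r} not supported; use PNG or TIFF")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"pixel_size_um": mask.pixel_size_um, "kind": mask.kind})
    )


def read_mask(
    path: str | Path,
    pixel_size_um: float | None = None,
    kind: str | None = None,
) -> BinaryMask:
    """Read a binary mask written by :func:`write_mask` (nonzero = true)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise PixelSizeError(f"pixel size unknown for mask {path}")
    k = kind if kind is not None else meta.get("kind", "tissue")
    if path.suffix.lower() == ".png":
        with Image.open(path) as img:
            arr = np.asarray(img.convert("L"))
    else:
        arr = tifffile.imread(path)
    return BinaryMask(pixels=arr > 0, pixel_size_um=float(px), kind=k)


# ---------------------------------------------------------------------------
# polygon export (GeoJSON, µm coordinates)
# ---------------------------------------------------------------------------


def _as_feature(region: Any) -> dict:
    """Build a GeoJSON feature from an AOI-like object or a bare polyline.

    Accepted inputs:

    * objects exposing ``polygon_um`` (N×2 array of (x, y) µm vertices) and
      optionally ``geojson_properties()``;
    * ``(coords, properties)`` pairs;
    * bare N×2 coordinate arrays (closed rings become Polygons, open
      polylines become LineStrings).
    """
    props: dict[str, Any] = {}
    if hasattr(region, "polygon_um"):
        coords = np.asarray(region.polygon_um, dtype=float)
        if hasattr(region, "geojson_properties"):
            props = dict(region.geojson_properties())
    elif isinstance(region, tuple) and len(region) == 2 and isinstance(region[1], dict):
        coords = np.asarray(region[0], dtype=float)
        props = dict(region[1])
    else:
        coords = np.asarray(region, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"expected N×2 µm coordinates, got shape {coords.shape}")

    closed = len(coords) >= 4 and np.allclose(coords[0], coords[-1])
    if closed:
        coords = coords.copy()
        coords[-1] = coords[0]  # snap exactly closed so shapely keeps the ring
        geom = Polygon(coords)
        props.setdefault("area_um2", float(geom.area))
    else:
        geom = LineString(coords)
        props.setdefault("length_um", float(geom.length))
    return {
        "type": "Feature",
        "geometry": geom.__geo_interface__,
        "properties": props,
    }


def export_polygons(regions: Iterable[Any], path: str | Path) -> None:
    """Write regions as a GeoJSON FeatureCollection with µm coordinates.

    An empty input produces a valid FeatureCollection with zero features.
    """
    features = [_as_feature(r) for r in regions]
    payload = {
        "type": "FeatureCollection",
        "features": features,
        "crs_note": "coordinates in micrometers; x = col*px, y = row*px",
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def import_polygons(path: str | Path) -> list[tuple[np.ndarray, dict]]:
    """Read a FeatureCollection back as (coords, properties) pairs."""
    payload = json.loads(Path(path).read_text())
    if payload.get("type") != "FeatureCollection":
        raise ValueError("not a GeoJSON FeatureCollection")
    out: list[tuple[np.ndarray, dict]] = []
    for feat in payload.get("features", []):
        geom = feat.get("geometry", {})
        gtype = geom.get("type")
        if gtype == "Polygon":
            coords = np.asarray(geom["coordinates"][0], dtype=float)
        elif gtype == "LineString":
            coords = np.asarray(geom["coordinates"], dtype=float)
        else:
            raise ValueError(f"unsupported geometry type {gtype!r}")
        out.append((coords, dict(feat.get("properties", {}))))
    return out
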