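"""Dermis and hypodermis thickness on skin sections.

Two thicknesses are measured, mirroring caliper measurements made on
oriented (epidermis-up) sections:

* dermis — mean vertical distance between the epidermal–dermal junction
  (EDJ) and the dermal–subcutaneous junction (DSJ);
* hypodermis — mean vertical distance between the DSJ and the top of the
  muscle layer (ML).

Measurements are taken in a fixed number of laterally non-overlapping
fields (default five, following common practice for this readout) placed
by a seeded RNG, so runs are bit-reproducible.  Thickness is per-column
vertical distance, not boundary-normal distance: inputs are assumed
orientation-normalized.

Automatic junction detection from raw stains is not attempted; inputs are
labeled layer masks or annotation polylines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .imgio import import_polygons

__all__ = [
    "SkinLayers",
    "ThicknessResult",
    "SKIN_LABELS",
    "layers_from_labeled_mask",
    "layers_from_geojson",
    "measure_thickness",
]

#: integer labels for the layered-mask input format (0 = background)
SKIN_LABELS = {"epidermis": 1, "dermis": 2, "hypodermis": 3, "muscle": 4}

_MEDIAN_WIDTH = 21  # px, boundary smoothing
_MAX_GAP_FRACTION = 0.05  # columns allowed to miss a label and be interpolated


@dataclass
class SkinLayers:
    """Three ordered layer boundaries sampled per column.

    ``x_um`` are lateral positions; ``edj_um``, ``dsj_um`` and ``ml_um``
    are boundary depths (µm from the image top), single-valued per column
    and satisfying EDJ ≤ DSJ ≤ ML everywhere.
    """

    x_um: np.ndarray
    edj_um: np.ndarray
    dsj_um: np.ndarray
    ml_um: np.ndarray
    source: str = "labeled_mask"

    def __post_init__(self) -> None:
        n = len(self.x_um)
        for name in ("edj_um", "dsj_um", "ml_um"):
            if len(getattr(self, name)) != n:
                raise ValueError("boundary arrays must share the lateral grid")
        if np.any(self.edj_um > self.dsj_um + 1e-6) or np.any(
            self.dsj_um > self.ml_um + 1e-6
        ):
            raise ValueError("layer ordering violated: require EDJ ≤ DSJ ≤ ML")

    @property
    def width_um(self) -> float:
        return float(self.x_um[-1] - self.x_um[0])


@dataclass
class ThicknessResult:
    dermis_um: float
    hypodermis_um: float
    n_fields: int
    per_field: list[tuple[tuple[float, float], float, float]]
    seed: int


def _interp_gaps(depths: np.ndarray, what: str) -> np.ndarray:
    """Linearly interpolate NaN columns; fail if too many are missing."""
    bad = ~np.isfinite(depths)
    if not bad.any():
        return depths
    if bad.mean() > _MAX_GAP_FRACTION:
        raise ValueError(
            f"{what}: {bad.mean():.1%} of columns lack the required label "
            f"(tolerance {_MAX_GAP_FRACTION:.0%})"
        )
    x = np.arange(len(depths))
    out = depths.copy()
    out[bad] = np.interp(x[bad], x[~bad], depths[~bad])
    return out


def layers_from_labeled_mask(mask: np.ndarray, pixel_size_um: float) -> SkinLayers:
    """Extract EDJ/DSJ/ML boundaries from a labeled layer raster.

    ``mask`` uses :data:`SKIN_LABELS` values; layers must run top-to-bottom
    (epidermis, dermis, hypodermis, muscle) in ≥ 95% of columns.  Each
    boundary is the first row of the deeper layer per column, interpolated
    through sparse gaps and smoothed with a width-21 median filter.
    A missing label class is an error.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("labeled mask must be 2-D")
    if not (pixel_size_um > 0):
        raise ValueError("pixel_size_um must be positive")
    for name, lab in SKIN_LABELS.items():
        if not (mask == lab).any():
            raise ValueError(f"labeled mask is missing the {name!r} class")

    ncols = mask.shape[1]
    bounds = {}
    for name in ("dermis", "hypodermis", "muscle"):
        lab = SKIN_LABELS[name]
        present = mask == lab
        first = np.where(present.any(axis=0), present.argmax(axis=0), np.nan).astype(
            float
        )
        first = _interp_gaps(first, f"{name} boundary")
        if ncols >= _MEDIAN_WIDTH:
            first = median_filter(first, size=_MEDIAN_WIDTH, mode="nearest")
        bounds[name] = first * pixel_size_um

    x_um = np.arange(ncols, dtype=float) * pixel_size_um
    return SkinLayers(
        x_um=x_um,
        edj_um=bounds["dermis"],
        dsj_um=bounds["hypodermis"],
        ml_um=bounds["muscle"],
        source="labeled_mask",
    )


_LAYER_KEYS = {"edj": "edj_um", "dsj": "dsj_um", "ml": "ml_um"}


def layers_from_geojson(
    path, pixel_size_um: float, n_columns: int | None = None
) -> SkinLayers:
    """Build SkinLayers from GeoJSON LineStrings with a ``layer`` property.

    Features must carry ``layer`` in {"edj", "dsj", "ml"}; coordinates are
    (x, y) µm.  Polylines are resampled onto a common per-column grid.
    """
    found: dict[str, np.ndarray] = {}
    for coords, props in import_polygons(path):
        layer = str(props.get("layer", "")).lower()
        if layer in _LAYER_KEYS:
            found[layer] = coords
    missing = set(_LAYER_KEYS) - set(found)
    if missing:
        raise ValueError(f"GeoJSON input is missing layer polylines: {sorted(missing)}")
    x_min = max(c[:, 0].min() for c in found.values())
    x_max = min(c[:, 0].max() for c in found.values())
    if n_columns is None:
        n_columns = max(2, int(round((x_max - x_min) / pixel_size_um)) + 1)
    x = np.linspace(x_min, x_max, n_columns)
    interp = {}
    for layer, coords in found.items():
        order = np.argsort(coords[:, 0])
        interp[layer] = np.interp(x, coords[order, 0], coords[order, 1])
    return SkinLayers(
        x_um=x,
        edj_um=interp["edj"],
        dsj_um=interp["dsj"],
        ml_um=interp["ml"],
        source="annotation",
    )


def _sample_fields(
    width_um: float, n_fields: int, field_width_um: float, rng: np.random.Generator
) -> np.ndarray:
    """Left edges of n non-overlapping fields, uniformly placed.

    Uses the spacings construction: draw the free slack uniformly, sort,
    and prepend cumulative field widths — exact non-overlap, no rejection.
    """
    free = width_um - n_fields * field_width_um
    if free < 0:
        raise ValueError(
            f"lateral extent {width_um:.0f} µm cannot hold {n_fields} "
            f"non-overlapping fields of {field_width_um:.0f} µm"
        )
    cuts = np.sort(rng.uniform(0.0, free, size=n_fields))
    return cuts + np.arange(n_fields) * field_width_um


def measure_thickness(
    layers: SkinLayers,
    n_fields: int = 5,
    field_width_um: float = 500.0,
    seed: int = 0,
) -> ThicknessResult:
    """Mean dermis and hypodermis thickness over randomly placed fields.

    Fields are ``n_fields`` non-overlapping windows of ``field_width_um``
    chosen by a seeded RNG; within each field the thickness is the mean
    per-column vertical distance between the bounding junctions, and the
    summary is the mean over fields.  Identical inputs and seed give
    bit-identical results.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if field_width_um <= 0:
        raise ValueError("field_width_um must be positive")
    rng = np.random.default_rng(seed)
    x0 = float(layers.x_um[0])
    starts = x0 + _sample_fields(layers.width_um, n_fields, field_width_um, rng)

    per_field = []
    for s in starts:
        sel = (layers.x_um >= s) & (layers.x_um < s + field_width_um)
        if not sel.any():  # extremely narrow field vs grid; take nearest column
            sel = np.zeros_like(sel)
            sel[np.argmin(np.abs(layers.x_um - s))] = True
        dermis = float(np.mean(layers.dsj_um[sel] - layers.edj_um[sel]))
        hypodermis = float(np.mean(layers.ml_um[sel] - layers.dsj_um[sel]))
        per_field.append(((float(s), float(s + field_width_um)), dermis, hypodermis))

    return ThicknessResult(
        dermis_um=float(np.mean([f[1] for f in per_field])),
        hypodermis_um=float(np.mean([f[2] for f in per_field])),
        n_fields=n_fields,
        per_field=per_field,
        seed=seed,
    )
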