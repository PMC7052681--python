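"""Shared synthetic fixtures (all generated at test time, no stored data)."""

from __future__ import annotations

import numpy as np
import pytest

from fibroframe import (
    BinaryMask,
    CalibratedImage,
    LungSynthParams,
    SkinSynthParams,
    StainModel,
    generate_lung_image,
    generate_skin_image,
)


def small_lung_params(**overrides) -> LungSynthParams:
    """A compact lung section that keeps unit tests fast."""
    kwargs = dict(
        canvas_px=(700, 700),
        lobe_radius_range_um=(550.0, 620.0),
        lumen_count=2,
        lumen_radius_range_um=(150.0, 220.0),
        focus_count=3,
        seed=11,
    )
    kwargs.update(overrides)
    return LungSynthParams(**kwargs)


@pytest.fixture(scope="session")
def lung_section():
    """(image, manifest) with three foci spanning the size-class boundary."""
    params = small_lung_params(focus_areas_um2=(5_000.0, 10_000.0, 20_000.0))
    return generate_lung_image(params)


@pytest.fixture(scope="session")
def skin_flat():
    return generate_skin_image(SkinSynthParams(seed=5))


@pytest.fixture(scope="session")
def skin_wavy():
    return generate_skin_image(
        SkinSynthParams(seed=5, waviness_amplitude_um=30.0)
    )


def disk_mask(
    radius_um: float, pixel_size_um: float = 1.0, pad_px: int = 30
) -> BinaryMask:
    """Filled disk tissue mask for analytic geometry oracles."""
    r_px = radius_um / pixel_size_um
    n = int(2 * r_px) + 2 * pad_px
    yy, xx = np.ogrid[:n, :n]
    c = n / 2
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= r_px**2
    return BinaryMask(pixels=mask, pixel_size_um=pixel_size_um, kind="tissue")


def paint_image(
    regions: dict[str, np.ndarray], pixel_size_um: float = 1.0
) -> CalibratedImage:
    """Compose an RGB image from loading masks, independent of synthgen.

    ``regions`` maps stain name ("collagen" | "cytoplasm" | "nuclei") to a
    boolean mask painted at OD 1.0; everything else stays background white.
    Quantized to uint8, no noise.
    """
    model = StainModel()
    order = {"collagen": 0, "cytoplasm": 1, "nuclei": 2}
    shape = next(iter(regions.values())).shape
    loadings = np.zeros(shape + (3,), dtype=float)
    for name, mask in regions.items():
        loadings[mask, order[name]] = 1.0
    od = loadings @ model.stain_vectors
    rgb = np.clip(np.round(255.0 * 10.0 ** (-od)), 0, 255).astype(np.uint8)
    return CalibratedImage(pixels=rgb, pixel_size_um=pixel_size_um, source_id="painted")
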