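"""Whole-section collagen content as a fraction of tissue area.

The denominator is the stained-tissue mask with only small internal holes
filled (finite cap, default 5×10⁴ µm²), so alveolar lumens count as tissue
texture while large airways and air spaces stay out of the denominator.
This differs deliberately from the band construction, which fills all
holes so the band anchors only to the pleural edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import CalibratedImage
from .stainseg import SegParams, StainModel, collagen_mask, tissue_mask

__all__ = ["CollagenResult", "collagen_fraction", "COLLAGEN_HOLE_FILL_UM2"]

#: default hole-fill cap for the tissue denominator (large airways excluded)
COLLAGEN_HOLE_FILL_UM2 = 5e4


@dataclass
class CollagenResult:
    collagen_area_um2: float
    tissue_area_um2: float
    collagen_fraction: float


def collagen_fraction(
    image: CalibratedImage,
    model: StainModel | None = None,
    params: SegParams | None = None,
) -> CollagenResult:
    """Collagen area / tissue area on a trichrome section.

    If ``params`` is not given, segmentation defaults are used with the
    finite hole-fill cap appropriate for an area denominator.  A section
    with no detectable tissue is an error.
    """
    model = model or StainModel()
    if params is None:
        params = SegParams(hole_fill_max_um2=COLLAGEN_HOLE_FILL_UM2)
    tissue = tissue_mask(image, params)
    t_area = tissue.area_um2()
    if t_area <= 0:
        raise ValueError("no tissue detected; collagen fraction undefined")
    collagen = collagen_mask(image, tissue, model, params)
    c_area = collagen.area_um2()
    return CollagenResult(
        collagen_area_um2=c_area,
        tissue_area_um2=t_area,
        collagen_fraction=c_area / t_area,
    )
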