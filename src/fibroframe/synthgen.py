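"""Synthetic trichrome-like lung sections and layered skin images with
exact ground truth.

No public image archive accompanies this kind of histomorphometry, so the
package validates itself on synthetic sections that emulate the relevant
structure of Masson-trichrome slides: lung-shaped tissue (perturbed
ellipses) with punched airway/vessel lumens, subpleural collagen foci of
controlled rendered area and depth, Light-Green / red / hematoxylin
coloring via the same Beer–Lambert stain vectors the segmentation module
uses by default, and Gaussian camera noise.  Skin images are layered bands
(epidermis / dermis / hypodermis / muscle) with controlled thicknesses and
optional boundary waviness.

Ground truth is recorded post-rasterization: a planted focus "area" is the
count of rendered pixels times the pixel area, never the analytic blob
area, so recovery tests have an exact target.  All randomness flows from a
single seeded generator; identical parameters and seed give byte-identical
images and manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy import ndimage
from skimage import draw, morphology

from .imgio import BinaryMask, CalibratedImage
from .stainseg import REFERENCE_STAIN_OD

__all__ = [
    "LungSynthParams",
    "SkinSynthParams",
    "FocusRecord",
    "SyntheticManifest",
    "generate_lung_image",
    "generate_skin_image",
]

GENERATOR_VERSION = "1.0"

# OD loadings used when painting synthetic pixels (collagen, cytoplasm, nuclei)
_OD_COLLAGEN = 1.0
_OD_CYTOPLASM = 0.9
_OD_NUCLEI = 0.8


@dataclass
class LungSynthParams:
    """Conditions for one synthetic lung section.

    Defaults emulate a mouse lung section with mild, subpleurally confined
    fibrosis: a single lobe about 2 mm across at 2 µm/px, a few large
    airway/vessel lumens, and six collagen foci spanning the small/large
    class boundary, planted at center depths that keep each focus entirely
    within a 250 µm subpleural band.  Background parenchymal collagen
    defaults to zero (mild disease); the collagen-content scenarios plant
    explicit fractions instead.
    """

    canvas_px: tuple[int, int] = (1200, 1200)
    pixel_size_um: float = 2.0
    n_lobes: int = 1
    lobe_radius_range_um: tuple[float, float] = (900.0, 1100.0)
    lobe_perturb_frac: float = 0.06
    lumen_count: int = 4
    lumen_radius_range_um: tuple[float, float] = (150.0, 300.0)
    focus_count: int = 6
    focus_area_range_um2: tuple[float, float] = (2_000.0, 20_000.0)
    focus_areas_um2: tuple[float, ...] | None = None  # explicit targets override
    focus_depth_range_um: tuple[float, float] = (90.0, 150.0)
    focus_perturb_frac: float = 0.10
    focus_gap_px: int = 6
    frame_depth_um: float = 250.0
    avoid_frame_straddle: bool = True
    target_frame_fraction: float | None = None
    background_collagen_fraction: float = 0.0
    nuclei_per_mm2: float = 400.0
    color_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rng_pair in (
            self.lobe_radius_range_um,
            self.lumen_radius_range_um,
            self.focus_area_range_um2,
            self.focus_depth_range_um,
        ):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError(f"range {rng_pair} must be ordered (min, max)")
        if not 0.0 <= self.background_collagen_fraction <= 1.0:
            raise ValueError("background_collagen_fraction must be in [0, 1]")
        if self.target_frame_fraction is not None and not (
            0.0 <= self.target_frame_fraction < 1.0
        ):
            raise ValueError("target_frame_fraction must be in [0, 1)")
        if self.color_noise_sd < 0:
            raise ValueError("color_noise_sd must be non-negative")


@dataclass
class SkinSynthParams:
    """Conditions for one synthetic skin section (epidermis-up).

    Default layer thicknesses approximate mouse gluteal skin: 50 µm
    epidermis, 300 µm dermis, 150 µm hypodermis (dermal white adipose),
    250 µm muscle.  Waviness perturbs the boundaries sinusoidally; in
    "shared" mode all boundaries undulate together (parallel layers, the
    usual appearance of sectioned skin) so per-column thickness stays at
    the planted value, while "independent" mode gives each boundary its
    own phase so thickness varies laterally around a mean-preserving
    waveform.
    """

    canvas_px: tuple[int, int] = (700, 2600)
    pixel_size_um: float = 2.0
    top_margin_um: float = 60.0
    epidermis_um: float = 50.0
    dermis_um: float = 300.0
    hypodermis_um: float = 150.0
    muscle_um: float = 250.0
    waviness_amplitude_um: float = 0.0
    waviness_wavelength_um: float = 800.0
    waviness_mode: str = "shared"
    color_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epidermis_um", "dermis_um", "hypodermis_um", "muscle_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.waviness_mode not in ("shared", "independent"):
            raise ValueError("waviness_mode must be 'shared' or 'independent'")
        total = (
            self.top_margin_um
            + self.epidermis_um
            + self.dermis_um
            + self.hypodermis_um
            + self.muscle_um
            + self.waviness_amplitude_um
        )
        if total >= self.canvas_px[0] * self.pixel_size_um:
            raise ValueError("planted layer depths exceed the canvas height")


@dataclass
class FocusRecord:
    """Ground truth for one planted focus (areas are rendered-pixel exact)."""

    id: int
    center_rc: tuple[int, int]
    center_um: tuple[float, float]
    area_um2: float
    center_depth_um: float
    min_depth_um: float
    max_depth_um: float


@dataclass
class SyntheticManifest:
    """Ground truth emitted alongside a synthetic image.

    Lung sections populate the mask/foci fields; skin images populate the
    boundary fields.  Arrays live in memory; :meth:`summary` returns the
    JSON-serializable part.
    """

    seed: int
    pixel_size_um: float
    kind: str  # "lung" | "skin"
    generator_version: str = GENERATOR_VERSION
    # lung
    tissue_mask: np.ndarray | None = None  # stained tissue (lumens open)
    filled_tissue_mask: np.ndarray | None = None
    lumen_mask: np.ndarray | None = None
    collagen_mask: np.ndarray | None = None  # all planted collagen incl. foci
    foci_labels: np.ndarray | None = None
    foci: list[FocusRecord] = field(default_factory=list)
    collagen_fraction: float | None = None  # planted collagen / tissue pixels
    frame_depth_um: float | None = None
    frame_mask: np.ndarray | None = None  # planted band on filled tissue
    frame_area_um2: float | None = None
    lung_area_um2: float | None = None
    aoi_frame_fraction: float | None = None  # planted Σ focus area / band area
    # skin
    boundary_rows_um: dict[str, np.ndarray] | None = None  # edj/dsj/ml per column
    planted_dermis_um: float | None = None
    planted_hypodermis_um: float | None = None

    def summary(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "seed": self.seed,
            "pixel_size_um": self.pixel_size_um,
            "kind": self.kind,
            "generator_version": self.generator_version,
        }
        for key in (
            "collagen_fraction",
            "frame_depth_um",
            "frame_area_um2",
            "lung_area_um2",
            "aoi_frame_fraction",
            "planted_dermis_um",
            "planted_hypodermis_um",
        ):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        if self.foci:
            out["foci"] = [asdict(f) for f in self.foci]
        return out


# ---------------------------------------------------------------------------
# shared rendering
# ---------------------------------------------------------------------------


def _render(
    loadings: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stain loadings (H, W, 3) → noisy uint8 RGB via Beer–Lambert."""
    od = loadings @ _unit_stains()
    od *= -np.log(10.0)
    rgb = np.exp(od, out=od)
    rgb *= 255.0
    if noise_sd > 0:
        rgb += rng.normal(0.0, noise_sd, size=rgb.shape)
    np.clip(rgb, 0, 255, out=rgb)
    return np.round(rgb, out=rgb).astype(np.uint8)


def _unit_stains() -> np.ndarray:
    m = REFERENCE_STAIN_OD
    return m / np.linalg.norm(m, axis=1)[:, None]


def _perturbed_disk(
    center_rc: tuple[float, float],
    radius_px: float,
    perturb_frac: float,
    shape: tuple[int, int],
    rng: np.random.Generator,
    n_vertices: int = 180,
) -> np.ndarray:
    """Rasterize a radially perturbed disk (low-order harmonic boundary).

    The region is star-shaped around its center, so it is filled directly
    in polar form: a pixel belongs to the blob iff its radius is below the
    boundary radius interpolated at its angle.
    """
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.full_like(theta, radius_px)
    if perturb_frac > 0:
        for k in (2, 3, 5):
            amp = rng.uniform(0, perturb_frac / 3) * radius_px
            phase = rng.uniform(0, 2 * np.pi)
            r = r + amp * np.cos(k * theta + phase)
    r = np.maximum(r, 0.0)
    max_r = float(r.max())
    r0, c0 = center_rc
    lo_r = max(int(np.floor(r0 - max_r)) - 1, 0)
    hi_r = min(int(np.ceil(r0 + max_r)) + 2, shape[0])
    lo_c = max(int(np.floor(c0 - max_r)) - 1, 0)
    hi_c = min(int(np.ceil(c0 + max_r)) + 2, shape[1])
    mask = np.zeros(shape, dtype=bool)
    if lo_r >= hi_r or lo_c >= hi_c:
        return mask
    rr, cc = np.meshgrid(
        np.arange(lo_r, hi_r, dtype=float),
        np.arange(lo_c, hi_c, dtype=float),
        indexing="ij",
    )
    dr, dc = rr - r0, cc - c0
    ang = np.mod(np.arctan2(dr, dc), 2 * np.pi)
    r_bound = np.interp(ang, theta, r, period=2 * np.pi)
    mask[lo_r:hi_r, lo_c:hi_c] = dr**2 + dc**2 <= r_bound**2
    return mask


def _dilate_local(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Binary dilation restricted to the mask's padded bounding box."""
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return mask.copy()
    pad = se.shape[0] // 2 + 1
    lo_r, hi_r = max(rows.min() - pad, 0), min(rows.max() + pad + 1, mask.shape[0])
    lo_c, hi_c = max(cols.min() - pad, 0), min(cols.max() + pad + 1, mask.shape[1])
    out = np.zeros_like(mask)
    out[lo_r:hi_r, lo_c:hi_c] = ndimage.binary_dilation(
        mask[lo_r:hi_r, lo_c:hi_c], structure=se
    )
    return out


# ---------------------------------------------------------------------------
# lung
# ---------------------------------------------------------------------------


def _place_lobes(
    params: LungSynthParams, rng: np.random.Generator
) -> np.ndarray:
    shape = params.canvas_px
    px = params.pixel_size_um
    mask = np.zeros(shape, dtype=bool)
    margin = 4  # px kept clear of the canvas edge
    for _ in range(params.n_lobes):
        radius_px = rng.uniform(*params.lobe_radius_range_um) / px
        max_r = radius_px * (1 + params.lobe_perturb_frac)
        lo_r, hi_r = max_r + margin, shape[0] - max_r - margin
        lo_c, hi_c = max_r + margin, shape[1] - max_r - margin
        if lo_r >= hi_r or lo_c >= hi_c:
            raise ValueError(
                f"lobe of radius {radius_px:.0f} px does not fit the canvas"
            )
        center = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        mask |= _perturbed_disk(
            center, radius_px, params.lobe_perturb_frac, shape, rng, n_vertices=720
        )
    return mask


def _punch_lumens(
    tissue: np.ndarray, params: LungSynthParams, rng: np.random.Generator
) -> np.ndarray:
    px = params.pixel_size_um
    lumens = np.zeros_like(tissue)
    if params.lumen_count == 0:
        return lumens
    edt = ndimage.distance_transform_edt(tissue)
    for _ in range(params.lumen_count):
        r_px = rng.uniform(*params.lumen_radius_range_um) / px
        candidates = np.argwhere(edt > r_px + 5)
        if len(candidates) == 0:
            continue  # lobe too small for this lumen; skip
        center = candidates[rng.integers(len(candidates))]
        rr, cc = draw.disk(tuple(center), r_px, shape=tissue.shape)
        lumens[rr, cc] = True
    return lumens & tissue


def _plant_focus(
    depth_um: np.ndarray,
    allowed: np.ndarray,
    blocked: np.ndarray,
    params: LungSynthParams,
    rng: np.random.Generator,
    target_area_um2: float | None = None,
) -> np.ndarray | None:
    """Try once to rasterize a focus honoring depth, containment and gap."""
    px = params.pixel_size_um
    if target_area_um2 is None:
        target_area_um2 = rng.uniform(*params.focus_area_range_um2)
    target_area = target_area_um2
    d = rng.uniform(*params.focus_depth_range_um)
    r_px = np.sqrt(target_area / np.pi) / px
    ring = allowed & (np.abs(depth_um - d) <= px)
    candidates = np.argwhere(ring)
    if len(candidates) == 0:
        return None
    center = candidates[rng.integers(len(candidates))]
    blob = _perturbed_disk(
        tuple(center), r_px, params.focus_perturb_frac, allowed.shape, rng
    )
    if not blob.any() or (blob & ~allowed).any() or (blob & blocked).any():
        return None
    if params.avoid_frame_straddle:
        depths = depth_um[blob]
        inside = depths.max() <= params.frame_depth_um - px
        outside = depths.min() > params.frame_depth_um + px
        if not (inside or outside):
            return None
    return blob


def _plant_background_collagen(
    tissue: np.ndarray,
    exclude: np.ndarray,
    fraction: float,
    px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Plant collagen blobs over ``tissue`` (minus exclusions) until the
    requested pixel fraction of tissue is reached exactly (last blob is
    trimmed in raster order)."""
    collagen = np.zeros_like(tissue)
    tissue_px = int(tissue.sum())
    target_px = int(round(fraction * tissue_px))
    if target_px <= 0:
        return collagen
    allowed = tissue & ~exclude
    if fraction >= 1.0:
        return allowed.copy()
    candidates = np.argwhere(allowed)
    attempts = 0
    while collagen.sum() < target_px and attempts < 10_000:
        attempts += 1
        center = candidates[rng.integers(len(candidates))]
        r_px = rng.uniform(20.0, 60.0)
        blob = _perturbed_disk(tuple(center), r_px, 0.1, tissue.shape, rng)
        new = blob & allowed & ~collagen
        excess = int(collagen.sum() + new.sum()) - target_px
        if excess > 0:
            idx = np.flatnonzero(new.ravel())
            new = new.copy()
            new.ravel()[idx[len(idx) - excess :]] = False
        collagen |= new
    return collagen


def generate_lung_image(
    params: LungSynthParams | None = None,
) -> tuple[CalibratedImage, SyntheticManifest]:
    """Render one synthetic trichrome lung section with ground truth.

    Raises ``RuntimeError`` if focus placement is infeasible after bounded
    retries (areas/depths that do not fit the lobes).
    """
    params = params or LungSynthParams()
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size_um
    shape = params.canvas_px

    tissue_full = _place_lobes(params, rng)  # lobes, lumens not yet punched
    filled = ndimage.binary_fill_holes(tissue_full)
    lumens = _punch_lumens(tissue_full, params, rng)
    tissue = tissue_full & ~lumens

    depth_um = ndimage.distance_transform_edt(filled) * px
    frame_mask = filled & (depth_um > 0) & (depth_um <= params.frame_depth_um)
    frame_area_um2 = float(frame_mask.sum()) * px**2
    lung_area_um2 = float(tissue.sum()) * px**2

    # --- plant foci ---------------------------------------------------------
    foci_labels = np.zeros(shape, dtype=np.int32)
    foci: list[FocusRecord] = []
    blocked = np.zeros(shape, dtype=bool)
    gap_se = morphology.disk(params.focus_gap_px)
    explicit_areas = params.focus_areas_um2
    if params.target_frame_fraction is not None:
        target_area_um2 = params.target_frame_fraction * frame_area_um2
        want = None
    else:
        target_area_um2 = None
        want = len(explicit_areas) if explicit_areas is not None else params.focus_count
    planted_area = 0.0
    attempts, max_attempts = 0, 400 * max(want or 1, 8)

    def _need_more() -> bool:
        if target_area_um2 is not None:
            return planted_area < target_area_um2
        return len(foci) < want

    while _need_more():
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "focus placement infeasible: could not fit the requested foci "
                "after bounded retries"
            )
        area_target = (
            explicit_areas[len(foci)] if explicit_areas is not None else None
        )
        blob = _plant_focus(depth_um, tissue, blocked, params, rng, area_target)
        if blob is None:
            continue
        fid = len(foci) + 1
        foci_labels[blob] = fid
        blocked |= _dilate_local(blob, gap_se)
        area_um2 = float(blob.sum()) * px**2
        planted_area += area_um2
        rows, cols = np.nonzero(blob)
        cr, cc = float(rows.mean()), float(cols.mean())
        depths = depth_um[rows, cols]
        foci.append(
            FocusRecord(
                id=fid,
                center_rc=(int(round(cr)), int(round(cc))),
                center_um=(cc * px, cr * px),
                area_um2=area_um2,
                center_depth_um=float(depth_um[int(round(cr)), int(round(cc))]),
                min_depth_um=float(depths.min()),
                max_depth_um=float(depths.max()),
            )
        )

    foci_mask = foci_labels > 0

    # --- background collagen ------------------------------------------------
    background = _plant_background_collagen(
        tissue, blocked | foci_mask, params.background_collagen_fraction, px, rng
    )
    collagen = foci_mask | background

    # --- paint --------------------------------------------------------------
    loadings = np.zeros(shape + (3,), dtype=float)
    loadings[tissue, 1] = _OD_CYTOPLASM
    loadings[collagen, 1] = 0.0
    loadings[collagen, 0] = _OD_COLLAGEN
    # nuclei: small dark speckles added on top of either stain
    area_mm2 = tissue.sum() * px**2 / 1e6
    n_nuclei = rng.poisson(params.nuclei_per_mm2 * area_mm2)
    if n_nuclei > 0:
        tissue_idx = np.argwhere(tissue)
        centers = tissue_idx[rng.integers(len(tissue_idx), size=n_nuclei)]
        nuc = np.zeros(shape, dtype=bool)
        for r, c in centers:
            rr, cc = draw.disk((r, c), rng.uniform(1.5, 3.0), shape=shape)
            nuc[rr, cc] = True
        nuc &= tissue
        loadings[nuc, 2] = _OD_NUCLEI

    image = CalibratedImage(
        pixels=_render(loadings, params.color_noise_sd, rng),
        pixel_size_um=px,
        source_id=f"synthetic-lung-seed{params.seed}",
    )
    manifest = SyntheticManifest(
        seed=params.seed,
        pixel_size_um=px,
        kind="lung",
        tissue_mask=tissue,
        filled_tissue_mask=filled,
        lumen_mask=lumens,
        collagen_mask=collagen,
        foci_labels=foci_labels,
        foci=foci,
        collagen_fraction=float(collagen.sum()) / max(int(tissue.sum()), 1),
        frame_depth_um=params.frame_depth_um,
        frame_mask=frame_mask,
        frame_area_um2=frame_area_um2,
        lung_area_um2=lung_area_um2,
        aoi_frame_fraction=planted_area / frame_area_um2 if frame_area_um2 else 0.0,
    )
    return image, manifest


# ---------------------------------------------------------------------------
# skin
# ---------------------------------------------------------------------------

# per-layer stain loadings (collagen, cytoplasm, nuclei)
_SKIN_LOADINGS = {
    "epidermis": (0.0, 0.7, 0.5),
    "dermis": (1.0, 0.0, 0.0),  # collagen-rich -> Light Green
    "hypodermis": (0.0, 0.25, 0.0),  # adipose, pale
    "muscle": (0.0, 1.0, 0.0),
}


def generate_skin_image(
    params: SkinSynthParams | None = None,
) -> tuple[CalibratedImage, np.ndarray, SyntheticManifest]:
    """Render a layered synthetic skin section.

    Returns the RGB image, the labeled layer mask (:data:`SKIN_LABELS`
    values from :mod:`fibroframe.skin`) and a manifest whose
    ``boundary_rows_um`` holds the exact per-column EDJ/DSJ/ML depths of
    the labeled mask.
    """
    params = params or SkinSynthParams()
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size_um
    rows, cols = params.canvas_px
    x_um = np.arange(cols) * px

    if params.waviness_amplitude_um > 0:
        k = 2 * np.pi / params.waviness_wavelength_um
        if params.waviness_mode == "shared":
            phase = rng.uniform(0, 2 * np.pi)
            waves = {
                name: params.waviness_amplitude_um * np.sin(k * x_um + phase)
                for name in ("top", "edj", "dsj", "ml", "bottom")
            }
        else:
            waves = {
                name: params.waviness_amplitude_um
                * np.sin(k * x_um + rng.uniform(0, 2 * np.pi))
                for name in ("top", "edj", "dsj", "ml", "bottom")
            }
    else:
        # consume the same RNG stream so amplitude 0 vs >0 share geometry draws
        _ = rng.uniform(0, 2 * np.pi)
        waves = {name: np.zeros(cols) for name in ("top", "edj", "dsj", "ml", "bottom")}

    top = params.top_margin_um + waves["top"]
    edj = top + params.epidermis_um + (waves["edj"] - waves["top"])
    dsj = edj + params.dermis_um + (waves["dsj"] - waves["edj"])
    ml = dsj + params.hypodermis_um + (waves["ml"] - waves["dsj"])
    bottom = ml + params.muscle_um + (waves["bottom"] - waves["ml"])

    # rasterize: label = band the row center falls in, per column
    row_um = (np.arange(rows, dtype=float)[:, None]) * px
    labeled = np.zeros((rows, cols), dtype=np.uint8)
    labeled[(row_um >= top) & (row_um < edj)] = 1
    labeled[(row_um >= edj) & (row_um < dsj)] = 2
    labeled[(row_um >= dsj) & (row_um < ml)] = 3
    labeled[(row_um >= ml) & (row_um < bottom)] = 4

    # exact per-column boundary rows of the rasterized mask
    def _first_row(lab: int) -> np.ndarray:
        present = labeled == lab
        return np.where(present.any(axis=0), present.argmax(axis=0), np.nan) * px

    boundary = {"edj": _first_row(2), "dsj": _first_row(3), "ml": _first_row(4)}

    loadings = np.zeros((rows, cols, 3), dtype=float)
    for name, lab in (("epidermis", 1), ("dermis", 2), ("hypodermis", 3), ("muscle", 4)):
        loadings[labeled == lab] = _SKIN_LOADINGS[name]

    image = CalibratedImage(
        pixels=_render(loadings, params.color_noise_sd, rng),
        pixel_size_um=px,
        source_id=f"synthetic-skin-seed{params.seed}",
    )
    manifest = SyntheticManifest(
        seed=params.seed,
        pixel_size_um=px,
        kind="skin",
        boundary_rows_um=boundary,
        planted_dermis_um=float(np.nanmean(boundary["dsj"] - boundary["edj"])),
        planted_hypodermis_um=float(np.nanmean(boundary["ml"] - boundary["dsj"])),
    )
    return image, labeled, manifest
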