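# Methods

This note describes the models and procedures implemented in `fibroframe`,
the parameter defaults and why they were chosen, the synthetic data used
for validation, and the known limitations.

## Problem setting

In low-dose bleomycin pump models of systemic sclerosis, lung lesions are
mild and concentrated in a thin subpleural rim; whole-section collagen
percentages dilute the signal over mostly normal parenchyma. The package
therefore restricts quantification to a band of fixed physical depth
under the pleural surface and characterizes the collagen-dense foci
inside it. All quantities are physical (µm, µm²), so a calibrated,
isotropic pixel size is mandatory; anisotropic inputs are rejected
because every downstream metric is an area.

## Tissue segmentation

Stained tissue is separated from the white background and air spaces by
an HSV saturation threshold (default 0.10 — stained tissue is strongly
chromatic, background and lumens are near-white), followed by removal of
objects under 1,000 µm² (debris) and bounded hole filling. A hole is a
background component not touching the image border; border-connected
background is never filled. Two hole-filling regimes are used on purpose:

* **Band construction** fills *all* internal holes (cap = ∞), so the band
  is anchored only to the pleural edge; otherwise a large airway near the
  pleura would spawn a spurious band around itself.
* **Collagen denominator** uses a finite cap (5×10⁴ µm²): alveolar-scale
  lumens count as tissue texture, while large airways and vessels stay
  out of the area denominator.

## Stain separation

Collagen is isolated by Beer–Lambert color deconvolution in the style of
Ruifrok & Johnston: per-pixel optical density `OD = −log10(I/I₀)` (I₀ =
reference white, default 255 per channel) is decomposed onto three unit
stain-absorbance vectors — Light Green (collagen), the red cytoplasm
stain, and hematoxylin — by inverting the 3×3 stain matrix; negative
projections are clipped to zero. The default matrix is the constant set
shared with the synthetic generator, which makes the default pipeline
self-consistent on synthetic data by construction; for real scanners the
nine numbers are supplied through the config file. Automatic stain-vector
estimation (Macenko-style) and cross-scanner color normalization are out
of scope. An HSV hue-band fallback (hue 70–180°, saturation-weighted) is
selectable for images whose stain vectors are unknown.

Intensities are floored at 1/512 before the logarithm so that saturated
dark pixels do not produce infinities while stain mixtures up to ~2 OD
per stain remain exactly invertible; the forward-synthesis → deconvolution
round trip is accurate to ~1e-15 in floating point and ~4e-3 after 8-bit
quantization.

The collagen mask is the thresholded collagen loading (default 0.30 OD,
or Otsu computed over tissue pixels only) intersected with the tissue
mask, minus objects under 50 µm² (sub-cellular specks). Bronchial
epithelium is excluded by the stain threshold itself (it is red/purple,
not green), not by an explicit epithelium segmentation.

## Subpleural band ("Frame")

The band of depth *d* (default 250 µm) is the Euclidean
distance-transform level set `0 < EDT·px ≤ d` on the hole-filled tissue,
computed per connected component of at least 10⁵ µm² (smaller fragments
are debris and are excluded from both band and lung-area denominator).
The level set is the exact offset curve for smooth boundaries and remains
well defined at concavities, where polygon offsetting self-intersects —
that is why a raster distance transform was chosen over a vector offset.
The pleural edge pixel row itself is included by default
(`include_boundary`, exposed as a flag). If tissue is thinner than *d*
the band saturates to the whole component. Pleural contours are extracted
by marching squares on each filled component and smoothed with a 7-point
periodic moving average, which removes pixel-staircase bias (a raw
marching-squares contour overestimates a circle's perimeter by ~5%; the
smoothed one is within ~0.2%).

Validation: for disks of radius 300–2,000 µm at 0.5–2 µm/px the band area
matches the analytic annulus `π(R² − (R−d)²)` within 1% (typically
0.02%), the maximum band depth equals the configured depth within one
pixel, the band is monotone in depth, and planting internal holes of any
size leaves it bit-identical.

## Fibrotic foci (AOI)

The fibrosis mask is the thresholded collagen loading restricted to the
band, opened with a radius-1 disk (breaks hairline bridges between
adjacent foci; a consequence is that single-pixel protrusions and sharp
raster corners are treated as noise), then labeled at 8-connectivity
(configurable to 4). Components under 100 µm² (≈ a few cells) are
discarded as noise. Each surviving component becomes one AOI with its
clipped-to-band area, centroid, pleural depth range, and size class:
small iff area ≤ 7,500 µm² (inclusive), large otherwise. A focus
straddling the inner band edge is clipped and its clipped area measured.

The detection is fully automatic; for parity with semiautomatic curation
workflows the CLI accepts an explicit exclude-list of AOI ids, which is
logged as an audit trail rather than applied silently.

Per-section metrics: `n_foci`; `foci_per_mm2_lung = n / (lung area in
mm²)` with lung area the tissue area of retained components;
`ΣAOI/Frame = Σ area / band area` (the headline fraction); the
lung-normalized variant; and the small/large tally.

## Collagen content

Whole-section collagen fraction = collagen-mask area / tissue-mask area,
with the finite hole-fill denominator described above. Reported as
`collagen_pct = 100 × fraction`.

## Skin thickness

Dermis thickness is the mean vertical (per-column) distance between the
epidermal–dermal junction and the dermal–subcutaneous junction;
hypodermis thickness between the latter and the muscle-layer top.
Vertical rather than boundary-normal distance mirrors on-screen caliper
measurements between junctions on orientation-normalized (epidermis-up)
sections; a rotation flag is provided. Boundaries come from labeled layer
masks (per-column first-row transitions, linear interpolation through
label gaps in < 5% of columns, width-21 median smoothing) or from GeoJSON
polylines resampled to a per-column grid; automatic junction detection
from raw stains is deliberately not attempted.

Measurement uses five non-overlapping fields of 500 µm (both
configurable), placed by a seeded RNG using the spacings construction
(draw the free slack uniformly, sort, prepend cumulative field widths),
which guarantees exact non-overlap without rejection sampling and makes
runs bit-reproducible. Whether fields may overlap is not standardized in
this kind of readout; non-overlap was chosen as the stricter convention.

## Ashcroft bookkeeping

Field scores are validated as integers in [0, 8]; a sample's mean score
may be fractional and is reported separately. Severity classes (mild 0–3,
moderate 4, severe 5–8) are applied to individual integer field scores,
never to fractional means — passing a fractional value raises an error
that points at the distinction. Frequency tables count field scores per
group (the frame's metadata records this convention, since counting over
per-animal means is the plausible alternative). Group-comparison
statistics (ANOVA, chi-squared, …) are delegated to scipy through the
report command and are not re-implemented.

## Synthetic data generator

The generator emulates the features of trichrome slides that the pipeline
actually consumes:

* **Lung**: one or more lobes as radially perturbed disks (low-order
  harmonics, ±6%), punched with 150–300 µm airway/vessel lumens; collagen
  foci rasterized as perturbed blobs at controlled center depth (default
  90–150 µm, keeping each focus entirely inside a 250 µm band) and target
  area (default 2,000–20,000 µm², spanning the small/large boundary);
  colors synthesized through the same Beer–Lambert stain matrix the
  segmentation uses by default, nuclei as additive hematoxylin speckle,
  Gaussian camera noise (σ = 3 grey levels). Defaults model a mouse
  section ~2 mm across at 2 µm/px with six foci and no diffuse
  parenchymal collagen (mild disease); collagen-content scenarios plant
  explicit fractions instead, trimming the final blob so the planted
  pixel fraction is exact. A target-ΣAOI/Frame mode plants foci until a
  prescribed band fraction is reached, for calibration studies.
* **Skin**: horizontal layer bands (defaults 50/300/150/250 µm for
  epidermis/dermis/hypodermis/muscle, approximating mouse gluteal skin)
  with optional sinusoidal waviness. In the default "shared" mode all
  boundaries undulate together — the usual appearance of sectioned skin —
  so planted thickness is constant per column; an "independent" mode
  gives each boundary its own phase for stress-testing field sampling.

Ground truth is recorded *post-rasterization*: a planted focus area is
the count of rendered pixels × pixel area, never the analytic blob area,
so recovery tests have an exact target. All randomness flows from one
seeded generator; identical parameters and seed yield byte-identical
images and manifests.

What passing on synthetic data does **not** show: robustness to real
stain variability between batches and scanners, out-of-focus regions,
tissue folds and torn edges, anisotropic compression artifacts, or
genuinely ambiguous fibrosis boundaries. The synthetic colors are exactly
the default stain model, so synthetic recovery validates geometry,
bookkeeping and thresholds — not stain-vector estimation, which the
package intentionally leaves to explicit configuration.

## Numerical choices

* Working resolution: batch analysis picks the coarsest pyramid level
  with pixel size ≤ 2 µm (a 250 µm band then has ≥ 125 px of radial
  support); overridable per run.
* Validation problem sizes: unit tests use ~1.4–2 mm synthetic sections
  at 2 µm/px; the recovery study uses 50 sections with per-section target
  band fractions drawn uniformly in [0.02, 0.15], matching the range this
  kind of model produces in vivo.
* Size classes use an inclusive ≤ at 7,500 µm²; at 1 µm²/px a single
  added pixel flips the class.
* CSV floats are printed at six significant digits so reruns are
  byte-stable; every output carries the config hash and package version.
* Degenerate inputs: an all-background image yields an empty tissue mask
  (not an error); an empty band yields zero metrics; a zero-tissue
  section makes the collagen fraction undefined and raises.

## Known limitations

* True pleura vs cut/torn tissue edges are not distinguished; both
  contribute band.
* Bronchial epithelium is excluded only insofar as it is not green under
  the stain threshold.
* The small/large area threshold and band depth are biological
  conventions taken as fixed defaults, not fitted quantities.
* Skin thickness assumes single-valued layer boundaries per lateral
  position (no folds or re-entrant junctions).
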