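"""Skin-layer boundary extraction and field-sampled thickness measurement."""

import numpy as np
import pytest

from fibroframe import (
    SkinSynthParams,
    generate_skin_image,
    layers_from_geojson,
    layers_from_labeled_mask,
    measure_thickness,
    export_polygons,
)
from fibroframe.skin import SKIN_LABELS, SkinLayers


def _flat_layers(width_um=5000.0, dermis=300.0, hypo=150.0, n=2500):
    x = np.linspace(0, width_um, n)
    edj = np.full(n, 100.0)
    return SkinLayers(
        x_um=x, edj_um=edj, dsj_um=edj + dermis, ml_um=edj + dermis + hypo
    )


class TestLayersFromMask:
    def test_flat_bands_boundaries_at_planted_rows(self, skin_flat):
        _, labels, manifest = skin_flat
        layers = layers_from_labeled_mask(labels, manifest.pixel_size_um)
        for key, arr in (
            ("edj", layers.edj_um), ("dsj", layers.dsj_um), ("ml", layers.ml_um)
        ):
            planted = manifest.boundary_rows_um[key]
            assert np.nanmax(np.abs(arr - planted)) <= manifest.pixel_size_um

    def test_small_gaps_interpolated(self, skin_flat):
        _, labels, manifest = skin_flat
        corrupted = labels.copy()
        # erase the hypodermis label in 1% of columns
        cols = np.arange(0, corrupted.shape[1], 100)
        for c in cols:
            corrupted[corrupted[:, c] == SKIN_LABELS["hypodermis"], c] = 0
        layers = layers_from_labeled_mask(corrupted, manifest.pixel_size_um)
        planted = manifest.boundary_rows_um["dsj"]
        assert np.nanmax(np.abs(layers.dsj_um - planted)) <= 2 * manifest.pixel_size_um

    def test_missing_label_is_error(self, skin_flat):
        _, labels, manifest = skin_flat
        no_muscle = labels.copy()
        no_muscle[no_muscle == SKIN_LABELS["muscle"]] = 0
        with pytest.raises(ValueError, match="muscle"):
            layers_from_labeled_mask(no_muscle, manifest.pixel_size_um)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            SkinLayers(
                x_um=np.arange(5, dtype=float),
                edj_um=np.full(5, 200.0),
                dsj_um=np.full(5, 100.0),
                ml_um=np.full(5, 300.0),
            )


class TestMeasureThickness:
    def test_flat_planted_recovered_any_seed(self):
        layers = _flat_layers(dermis=300.0, hypo=150.0)
        for seed in (0, 1, 99):
            res = measure_thickness(layers, seed=seed)
            assert res.dermis_um == pytest.approx(300.0, abs=2.0)
            assert res.hypodermis_um == pytest.approx(150.0, abs=2.0)
            assert res.n_fields == 5

    def test_degenerate_zero_dermis(self):
        layers = _flat_layers(dermis=0.0, hypo=120.0)
        assert measure_thickness(layers).dermis_um == 0.0

    def test_seed_determinism(self):
        layers = _flat_layers()
        a = measure_thickness(layers, seed=7)
        b = measure_thickness(layers, seed=7)
        assert a.per_field == b.per_field

    def test_fields_do_not_overlap(self):
        layers = _flat_layers(width_um=3000.0)
        res = measure_thickness(layers, n_fields=5, field_width_um=500.0, seed=3)
        spans = sorted(fr[0] for fr in res.per_field)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 <= b0 + 1e-9

    def test_too_narrow_is_error(self):
        layers = _flat_layers(width_um=1000.0)
        with pytest.raises(ValueError, match="cannot hold"):
            measure_thickness(layers, n_fields=5, field_width_um=500.0)

    def test_sinusoidal_mean_convergence(self):
        """Independently wavy boundaries: many-field mean approaches the
        analytic mean separation (sin averages to zero)."""
        n = 6000
        x = np.linspace(0, 30_000.0, n)
        rng = np.random.default_rng(0)
        a = 30.0
        # wavelengths shorter than the field width, so each field averages
        # over whole undulations and its mean is nearly unbiased
        edj = 100.0 + a * np.sin(2 * np.pi * x / 260.0 + rng.uniform(0, 2 * np.pi))
        dsj = 400.0 + a * np.sin(2 * np.pi * x / 300.0 + rng.uniform(0, 2 * np.pi))
        ml = 550.0 + a * np.sin(2 * np.pi * x / 340.0 + rng.uniform(0, 2 * np.pi))
        layers = SkinLayers(x_um=x, edj_um=edj, dsj_um=dsj, ml_um=ml)
        res = measure_thickness(layers, n_fields=50, field_width_um=400.0, seed=1)
        assert res.dermis_um == pytest.approx(300.0, rel=0.01)
        assert res.hypodermis_um == pytest.approx(150.0, rel=0.01)


class TestEndToEnd:
    def test_wavy_synthetic_recovered(self, skin_wavy):
        _, labels, manifest = skin_wavy
        layers = layers_from_labeled_mask(labels, manifest.pixel_size_um)
        res = measure_thickness(layers, seed=0)
        assert res.dermis_um == pytest.approx(manifest.planted_dermis_um, abs=2.0)
        assert res.hypodermis_um == pytest.approx(
            manifest.planted_hypodermis_um, abs=2.0
        )

    def test_geojson_polyline_input_matches_mask(self, tmp_path, skin_flat):
        _, labels, manifest = skin_flat
        px = manifest.pixel_size_um
        mask_layers = layers_from_labeled_mask(labels, px)
        path = tmp_path / "layers.geojson"
        export_polygons(
            [
                (np.stack([mask_layers.x_um, arr], axis=1), {"layer": name})
                for name, arr in (
                    ("edj", mask_layers.edj_um),
                    ("dsj", mask_layers.dsj_um),
                    ("ml", mask_layers.ml_um),
                )
            ],
            path,
        )
        geo_layers = layers_from_geojson(path, px)
        a = measure_thickness(mask_layers, seed=2)
        b = measure_thickness(geo_layers, seed=2)
        assert b.dermis_um == pytest.approx(a.dermis_um, abs=px)
        assert b.hypodermis_um == pytest.approx(a.hypodermis_um, abs=px)

    def test_hypodermis_reduction_readout(self):
        """A planted 40% adipose-layer loss is recovered within 2 points."""
        control = generate_skin_image(SkinSynthParams(seed=8, hypodermis_um=150.0))
        treated = generate_skin_image(SkinSynthParams(seed=9, hypodermis_um=90.0))
        values = []
        for _, labels, manifest in (control, treated):
            layers = layers_from_labeled_mask(labels, manifest.pixel_size_um)
            values.append(measure_thickness(layers, seed=0).hypodermis_um)
        reduction = 100.0 * (1.0 - values[1] / values[0])
        assert reduction == pytest.approx(40.0, abs=2.0)
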