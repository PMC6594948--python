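"""Tests for the synthetic flux-table and landscape generators."""

import json

import numpy as np
import pandas as pd
import pytest

from peatline import (
    ClassGenSpec,
    GenerationConfig,
    fit_class_regression,
    generate_flux_table,
    generate_landscape,
    read_bundle,
    write_bundle,
)
from peatline.synthetic import BundleParseError, DEFAULT_RESID_SD


class TestFluxTable:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = GenerationConfig.default(seed=123)
        a = generate_flux_table(cfg)
        b = generate_flux_table(cfg)
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        a = generate_flux_table(GenerationConfig.default(seed=1))
        b = generate_flux_table(GenerationConfig.default(seed=2))
        assert not a["flux_mg_m2_d"].equals(b["flux_mg_m2_d"])

    def test_sample_sizes_and_columns(self, default_flux_table):
        counts = default_flux_table["peat_class"].value_counts()
        assert counts["bog"] == 57 and counts["fen"] == 176 and counts["swamp"] == 34
        assert list(default_flux_table.columns) == [
            "site_id", "peat_class", "water_table_cm", "flux_mg_m2_d",
        ]

    def test_all_fluxes_above_back_transform_floor(self):
        for seed in range(5):
            t = generate_flux_table(GenerationConfig.default(seed=seed))
            assert (t["flux_mg_m2_d"] > -2.0).all()

    def test_noise_free_limit_lies_on_the_curve(self):
        """With vanishing residual sd every flux equals 10^(a WT + b) - 2."""
        spec = ClassGenSpec(slope=0.022, intercept=1.53, resid_sd=1e-12, n=40, wt_mean=-22)
        t = generate_flux_table(GenerationConfig(classes={"bog": spec}, seed=0))
        expected = 10 ** (0.022 * t["water_table_cm"] + 1.53) - 2
        np.testing.assert_allclose(t["flux_mg_m2_d"], expected, rtol=1e-9)

    def test_refit_recovers_generating_slope_within_ci(self):
        """A bog table at the study conditions refits to a slope whose 95% CI
        covers the generating value."""
        t = generate_flux_table(GenerationConfig.default(seed=7))
        reg = fit_class_regression(t, "bog")
        se = np.sqrt(reg.cov_params[1, 1])
        assert abs(reg.slope - 0.022) < 1.96 * se

    def test_water_tables_respect_truncation(self, default_flux_table):
        wt = default_flux_table["water_table_cm"]
        assert wt.between(-60, 10).all()

    def test_mean_slope_unbiased_over_regenerations(self):
        """Over 200 regenerations the mean fitted slope sits within 2
        standard errors of the generating slope, per class."""
        slopes = {c: [] for c in ("bog", "fen", "swamp")}
        for seed in range(200):
            t = generate_flux_table(GenerationConfig.default(seed=seed))
            for c in slopes:
                slopes[c].append(fit_class_regression(t, c).slope)
        from peatline.constants import REGRESSION_COEFFICIENTS

        for c, vals in slopes.items():
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - REGRESSION_COEFFICIENTS[c][0]) < 2 * se, c

    def test_generated_r_squared_matches_study_conditions(self):
        """Default residual sds were set so refits land near the compiled
        R^2 values; check within a loose stochastic band."""
        from peatline.constants import REGRESSION_R2

        r2 = {c: [] for c in REGRESSION_R2}
        for seed in range(20):
            t = generate_flux_table(GenerationConfig.default(seed=seed))
            for c in r2:
                r2[c].append(fit_class_regression(t, c).r_squared)
        for c, target in REGRESSION_R2.items():
            assert np.mean(r2[c]) == pytest.approx(target, abs=0.08), c

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n=2), dict(resid_sd=0.0), dict(resid_sd=-1.0)],
    )
    def test_invalid_spec_rejected(self, kwargs):
        base = dict(slope=0.02, intercept=1.5, resid_sd=0.3, n=10, wt_mean=-20)
        with pytest.raises(ValueError):
            ClassGenSpec(**{**base, **kwargs})


class TestLandscape:
    def test_zero_density_gives_polygons_only(self):
        b = generate_landscape(
            (0, 0, 4000, 4000),
            line_densities={"legacy": 0.0, "LIS": 0.0, "trail": 0.0},
            seed=0,
        )
        assert b.lines == [] and len(b.polygons) > 0
        assert b.truth_lengths().to_numpy().sum() == 0.0

    def test_single_bog_tile_one_kilometre_line(self):
        """A 1 km2 all-bog region with legacy density 1 km/km2 carries one
        straight 1 km line whose truth length is exactly 1.0 km."""
        b = generate_landscape(
            (0, 0, 1000, 1000),
            class_fractions={"bog": 1.0},
            line_densities={"legacy": 1.0, "LIS": 0.0, "trail": 0.0},
            seed=0,
        )
        assert len(b.polygons) == 1 and b.polygons[0][1] == "bog"
        assert len(b.lines) == 1
        assert b.truth_lengths().loc["bog", "legacy"] == pytest.approx(1.0)

    @pytest.mark.parametrize("line_type", ["legacy", "LIS", "trail"])
    def test_generated_length_matches_requested_density(self, line_type):
        """Total generated length per type is within 5% of density x area."""
        b = generate_landscape((0, 0, 10_000, 10_000), seed=3)
        dens = b.metadata["line_densities_km_per_km2"][line_type]
        total = sum(g.length for g, t in b.lines if t == line_type) / 1000.0
        assert total == pytest.approx(dens * 100.0, rel=0.05)

    def test_class_fractions_approximated(self):
        b = generate_landscape((0, 0, 10_000, 10_000), seed=1)
        counts = pd.Series([lab for _, lab in b.polygons]).value_counts()
        for c, frac in b.metadata["class_fractions"].items():
            assert counts.get(c, 0) == pytest.approx(frac * 100, abs=1.01)

    def test_polygons_do_not_overlap(self):
        b = generate_landscape((0, 0, 5000, 5000), seed=2)
        total = sum(g.area for g, _ in b.polygons)
        from shapely.ops import unary_union

        assert unary_union([g for g, _ in b.polygons]).area == pytest.approx(total)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty region"):
            generate_landscape((0, 0, 0, 1000))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(class_fractions={"bog": 0.8, "fen": 0.5}),
            dict(line_densities={"legacy": -1.0}),
            dict(class_fractions={"prairie": 0.5}),
        ],
    )
    def test_invalid_landscape_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_landscape((0, 0, 2000, 2000), **kwargs)

    def test_seed_determinism(self):
        a = generate_landscape((0, 0, 4000, 4000), seed=9)
        b = generate_landscape((0, 0, 4000, 4000), seed=9)
        assert [(g.wkt, lab) for g, lab in a.polygons] == [
            (g.wkt, lab) for g, lab in b.polygons
        ]
        assert [(g.wkt, lab) for g, lab in a.lines] == [
            (g.wkt, lab) for g, lab in b.lines
        ]


class TestBundleIO:
    def test_round_trip_identity(self, tmp_path):
        b = generate_landscape((0, 0, 4000, 4000), seed=11)
        write_bundle(b, tmp_path)
        back = read_bundle(tmp_path)
        assert len(back.polygons) == len(b.polygons)
        assert len(back.lines) == len(b.lines)
        for (g0, l0), (g1, l1) in zip(b.polygons, back.polygons):
            assert l0 == l1 and g0.equals_exact(g1, 0.0)
        for (g0, l0), (g1, l1) in zip(b.lines, back.lines):
            assert l0 == l1 and g0.equals_exact(g1, 0.0)
        assert back.metadata == json.loads(json.dumps(b.metadata))

    def test_empty_bundle_round_trip(self, tmp_path):
        from peatline import LandscapeBundle

        write_bundle(LandscapeBundle([], [], {}), tmp_path)
        fc = json.loads((tmp_path / "wetlands.geojson").read_text())
        assert fc == {"type": "FeatureCollection", "features": []}
        back = read_bundle(tmp_path)
        assert back.polygons == [] and back.lines == []

    def test_hand_written_geojson_parses(self, tmp_path):
        polys = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[0, 0], [100, 0], [100, 100], [0, 100], [0, 0]]],
                    },
                    "properties": {"peat_class": "fen"},
                },
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[100, 0], [200, 0], [200, 100], [100, 100], [100, 0]]],
                    },
                    "properties": {"peat_class": "open_water"},
                },
            ],
        }
        (tmp_path / "wetlands.geojson").write_text(json.dumps(polys))
        (tmp_path / "lines.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": []})
        )
        b = read_bundle(tmp_path)
        assert [lab for _, lab in b.polygons] == ["fen", "open_water"]

    def test_missing_file_raises_parse_error(self, tmp_path):
        with pytest.raises(BundleParseError, match="missing bundle file"):
            read_bundle(tmp_path)

    def test_garbled_json_names_the_file(self, tmp_path):
        (tmp_path / "wetlands.geojson").write_text("{not json")
        with pytest.raises(BundleParseError, match="wetlands.geojson"):
            read_bundle(tmp_path)

    def test_bad_label_names_the_feature(self, tmp_path):
        fc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 0]]],
                    },
                    "properties": {"peat_class": "tundra"},
                }
            ],
        }
        (tmp_path / "wetlands.geojson").write_text(json.dumps(fc))
        (tmp_path / "lines.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": []})
        )
        with pytest.raises(BundleParseError, match="feature 0"):
            read_bundle(tmp_path)


def test_default_resid_sd_consistent_with_r2_inversion():
    """The shipped residual sds follow from sd = a * sd_WT * sqrt(1/R2 - 1)
    with the 10-cm water-table spread (before truncation)."""
    from peatline.constants import REGRESSION_COEFFICIENTS, REGRESSION_R2

    for c, (a, _) in REGRESSION_COEFFICIENTS.items():
        implied = a * 10.0 * np.sqrt(1.0 / REGRESSION_R2[c] - 1.0)
        assert DEFAULT_RESID_SD[c] == pytest.approx(implied, abs=0.005), c
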