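"""Synthetic city generator: determinism, completeness, the log-linear
concentration model and missingness mechanisms."""

import numpy as np
import pandas as pd
import pytest

import lurcity as L
from lurcity.synth import (LANDUSE_TYPES, WARMER_MONTHS, apply_missingness,
                           season_of, series_to_frame, year_index)


class TestGenerateCity:
    def test_all_landuse_types_present(self, small_scene):
        types = {a["type"] for _, a in small_scene.landuse}
        assert types == set(LANDUSE_TYPES)

    def test_determinism(self):
        cfg = L.CityConfig(cell_size=20.0)
        a = L.generate_city(cfg, seed=1)
        b = L.generate_city(cfg, seed=1)
        assert a.roads.to_geojson() == b.roads.to_geojson()
        assert a.landuse.to_geojson() == b.landuse.to_geojson()
        assert np.array_equal(a.dem.values, b.dem.values)
        c = L.generate_city(cfg, seed=2)
        assert a.roads.to_geojson() != c.roads.to_geojson()

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            L.CityConfig(taczone_radius=0.0)
        with pytest.raises(ValueError):
            L.CityConfig(width=100.0, height=100.0)  # < 1 km^2

    def test_population_weights_nonnegative(self, small_scene):
        for _, a in small_scene.population:
            assert a["total"] >= 0 and a["adjusted"] >= 0

    def test_facilities_inside_extent(self, small_scene):
        for g, _ in small_scene.facilities:
            assert small_scene.contains(g.x, g.y)

    def test_scene_roundtrips_to_disk(self, small_scene, tmp_path):
        small_scene.write(tmp_path)
        back = L.VectorLayer.read(tmp_path / "landuse.geojson")
        assert len(back) == len(small_scene.landuse)


class TestSimulateConcentrations:
    def test_noise_free_closed_form(self, small_scene):
        """With no noise and unit season multipliers the annual NOx mean
        is exactly exp(base + coef * x)."""
        st = L.place_stations(small_scene, 5, seed=3)
        truth = L.GroundTruth(active_ppvs={"SLP": -0.1}, noise_sd=0.0,
                              base_level=50.0)
        series = L.simulate_concentrations(small_scene, st, truth, seed=4)
        x = L.compute_station_ppvs(small_scene, st, ["SLP"])["SLP"]
        for s, xi in zip(series, x):
            expect = 50.0 * np.exp(-0.1 * xi)
            assert s.data["nox"].mean() == pytest.approx(expect, rel=1e-9)

    def test_species_identity_holds_every_hour(self, small_scene):
        st = L.place_stations(small_scene, 3, seed=3)
        truth = L.GroundTruth(active_ppvs={"SLP": -0.1}, noise_sd=0.5)
        for s in L.simulate_concentrations(small_scene, st, truth, seed=5):
            assert np.allclose(s.data["nox"], s.data["no"] + s.data["no2"])
            assert (s.data >= 0).all().all()

    def test_cooler_season_doubling(self, small_scene):
        """cooler base multiplier 2x warmer -> cooler mean exceeds warmer
        at every one of 10 stations."""
        st = L.place_stations(small_scene, 10, seed=3)
        truth = L.GroundTruth(
            active_ppvs={"SLP": -0.1}, noise_sd=0.3,
            seasonal_shift={"warmer": L.SeasonEffect(base=1.0),
                            "cooler": L.SeasonEffect(base=2.0)})
        series = L.simulate_concentrations(small_scene, st, truth, seed=6)
        warm = series[0].data.index.month.isin(WARMER_MONTHS)
        for s in series:
            assert (s.data["nox"][~warm].mean()
                    > s.data["nox"][warm].mean())

    def test_station_outside_extent_rejected(self, small_scene):
        truth = L.GroundTruth(active_ppvs={"SLP": -0.1})
        with pytest.raises(ValueError, match="outside"):
            L.simulate_concentrations(small_scene, [(-10.0, 50.0)], truth)

    def test_truth_sign_contradiction_rejected(self, small_scene):
        st = L.place_stations(small_scene, 3, seed=3)
        truth = L.GroundTruth(active_ppvs={"GRS.500": +1e-6})  # prior is -
        with pytest.raises(ValueError, match="sign"):
            L.simulate_concentrations(small_scene, st, truth)

    def test_series_csv_roundtrip(self, small_scene, tmp_path):
        from lurcity.synth import read_series_csv, write_series_csv
        st = L.place_stations(small_scene, 3, seed=3)
        truth = L.GroundTruth(active_ppvs={"SLP": -0.1}, noise_sd=0.2)
        series = L.simulate_concentrations(small_scene, st, truth, seed=7)
        series = [apply_missingness(s, 0.2, seed=i) for i, s in
                  enumerate(series)]
        write_series_csv(series, tmp_path / "s.csv")
        back = read_series_csv(tmp_path / "s.csv")
        assert [b.station_id for b in back] == [s.station_id for s in series]
        for b, s in zip(back, series):
            assert np.array_equal(b.data["nox"].isna(), s.data["nox"].isna())
            assert np.allclose(b.data["nox"].dropna(),
                               s.data["nox"].dropna(), rtol=1e-5)


def _dummy_series():
    idx = year_index()
    rng = np.random.default_rng(0)
    vals = np.exp(rng.normal(3, 0.4, 8760))
    df = pd.DataFrame({"no": vals * 0.6, "no2": vals * 0.4, "nox": vals},
                      index=idx)
    return L.HourlySeries("S00", df)


class TestMissingness:
    def test_rate_zero_is_identity(self):
        s = _dummy_series()
        out = apply_missingness(s, 0.0, seed=1)
        assert out.data.equals(s.data)

    def test_mcar_hits_the_paper_rate(self):
        """28.1% MCAR on 8760 hours: realized count within the +/-1% band
        [2377, 2529] around 0.28 x 8760."""
        out = apply_missingness(_dummy_series(), 0.281, seed=2)
        k = out.data["no"].isna().sum()
        assert k == round(0.281 * 8760)
        out28 = apply_missingness(_dummy_series(), 0.28, seed=3)
        assert 2377 <= out28.data["no"].isna().sum() <= 2529

    def test_block_mechanism_contiguous(self):
        out = apply_missingness(_dummy_series(), 0.28, "block", seed=4)
        mask = out.data["no"].isna().to_numpy()
        assert mask.sum() == round(0.28 * 8760)
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, mask, 0])))[::2]
        assert np.mean(runs) > 5  # outages, not scattered single hours

    def test_determinism_and_rate_validation(self):
        s = _dummy_series()
        a = apply_missingness(s, 0.3, seed=9)
        b = apply_missingness(s, 0.3, seed=9)
        assert a.data.equals(b.data)
        with pytest.raises(ValueError):
            apply_missingness(s, 1.0)

    def test_series_to_frame_shape(self):
        mat = series_to_frame([_dummy_series()], "nox")
        assert mat.shape == (8760, 1)


def test_season_of_convention():
    idx = year_index()
    s = season_of(idx.month)
    assert (s[idx.month == 1] == "cooler").all()
    assert (s[idx.month == 7] == "warmer").all()
    assert (s == "warmer").sum() == 24 * (30 + 31 + 30 + 31 + 31 + 30)
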