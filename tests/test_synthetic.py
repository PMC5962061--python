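"""Synthetic landscapes, populations and surveys: determinism,
calibration of the generator, and the certain-detection strip rule."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from stripdsm.synthetic import (IntensityModel, _sample_group_sizes,
                                default_flight_paths, simulate_landscape,
                                simulate_population, simulate_survey)


class TestLandscape:
    def test_seeded_determinism(self):
        a = simulate_landscape(200.0, 700.0, seed=5)
        b = simulate_landscape(200.0, 700.0, seed=5)
        assert np.array_equal(a.elevation, b.elevation)
        assert np.array_equal(a.forest_fraction, b.forest_fraction)
        c = simulate_landscape(200.0, 700.0, seed=6)
        assert not np.array_equal(a.elevation, c.elevation)

    def test_zero_variance_gives_constant_elevation(self):
        land = simulate_landscape(100.0, 500.0,
                                  elevation_params={"mean": 450.0, "sd": 0.0},
                                  seed=1)
        assert np.unique(land.elevation).tolist() == [450.0]

    def test_elevation_coast_correlation_near_target(self):
        """On 10,000 cells the realized elevation/distance-to-coast
        correlation sits within +-0.1 of the configured 0.65."""
        land = simulate_landscape(4900.0, 700.0, seed=5)
        assert land.n_cols * land.n_rows == 10_000
        X, Y = land.cell_centers()
        d = land.distance_to_coast(np.column_stack([X.ravel(), Y.ravel()]))
        r = np.corrcoef(land.elevation.ravel(), d)[0, 1]
        assert abs(r - 0.65) < 0.1

    def test_field_invariants(self):
        land = simulate_landscape(300.0, 700.0, seed=3)
        assert np.all(np.isfinite(land.elevation))
        assert land.forest_fraction.min() >= 0.0
        assert land.forest_fraction.max() <= 1.0
        assert land.area_km2 == pytest.approx(
            land.n_cols * land.n_rows * land.cell_size**2 / 1e6)
        pts = np.array([[0.0, 0.0], [5000.0, 100.0]])
        assert np.all(land.distance_to_coast(pts) >= 0.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_landscape(-1.0, 700.0)
        with pytest.raises(ValueError):
            simulate_landscape(100.0, 0.0)


class TestPopulation:
    def test_intensity_model_validation(self):
        with pytest.raises(ValueError):
            IntensityModel(intercept=0.0, p=2.5)
        with pytest.raises(ValueError):
            IntensityModel(intercept=0.0, phi=-1.0)

    def test_vanishing_intercept_gives_empty_population(self, landscape):
        model = IntensityModel(intercept=-700.0)
        pop = simulate_population(landscape, model, seed=0)
        assert len(pop) == 0

    def test_nonfinite_intensity_rejected(self, landscape):
        model = IntensityModel(intercept=0.0,
                               effects={"elevation": lambda e: np.full_like(e, np.nan)})
        with pytest.raises(ValueError, match="finite"):
            simulate_population(landscape, model, seed=0)

    def test_constant_intensity_mean_total(self):
        """Monte-Carlo mean of total individuals matches the closed form
        c * area * E[group size] within three standard errors."""
        land = simulate_landscape(100.0, 500.0,
                                  elevation_params={"sd": 0.0}, seed=1)
        c = 2.0
        model = IntensityModel(intercept=np.log(c), group_size_mean=1.0,
                               group_size_shape=None)
        totals = [simulate_population(land, model, seed=s)["group_size"].sum()
                  for s in range(60)]
        expect = c * land.area_km2 * 1.0
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expect) < 3.0 * se

    def test_log_intercept_shift_multiplies_counts_by_e(self):
        land = simulate_landscape(100.0, 500.0,
                                  elevation_params={"sd": 0.0}, seed=1)
        base = IntensityModel(intercept=np.log(2.0), group_size_mean=1.0,
                              group_size_shape=None)
        up = IntensityModel(intercept=np.log(2.0) + 1.0, group_size_mean=1.0,
                            group_size_shape=None)
        t0 = np.mean([len(simulate_population(land, base, seed=s))
                      for s in range(40)])
        t1 = np.mean([len(simulate_population(land, up, seed=1000 + s))
                      for s in range(40)])
        assert t1 / t0 == pytest.approx(np.e, rel=0.1)

    def test_group_sizes_zero_truncated_with_target_mean(self):
        rng = np.random.default_rng(0)
        sizes = _sample_group_sizes(rng, 20_000, mean=4.0, shape=2.0)
        assert sizes.min() >= 1
        assert np.mean(sizes) == pytest.approx(4.0, abs=0.1)

    def test_seeded_determinism(self, landscape, elevation_model):
        a = simulate_population(landscape, elevation_model, seed=7)
        b = simulate_population(landscape, elevation_model, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestSurvey:
    def test_group_on_path_always_detected(self):
        pop = pd.DataFrame({"x": [500.0], "y": [100.0], "group_size": [4]})
        path = LineString([(0.0, 100.0), (1000.0, 100.0)])
        sv = simulate_survey(pop, [path], bandwidth=1400.0, seed=0)
        assert len(sv.detected_records) == 1

    def test_hard_truncation_just_outside_half_bandwidth(self):
        pop = pd.DataFrame({"x": [500.0], "y": [701.0], "group_size": [4]})
        path = LineString([(0.0, 0.0), (1000.0, 0.0)])
        sv = simulate_survey(pop, [path], bandwidth=1400.0, seed=0)
        assert len(sv.detected_records) == 0
        pop["y"] = 699.0
        assert len(simulate_survey(pop, [path], 1400.0, seed=0
                                   ).detected_records) == 1

    def test_detected_are_subset_with_conserved_sizes(self, landscape,
                                                      elevation_model):
        pop = simulate_population(landscape, elevation_model, seed=3)
        paths = default_flight_paths(landscape, n_transects=3)
        sv = simulate_survey(pop, paths, bandwidth=1400.0, seed=4)
        assert sv.detected_records["group_size"].sum() \
            <= pop["group_size"].sum()
        detected_xy = set(map(tuple, sv.detected_records[["x", "y"]].to_numpy()))
        all_xy = set(map(tuple, pop[["x", "y"]].to_numpy()))
        assert detected_xy <= all_xy

    def test_strip_coverage_fraction_detected(self):
        """A strip covering 10 % of a uniform population detects ~10 % of
        groups, within binomial three-sigma."""
        land = simulate_landscape(100.0, 500.0,
                                  elevation_params={"sd": 0.0}, seed=1)
        model = IntensityModel(intercept=np.log(5.0), group_size_mean=1.0,
                               group_size_shape=None)
        pop = simulate_population(land, model, seed=2)
        path = default_flight_paths(land, n_transects=1)
        sv = simulate_survey(pop, path, bandwidth=1000.0, seed=0)
        p = 0.10
        n = len(pop)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(len(sv.detected_records) - n * p) < 3.0 * sigma

    def test_timestamps_monotone_along_flight(self, landscape, elevation_model):
        pop = simulate_population(landscape, elevation_model, seed=5)
        paths = default_flight_paths(landscape, n_transects=2)
        sv = simulate_survey(pop, paths, bandwidth=1400.0, seed=6)
        times = pd.to_datetime(sv.detected_records["t"])
        assert times.is_monotonic_increasing

    def test_empty_flight_paths_rejected(self):
        pop = pd.DataFrame({"x": [0.0], "y": [0.0], "group_size": [1]})
        with pytest.raises(ValueError, match="path"):
            simulate_survey(pop, [], bandwidth=1400.0, seed=0)

    def test_end_to_end_reproducibility(self, landscape, elevation_model):
        paths = default_flight_paths(landscape, n_transects=3)
        runs = []
        for _ in range(2):
            pop = simulate_population(landscape, elevation_model, seed=8)
            runs.append(simulate_survey(pop, paths, 1400.0, seed=9
                                        ).detected_records)
        pd.testing.assert_frame_equal(runs[0], runs[1])
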