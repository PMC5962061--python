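"""Segmentation: arc-length slicing, record assignment, covariate
summaries and the collinearity screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString

from stripdsm import (IntensityModel, simulate_landscape, simulate_population,
                      simulate_survey)
from stripdsm.segments import (assign_records, build_segment_table,
                               collinearity_screen, segment_table,
                               segmentize_transect, summarize_covariates,
                               survey_effort_summary)


def straight(length, y=0.0):
    return np.array([[0.0, y], [length, y]])


class TestSegmentize:
    def test_full_bandwidth_slices_have_square_area(self):
        segs = segmentize_transect(straight(5600.0), 1400.0)
        assert len(segs) == 4
        assert all(s.area == pytest.approx(1.96) for s in segs)
        assert [s.order for s in segs] == [0, 1, 2, 3]

    def test_exact_multiple_leaves_no_remainder(self):
        assert len(segmentize_transect(straight(2800.0), 1400.0)) == 2

    def test_short_remainder_dropped_long_remainder_kept(self):
        dropped = segmentize_transect(straight(3000.0), 1400.0, min_fraction=0.5)
        assert len(dropped) == 2
        kept = segmentize_transect(straight(3500.0), 1400.0, min_fraction=0.5)
        assert len(kept) == 3
        assert kept[-1].length == pytest.approx(700.0)
        assert kept[-1].area == pytest.approx(0.98)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            segmentize_transect(np.array([[0.0, 0.0]]), 1400.0)
        with pytest.raises(ValueError):
            segmentize_transect(straight(1000.0), -1.0)
        with pytest.raises(ValueError):
            segmentize_transect(straight(1000.0), 1400.0, min_fraction=1.5)

    @given(st.floats(1500.0, 30000.0))
    @settings(max_examples=50, deadline=None)
    def test_length_conservation(self, length):
        """Segment lengths sum to the path length minus any dropped
        remainder."""
        segs = segmentize_transect(straight(length), 1400.0, min_fraction=0.5)
        total = sum(s.length for s in segs)
        dropped = length - total
        assert 0.0 <= dropped < 0.5 * 1400.0 + 1e-6
        assert total == pytest.approx(length - dropped)

    def test_concatenation_commutes_for_exact_multiples(self):
        """Slicing two abutting multiples-of-bandwidth paths equals
        slicing their concatenation."""
        a = segmentize_transect(straight(2800.0), 1400.0)
        b = segmentize_transect(np.array([[2800.0, 0.0], [5600.0, 0.0]]), 1400.0)
        both = segmentize_transect(straight(5600.0), 1400.0)
        got = [np.asarray(s.centerline.coords) for s in a + b]
        want = [np.asarray(s.centerline.coords) for s in both]
        for g, w in zip(got, want):
            assert np.allclose(g, w)


class TestAssignRecords:
    def setup_method(self):
        self.segs = segmentize_transect(straight(5600.0), 1400.0)

    def test_record_at_centroid_counts_group_size(self):
        rec = pd.DataFrame({"x": [700.0], "y": [0.0], "group_size": [5]})
        segs, un = assign_records(self.segs, rec, 1400.0)
        assert segs[0].count == 5
        assert len(un) == 0

    def test_record_outside_strip_is_unassigned(self):
        rec = pd.DataFrame({"x": [700.0], "y": [800.0], "group_size": [3]})
        segs, un = assign_records(self.segs, rec, 1400.0)
        assert sum(s.count for s in segs) == 0
        assert len(un) == 1

    def test_boundary_record_goes_to_lower_order_index(self):
        rec = pd.DataFrame({"x": [1400.0], "y": [100.0], "group_size": [2]})
        segs, _ = assign_records(self.segs, rec, 1400.0)
        assert segs[0].count == 2
        assert segs[1].count == 0

    def test_group_size_below_one_rejected(self):
        rec = pd.DataFrame({"x": [1.0], "y": [0.0], "group_size": [0]})
        with pytest.raises(ValueError, match="group size"):
            assign_records(self.segs, rec, 1400.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_count_conservation(self, seed):
        """Assigned counts plus unassigned sizes always equal the total."""
        rng = np.random.default_rng(seed)
        n = 40
        rec = pd.DataFrame({
            "x": rng.uniform(-500.0, 6500.0, n),
            "y": rng.uniform(-1200.0, 1200.0, n),
            "group_size": rng.integers(1, 9, n),
        })
        segs = segmentize_transect(straight(5600.0), 1400.0)
        segs, un = assign_records(segs, rec, 1400.0)
        assert sum(s.count for s in segs) + un["group_size"].sum() \
            == rec["group_size"].sum()


class TestCovariateSummary:
    def test_constant_raster_and_coastal_centroid(self):
        landscape = simulate_landscape(100.0, 500.0,
                                       elevation_params={"mean": 100.0, "sd": 0.0},
                                       seed=0)
        seg = segmentize_transect(straight(1400.0, y=3000.0), 1400.0)[0]
        summarize_covariates(seg, landscape)
        assert seg.mean_elevation == pytest.approx(100.0)
        assert seg.distance_to_coast == pytest.approx(700.0)  # centroid x
        assert not seg.excluded
        coast_seg = segmentize_transect(
            np.array([[0.0, 2000.0], [0.0, 3400.0]]), 1400.0)[0]
        summarize_covariates(coast_seg, landscape)
        assert coast_seg.distance_to_coast == pytest.approx(0.0)

    def test_forest_exclusion_rule_is_inclusive_at_095(self):
        landscape = simulate_landscape(100.0, 500.0, seed=0)
        landscape.forest_fraction[:] = 0.96
        seg = segmentize_transect(straight(1400.0, y=3000.0), 1400.0)[0]
        summarize_covariates(seg, landscape)
        assert seg.excluded
        landscape.forest_fraction[:] = 0.95
        summarize_covariates(seg, landscape)
        assert seg.excluded
        landscape.forest_fraction[:] = 0.9499
        summarize_covariates(seg, landscape)
        assert not seg.excluded

    def test_strip_outside_landscape_raises(self):
        landscape = simulate_landscape(100.0, 500.0, seed=0)
        seg = segmentize_transect(straight(1400.0, y=90000.0), 1400.0)[0]
        with pytest.raises(ValueError, match="outside"):
            summarize_covariates(seg, landscape)


class TestCollinearityScreen:
    def test_identical_vectors(self):
        r, sep = collinearity_screen(np.arange(10.0), 2.0 * np.arange(10.0))
        assert r == pytest.approx(1.0)
        assert sep

    def test_orthogonal_vectors(self):
        x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])
        r, sep = collinearity_screen(x, y)
        assert abs(r) < 1e-12
        assert not sep

    def test_threshold_is_inclusive(self):
        """|r| exactly at the threshold already forces separate models."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        x = (x - x.mean()) / x.std()
        e = rng.normal(size=300)
        e -= e.mean() + (e @ x) / (x @ x) * x
        target = 0.69
        y = target * x + np.sqrt(1 - target**2) * e / e.std()
        r, sep = collinearity_screen(x, y)
        assert abs(r) == pytest.approx(0.69, abs=1e-6)
        assert sep
        assert collinearity_screen(x, y, threshold=abs(r))[1]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            collinearity_screen(np.ones(5), np.arange(5.0))


def test_survey_counts_conserved_through_segmentation(landscape):
    """Total assigned segment counts equal the individuals the survey
    detected inside the strips (min_fraction = 0 keeps all effort)."""
    model = IntensityModel(intercept=np.log(0.8), group_size_mean=3.0)
    pop = simulate_population(landscape, model, seed=9)
    paths = [LineString([(0.0, 4000.0), (19000.0, 4200.0)]),
             LineString([(0.0, 12000.0), (19000.0, 11800.0)])]
    survey = simulate_survey(pop, paths, bandwidth=1400.0, seed=10)
    seg, unassigned = build_segment_table(paths, survey.detected_records,
                                          landscape, bandwidth=1400.0,
                                          min_fraction=0.0)
    assert seg["count"].sum() + unassigned["group_size"].sum() \
        == survey.detected_records["group_size"].sum()
    # with full effort kept, essentially everything detected is assigned
    assert unassigned["group_size"].sum() <= 0.02 * survey.detected_records["group_size"].sum()


def test_survey_effort_summary_accounting():
    rec = pd.DataFrame({
        "survey": ["a", "a", "b", "c"],
        "season": ["w", "w", "w", "s"],
        "group_size": [3, 4, 5, 6],
    })
    out = survey_effort_summary(rec)
    total = out.loc[out["survey"] == "total"].iloc[0]
    assert total["photo_records"] == 4
    assert total["individuals"] == 18
    sub_w = out.loc[(out["survey"] == "subtotal") & (out["season"] == "w")].iloc[0]
    assert sub_w["individuals"] == 12
    with pytest.raises(ValueError):
        survey_effort_summary(rec.drop(columns="season"))
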