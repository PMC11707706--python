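"""Growing-season window, village radius, era assignment and season metrics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gardentrends as gt
from gardentrends.errors import ConfigurationError


def _obs(dates, cid="g1", sensor="L5", ndvi=0.5):
    return pd.DataFrame({"centroid_id": cid, "date": pd.to_datetime(dates),
                         "sensor": sensor, "ndvi": ndvi})


class TestGrowingSeason:
    @pytest.mark.parametrize("date, kept", [
        ("1995-05-01", True),    # window start, inclusive
        ("1995-09-30", True),    # window end, inclusive
        ("1995-04-30", False),
        ("1995-10-01", False),
        ("1995-07-15", True),
    ])
    def test_window_boundaries(self, date, kept):
        out = gt.filter_growing_season(_obs([date]))
        assert (len(out) == 1) == kept

    def test_idempotent(self, observation_table):
        once = gt.filter_growing_season(observation_table)
        twice = gt.filter_growing_season(once)
        pd.testing.assert_frame_equal(once, twice)


class TestVillageRadius:
    def _centroids(self, rows):
        return pd.DataFrame(rows, columns=["centroid_id", "role", "x", "y"])

    def test_inside_and_outside(self):
        cents = self._centroids([
            ("g_near", "garden", 0.0, 999.0),
            ("g_far", "garden", 0.0, 1001.0),
            ("v", "village_center", 0.0, 0.0),
        ])
        kept = gt.filter_village_radius(cents, 1000.0)
        assert set(kept["centroid_id"]) == {"g_near", "v"}

    def test_boundary_is_closed(self):
        cents = self._centroids([
            ("g", "garden", 600.0, 800.0),       # exactly 1000 m
            ("v", "village_center", 0.0, 0.0),
        ])
        kept = gt.filter_village_radius(cents, 1000.0)
        assert "g" in set(kept["centroid_id"])

    def test_nearest_of_several_villages(self):
        # nearest village is the second one, at Pythagorean distance 1000
        cents = self._centroids([
            ("g", "garden", 0.0, 0.0),
            ("v1", "village_center", 3000.0, 4000.0),
            ("v2", "village_center", 600.0, 800.0),
        ])
        kept = gt.filter_village_radius(cents, 1000.0)
        assert "g" in set(kept["centroid_id"])

    def test_no_village_is_configuration_error(self):
        cents = self._centroids([("g", "garden", 0.0, 0.0)])
        with pytest.raises(ConfigurationError):
            gt.filter_village_radius(cents, 1000.0)

    def test_idempotent(self, small_scene):
        once = gt.filter_village_radius(small_scene.centroids, 1000.0)
        twice = gt.filter_village_radius(once, 1000.0)
        pd.testing.assert_frame_equal(once, twice)


class TestEraAssignment:
    @pytest.mark.parametrize("sensor, year, era", [
        ("L5", 2005, "E1"),
        ("L5", 1990, "E1"),
        ("L5", 2011, "E1"),
        ("L8", 2013, "E2"),
        ("L8", 2024, "E2"),
        ("L8", 2012, None),   # gap year
        ("L5", 2012, None),
        ("L5", 2015, None),   # sensor-era mismatch
        ("L8", 2005, None),
    ])
    def test_scalar_rule(self, sensor, year, era):
        assert gt.assign_era(sensor, year) == era

    def test_vectorized_matches_scalar(self, small_scene):
        obs = gt.with_era(small_scene.observations)
        years = obs["date"].dt.year
        expected = [gt.assign_era(s, y) for s, y in zip(obs["sensor"], years)]
        got = [e if pd.notna(e) else None for e in obs["era"]]
        assert got == expected


class TestSeasonStats:
    def test_hand_computed_mean_and_variance(self):
        obs = gt.with_era(_obs(["1995-06-01", "1995-07-01", "1995-08-01"],
                               ndvi=[0.2, 0.4, 0.6]))
        out = gt.season_stats(obs, min_obs_per_season=3)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["mean_ndvi"] == pytest.approx(0.4)
        assert row["var_ndvi"] == pytest.approx(0.04)   # n-1 divisor
        assert row["n_obs"] == 3

    def test_population_divisor_option(self):
        obs = gt.with_era(_obs(["1995-06-01", "1995-07-01", "1995-08-01"],
                               ndvi=[0.2, 0.4, 0.6]))
        out = gt.season_stats(obs, min_obs_per_season=3, variance_divisor="n")
        assert out.iloc[0]["var_ndvi"] == pytest.approx(0.08 / 3)

    def test_small_group_omitted(self):
        obs = gt.with_era(_obs(["1995-06-01"], ndvi=[0.5]))
        out = gt.season_stats(obs, min_obs_per_season=3)
        assert out.empty

    def test_constant_values_zero_variance(self):
        obs = gt.with_era(_obs(["1995-06-01", "1995-06-15", "1995-07-01", "1995-08-01"],
                               ndvi=0.37))
        out = gt.season_stats(obs, min_obs_per_season=3)
        assert out.iloc[0]["mean_ndvi"] == pytest.approx(0.37)
        assert out.iloc[0]["var_ndvi"] == 0.0

    def test_years_stay_within_era_bounds(self, small_result):
        m = small_result.season_metrics
        e1 = m[m["era"] == "E1"]["year"]
        e2 = m[m["era"] == "E2"]["year"]
        assert e1.between(1990, 2011).all()
        assert e2.between(2013, 2024).all()

    @given(values=st.lists(st.floats(-1, 1, allow_nan=False, width=32),
                           min_size=3, max_size=12))
    def test_matches_independent_single_pass_oracle(self, values):
        """Group stats agree with an independent single-pass (Welford) accumulator."""
        dates = pd.date_range("1995-06-01", periods=len(values), freq="D")
        obs = gt.with_era(_obs(dates, ndvi=values))
        out = gt.season_stats(obs, min_obs_per_season=3)
        # independent oracle: Welford accumulation
        mean, m2 = 0.0, 0.0
        for k, v in enumerate(values, 1):
            d = v - mean
            mean += d / k
            m2 += d * (v - mean)
        assert out.iloc[0]["mean_ndvi"] == pytest.approx(mean, abs=1e-12)
        assert out.iloc[0]["var_ndvi"] == pytest.approx(m2 / (len(values) - 1), abs=1e-12)
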