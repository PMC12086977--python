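import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from litterdecay.environment_stats import (
    MoistureGrid,
    StandInventory,
    clr_transform,
    grid_summary,
    group_means,
    moisture_delta,
    permutation_group_test,
    weighted_shade_tolerance,
)
from litterdecay.study import PLOT_TABLE


class TestGridSummary:
    def test_constant_grid_has_zero_cv(self):
        s = grid_summary([10.0] * 42)
        assert s.mean == 10.0 and s.sd == 0.0 and s.cv_percent == 0.0

    def test_two_value_hand_arithmetic(self):
        s = grid_summary([8.0, 12.0])
        assert s.mean == pytest.approx(10.0)
        assert s.sd == pytest.approx(math.sqrt(8.0))
        assert s.cv_percent == pytest.approx(28.284271, abs=1e-5)

    def test_rainfall_plot_means_average_to_published_value(self):
        rain = PLOT_TABLE[~PLOT_TABLE.exclusion]
        assert rain.swc_mean.mean() == pytest.approx(15.57, abs=0.005)

    def test_cv_is_scale_invariant(self):
        values = [8.0, 12.0, 9.5, 14.2]
        base = grid_summary(values).cv_percent
        assert grid_summary([v * 7.3 for v in values]).cv_percent == \
            pytest.approx(base, rel=1e-12)

    def test_nonpositive_reading_rejected(self):
        with pytest.raises(ValueError):
            grid_summary([10.0, 0.0])

    def test_moisture_grid_wraps_summary_and_checks_node_count(self):
        grid = MoistureGrid("1-1", np.full(42, 12.0))
        assert grid.cv_percent == 0.0
        with pytest.raises(ValueError, match="nodes"):
            MoistureGrid("1-1", np.full(40, 12.0))


class TestWeightedShadeTolerance:
    def test_single_species_returns_its_rating(self):
        inv = StandInventory("p", {"ACSA": 30.0}, shade_ratings={"ACSA": 1.0})
        assert weighted_shade_tolerance(inv) == 1.0

    def test_equal_basal_areas_give_midpoint(self):
        inv = StandInventory("p", {"A": 10.0, "B": 10.0},
                             shade_ratings={"A": 1.0, "B": 3.0})
        assert weighted_shade_tolerance(inv) == pytest.approx(2.0)

    def test_uniform_ratings_invariant_to_weights(self):
        inv = StandInventory("p", {"A": 3.0, "B": 27.0},
                             shade_ratings={"A": 2.0, "B": 2.0})
        assert weighted_shade_tolerance(inv) == pytest.approx(2.0)

    def test_missing_rating_or_zero_ba_rejected(self):
        with pytest.raises(ValueError, match="rating"):
            weighted_shade_tolerance(StandInventory("p", {"A": 5.0}))
        with pytest.raises(ValueError, match="basal"):
            weighted_shade_tolerance(
                StandInventory("p", {"A": 0.0}, shade_ratings={"A": 1.0}))


class TestClrTransform:
    def test_uniform_composition_maps_to_zero(self):
        assert np.allclose(clr_transform([1 / 3, 1 / 3, 1 / 3]), 0.0)

    def test_soil_texture_means_sum_to_zero(self):
        # published mean sand/silt/clay fractions
        out = clr_transform([58.4, 38.6, 3.0])
        assert out.sum() == pytest.approx(0.0, abs=1e-12)
        assert out[0] > out[1] > out[2]

    @given(st.lists(st.floats(min_value=0.01, max_value=100), min_size=2,
                    max_size=6), st.floats(min_value=0.01, max_value=50))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_and_zero_sum(self, parts, c):
        a = clr_transform(parts)
        b = clr_transform([p * c for p in parts])
        assert np.allclose(a, b)
        assert a.sum() == pytest.approx(0.0, abs=1e-9)

    def test_zero_part_rejected(self):
        with pytest.raises(ValueError):
            clr_transform([0.5, 0.5, 0.0])


class TestPermutationGroupTest:
    def test_univariate_pseudo_f_equals_classical_f(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=18)
        labels = np.repeat(["a", "b", "c"], 6)
        result = permutation_group_test(x, labels, n_permutations=9, seed=0)
        f_classic = stats.f_oneway(x[:6], x[6:12], x[12:]).statistic
        assert result.pseudo_f == pytest.approx(f_classic, rel=1e-10)

    def test_published_mineral_ph_pseudo_f(self):
        result = permutation_group_test(
            PLOT_TABLE.mineral_ph.to_numpy(),
            PLOT_TABLE.proliferation.to_numpy(), n_permutations=999, seed=1)
        assert result.pseudo_f == pytest.approx(18.14, abs=0.01)
        assert result.p_value < 0.05

    def test_matches_scikit_bio_permanova_pseudo_f(self):
        from skbio.stats.distance import DistanceMatrix, permanova
        rng = np.random.default_rng(12)
        data = rng.normal(size=(12, 3))
        data[6:] += 1.0
        labels = np.repeat(["a", "b"], 6)
        mine = permutation_group_test(data, labels, n_permutations=99, seed=0)
        dm = DistanceMatrix(
            np.sqrt(((data[:, None, :] - data[None, :, :]) ** 2).sum(-1)))
        ref = permanova(dm, labels, permutations=99)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_separated_groups_reach_minimal_p(self):
        # groups large enough that no random permutation recreates the
        # original split, so the add-one floor is attainable
        rng = np.random.default_rng(8)
        data = np.vstack([rng.normal(0, 0.01, size=(10, 2)),
                          rng.normal(50, 0.01, size=(10, 2))])
        labels = np.repeat(["a", "b"], 10)
        result = permutation_group_test(data, labels, n_permutations=199, seed=3)
        assert result.p_value == pytest.approx(1 / 200)

    def test_seed_makes_p_reproducible(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(10, 2))
        labels = np.repeat(["a", "b"], 5)
        p1 = permutation_group_test(data, labels, 199, seed=9).p_value
        p2 = permutation_group_test(data, labels, 199, seed=9).p_value
        assert p1 == p2

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_group_test(np.ones((3, 2)), ["a", "a", "b"])


class TestGroupMeans:
    def test_published_group_summaries(self):
        ph = group_means(PLOT_TABLE.mineral_ph,
                         np.where(PLOT_TABLE.proliferation, "Yes", "No"))
        assert ph.loc["No", "mean"] == pytest.approx(4.91, abs=0.005)
        assert ph.loc["Yes", "mean"] == pytest.approx(4.16, abs=0.005)
        ba = group_means(PLOT_TABLE.canopy_ba, ["all"] * len(PLOT_TABLE))
        assert ba.loc["all", "mean"] == pytest.approx(33.62, abs=0.0051)

    def test_single_element_group_has_nan_sd(self):
        out = group_means([1.0, 2.0, 3.0], ["a", "a", "b"])
        assert out.loc["b", "mean"] == 3.0
        assert np.isnan(out.loc["b", "sd"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            group_means([], [])


class TestMoistureDelta:
    @pytest.mark.parametrize("start,end,days,expected", [
        (10.0, 10.0, 30, 0.0),
        (10.0, 16.0, 30, 6.0),
        (16.0, 10.0, 60, -3.0),
    ])
    def test_hand_arithmetic(self, start, end, days, expected):
        assert moisture_delta(start, end, days) == pytest.approx(expected)

    def test_nonpositive_days_rejected(self):
        with pytest.raises(ValueError):
            moisture_delta(10.0, 12.0, 0)
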