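import math

import numpy as np
import pandas as pd
import pytest

from litterdecay.data_model import ALL_CELLS, BagRecord, TreatmentCell
from litterdecay.decay_estimation import (
    EstimationError,
    accumulate_gdd,
    build_design_matrix,
    fit_multigroup,
    instantaneous_k,
)
from litterdecay.synthetic_data import (
    default_study_config,
    generate_bags,
    generate_temperature_log,
)


class TestInstantaneousK:
    @pytest.mark.parametrize("pct,yf,expected", [
        (100.0, 0.2466, 0.0),
        (75.6, 0.2466, math.log(0.756) / 0.2466),    # = -1.134 to 3 decimals
        (92.9, 0.0822, math.log(0.929) / 0.0822),    # = -0.8959
    ])
    def test_closed_form(self, pct, yf, expected):
        assert instantaneous_k(pct, yf) == pytest.approx(expected, abs=1e-12)

    def test_printed_rounding(self):
        assert round(instantaneous_k(75.6, 0.2466), 3) == -1.134

    def test_total_disappearance_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_k(0.0, 0.2466)
        with pytest.raises(ValueError):
            instantaneous_k(-5.0, 0.2466)


class TestDesignMatrix:
    def test_single_bag_row(self, mono_bag):
        y, X = build_design_matrix([mono_bag])
        assert list(X.columns) == ["intercept", mono_bag.cell.label]
        assert X.iloc[0, 0] == 1.0
        assert X.iloc[0, 1] == 0.2466
        assert y[0] == pytest.approx(math.log(75.6))

    def test_full_design_has_thirteen_columns_full_rank(self, study_bags):
        y, X = build_design_matrix(study_bags)
        assert X.shape == (540, 13)
        assert np.linalg.matrix_rank(X.to_numpy()) == 13

    def test_columns_follow_canonical_cell_order(self, study_bags):
        _, X = build_design_matrix(study_bags)
        assert list(X.columns[1:]) == [c.label for c in ALL_CELLS]

    def test_empty_input_rejected(self):
        with pytest.raises(EstimationError):
            build_design_matrix([])


class TestFitMultigroup:
    def test_noiseless_round_trip_recovers_truth_exactly(self, noiseless_bags):
        cfg = default_study_config(ln_noise_sd=0.0)
        fit = fit_multigroup(noiseless_bags)
        assert fit.intercept == pytest.approx(math.log(100), abs=1e-10)
        for cell, k in cfg.true_k_table.items():
            assert fit.slopes[cell] == pytest.approx(-k, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_single_cell_single_time_equals_instantaneous_k_of_mean(self):
        # equivalence oracle: slope through (0, ln 100) and one time point
        bags = [BagRecord("1", "1-2", True, False, "maple", m, r, 90, 3.0, 2.4)
                for m in ("L", "M", "S") for r in (1, 2)]
        # two times needed for estimability: add the same cell at day 30
        bags30 = [BagRecord("1", "1-2", True, False, "maple", "L", r, 30, 3.0, 2.8)
                  for r in (1, 2)]
        fit = fit_multigroup(bags + bags30)
        # noiseless within-time, so OLS passes through both cell means and
        # the intercept absorbs the ln(100) offset; check against the exact
        # two-point solution
        y30, y90 = math.log(2.8 / 3 * 100), math.log(2.4 / 3 * 100)
        slope = (y90 - y30) / (0.2466 - 0.0822)
        cell = TreatmentCell(True, False, "maple")
        assert fit.slopes[cell] == pytest.approx(slope, abs=1e-9)

    def test_interval_contains_point_estimate(self, study_bags):
        fit = fit_multigroup(study_bags)
        assert 0 <= fit.r_squared <= 1
        for cell, (lo, hi) in fit.slope_intervals.items():
            assert lo <= fit.slopes[cell] <= hi

    def test_recovery_within_intervals_on_noisy_data(self):
        cfg = default_study_config(seed=17)
        fit = fit_multigroup(generate_bags(cfg))
        inside = sum(lo <= -cfg.true_k_table[c] <= hi
                     for c, (lo, hi) in fit.slope_intervals.items())
        assert inside >= 10  # 12 cells, 95% intervals

    def test_cell_with_single_time_point_raises_naming_cell(self):
        bags = [BagRecord("1", "1-1", True, True, "beech", m, r, 90, 3.0, 2.7)
                for m in ("L", "M") for r in (1, 2)]
        with pytest.raises(EstimationError, match="Yes-Yes-Beech"):
            fit_multigroup(bags)

    def test_gdd_time_basis_rescales_slopes_by_constant_factor(self, noiseless_bags):
        # constant soil temperature: GDD accrues at a fixed daily rate, so
        # each slope is the year-fraction slope divided by GDD per
        # year-fraction (exact algebraic identity)
        log = generate_temperature_log(0, 90, [15.0], interval_minutes=1440)
        gdd = accumulate_gdd(log, base=5.0)
        plots = {r.plot for r in noiseless_bags}
        fit_y = fit_multigroup(noiseless_bags)
        fit_g = fit_multigroup(noiseless_bags, time_basis="gdd",
                               gdd_by_plot={p: gdd for p in plots})
        factor = 0.0822 / 300.0  # year-fraction per degree-day at 10 GDD/day
        for cell in fit_y.slopes:
            assert fit_g.slopes[cell] == pytest.approx(
                fit_y.slopes[cell] * factor, rel=1e-9)

    def test_covariate_coefficients_reported_with_intervals(self, study_bags):
        plots = sorted({r.plot for r in study_bags})
        cov = pd.DataFrame({"swc_cv": np.linspace(20, 60, len(plots))},
                           index=plots)
        fit = fit_multigroup(study_bags, covariates=cov)
        assert "swc_cv" in fit.covariate_coefficients
        coef, (lo, hi) = fit.covariate_coefficients["swc_cv"]
        assert lo <= coef <= hi


class TestAccumulateGdd:
    def test_constant_15C_for_10_days_gives_100_degree_days(self):
        log = generate_temperature_log(0, 10, [15.0])
        gdd = accumulate_gdd(log, base=5.0)
        assert gdd.iloc[-1] == pytest.approx(100.0)
        assert gdd.loc[1] == pytest.approx(10.0)

    def test_below_base_contributes_zero(self):
        log = generate_temperature_log(0, 10, [4.0])
        assert accumulate_gdd(log, base=5.0).iloc[-1] == 0.0

    def test_alternating_days_sum_by_hand(self):
        log = generate_temperature_log(0, 10, [10.0, 0.0] * 5)
        assert accumulate_gdd(log, base=5.0).iloc[-1] == pytest.approx(25.0)

    def test_series_is_non_decreasing(self):
        log = generate_temperature_log(0, 20, list(range(0, 20)))
        gdd = accumulate_gdd(log, base=5.0)
        assert (gdd.diff().dropna() >= 0).all()

    def test_gappy_day_excluded_with_warning(self):
        log = generate_temperature_log(0, 3, [15.0])
        # knock a hole in day 2 large enough to count as a logging gap
        day2 = log["timestamp"].dt.day == log["timestamp"].dt.day.unique()[1]
        keep = ~(day2 & (log["timestamp"].dt.hour.between(6, 18)))
        with pytest.warns(UserWarning, match="gap"):
            gdd = accumulate_gdd(log[keep], base=5.0)
        assert list(gdd.index) == [1, 3]
        assert gdd.iloc[-1] == pytest.approx(20.0)
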