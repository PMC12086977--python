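import math

import numpy as np
import pytest

from litterdecay.data_model import ALL_CELLS
from litterdecay.synthetic_data import (
    STUDY_SITE_DROPOUT,
    SyntheticConfig,
    SyntheticEnvironmentConfig,
    default_study_config,
    generate_bags,
    generate_moisture_grid,
    generate_temperature_log,
)


def flat_config(**overrides):
    kwargs = dict(true_k_table={c: 1.0 for c in ALL_CELLS}, ln_noise_sd=0.0,
                  seed=0)
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


class TestGenerateBags:
    def test_noiseless_percent_is_closed_form(self):
        records = generate_bags(flat_config())
        for r in (x for x in records if x.removal_day == 90):
            assert r.percent_remaining == pytest.approx(100 * math.exp(-0.2466),
                                                        rel=1e-12)

    def test_full_design_has_648_bags(self):
        assert len(generate_bags(default_study_config(drop_lost_site=False))) == 648

    def test_site_dropout_removes_one_sites_bags(self):
        records = generate_bags(default_study_config())
        assert len(records) == 540  # 648 minus the lost site's 108 bags
        assert STUDY_SITE_DROPOUT.isdisjoint({r.site for r in records})
        assert {r.site for r in records} == {"1", "2", "5", "6", "7"}

    def test_seed_fixes_the_output_stream(self):
        a = generate_bags(default_study_config(seed=5))
        b = generate_bags(default_study_config(seed=5))
        c = generate_bags(default_study_config(seed=6))
        assert [r.final_mass_g for r in a] == [r.final_mass_g for r in b]
        assert [r.final_mass_g for r in a] != [r.final_mass_g for r in c]

    def test_percent_remaining_bounded_in_unit_interval(self):
        records = generate_bags(default_study_config(seed=3, ln_noise_sd=0.4))
        pct = np.array([r.percent_remaining for r in records])
        assert np.all(pct > 0) and np.all(pct <= 100)

    def test_noise_is_mean_zero_on_ln_scale(self):
        # large-n check that ln(percent) averages to the noiseless value
        cfg = flat_config(ln_noise_sd=0.1, n_replicates=60, seed=9)
        records = [r for r in generate_bags(cfg)
                   if r.removal_day == 90 and r.species == "maple"]
        lnpct = np.array([math.log(r.percent_remaining) for r in records])
        assert lnpct.mean() == pytest.approx(math.log(100) - 0.2466,
                                             abs=3 * 0.1 / math.sqrt(len(records)))

    def test_mesh_effects_scale_the_rate(self):
        cfg = flat_config(mesh_effects={"L": 2.0, "M": 1.0, "S": 0.5})
        by_mesh = {}
        for r in generate_bags(cfg):
            if r.removal_day == 30 and r.species == "beech":
                by_mesh[r.mesh] = r.percent_remaining
        assert by_mesh["L"] < by_mesh["M"] < by_mesh["S"]
        assert by_mesh["L"] == pytest.approx(100 * math.exp(-2 * 0.0822))

    def test_mixed_bags_sum_components_exactly(self):
        for r in generate_bags(default_study_config(seed=2)):
            if r.species == "mixed":
                assert r.maple_final_mass_g + r.beech_final_mass_g == \
                    pytest.approx(r.final_mass_g, abs=1e-12)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            flat_config(true_k_table={c: -1.0 for c in ALL_CELLS})

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_study_config(seed=4)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SyntheticConfig.from_yaml(path)
        assert back.true_k_table == dict(cfg.true_k_table)
        assert back.site_dropout == cfg.site_dropout
        assert [r.final_mass_g for r in generate_bags(back)] == \
            [r.final_mass_g for r in generate_bags(cfg)]


class TestMoistureGrid:
    def test_zero_cv_collapses_to_the_mean(self):
        cfg = SyntheticEnvironmentConfig(
            swc_mean_by_exclusion={True: 8.0, False: 15.0},
            swc_cv_by_exclusion={True: 0.0, False: 0.0})
        grid = generate_moisture_grid(cfg, exclusion=False, seed=0)
        assert grid.node_values.shape == (42,)
        assert np.all(grid.node_values == 15.0)

    def test_seeded_grid_is_reproducible(self):
        cfg = SyntheticEnvironmentConfig()
        a = generate_moisture_grid(cfg, exclusion=True, seed=42)
        b = generate_moisture_grid(cfg, exclusion=True, seed=42)
        assert np.array_equal(a.node_values, b.node_values)

    def test_monte_carlo_mean_and_cv_match_configuration(self):
        # rainfall-plot conditions: mean 15.57 % v/v, CV 24.40 %
        cfg = SyntheticEnvironmentConfig()
        nodes = np.concatenate([
            generate_moisture_grid(cfg, exclusion=False, seed=s).node_values
            for s in range(2000)])
        assert nodes.mean() == pytest.approx(15.57, rel=0.01)
        cv = 100 * nodes.std(ddof=1) / nodes.mean()
        assert cv == pytest.approx(24.40, rel=0.05)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            SyntheticEnvironmentConfig(swc_mean_by_exclusion={True: 0.0, False: 15.0})


class TestTemperatureLog:
    def test_constant_profile_gives_exact_daily_means(self):
        log = generate_temperature_log(0, 10, [15.0], interval_minutes=15)
        assert len(log) == 960
        daily = log.groupby(log["timestamp"].dt.normalize())["temp_c"].mean()
        assert np.allclose(daily, 15.0)

    def test_diurnal_cycle_preserves_daily_means(self):
        profile = [12.0, 14.0, 16.0]
        log = generate_temperature_log(0, 3, profile, interval_minutes=30,
                                       diurnal_amplitude=5.0)
        daily = log.groupby(log["timestamp"].dt.normalize())["temp_c"].mean()
        assert np.allclose(daily.to_numpy(), profile)
        assert log["temp_c"].max() > 16.0  # the cycle is actually present

    def test_daily_interval_gives_one_reading_per_day(self):
        log = generate_temperature_log(0, 5, [10.0], interval_minutes=1440)
        assert len(log) == 5
        assert np.allclose(log["temp_c"], 10.0)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_temperature_log(0, 3, [])
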