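import json
import math

import numpy as np
import pandas as pd
import pytest

from spac.experiments import (
    ExperimentConfig,
    MicrometState,
    ModelConfig,
    bin_gs_vpd,
    diurnal_composite,
    forward_penman_monteith,
    invert_penman_monteith,
    metric_decline_time,
    metric_wue,
    run_simulation,
    _scenario_day,
)
from spac.forcing import repeat_forcing


@pytest.fixture(scope="module")
def short_forcing():
    return repeat_forcing(_scenario_day(ExperimentConfig(scenario="e1a")), 2)


class TestDeclineTime:
    def test_exponential_closed_form(self):
        t = np.arange(0, 120)
        g = 10.0 * np.exp(-t / 20.0)
        expected = 20.0 * (math.log(2.0) - math.log(10.0 / 9.0))
        assert metric_decline_time(g) == pytest.approx(expected, abs=0.05)

    def test_constant_series_undefined(self):
        assert math.isnan(metric_decline_time(np.full(50, 5.0)))

    def test_step_drop_crossings_in_same_interval(self):
        g = np.concatenate([np.full(20, 10.0), np.full(20, 2.0)])
        d = metric_decline_time(g)
        assert 0.0 <= d < 1.0  # both crossings within the drop day

    def test_short_series_undefined(self):
        assert math.isnan(metric_decline_time([1.0, 2.0]))


class TestWue:
    def test_doubling_gpp_doubles_wue(self):
        g = np.array([5.0, 6.0, 7.0])
        t = np.array([2.0, 2.5, 3.0])
        assert metric_wue(2 * g, t) == pytest.approx(2 * metric_wue(g, t))

    def test_constant_series_equals_single_ratio(self):
        assert metric_wue(np.full(10, 8.0), np.full(10, 2.0)) == pytest.approx(4.0)

    def test_hand_computed_block(self):
        g = np.arange(1.0, 11.0)
        t = np.arange(2.0, 12.0)
        assert metric_wue(g, t) == pytest.approx(np.mean(g / t))

    def test_zero_transpiration_days_excluded(self):
        g = np.array([5.0, 5.0])
        t = np.array([0.0, 2.0])
        assert metric_wue(g, t) == pytest.approx(2.5)
        with pytest.raises(ValueError):
            metric_wue(g, np.zeros(2))


class TestDiurnalComposite:
    def test_single_day_normalised(self):
        s = np.arange(24.0)
        c = diurnal_composite(s, normalize=True)
        assert c.max() == pytest.approx(1.0)
        np.testing.assert_allclose(c, s / 23.0)

    def test_two_day_alternating_mean(self):
        a, b = np.arange(24.0), np.arange(24.0) + 10.0
        c = diurnal_composite(np.concatenate([a, b]))
        np.testing.assert_allclose(c, (a + b) / 2.0)

    def test_partial_days_excluded(self):
        s = np.concatenate([np.full(24, 2.0), np.full(12, 100.0)])
        np.testing.assert_allclose(diurnal_composite(s), np.full(24, 2.0))


class TestPenmanMonteith:
    def test_forward_inverse_round_trip(self):
        m = MicrometState(Rn=500.0, G=30.0, Ga=0.05, Ta=25.0)
        for gs in (0.002, 0.01, 0.03):
            le = forward_penman_monteith(m, 1500.0, gs)
            assert invert_penman_monteith(m, 1500.0, le) == pytest.approx(gs, rel=1e-12)

    def test_zero_latent_heat(self):
        m = MicrometState(Rn=400.0)
        assert invert_penman_monteith(m, 800.0, 0.0) == 0.0

    def test_monotone_in_latent_heat(self):
        m = MicrometState(Rn=500.0, Ga=0.05, Ta=25.0)
        les = [forward_penman_monteith(m, 1200.0, gs) for gs in (0.005, 0.01, 0.02)]
        gss = [invert_penman_monteith(m, 1200.0, le) for le in les]
        assert gss[0] < gss[1] < gss[2]

    def test_non_physical_denominator_flagged(self):
        m = MicrometState(Rn=10.0, Ga=0.01, Ta=25.0)
        assert math.isnan(invert_penman_monteith(m, 100.0, 5000.0))


class TestBinning:
    def test_single_bin(self):
        out = bin_gs_vpd([0.01, 0.02, 0.03], [50.0, 100.0, 150.0])
        assert len(out) == 1
        assert out["gs_mean"].iloc[0] == pytest.approx(0.02)
        assert out["n"].iloc[0] == 3
        assert out["bin_center"].iloc[0] == pytest.approx(100.0)

    def test_half_open_edges(self):
        out = bin_gs_vpd([1.0, 2.0], [199.999, 200.0])
        assert len(out) == 2  # 200.0 falls in the second bin

    def test_linear_relation_recovered(self):
        d = np.arange(0.0, 2000.0, 0.5)
        gs = 0.05 - 1e-5 * d
        out = bin_gs_vpd(gs, d)
        expected = 0.05 - 1e-5 * out["bin_center"].to_numpy()
        # bin means sit within half a sample spacing of the bin-centre value
        np.testing.assert_allclose(out["gs_mean"].to_numpy(), expected, atol=5e-6)


class TestSimulatorContracts:
    def test_same_seed_bitwise_reproducible(self, short_forcing):
        cfg = ModelConfig(variant="H", seed=3)
        a = run_simulation(short_forcing, cfg)
        b = run_simulation(short_forcing, cfg)
        pd.testing.assert_frame_equal(a.hourly, b.hourly)

    def test_checkpoint_restart_bit_identical(self, short_forcing):
        cfg = ModelConfig(variant="H", seed=3)
        full = run_simulation(short_forcing, cfg)
        first = run_simulation(short_forcing.iloc[:24].reset_index(drop=True), cfg)
        second = run_simulation(
            short_forcing.iloc[24:].reset_index(drop=True), cfg, state=first.state
        )
        stitched = pd.concat([first.hourly, second.hourly], ignore_index=True)
        pd.testing.assert_frame_equal(stitched, full.hourly)

    def test_capacitance_variant_restart(self, short_forcing):
        cfg = ModelConfig(variant="HC", seed=1)
        full = run_simulation(short_forcing, cfg)
        first = run_simulation(short_forcing.iloc[:24].reset_index(drop=True), cfg)
        second = run_simulation(
            short_forcing.iloc[24:].reset_index(drop=True), cfg, state=first.state
        )
        np.testing.assert_allclose(
            second.hourly["T"].to_numpy(), full.hourly["T"].to_numpy()[24:], rtol=1e-12
        )

    def test_baseline_forces_leuning(self):
        with pytest.raises(ValueError, match="Leuning"):
            ModelConfig(variant="baseline", stomata="tuzet")
        assert ModelConfig(variant="baseline").stomata == "leuning"
        assert ModelConfig(variant="H").stomata == "tuzet"
        with pytest.raises(ValueError, match="unknown variant"):
            ModelConfig(variant="HX")

    def test_steady_damage_variant_runs_and_only_loses_conductivity(self, short_forcing):
        from spac.experiments import DamageConfig

        cfg = ModelConfig(
            variant="H-d", damage=DamageConfig(n_classes_xylem=100, n_classes_leaf=50)
        )
        res = run_simulation(short_forcing, cfg)
        kxe = res.hourly["kx_eff"].to_numpy()
        assert (kxe <= cfg.traits.kxmax + 1e-20).all()
        # static vegetation: no recruitment, so memory damage is permanent
        assert (np.diff(kxe) <= 1e-20).all()

    def test_hourly_outputs_have_no_nans_in_core_fields(self, short_forcing):
        res = run_simulation(short_forcing, ModelConfig(variant="H"))
        for col in ("psis", "psix", "psil", "gpp", "T", "fs"):
            assert res.hourly[col].notna().all()

    def test_potential_ordering_when_transpiring(self, short_forcing):
        res = run_simulation(short_forcing, ModelConfig(variant="H"))
        h = res.hourly
        active = h["T"] > 1e-10
        assert (h.loc[active, "psil"] <= h.loc[active, "psix"] + 1e-9).all()
        assert (h.loc[active, "psix"] <= h.loc[active, "psis"] + 1e-9).all()


class TestConfigAndCli:
    def test_yaml_config_round_trip(self, tmp_path):
        from spac.config import build_experiment, load_config

        cfg_text = """
traits: {kxmax: 1.0e-7, LAI: 2.5}
gasx:
  Vcmax25: 55.0
  fl_anchors: [[1.0, 0.5], [0.2, 0.1]]
soil:
  retention: {model: van_genuchten, alpha: 1.5}
experiment: {scenario: e1b, n_days: 5, variants: [baseline, H]}
"""
        path = tmp_path / "cfg.yaml"
        path.write_text(cfg_text)
        cfg = build_experiment(load_config(path), seed=7)
        assert cfg.scenario == "e1b"
        assert cfg.n_days == 5
        assert cfg.model.traits.kxmax == pytest.approx(1.0e-7)
        assert cfg.model.gasx.al == pytest.approx(math.log(2.0))
        assert cfg.seed == 7

    def test_cli_metrics_subcommand(self, tmp_path):
        from click.testing import CliRunner

        from spac.cli import main

        t = np.arange(0, 60)
        daily = pd.DataFrame({"gpp": 10.0 * np.exp(-t / 20.0), "T_mm": np.full(60, 2.0)})
        path = tmp_path / "daily.csv"
        daily.to_csv(path, index=False)
        runner = CliRunner()
        result = runner.invoke(main, ["metrics", "--daily", str(path)])
        assert result.exit_code == 0
        out = json.loads(result.output)
        assert out["decline_time_90_50_days"] == pytest.approx(11.76, abs=0.1)

    def test_cli_run_subcommand_baseline(self, tmp_path, short_forcing):
        from click.testing import CliRunner

        from spac.cli import main
        from spac.forcing import write_forcing_csv

        fpath = tmp_path / "forcing.csv"
        write_forcing_csv(short_forcing.iloc[:24].reset_index(drop=True), fpath)
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["run", "--forcing", str(fpath), "--variant", "baseline",
             "--out", str(tmp_path / "out"), "--seed", "1"],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "baseline_hourly.csv").exists()
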