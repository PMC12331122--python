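"""Circuit simulator: closed-form oracles, invariants, valve model."""

import numpy as np
import pandas as pd
import pytest

from splitvent import (CircuitSpec, LungParams, OrificeValveModel,
                       TableValveModel, VentilatorSettings,
                       characterize_valve, fit_orifice_coefficients,
                       simulate_setting, valve_pressure_drop)
from splitvent.simulator import (ConfigError, VALVE_FEASIBLE_MAX_CMH2O,
                                 DEFAULT_VALVE_K)


class TestRCOracle:
    """Single-branch responses against the first-order RC closed form."""

    def test_step_response_matches_exponential(self, single_branch_pcv):
        # V(t) = C * dP * (1 - exp(-t/tau)), tau = Raw * C = 3 s
        ch = single_branch_pcv.channels
        t = ch["t_s"].to_numpy()
        v = ch["v_sim1"].to_numpy()
        mask = (t >= 0) & (t <= 14.99)  # first inspiration (15 s)
        v_theory = 0.1 * 10.0 * (1.0 - np.exp(-t[mask] / 3.0))
        rms = np.sqrt(np.mean((v[mask] - v_theory) ** 2)) / (0.1 * 10.0)
        assert rms < 0.005

    def test_volume_at_one_time_constant(self, single_branch_pcv):
        ch = single_branch_pcv.channels
        t = ch["t_s"].to_numpy()
        v = ch["v_sim1"].to_numpy()
        v_tau = np.interp(3.0, t, v)
        assert v_tau == pytest.approx(1.0 * (1 - np.exp(-1)), rel=0.005)

    def test_occluded_branch_reaches_elastic_limit(self):
        # inspiratory time >> tau: VT -> C * dP = 200 ml
        s = VentilatorSettings(mode="PCV", rr=2, insp_frac=0.5, peep=0.0,
                               pinsp_above_peep=10.0, rise_time=0.0)
        l1 = LungParams(compliance=0.020, raw=30.0)
        l2 = LungParams(compliance=0.001, raw=1e7)
        c = CircuitSpec(topology="circuit1", tube_resistance_per_limb=0.0,
                        circuit_compliance=1e-3, vent_resistance=1e-2)
        rec = simulate_setting(s, l1, l2, c, duration=60.0)
        vt = rec.channels["v_sim1"].max()
        assert vt == pytest.approx(0.200, rel=0.01)


class TestSimulatorInvariants:

    def test_identical_lungs_are_symmetric(self, pcv_record):
        ch = pcv_record.channels
        np.testing.assert_allclose(ch["q_sim1"], ch["q_sim2"],
                                   rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(ch["p_sim1"], ch["p_sim2"],
                                   rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("record_name", ["pcv_record", "vcv_record"])
    def test_volume_conservation_per_inspiration(self, record_name, request):
        # delivered = branch1 + branch2 + circuit_compliance * node rise
        rec = request.getfixturevalue(record_name)
        ch = rec.channels
        c_ckt = rec.metadata["circuit"]["circuit_compliance"]
        t_cyc = 60.0 / rec.metadata["settings"]["rr"]
        t_insp = t_cyc * rec.metadata["settings"]["insp_frac"]
        fs = rec.sample_rate
        for k in range(20, 30):  # steady-state breaths
            i0 = int(round(k * t_cyc * fs))
            i1 = i0 + int(t_insp * fs)
            delivered = ch["v_vent"][i1] - ch["v_vent"][i0]
            received = (ch["v_sim1"][i1] - ch["v_sim1"][i0]
                        + ch["v_sim2"][i1] - ch["v_sim2"][i0]
                        + c_ckt * (ch["p_vent"][i1] - ch["p_vent"][i0]))
            assert received == pytest.approx(delivered, rel=0.01)

    def test_node_pressure_respects_cap(self):
        # VCV into two stiff lungs is flow-truncated, never above p_max
        s = VentilatorSettings(mode="VCV", rr=30, vt_set_per_lung=0.450)
        lung = LungParams(compliance=0.020, raw=30.0)
        rec = simulate_setting(s, lung, lung, CircuitSpec(topology="circuit1"),
                               duration=30.0)
        assert rec.metadata["cap_limited"]
        assert rec.channels["p_vent"].max() <= s.p_max + 1e-6

    def test_expiration_relaxes_toward_peep(self, pcv_record):
        ch = pcv_record.channels
        t = ch["t_s"].to_numpy()
        # late-expiration alveolar pressure approaches PEEP from above
        t_cyc = 4.0
        mask = (t % t_cyc) > 0.95 * t_cyc
        p_end_exp = ch["p_sim1"].to_numpy()[mask]
        peep = pcv_record.metadata["settings"]["peep"]
        assert np.all(p_end_exp > peep - 1e-9)
        # pressure decreases within late expiration
        assert p_end_exp[-1] < ch["p_sim1"].to_numpy()[mask][0] + 1.0

    def test_deterministic_with_fixed_seed(self, pcv_rr15, lung_normal,
                                           circuit1):
        kw = dict(duration=20.0, noise_sd=(0.05, 0.005), seed=42)
        a = simulate_setting(pcv_rr15, lung_normal, lung_normal, circuit1, **kw)
        b = simulate_setting(pcv_rr15, lung_normal, lung_normal, circuit1, **kw)
        pd.testing.assert_frame_equal(a.channels, b.channels)

    def test_noise_changes_with_seed(self, pcv_rr15, lung_normal, circuit1):
        a = simulate_setting(pcv_rr15, lung_normal, lung_normal, circuit1,
                             duration=20.0, noise_sd=(0.05, 0.005), seed=1)
        b = simulate_setting(pcv_rr15, lung_normal, lung_normal, circuit1,
                             duration=20.0, noise_sd=(0.05, 0.005), seed=2)
        assert not np.allclose(a.channels["p_sim1"], b.channels["p_sim1"])


class TestConfigValidation:

    def test_non_positive_compliance_rejected(self):
        with pytest.raises(ConfigError):
            LungParams(compliance=0.0)

    def test_valve_setting_on_circuit1_rejected(self):
        with pytest.raises(ConfigError):
            CircuitSpec(topology="circuit1", valve_setting=3)

    def test_circuit2_requires_valve_setting(self):
        with pytest.raises(ConfigError):
            CircuitSpec(topology="circuit2")

    def test_duration_below_two_periods_rejected(self, pcv_rr15, lung_normal,
                                                 circuit1):
        with pytest.raises(ConfigError, match="duration"):
            simulate_setting(pcv_rr15, lung_normal, lung_normal, circuit1,
                             duration=5.0)

    def test_mode_requires_matching_target(self):
        with pytest.raises(ConfigError):
            VentilatorSettings(mode="PCV", rr=15, vt_set_per_lung=0.45)
        with pytest.raises(ConfigError):
            VentilatorSettings(mode="VCV", rr=15, pinsp_above_peep=10.0)


class TestValveModel:

    def test_zero_flow_zero_drop_any_setting(self):
        m = OrificeValveModel()
        for s in range(1, 7):
            dp, feasible = valve_pressure_drop(m, s, 0.0)
            assert dp == 0.0 and feasible

    def test_orifice_law_quadratic_in_flow(self):
        m = OrificeValveModel()
        dp1, _ = valve_pressure_drop(m, 3, 15.0)
        dp2, _ = valve_pressure_drop(m, 3, 30.0)
        assert dp2 == pytest.approx(4.0 * dp1)

    def test_high_settings_infeasible_at_50_lpm(self):
        m = OrificeValveModel()
        for s in (5, 6):
            dp, feasible = valve_pressure_drop(m, s, 50.0)
            assert dp > VALVE_FEASIBLE_MAX_CMH2O and not feasible
        _, feasible_open = valve_pressure_drop(m, 1, 50.0)
        assert feasible_open

    def test_characterization_table_shape_and_monotonicity(self):
        flows = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
        table = characterize_valve(OrificeValveModel(), flows)
        assert len(table) == 36
        for f in flows:
            dps = table[table["flow_lpm"] == f].sort_values("setting")
            assert dps["dp_cmh2o"].is_monotonic_increasing

    def test_orifice_resistance_linear_in_flow(self):
        table = characterize_valve(OrificeValveModel(), [10.0, 20.0],
                                   settings=[4])
        r10, r20 = table.sort_values("flow_lpm")["resistance_cmh2o_s_l"]
        assert r20 == pytest.approx(2.0 * r10)

    def test_fit_recovers_orifice_coefficients(self):
        # least-squares oracle on a characterisation-style table
        table = characterize_valve(OrificeValveModel(), [10.0, 25.0, 40.0])
        k_fit = fit_orifice_coefficients(table)
        np.testing.assert_allclose(k_fit.to_numpy(), DEFAULT_VALVE_K,
                                   rtol=1e-9)

    def test_table_model_interpolates_in_q_squared(self):
        table = characterize_valve(OrificeValveModel(), [10.0, 40.0])
        tm = TableValveModel(table.rename(columns={})[
            ["setting", "flow_lpm", "dp_cmh2o"]])
        # exact for an orifice at any intermediate flow
        dp_tm, _ = valve_pressure_drop(tm, 2, 25.0)
        dp_or, _ = valve_pressure_drop(OrificeValveModel(), 2, 25.0)
        assert dp_tm == pytest.approx(dp_or, rel=1e-9)

    def test_invalid_inputs(self):
        m = OrificeValveModel()
        with pytest.raises(ValueError):
            valve_pressure_drop(m, 0, 10.0)
        with pytest.raises(ValueError):
            valve_pressure_drop(m, 7, 10.0)
        with pytest.raises(ValueError):
            valve_pressure_drop(m, 3, -1.0)
        with pytest.raises(ValueError):
            characterize_valve(m, [])
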