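"""Circuit behavioral model: bias mapping, simulators, rails, mismatch."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from tstdpsim.circuit import (
    CircuitBiases,
    DeviceParams,
    active_transistors,
    apply_mismatch,
    biases_to_effective,
    draw_mismatch,
    simulate_event,
    simulate_ramp_ode,
    triplet_params_from_effective,
    unbounded_windows,
)
from tstdpsim.presets import biases_for_params, hippocampal_biases
from tstdpsim.protocols import SpikeTrain, make_pairing, make_quadruplet, make_triplet
from tstdpsim.rules import TripletParams, tstdp_apply

DEV = DeviceParams()

#: Cross-validation parameter set: same amplitude structure as the
#: hippocampal preset, with time constants of roughly twice the canonical
#: values (still ordinary STDP magnitudes).  The per-pulse difference
#: between the event and ramp integration schemes scales as
#: pulse_width/tau, so the scheme comparison is run where that ratio is
#: comfortably small.
XVAL_PARAMS = TripletParams(
    A2_plus=4.6e-3, A2_minus=3.0e-3, A3_plus=9.1e-3, A3_minus=0.0,
    tau_plus=33.6e-3, tau_minus=67.4e-3, tau_x=202e-3, tau_y=228e-3,
)
XVAL_BIASES = biases_for_params(XVAL_PARAMS)


class TestBiasMapping:
    def test_amplitude_current_efolds_per_ut_over_kappa(self):
        b = hippocampal_biases()
        eff0 = biases_to_effective(b, DEV, "minimal14")
        b2 = dataclasses.replace(b, V_A2p=b.V_A2p + DEV.UT / DEV.kappa)
        eff1 = biases_to_effective(b2, DEV, "minimal14")
        assert eff1.I_A2p == pytest.approx(math.e * eff0.I_A2p, rel=1e-9)
        assert eff1.I_A2m == eff0.I_A2m

    def test_raising_ramp_bias_slows_the_ramp(self):
        b = hippocampal_biases()
        eff0 = biases_to_effective(b, DEV, "minimal14")
        b2 = dataclasses.replace(b, V_tp=b.V_tp + 0.05)
        eff1 = biases_to_effective(b2, DEV, "minimal14")
        assert eff1.tau_plus > eff0.tau_plus
        assert eff1.window_plus > eff0.window_plus
        assert eff1.tau_minus == eff0.tau_minus

    def test_minimal13_disables_pair_potentiation_branch(self):
        b = dataclasses.replace(hippocampal_biases(), V_A2p=1.0)
        eff = biases_to_effective(b, DEV, "minimal13")
        assert eff.I_A2p == 0.0
        assert eff.I_A3p > 0.0

    def test_triplet_depression_branch_only_in_full_circuit(self):
        b = dataclasses.replace(hippocampal_biases(), V_A3m=0.5)
        assert biases_to_effective(b, DEV, "minimal14").I_A3m == 0.0
        assert biases_to_effective(b, DEV, "full18").I_A3m > 0.0

    def test_out_of_rail_bias_rejected(self):
        b = dataclasses.replace(hippocampal_biases(), V_A2p=DEV.Vdd + 0.1)
        with pytest.raises(ValueError):
            biases_to_effective(b, DEV, "minimal14")

    def test_windows_dominate_time_constants(self):
        eff = biases_to_effective(hippocampal_biases(), DEV, "minimal14")
        for tau, win in [(eff.tau_plus, eff.window_plus),
                         (eff.tau_minus, eff.window_minus),
                         (eff.tau_y, eff.window_y)]:
            assert win >= tau


class TestEventSimulator:
    def test_no_spikes_no_change(self):
        res = simulate_event(SpikeTrain([]), SpikeTrain([]), XVAL_BIASES, DEV)
        assert res.total_dv == 0.0

    def test_single_pair_closed_form(self):
        eff = biases_to_effective(XVAL_BIASES, DEV, "minimal14")
        dt = 0.010
        res = simulate_event(
            SpikeTrain([0.0]), SpikeTrain([dt]), XVAL_BIASES, DEV, "minimal14"
        )
        dt_circ = dt / DEV.time_accel
        expected = (DEV.pulse_width_accel / DEV.Cw) * eff.I_A2p * math.exp(
            -dt_circ / eff.tau_plus
        )
        assert res.total_dv == pytest.approx(expected, rel=1e-12)

    def test_pairing_window_signs_and_decay(self):
        lags = np.array([5e-3, 10e-3, 20e-3, 50e-3, 100e-3])
        pot, dep = [], []
        for d in lags:
            pre, post = make_pairing(d, 1, 1.0)
            pot.append(simulate_event(pre, post, XVAL_BIASES, DEV).total_dv)
            pre, post = make_pairing(-d, 1, 1.0)
            dep.append(simulate_event(pre, post, XVAL_BIASES, DEV).total_dv)
        pot, dep = np.array(pot), np.array(dep)
        assert np.all(pot > 0) and np.all(dep < 0)
        assert np.all(np.diff(pot) < 0) and np.all(np.diff(-dep) < 0)
        # exponential in |dt|: log-spacing matches the realised tau
        eff = biases_to_effective(XVAL_BIASES, DEV, "minimal14")
        slope = np.diff(np.log(pot)) / np.diff(-lags / DEV.time_accel)
        np.testing.assert_allclose(slope, 1.0 / eff.tau_plus, rtol=1e-6)

    def test_weight_clamped_to_rails(self):
        strong = dataclasses.replace(XVAL_BIASES, V_A2p=1.2)
        pre, post = make_pairing(5e-3, 60, 1.0)
        res = simulate_event(pre, post, strong, DEV, w_init=3.2)
        assert np.all(res.v_w >= 0.0) and np.all(res.v_w <= DEV.Vdd)
        assert res.v_w[-1] == DEV.Vdd

    def test_doubling_cw_halves_every_step(self):
        pre, post = make_quadruplet(20e-3, 5e-3, 3, 1.0)
        eff = biases_to_effective(XVAL_BIASES, DEV, "minimal14")
        big = dataclasses.replace(DEV, Cw=2 * DEV.Cw)
        a = simulate_event(pre, post, eff, DEV).total_dv
        b = simulate_event(pre, post, eff, big).total_dv
        assert b == pytest.approx(a / 2, rel=1e-12)

    def test_overlapping_cross_train_pulses_rejected(self):
        with pytest.raises(ValueError):
            simulate_event(
                SpikeTrain([0.0]), SpikeTrain([0.5e-3]), XVAL_BIASES, DEV
            )

    def test_bad_w_init_rejected(self):
        with pytest.raises(ValueError):
            simulate_event(SpikeTrain([]), SpikeTrain([]), XVAL_BIASES, DEV,
                           w_init=-0.1)


class TestCircuitRealisesTripletRule:
    def test_event_simulator_matches_rule_with_unbounded_windows(self):
        # with the ramp windows removed the circuit *is* the triplet rule,
        # up to the global pulse_width/Cw scale
        eff = unbounded_windows(
            biases_to_effective(XVAL_BIASES, DEV, "minimal14")
        )
        params = triplet_params_from_effective(eff, DEV)
        for pre, post in [
            make_pairing(10e-3, 10, 1.0),
            make_triplet(5e-3, 5e-3, "post_pre_post", 10, 1.0),
            make_quadruplet(-20e-3, 5e-3, 10, 1.0),
        ]:
            dv = simulate_event(pre, post, eff, DEV).total_dv
            scale = 1.0  # params already absorb pulse_width/Cw
            dw = tstdp_apply(pre, post, params).total_dw
            # epsilon read-out offset of the rule is ~1e-9 relative here
            assert dv == pytest.approx(scale * dw, rel=1e-6)


class TestRampSimulator:
    def test_rest_state_without_input(self):
        res = simulate_ramp_ode(SpikeTrain([]), SpikeTrain([]), XVAL_BIASES, DEV)
        assert res.total_dv == 0.0
        assert np.all(res.v_pot == DEV.Vdd)
        assert np.all(res.v_dep == DEV.Vdd)
        assert np.all(res.v_w == DEV.Vdd / 2)

    def test_node_is_triangular_after_one_pre_pulse(self):
        pre = SpikeTrain([1e-3])  # 1 us on the circuit timescale
        res = simulate_ramp_ode(pre, SpikeTrain([]), XVAL_BIASES, DEV)
        eff = biases_to_effective(XVAL_BIASES, DEV, "minimal14")
        pw = DEV.pulse_width_accel
        t0 = 1e-3 / DEV.time_accel
        slope = DEV.Vdd / eff.window_plus
        from tstdpsim.circuit import _node_voltage

        ts = np.array([0.0, t0 + 0.5 * pw, t0 + pw + 1e-6, t0 + pw + 3e-6])
        v = _node_voltage(ts, np.array([t0]), slope, pw, DEV.Vdd)
        assert v[0] == DEV.Vdd          # at rest before the pulse
        assert v[1] == 0.0              # grounded during the pulse
        assert v[2] == pytest.approx(slope * 1e-6)   # linear recovery
        assert v[3] == pytest.approx(slope * 3e-6)
        assert res.total_dv == 0.0      # no post pulse ever gates a current

    def test_too_coarse_step_rejected(self):
        with pytest.raises(ValueError):
            simulate_ramp_ode(SpikeTrain([]), SpikeTrain([]), XVAL_BIASES,
                              DEV, step=DEV.pulse_width_accel)

    def test_single_pair_matches_event_simulator(self):
        pre, post = make_pairing(10e-3, 1, 1.0)
        ev = simulate_event(pre, post, XVAL_BIASES, DEV).total_dv
        rp = simulate_ramp_ode(pre, post, XVAL_BIASES, DEV).total_dv
        assert rp == pytest.approx(ev, rel=0.05)

    @pytest.mark.parametrize("dt_ms", [2, 5, 20, 50, -2, -5, -20, -50])
    def test_pairing_cross_validation(self, dt_ms):
        pre, post = make_pairing(dt_ms * 1e-3, 3, 1.0)
        ev = simulate_event(pre, post, XVAL_BIASES, DEV).total_dv
        rp = simulate_ramp_ode(pre, post, XVAL_BIASES, DEV).total_dv
        assert rp == pytest.approx(ev, rel=0.05)


class TestMismatch:
    def test_zero_sample_is_identity(self):
        eff = biases_to_effective(XVAL_BIASES, DEV, "minimal14")
        sample = {m: 0.0 for m in active_transistors("minimal14")}
        assert apply_mismatch(eff, sample, DEV, "minimal14") == eff

    def test_m7_deviation_divides_pair_current_by_e(self):
        eff = biases_to_effective(XVAL_BIASES, DEV, "minimal14")
        out = apply_mismatch(eff, {"M7": DEV.UT / DEV.kappa}, DEV, "minimal14")
        assert out.I_A2p == pytest.approx(eff.I_A2p / math.e, rel=1e-12)
        assert out.I_A2m == eff.I_A2m
        assert out.I_A3p == eff.I_A3p
        assert out.tau_plus == eff.tau_plus

    def test_m5_deviation_touches_only_potentiation_ramp(self):
        eff = biases_to_effective(XVAL_BIASES, DEV, "minimal14")
        out = apply_mismatch(eff, {"M5": 5e-3}, DEV, "minimal14")
        changed = {"tau_plus", "window_plus"}
        for field in eff._fields:
            if field in changed:
                assert getattr(out, field) != getattr(eff, field)
            else:
                assert getattr(out, field) == getattr(eff, field)

    def test_switch_transistors_are_ideal(self):
        eff = biases_to_effective(XVAL_BIASES, DEV, "minimal14")
        out = apply_mismatch(eff, {"M6": 0.05, "M13": -0.05}, DEV, "minimal14")
        assert out == eff

    def test_labels_restricted_to_variant(self):
        eff = biases_to_effective(XVAL_BIASES, DEV, "minimal14")
        with pytest.raises(ValueError):
            apply_mismatch(eff, {"M2": 1e-3}, DEV, "minimal14")
        with pytest.raises(ValueError):
            apply_mismatch(eff, {"M7": 1e-3}, DEV, "minimal13")
        with pytest.raises(ValueError):
            apply_mismatch(eff, {"M99": 1e-3}, DEV, "full18")

    def test_variant_transistor_counts(self):
        assert len(active_transistors("full18")) == 18
        assert len(active_transistors("minimal14")) == 14
        assert len(active_transistors("minimal13")) == 13

    def test_draw_matches_variant_and_sigma(self):
        rng = np.random.default_rng(0)
        s = draw_mismatch(rng, 0.010, "minimal13")
        assert set(s) == set(active_transistors("minimal13"))
        z = draw_mismatch(rng, 0.0, "minimal13")
        assert all(v == 0.0 for v in z.values())
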