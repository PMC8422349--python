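"""Current-analysis pipeline tests: fits, kinetics, SSI, window, AP-clamp."""

import numpy as np
import pytest

from cav33sim import fitting, gating, vclamp, workbench
from conftest import random_gating_params


def iv_peaks(params, pulse_ms=500.0):
    proto = vclamp.make_iv_protocol(pulse_ms=pulse_ms)
    sw = vclamp.simulate_sweeps(params, proto)
    levels = np.asarray(proto.extras["levels"])
    peaks = np.array([i.min() for i in sw.current])
    return levels, peaks, sw, proto


def pipeline_activation_vhalf(params):
    levels, peaks, _, _ = iv_peaks(params)
    ivfit = fitting.fit_iv(levels, peaks)
    return fitting.fractional_activation(ivfit).v_half


class TestPeakAndTtp:
    def test_monotone_decay_peaks_at_window_start(self):
        t = np.arange(0.0, 100.0, 0.5)
        i = -100.0 * np.exp(-t / 30.0)
        pk, ttp = fitting.peak_and_ttp(t, i, (0.0, 100.0))
        assert pk == -100.0
        assert ttp == 0.0

    def test_empty_window_rejected(self):
        t = np.arange(0.0, 10.0, 0.5)
        with pytest.raises(ValueError):
            fitting.peak_and_ttp(t, -t, (50.0, 60.0))

    def test_variant_time_to_peak_ratios(self, shipped):
        """I860N peaks > 3x slower, I860M ~ 2x slower than wild-type at Vmax."""
        ttp = {}
        for name in ("WT", "I860N", "I860M"):
            levels, peaks, sw, proto = iv_peaks(shipped[name])
            k = int(np.argmin(peaks))
            _, ttp[name] = fitting.peak_and_ttp(sw.time[k], sw.current[k], (0.0, 500.0))
        assert ttp["I860N"] / ttp["WT"] > 3.0
        assert ttp["I860M"] / ttp["WT"] == pytest.approx(2.0, rel=0.25)


class TestIVFit:
    def test_parameter_recovery_from_exact_model(self):
        # peaks generated from the fitted functional form itself
        v = np.arange(-90.0, 31.0, 10.0)
        g, erev, vh, k = 12.0, 120.0, -45.0, 6.0
        i = g * (v - erev) / (1.0 + np.exp(-(v - vh) / k))
        fit = fitting.fit_iv(v, i)
        assert fit.g_max == pytest.approx(g, rel=0.01)
        assert fit.e_rev == pytest.approx(erev, rel=0.01)
        assert fit.v_half == pytest.approx(vh, rel=0.01)

    def test_all_zero_currents_rejected(self):
        v = np.arange(-90.0, 31.0, 10.0)
        with pytest.raises(ValueError):
            fitting.fit_iv(v, np.zeros_like(v))

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fitting.fit_iv([-50, -40, -30], [-10, -20, -15])

    def test_m1425i_peak_current_doubled(self, shipped):
        _, pk_wt, _, _ = iv_peaks(shipped["WT"])
        _, pk_m, _, _ = iv_peaks(shipped["M1425I"])
        ratio = pk_m.min() / pk_wt.min()
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_vmax_among_levels(self, wt):
        levels, peaks, _, _ = iv_peaks(wt)
        fit = fitting.fit_iv(levels, peaks)
        assert fit.v_max in levels


class TestFractionalActivation:
    def test_recovery_from_pure_boltzmann_conductance(self):
        v = np.arange(-90.0, 31.0, 10.0)
        vh, k, erev = -48.0, 5.5, 120.0
        g = 10.0 / (1.0 + np.exp(-(v - vh) / k))
        i = g * (v - erev)
        fit = fitting.fit_iv(v, i)
        act = fitting.fractional_activation(fit)
        assert act.v_half == pytest.approx(vh, abs=0.1)
        assert act.direction == "ascending"

    def test_shift_examples_from_shipped_parameters(self, shipped):
        """The measured activation shifts reproduce the reported 15.5/8.1 mV."""
        vh = {n: pipeline_activation_vhalf(shipped[n]) for n in ("WT", "I860N", "I860M")}
        assert vh["I860N"] - vh["WT"] == pytest.approx(-15.5, abs=0.5)
        assert vh["I860M"] - vh["WT"] == pytest.approx(-8.1, abs=0.5)


class TestFractionalInactivation:
    def test_non_inactivating_current_gives_zero(self):
        t = np.arange(0.0, 600.0, 0.5)
        i = np.full_like(t, -200.0)
        assert fitting.fractional_inactivation_500(t, i, 0.0) == 0.0

    def test_too_short_pulse_rejected(self):
        t = np.arange(0.0, 400.0, 0.5)
        with pytest.raises(ValueError):
            fitting.fractional_inactivation_500(t, -np.exp(-t / 100), 0.0)

    @pytest.mark.parametrize("variant,lo,hi", [
        ("WT", 0.95, 0.98), ("I860N", 0.50, 0.54), ("I860M", 0.85, 0.89)])
    def test_variant_fractions(self, shipped, variant, lo, hi):
        levels, peaks, sw, _ = iv_peaks(shipped[variant])
        k = int(np.argmin(peaks))
        frac = fitting.fractional_inactivation_500(sw.time[k], sw.current[k], 0.0)
        assert lo <= frac <= hi


class TestExpFits:
    def test_exact_exponential_recovery(self):
        t = np.arange(0.0, 600.0, 0.5)
        i = -300.0 * np.exp(-t / 100.0) - 5.0
        fit = fitting.fit_exp_decay(t, i, (0.0, 600.0))
        assert fit.ok
        assert fit.tau == pytest.approx(100.0, rel=1e-3)
        assert fit.offset == pytest.approx(-5.0, abs=0.01)

    def test_constant_current_flagged(self):
        t = np.arange(0.0, 100.0, 0.5)
        fit = fitting.fit_exp_decay(t, np.full_like(t, -50.0), (0.0, 100.0))
        assert not fit.ok

    def test_gate_model_decay_recovers_tau_inact(self, wt):
        # after activation settles, the 5-s decay at constant V is a pure
        # exponential in h with tau = tau_inact(V)
        proto = vclamp.make_iv_protocol(pulse_ms=5000.0, sample_interval=1.0,
                                        v_start=-20, v_end=-20)
        sw = vclamp.simulate_sweeps(wt, proto)
        t, i = sw.time[0], sw.current[0]
        t_start = 10.0 * wt.tau_m(-20.0)  # activation fully settled
        fit = fitting.fit_exp_decay(t, i, (t_start, 5000.0))
        assert fit.tau == pytest.approx(wt.tau_h(-20.0), rel=0.01)

    def test_deactivation_tau_first_order_oracle(self):
        # with a single activation gate (p=1) the tail decays with tau_m(v_tail)
        p = gating.GatingParams(
            name="p1", v_half_act=-50, k_act=6, v_half_inact=-72, k_inact=5,
            p_act=1,
            tau_act_table=[(-70, 40), (-30, 4), (0, 2.5)],
            tau_inact_table=[(-100, 2000), (-30, 2000), (0, 2000)],
            tau_deact_table=[(-120, 1.0), (-100, 1.5), (-80, 2.8)],
        )
        proto = vclamp.make_deactivation_protocol(v_act=-30.0, act_ms=15.0)
        sw = vclamp.simulate_sweeps(p, proto)
        fit = fitting.deactivation_tau(sw)
        assert fit.tau == pytest.approx(p.tau_m(-100.0), rel=0.01)

    def test_variant_deactivation_ratios(self, shipped):
        """Tail deactivation ~9-10x slower for I860N, unchanged for I860M."""
        taus = {}
        for name in ("WT", "I860N", "I860M"):
            act_ms = 15.0 if name == "WT" else 50.0
            vmax = workbench.variant_vmax(shipped[name])
            proto = vclamp.make_deactivation_protocol(v_act=vmax, act_ms=act_ms)
            sw = vclamp.simulate_sweeps(shipped[name], proto)
            taus[name] = fitting.deactivation_tau(sw).tau
        assert 7.0 < taus["I860N"] / taus["WT"] < 11.0
        assert taus["I860M"] / taus["WT"] == pytest.approx(1.1, rel=0.15)


class TestSSI:
    def test_noise_free_recovery(self, wt):
        proto = vclamp.make_ssi_protocol(v_test=workbench.variant_vmax(wt))
        sw = vclamp.simulate_sweeps(wt, proto)
        fit, table = fitting.ssi_curve(sw)
        assert fit.ok and fit.direction == "descending"
        assert fit.v_half == pytest.approx(wt.v_half_inact, abs=0.5)
        # availability ~ 1 at the holding level
        row = table[table.v_conditioning == -100.0]
        assert row.availability.iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_m1425i_inactivation_shift(self, shipped):
        """Steady-state inactivation shift of M1425I vs wild-type: 6.8 mV."""
        fits = {}
        for name in ("WT", "M1425I"):
            proto = vclamp.make_ssi_protocol(v_test=workbench.variant_vmax(shipped[name]))
            sw = vclamp.simulate_sweeps(shipped[name], proto)
            fits[name], _ = fitting.ssi_curve(sw)
        shift = fitting.v_half_shift(fits["WT"], fits["M1425I"])
        assert shift == pytest.approx(-6.8, abs=0.5)


class TestVHalfShift:
    def test_identity_and_antisymmetry(self):
        a = fitting.BoltzmannFit(-45.0, 5.0, "ascending", 0.0, 10)
        b = fitting.BoltzmannFit(-52.5, 5.0, "ascending", 0.0, 10)
        assert fitting.v_half_shift(a, a) == 0.0
        assert fitting.v_half_shift(a, b) == -fitting.v_half_shift(b, a)
        assert fitting.v_half_shift(a, b) == pytest.approx(-7.5)

    def test_direction_mismatch_rejected(self):
        a = fitting.BoltzmannFit(-45.0, 5.0, "ascending", 0.0, 10)
        b = fitting.BoltzmannFit(-72.0, 5.0, "descending", 0.0, 10)
        with pytest.raises(ValueError):
            fitting.v_half_shift(a, b)


class TestWindowCompare:
    def test_wt_only_ratio_one(self, wt):
        df = fitting.window_compare([wt])
        assert df.area_ratio_vs_wt.iloc[0] == 1.0

    def test_requires_wild_type(self, shipped):
        with pytest.raises(ValueError):
            fitting.window_compare([shipped["I860N"]])

    def test_variant_windows_left_shifted_with_expected_sizes(self, shipped):
        df = fitting.window_compare(list(shipped.values())).set_index("variant")
        wt_peak = df.loc["WT", "peak_voltage"]
        assert -55.0 < wt_peak < -48.0
        for name in ("I860N", "I860M", "I1306T", "M1425I"):
            assert -70.0 <= df.loc[name, "peak_voltage"] <= -60.0
        # enlarged windows for I860N / I1306T, not for I860M
        assert df.loc["I860N", "area_ratio_vs_wt"] > 2.0
        assert df.loc["I1306T", "area_ratio_vs_wt"] > 2.0
        assert df.loc["I860M", "area_ratio_vs_wt"] < 2.0


class TestAPClamp:
    def test_zero_current_gives_zero_metrics(self, wt):
        proto = vclamp.make_ap_train_protocol(n=5)
        sw = vclamp.simulate_sweeps(wt, proto)
        for k in range(len(sw.current)):
            sw.current[k] = np.zeros_like(sw.current[k])
        m = fitting.ap_clamp_metrics(sw)
        assert np.allclose(m.persistent_pa, 0) and np.allclose(m.charge_during_pc, 0)
        assert len(m.sweep_index) == 5

    def test_charge_additivity(self, wt):
        proto = vclamp.make_ap_train_protocol(n=3)
        sw = vclamp.simulate_sweeps(wt, proto)
        m = fitting.ap_clamp_metrics(sw)
        t, i = sw.time[0], sw.current[0]
        on = proto.extras["ap_onsets"][1]
        dur = proto.extras["ap_duration_ms"]
        ka = int(np.searchsorted(t, on - 1e-9))
        kb = int(np.searchsorted(t, on + dur + 10.0 - 1e-9))
        total = np.trapezoid(i[ka:kb + 1], t[ka:kb + 1]) * 1e-3
        assert m.charge_during_pc[1] + m.charge_after_pc[1] == pytest.approx(total, rel=1e-6)

    def test_i860n_persistent_current_order_of_magnitude_larger(self, shipped):
        # the pace-making (window) current at the -70 mV baseline, before the
        # first AP of the train, is ~an order of magnitude larger for I860N
        res = {}
        for name in ("WT", "I860N"):
            sw = vclamp.simulate_sweeps(shipped[name], vclamp.make_ap_train_protocol())
            m = fitting.ap_clamp_metrics(sw)
            res[name] = abs(m.persistent_pa[0])
        assert res["I860N"] / res["WT"] > 8.0

    def test_wrong_protocol_rejected(self, wt):
        sw = vclamp.simulate_sweeps(wt, vclamp.make_iv_protocol(v_start=-40, v_end=-30))
        with pytest.raises(ValueError):
            fitting.ap_clamp_metrics(sw)


class TestEndToEndRecovery:
    """Generate noise-free sweep families for random channels and recover them."""

    @pytest.mark.parametrize("seed", range(6))
    def test_random_channel_recovery(self, seed):
        rng = np.random.default_rng(1000 + seed)
        p = random_gating_params(rng)
        vh_meas = pipeline_activation_vhalf(p)
        vh_ref = pipeline_activation_vhalf(
            gating.shift_params(p, 0.0, 0.0, 1.0))  # identity: same pipeline
        assert vh_meas == pytest.approx(vh_ref, abs=1e-9)
        # steady-state inactivation midpoint recovered within 0.5 mV
        proto = vclamp.make_ssi_protocol(v_test=workbench.variant_vmax(p))
        sw = vclamp.simulate_sweeps(p, proto)
        fit, _ = fitting.ssi_curve(sw)
        assert fit.v_half == pytest.approx(p.v_half_inact, abs=0.5)
        # inactivation time constant at Vmax recovered within 2%
        vmax = workbench.variant_vmax(p)
        proto5 = vclamp.make_iv_protocol(pulse_ms=5000.0, sample_interval=1.0,
                                         v_start=vmax, v_end=vmax)
        sw5 = vclamp.simulate_sweeps(p, proto5)
        t_start = 10.0 * p.tau_m(vmax)
        dec = fitting.fit_exp_decay(sw5.time[0], sw5.current[0], (t_start, 5000.0))
        assert dec.tau == pytest.approx(p.tau_h(vmax), rel=0.02)

    def test_full_translation_shifts_measured_vhalf_exactly(self):
        # translating the whole channel (both midpoints AND the voltage axes
        # of the tau tables) by d shifts the measured midpoint by exactly d
        from dataclasses import replace
        rng = np.random.default_rng(7)
        p = random_gating_params(rng)
        d = -9.0
        q = replace(
            p,
            v_half_act=p.v_half_act + d, v_half_inact=p.v_half_inact + d,
            tau_act_table=[(v + d, tau) for v, tau in p.tau_act_table],
            tau_inact_table=[(v + d, tau) for v, tau in p.tau_inact_table],
            tau_deact_table=[(v + d, tau) for v, tau in p.tau_deact_table],
        )
        # shifted channel measured on a correspondingly shifted level grid
        def vhalf(params, v0, v1):
            proto = vclamp.make_iv_protocol(v_start=v0, v_end=v1)
            sw = vclamp.simulate_sweeps(params, proto)
            levels = np.asarray(proto.extras["levels"])
            peaks = np.array([i.min() for i in sw.current])
            return fitting.fractional_activation(fitting.fit_iv(levels, peaks)).v_half
        # same absolute grid for both (kinetic bias is translation-invariant
        # only on a translated grid; use a wide grid to make it negligible)
        shift = vhalf(q, -99.0, 21.0) - vhalf(p, -90.0, 30.0)
        assert shift == pytest.approx(d, abs=0.3)

    def test_noisy_recovery_unbiased(self, wt):
        """With 5%-of-peak noise, the recovered V1/2 is unbiased within 1 mV."""
        proto = vclamp.make_ssi_protocol(v_test=workbench.variant_vmax(wt))
        clean = vclamp.simulate_sweeps(wt, proto)
        peak = max(np.abs(i).max() for i in clean.current)
        vhs = []
        for seed in range(10):
            noisy = vclamp.add_noise(clean, 0.05 * peak, seed=seed)
            fit, _ = fitting.ssi_curve(noisy)
            vhs.append(fit.v_half)
        assert np.mean(vhs) == pytest.approx(wt.v_half_inact, abs=1.0)
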