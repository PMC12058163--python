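"""Voltage-clamp analysis: amplitudes, I-V fits, kinetics, charge, APs."""

import math

import numpy as np
import pytest

from cardioqt import clamp as C
from cardioqt.simulate import GatingSpec, gen_ap, gen_voltage_clamp


def make_sweep(i_fn, *, fs=10000.0, pre_ms=5.0, pulse_ms=50.0, post_ms=5.0, vm=-20.0):
    """Sweep with current i_fn(t_from_pulse_start_ms) inside the pulse."""
    dt = 1000.0 / fs
    n_pre, n_pulse, n_post = (int(round(x / dt)) for x in (pre_ms, pulse_ms, post_ms))
    t = np.arange(n_pre + n_pulse + n_post) * dt
    i = np.zeros_like(t)
    tp = np.arange(n_pulse) * dt
    i[n_pre : n_pre + n_pulse] = i_fn(tp)
    return C.Sweep(t, i, vm, -120.0, float(t[n_pre]), pulse_ms)


class TestAmplitudes:
    def test_peak_minus_end_subtraction(self):
        sweep = make_sweep(lambda t: -100.0 + -1400.0 * (t < 10.0))
        assert C.peak_amplitude(sweep) == pytest.approx(-1400.0, rel=1e-6)

    def test_flat_trace_zero(self):
        sweep = make_sweep(lambda t: np.zeros_like(t))
        assert C.peak_amplitude(sweep) == 0.0
        assert C.sustained_amplitude(sweep) == 0.0

    def test_sustained_flat_pulse(self):
        sweep = make_sweep(lambda t: np.full_like(t, 200.0))
        assert C.sustained_amplitude(sweep) == pytest.approx(200.0)

    def test_sustained_biexponential_plateau(self):
        sweep = make_sweep(lambda t: 150.0 + 400 * np.exp(-t / 1.5) + 200 * np.exp(-t / 4.0),
                           pulse_ms=100.0)
        assert C.sustained_amplitude(sweep) == pytest.approx(150.0, abs=2.0)

    def test_density_arithmetic(self):
        assert C.current_density(-1500.0, 150.0) == -10.0
        assert C.current_density(0.0, 77.0) == 0.0
        assert C.current_density(-1500.0, 300.0) == 0.5 * C.current_density(-1500.0, 150.0)
        with pytest.raises(ValueError):
            C.current_density(-1500.0, 0.0)

    def test_blanking_window_validation(self):
        sweep = make_sweep(lambda t: np.zeros_like(t), pulse_ms=0.2, fs=50000.0)
        with pytest.raises(ValueError):
            C.peak_amplitude(sweep)


class TestIV:
    def test_gating_model_peaks_match_truth(self):
        ss = gen_voltage_clamp(GatingSpec(noise_sd_pA=0.0), "iv_na")
        curve = C.build_iv(ss)
        truth = ss.truth["peak"]
        for vm, dens in zip(curve.vm_mV, curve.density_pA_pF):
            if abs(truth[vm]) > 1.0:
                assert dens == pytest.approx(truth[vm], rel=0.01)

    def test_duplicate_potentials_rejected(self):
        s = make_sweep(lambda t: np.zeros_like(t))
        with pytest.raises(ValueError):
            C.build_iv(C.SweepSet((s, s), "iv_na", 150.0))

    def test_fit_recovers_analytic_curve_parameters(self):
        gmax, erev, vh, k = 1.2, 65.0, -52.9, 4.0
        vm = np.arange(-100.0, 35.0, 5.0)
        i = (vm - erev) * gmax / (1.0 + np.exp(-(vm - vh) / k))
        fit = C.fit_iv(C.IVCurve(vm, i, "peak_minus_end"))
        assert fit.Gmax == pytest.approx(gmax, rel=1e-3)
        assert fit.Erev_mV == pytest.approx(erev, rel=1e-3)
        assert fit.Vh_mV == pytest.approx(vh, rel=1e-3)
        assert fit.k_mV == pytest.approx(k, rel=1e-3)

    def test_fit_on_gating_sweeps_recovers_vh_k_erev(self):
        spec = GatingSpec(noise_sd_pA=0.0)
        fit = C.fit_iv(C.build_iv(gen_voltage_clamp(spec, "iv_na")))
        assert fit.Vh_mV == pytest.approx(spec.Vh_act_mV, abs=0.5)
        assert fit.k_mV == pytest.approx(spec.k_act_mV, abs=0.05)
        assert fit.Erev_mV == pytest.approx(spec.Erev_mV, abs=0.5)

    def test_saturated_limb_is_ohmic(self):
        fit = C.fit_iv(C.build_iv(gen_voltage_clamp(GatingSpec(noise_sd_pA=0.0), "iv_na")))
        vm = 30.0  # far above Vh: occupancy ~ 1
        model = (vm - fit.Erev_mV) * fit.Gmax / (1 + math.exp(-(vm - fit.Vh_mV) / fit.k_mV))
        assert model == pytest.approx((vm - fit.Erev_mV) * fit.Gmax, rel=0.001)


class TestConductanceAndBoltzmann:
    def test_linear_iv_gives_constant_conductance(self):
        vm = np.arange(-60.0, 41.0, 10.0)
        curve = C.IVCurve(vm, 0.5 * (vm - 65.0), "peak_minus_end")
        v, g = C.conductance_curve(curve, 65.0)
        assert np.allclose(g, g[0])

    def test_point_at_erev_excluded(self):
        vm = np.array([-20.0, 0.0, 65.0, 80.0])
        curve = C.IVCurve(vm, vm - 65.0, "peak_minus_end")
        v, _ = C.conductance_curve(curve, 65.0)
        assert 65.0 not in v

    def test_conductance_route_matches_fit_iv_route(self):
        # two routes, one truth: direct I-V fit vs conductance transform + Boltzmann
        spec = GatingSpec(noise_sd_pA=0.0)
        curve = C.build_iv(gen_voltage_clamp(spec, "iv_na"))
        fit = C.fit_iv(curve)
        vm, g = C.conductance_curve(curve, fit.Erev_mV)
        keep = vm <= 20.0  # near Erev the chord conductance is noise-amplifying
        vh, k = C.boltzmann_fit(vm[keep], np.abs(g[keep]), "rising")
        assert vh == pytest.approx(fit.Vh_mV, abs=1.0)
        assert k == pytest.approx(fit.k_mV, abs=0.5)

    def test_boltzmann_falling_recovery_and_midpoint(self):
        vh, k = -86.9, 5.0
        vm = np.arange(-140.0, -10.0, 10.0)
        y = 1.0 / (1.0 + np.exp((vm - vh) / k))
        vh_fit, k_fit = C.boltzmann_fit(vm, y, "falling")
        assert vh_fit == pytest.approx(vh, abs=1e-6)
        assert k_fit == pytest.approx(k, abs=1e-6)
        assert 1.0 / (1.0 + math.exp((vh_fit - vh) / k)) == pytest.approx(0.5, abs=1e-9)

    def test_boltzmann_translation_equivariance(self):
        vm = np.arange(-60.0, 41.0, 5.0)
        y = 1.0 / (1.0 + np.exp(-(vm + 10.0) / 6.0))
        _, k1 = C.boltzmann_fit(vm, y, "rising")
        _, k2 = C.boltzmann_fit(vm + 25.0, y, "rising")
        assert k1 == pytest.approx(k2, rel=1e-6)


class TestInactivationRecovery:
    def test_inactivation_curve_endpoints_and_midpoint(self):
        spec = GatingSpec(noise_sd_pA=0.0)
        pre, norm = C.inactivation_curve(gen_voltage_clamp(spec, "inact_na"))
        assert norm[0] == pytest.approx(1.0, abs=0.01)  # most negative prepulse
        assert norm[-1] == pytest.approx(0.0, abs=0.01)  # fully inactivating
        vh, k = C.boltzmann_fit(pre, norm, "falling")
        assert vh == pytest.approx(spec.Vh_inact_mV, abs=1.0)
        assert k == pytest.approx(spec.k_inact_mV, abs=0.25)

    def test_recovery_tau_recovered(self):
        spec = GatingSpec(noise_sd_pA=0.0)
        fit = C.recovery_from_inactivation(gen_voltage_clamp(spec, "recovery_na"))
        assert fit.tau_react_ms == pytest.approx(spec.tau_react_ms, rel=0.01)

    def test_recovery_saturates_at_one(self):
        ss = gen_voltage_clamp(GatingSpec(noise_sd_pA=0.0), "recovery_na")
        assert ss.truth["peak"][500.0] == pytest.approx(1.0, abs=1e-9)

    def test_too_few_intervals_rejected(self):
        ss = gen_voltage_clamp(GatingSpec(noise_sd_pA=0.0), "recovery_na")
        small = C.SweepSet(ss.sweeps[:3], ss.protocol, ss.cell_capacitance_pF)
        with pytest.raises(ValueError):
            C.recovery_from_inactivation(small)


class TestKinetics:
    def test_mono_decay_tau(self):
        sweep = make_sweep(lambda t: 500.0 * np.exp(-t / 156.0), pulse_ms=500.0, fs=4000.0)
        fit = C.decay_kinetics(sweep, "mono")
        assert fit.tau_inact_mono_ms == pytest.approx(156.0, rel=0.01)

    def test_biexponential_decay_taus(self):
        # near-instant activation so the decay segment is exactly biexponential
        spec = GatingSpec(tau_act_ms=0.01, noise_sd_pA=0.0)
        ss = gen_voltage_clamp(spec, "iv_na")
        sweep = next(s for s in ss.sweeps if s.test_potential_mV == -20.0)
        fit = C.decay_kinetics(sweep, "bi")
        assert fit.tau_fast_inact_ms == pytest.approx(spec.tau_f_ms, rel=0.05)
        assert fit.tau_slow_inact_ms == pytest.approx(spec.tau_s_ms, rel=0.05)
        assert fit.tau_fast_inact_ms < fit.tau_slow_inact_ms
        assert fit.amp_fast_fraction == pytest.approx(spec.frac_fast, abs=0.05)

    def test_degenerate_flat_trace_flagged(self):
        sweep = make_sweep(lambda t: np.full_like(t, 7.0))
        assert C.decay_kinetics(sweep, "mono").degenerate

    def test_single_exponential_bi_fit_degrades_to_mono(self):
        sweep = make_sweep(lambda t: 400.0 * np.exp(-t / 5.0), pulse_ms=50.0, fs=50000.0)
        fit = C.decay_kinetics(sweep, "bi")
        if fit.degraded_to_mono:
            assert fit.tau_inact_mono_ms == pytest.approx(5.0, rel=0.02)
        else:  # both components converge onto the single true tau
            assert fit.tau_fast_inact_ms == pytest.approx(5.0, rel=0.1)
            assert fit.tau_slow_inact_ms == pytest.approx(5.0, rel=0.1)


class TestLateCharge:
    def test_late_fraction_endpoints(self):
        decaying = make_sweep(
            lambda t: -1000.0 * np.maximum(np.exp(-t * np.log(100) / 20.0), 0.01),
            pulse_ms=50.0, fs=50000.0,
        )
        # trace decays to a floor at exactly 1% of its peak
        assert C.late_current_percent(decaying, blank_ms=0.0) == pytest.approx(1.0, abs=0.01)
        flat = make_sweep(lambda t: np.full_like(t, -500.0))
        assert C.late_current_percent(flat) == pytest.approx(100.0)

    def test_late_na_generator_truth(self):
        spec = GatingSpec(tau_act_ms=0.01, noise_sd_pA=0.0)
        ss = gen_voltage_clamp(spec, "late_na")
        measured = C.late_current_percent(ss.sweeps[0], blank_ms=0.0)
        assert measured == pytest.approx(ss.truth["late_percent"][-40.0], abs=0.05)
        assert measured == pytest.approx(0.5, abs=0.05)  # programmed late fraction

    def test_zero_peak_rejected(self):
        with pytest.raises(ValueError):
            C.late_current_percent(make_sweep(lambda t: np.zeros_like(t)))

    def test_charge_flat_trace_zero(self):
        sweep = make_sweep(lambda t: np.full_like(t, 300.0), pulse_ms=500.0, fs=4000.0)
        assert C.charge_density(sweep, 150.0) == pytest.approx(0.0, abs=1e-9)

    def test_charge_exponential_closed_form(self):
        a, tau, dur, cm = 800.0, 30.0, 500.0, 150.0
        sweep = make_sweep(lambda t: a * np.exp(-t / tau), pulse_ms=dur, fs=4000.0)
        expected = a * tau * (1 - math.exp(-dur / tau)) / 1000.0 / cm
        assert C.charge_density(sweep, cm) == pytest.approx(expected, rel=0.02)

    def test_charge_triangle(self):
        b, h = 100.0, 600.0
        sweep = make_sweep(
            lambda t: np.where(t < b, h * (1 - t / b), 0.0), pulse_ms=500.0, fs=4000.0
        )
        assert C.charge_density(sweep, 150.0) == pytest.approx(h * b / 2 / 1000.0 / 150.0, rel=0.02)

    def test_charge_linearity(self):
        f1 = lambda t: 500.0 * np.exp(-t / 20.0)
        f2 = lambda t: 300.0 * np.exp(-t / 20.0)
        s1 = make_sweep(f1, pulse_ms=500.0, fs=4000.0)
        s2 = make_sweep(f2, pulse_ms=500.0, fs=4000.0)
        s12 = make_sweep(lambda t: f1(t) + f2(t), pulse_ms=500.0, fs=4000.0)
        assert C.charge_density(s12, 150.0) == pytest.approx(
            C.charge_density(s1, 150.0) + C.charge_density(s2, 150.0), rel=1e-6
        )

    def test_density_scales_inversely_with_capacitance(self):
        sweep = make_sweep(lambda t: 500.0 * np.exp(-t / 20.0), pulse_ms=500.0, fs=4000.0)
        assert C.charge_density(sweep, 300.0) == pytest.approx(
            0.5 * C.charge_density(sweep, 150.0), rel=1e-9
        )


class TestIK1:
    def test_linear_model_reproduced_at_all_potentials(self):
        spec = GatingSpec(Gmax_nS=30.0, Erev_mV=-85.0, noise_sd_pA=0.0)
        ss = gen_voltage_clamp(spec, "ik1")
        curve = C.ik1_measure(ss)
        assert curve.vm_mV.size == 10
        assert np.all(np.diff(curve.vm_mV) > 0)
        expected = 30.0 * (curve.vm_mV + 85.0) / spec.capacitance_pF
        assert np.allclose(curve.density_pA_pF, expected, atol=1e-9)

    def test_zero_traces_zero_curve(self):
        ss = gen_voltage_clamp(GatingSpec(Gmax_nS=0.0, noise_sd_pA=0.0), "ik1")
        assert np.allclose(C.ik1_measure(ss).density_pA_pF, 0.0)


class TestAP:
    def test_trapezoidal_ap_linear_repolarization(self):
        # RMP -80, peak +40, linear 100-ms repolarisation: APDx = x ms
        fs, dt = 10000.0, 0.1
        t = np.arange(0, 150.0, dt)
        v = np.full_like(t, -80.0)
        up = (t >= 20.0) & (t < 21.0)
        v[up] = -80.0 + 120.0 * (t[up] - 20.0)
        rep = (t >= 21.0) & (t <= 121.0)
        v[rep] = 40.0 - 1.2 * (t[rep] - 21.0)
        sweep = C.Sweep(t, v, 0.0, -80.0, 20.0, 2.0)
        m = C.ap_metrics(sweep, (20.0, 22.0))
        assert m.RMP_mV == pytest.approx(-80.0)
        assert m.APA_mV == pytest.approx(120.0)
        assert m.APD20_ms == pytest.approx(20.0, abs=0.2)
        assert m.APD50_ms == pytest.approx(50.0, abs=0.2)
        assert m.APD90_ms == pytest.approx(90.0, abs=0.2)

    def test_generated_ap_round_trip(self):
        sweep = gen_ap(rmp_mV=-78.0, apa_mV=115.0, apd20_ms=5.0, apd50_ms=15.0, apd90_ms=60.0)
        m = C.ap_metrics(sweep, sweep.meta["stim_window_ms"])
        truth = sweep.meta["truth"]
        assert m.RMP_mV == pytest.approx(truth["RMP_mV"], abs=0.1)
        assert m.APA_mV == pytest.approx(truth["APA_mV"], abs=0.5)
        assert m.APD20_ms == pytest.approx(truth["APD20_ms"], abs=0.5)
        assert m.APD50_ms == pytest.approx(truth["APD50_ms"], abs=0.5)
        assert m.APD90_ms == pytest.approx(truth["APD90_ms"], abs=0.5)
        assert m.APD20_ms <= m.APD50_ms <= m.APD90_ms

    def test_no_ap_raises(self):
        sweep = gen_ap(apa_mV=0.0)
        with pytest.raises(ValueError):
            C.ap_metrics(sweep, sweep.meta["stim_window_ms"])

    def test_rmp_offset_leaves_durations_unchanged(self):
        a = gen_ap(rmp_mV=-75.0)
        b = gen_ap(rmp_mV=-85.0)
        ma = C.ap_metrics(a, a.meta["stim_window_ms"])
        mb = C.ap_metrics(b, b.meta["stim_window_ms"])
        assert ma.APD90_ms == pytest.approx(mb.APD90_ms, abs=0.1)
        assert mb.RMP_mV == pytest.approx(-85.0, abs=0.1)
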