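import numpy as np
import pytest

from puffsense import signals as sp
from puffsense import simulate as sim


def make_raw(optical_time, i_uv, i_r, i_ir, pressure_time, p_abs):
    return sim.RawPuffSignals(
        optical_time=np.asarray(optical_time, dtype=float),
        intensity_uv=np.asarray(i_uv, dtype=float),
        intensity_r=np.asarray(i_r, dtype=float),
        intensity_ir=np.asarray(i_ir, dtype=float),
        pressure_time=np.asarray(pressure_time, dtype=float),
        pressure_abs=np.asarray(p_abs, dtype=float),
        baseline_intensity={},
    )


def triangle_traces(peak=1.0, dt=0.05):
    """A_r triangular pulse: rises 2->4 s, falls 4->6 s, peak at t=4."""
    t = np.arange(0.0, 8.0 + dt / 2, dt)
    a = np.interp(t, [0.0, 2.0, 4.0, 6.0, 8.0], [0.0, 0.0, peak, 0.0, 0.0])
    zeros = np.zeros_like(t)
    return sp.AttenuationTraces(t, zeros, a, zeros, np.full(t.size, 400.0))


class TestAttenuation:
    def test_constant_intensity_gives_zero_attenuation(self):
        t = np.arange(0.0, 6.0, 0.044)
        raw = make_raw(t, np.full(t.size, 5e3), np.full(t.size, 5e3),
                       np.full(t.size, 5e3), t, np.full(t.size, 101325.0))
        atten = sp.compute_attenuation(raw)
        for a in atten.values():
            assert np.allclose(a, 0.0, atol=1e-14)

    def test_decade_drop_gives_unit_attenuation(self):
        t = np.arange(0.0, 8.0, 0.044)
        i = np.full(t.size, 1e4)
        i[(t > 3) & (t < 5)] = 1e3
        raw = make_raw(t, i, i, i, t, np.full(t.size, 101325.0))
        atten = sp.compute_attenuation(raw)
        assert np.max(atten["r"]) == pytest.approx(1.0, rel=1e-12)

    def test_invariant_to_overall_gain(self, ext):
        raw = sim.simulate_puff(sim.PuffConditions(), ext, noise=sim.NOISELESS, seed=4)
        scaled = make_raw(
            raw.optical_time, 3.7 * raw.intensity_uv, 3.7 * raw.intensity_r,
            3.7 * raw.intensity_ir, raw.pressure_time, raw.pressure_abs,
        )
        f1 = sp.process_puff(raw)
        f2 = sp.process_puff(scaled)
        assert f1.as_array() == pytest.approx(f2.as_array(), rel=1e-9)

    def test_short_trace_rejected(self):
        t = np.arange(0.0, 3.0, 0.044)
        raw = make_raw(t, np.ones(t.size), np.ones(t.size), np.ones(t.size),
                       t, np.ones(t.size))
        with pytest.raises(ValueError, match="short"):
            sp.compute_attenuation(raw)

    def test_recovers_simulator_attenuation_at_noise_level(self, ext):
        raw = sim.simulate_puff(sim.PuffConditions(), ext, seed=6)
        atten = sp.compute_attenuation(raw)
        resid = atten["r"] - raw.truth_attenuation[1]
        assert np.std(resid) < 0.02  # consistent with 0.3% intensity noise


class TestInhalationPressure:
    def test_constant_pressure_gives_zero(self):
        t = np.arange(0.0, 6.0, 0.338)
        raw = make_raw(t, np.ones(t.size), np.ones(t.size), np.ones(t.size),
                       t, np.full(t.size, 101325.0))
        assert np.allclose(sp.compute_inhalation_pressure(raw), 0.0, atol=1e-12)

    def test_negative_step_maps_to_positive_inhalation(self):
        t = np.arange(0.0, 10.0, 0.338)
        p = np.full(t.size, 101325.0)
        p[(t > 3) & (t < 6)] -= 500.0
        raw = make_raw(t, np.ones(t.size), np.ones(t.size), np.ones(t.size), t, p)
        dp = sp.compute_inhalation_pressure(raw)
        assert np.max(dp) == pytest.approx(500.0, rel=1e-12)

    def test_simulator_plateau_recovered_within_noise(self, ext):
        raw = sim.simulate_puff(sim.PuffConditions(), ext, seed=8)
        dp = sp.compute_inhalation_pressure(raw)
        assert np.max(dp) == pytest.approx(raw.truth_mean_dp, rel=0.02)


class TestResampling:
    def test_identical_grids_are_identity(self):
        t = np.arange(0.0, 6.0, 0.044)
        p = 101325.0 - np.linspace(0, 100, t.size)
        raw = make_raw(t, np.ones(t.size), np.ones(t.size), np.ones(t.size), t, p)
        traces = sp.resample_common_grid(raw)
        p_amb = np.mean(p[t >= t[-1] - 2.0])
        assert np.allclose(traces.delta_p, p_amb - p, atol=1e-9)

    def test_sine_pressure_within_interpolation_bound(self):
        t_opt = np.arange(0.0, 12.0, 0.044)
        t_pre = np.arange(0.0, 12.0, 0.338)
        omega = 2 * np.pi / 5.0
        p = 101325.0 + 50.0 * np.sin(omega * t_pre)
        raw = make_raw(t_opt, np.ones(t_opt.size), np.ones(t_opt.size),
                       np.ones(t_opt.size), t_pre, p)
        traces = sp.resample_common_grid(raw)
        expected = -(50.0 * np.sin(omega * traces.time)) + np.mean(
            50.0 * np.sin(omega * t_pre[t_pre >= t_pre[-1] - 2.0])
        )
        bound = 0.338**2 / 8 * 50.0 * omega**2 + 1e-9
        assert np.max(np.abs(traces.delta_p - expected)) < bound

    def test_disjoint_spans_rejected(self):
        t_opt = np.arange(0.0, 6.0, 0.044)
        t_pre = np.arange(10.0, 16.0, 0.338)
        raw = make_raw(t_opt, np.ones(t_opt.size), np.ones(t_opt.size),
                       np.ones(t_opt.size), t_pre, np.ones(t_pre.size))
        with pytest.raises(ValueError, match="overlap"):
            sp.resample_common_grid(raw)


class TestEffectiveWindow:
    def test_triangular_pulse_crossings(self):
        window = sp.detect_effective_window(triangle_traces())
        assert window.t0 == pytest.approx(2.2, abs=1e-9)
        assert window.t1 == pytest.approx(5.8, abs=1e-9)

    def test_rectangular_pulse_support(self):
        t = np.arange(0.0, 8.0, 0.044)
        a = np.where((t >= 3.0) & (t <= 5.0), 1.0, 0.0)
        z = np.zeros_like(t)
        traces = sp.AttenuationTraces(t, z, a, z, z)
        window = sp.detect_effective_window(traces)
        assert window.t0 == pytest.approx(3.0, abs=0.05)
        assert window.t1 == pytest.approx(5.0, abs=0.05)

    def test_flat_trace_raises_no_puff(self):
        t = np.arange(0.0, 8.0, 0.044)
        z = np.zeros_like(t)
        with pytest.raises(sp.NoPuffDetectedError):
            sp.detect_effective_window(sp.AttenuationTraces(t, z, z, z, z))

    def test_multimodal_uses_first_rise_last_fall(self, caplog):
        t = np.arange(0.0, 12.0, 0.05)
        a = np.interp(t, [0, 2, 3, 4, 5, 6, 7, 8, 12], [0, 0, 1, 0.02, 0.02, 1, 0, 0, 0])
        z = np.zeros_like(t)
        import logging

        with caplog.at_level(logging.WARNING):
            window = sp.detect_effective_window(sp.AttenuationTraces(t, z, a, z, z))
        assert window.t0 < 3.0 < 6.0 < window.t1 + 1.0
        assert any("crossings" in rec.message for rec in caplog.records)


class TestFeatures:
    def test_constant_attenuation_window_area(self):
        t = np.arange(0.0, 8.0, 0.05)
        a = np.ones_like(t)
        z = np.zeros_like(t)
        traces = sp.AttenuationTraces(t, z, a, z, np.full(t.size, 123.0))
        feats = sp.extract_features(traces, sp.EffectiveWindow(2.0, 4.0))
        assert feats.auc_r == pytest.approx(2.0, rel=1e-12)
        assert feats.mean_dp == pytest.approx(123.0)

    def test_triangle_area_between_tenth_max_crossings(self):
        traces = triangle_traces()
        window = sp.detect_effective_window(traces)
        feats = sp.extract_features(traces, window)
        assert feats.auc_r == pytest.approx(1.98, rel=1e-9)

    def test_window_split_additivity(self):
        traces = triangle_traces()
        full = sp.extract_features(traces, sp.EffectiveWindow(2.2, 5.8)).auc_r
        left = sp.extract_features(traces, sp.EffectiveWindow(2.2, 3.63)).auc_r
        right = sp.extract_features(traces, sp.EffectiveWindow(3.63, 5.8)).auc_r
        assert left + right == pytest.approx(full, rel=1e-9)

    def test_features_track_simulator_quadrature(self, ext):
        raw = sim.simulate_puff(sim.PuffConditions(), ext, noise=sim.NOISELESS, seed=12)
        feats = sp.process_puff(raw)
        direct = np.trapezoid(raw.truth_attenuation, raw.optical_time, axis=1)
        assert feats.as_array()[:3] == pytest.approx(direct, rel=0.01)

    def test_auc_proportional_to_emitted_mass(self, ext):
        """At fixed distribution shape, each AUC is linear in total mass."""
        aucs, masses = [], []
        for scale in (2.0, 3.0, 4.0, 5.0, 6.0):
            em = sim.EmissionModel(mass_scale=scale, cmd_noise=0.0, gsd_noise=0.0,
                                   mass_rel_noise=0.0, coarse_fraction_noise=0.0)
            raw = sim.simulate_puff(sim.PuffConditions(), ext, emission=em,
                                    noise=sim.NOISELESS, seed=1)
            aucs.append(sp.process_puff(raw).as_array()[:3])
            masses.append(raw.truth.as_array().sum())
        aucs = np.array(aucs)
        for j in range(3):
            r = np.corrcoef(masses, aucs[:, j])[0, 1]
            assert r**2 > 0.999
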