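from dataclasses import replace

import numpy as np
import pytest

from puffsense import signals
from puffsense import simulate as sim


def quiet_emission(**overrides):
    """Emission model with puff-to-puff randomness switched off."""
    return sim.EmissionModel(
        cmd_noise=0.0, gsd_noise=0.0, mass_rel_noise=0.0,
        coarse_fraction_noise=0.0, **overrides,
    )


class TestFlow:
    def test_zero_pressure_zero_flow(self):
        assert sim.flow_rate(0.0) == 0.0

    def test_square_root_law_doubles_under_quadrupled_pressure(self):
        q1 = sim.flow_rate(400.0)
        q4 = sim.flow_rate(1600.0)
        assert q4 == pytest.approx(2.0 * q1, rel=1e-12)

    def test_higher_resistance_lowers_flow(self):
        tight = sim.FlowModel(resistance=2.0)
        assert sim.flow_rate(1000.0, tight) < sim.flow_rate(1000.0)

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            sim.flow_rate(-5.0)

    def test_nominal_puffs_draw_one_to_three_lpm(self):
        for t_p in (30.0, 60.0, 120.0):
            q = sim.flow_rate(sim.inhalation_pressure(t_p))
            assert 0.5 < q < 3.0


class TestEmission:
    def test_emitted_mass_vanishes_with_button_duration(self):
        em = quiet_emission()
        rng = np.random.default_rng(0)
        tiny = sim.PuffConditions(20.0, 1e-6, 60.0)
        _, _, mass, _ = em.draw(tiny, 1000.0, rng)
        assert mass < 1e-5

    def test_power_monotonically_raises_cmd_and_mass(self):
        em = quiet_emission()
        rng = np.random.default_rng(0)
        low = em.draw(sim.PuffConditions(16.0, 2.0, 60.0), 1000.0, rng)
        high = em.draw(sim.PuffConditions(24.0, 2.0, 60.0), 1000.0, rng)
        assert high[0] > low[0]  # cmd
        assert high[2] > low[2]  # mass

    def test_mass_monotone_in_duration_and_pressure(self):
        em = quiet_emission()
        rng = np.random.default_rng(0)
        base = em.draw(sim.PuffConditions(20.0, 2.0, 60.0), 800.0, rng)[2]
        longer = em.draw(sim.PuffConditions(20.0, 3.0, 60.0), 800.0, rng)[2]
        harder = em.draw(sim.PuffConditions(20.0, 2.0, 60.0), 1600.0, rng)[2]
        assert longer > base and harder > base

    def test_concentration_pulse_integrates_to_truth_masses(self):
        _, trace, truth, delta_p = sim.emit_aerosol(
            sim.PuffConditions(), quiet_emission(), sim.FlowModel(),
            np.random.default_rng(3),
        )
        q_lps = sim.flow_rate(delta_p) / 60.0
        recovered = np.trapezoid(trace.concentrations, trace.time, axis=1) * q_lps
        assert np.allclose(recovered, truth.as_array(), rtol=0.005)

    def test_number_distribution_is_bimodal_mixture_with_unit_total(self):
        em = sim.EmissionModel()
        dist = em.number_distribution(230.0, 1.9, 0.3)
        assert dist.total_number() == pytest.approx(1.0, rel=1e-9)


class TestSimulatePuff:
    def test_zero_emission_gives_baseline_intensities(self, ext):
        em = quiet_emission(mass_scale=1e-9)
        raw = sim.simulate_puff(sim.PuffConditions(), ext, emission=em,
                                noise=sim.NOISELESS, seed=0)
        for trace in (raw.intensity_uv, raw.intensity_r, raw.intensity_ir):
            assert np.allclose(trace, trace[0], rtol=1e-9)

    def test_beer_lambert_consistency(self, ext):
        raw = sim.simulate_puff(sim.PuffConditions(), ext, noise=sim.NOISELESS, seed=5)
        i0 = raw.baseline_intensity
        for j, (label, trace) in enumerate(
            (("UV", raw.intensity_uv), ("R", raw.intensity_r), ("IR", raw.intensity_ir))
        ):
            recomputed = -np.log10(trace / i0[label])
            assert np.allclose(recomputed, raw.truth_attenuation[j], atol=1e-12)

    def test_single_bin_aerosol_has_constant_attenuation_ratio(self, ext):
        t = np.arange(0.0, 8.0, 0.044)
        pulse = np.where((t > 3.0) & (t < 5.0), 50.0, 0.0)
        conc = np.vstack([np.zeros_like(t), pulse, np.zeros_like(t)])
        atten = sim.attenuation_from_concentrations(
            sim.BinnedConcentrationTrace(t, conc), ext
        )
        mask = pulse > 0
        ratio = atten[0, mask] / atten[1, mask]
        expected = ext.coefficients[1, 0] / ext.coefficients[1, 1]
        assert np.allclose(ratio, expected, rtol=1e-12)

    def test_attenuation_linear_in_concentration(self, ext):
        t = np.arange(0.0, 4.0, 0.044)
        conc = np.abs(np.random.default_rng(1).random((3, t.size)))
        a1 = sim.attenuation_from_concentrations(sim.BinnedConcentrationTrace(t, conc), ext)
        a2 = sim.attenuation_from_concentrations(
            sim.BinnedConcentrationTrace(t, 2.0 * conc), ext
        )
        assert np.allclose(a2, 2.0 * a1, rtol=1e-12)

    def test_unphysical_attenuation_rejected(self, ext):
        em = quiet_emission(mass_scale=5000.0)
        with pytest.raises(ValueError, match="attenuation"):
            sim.simulate_puff(sim.PuffConditions(), ext, emission=em,
                              noise=sim.NOISELESS, seed=0)

    def test_baseline_segments_are_aerosol_free(self, ext):
        raw = sim.simulate_puff(sim.PuffConditions(), ext, noise=sim.NOISELESS, seed=2)
        t = raw.optical_time
        head = raw.truth_attenuation[:, t <= 2.0]
        tail = raw.truth_attenuation[:, t >= t[-1] - 2.0]
        assert np.all(head == 0) and np.all(tail == 0)
        p_tail = raw.pressure_abs[raw.pressure_time >= raw.pressure_time[-1] - 2.0]
        assert np.allclose(p_tail, sim.AMBIENT_PRESSURE, atol=1e-9)


class TestDataset:
    def test_same_seed_reproduces_dataset(self, ext):
        a = sim.generate_dataset(4, ext, seed=42)
        b = sim.generate_dataset(4, ext, seed=42)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.intensity_uv, rb.intensity_uv)
            assert np.array_equal(ra.pressure_abs, rb.pressure_abs)
            assert ra.truth.as_array() == pytest.approx(rb.truth.as_array())

    def test_mean_masses_increase_from_fine_to_coarse_bins(self, ext):
        dataset = sim.generate_dataset(100, ext, seed=9)
        truths = np.array([r.truth.as_array() for r in dataset])
        means = truths.mean(axis=0)
        assert means[2] > means[1] > means[0]
        assert 0.05 < means[0] and means[2] < 20.0  # mg scale

    def test_empty_dataset_rejected(self, ext):
        with pytest.raises(ValueError):
            sim.generate_dataset(0, ext)

    def test_schedules_cover_ranges_and_test_combos_are_interior(self):
        train = sim.default_condition_schedule(100)
        test = sim.test_condition_schedule(10)
        powers = [c.atomizer_power for c in train]
        assert min(powers) == pytest.approx(15.0) and max(powers) == pytest.approx(25.0)
        for c in test:
            assert 15.0 < c.atomizer_power < 25.0
            assert 1.5 < c.button_duration < 3.0
            assert 7.0 < c.pressurization_time < 150.0
        train_tuples = {(c.atomizer_power, c.button_duration, c.pressurization_time)
                        for c in train}
        for c in test:
            assert (c.atomizer_power, c.button_duration, c.pressurization_time) not in train_tuples


class TestRoundTrip:
    def test_noiseless_linear_inversion_recovers_masses(self, ext):
        """Simulate -> features -> exact linear inversion with the true
        extinction matrix and flow model recovers M1-M3 within 2%."""
        raw = sim.simulate_puff(sim.PuffConditions(), ext, noise=sim.NOISELESS, seed=17)
        feats = signals.process_puff(raw)
        g = ext.coefficients.T * sim.OpticalPathConfig().path_length
        integrals = np.linalg.solve(g, feats.as_array()[:3])
        masses = integrals * sim.flow_rate(feats.mean_dp) / 60.0
        assert np.allclose(masses, raw.truth.as_array(), rtol=0.02)

    def test_raw_record_csv_round_trip(self, ext, tmp_path):
        raw = sim.simulate_puff(sim.PuffConditions(), ext, seed=3)
        sim.write_raw_puff(raw, tmp_path, 7)
        back = sim.read_raw_puff(tmp_path, 7)
        assert np.allclose(back.intensity_r, raw.intensity_r, rtol=1e-9)
        assert np.allclose(back.pressure_abs, raw.pressure_abs, rtol=1e-9)
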