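"""Synthetic cohort generator: regressor shape, noise structure, determinism."""

import numpy as np
import pytest

from freqtag.preprocess import remove_dummy
from freqtag.simulate import (
    EccentricityProfile,
    SimulationConfig,
    _ar1_noise,
    dot_speed_deg_per_sec,
    make_block_regressor,
    simulate_cohort,
    simulate_scan,
)
from freqtag.spectral import response_at_frequency, spectrum


class TestBlockRegressor:
    def test_zero_delay_is_cosine_at_tr_centers(self, noiseless_cfg):
        reg = make_block_regressor(noiseless_cfg, delay=0.0)
        retained = reg[noiseless_cfg.dummy_trs:]
        t = np.arange(120) * 2.0 + 1.0  # TR centers, seconds after A onset
        np.testing.assert_allclose(retained, np.cos(2 * np.pi * t / 24.0),
                                   atol=1e-12)

    def test_delay_is_circular_shift(self, noiseless_cfg):
        base = make_block_regressor(noiseless_cfg, delay=0.0)
        shifted = make_block_regressor(noiseless_cfg, delay=6.0)
        # 6 s = 3 samples at TR 2 s; periodicity makes the shift circular
        retained = base[noiseless_cfg.dummy_trs:]
        np.testing.assert_allclose(shifted[noiseless_cfg.dummy_trs:],
                                   np.roll(retained, 3), atol=1e-12)

    def test_cycle_count_after_dummy(self, noiseless_cfg):
        reg = make_block_regressor(noiseless_cfg, delay=0.0)
        retained = reg[noiseless_cfg.dummy_trs:]
        assert retained.size == noiseless_cfg.cycles_per_scan * 12
        # all 10 cycles are identical
        folded = retained.reshape(10, 12)
        np.testing.assert_allclose(folded - folded[0], 0.0, atol=1e-12)

    def test_hrf_shape_peaks_at_requested_delay(self):
        cfg = SimulationConfig(noise_sd=0, drift_coefficients=(0, 0, 0),
                               response_shape="boxcar_hrf")
        reg = make_block_regressor(cfg, delay=5.0)
        cycle = reg[cfg.dummy_trs:cfg.dummy_trs + 12]
        peak_time = np.argmax(cycle) * cfg.tr_seconds + cfg.tr_seconds / 2
        assert abs(peak_time - 5.0) <= cfg.tr_seconds / 2

    @pytest.mark.parametrize("delay", [-0.1, 24.0, 30.0])
    def test_out_of_range_delay_rejected(self, noiseless_cfg, delay):
        with pytest.raises(ValueError):
            make_block_regressor(noiseless_cfg, delay=delay)


class TestSimulateScan:
    def test_noiseless_scan_recovers_amplitude_and_phase(self, noiseless_cfg, rng):
        ts = simulate_scan(noiseless_cfg, amplitude=2.0, delay=0.0, rng=rng)
        assert ts.n_samples == 126
        cr = response_at_frequency(remove_dummy(ts), k=10)
        assert cr.amplitude == pytest.approx(2.0, abs=1e-10)
        # TR-center sampling: zero-delay response has phase 2*pi/24 (15 deg)
        assert cr.phase == pytest.approx(2 * np.pi / 24, abs=1e-10)

    def test_null_scan_has_no_preferred_bin(self, rng):
        cfg = SimulationConfig(noise_sd=1.0, ar1_coefficient=0.0,
                               drift_coefficients=(0, 0, 0))
        hits = 0
        for _ in range(100):
            ts = remove_dummy(simulate_scan(cfg, amplitude=0.0, delay=0.0,
                                            rng=rng))
            if np.argmax(np.abs(spectrum(ts))) == 9:  # array index of bin 10
                hits += 1
        # under the null, bin 10 wins ~1/60 of the time; 10+ wins would be
        # astronomically unlikely
        assert hits < 10

    def test_ar1_autocorrelation_matches_coefficient(self, rng):
        e = _ar1_noise(10_000, sd=1.0, phi=0.4, rng=rng)
        r1 = np.corrcoef(e[:-1], e[1:])[0, 1]
        assert r1 == pytest.approx(0.4, abs=0.05)

    def test_drift_is_removed_by_detrending(self, rng):
        from freqtag.preprocess import NuisanceDesign, detrend
        cfg = SimulationConfig(noise_sd=0.0, drift_coefficients=(1.0, 2.0, 3.0))
        flat = SimulationConfig(noise_sd=0.0, drift_coefficients=(0.0, 0.0, 0.0))
        a = remove_dummy(simulate_scan(cfg, 2.0, 5.0, rng))
        b = remove_dummy(simulate_scan(flat, 2.0, 5.0, rng))
        design = NuisanceDesign.build(a.n_samples)
        ra = response_at_frequency(detrend(a, design), 10)
        rb = response_at_frequency(detrend(b, design), 10)
        assert abs(complex(ra.real, ra.imag) - complex(rb.real, rb.imag)) < 1e-6


class TestCohort:
    def test_same_seed_is_bit_identical(self):
        cfg = SimulationConfig(n_participants=3, n_scans_per_condition=2, seed=7)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for pid in a["scans"]:
            for sa, sb in zip(a["scans"][pid], b["scans"][pid]):
                np.testing.assert_array_equal(sa.values, sb.values)

    def test_profile_controls_vertex_signs(self):
        cfg = SimulationConfig(n_participants=3, n_scans_per_condition=1,
                               noise_sd=0.0, amplitude_sd=0.0,
                               delay_sd_seconds=0.0,
                               drift_coefficients=(0, 0, 0), seed=1)
        profile = EccentricityProfile()
        ecc = {"v_low": 1.0, "v_high": 5.0}
        cohort = simulate_cohort(cfg, profile, ecc)
        for truth in cohort["truth"].values():
            assert truth["v_low"][0] > 0
            assert truth["v_high"][0] < 0

    def test_vertex_outside_domain_rejected(self):
        cfg = SimulationConfig(n_participants=2, seed=0)
        with pytest.raises(ValueError, match="v_far"):
            simulate_cohort(cfg, EccentricityProfile(), {"v_far": 7.0})

    def test_roundtrip_through_tsv(self, tmp_path):
        from freqtag.simulate import load_cohort, write_cohort
        cfg = SimulationConfig(n_participants=2, n_scans_per_condition=2, seed=3)
        cohort = simulate_cohort(cfg)
        write_cohort(cohort, tmp_path / "cohort")
        back = load_cohort(tmp_path / "cohort")
        assert back["config"] == cfg
        for pid in cohort["scans"]:
            for sa, sb in zip(cohort["scans"][pid], back["scans"][pid]):
                np.testing.assert_allclose(sa.values, sb.values, atol=1e-5)


def test_dot_speed_parameter():
    """10 arcmin per update at a 20 Hz update rate is 3.33 deg/s."""
    assert dot_speed_deg_per_sec(10, 20) == pytest.approx(10 / 60 * 20)
    assert dot_speed_deg_per_sec(10, 20) == pytest.approx(3.33, abs=0.005)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(response_delay_seconds=24.0)
    with pytest.raises(ValueError):
        SimulationConfig(ar1_coefficient=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(response_shape="sawtooth")
    assert SimulationConfig().samples_per_scan == 126
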