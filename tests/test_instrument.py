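"""Dual-PEM forward model: Mueller elements, time series, demodulation."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from stokespol import (HarmonicSignalSet, PolarimeterConfig, PolarisationState,
                       analytic_harmonics, detector_intensity, lockin_demodulate,
                       mueller_polariser, mueller_retarder, mueller_rotator,
                       signal_matrix, simulate_time_series)

from conftest import random_states


class TestMuellerElements:
    def test_rotator_identity_and_composition(self):
        assert_allclose(mueller_rotator(0.0), np.eye(4), atol=1e-15)
        assert_allclose(mueller_rotator(np.pi / 2) @ mueller_rotator(-np.pi / 2),
                        np.eye(4), atol=1e-15)
        assert_allclose(mueller_rotator(0.3) @ mueller_rotator(0.4),
                        mueller_rotator(0.7), atol=1e-15)

    def test_rotator_orthogonal(self):
        r = mueller_rotator(0.77)
        assert_allclose(r @ r.T, np.eye(4), atol=1e-15)

    def test_retarder_trivial_cases(self):
        assert_allclose(mueller_retarder(0.0, 1.234), np.eye(4), atol=1e-15)
        assert_allclose(mueller_retarder(np.pi, 0.0), np.diag([1, 1, -1, -1]),
                        atol=1e-15)

    def test_retarder_matches_uniaxial_model_entries(self):
        # independent entry-by-entry construction of the uniaxial retarder
        d, g = 0.5, np.pi / 6
        s2, c2, sd = np.sin(d / 2) ** 2, np.cos(d / 2) ** 2, np.sin(d)
        expected = np.array([
            [1, 0, 0, 0],
            [0, np.cos(4 * g) * s2 + c2, np.sin(4 * g) * s2, -np.sin(2 * g) * sd],
            [0, np.sin(4 * g) * s2, -np.cos(4 * g) * s2 + c2, np.cos(2 * g) * sd],
            [0, np.sin(2 * g) * sd, -np.cos(2 * g) * sd, np.cos(d)]])
        assert_allclose(mueller_retarder(d, g), expected, atol=1e-15)

    def test_polariser_aligned_and_crossed(self):
        h = np.array([1.0, 1.0, 0.0, 0.0])
        assert_allclose(mueller_polariser(0.0) @ h, h, atol=1e-15)
        assert_allclose(mueller_polariser(np.pi / 2) @ h, np.zeros(4), atol=1e-15)

    def test_polariser_malus_average_and_idempotent(self):
        m = mueller_polariser(0.4014)
        out = m @ np.array([1.0, 0, 0, 0])
        assert out[0] == pytest.approx(0.5)
        assert_allclose(m @ m, m, atol=1e-15)
        # output is fully polarised
        assert out[1] ** 2 + out[2] ** 2 + out[3] ** 2 == pytest.approx(out[0] ** 2)


class TestDetectorIntensity:
    def test_unpolarised_input_is_constant_half(self, cfg):
        t = np.linspace(0, cfg.common_period, 57)
        y = detector_intensity(PolarisationState.unpolarised(), cfg, t)
        assert_allclose(y, 0.5, atol=1e-15)

    def test_static_aligned_polariser(self):
        # at t=0 both PEM retardances vanish: pure polariser at beta=0 on H light
        cfg0 = PolarimeterConfig(beta=0.0)
        assert detector_intensity(PolarisationState.linear(0.0), cfg0, 0.0) == \
            pytest.approx(1.0)

    def test_nonnegative_for_physical_states(self, cfg, rng):
        t = np.linspace(0, cfg.common_period, 401)
        for s in random_states(rng, 10):
            y = detector_intensity(PolarisationState(*s), cfg, t)
            assert np.min(y) >= -1e-12

    def test_spectrum_contains_expected_lines(self, cfg):
        # a state exciting all of Q, U, V puts lines at f1 (from V),
        # 2 f1 (from Q) and 2 f2 (from U)
        state = PolarisationState.elliptical(np.deg2rad(20), np.deg2rad(30))
        t, y = simulate_time_series(state, cfg, n_samples=8192)
        spec = np.abs(np.fft.rfft(y - y.mean())) / y.size
        freqs = np.fft.rfftfreq(y.size, d=cfg.common_period / y.size)
        df = freqs[1]
        floor = np.median(spec)
        for f in (cfg.f1, 2 * cfg.f1, 2 * cfg.f2):
            k = int(round(f / df))
            assert spec[k] > 100 * floor, f"missing spectral line at {f}"

    def test_negative_time_rejected(self, cfg):
        with pytest.raises(ValueError):
            detector_intensity(PolarisationState.unpolarised(), cfg, -0.1)


class TestLockinDemodulation:
    def test_constant_series_is_dc_only(self, cfg):
        n = 4096
        h = lockin_demodulate(np.full(n, 3.7), cfg)
        assert h.s_dc == pytest.approx(3.7)
        for x in (h.s_qu1, h.s_qu2, h.s_v):
            assert x == pytest.approx(0.0, abs=1e-12)

    def test_single_tone_recovered(self, cfg):
        n = 8192
        t = np.arange(n) * cfg.common_period / n
        series = 3.0 + 2.0 * np.sin(2 * np.pi * cfg.f1 * t)
        h = lockin_demodulate(series, cfg)
        assert h.s_dc == pytest.approx(3.0)
        assert h.s_v == pytest.approx(2.0)
        assert h.s_qu1 == pytest.approx(0.0, abs=1e-12)
        assert h.s_qu2 == pytest.approx(0.0, abs=1e-12)

    def test_non_commensurate_frequencies_rejected(self):
        cfg_bad = PolarimeterConfig(f1=50.0, f2=50.0 * np.pi / 3)
        with pytest.raises(ValueError, match="commensurate"):
            lockin_demodulate(np.ones(4096), cfg_bad)

    def test_undersampled_series_rejected(self, cfg):
        with pytest.raises(ValueError, match="samples"):
            lockin_demodulate(np.ones(100), cfg)

    def test_agrees_with_bessel_series_oracle(self, cfg, rng):
        """Two independent demodulation routes agree to 1e-6 relative."""
        for s in random_states(rng, 8):
            state = PolarisationState(*s)
            _, y = simulate_time_series(state, cfg)
            num = lockin_demodulate(y, cfg).as_array()
            ana = analytic_harmonics(state, cfg).as_array()
            scale = np.max(np.abs(ana))
            assert_allclose(num, ana, atol=1e-6 * scale)


class TestAnalyticHarmonics:
    def test_unpolarised_input(self, cfg):
        h = analytic_harmonics(PolarisationState.unpolarised(), cfg)
        assert h.s_dc == pytest.approx(0.5)
        for x in (h.s_qu1, h.s_qu2, h.s_v):
            assert x == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_stokes(self, cfg, rng):
        s1, s2 = random_states(rng, 2)
        a, b = 0.7, -1.3
        combo = analytic_harmonics(PolarisationState(*(a * s1 + b * s2)), cfg).as_array()
        parts = (a * analytic_harmonics(PolarisationState(*s1), cfg).as_array()
                 + b * analytic_harmonics(PolarisationState(*s2), cfg).as_array())
        assert_allclose(combo, parts, atol=1e-14)

    def test_signal_matrix_reproduces_harmonics(self, cfg, rng):
        m = signal_matrix(cfg)
        for s in random_states(rng, 3):
            assert_allclose(m @ s, analytic_harmonics(PolarisationState(*s), cfg).as_array(),
                            atol=1e-14)

    def test_signal_matrix_invertible_at_default_geometry(self, cfg):
        m = signal_matrix(cfg)
        assert np.linalg.cond(m) < 50


class TestPropertyInvariants:
    from hypothesis import given, settings, strategies as st

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(ex=st.floats(-np.pi / 4, np.pi / 4), az=st.floats(0, np.pi),
           dop=st.floats(0, 1), t=st.floats(0, 0.5))
    def test_intensity_nonnegative_and_dc_positive(self, ex, az, dop, t):
        """Physical input states always yield non-negative detector
        intensity and a strictly positive DC level."""
        cfg = PolarimeterConfig()
        state = PolarisationState.elliptical(ex, az, intensity=1.0, dop=dop)
        assert detector_intensity(state, cfg, t) >= -1e-12
        assert analytic_harmonics(state, cfg).s_dc > 0


class TestContainers:
    def test_polarisation_state_validation(self):
        with pytest.raises(ValueError):
            PolarisationState(-1.0, 0, 0, 0).validate()
        with pytest.raises(ValueError):
            PolarisationState(1.0, 1.0, 1.0, 0).validate()
        PolarisationState.elliptical(np.deg2rad(41)).validate()

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            PolarimeterConfig(f1=50, f2=50)
        with pytest.raises(ValueError):
            PolarimeterConfig(A1=0.0)
        with pytest.raises(ValueError):
            PolarimeterConfig(f1=-1.0)

    def test_harmonic_set_array_round_trip(self, rng):
        arr = rng.normal(size=(4, 5, 5))
        assert_allclose(HarmonicSignalSet.from_array(arr).as_array(), arr)
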