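"""Uniaxial sample model: propagation, inversion, error profile, baseline."""

import numpy as np
import numpy.ma as ma
import pytest
from numpy.testing import assert_allclose

from stokespol import (SampleMap, axis_from_linear, background_correct,
                       circular_input_error_profile, mueller_retarder,
                       propagate, retardation_from_circular,
                       retardation_full_inversion, sample_mueller)

from conftest import circular_angle_distance

CIRCULAR = np.array([1.0, 0.0, 0.0, 1.0])


class TestSampleMueller:
    def test_zero_retardation_is_sigma_identity(self):
        assert_allclose(sample_mueller(0.0, 0.7, 2.0), np.diag([2.0, 1, 1, 1]))

    def test_polarisation_block_is_rotation_for_sigma_one(self):
        m = sample_mueller(0.7, 0.3, 1.0)
        block = m[1:, 1:]
        assert_allclose(block @ block.T, np.eye(3), atol=1e-14)
        assert np.linalg.det(block) == pytest.approx(1.0)

    def test_equals_ideal_retarder_at_sigma_one(self):
        assert_allclose(sample_mueller(0.5, np.pi / 6, 1.0),
                        mueller_retarder(0.5, np.pi / 6), atol=1e-15)

    def test_sigma_below_one_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            sample_mueller(0.5, 0.0, 0.5)


class TestPropagation:
    def test_circular_input_closed_form(self):
        # with gamma=0: q'=0, u'=sin(d), v'=cos(d)
        smap = SampleMap(np.array([0.8]), np.array([0.0]), np.array([1.0]))
        out = propagate(CIRCULAR, smap)
        assert_allclose(out[1], 0.0, atol=1e-15)
        assert_allclose(out[2], np.sin(0.8))
        assert_allclose(out[3], np.cos(0.8))

    def test_zero_retardation_passes_state_through(self, rng):
        smap = SampleMap(np.zeros((4, 4)), rng.uniform(0, np.pi, (4, 4)),
                         np.ones((4, 4)))
        state = np.array([1.0, 0.6, -0.64, 0.48])
        out = propagate(state, smap)
        assert_allclose(out, state[:, None, None] * np.ones((4, 4)), atol=1e-15)

    def test_norm_preserved_at_sigma_one(self, rng):
        smap = SampleMap(rng.uniform(0, np.pi, (6, 6)), rng.uniform(0, np.pi, (6, 6)),
                         np.ones((6, 6)))
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        out = propagate(np.array([1.0, *v]), smap)
        assert_allclose(out[1] ** 2 + out[2] ** 2 + out[3] ** 2, 1.0, atol=1e-12)

    def test_fully_polarised_condition_preserved(self, rng):
        # with sigma=1 the model keeps I^2 = Q^2+U^2+V^2 for unit states
        smap = SampleMap(np.array([1.1]), np.array([0.4]), np.array([1.0]))
        out = propagate(CIRCULAR, smap)
        assert_allclose(out[0] ** 2, out[1] ** 2 + out[2] ** 2 + out[3] ** 2)

    def test_sigma_sets_output_depolarisation(self):
        """Propagating with sigma = s gives P = 1/s, Dp = sqrt(1 - s^-2)."""
        s = 2.5
        smap = SampleMap(np.array([0.6]), np.array([0.2]), np.array([s]))
        out = propagate(CIRCULAR, smap)
        ip = np.sqrt(out[1] ** 2 + out[2] ** 2 + out[3] ** 2)
        p = ip / out[0]
        assert_allclose(p, 1 / s)
        assert_allclose(np.sqrt(1 - p ** 2), smap.depolarisation)


class TestCircularInversion:
    @pytest.mark.parametrize("v_prime, expected", [(1.0, 0.0), (0.0, np.pi / 2)])
    def test_reference_points(self, v_prime, expected):
        assert retardation_from_circular(v_prime) == pytest.approx(expected)

    def test_clamping_diagnostics(self):
        d, n = retardation_from_circular(np.array([1.0001, 0.5, -1.01]),
                                         return_diagnostics=True)
        assert n == 2
        assert d[0] == 0.0 and d[2] == pytest.approx(np.pi)

    def test_placental_scale_round_trip(self):
        smap = SampleMap(np.array([0.04]), np.array([0.0]), np.array([1.0]))
        out = propagate(CIRCULAR, smap)
        assert retardation_from_circular(out[3])[0] == pytest.approx(0.04, abs=1e-12)

    def test_round_trip_exactness_over_grid(self):
        """Forward then invert reproduces (delta, gamma mod pi) to 1e-10."""
        deltas = np.linspace(0.01, 3.1, 12)
        gammas = np.linspace(0.0, np.pi, 9, endpoint=False)
        dg, gg = np.meshgrid(deltas, gammas, indexing="ij")
        smap = SampleMap(dg, gg, np.ones_like(dg))
        out = propagate(CIRCULAR, smap)
        d_est = retardation_from_circular(out[3])
        g_est = axis_from_linear(out[1], out[2])
        assert np.max(np.abs(d_est - dg)) < 1e-10
        assert np.max(circular_angle_distance(np.asarray(g_est), gg)) < 1e-10

    def test_axis_reference_direction(self):
        # q'=0, u'>0 corresponds to gamma=0
        assert axis_from_linear(np.array([0.0]), np.array([0.3]))[0] == pytest.approx(0.0)

    def test_axis_distinguishes_orthogonal_orientations(self):
        g30 = np.deg2rad(30)
        for g in (g30, g30 + np.pi / 2):
            smap = SampleMap(np.array([0.5]), np.array([g]), np.array([1.0]))
            out = propagate(CIRCULAR, smap)
            est = float(axis_from_linear(out[1], out[2])[0])
            assert circular_angle_distance(est, g) < 1e-12

    def test_axis_masked_where_undefined(self):
        g = axis_from_linear(np.array([0.0, 0.1]), np.array([0.0, 0.2]))
        assert g.mask[0] and not g.mask[1]


class TestFullInversion:
    def test_matches_circular_estimator_for_circular_input(self, rng):
        deltas = rng.uniform(0.1, 3.0, 9)
        gammas = rng.uniform(0, np.pi, 9)
        smap = SampleMap(deltas, gammas, np.ones(9))
        out = propagate(CIRCULAR, smap)
        d_full, g_full, _ = retardation_full_inversion(out[1], out[2], out[3],
                                                       CIRCULAR[1:])
        assert_allclose(d_full, retardation_from_circular(out[3]), atol=1e-9)
        assert np.max(circular_angle_distance(np.asarray(g_full), gammas)) < 1e-9

    def test_unbiased_under_elliptical_input(self):
        """At 41 deg illumination ellipticity the joint inversion recovers
        delta at every orientation while the direct estimator is biased."""
        ell = np.deg2rad(41)
        state = np.array([1.0, np.cos(2 * ell), 0.0, np.sin(2 * ell)])
        gammas = np.linspace(0, np.pi, 24, endpoint=False)
        smap = SampleMap(np.full_like(gammas, 1.0), gammas, np.ones_like(gammas))
        out = propagate(state, smap)
        d_full, _, _ = retardation_full_inversion(out[1], out[2], out[3], state[1:])
        assert np.max(np.abs(d_full - 1.0)) < 1e-6
        d_circ = retardation_from_circular(out[3])
        assert np.max(np.abs(d_circ - 1.0)) > 0.01  # estimator bias is real
        # the joint inversion beats the approximation everywhere
        assert np.all(np.abs(d_full - 1.0) <= np.abs(d_circ - 1.0) + 1e-12)

    def test_zero_retardation_returns_zero_with_masked_axis(self):
        d, g, _ = retardation_full_inversion(np.array([0.0]), np.array([0.0]),
                                             np.array([1.0]), CIRCULAR[1:])
        assert d[0] == pytest.approx(0.0, abs=1e-8)
        assert g.mask[0]


class TestErrorProfile:
    def test_exactly_circular_input_has_zero_error(self):
        prof = circular_input_error_profile(1.0, np.pi / 4)
        assert prof.max_abs < 1e-12

    def test_elliptical_bias_peaks_where_linear_leaks_into_v(self):
        prof = circular_input_error_profile(1.0, np.deg2rad(41))
        assert prof.max_abs > 0.01
        # v' = sin(2g) sin(d) q + cos(d) v for azimuth-0 input: extremes at 2g = +-pi/2
        peak_gamma = prof.gamma[np.argmax(np.abs(prof.error))]
        assert min(abs(peak_gamma - np.pi / 4), abs(peak_gamma - 3 * np.pi / 4)) < 0.05

    def test_envelope_periodicity_half_pi(self):
        grid = np.linspace(0, np.pi, 360, endpoint=False)
        prof = circular_input_error_profile(1.0, np.deg2rad(41), grid)
        # |error| peaks recur every pi/2 with near-identical envelope height
        quarters = np.abs(prof.error).reshape(4, 90).max(axis=1)
        assert_allclose(quarters, quarters[0], rtol=1e-2)
        peaks = [grid[np.argmax(np.abs(prof.error[:180]))],
                 grid[180 + np.argmax(np.abs(prof.error[180:]))]]
        assert peaks[1] - peaks[0] == pytest.approx(np.pi / 2, abs=0.05)

    def test_invalid_ellipticity_rejected(self):
        with pytest.raises(ValueError):
            circular_input_error_profile(1.0, 0.0)


class TestBackgroundCorrection:
    @pytest.fixture()
    def baseline_map(self):
        m = np.full((40, 40), 0.11)
        m[10:20, 10:20] = 0.15
        return m

    def test_region_method_recovers_baseline_and_blob(self, baseline_map):
        corrected, baseline = background_correct(baseline_map, (0, 0, 8, 8),
                                                 method="region")
        assert baseline == pytest.approx(0.11)
        assert corrected[15, 15] == pytest.approx(0.04)
        assert corrected[0, 0] == pytest.approx(0.0, abs=1e-15)

    def test_mode_method_agrees_on_dominant_background(self, baseline_map):
        _, b_region = background_correct(baseline_map, (0, 0, 8, 8), method="region")
        _, b_mode = background_correct(baseline_map, method="mode")
        assert b_mode == pytest.approx(b_region)

    def test_all_zero_map_unchanged(self):
        corrected, baseline = background_correct(np.zeros((5, 5)), method="mode")
        assert baseline == 0.0
        assert_allclose(np.asarray(corrected), 0.0)

    def test_negative_values_are_retained(self):
        # optic axis rotated by 90 deg shows below-baseline retardation
        m = np.full((10, 10), 0.11)
        m[5, 5] = 0.07
        corrected, _ = background_correct(m, (0, 0, 3, 3), method="region")
        assert corrected[5, 5] == pytest.approx(-0.04)

    def test_empty_background_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            background_correct(ma.masked_all((5, 5)), (0, 0, 2, 2), method="region")


class TestRoundTripProperty:
    from hypothesis import given, settings, strategies as st

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(delta=st.floats(1e-3, np.pi - 1e-3), gamma=st.floats(0, np.pi,
                                                                exclude_max=True))
    def test_circular_forward_invert_recovers_parameters(self, delta, gamma):
        """Any (delta, gamma) forward-propagated under circular light is
        recovered exactly by the direct estimators (gamma modulo pi)."""
        smap = SampleMap(np.array([delta]), np.array([gamma]), np.array([1.0]))
        out = propagate(CIRCULAR, smap)
        assert retardation_from_circular(out[3])[0] == pytest.approx(delta, abs=1e-9)
        g = float(axis_from_linear(out[1], out[2])[0])
        assert circular_angle_distance(g, gamma) < 1e-9


class TestSampleMapValidation:
    def test_invariants(self):
        with pytest.raises(ValueError, match="sigma"):
            SampleMap(np.array([0.1]), np.array([0.0]), np.array([0.9])).validate()
        with pytest.raises(ValueError, match="principal"):
            SampleMap(np.array([3.5]), np.array([0.0]), np.array([1.0])).validate()
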