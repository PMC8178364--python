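"""AEC construction: filtering, envelopes, orthogonalisation, vectorisation."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from megstrat.bands import BAND_MAP
from megstrat.cohort import EffectSpec, SubjectRecording, generate_subject
from megstrat.connectivity import (ConnectivityMatrix, aec_matrix,
                                   analytic_envelope, bandpass,
                                   orthogonalize_pair, unpack_edges,
                                   vectorize_edges)

ALPHA = BAND_MAP["alpha"]
FS = 128.0
T = np.arange(int(10 * FS)) / FS


class TestBandpass:
    def test_in_band_amplitude_preserved(self):
        x = np.sin(2 * np.pi * 11.0 * T)
        y = bandpass(x, ALPHA, FS)
        assert np.abs(y[100:-100]).max() == pytest.approx(1.0, rel=0.05)

    def test_one_octave_outside_attenuated_40db(self):
        # an octave above the 14 Hz edge
        x = np.sin(2 * np.pi * 28.0 * T)
        y = bandpass(x, ALPHA, FS)
        assert np.abs(y[100:-100]).max() < 10 ** (-40 / 20)

    def test_dc_removed_and_zero_maps_to_zero(self):
        assert np.abs(bandpass(np.full(T.size, 5.0), ALPHA, FS)).max() < 1e-6
        assert np.allclose(bandpass(np.zeros(T.size), ALPHA, FS), 0.0)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(T.size), BAND_MAP["high_gamma"], FS)


class TestEnvelope:
    def test_constant_sinusoid_envelope_is_amplitude(self):
        env = analytic_envelope(2.0 * np.sin(2 * np.pi * 10 * T))
        assert env[100:-100] == pytest.approx(np.full(T.size - 200, 2.0),
                                              rel=0.01)

    def test_am_signal_recovers_modulator(self):
        mod = 1 + 0.5 * np.sin(2 * np.pi * 0.3 * T)
        env = analytic_envelope(mod * np.sin(2 * np.pi * 10 * T))
        r = np.corrcoef(env[100:-100], mod[100:-100])[0, 1]
        assert r > 0.99

    def test_zero_signal_zero_envelope(self):
        assert np.allclose(analytic_envelope(np.zeros(128)), 0.0)


class TestOrthogonalize:
    def test_self_residual_uncorrelated_and_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        res = orthogonalize_pair(x, x)
        assert np.abs(res - res.mean()).max() < 1e-10

    def test_orthogonal_input_unchanged(self):
        t = np.arange(1000)
        x = np.sin(2 * np.pi * t / 100)
        y = np.cos(2 * np.pi * t / 100)  # exactly out of phase
        assert orthogonalize_pair(x, y) == pytest.approx(y, abs=1e-6)

    def test_partial_correlation_closed_form(self):
        # y = x + z with independent z: residual should be z (up to mean)
        rng = np.random.default_rng(1)
        x, z = rng.standard_normal((2, 2000))
        res = orthogonalize_pair(x, x + z)
        assert abs(np.corrcoef(res, x)[0, 1]) < 1e-10
        assert np.corrcoef(res, z)[0, 1] > 0.99

    def test_constant_regressor_returns_y(self):
        y = np.arange(10.0)
        assert np.array_equal(orthogonalize_pair(np.ones(10), y), y)


class TestAECMatrix:
    def test_shared_envelope_without_correction_gives_unit_aec(self, tiny_config):
        config = replace(tiny_config, noise_scale=0.0)
        eff = [EffectSpec("edge", "alpha", (0, 1), ("PTSD",), 1.0)]
        rec = generate_subject(config, "PTSD", eff, seed=3)
        m = aec_matrix(rec, ALPHA, leakage_correction=False)
        assert m.values[0, 1] > 0.95

    def test_duplicated_channel_with_correction_gives_zero(self, tiny_config):
        rec = generate_subject(replace(tiny_config, noise_scale=0.0),
                               "PTSD", [], seed=3)
        d = rec.data.copy()
        d[:, 1, :] = d[:, 0, :]
        m = aec_matrix(SubjectRecording("dup", "PTSD", d, tiny_config.fs),
                       ALPHA, leakage_correction=True)
        assert abs(m.values[0, 1]) < 0.05

    def test_independent_noise_aec_near_zero(self):
        rng = np.random.default_rng(4)
        rec = SubjectRecording("n", "TC",
                               rng.standard_normal((10, 8, int(10 * FS))), FS)
        m = aec_matrix(rec, ALPHA, leakage_correction=True)
        iu = np.triu_indices(8, 1)
        assert abs(m.values[iu].mean()) < 0.05

    def test_symmetry_and_range(self, tiny_config):
        rec = generate_subject(tiny_config, "TC", [], seed=9)
        m = aec_matrix(rec, ALPHA)
        assert np.array_equal(m.values, m.values.T)
        assert np.all(np.abs(m.values) <= 1.0)

    def test_aec_invariant_to_per_roi_rescaling(self, tiny_config):
        rec = generate_subject(tiny_config, "TC", [], seed=9)
        m1 = aec_matrix(rec, ALPHA)
        scaled = rec.data * np.array([1.0, 7.0, 0.1, 3.0, 2.0])[None, :, None]
        m2 = aec_matrix(SubjectRecording("s", "TC", scaled, tiny_config.fs),
                        ALPHA)
        assert m2.values == pytest.approx(m1.values, abs=1e-8)


class TestEdgeVectorisation:
    def test_90_regions_give_4005_edges(self):
        m = ConnectivityMatrix("s", "alpha", np.zeros((90, 90)))
        assert vectorize_edges(m).values.size == 4005

    def test_toy_order_is_row_major_upper_triangle(self):
        v = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for k, (i, j) in enumerate(pairs):
            v[i, j] = v[j, i] = k + 1
        ev = vectorize_edges(ConnectivityMatrix("s", "alpha", v / 10))
        assert ev.values == pytest.approx((np.arange(6) + 1) / 10)
        assert ev.names[0] == "aec_alpha_0_1"

    def test_pack_unpack_roundtrip(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(-1, 1, (7, 7))
        sym = np.triu(a, 1) + np.triu(a, 1).T
        m = ConnectivityMatrix("s", "beta", sym)
        back = unpack_edges(vectorize_edges(m))
        assert np.array_equal(back.values, m.values)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(n=st.integers(min_value=2, max_value=40),
           seed=st.integers(min_value=0, max_value=2 ** 16))
    def test_edge_count_identity_and_roundtrip_for_any_size(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-1, 1, (n, n))
        sym = np.triu(a, 1) + np.triu(a, 1).T
        ev = vectorize_edges(ConnectivityMatrix("s", "alpha", sym))
        assert ev.values.size == n * (n - 1) // 2
        assert np.array_equal(unpack_edges(ev).values, sym)

    def test_asymmetric_matrix_rejected(self):
        bad = np.zeros((4, 4))
        bad[0, 1] = 0.5
        with pytest.raises(ValueError):
            ConnectivityMatrix("s", "alpha", bad)
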