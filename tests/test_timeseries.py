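"""Preprocessing chain: voxel averaging, confound regression, band-pass
filtering, Pearson/Fisher-z connectivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fconn.timeseries import (ConnectivityTransformer, RoiTimeSeries,
                              average_labeled_voxels, bandpass_chebyshev,
                              build_confound_matrix, fisher_z,
                              pearson_connectivity, regress_confounds)


def make_ts(data, tr=2.0):
    data = np.asarray(data, dtype=float)
    return RoiTimeSeries("s", data, tr, [f"r{i}" for i in range(data.shape[1])])


class TestVoxelAveraging:
    def test_one_voxel_per_region_is_identity_with_reordering(self, rng):
        vox = rng.standard_normal((20, 3))
        ts = average_labeled_voxels(vox, ["c", "a", "b"],
                                    region_order=["a", "b", "c"])
        np.testing.assert_allclose(ts.data, vox[:, [1, 2, 0]])
        assert ts.region_labels == ["a", "b", "c"]

    def test_opposite_voxels_cancel(self, rng):
        x = rng.standard_normal(30)
        ts = average_labeled_voxels(np.column_stack([x, -x]), ["a", "a"])
        np.testing.assert_allclose(ts.data[:, 0], 0.0, atol=1e-12)

    def test_hand_mean(self):
        vox = np.array([[1.0, 2.0, 3.0]])
        ts = average_labeled_voxels(np.repeat(vox, 12, axis=0), ["a"] * 3)
        assert ts.data[0, 0] == pytest.approx(2.0)

    def test_empty_region_raises_with_name(self, rng):
        with pytest.raises(ValueError, match="ghost"):
            average_labeled_voxels(rng.standard_normal((10, 2)), ["a", "a"],
                                   region_order=["a", "ghost"])


class TestConfoundRegression:
    def test_confound_equal_to_region_zeroes_it(self, rng):
        x = rng.standard_normal(50)
        ts = make_ts(np.column_stack([x, rng.standard_normal(50)]))
        res = regress_confounds(ts, x[:, None])
        np.testing.assert_allclose(res.data[:, 0], 0.0, atol=1e-10)

    def test_intercept_only_demeans(self, rng):
        data = rng.standard_normal((40, 3)) + 5.0
        with pytest.warns(UserWarning, match="collinear"):
            # all-zero confound column is pruned, leaving the intercept
            res = regress_confounds(make_ts(data), np.zeros((40, 1)))
        np.testing.assert_allclose(res.data, data - data.mean(0), atol=1e-12)

    def test_residuals_orthogonal_to_confounds(self, rng):
        """OLS residual inner products with every design column vanish."""
        ts = make_ts(rng.standard_normal((80, 5)))
        conf = rng.standard_normal((80, 4))
        res = regress_confounds(ts, conf, add_derivatives=True)
        design = build_confound_matrix(conf)
        prods = np.abs(design.T @ res.data)
        scale = (np.linalg.norm(design, axis=0)[:, None]
                 * np.linalg.norm(res.data, axis=0))
        assert np.all(prods <= 1e-8 * scale)

    def test_frame_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="frames"):
            regress_confounds(make_ts(rng.standard_normal((30, 2))),
                              rng.standard_normal((29, 1)))

    def test_derivative_padding(self):
        conf = np.array([[1.0], [3.0], [6.0]])
        full = build_confound_matrix(conf)
        np.testing.assert_allclose(full[:, 1], [0.0, 2.0, 3.0])


class TestBandpass:
    def amplitude_ratio(self, freq_hz, tr=2.0, n=512):
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * freq_hz * t)
        out = bandpass_chebyshev(make_ts(x[:, None], tr)).data[:, 0]
        core = slice(n // 4, 3 * n // 4)  # ignore filter edge transients
        return np.abs(out[core]).max() / np.abs(x[core]).max()

    def test_dc_removed(self):
        ts = make_ts(np.full((200, 1), 3.7))
        out = bandpass_chebyshev(ts)
        assert np.abs(out.data).max() < 1e-6

    def test_passband_sine_retained(self):
        assert self.amplitude_ratio(0.04) >= 0.9

    def test_stopband_sine_attenuated(self):
        assert self.amplitude_ratio(0.2) <= 0.1

    def test_output_length_preserved(self, rng):
        ts = make_ts(rng.standard_normal((100, 2)))
        assert bandpass_chebyshev(ts).n_frames == 100

    def test_band_above_nyquist_rejected(self, rng):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_chebyshev(make_ts(np.zeros((50, 1))), 0.01, 0.3)


class TestConnectivity:
    def test_duplicate_region_clipped_finite(self, rng):
        x = rng.standard_normal(60)
        z = pearson_connectivity(make_ts(np.column_stack([x, x])))
        assert z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_negated_region_symmetric_value(self, rng):
        x = rng.standard_normal(60)
        z = pearson_connectivity(make_ts(np.column_stack([x, -x])))
        assert z[0, 1] == pytest.approx(-np.arctanh(1 - 1e-7))

    def test_known_correlation_half(self):
        """r = 0.5 -> z = atanh(0.5) = 0.5493 (checked against the
        log-series form atanh(r) = 0.5 log((1+r)/(1-r)))."""
        n = 4000
        t = np.arange(n)
        a = np.sin(0.1 * t)
        b = 0.5 * a + np.sqrt(0.75) * np.sin(0.37 * t + 1.0)
        z = pearson_connectivity(make_ts(np.column_stack([a, b])))
        r = np.tanh(z[0, 1])
        assert 0.5 * np.log((1 + r) / (1 - r)) == pytest.approx(z[0, 1])
        assert z[0, 1] == pytest.approx(0.5493, abs=0.02)

    def test_zero_variance_region_zeroed_with_warning(self, rng):
        data = rng.standard_normal((50, 3))
        data[:, 1] = 2.0
        with pytest.warns(UserWarning, match="zero-variance"):
            z = pearson_connectivity(make_ts(data))
        assert np.all(z[1, :] == 0) and np.all(z[:, 1] == 0)
        assert z[0, 2] != 0

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError, match="frames"):
            pearson_connectivity(make_ts(rng.standard_normal((5, 3))))

    def test_symmetry_zero_diagonal(self, rng):
        z = pearson_connectivity(make_ts(rng.standard_normal((80, 6))))
        np.testing.assert_allclose(z, z.T)
        np.testing.assert_allclose(np.diag(z), 0.0)

    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    def test_fisher_transform_monotone(self, r1, r2):
        if r1 < r2:
            assert fisher_z(np.array(r1)) < fisher_z(np.array(r2))

    def test_affine_rescaling_invariance(self, rng):
        data = rng.standard_normal((70, 4))
        z1 = pearson_connectivity(make_ts(data))
        scaled = data * np.array([2.0, 0.5, 7.0, 1.0]) + np.array([1, -3, 0, 9])
        z2 = pearson_connectivity(make_ts(scaled))
        np.testing.assert_allclose(z1, z2, atol=1e-10)


class TestFullChain:
    def test_chain_deterministic(self, rng):
        data = rng.standard_normal((150, 5))
        conf = rng.standard_normal((150, 3))
        tf = ConnectivityTransformer()
        z1 = tf.fit_transform([data], confounds=[conf])
        z2 = tf.fit_transform([data], confounds=[conf])
        np.testing.assert_array_equal(z1, z2)

    def test_discard_frames_applied(self, rng):
        data = rng.standard_normal((150, 4))
        z_manual = ConnectivityTransformer().fit_transform([data[10:]])
        z_flag = ConnectivityTransformer(discard_frames=10).fit_transform([data])
        np.testing.assert_allclose(z_manual, z_flag)

    def test_confound_regression_removes_shared_signal(self, rng):
        """Signals built as confound + independent noise: after
        regression, |z| between regions is statistically indistinguishable
        from the confound-free case (the shared component is gone)."""
        n = 400
        shared = np.cumsum(rng.standard_normal(n)) / 10
        noise = rng.standard_normal((n, 6))
        with_conf = noise + shared[:, None]
        ts = make_ts(with_conf, tr=2.0)
        cleaned = regress_confounds(ts, shared[:, None])
        z_clean = pearson_connectivity(cleaned)
        z_pure = pearson_connectivity(make_ts(noise))
        z_dirty = pearson_connectivity(make_ts(with_conf))
        iu = np.triu_indices(6, 1)
        # shared signal inflates |z|; regression restores the clean level
        assert np.abs(z_dirty[iu]).mean() > np.abs(z_pure[iu]).mean() + 0.05
        assert abs(np.abs(z_clean[iu]).mean()
                   - np.abs(z_pure[iu]).mean()) < 0.05
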