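"""Preprocessing: discard/segments arithmetic, regression, smoothing,
zero-phase filtering, FD and DVARS."""

import numpy as np
import pytest

from bolddelay import (
    BoldSeries,
    MotionTrace,
    band_pass,
    discard_initial,
    dvars,
    framewise_displacement,
    make_segments,
    regress_confounds,
    smooth_spatial,
)
from bolddelay.preprocess import FWHM_TO_SIGMA


def _series(n_frames=850, shape=(4, 4, 2), tr=0.4, seed=0):
    rng = np.random.default_rng(seed)
    data = 100 + rng.standard_normal(shape + (n_frames,))
    return BoldSeries(data=data, voxel_size=(3, 3, 4), tr=tr,
                      brain_mask=np.ones(shape, dtype=bool))


class TestDiscardAndSegments:
    def test_discard_25_of_850_leaves_330_seconds(self):
        s = discard_initial(_series(), 25)
        assert s.n_frames == 825
        assert s.duration == pytest.approx(330.0)

    def test_discard_zero_is_identity(self):
        s = _series(n_frames=30)
        out = discard_initial(s, 0)
        np.testing.assert_array_equal(out.data, s.data)

    def test_discard_everything_rejected(self):
        with pytest.raises(ValueError):
            discard_initial(_series(n_frames=10), 10)

    def test_remaining_frames_unchanged(self):
        s = _series(n_frames=50)
        out = discard_initial(s, 5)
        np.testing.assert_array_equal(out.data, s.data[..., 5:])

    @pytest.mark.parametrize("fraction,n_frames,duration", [
        (0.2, 170, 68.0), (0.4, 340, 136.0), (0.6, 510, 204.0),
        (0.8, 680, 272.0), (1.0, 825, 330.0),
    ])
    def test_segment_accounting_matches_protocol(self, fraction, n_frames, duration):
        """0.2/0.4/0.6/0.8 of the 340 s scan are 68/136/204/272 s; the full
        post-discard segment is 330 s."""
        post = discard_initial(_series(), 25)
        [(spec, seg)] = make_segments(post, [fraction], n_original=850)
        assert spec.n_frames_segment == n_frames
        assert spec.duration == pytest.approx(duration)
        assert seg.n_frames == n_frames
        np.testing.assert_array_equal(seg.data, post.data[..., :n_frames])

    def test_tiny_fraction_rejected(self):
        post = discard_initial(_series(n_frames=100), 10)
        with pytest.raises(ValueError):
            make_segments(post, [0.01], n_original=100)


class TestRegressConfounds:
    def test_confound_column_removed(self):
        s = _series(n_frames=200)
        conf = np.sin(np.arange(200) / 7.0)[:, None]
        s.data[...] = 100 + 3.0 * conf[:, 0]
        out = regress_confounds(s, conf)
        assert np.abs(out.data).max() < 1e-8

    def test_zero_confounds_demean_only(self):
        s = _series(n_frames=100)
        with pytest.warns(UserWarning):  # all-zero column is collinear with intercept
            out = regress_confounds(s, np.zeros((100, 1)))
        expected = s.data - s.data.mean(axis=-1, keepdims=True)
        np.testing.assert_allclose(out.data, expected, atol=1e-9)

    def test_orthogonal_signal_survives(self):
        """voxel = signal + 2*confound with signal ⟂ confound → residual ≈ signal."""
        n = 400
        t = np.arange(n)
        conf = np.cos(2 * np.pi * 5 * t / n)
        sig = np.sin(2 * np.pi * 3 * t / n)  # orthogonal Fourier modes
        s = _series(n_frames=n, shape=(1, 1, 1))
        s.data[0, 0, 0] = sig + 2.0 * conf
        out = regress_confounds(s, conf[:, None])
        np.testing.assert_allclose(out.data[0, 0, 0], sig, atol=1e-8)

    def test_residuals_orthogonal_to_confounds(self):
        s = _series(n_frames=150)
        rng = np.random.default_rng(1)
        conf = rng.standard_normal((150, 6))
        out = regress_confounds(s, conf)
        flat = out.data.reshape(-1, 150)
        inner = np.abs(flat @ conf)
        norms = np.linalg.norm(flat, axis=1)[:, None] * np.linalg.norm(conf, axis=0)[None, :]
        assert (inner <= 1e-6 * norms).all()

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regress_confounds(_series(n_frames=100), np.zeros((99, 2)))


class TestSmoothSpatial:
    def test_fwhm_zero_identity(self):
        s = _series(n_frames=5)
        np.testing.assert_array_equal(smooth_spatial(s, 0.0).data, s.data)

    def test_constant_frame_unchanged(self):
        s = _series(n_frames=3, shape=(8, 8, 8))
        s.data[...] = 42.0
        np.testing.assert_allclose(smooth_spatial(s, 6.0).data, 42.0, rtol=1e-12)

    def test_impulse_peak_matches_gaussian(self):
        """A single-voxel impulse smoothed at 6 mm peaks at the 3D Gaussian
        normalization constant for sigma = 6/2.3548 mm per axis."""
        shape = (21, 21, 21)
        data = np.zeros(shape + (1,))
        data[10, 10, 10, 0] = 1.0
        s = BoldSeries(data=data, voxel_size=(3, 3, 3), tr=1.0,
                       brain_mask=np.ones(shape, dtype=bool))
        out = smooth_spatial(s, 6.0)
        sigma_vox = 6.0 * FWHM_TO_SIGMA / 3.0  # = 0.8493 voxels per axis
        expected_peak = (1.0 / (np.sqrt(2 * np.pi) * sigma_vox)) ** 3
        assert out.data[10, 10, 10, 0] == pytest.approx(expected_peak, rel=0.02)

    def test_mass_preserved_away_from_boundary(self):
        s = _series(n_frames=2, shape=(16, 16, 16))
        out = smooth_spatial(s, 6.0)
        assert out.data[..., 0].sum() == pytest.approx(s.data[..., 0].sum(), rel=1e-3)


class TestBandPass:
    def _tone(self, freq, n=825, tr=0.4):
        t = np.arange(n) * tr
        data = np.cos(2 * np.pi * freq * t)[None, None, None, :]
        return BoldSeries(data=data, voxel_size=(3, 3, 4), tr=tr,
                          brain_mask=np.ones((1, 1, 1), dtype=bool))

    def test_in_band_tone_preserved_without_phase_shift(self):
        s = self._tone(0.05)
        out = band_pass(s, 0.01, 0.15)
        core = slice(100, -100)  # ignore filter edge transients
        ratio = out.data[0, 0, 0, core].std() / s.data[0, 0, 0, core].std()
        assert ratio >= 0.9
        # zero-phase: cross-correlation of input and output peaks at lag 0
        x = s.data[0, 0, 0, core] - s.data[0, 0, 0, core].mean()
        y = out.data[0, 0, 0, core]
        lags = np.arange(-10, 11)
        r = [np.corrcoef(x[max(0, d):len(x) + min(0, d)],
                         y[max(0, -d):len(y) - max(0, d)])[0, 1] for d in lags]
        assert lags[int(np.argmax(r))] == 0

    def test_out_of_band_tone_suppressed(self):
        s = self._tone(0.5)
        out = band_pass(s, 0.01, 0.15)
        core = slice(100, -100)  # steady-state response, away from transients
        assert out.data[0, 0, 0, core].std() / s.data[0, 0, 0, core].std() <= 0.1

    def test_constant_series_removed(self):
        s = self._tone(0.05)
        s.data[...] = 7.0
        out = band_pass(s, 0.01, 0.15)
        assert np.abs(out.data).max() < 1e-6

    def test_preserves_relative_delay_of_a_shifted_pair(self):
        """Zero-phase filtering must not move the cross-correlation peak of a
        delayed pair."""
        from bolddelay import generate_slfo
        from conftest import brute_force_lag
        from bolddelay.synthetic import delay_series
        x = generate_slfo(825, 0.4, (0.02, 0.12), seed=3)
        y = delay_series(x, [2.0], 0.4)[0]
        data = np.stack([x, y])[:, None, None, :]
        s = BoldSeries(data=data, voxel_size=(3, 3, 4), tr=0.4,
                       brain_mask=np.ones((2, 1, 1), dtype=bool))
        out = band_pass(s, 0.01, 0.15)
        lag, r = brute_force_lag(out.data[1, 0, 0], out.data[0, 0, 0], 10.0, 0.4)
        assert lag == pytest.approx(2.0, abs=0.2)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            band_pass(self._tone(0.05), 0.15, 0.01)


class TestMotionQC:
    def test_zero_motion_zero_fd(self):
        trace = MotionTrace(np.zeros((50, 3)), np.zeros((50, 3)))
        fd, mean_fd, mean_fd_x10 = framewise_displacement(trace)
        assert np.isnan(fd[0])
        assert np.nanmax(fd) == 0.0 and mean_fd == 0.0 and mean_fd_x10 == 0.0

    def test_translation_step_sums_absolute_deltas(self):
        trans = np.zeros((4, 3))
        trans[2:] = [0.1, 0.2, 0.3]
        fd, _, _ = framewise_displacement(MotionTrace(trans, np.zeros((4, 3))))
        assert fd[2] == pytest.approx(0.6, abs=1e-12)
        assert fd[1] == 0.0 and fd[3] == 0.0

    def test_rotation_converted_on_head_sphere(self):
        rot = np.zeros((3, 3))
        rot[1:, 0] = 0.01
        fd, _, _ = framewise_displacement(MotionTrace(np.zeros((3, 3)), rot),
                                          head_radius=50.0)
        assert fd[1] == pytest.approx(0.5, abs=1e-12)

    def test_rescaled_mean_is_ten_times(self):
        rng = np.random.default_rng(0)
        trace = MotionTrace(rng.normal(size=(20, 3)), rng.normal(size=(20, 3)) / 50)
        _, mean_fd, mean_fd_x10 = framewise_displacement(trace)
        assert mean_fd_x10 == pytest.approx(10 * mean_fd)

    def test_dvars_constant_data_zero(self, toy_series):
        s = toy_series(np.full((2, 1, 1, 10), 5.0))
        dv, mean_dv = dvars(s)
        assert np.nanmax(dv) == 0.0 and mean_dv == 0.0

    def test_dvars_hand_computed(self, toy_series):
        data = np.zeros((2, 1, 1, 2))
        data[0, 0, 0] = [0, 3]
        data[1, 0, 0] = [0, 4]
        dv, mean_dv = dvars(toy_series(data))
        assert dv[1] == pytest.approx(np.sqrt((9 + 16) / 2), abs=1e-9)
        assert mean_dv == pytest.approx(3.5355339, abs=1e-6)

    def test_dvars_homogeneous_of_degree_one(self, toy_series):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((3, 2, 1, 30))
        _, m1 = dvars(toy_series(data))
        _, m2 = dvars(toy_series(2 * data))
        assert m2 == pytest.approx(2 * m1)

    def test_empty_mask_rejected(self, toy_series):
        s = toy_series(np.zeros((2, 1, 1, 5)),
                       brain_mask=np.zeros((2, 1, 1), dtype=bool))
        with pytest.raises(ValueError):
            dvars(s)
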