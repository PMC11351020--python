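"""Level binning, normalization, joint TRF estimation, click ERPs."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from conftest import dense_trf_oracle
from leveltrf.deconvolve import (
    bin_by_ground_truth,
    bin_by_inherent_intensity,
    estimate_click_erp,
    estimate_trf,
    normalize_bins,
)
from leveltrf.predictors import Predictor
from leveltrf.preprocess import EEGRecording
from leveltrf.stimuli import ClickTrain, build_trial_schedule


class TestGroundTruthBinning:
    def test_each_level_gets_equal_support(self):
        fs = 256.0
        sched = build_trial_schedule(4, 4, seed=0)
        pred = Predictor(np.abs(np.random.default_rng(0).standard_normal(int(sched.duration * fs))), fs)
        bins = bin_by_ground_truth(pred, sched)
        assert bins.n_bins == 4
        assert np.allclose(bins.support_duration(), sched.duration / 4)

    def test_single_level_schedule_reproduces_predictor(self):
        fs = 128.0
        sched = build_trial_schedule(1, 0, levels=(60.0,), seed=0)
        x = np.abs(np.random.default_rng(1).standard_normal(int(60 * fs)))
        bins = bin_by_ground_truth(Predictor(x, fs), sched)
        assert np.array_equal(bins.binned[0], x)

    def test_partition_conserves_predictor_sample_exactly(self):
        fs = 256.0
        sched = build_trial_schedule(0, 4, seed=3)
        x = np.abs(np.random.default_rng(2).standard_normal(int(sched.duration * fs)))
        bins = bin_by_ground_truth(Predictor(x, fs), sched)
        assert np.array_equal(bins.binned.sum(axis=0), x)
        assert not np.any(bins.masks.sum(axis=0) > 1)


class TestInherentBinning:
    def test_equal_counts_for_continuous_data(self):
        rng = np.random.default_rng(0)
        pred = Predictor(rng.random(100_000), 1000.0)
        bins = bin_by_inherent_intensity(pred, n_bins=4)
        counts = bins.masks.sum(axis=1)
        assert counts.max() - counts.min() <= 1

    def test_monotone_ramp_splits_in_half(self):
        n = 10_000
        pred = Predictor(np.linspace(0.01, 1.0, n), 1000.0)
        bins = bin_by_inherent_intensity(pred, n_bins=2, smooth_width=0.01)
        assert bins.masks[0, : n // 2 - 20].all()
        assert bins.masks[1, n // 2 + 20 :].all()

    def test_octile_binning_gives_equal_time_per_bin(self):
        # eight equal-count bins each hold 1/8 of the session
        fs = 512.0
        rng = np.random.default_rng(1)
        pred = Predictor(np.abs(rng.standard_normal(int(120 * fs))) * rng.random(int(120 * fs)), fs)
        bins = bin_by_inherent_intensity(pred, n_bins=8)
        assert np.allclose(bins.support_duration(), 15.0, atol=1 / fs)

    def test_partition_conserves_predictor(self):
        rng = np.random.default_rng(3)
        x = np.abs(rng.standard_normal(5000))
        bins = bin_by_inherent_intensity(Predictor(x, 500.0), n_bins=8)
        assert np.array_equal(bins.binned.sum(axis=0), x)

    def test_constant_predictor_raises(self):
        with pytest.raises(ValueError, match="constant"):
            bin_by_inherent_intensity(Predictor(np.ones(1000), 100.0), n_bins=4)


class TestNormalization:
    def test_unit_rms_bins_get_scale_one(self):
        fs = 100.0
        x = np.zeros(400)
        x[:200] = 1.0  # rms over support = 1
        sched = build_trial_schedule(2, 0, levels=(60.0, 72.0), seed=0,
                                     trial_duration=2.0, short_segment=1.0)
        bins = bin_by_ground_truth(Predictor(np.ones(400), fs), sched)
        out = normalize_bins(bins)
        assert np.allclose(out.norm_scales, 1.0)

    def test_constant_two_gets_scale_half(self):
        fs = 100.0
        sched = build_trial_schedule(1, 0, levels=(60.0,), seed=0, trial_duration=4.0,
                                     short_segment=1.0)
        bins = bin_by_ground_truth(Predictor(2 * np.ones(400), fs), sched)
        out = normalize_bins(bins)
        assert out.norm_scales[0] == pytest.approx(0.5)
        assert np.allclose(out.reconstruct(), 2.0)

    def test_empty_bin_raises_with_label(self):
        fs = 100.0
        sched = build_trial_schedule(2, 0, levels=(60.0, 72.0), seed=0,
                                     trial_duration=2.0, short_segment=1.0)
        x = np.ones(400)
        lvl = sched.level_at_samples(400, fs)
        x[lvl == 60.0] = 0.0
        bins = bin_by_ground_truth(Predictor(x, fs), sched)
        with pytest.raises(ValueError, match="60"):
            normalize_bins(bins)

    def test_downscaled_level_downscales_fitted_trf(self):
        # one physical kernel, two levels differing by a known gain: after
        # per-bin normalization the fitted kernel for the quiet level shrinks
        # by the same gain factor
        fs = 512.0
        rng = np.random.default_rng(0)
        n = int(120 * fs)
        base = np.abs(rng.standard_normal(n))
        gain = 10 ** (-12 / 20)  # 60 dB vs 72 dB
        mask_quiet = (np.arange(n) // int(5 * fs)) % 2 == 0
        x = np.where(mask_quiet, base * gain, base)
        kernel = np.exp(-0.5 * ((np.arange(20) - 8) / 3.0) ** 2)
        y = fftconvolve(x, kernel)[:n]
        sched = build_trial_schedule(0, 2, levels=(60.0, 72.0), seed=0)
        # build a schedule-free bin set directly from the masks
        from leveltrf.deconvolve import LevelBinSet

        bins = LevelBinSet(
            labels=np.array([60.0, 72.0]),
            binned=np.stack([np.where(mask_quiet, x, 0.0), np.where(~mask_quiet, x, 0.0)]),
            masks=np.stack([mask_quiet, ~mask_quiet]),
            rate=fs,
        )
        trfs = estimate_trf(EEGRecording(y, fs), normalize_bins(bins), (-10.0, 40.0))
        amp_quiet = trfs.kernel(60.0).max()
        amp_loud = trfs.kernel(72.0).max()
        assert amp_quiet / amp_loud == pytest.approx(gain, rel=0.02)


class TestEstimateTrf:
    def test_sparse_impulse_train_recovers_kernel_exactly(self):
        fs = 1000.0
        rng = np.random.default_rng(0)
        n = 8000
        x = np.zeros(n)
        x[rng.choice(np.arange(100, n - 100, 80), 60, replace=False)] = 1.0
        h = np.zeros(41)
        h[5:20] = rng.standard_normal(15)
        y = fftconvolve(x, h)[:n]
        sched_bins = bin_by_ground_truth(
            Predictor(x, fs), build_trial_schedule(1, 0, levels=(60.0,), seed=0,
                                                   trial_duration=n / fs, short_segment=1.0)
        )
        trfs = estimate_trf(EEGRecording(y, fs), sched_bins, (0.0, 40.0))
        assert np.allclose(trfs.kernels[0], h, atol=1e-8)

    def test_matches_dense_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        n, lags = 300, np.arange(-5, 11)
        xs = np.abs(rng.standard_normal((2, n)))
        y = rng.standard_normal(n)
        from leveltrf.deconvolve import LevelBinSet

        bins = LevelBinSet(np.array([0.0, 1.0]), xs, xs > 0, 1000.0)
        trfs = estimate_trf(EEGRecording(y, 1000.0), bins, (-5.0, 10.0))
        expected = dense_trf_oracle(list(xs), y, lags)
        assert np.allclose(trfs.kernels, expected, rtol=1e-8, atol=1e-10)

    def test_joint_fit_avoids_cross_level_leakage(self):
        # correlated, rapidly alternating bins: joint estimation separates the
        # two kernels; separate per-level fits leak across levels
        fs = 500.0
        rng = np.random.default_rng(1)
        n = int(200 * fs)
        smooth = fftconvolve(np.abs(rng.standard_normal(n)), np.ones(50) / 50, mode="same")
        mask = (np.arange(n) // int(0.25 * fs)) % 2 == 0
        x1 = np.where(mask, smooth, 0.0)
        x2 = np.where(~mask, smooth, 0.0)
        t = np.arange(30)
        h1 = np.exp(-0.5 * ((t - 8) / 2.0) ** 2)
        h2 = -0.8 * np.exp(-0.5 * ((t - 15) / 2.0) ** 2)
        y = fftconvolve(x1, h1)[:n] + fftconvolve(x2, h2)[:n]
        from leveltrf.deconvolve import LevelBinSet

        joint = estimate_trf(
            EEGRecording(y, fs),
            LevelBinSet(np.array([0.0, 1.0]), np.stack([x1, x2]), np.stack([mask, ~mask]), fs),
            (0.0, 58.0),
        )
        sep1 = estimate_trf(
            EEGRecording(y, fs),
            LevelBinSet(np.array([0.0]), x1[None, :], mask[None, :], fs),
            (0.0, 58.0),
        )
        k = len(joint.lags_ms)
        err_joint = np.linalg.norm(joint.kernels[0] - h1[:k]) / np.linalg.norm(h1[:k])
        err_sep = np.linalg.norm(sep1.kernels[0] - h1[:k]) / np.linalg.norm(h1[:k])
        assert err_joint < 0.05
        assert err_sep > 2 * err_joint

    def test_singular_design_falls_back_with_warning(self):
        fs = 100.0
        n = 1000
        x = np.abs(np.random.default_rng(0).standard_normal(n))
        from leveltrf.deconvolve import LevelBinSet

        # duplicated predictor rows -> perfectly collinear design
        bins = LevelBinSet(np.array([0.0, 1.0]), np.stack([x, x]), np.stack([x > 0, x > 0]), fs)
        with pytest.warns(RuntimeWarning, match="singular"):
            estimate_trf(EEGRecording(x.copy(), fs), bins, (0.0, 20.0))


class TestClickErp:
    def test_noise_free_alternating_train_recovers_kernel(self):
        # response is polarity-symmetric; a signed feedthrough component
        # cancels in the average of an alternating train
        fs = 2000.0
        n = int(30 * fs)
        onsets = np.arange(0.5, 29.0, 0.1)
        pol = np.where(np.arange(len(onsets)) % 2 == 0, -1, 1)
        train = ClickTrain(onsets, pol, sample_rate=fs)
        h = np.zeros(40)
        h[8:24] = np.hanning(16)
        idx = np.round(onsets * fs).astype(int)
        unsigned = np.zeros(n)
        unsigned[idx] = 1.0
        y = fftconvolve(unsigned, h)[:n]
        y[idx] += 0.7 * pol  # signed stimulus artifact
        erp = estimate_click_erp(EEGRecording(y, fs), train, (-10.0, 30.0))
        lag0 = np.flatnonzero(erp.times_ms == 0.0)[0]
        recovered = erp.waveform[lag0 : lag0 + len(h)]
        expected = h - h[: int(10 * fs / 1000)].mean()  # baseline corrected
        assert np.allclose(recovered[1:], h[1:], atol=1e-9)
        assert erp.n_epochs == len(onsets)

    def test_baseline_mean_is_zero(self):
        fs = 1000.0
        rng = np.random.default_rng(0)
        y = rng.standard_normal(int(10 * fs))
        train = ClickTrain(np.arange(0.5, 9.0, 0.05),
                           np.where(np.arange(170) % 2 == 0, -1, 1), sample_rate=fs)
        erp = estimate_click_erp(EEGRecording(y, fs), train)
        assert erp.waveform[erp.times_ms < 0].mean() == pytest.approx(0.0, abs=1e-12)

    def test_full_click_block_yields_5280_epochs(self):
        from leveltrf.stimuli import generate_click_train

        fs = 2048.0
        train = generate_click_train(120.0, 44.0, sample_rate=fs, seed=0)
        train = ClickTrain(train.onset_times + 0.5, train.polarities, train.click_duration, fs)
        eeg = EEGRecording(np.random.default_rng(1).standard_normal(int(121.5 * fs)), fs)
        erp = estimate_click_erp(eeg, train)
        assert erp.n_epochs == 5280

    def test_no_usable_epochs_raises(self):
        fs = 1000.0
        train = ClickTrain(np.array([50.0]), np.array([-1]), sample_rate=fs)
        with pytest.raises(ValueError, match="no usable"):
            estimate_click_erp(EEGRecording(np.zeros(100), fs), train)
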