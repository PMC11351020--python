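"""Forward simulation: predictor realism, identifiability, click sessions."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from leveltrf import waves
from leveltrf.deconvolve import (
    bin_by_ground_truth,
    bin_by_inherent_intensity,
    estimate_click_erp,
    estimate_trf,
    normalize_bins,
)
from leveltrf.predictors import Predictor
from leveltrf.stimuli import build_trial_schedule
from leveltrf.synthetic import (
    GroundTruthKernels,
    NoiseSpec,
    default_ground_truth,
    make_adaptive_predictor,
    make_speech_like_predictor,
    simulate_click_session,
    simulate_session,
)

QUIET = NoiseSpec(background_rms=0.0, white_rms=0.0, artifact_rate_per_min=0.0)


class TestSpeechLikePredictor:
    def test_non_negative_and_unit_support_rms(self):
        pred = make_speech_like_predictor(30.0, 2048.0, seed=0)
        assert np.all(pred.series >= 0)
        nz = pred.series != 0
        assert np.sqrt(np.mean(pred.series[nz] ** 2)) == pytest.approx(1.0)

    def test_octile_binning_is_non_degenerate(self):
        pred = make_speech_like_predictor(60.0, 1024.0, seed=1)
        bins = bin_by_inherent_intensity(pred, n_bins=8)
        assert all(np.any(b != 0) for b in bins.binned)

    def test_pause_fraction_is_close_to_configured(self):
        pred = make_speech_like_predictor(120.0, 1024.0, seed=2, pause_fraction=0.15)
        zero_frac = np.mean(pred.series == 0)
        assert zero_frac == pytest.approx(0.15, abs=0.06)

    def test_deterministic_given_seed(self):
        a = make_speech_like_predictor(5.0, 1024.0, seed=3)
        b = make_speech_like_predictor(5.0, 1024.0, seed=3)
        assert np.array_equal(a.series, b.series)


class TestGroundTruthKernels:
    def test_default_invariants(self):
        gt = default_ground_truth()
        lats = np.array(gt.latencies_ms)
        amps = np.array(gt.amplitudes)
        assert np.all(np.diff(lats) < 0) and np.all(np.diff(amps) > 0)
        assert np.all((lats >= 4) & (lats <= 10))

    def test_kernel_peaks_at_stated_latency_and_amplitude(self):
        gt = default_ground_truth()
        lags = np.arange(-10, 30, 0.01)
        for lvl in gt.levels:
            k = gt.kernel_on_axis(lvl, lags)
            lat, amp = gt.params(lvl)
            assert lags[np.argmax(k)] == pytest.approx(lat, abs=0.02)
            assert k.max() == pytest.approx(amp, rel=1e-6)
            assert np.all(k[lags < 0] == 0)  # causal

    def test_non_monotone_parameters_raise(self):
        with pytest.raises(ValueError):
            GroundTruthKernels((36.0, 72.0), (5.0, 7.0), (1.0, 2.0))
        with pytest.raises(ValueError):
            GroundTruthKernels((36.0, 72.0), (7.0, 5.0), (2.0, 1.0))


class TestForwardInverseConsistency:
    def test_zero_noise_single_level_recovery_to_solver_precision(self):
        sched = build_trial_schedule(1, 0, levels=(60.0,), seed=0)
        gt = GroundTruthKernels((60.0,), (6.0,), (1.5,))
        session = simulate_session(sched, gt, QUIET, seed=0, rate=2048.0)
        bins = normalize_bins(bin_by_ground_truth(session.predictor, sched))
        trfs = estimate_trf(session.eeg, bins)
        fitted = trfs.kernels[0] * bins.norm_scales[0] / session.level_scales[60.0]
        truth = gt.kernel_on_axis(60.0, trfs.lags_ms)
        assert np.abs(fitted - truth).max() / truth.max() < 1e-6

    def test_zero_noise_four_levels_recover_orderings(self):
        sched = build_trial_schedule(0, 4, seed=1)
        session = simulate_session(sched, noise=QUIET, seed=1, rate=2048.0)
        bins = normalize_bins(bin_by_ground_truth(session.predictor, sched))
        feats = waves.extract_wave_v(estimate_trf(session.eeg, bins), smooth_ms=None)
        lats = [f.latency_ms for f in feats]  # labels ascend with level
        amps = [f.amplitude for f in feats]
        assert np.all(np.diff(lats) < 0)
        assert np.all(np.diff(amps) > 0)

    def test_latency_ordering_survives_realistic_noise(self):
        ok = 0
        for seed in range(3):
            sched = build_trial_schedule(4, 4, seed=seed)
            session = simulate_session(sched, seed=seed)
            bins = normalize_bins(bin_by_ground_truth(session.predictor, sched))
            feats = waves.extract_wave_v(estimate_trf(session.eeg, bins))
            lats = [f.latency_ms for f in feats]
            ok += int(np.all(np.diff(lats) < 0))
        assert ok >= 2


class TestAdaptivePredictor:
    def test_per_level_rms_is_equalized(self):
        sched = build_trial_schedule(0, 4, seed=2)
        session = simulate_session(sched, noise=QUIET, seed=2, rate=1024.0)
        adaptive = make_adaptive_predictor(session.predictor, sched, session.kernels)
        lvl = sched.level_at_samples(len(adaptive), adaptive.rate)
        rmss = []
        for level in sorted(sched.levels):
            x = adaptive.series[lvl == level]
            rmss.append(np.sqrt(np.mean(x[x != 0] ** 2)))
        assert np.allclose(rmss, rmss[0], rtol=0.01)


class TestClickSession:
    def test_four_blocks_give_21120_clicks(self):
        eeg, trains = simulate_click_session(
            (36.0, 48.0, 60.0, 66.0), noise=QUIET, seed=0, rate=1024.0
        )
        assert sum(len(t) for t in trains) == 4 * 5280

    def test_zero_noise_erp_peaks_at_kernel_latency(self):
        levels = (48.0, 66.0)
        gt = GroundTruthKernels(levels, (7.0, 6.0), (1.0, 2.0))
        eeg, trains = simulate_click_session(levels, gt, QUIET, seed=1, rate=4096.0,
                                             block_duration=20.0)
        for train, level in zip(trains, sorted(levels, reverse=True)):
            erp = estimate_click_erp(eeg, train)
            f = waves.detect_wave_v(erp.waveform, erp.times_ms)
            lat, amp = gt.params(level)
            assert f.latency_ms == pytest.approx(lat, abs=1000.0 / 4096.0)

    def test_erp_snr_grows_with_epoch_count(self):
        # noise floor of the average shrinks ~1/sqrt(n): quadrupling the
        # epoch count should raise the wave V SNR (~6 dB in expectation)
        from leveltrf.stimuli import ClickTrain

        gains = []
        for seed in range(3):
            levels = (66.0,)
            gt = GroundTruthKernels(levels, (6.0,), (2.0,))
            eeg, (train,) = simulate_click_session(
                levels, gt, NoiseSpec(background_rms=20.0, artifact_rate_per_min=0.0),
                seed=seed, rate=2048.0, block_duration=120.0)
            quarter = ClickTrain(train.onset_times[:1320], train.polarities[:1320],
                                 train.click_duration, train.sample_rate)
            def snr_of(t):
                erp = estimate_click_erp(eeg, t)
                w = waves.smooth_waveform(erp.waveform, 1.0, 2048.0)
                f = waves.detect_wave_v(w, erp.times_ms)
                return waves.compute_snr(w, erp.times_ms, f.latency_ms)
            gains.append(snr_of(train) - snr_of(quarter))
        assert np.median(gains) > 2.0


class TestSweep:
    def test_full_length_row_matches_direct_pipeline(self):
        sched = build_trial_schedule(0, 8, seed=3)
        session = simulate_session(sched, seed=3, rate=1024.0)
        feats_df, trends_df = waves.datalength_sweep(
            session.eeg, session.predictor, sched, [4.0, 8.0]
        )
        bins = normalize_bins(bin_by_ground_truth(session.predictor, sched))
        direct = waves.extract_wave_v(estimate_trf(session.eeg, bins))
        last = feats_df[feats_df.datalength_min == 8.0].sort_values("level")
        assert np.allclose(last["latency_ms"].to_numpy(),
                           [f.latency_ms for f in direct])
        assert np.allclose(last["amplitude"].to_numpy(),
                           [f.amplitude for f in direct])

    def test_balanced_prefix_uses_one_minute_per_level(self):
        sched = build_trial_schedule(0, 8, seed=4)
        pred = make_speech_like_predictor(sched.duration, 512.0, seed=4)
        n = int(4 * 60 * 512)
        sub = Predictor(pred.series[:n], 512.0)
        bins = bin_by_ground_truth(sub, sched)
        assert np.allclose(bins.support_duration(), 60.0)

    def test_snr_improves_with_data_length(self):
        deltas = []
        for seed in range(3):
            sched = build_trial_schedule(0, 8, seed=seed)
            session = simulate_session(sched, seed=seed, rate=1024.0)
            feats_df, _ = waves.datalength_sweep(
                session.eeg, session.predictor, sched, [2.0, 8.0]
            )
            loud = feats_df[feats_df.level == 72.0].set_index("datalength_min")["snr_db"]
            deltas.append(loud.loc[8.0] - loud.loc[2.0])
        assert np.median(deltas) > 0

    def test_increment_beyond_session_raises(self):
        sched = build_trial_schedule(0, 2, seed=0)
        session = simulate_session(sched, seed=0, rate=512.0)
        with pytest.raises(ValueError, match="exceeds"):
            waves.datalength_sweep(session.eeg, session.predictor, sched, [10.0])
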