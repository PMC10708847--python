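"""Processing-chain tests, each checked against an independent oracle."""

import numpy as np
import pytest
from scipy import signal

from betawatch import dsp
from betawatch.core import (
    DegenerateEpochError,
    EmptyBandError,
    Epoch,
    EpochLengthError,
    EpochStatus,
    NormalizationError,
    SessionAnnotation,
)
from betawatch.pipeline import process_trace
from betawatch.synthetic import SignalSpec, generate_trace

CFG = dsp.ProcessingConfig()
FS = 512.0
T = np.arange(1024) / FS


class TestConversion:
    @pytest.mark.parametrize("raw, volts", [
        (0, 0.0),
        (4096, 9.0e-4),   # 4096 * (1.8/4096) / 2000
        (2048, 4.5e-4),   # i.e. 450 uV
        (1, 1.8 / 4096 / 2000),
    ])
    def test_hand_arithmetic(self, raw, volts):
        assert dsp.raw_to_volts(raw) == pytest.approx(volts, rel=1e-12)

    def test_vectorized_and_microvolts(self):
        raw = np.array([0, 2048, -2048])
        np.testing.assert_allclose(dsp.raw_to_microvolts(raw), [0.0, 450.0, -450.0])

    def test_round_trip(self):
        uv = np.array([1.0, -75.0, 449.9])
        np.testing.assert_allclose(
            dsp.raw_to_microvolts(dsp.microvolts_to_raw(uv)), uv, rtol=1e-12)


class TestArtifactGate:
    def test_sample_above_threshold_rejects(self):
        epoch = np.zeros(1024)
        epoch[500] = 80.0
        assert dsp.is_artifact(epoch, 75.0)

    def test_below_threshold_accepts(self):
        rng = np.random.default_rng(0)
        epoch = rng.uniform(-74.9, 74.9, 1024)
        assert not dsp.is_artifact(epoch, 75.0)

    def test_exactly_threshold_accepts(self):
        epoch = np.zeros(1024)
        epoch[0] = 75.0
        assert not dsp.is_artifact(epoch, 75.0)  # strict inequality

    def test_wrong_length_raises(self):
        with pytest.raises(EpochLengthError):
            dsp.is_artifact(np.zeros(100), 75.0, epoch_len=1024)


class TestPreprocess:
    def test_output_is_zscored(self):
        rng = np.random.default_rng(1)
        out = dsp.preprocess(rng.normal(0, 10, 1024), CFG)
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    def test_dc_offset_removed(self):
        x = 20.0 * np.sin(2 * np.pi * 20.0 * T)
        with_dc = dsp.preprocess(x + 50.0, CFG)
        without = dsp.preprocess(x, CFG)
        assert np.corrcoef(with_dc, without)[0, 1] > 0.99

    def test_line_frequency_attenuated_per_filter_response(self):
        # oracle: zero-phase order-4 Butterworth has squared-magnitude gain
        # |H(f)|^2; the filtered RMS ratio (50 Hz vs 20 Hz tone) must match it
        sos = signal.butter(CFG.filter_order, CFG.bandpass, btype="bandpass",
                            fs=CFG.fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=[20.0, 50.0], fs=CFG.fs)
        predicted = np.abs(h[1]) ** 2 / np.abs(h[0]) ** 2
        rms = {}
        for f0 in (20.0, 50.0):
            x = 30.0 * np.sin(2 * np.pi * f0 * T)
            y = signal.sosfiltfilt(sos, x)
            rms[f0] = y[256:-256].std()  # central region, clear of edge transients
        ratio = rms[50.0] / rms[20.0]
        assert ratio == pytest.approx(predicted, abs=0.03)
        assert ratio <= 0.15  # strong mains suppression

    def test_constant_epoch_is_degenerate(self):
        with pytest.raises(DegenerateEpochError):
            dsp.preprocess(np.full(1024, 3.0), CFG)


class TestWelch:
    def test_white_noise_is_roughly_flat(self):
        # per-Hz beta power within 3x of the per-Hz 3-12 Hz power
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(1024)
            x = (x - x.mean()) / x.std()
            spec = dsp.welch_psd(x, CFG)
            beta = dsp.band_power(spec, (12, 30)) / 18.0
            low = dsp.band_power(spec, (3, 12)) / 9.0
            assert 1 / 3 <= beta / low <= 3

    def test_sinusoid_peaks_at_its_bin(self):
        x = np.sin(2 * np.pi * 20.0 * T)
        x = (x - x.mean()) / x.std()
        spec = dsp.welch_psd(x, CFG)
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(20.0)

    def test_parseval_on_zscored_epoch(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1024)
        x = (x - x.mean()) / x.std()
        spec = dsp.welch_psd(x, CFG)
        total = np.sum(spec.power) * spec.df
        assert total == pytest.approx(1.0, rel=0.25)

    def test_single_segment_equals_direct_periodogram(self):
        # oracle: one Tukey-tapered segment is a plain modified periodogram
        cfg1 = dsp.ProcessingConfig(welch_segment_len=1024)
        rng = np.random.default_rng(3)
        x = rng.standard_normal(1024)
        spec = dsp.welch_psd(x, cfg1)
        w = signal.get_window(("tukey", 0.15), 1024)  # periodic, as Welch uses
        X = np.fft.rfft(w * x)
        pxx = np.abs(X) ** 2 / (FS * np.sum(w ** 2))
        pxx[1:-1] *= 2
        np.testing.assert_allclose(spec.power, pxx, rtol=1e-10, atol=1e-12)

    def test_segment_longer_than_epoch_is_config_error(self):
        from betawatch.core import ConfigError
        with pytest.raises(ConfigError):
            dsp.welch_psd(np.zeros(200), CFG)


class TestBandPower:
    def test_zero_spectrum(self):
        spec = dsp.PSDSpectrum(np.arange(0, 41, 2.0), np.zeros(21))
        assert dsp.band_power(spec, (12, 30)) == 0.0

    def test_single_bin_carries_all_power(self):
        freqs = np.arange(0, 41, 2.0)
        power = np.zeros(21)
        power[freqs == 20.0] = 7.0
        spec = dsp.PSDSpectrum(freqs, power)
        assert dsp.band_power(spec, (12, 30)) == pytest.approx(np.sum(power) * 2.0)

    def test_additivity_over_partition(self):
        rng = np.random.default_rng(4)
        spec = dsp.PSDSpectrum(np.arange(0, 41, 2.0), rng.uniform(0, 1, 21))
        total = dsp.band_power(spec, (3, 40))
        parts = (dsp.band_power(spec, (3, 12))
                 + dsp.band_power(spec, (12, 30), closed="right")
                 + dsp.band_power(spec, (30, 40), closed="right"))
        assert parts == pytest.approx(total, rel=1e-12)

    def test_empty_band_raises(self):
        spec = dsp.PSDSpectrum(np.arange(0, 41, 2.0), np.zeros(21))
        with pytest.raises(EmptyBandError):
            dsp.band_power(spec, (30.5, 31.5))


def _epochs_from_uv(uv_epochs):
    """Wrap per-epoch uV arrays into raw Epochs at consecutive start times."""
    out = []
    for i, uv in enumerate(uv_epochs):
        raw = np.round(dsp.microvolts_to_raw(uv)).astype(np.int32)
        out.append(Epoch("S00", i, 2.0 * i, raw))
    return out


class TestSummarize:
    def test_constant_beta_power_summary(self, tiny_annotation):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 5, 1024)
        epochs = _epochs_from_uv([base] * 4)
        summary = dsp.summarize_subject(epochs, tiny_annotation, CFG)
        # all epochs identical: mean equals each per-epoch value
        assert summary.n_accepted == summary.n_epochs_total - summary.n_excluded_by_mask
        assert summary.total_mean_beta == pytest.approx(summary.per_epoch_beta[0])

    def test_epochs_outside_video_are_masked(self):
        ann = SessionAnnotation([("video", 0.0, 4.0), ("survey", 4.0, 8.0)])
        rng = np.random.default_rng(6)
        epochs = _epochs_from_uv([rng.normal(0, 5, 1024) for _ in range(4)])
        summary = dsp.summarize_subject(epochs, ann, CFG)
        assert summary.n_excluded_by_mask == 2
        assert summary.n_accepted == 2
        statuses = [r.status for r in summary.epoch_records]
        assert statuses[2:] == [EpochStatus.EXCLUDED_BY_MASK] * 2

    def test_all_artifact_epochs_invalidate_summary(self, tiny_annotation):
        blinky = np.zeros(1024)
        blinky[100] = 200.0
        epochs = _epochs_from_uv([blinky] * 4)
        with pytest.warns(UserWarning, match="invalid"):
            summary = dsp.summarize_subject(epochs, tiny_annotation, CFG)
        assert not summary.valid
        assert summary.n_rejected_artifact == 4

    def test_counts_partition_the_epochs(self, tiny_annotation):
        rng = np.random.default_rng(7)
        uvs = [rng.normal(0, 5, 1024) for _ in range(7)]
        uvs[1][0] = 200.0           # artifact
        epochs = _epochs_from_uv(uvs)
        summary = dsp.summarize_subject(epochs, tiny_annotation, CFG)
        assert (summary.n_accepted + summary.n_rejected_artifact
                + summary.n_rejected_degenerate + summary.n_excluded_by_mask
                ) == summary.n_epochs_total

    def test_sum_aggregate_option(self, tiny_annotation):
        cfg_sum = dsp.ProcessingConfig(epoch_aggregate="sum")
        rng = np.random.default_rng(8)
        epochs = _epochs_from_uv([rng.normal(0, 5, 1024) for _ in range(4)])
        mean_s = dsp.summarize_subject(epochs, tiny_annotation, CFG)
        sum_s = dsp.summarize_subject(epochs, tiny_annotation, cfg_sum)
        assert sum_s.total_mean_beta == pytest.approx(
            mean_s.total_mean_beta * mean_s.n_accepted)


class TestNormalizeCohort:
    def _summaries(self, totals):
        return [dsp.SubjectSummary(f"S{i}", np.array([t]), 1, 0, 0, 0, t)
                for i, t in enumerate(totals)]

    def test_min_max_scaling(self):
        out = dsp.normalize_cohort(self._summaries([2.0, 4.0, 6.0]))
        assert [s.normalized_beta for s in out] == [0.0, 0.5, 1.0]

    def test_extremes_map_to_unit_interval_ends(self):
        out = dsp.normalize_cohort(self._summaries([0.3, 0.9, 0.1, 0.5]))
        values = [s.normalized_beta for s in out]
        assert min(values) == 0.0 and max(values) == 1.0

    def test_order_preserved(self):
        totals = [0.7, 0.2, 0.9, 0.4]
        out = dsp.normalize_cohort(self._summaries(totals))
        assert np.argsort([s.normalized_beta for s in out]).tolist() == \
            np.argsort(totals).tolist()

    def test_identical_totals_undefined(self):
        with pytest.raises(NormalizationError):
            dsp.normalize_cohort(self._summaries([1.0, 1.0, 1.0]))


class TestEndToEndProperties:
    def test_beta_summary_increases_with_beta_gain(self, tiny_annotation):
        totals = []
        for gain in (2.0, 4.0, 8.0):
            spec = SignalSpec(duration_s=tiny_annotation.end_s,
                              band_gains={"delta": 6, "theta": 4, "alpha": 5,
                                          "beta": gain},
                              seed=31)
            summary, _ = process_trace(generate_trace(spec), tiny_annotation, CFG)
            totals.append(summary.total_mean_beta)
        assert totals[0] < totals[1] < totals[2]

    def test_blink_rejects_exactly_touched_epochs(self, tiny_annotation):
        quiet = dict(duration_s=tiny_annotation.end_s,
                     band_gains={"beta": 3.0}, pink_gain=4.0, line_amp_uV=1.0,
                     seed=12)
        clean, _ = process_trace(generate_trace(SignalSpec(**quiet)),
                                 tiny_annotation, CFG)
        blink, _ = process_trace(
            generate_trace(SignalSpec(**quiet, blink_schedule=[(3.0, 150.0, 0.4)])),
            tiny_annotation, CFG)
        # blink support [3.0, 3.4] s touches only epoch [2 s, 4 s)
        assert clean.n_accepted - blink.n_accepted == 1
        assert blink.n_rejected_artifact == clean.n_rejected_artifact + 1
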