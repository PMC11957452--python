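import numpy as np
import pytest

import belumask as bm
from belumask.calls import BUZZ_EXCLUDED, CC, HFBP_B, HFBP_M, OTHER, CallMeasurements, PulseTrain


def make_pulse_clip(fs, times_s, dur_s, band=(30_000, 140_000), amp=1e5):
    """Bandpassed 0.3-ms transients at the given onset times."""
    rng = np.random.default_rng(0)
    n = int(dur_s * fs)
    env = np.zeros(n)
    w = int(0.3e-3 * fs)
    win = np.hanning(w)
    for t in times_s:
        i = int(t * fs)
        env[i : i + w] += win[: max(0, min(w, n - i))]
    x = env * rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0
    return bm.CalibratedClip(amp * np.fft.irfft(spec, n), fs)


class TestDetectPulses:
    def test_silence_gives_empty_train(self, fs):
        train = bm.detect_pulses(bm.CalibratedClip(np.zeros(fs // 4), fs), (30e3, 140e3))
        assert train.n_pulses == 0

    def test_regular_train_recovered(self, fs):
        times = 0.02 + np.arange(10) * 0.01  # 100 pulses/s, padded off the edges
        clip = make_pulse_clip(fs, times, 0.15)
        train = bm.detect_pulses(clip, (30_000, 140_000))
        assert train.n_pulses == 10
        assert train.rate_hz == pytest.approx(100.0, rel=0.02)
        assert train.ipi_cv < 0.02
        assert np.allclose(np.diff(train.pulse_times_s), 0.01, atol=2e-4)

    def test_accelerating_train_negative_slope(self, fs):
        # IPI shrinking 20 ms -> 2 ms
        ipis = np.linspace(0.02, 0.002, 15)
        times = np.concatenate([[0.0], np.cumsum(ipis)])
        clip = make_pulse_clip(fs, times, times[-1] + 0.01)
        train = bm.detect_pulses(clip, (30_000, 140_000))
        assert train.ipi_slope < 0

    def test_invalid_band_rejected(self, fs):
        with pytest.raises(ValueError, match="invalid band"):
            bm.detect_pulses(bm.CalibratedClip(np.zeros(1000), fs), (150_000, 200_000))


class TestPulseTrain:
    def test_statistics_definitions(self):
        t = np.array([0.0, 0.01, 0.02, 0.04])
        train = PulseTrain(t)
        assert np.allclose(train.ipis_s, [0.01, 0.01, 0.02])
        assert train.rate_hz == pytest.approx(100.0)
        ipis = np.diff(t)
        assert train.ipi_cv == pytest.approx(np.std(ipis) / np.mean(ipis))

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            PulseTrain(np.array([0.0, 0.1, 0.05]))


class TestMeasureCall:
    def test_flat_band_quantiles(self, fs):
        """Uniform energy over 36-144 kHz: center 90.2, q1 63.3, q3 117.1 kHz."""
        rng = np.random.default_rng(2)
        n = fs // 2
        x = rng.standard_normal(n)
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(n, 1 / fs)
        spec[(f < 36_000) | (f > 144_000)] = 0
        clip = bm.CalibratedClip(1e4 * np.fft.irfft(spec, n), fs)
        m = bm.measure_call(clip, bm.SelectionRecord(0.0, 0.5, 36_000, 144_000))
        assert m.center_freq_khz == pytest.approx(90.0, abs=2.0)
        assert m.q1_freq_khz == pytest.approx(63.0, abs=2.0)
        assert m.q3_freq_khz == pytest.approx(117.0, abs=2.0)
        assert m.low_freq_khz == pytest.approx(36.0, abs=1.0)
        assert m.high_freq_khz == 144.0  # Nyquist reached exactly

    def test_pure_tone_degenerate_quantiles(self, fs):
        t = np.arange(fs // 2) / fs
        clip = bm.CalibratedClip(1e4 * np.sin(2 * np.pi * 50_000 * t), fs)
        m = bm.measure_call(clip, bm.SelectionRecord(0.0, 0.5, 40_000, 60_000))
        for v in (m.peak_freq_khz, m.center_freq_khz, m.q1_freq_khz, m.q3_freq_khz):
            assert v == pytest.approx(50.0, abs=0.3)

    def test_quantiles_match_cumsum_oracle(self, fs):
        """Two-band shaped spectrum: quantiles equal brute-force cumulative sums."""
        from scipy import signal as sps

        rng = np.random.default_rng(3)
        n = fs // 2
        x = rng.standard_normal(n)
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(n, 1 / fs)
        shape = np.where((f > 30e3) & (f < 60e3), 1.0, 0.0) + np.where(
            (f > 90e3) & (f < 120e3), 2.0, 0.0
        )
        clip = bm.CalibratedClip(1e4 * np.fft.irfft(spec * shape, n), fs)
        sel = bm.SelectionRecord(0.0, 0.5, 25_000, 130_000)
        m = bm.measure_call(clip, sel)
        freqs, psd = sps.welch(
            clip.samples, fs=fs, window="hann", nperseg=1024, noverlap=512,
            detrend=False, scaling="density",
        )
        keep = (freqs >= sel.low_hz) & (freqs <= sel.high_hz)
        fb, pb = freqs[keep], psd[keep]
        cum = np.cumsum(pb)
        bin_hz = fs / 1024
        for frac, got in ((0.25, m.q1_freq_khz), (0.5, m.center_freq_khz), (0.75, m.q3_freq_khz)):
            want = fb[np.searchsorted(cum, frac * cum[-1])]
            assert abs(got * 1e3 - want) <= bin_hz + 1e-9

    def test_quantile_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            CallMeasurements(50.0, 144.0, 0.4, 60.0, 40.0, 45.0, 80.0)

    def test_bad_selections_rejected(self, fs):
        clip = bm.CalibratedClip(np.random.default_rng(0).normal(0, 1, fs), fs)
        with pytest.raises(ValueError, match="Nyquist"):
            bm.measure_call(clip, bm.SelectionRecord(0.0, 0.5, 10_000, 200_000))
        with pytest.raises(ValueError):
            bm.measure_call(clip, bm.SelectionRecord(2.0, 2.5, 1_000, 2_000))


class TestClassifyRules:
    def _measure(self, low, high=144.0, dur=0.4):
        mid = (low + high) / 2
        return CallMeasurements(low, high, dur, mid, mid, (low + mid) / 2, (mid + high) / 2)

    def _train(self, n=50, rate=300.0, cv_jitter=0.0, accel=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ipis = (1 / rate) * (1 + cv_jitter * rng.standard_normal(n)) * (
            1 + accel * np.linspace(0, 1, n)
        )
        return PulseTrain(np.concatenate([[0.0], np.cumsum(np.abs(ipis))]))

    def test_rule_cascade(self):
        # constant-rate ultrasonic train -> HFBP_M
        assert bm.classify_call(self._measure(40.0), self._train()) == HFBP_M
        # same with an isolated LF element -> HFBP_B
        assert bm.classify_call(self._measure(34.0), self._train(), lf_present=True) == HFBP_B
        # broadband long pulsed signal -> CC
        assert bm.classify_call(self._measure(0.2, dur=1.2), self._train()) == CC
        # tonal (no pulse train) -> OTHER
        assert bm.classify_call(self._measure(5.0, 20.0), PulseTrain(np.empty(0))) == OTHER

    def test_buzz_exclusions_take_priority(self):
        accel = self._train(accel=-0.8)
        assert accel.ipi_fractional_trend < -0.3
        assert bm.classify_call(self._measure(40.0), accel) == BUZZ_EXCLUDED
        # adjacency to an echolocation click train also excludes
        assert (
            bm.classify_call(self._measure(40.0), self._train(), near_click_train=True)
            == BUZZ_EXCLUDED
        )

    def test_inconsistent_ipis_not_hfbp(self):
        jittery = self._train(cv_jitter=0.6, seed=4)
        assert jittery.ipi_cv > 0.35
        assert bm.classify_call(self._measure(40.0), jittery) == OTHER

    def test_strict_monophonic_threshold_configurable(self):
        m = self._measure(25.0)
        assert bm.classify_call(m, self._train()) == HFBP_M
        strict = bm.ClassifierConfig(strict_hfbp_m=True)
        assert bm.classify_call(m, self._train(), config=strict) == OTHER

    def test_deterministic(self):
        m, tr = self._measure(40.0), self._train()
        assert len({bm.classify_call(m, tr) for _ in range(5)}) == 1


class TestClassifySelectionEndToEnd:
    @pytest.mark.parametrize(
        "cls,want",
        [("HFBP_M", HFBP_M), ("HFBP_B", HFBP_B), ("CC", CC), ("WHISTLE", OTHER), ("BUZZ", BUZZ_EXCLUDED)],
    )
    def test_each_class_recovered_in_ambient(self, fs, cls, want):
        rng = np.random.default_rng(hash(cls) % 2**31)
        lib = bm.TemplateLibrary()
        tpl = lib.draw(cls, fs, rng)
        call = bm.synth_call(tpl, fs, rng)
        bed = bm.synth_ambient(bm.AmbientSpec(), (call.size + 2 * fs) / fs, fs, rng)
        bed[fs : fs + call.size] += call
        clip = bm.CalibratedClip(bed, fs)
        sel = bm.SelectionRecord(1.0, 1.0 + tpl.duration_s, tpl.selection_low_hz, tpl.band_high_hz)
        label, m, _ = bm.classify_selection(clip, sel)
        assert label == want
        assert m.low_freq_khz <= m.q1_freq_khz <= m.center_freq_khz <= m.q3_freq_khz <= m.high_freq_khz

    def test_perfect_recall_and_precision_on_quiet_scene(self, quiet_scene):
        """At high in-band SNR every HFBP-M/B and CC selection is recovered."""
        from collections import Counter

        hits, preds, truths = Counter(), Counter(), Counter()
        for t in ("before", "during", "after"):
            clip = quiet_scene.clips[t]
            for s in quiet_scene.truth_for(t):
                sel = bm.SelectionRecord(s["begin_s"], s["end_s"], s["low_hz"], s["high_hz"])
                label, _, _ = bm.classify_selection(clip, sel)
                truths[s["call_class"]] += 1
                preds[label] += 1
                if label == s["call_class"]:
                    hits[label] += 1
        assert sum(truths.values()) > 10
        for cls in ("HFBP_M", "HFBP_B", "CC"):
            assert hits[cls] == truths[cls], f"recall < 1 for {cls}"
            assert hits[cls] == preds[cls], f"precision < 1 for {cls}"
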