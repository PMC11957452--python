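import numpy as np
import pytest

import belumask as bm
from belumask.synth import TREATMENTS, _pulse_times


def band_density_db(x, fs, lo, hi):
    clip = bm.CalibratedClip(x, fs)
    spec = bm.welch_ssdl(clip, window_s=min(1.0, x.size / fs / 2))
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    return 10 * np.log10(spec.power[sel].mean())


class TestSynthCall:
    def test_rms_matches_stated_level(self, fs):
        for cls, kw in [
            ("HFBP_M", dict(band_low_hz=36_400, band_high_hz=144_000)),
            ("CC", dict(band_low_hz=200, band_high_hz=144_000, duration_s=1.2)),
            ("WHISTLE", dict(band_low_hz=2_000, band_high_hz=20_000)),
        ]:
            kw.setdefault("duration_s", 0.4)
            tpl = bm.CallTemplate(cls, level_db=128.0, **kw)
            x = bm.synth_call(tpl, fs, 0)
            rms_db = 20 * np.log10(np.sqrt(np.mean(x**2)))
            assert rms_db == pytest.approx(128.0, abs=1.0)

    def test_out_of_band_suppression(self, fs):
        tpl = bm.CallTemplate("HFBP_M", 36_400, 144_000, 0.4)
        x = bm.synth_call(tpl, fs, 1)
        in_band = band_density_db(x, fs, 40_000, 140_000)
        below = band_density_db(x, fs, 1_000, 30_000)
        assert in_band - below > 30

    def test_biphonal_call_has_lf_and_silent_gap(self, fs):
        tpl = bm.CallTemplate(
            "HFBP_B", 34_500, 144_000, 0.4, lf_component=(800.0, 11_000.0)
        )
        x = bm.synth_call(tpl, fs, 2)
        lf = band_density_db(x, fs, 600, 11_000)
        gap = band_density_db(x, fs, 14_000, 30_000)
        main = band_density_db(x, fs, 40_000, 140_000)
        assert lf - gap > 30 and main - gap > 30

    def test_invalid_requests_rejected(self, fs):
        with pytest.raises(ValueError):
            bm.CallTemplate("HFBP_M", 36_400, 144_000, 0.0)  # zero duration
        tpl = bm.CallTemplate("HFBP_M", 36_400, 200_000, 0.4)
        with pytest.raises(ValueError, match="Nyquist"):
            bm.synth_call(tpl, fs, 0)
        short = bm.CallTemplate("HFBP_M", 36_400, 144_000, 0.005)
        with pytest.raises(ValueError, match="inter-pulse"):
            bm.synth_call(short, fs, 0)

    def test_template_invariants(self):
        with pytest.raises(ValueError, match="20 kHz"):
            bm.CallTemplate("HFBP_M", 15_000, 144_000, 0.4)
        with pytest.raises(ValueError, match="silent gap"):
            bm.CallTemplate("HFBP_B", 34_000, 144_000, 0.4, lf_component=(800, 40_000))
        with pytest.raises(ValueError, match="accelerate"):
            bm.CallTemplate("BUZZ", 25_000, 144_000, 0.4, ipi_trend=0.0)

    def test_buzz_ipis_strictly_decreasing(self, fs):
        """ipi_trend=-0.8 yields a strictly accelerating detected train."""
        tpl = bm.CallTemplate("BUZZ", 25_000, 144_000, 0.5, ipi_trend=-0.8, pulse_rate_hz=200)
        times = _pulse_times(tpl)
        assert np.all(np.diff(np.diff(times)) < 0)
        x = bm.synth_call(tpl, fs, 3)
        train = bm.detect_pulses(bm.CalibratedClip(x, fs), (20_000, 143_000))
        assert train.n_pulses == len(times)
        # detected times carry one-sample jitter; the acceleration must
        # still dominate the IPI sequence
        assert train.ipi_slope < 0
        assert train.ipi_fractional_trend < -0.3


class TestVesselNoise:
    def test_realized_spectrum_matches_model(self, fs):
        spec = bm.VesselNoiseSpec(level_db_at_ref=70.0, slope_db_per_decade=15.0,
                                  rolloff_hz=50_000.0, duration_s=5.0)
        x = bm.synth_vessel_noise(spec, fs, 4)
        ssdl = bm.welch_ssdl(bm.CalibratedClip(x, fs))
        bands = bm.third_octave_levels(ssdl)
        model = spec.density_upa2_per_hz(ssdl.freqs)
        model_bands = bm.third_octave_levels(bm.SpectrumSSDL(ssdl.freqs, 10 * np.log10(model)))
        keep = bands.centers < 80_000  # beyond the rolloff the target is ~zero
        assert np.all(np.abs(bands.levels[keep] - model_bands.levels[keep]) < 1.5)

    def test_flat_spec_recovers_level(self, fs):
        spec = bm.VesselNoiseSpec(level_db_at_ref=40.0, slope_db_per_decade=0.0,
                                  rolloff_hz=144_000.0, duration_s=5.0, rolloff_order=10)
        x = bm.synth_vessel_noise(spec, fs, 5)
        level = band_density_db(x, fs, 1_000, 100_000)
        assert level == pytest.approx(40.0, abs=0.5)

    def test_excess_nonpositive_above_rolloff(self, fs):
        """Injected vessel density falls below the ambient bed above rolloff."""
        amb = bm.AmbientSpec()
        f = np.linspace(100, 144_000, 1000)
        amb_db = 10 * np.log10(amb.density_upa2_per_hz(f))
        roll = 50_000.0
        level_ref = amb_db[np.argmin(np.abs(f - roll))] + 10 * np.log10(2) + 15 * np.log10(roll / 1000)
        spec = bm.VesselNoiseSpec(level_db_at_ref=level_ref, rolloff_hz=roll)
        ves_db = 10 * np.log10(spec.density_upa2_per_hz(f))
        above = f > roll * 1.01
        assert np.all(ves_db[above] - amb_db[above] <= 0.1)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            bm.VesselNoiseSpec(level_db_at_ref=np.inf)
        with pytest.raises(ValueError):
            bm.VesselNoiseSpec(level_db_at_ref=60.0, rolloff_hz=50.0)


class TestEventCounts:
    def _spec(self, mu, theta=2.0, sd=0.8, seed=0):
        return bm.EventSpec(
            event_id="e",
            seed=seed,
            treatment_durations_s={t: 60.0 for t in TREATMENTS},
            expected_counts={(t, "CC"): mu for t in TREATMENTS},
            nb_dispersion=theta,
            event_random_intercept_sd=sd,
        )

    def test_identical_seeds_identical_counts(self):
        a = bm.sample_event_counts(self._spec(5.0, seed=42))
        b = bm.sample_event_counts(self._spec(5.0, seed=42))
        assert a == b

    def test_zero_mean_gives_zero_counts(self):
        counts = bm.sample_event_counts(self._spec(0.0))
        assert all(v == 0 for v in counts.values())

    def test_poisson_limit_monte_carlo(self):
        """sd=0, theta -> inf: empirical mean within 3 s.e. of mu."""
        mu = 4.0
        draws = [
            bm.sample_event_counts(self._spec(mu, theta=np.inf, sd=0.0, seed=s))[
                ("during", "CC")
            ]
            for s in range(1000)
        ]
        se = np.sqrt(mu / 1000)
        assert abs(np.mean(draws) - mu) < 3 * se

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="duration"):
            bm.EventSpec("e", 0, treatment_durations_s={"before": 400.0, "during": 10.0, "after": 10.0})
        with pytest.raises(ValueError, match="dispersion"):
            bm.EventSpec("e", 0, nb_dispersion=0.0)


class TestRenderEvent:
    def test_empty_scene_pure_ambient(self, fs):
        spec = bm.EventSpec(
            "empty", 9, treatment_durations_s={t: 6.0 for t in TREATMENTS}
        )
        scene = bm.render_event(spec, vessel_rolloff_hz=None)
        assert scene.truth == []
        assert set(scene.clips) == set(TREATMENTS)
        assert scene.vessel_rolloff_hz is None
        for clip in scene.clips.values():
            assert clip.samples.size == 6 * fs

    def test_determinism_bit_identical(self):
        spec = bm.EventSpec(
            "det", 123, treatment_durations_s={t: 5.0 for t in TREATMENTS},
            expected_counts={("during", "HFBP_M"): 2.0},
        )
        a = bm.render_event(spec)
        b = bm.render_event(spec)
        for t in TREATMENTS:
            assert np.array_equal(a.clips[t].samples, b.clips[t].samples)
        assert a.truth == b.truth and a.counts == b.counts

    def test_truth_counts_match_selections(self, quiet_scene):
        for cls in ("HFBP_M", "HFBP_B", "CC"):
            for t in TREATMENTS:
                n_truth = sum(
                    1 for s in quiet_scene.truth_for(t) if s["call_class"] == cls
                )
                assert n_truth == quiet_scene.counts[(t, cls)]
        for s in quiet_scene.truth:
            clip = quiet_scene.clips[s["treatment"]]
            assert 0 <= s["begin_s"] < s["end_s"] <= clip.duration_s + 1e-6

    def test_vessel_energy_only_in_during(self):
        spec = bm.EventSpec(
            "ves", 31, treatment_durations_s={t: 6.0 for t in TREATMENTS}
        )
        scene = bm.render_event(spec, vessel_rolloff_hz=50_000.0)
        lows = {
            t: band_density_db(scene.clips[t].samples, scene.clips[t].fs, 200, 2_000)
            for t in TREATMENTS
        }
        assert lows["during"] - max(lows["before"], lows["after"]) > 6

    def test_quiet_window_guarantee(self, quiet_scene):
        for t in TREATMENTS:
            occupied = [(s["begin_s"], s["end_s"]) for s in quiet_scene.truth_for(t)]
            wins = bm.extract_noise_snippets(
                quiet_scene.clips[t].duration_s, occupied, n=10, len_s=0.5
            )
            assert len(wins) == 10

    def test_impossible_density_raises(self):
        spec = bm.EventSpec(
            "dense", 7, treatment_durations_s={t: 6.0 for t in TREATMENTS},
            expected_counts={("before", "CC"): 40.0},
            event_random_intercept_sd=0.0,
        )
        with pytest.raises(ValueError, match="quiet"):
            bm.render_event(spec, vessel_rolloff_hz=None)

    def test_no_clipping_and_calibration_round_trip(self, quiet_scene, tmp_path):
        """Writing a clip through WAV at the deployment calibration loses < 0.1 dB."""
        from belumask.audio import read_wav, write_wav

        assert quiet_scene.log == []  # no clipping recorded
        cal = quiet_scene.calibration
        clip = quiet_scene.clips["during"]
        digital = bm.pressure_to_digital(clip, cal)
        assert np.max(np.abs(digital)) < 1.0
        p = tmp_path / "d.wav"
        write_wav(p, digital, cal.fs, cal.bit_depth)
        back, _ = read_wav(p)
        restored = bm.wav_to_pressure(back, cal)
        rms_a = np.sqrt(np.mean(clip.samples**2))
        rms_b = np.sqrt(np.mean(restored.samples**2))
        assert abs(20 * np.log10(rms_a / rms_b)) < 0.1
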