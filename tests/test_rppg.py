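"""POS pulse extraction, windowed spectral HR, aggregation, quality index."""

import numpy as np
import pytest
from conftest import make_hr_series
from scipy.signal import periodogram

from pulsetherm import rppg, sim


def constant_traces(n=300, fps=30.0, rgb=(120.0, 100.0, 80.0)):
    arr = np.tile(np.asarray(rgb), (n, 1))
    return rppg.RoiTraceSet(fps=fps, rgb={0: arr})


class TestPosBvp:
    def test_constant_input_gives_identically_zero_bvp(self):
        bvp = rppg.pos_bvp(constant_traces())[0]
        assert np.allclose(bvp.samples, 0.0, atol=1e-12)

    def test_gain_invariance_under_channel_scaling(self, clean_traces):
        scaled = rppg.RoiTraceSet(
            fps=clean_traces.fps,
            rgb={k: 3.0 * v for k, v in clean_traces.rgb.items()},
        )
        a = rppg.pos_bvp(clean_traces)
        b = rppg.pos_bvp(scaled)
        for x, y in zip(a, b):
            assert np.allclose(x.samples, y.samples, atol=1e-9)

    def test_bvp_peak_frequency_matches_pulse_rate(self):
        beats = sim.generate_beat_series(120, 72, 0, 0, 0, seed=0)  # 1.2 Hz
        tr = sim.synthesize_rgb_traces(beats, fps=30, n_rois=1, pulse_amp=0.02,
                                       noise_sd=0.0, seed=0)
        bvp = rppg.pos_bvp(tr)[0]
        f, p = periodogram(bvp.samples, fs=30)
        assert f[np.argmax(p)] == pytest.approx(1.2, abs=0.02)

    def test_output_length_equals_input_length(self, clean_traces):
        for bvp in rppg.pos_bvp(clean_traces):
            assert len(bvp.samples) == clean_traces.n_samples

    def test_nonpositive_intensities_rejected(self):
        arr = np.ones((100, 3))
        arr[50, 1] = 0.0
        with pytest.raises(ValueError, match="> 0"):
            rppg.RoiTraceSet(fps=30, rgb={0: arr})

    def test_trace_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="POS window"):
            rppg.pos_bvp(constant_traces(n=20))


class TestWindowedHr:
    @staticmethod
    def sinusoid_bvp(freq_hz, fps=30.0, dur_s=30.0, amp=1.0):
        t = np.arange(int(dur_s * fps)) / fps
        return rppg.BvpSignal(roi_id=0, samples=amp * np.sin(2 * np.pi * freq_hz * t), fps=fps)

    def test_pure_tone_recovered_in_every_window(self):
        hr = rppg.windowed_hr(self.sinusoid_bvp(1.2))
        assert np.allclose(hr.hr_bpm, 72.0, atol=0.25)

    def test_larger_amplitude_wins_the_argmax(self):
        b1 = self.sinusoid_bvp(1.0, amp=1.0)
        b2 = self.sinusoid_bvp(2.0, amp=0.3)
        mix = rppg.BvpSignal(roi_id=0, samples=b1.samples + b2.samples, fps=30.0)
        hr = rppg.windowed_hr(mix)
        assert np.allclose(hr.hr_bpm, 60.0, atol=0.25)

    def test_argmax_restricted_to_search_band(self):
        # 0.5 Hz is below the band; the in-band argmax is reported instead
        hr = rppg.windowed_hr(self.sinusoid_bvp(0.5))
        assert np.all(hr.hr_bpm >= 60 * hr.band_hz[0])
        assert not np.any(np.isclose(hr.hr_bpm, 30.0, atol=1.0))

    def test_all_zero_window_emitted_missing(self):
        bvp = rppg.BvpSignal(roi_id=0, samples=np.zeros(300), fps=30.0)
        hr = rppg.windowed_hr(bvp)
        assert np.all(np.isnan(hr.hr_bpm))

    def test_window_count_formula(self):
        for dur, win, hop in [(30, 6, 1), (45.5, 6, 2), (12, 6, 1)]:
            bvp = self.sinusoid_bvp(1.2, dur_s=dur)
            hr = rppg.windowed_hr(bvp, win_s=win, hop_s=hop)
            expected = int((dur - win) // hop) + 1
            assert len(hr) == expected


class TestAggregateAndQuality:
    def make(self, values, **kw):
        return make_hr_series(values, **kw)

    def test_unanimous_rois_pass_through(self):
        series = [self.make([72, 72, 72]) for _ in range(3)]
        agg = rppg.aggregate_hr(series)
        assert np.allclose(agg.hr_bpm, 72.0)
        assert agg.roi_id is None

    def test_median_resists_outlier_roi(self):
        series = [self.make([60] * 3), self.make([72] * 3), self.make([150] * 3)]
        assert np.allclose(rppg.aggregate_hr(series).hr_bpm, 72.0)

    def test_missing_roi_excluded_from_median(self):
        series = [self.make([70, np.nan]), self.make([80, 90]), self.make([90, 100])]
        agg = rppg.aggregate_hr(series)
        assert agg.hr_bpm[0] == 80.0 and agg.hr_bpm[1] == 95.0

    def test_quality_zero_iff_rois_equal_aggregate(self):
        series = [self.make([72, 80]), self.make([72, 80])]
        agg = rppg.aggregate_hr(series)
        qi = rppg.quality_mae_over_hr(series, agg)
        assert qi.mae_over_hr == 0.0

    def test_quality_hand_computed_example(self):
        series = [self.make([60.0]), self.make([80.0])]
        agg = self.make([70.0])
        qi = rppg.quality_mae_over_hr(series, agg)
        assert qi.mae_bpm == pytest.approx(10.0)
        assert qi.mae_over_hr == pytest.approx(10.0 / 70.0)

    def test_quality_is_scale_free(self):
        series = [self.make([60.0]), self.make([80.0])]
        agg = self.make([70.0])
        doubled = [self.make([120.0]), self.make([160.0])]
        agg2 = self.make([140.0])
        a = rppg.quality_mae_over_hr(series, agg).mae_over_hr
        b = rppg.quality_mae_over_hr(doubled, agg2).mae_over_hr
        assert a == pytest.approx(b)

    def test_quality_grows_with_added_noise(self):
        """Noising a subset of ROIs never lowers MAE/HR in expectation."""
        beats = sim.generate_beat_series(120, 72, 0.02, 0.02, 0.005, seed=0)
        deltas = []
        for rep in range(20):
            tr = sim.synthesize_rgb_traces(beats, n_rois=4, noise_sd=0.002, seed=rep)
            _, _, qi_clean = rppg.extract_hr(tr)
            rng = np.random.default_rng(1000 + rep)
            noisy = {k: v.copy() for k, v in tr.rgb.items()}
            for k in list(noisy)[:2]:
                noisy[k] = noisy[k] * (1 + rng.normal(0, 0.01, noisy[k].shape))
            tr2 = rppg.RoiTraceSet(fps=tr.fps, rgb=noisy, time_s=tr.time_s)
            _, _, qi_noisy = rppg.extract_hr(tr2)
            deltas.append(qi_noisy.mae_over_hr - qi_clean.mae_over_hr)
        assert np.mean(deltas) > 0

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            rppg.aggregate_hr([self.make([72, 72]), self.make([72, 72, 72])])
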