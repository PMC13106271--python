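"""Frequency-domain chain: SNR estimation, adaptive band, DESA-1, stitching."""

import numpy as np
import pytest

import camhrv
from camhrv.freqdomain import (
    DemodParams,
    WindowEstimate,
    adaptive_band,
    center_freq_snr,
    desa1,
    hrvcam,
    stitch,
)
from camhrv.pos import pos
from camhrv.signals import BVPSignal


def _bvp(value, fs=30.0):
    return BVPSignal(t=np.arange(value.size) / fs, value=value, fs=fs)


class TestCenterFreqSNR:
    def test_pure_tone_center_frequency(self):
        t = np.arange(360) / 30
        f_c, snr = center_freq_snr(np.sin(2 * np.pi * 1.0 * t), 30)
        assert f_c == pytest.approx(1.0, abs=1 / 12)
        assert snr > 10

    def test_snr_decreases_with_noise(self, rng):
        t = np.arange(360) / 30
        tone = np.sin(2 * np.pi * 1.0 * t)
        snrs = []
        for sd in (0.1, 0.5, 2.0):
            _, snr = center_freq_snr(tone + sd * rng.standard_normal(t.size), 30)
            snrs.append(snr)
        assert snrs[0] > snrs[1] > snrs[2]

    def test_stronger_tone_wins(self):
        t = np.arange(360) / 30
        x = 0.5 * np.sin(2 * np.pi * 0.8 * t) + np.sin(2 * np.pi * 1.2 * t)
        f_c, _ = center_freq_snr(x, 30)
        assert f_c == pytest.approx(1.2, abs=1 / 12)

    def test_zero_window_flagged(self):
        f_c, snr = center_freq_snr(np.zeros(360), 30)
        assert np.isnan(f_c) and snr == float("-inf")


class TestAdaptiveBand:
    def test_floor_and_ceiling(self):
        p = DemodParams()
        lo, hi = adaptive_band(1.25, p.snr_lo - 5, p)
        assert hi - lo == pytest.approx(p.b_min)
        lo, hi = adaptive_band(1.25, p.snr_hi + 5, p)
        assert hi - lo == pytest.approx(p.b_max)

    def test_midpoint_gives_mean_bandwidth(self):
        p = DemodParams()
        lo, hi = adaptive_band(1.25, (p.snr_lo + p.snr_hi) / 2, p)
        assert hi - lo == pytest.approx(0.5)

    def test_band_clipped_to_search_band(self):
        p = DemodParams()
        lo, hi = adaptive_band(0.55, p.snr_hi, p)
        assert lo == pytest.approx(p.search_band[0])


class TestDESA1:
    @pytest.mark.parametrize("f", [0.8, 1.2, 1.6, 2.0])
    def test_exact_on_pure_sinusoid(self, f):
        t = np.arange(900) / 30
        inst, valid = desa1(np.cos(2 * np.pi * f * t), 30)
        interior = inst[50:-50]
        assert np.max(np.abs(interior - f) / f) < 1e-3
        assert valid[50:-50].all()

    def test_tracks_linear_chirp(self):
        fs = 30.0
        t = np.arange(int(30 * fs)) / fs
        f0, f1 = 0.8, 1.6
        k = (f1 - f0) / 30.0
        x = np.cos(2 * np.pi * (f0 * t + 0.5 * k * t**2))
        truth = f0 + k * t
        inst, _ = desa1(x, fs)
        rel = np.abs(inst[50:-50] - truth[50:-50]) / truth[50:-50]
        assert np.max(rel) < 0.02

    def test_zero_signal_flagged_empty(self):
        inst, valid = desa1(np.zeros(100), 30)
        assert not valid.any()
        assert np.isnan(inst).all()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            desa1(np.ones(2), 30)


class TestStitch:
    def _west(self, idx, start, freq, wlen):
        return WindowEstimate(
            window_index=idx, t_center=0.0, f_c=freq, snr_db=10.0,
            band=(0.5, 2.5), inst_freq=np.full(wlen, freq),
            valid_mask=np.ones(wlen, bool), start=start,
            weight=np.hanning(wlen + 2)[1:-1],
        )

    def test_single_full_window_identity(self):
        w = self._west(0, 0, 1.0, 300)
        out = stitch([w], hop=300, out_len=300)
        assert np.allclose(out.hr_bpm, 60.0)

    def test_constant_windows_give_constant_bpm(self):
        wins = [self._west(i, 150 * i, 1.2, 300) for i in range(5)]
        out = stitch(wins, hop=150, out_len=750)
        assert np.allclose(out.hr_bpm, 72.0)

    def test_weight_normalization_exact(self):
        wins = [self._west(i, 100 * i, 1.0, 300) for i in range(4)]
        out = stitch(wins, hop=100, out_len=600)
        assert np.allclose(out.hr_bpm, 60.0)


class TestHRVCam:
    def test_clean_recording_mean_hr(self):
        truth = camhrv.generate_rr(n_beats=80, mean_ibi_ms=60000 / 72,
                                   lf_amp_ms=20, hf_amp_ms=15, jitter_sd_ms=5,
                                   seed=6)
        rgb = camhrv.generate_rgb(truth, noise=None)
        inst, _ = hrvcam(pos(rgb))
        assert abs(np.mean(inst.hr_bpm) - 72.0) < 1.0

    def test_tracks_sinusoidal_hr_modulation(self):
        # +-5 BPM at 0.25 Hz on a 75 BPM carrier
        truth = camhrv.generate_rr(n_beats=80, mean_ibi_ms=800, lf_amp_ms=0,
                                   hf_amp_ms=800 * 5 / 75, jitter_sd_ms=0)
        rgb = camhrv.generate_rgb(truth, noise=None)
        inst, _ = hrvcam(pos(rgb))
        t = inst.t
        z = inst.hr_bpm - inst.hr_bpm.mean()
        c = 2 * np.mean(z * np.sin(2 * np.pi * 0.25 * t))
        s = 2 * np.mean(z * np.cos(2 * np.pi * 0.25 * t))
        assert np.hypot(c, s) >= 0.6 * 5.0

    def test_noise_input_flagged_by_low_snr(self, rng):
        noise = rng.standard_normal(1800)
        inst, wins = hrvcam(_bvp(noise))
        assert all(w.snr_db < 5 for w in wins)

    def test_output_within_search_band_bounds(self, clean_rgb):
        inst, _ = hrvcam(pos(clean_rgb))
        assert inst.hr_bpm.min() >= 30.0 - 1e-9
        assert inst.hr_bpm.max() <= 150.0 + 1e-9

    def test_deterministic(self, clean_rgb):
        a, _ = hrvcam(pos(clean_rgb))
        b, _ = hrvcam(pos(clean_rgb))
        assert np.array_equal(a.hr_bpm, b.hr_bpm)

    def test_too_short_recording(self):
        from camhrv.signals import TooShortError

        with pytest.raises(TooShortError):
            hrvcam(_bvp(np.random.default_rng(0).standard_normal(100)))
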