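"""Benchmark metrics: DTW vs brute force, HRV formulas, agreement stats."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import camhrv
from camhrv.evaluation import (
    RecordingPair,
    aggregate,
    align,
    bland_altman,
    dtw_normalized,
    evaluate_pair,
    pearson_r,
    pseudo_ibis,
    rmssd,
    sdnn,
)
from camhrv.signals import IBISeries, InstHRSeries


def brute_force_dtw(a, b):
    """Enumerate every monotone warping path; minimum cost, then minimum
    length among minimum-cost paths; return cost/length.  Independent of
    the DP implementation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = a.size, b.size
    best = [np.inf, np.inf]  # cost, length

    def walk(i, j, cost, length):
        cost += abs(a[i] - b[j])
        if i == n - 1 and j == m - 1:
            eps = 1e-9 * (1.0 + abs(best[0])) if np.isfinite(best[0]) else 0.0
            if cost < best[0] - eps or (
                abs(cost - best[0]) <= eps and length < best[1]
            ):
                best[0], best[1] = cost, length
            return
        if i + 1 < n:
            walk(i + 1, j, cost, length + 1)
        if j + 1 < m:
            walk(i, j + 1, cost, length + 1)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost, length + 1)

    walk(0, 0, 0.0, 1)
    return best[0] / best[1]


class TestDTW:
    def test_identical_series_zero(self):
        assert dtw_normalized([1, 5, 3], [1, 5, 3]) == 0.0

    def test_duplicate_absorbed_at_zero_cost(self):
        assert dtw_normalized([1, 2, 3], [1, 2, 2, 3]) == 0.0

    def test_constant_offset_costs_offset(self):
        a = np.array([1.0, 2.0, 3.0])
        assert dtw_normalized(a, a + 2.0) == pytest.approx(
            brute_force_dtw(a, a + 2.0)
        )

    def test_matches_brute_force_on_random_short_series(self, rng):
        for _ in range(220):
            n, m = rng.integers(1, 7), rng.integers(1, 7)
            a = rng.integers(0, 10, n).astype(float)
            b = rng.integers(0, 10, m).astype(float)
            assert dtw_normalized(a, b) == pytest.approx(
                brute_force_dtw(a, b), abs=1e-12
            )

    @given(
        st.lists(st.integers(0, 9), min_size=1, max_size=6),
        st.lists(st.integers(0, 9), min_size=1, max_size=6),
        st.integers(-5, 5),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_shift_invariance(self, a, b, c):
        a, b = np.asarray(a, float), np.asarray(b, float)
        d = dtw_normalized(a, b)
        assert d == pytest.approx(dtw_normalized(b, a), abs=1e-12)
        assert d == pytest.approx(dtw_normalized(a + c, b + c), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dtw_normalized([], [1.0])


class TestHRVFormulas:
    def test_worked_example(self):
        vals = np.array([800.0, 810.0, 790.0, 805.0])
        # independent two-line oracles
        sdnn_ref = float(np.sqrt(np.sum((vals - vals.mean()) ** 2) / 3))
        rmssd_ref = float(np.sqrt(np.mean(np.diff(vals) ** 2)))
        assert sdnn(vals) == pytest.approx(sdnn_ref, abs=1e-12)
        assert rmssd(vals) == pytest.approx(rmssd_ref, abs=1e-12)
        assert round(sdnn(vals), 2) == 8.54
        assert round(rmssd(vals), 2) == 15.55

    def test_agreement_with_oracle_on_random_series(self, rng):
        for _ in range(1000):
            vals = rng.uniform(400, 1500, rng.integers(3, 40))
            assert sdnn(vals) == pytest.approx(np.std(vals, ddof=1), abs=1e-9)
            assert rmssd(vals) == pytest.approx(
                np.sqrt(np.mean(np.diff(vals) ** 2)), abs=1e-9
            )

    def test_constant_series_zero(self):
        assert sdnn(np.full(10, 900.0)) == 0.0
        assert rmssd(np.full(10, 900.0)) == 0.0

    def test_scale_equivariance_and_reversal(self):
        vals = np.array([700.0, 820.0, 760.0, 905.0, 840.0])
        assert sdnn(2 * vals) == pytest.approx(2 * sdnn(vals))
        assert rmssd(vals[::-1]) == pytest.approx(rmssd(vals))

    def test_flagged_intervals_excluded(self):
        ib = IBISeries.from_ibis([1.0, 2.0, 3.0, 4.0],
                                 [800.0, 2500.0, 810.0, 790.0])
        assert ib.flags[1]
        assert sdnn(ib) == pytest.approx(sdnn(np.array([800.0, 810.0, 790.0])))

    def test_too_few_values_flagged_missing(self):
        assert np.isnan(sdnn(np.array([800.0])))
        assert np.isnan(rmssd(np.array([800.0, 810.0])))


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(a, a) == pytest.approx(1.0)
        z = a - a.mean()
        assert pearson_r(z, -z) == pytest.approx(-1.0)

    def test_constant_input_flagged(self):
        assert np.isnan(pearson_r(np.full(5, 2.0), np.arange(5.0)))


class TestAlign:
    def _series(self, hr, t0=0.0, fs=30.0):
        n = hr.size
        return InstHRSeries(
            t=t0 + np.arange(n) / fs, hr_bpm=hr, valid=np.ones(n, bool), fs=fs
        )

    def test_zero_shift_identity(self):
        hr = 70 + np.sin(np.arange(300) / 10.0)
        pair = align(RecordingPair(self._series(hr), self._series(hr.copy())),
                     shift_ms=0)
        assert pearson_r(pair.rppg.hr_bpm, pair.ecg.hr_bpm) == pytest.approx(1.0)

    def test_500ms_delayed_copy_realigned(self):
        rng = np.random.default_rng(0)
        base = 70 + np.cumsum(rng.standard_normal(400)) * 0.1
        # rPPG observes the same HR 500 ms (15 samples) later
        rppg = self._series(base, t0=0.5)
        ecg = self._series(base, t0=0.0)
        pair = align(RecordingPair(rppg, ecg), shift_ms=500)
        assert pearson_r(pair.rppg.hr_bpm, pair.ecg.hr_bpm) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_non_grid_shift_interpolates(self):
        hr = 70 + np.sin(np.arange(300) / 10.0)
        pair = align(RecordingPair(self._series(hr), self._series(hr.copy())),
                     shift_ms=505)
        assert pair.rppg.hr_bpm.size == pair.ecg.hr_bpm.size
        assert np.isfinite(pair.rppg.hr_bpm).all()

    def test_insufficient_overlap_rejected(self):
        a = self._series(np.full(40, 70.0), t0=0.0)
        b = self._series(np.full(40, 70.0), t0=10.0)
        with pytest.raises(ValueError):
            align(RecordingPair(a, b))


class TestPseudoIBIs:
    def test_constant_60_bpm(self):
        t = np.arange(301) / 30.0
        s = InstHRSeries(t=t, hr_bpm=np.full(t.size, 60.0),
                         valid=np.ones(t.size, bool))
        ib = pseudo_ibis(s)
        assert ib.ibi_ms.size == 9
        assert np.allclose(ib.ibi_ms, 1000.0)

    def test_constant_120_bpm(self):
        t = np.arange(301) / 30.0
        s = InstHRSeries(t=t, hr_bpm=np.full(t.size, 120.0),
                         valid=np.ones(t.size, bool))
        assert np.allclose(pseudo_ibis(s).ibi_ms, 500.0)

    def test_inverse_of_generator_phase_model(self, truth):
        t_grid = np.arange(int(truth.duration_s() * 30)) / 30.0
        s = InstHRSeries(t=t_grid, hr_bpm=truth.inst_hr_bpm(t_grid),
                         valid=np.ones(t_grid.size, bool))
        ib = pseudo_ibis(s)
        # each reconstructed beat within one grid step of a true beat
        d = np.abs(ib.onset_t[:, None] - truth.beat_times[None, :]).min(1)
        assert d.max() <= 1 / 30 + 1e-9

    def test_mostly_invalid_rejected(self):
        t = np.arange(301) / 30.0
        valid = np.zeros(t.size, bool)
        valid[:100] = True
        s = InstHRSeries(t=t, hr_bpm=np.full(t.size, 60.0), valid=valid)
        with pytest.raises(ValueError):
            pseudo_ibis(s)


class TestEvaluatePair:
    def _series(self, hr, fs=30.0):
        return InstHRSeries(t=np.arange(hr.size) / fs, hr_bpm=hr,
                            valid=np.ones(hr.size, bool), fs=fs)

    def test_identical_pair_perfect_scores(self):
        hr = 70 + np.sin(np.arange(300) / 10.0)
        ib = IBISeries.from_ibis([1.0, 2.0, 3.0], [800.0, 820.0, 790.0])
        pair = RecordingPair(self._series(hr), self._series(hr.copy()),
                             rppg_ibis=ib, ecg_ibis=ib)
        m = evaluate_pair(pair)
        assert m.r == pytest.approx(1.0)
        assert m.dtw_norm == 0.0
        assert m.abs_dhr_bpm == 0.0
        assert m.abs_dsdnn_ms == 0.0
        assert m.abs_drmssd_ms == 0.0

    def test_constant_offset_pair(self):
        hr = 70 + np.sin(np.arange(300) / 10.0)
        pair = RecordingPair(self._series(hr + 2.0), self._series(hr))
        m = evaluate_pair(pair)
        assert m.abs_dhr_bpm == pytest.approx(2.0)
        assert m.dtw_norm == pytest.approx(2.0, abs=1e-9)
        assert m.r == pytest.approx(1.0)
        assert np.isnan(m.abs_dsdnn_ms)  # missing IBIs stay missing


class TestBlandAltman:
    def test_identical_inputs(self):
        x = np.array([50.0, 60.0, 70.0])
        ba = bland_altman(x, x)
        assert ba.bias == 0.0 and ba.loa_lo == 0.0 and ba.loa_hi == 0.0

    def test_constant_offset(self):
        x = np.array([50.0, 60.0, 70.0])
        ba = bland_altman(x + 2.0, x)
        assert ba.bias == pytest.approx(2.0)
        assert ba.loa_hi - ba.loa_lo == pytest.approx(0.0, abs=1e-12)

    def test_known_differences(self):
        x_ecg = np.zeros(4)
        d = np.array([1.0, -1.0, 2.0, -2.0])
        ba = bland_altman(d, x_ecg)
        assert ba.bias == 0.0
        assert ba.loa_hi == pytest.approx(1.96 * np.std(d, ddof=1))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman(np.ones(2), np.ones(2))


class TestAggregate:
    def _metrics(self, values):
        from camhrv.evaluation import EvalMetrics

        return [EvalMetrics(r=v, dtw_norm=v, abs_dhr_bpm=v, abs_dsdnn_ms=v,
                            abs_drmssd_ms=v) for v in values]

    def test_single_recording(self):
        out = aggregate(self._metrics([3.0]))
        assert out["r"]["mean"] == 3.0
        assert np.isnan(out["r"]["sd"])
        assert out["r"]["mad"] == 0.0

    def test_unscaled_mad(self):
        out = aggregate(self._metrics([1.0, 2.0, 9.0]))
        assert out["dtw_norm"]["mad"] == 1.0

    def test_participant_grouping_with_singletons_is_identity(self):
        vals = [1.0, 2.0, 3.0]
        a = aggregate(self._metrics(vals))
        b = aggregate(self._metrics(vals), participant_ids=["p1", "p2", "p3"])
        assert a == b
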