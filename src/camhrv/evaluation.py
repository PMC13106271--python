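"""Benchmark metrics: alignment, the five accuracy scores, HRV summaries,
pseudo-beat reconstruction, Bland–Altman agreement, and aggregation.

The five benchmark scores per recording are Pearson's r and normalized DTW
on the aligned instantaneous-HR series, plus absolute errors of mean HR,
SDNN, and RMSSD.  Normalized DTW is the optimal alignment cost divided by
the optimal warping-path length (BPM-consistent units: it reflects both
amplitude differences and timing shifts along the path).

SDNN is the sample standard deviation (n − 1) of the inter-beat intervals;
RMSSD the root mean square of their successive differences.  For the
peak-free frequency-domain pipelines, beats are reconstructed from the HR
trajectory by integrating f(t) = HR/60 and placing a pseudo-beat at each
unit crossing of cumulative phase — the exact inverse of the generator's
linear-phase model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import RecordingMeta
from .signals import IBISeries, InstHRSeries

__all__ = [
    "RecordingPair",
    "HRVMetrics",
    "EvalMetrics",
    "BlandAltman",
    "align",
    "pearson_r",
    "dtw_normalized",
    "sdnn",
    "rmssd",
    "hrv_metrics",
    "pseudo_ibis",
    "evaluate_pair",
    "bland_altman",
    "aggregate",
]

METRIC_NAMES = ("r", "dtw_norm", "abs_dhr_bpm", "abs_dsdnn_ms", "abs_drmssd_ms")


@dataclass
class RecordingPair:
    rppg: InstHRSeries
    ecg: InstHRSeries
    rppg_ibis: IBISeries | None = None
    ecg_ibis: IBISeries | None = None
    meta: RecordingMeta | None = None


@dataclass
class HRVMetrics:
    mean_hr_bpm: float
    sdnn_ms: float
    rmssd_ms: float
    n_ibis: int


@dataclass
class EvalMetrics:
    r: float  # NaN == flagged missing
    dtw_norm: float
    abs_dhr_bpm: float
    abs_dsdnn_ms: float
    abs_drmssd_ms: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class BlandAltman:
    bias: float
    loa_lo: float
    loa_hi: float
    n: int


def align(pair: RecordingPair, shift_ms: float = 500.0) -> RecordingPair:
    """Advance the rPPG timeline by ``shift_ms`` and truncate to overlap.

    The backward shift compensates pulse-arrival and camera-system latency
    between electrical (ECG) and optical (rPPG) events.  When the shift is
    a multiple of the 30 Hz grid step the series are re-indexed without
    interpolation; otherwise the rPPG series is linearly interpolated onto
    the shifted grid.
    """
    rppg, ecg = pair.rppg, pair.ecg
    fs = rppg.fs
    shift_s = shift_ms / 1000.0
    step = 1.0 / fs
    n_steps = shift_s / step
    if abs(n_steps - round(n_steps)) < 1e-9:
        t_shifted = rppg.t - shift_s
        hr = rppg.hr_bpm
        valid = rppg.valid
    else:
        t_shifted_grid = np.round((rppg.t - shift_s) * fs) / fs
        hr = np.interp(t_shifted_grid + shift_s, rppg.t, rppg.hr_bpm)
        valid = (
            np.interp(t_shifted_grid + shift_s, rppg.t, rppg.valid.astype(float))
            >= 1.0
        )
        t_shifted = t_shifted_grid
    lo = max(t_shifted[0], ecg.t[0])
    hi = min(t_shifted[-1], ecg.t[-1])
    if hi - lo < 1.0:
        raise ValueError("less than 1 s overlap after alignment")
    sel_r = (t_shifted >= lo - 1e-9) & (t_shifted <= hi + 1e-9)
    sel_e = (ecg.t >= lo - 1e-9) & (ecg.t <= hi + 1e-9)
    n = min(sel_r.sum(), sel_e.sum())
    ir = np.flatnonzero(sel_r)[:n]
    ie = np.flatnonzero(sel_e)[:n]
    rppg2 = InstHRSeries(
        t=t_shifted[ir], hr_bpm=hr[ir], valid=valid[ir], fs=fs
    )
    ecg2 = InstHRSeries(
        t=ecg.t[ie], hr_bpm=ecg.hr_bpm[ie], valid=ecg.valid[ie], fs=ecg.fs
    )
    return RecordingPair(
        rppg=rppg2, ecg=ecg2, rppg_ibis=pair.rppg_ibis, ecg_ibis=pair.ecg_ibis,
        meta=pair.meta,
    )


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation; NaN (flagged missing) for constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length series of at least 3 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    am = a - a.mean()
    bm = b - b.mean()
    return float(am @ bm / math.sqrt((am @ am) * (bm @ bm)))


def _dtw_core(cost: np.ndarray) -> float:
    """Min-cost DP with a min-path-length tie-break; returns cost/length.

    Cost ties are detected with a small relative tolerance so the
    normalization is stable under floating-point perturbations (e.g. adding
    the same constant to both series).
    """
    n, m = cost.shape
    D = np.full((n + 1, m + 1), np.inf)
    L = np.zeros((n + 1, m + 1), dtype=np.int64)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = D[i - 1, j - 1]
            blen = L[i - 1, j - 1]
            for di, dj in ((i - 1, j), (i, j - 1)):
                d = D[di, dj]
                le = L[di, dj]
                if not np.isfinite(best):
                    if d < best:
                        best, blen = d, le
                    continue
                eps = 1e-9 * (1.0 + abs(best))
                if d < best - eps or (abs(d - best) <= eps and le < blen):
                    best, blen = d, le
            D[i, j] = best + cost[i - 1, j - 1]
            L[i, j] = blen + 1
    return D[n, m] / L[n, m]


try:  # long recordings make the quadratic DP worth compiling
    from numba import njit

    _dtw_core = njit(cache=True)(_dtw_core)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


def dtw_normalized(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized dynamic-time-warping distance.

    Local cost |a_i − b_j|; steps (i−1, j), (i, j−1), (i−1, j−1); no global
    window.  The optimal total cost is divided by the optimal warping-path
    length (the shortest path among minimum-cost paths — a deterministic
    tie-break).  Symmetric, and invariant to adding the same constant to
    both series.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    cost = np.abs(a[:, None] - b[None, :])
    return float(_dtw_core(cost))


def sdnn(ibis: IBISeries | np.ndarray) -> float:
    """Sample standard deviation (n − 1) of usable IBIs, ms; NaN if < 2."""
    vals = ibis.usable() if isinstance(ibis, IBISeries) else np.asarray(ibis, float)
    if vals.size < 2:
        return float("nan")
    return float(np.std(vals, ddof=1))


def rmssd(ibis: IBISeries | np.ndarray) -> float:
    """Root mean square of successive IBI differences, ms; NaN if < 3."""
    vals = ibis.usable() if isinstance(ibis, IBISeries) else np.asarray(ibis, float)
    if vals.size < 3:
        return float("nan")
    d = np.diff(vals)
    return float(np.sqrt(np.mean(d**2)))


def hrv_metrics(ibis: IBISeries) -> HRVMetrics:
    vals = ibis.usable()
    mean_hr = float(60000.0 / np.mean(vals)) if vals.size else float("nan")
    return HRVMetrics(
        mean_hr_bpm=mean_hr, sdnn_ms=sdnn(ibis), rmssd_ms=rmssd(ibis),
        n_ibis=int(vals.size),
    )


def pseudo_ibis(inst_hr: InstHRSeries, min_valid_fraction: float = 0.8) -> IBISeries:
    """Reconstruct pseudo-beats from an instantaneous-HR trajectory.

    Integrates f(t) = HR/60 Hz with the trapezoid rule; a pseudo-beat lies
    at each unit crossing of cumulative phase (sub-step position by linear
    interpolation).  Exact inverse of a linear-between-beats phase model.
    """
    if inst_hr.valid.mean() < min_valid_fraction:
        raise ValueError(
            f"only {inst_hr.valid.mean():.0%} of samples valid (< "
            f"{min_valid_fraction:.0%})"
        )
    t = inst_hr.t
    f = inst_hr.hr_bpm / 60.0
    dt = np.diff(t)
    phase = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * dt)])
    n_beats = int(np.floor(phase[-1]))
    if n_beats < 2:
        raise ValueError("fewer than two pseudo-beat crossings")
    targets = np.arange(1, n_beats + 1, dtype=float)
    beat_times = np.interp(targets, phase, t)
    ibi_ms = np.diff(beat_times) * 1000.0
    if ibi_ms.size < 1:
        raise ValueError("fewer than two pseudo-beat crossings")
    return IBISeries.from_ibis(onset_t=beat_times[1:], ibi_ms=ibi_ms)


def evaluate_pair(pair: RecordingPair) -> EvalMetrics:
    """The five benchmark scores for one aligned recording pair.

    Flagged-missing components (constant series, unusable IBIs) propagate
    as NaN, never as zero.
    """
    a = pair.rppg.hr_bpm
    b = pair.ecg.hr_bpm
    r = pearson_r(a, b)
    d = dtw_normalized(a, b)
    abs_dhr = float(abs(a.mean() - b.mean()))
    if pair.rppg_ibis is not None and pair.ecg_ibis is not None:
        s_r, s_e = sdnn(pair.rppg_ibis), sdnn(pair.ecg_ibis)
        m_r, m_e = rmssd(pair.rppg_ibis), rmssd(pair.ecg_ibis)
        abs_dsdnn = float(abs(s_r - s_e))
        abs_drmssd = float(abs(m_r - m_e))
    else:
        abs_dsdnn = float("nan")
        abs_drmssd = float("nan")
    return EvalMetrics(
        r=r, dtw_norm=d, abs_dhr_bpm=abs_dhr, abs_dsdnn_ms=abs_dsdnn,
        abs_drmssd_ms=abs_drmssd,
    )


def bland_altman(x_rppg: np.ndarray, x_ecg: np.ndarray) -> BlandAltman:
    """Bias and 95% limits of agreement of paired per-recording estimates."""
    x_rppg = np.asarray(x_rppg, dtype=float)
    x_ecg = np.asarray(x_ecg, dtype=float)
    if x_rppg.size != x_ecg.size or x_rppg.size < 3:
        raise ValueError("need at least 3 paired recordings")
    d = x_rppg - x_ecg
    bias = float(d.mean())
    half = 1.96 * float(np.std(d, ddof=1))
    return BlandAltman(bias=bias, loa_lo=bias - half, loa_hi=bias + half, n=d.size)


def aggregate(
    metrics: list[EvalMetrics],
    participant_ids: list[str] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-metric mean, sample SD, and unscaled MAD across recordings.

    MAD is the raw median absolute deviation from the median (no 1.4826
    consistency factor).  With ``participant_ids``, recordings are first
    averaged within participant, then summarized across participants.
    Missing (NaN) values are excluded listwise per metric.
    """
    if not metrics:
        raise ValueError("need at least one recording")
    table = {name: np.array([m.as_dict()[name] for m in metrics]) for name in
             METRIC_NAMES}
    if participant_ids is not None:
        if len(participant_ids) != len(metrics):
            raise ValueError("one participant id per recording required")
        pids = np.asarray(participant_ids)
        for name, vals in table.items():
            agg = []
            for pid in dict.fromkeys(participant_ids):  # stable unique
                v = vals[pids == pid]
                v = v[~np.isnan(v)]
                if v.size:
                    agg.append(v.mean())
            table[name] = np.asarray(agg)
    out: dict[str, dict[str, float]] = {}
    for name, vals in table.items():
        v = vals[~np.isnan(vals)]
        if v.size == 0:
            out[name] = {"mean": float("nan"), "sd": float("nan"),
                         "mad": float("nan")}
            continue
        med = np.median(v)
        out[name] = {
            "mean": float(v.mean()),
            "sd": float(np.std(v, ddof=1)) if v.size >= 2 else float("nan"),
            "mad": float(np.median(np.abs(v - med))),
        }
    return out
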