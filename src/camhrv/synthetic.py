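"""Ground-truthed synthetic physiology: beat series, ECG, RGB traces, toy frames.

The generator emulates the signal structure the measurement chain must
recover, without attempting photorealism:

* beat-to-beat intervals follow an integral-pulse-frequency-modulation
  (IPFM) style model — instantaneous phase advances linearly between beat
  times, one beat per 2π — with low-frequency (~0.1 Hz, sympathetic/
  baroreflex band) and high-frequency (~0.25 Hz, respiratory sinus
  arrhythmia) sinusoidal modulation plus white jitter;
* the ECG is a train of unit Gaussian R-waves at the beat times;
* the RGB trace carries a green-dominant pulsatile component (hemoglobin
  absorbs green most strongly) riding on per-channel baselines, plus
  common-mode specular flicker, slow baseline drift, optional motion
  bursts, and white sensor noise.

Because the phase model is linear between beats, pseudo-beat reconstruction
from an instantaneous-HR trajectory has an exact inverse to test against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import ECGRecording, FrameSequence, IBI_PLAUSIBLE_MS, RGBTrace

__all__ = [
    "GroundTruthPhysiology",
    "NoiseSpec",
    "generate_rr",
    "generate_ecg",
    "generate_rgb",
    "generate_face_frames",
]


def _sdnn(rr_ms: np.ndarray) -> float:
    return float(np.std(rr_ms, ddof=1)) if rr_ms.size >= 2 else 0.0


def _rmssd(rr_ms: np.ndarray) -> float:
    d = np.diff(rr_ms)
    return float(np.sqrt(np.mean(d**2))) if d.size else 0.0


@dataclass
class GroundTruthPhysiology:
    """Beat times with their derived interval series and true HRV summary."""

    beat_times: np.ndarray  # s, strictly increasing
    rr_ms: np.ndarray  # ms, one per interval
    mean_hr_bpm: float
    sdnn_true_ms: float
    rmssd_true_ms: float
    lf_freq: float = 0.1
    hf_freq: float = 0.25
    seed: int = 0

    def phase(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous cardiac phase: 2π per beat, linear between beats.

        Outside the observed beats the phase is extrapolated at the rate of
        the first/last interval.
        """
        t = np.asarray(t, dtype=float)
        k = 2.0 * np.pi * np.arange(self.beat_times.size)
        interp = np.interp(t, self.beat_times, k)
        # linear extrapolation at the edges (np.interp clamps)
        ib0 = self.beat_times[1] - self.beat_times[0]
        ib1 = self.beat_times[-1] - self.beat_times[-2]
        before = t < self.beat_times[0]
        after = t > self.beat_times[-1]
        interp[before] = 2 * np.pi * (t[before] - self.beat_times[0]) / ib0
        interp[after] = k[-1] + 2 * np.pi * (t[after] - self.beat_times[-1]) / ib1
        return interp

    def inst_hr_bpm(self, t: np.ndarray) -> np.ndarray:
        """True instantaneous HR: 60000/IBI of the interval containing t."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.beat_times, t, side="right") - 1
        idx = np.clip(idx, 0, self.rr_ms.size - 1)
        return 60000.0 / self.rr_ms[idx]

    def duration_s(self) -> float:
        return float(self.beat_times[-1])


@dataclass
class NoiseSpec:
    """Disturbance amplitudes for the RGB generator (all relative, all ≥ 0).

    ``specular_amp`` — common-mode multiplicative flicker (light bounced off
    the epidermis, identical across channels, carrying no pulse).
    ``drift_amp``/``drift_freq`` — slow sinusoidal baseline wander.
    ``sensor_noise_sd`` — additive white noise in 8-bit counts.
    ``motion_burst_rate``/``motion_burst_amp`` — Poisson-timed ~0.5 s bursts
    of non-common-mode disturbance emulating head movement.
    """

    specular_amp: float = 0.0
    drift_amp: float = 0.0
    drift_freq: float = 0.05
    sensor_noise_sd: float = 0.0
    motion_burst_rate: float = 0.0
    motion_burst_amp: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "specular_amp",
            "drift_amp",
            "sensor_noise_sd",
            "motion_burst_rate",
            "motion_burst_amp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# Study-condition defaults: a seated adult at 75 BPM with realistic
# short-term variability (SDNN ~ 32 ms, RMSSD ~ 28 ms) and mild webcam noise.
# The sensor-noise SD applies to the per-frame *mean* trace: per-pixel noise
# of a consumer sensor (~1-2 counts) averaged over thousands of skin pixels
# leaves a few hundredths of a count on the trace.
DEFAULT_MEAN_IBI_MS = 800.0
DEFAULT_LF_AMP_MS = 35.0
DEFAULT_HF_AMP_MS = 25.0
DEFAULT_JITTER_SD_MS = 10.0
DEFAULT_PULSE_AMP = 0.005
DEFAULT_CHANNEL_GAINS = (0.35, 1.0, 0.6)
DEFAULT_BASE_RGB = (140.0, 120.0, 100.0)
MILD_NOISE = NoiseSpec(
    specular_amp=0.003, drift_amp=0.005, drift_freq=0.05, sensor_noise_sd=0.05
)
#: mild noise plus head-movement bursts (~6 per minute, 2% relative amplitude)
MOTION_NOISE = NoiseSpec(
    specular_amp=0.003,
    drift_amp=0.005,
    drift_freq=0.05,
    sensor_noise_sd=0.05,
    motion_burst_rate=0.1,
    motion_burst_amp=0.02,
)


def generate_rr(
    n_beats: int = 75,
    mean_ibi_ms: float = DEFAULT_MEAN_IBI_MS,
    lf_amp_ms: float = DEFAULT_LF_AMP_MS,
    hf_amp_ms: float = DEFAULT_HF_AMP_MS,
    lf_freq: float = 0.1,
    hf_freq: float = 0.25,
    jitter_sd_ms: float = DEFAULT_JITTER_SD_MS,
    seed: int = 0,
) -> GroundTruthPhysiology:
    """Generate a beat-time series with sinusoidally modulated intervals.

    ``IBI_k = mean + lf_amp·sin(2π·lf_freq·t_k) + hf_amp·sin(2π·hf_freq·t_k)
    + N(0, jitter_sd²)`` where ``t_k`` is the interval onset; beat times are
    the cumulative sum.  Any interval outside [300, 2000] ms is rejected.
    """
    lo, hi = IBI_PLAUSIBLE_MS
    if not lo <= mean_ibi_ms <= hi:
        raise ValueError(f"mean_ibi_ms must be in [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, jitter_sd_ms, size=n_beats) if jitter_sd_ms > 0 else (
        np.zeros(n_beats)
    )
    beat_times = np.empty(n_beats + 1)
    rr_ms = np.empty(n_beats)
    t = 0.0
    beat_times[0] = 0.0
    for k in range(n_beats):
        ibi = (
            mean_ibi_ms
            + lf_amp_ms * np.sin(2 * np.pi * lf_freq * t)
            + hf_amp_ms * np.sin(2 * np.pi * hf_freq * t)
            + jitter[k]
        )
        if not lo <= ibi <= hi:
            raise ValueError(
                f"interval {k} = {ibi:.1f} ms outside plausible range "
                f"[{lo}, {hi}] ms; reduce modulation/jitter amplitudes"
            )
        rr_ms[k] = ibi
        t += ibi / 1000.0
        beat_times[k + 1] = t
    return GroundTruthPhysiology(
        beat_times=beat_times,
        rr_ms=rr_ms,
        mean_hr_bpm=float(60000.0 / np.mean(rr_ms)),
        sdnn_true_ms=_sdnn(rr_ms),
        rmssd_true_ms=_rmssd(rr_ms),
        lf_freq=lf_freq,
        hf_freq=hf_freq,
        seed=seed,
    )


def generate_ecg(
    truth: GroundTruthPhysiology,
    fs: float = 330.0,
    r_width_ms: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin_s: float = 0.5,
) -> ECGRecording:
    """ECG-like trace: unit-amplitude Gaussian R-waves at each beat time.

    The trace spans all beats with ``margin_s`` of pre/post-roll (the ECG
    device runs before and after the video), so no R-wave is truncated at a
    record boundary.
    """
    if fs < 100:
        raise ValueError("ECG sampling rate must be at least 100 Hz")
    n0 = int(np.ceil(margin_s * fs))
    n = n0 + int(np.ceil((truth.beat_times[-1] + margin_s) * fs))
    t = (np.arange(n) - n0) / fs
    sigma = r_width_ms / 1000.0
    value = np.zeros(n)
    for tb in truth.beat_times:
        lo = max(0, n0 + int((tb - 5 * sigma) * fs))
        hi = min(n, n0 + int((tb + 5 * sigma) * fs) + 1)
        value[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - tb) / sigma) ** 2)
    if noise_sd > 0:
        value += np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return ECGRecording(t=t, value=value, fs=fs)


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, smooth_s: float = 0.25):
    """Band-limited unit-variance noise (moving-average smoothed white noise)."""
    raw = rng.standard_normal(n + 1)
    win = max(1, int(round(smooth_s * fs)))
    kernel = np.ones(win) / win
    sm = np.convolve(raw, kernel, mode="same")[:n]
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_rgb(
    truth: GroundTruthPhysiology,
    fs: float = 30.0,
    pulse_amp: float = DEFAULT_PULSE_AMP,
    channel_gains: tuple[float, float, float] = DEFAULT_CHANNEL_GAINS,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    base_rgb: tuple[float, float, float] = DEFAULT_BASE_RGB,
    n_patches: int = 1,
) -> RGBTrace:
    """Green-dominant pulsatile RGB trace with controllable disturbances.

    Channel model: ``c(t) = base_c·(1 + g_c·pulse_amp·p(φ(t)) + s(t) + d(t))
    + ε(t)`` with the asymmetric pulse ``p(φ) = sin φ + 0.3·sin(2φ + 1)``,
    common-mode specular flicker ``s``, drift ``d``, and per-channel sensor
    noise ``ε``.  With ``n_patches > 1`` each patch gets independent sensor
    noise and motion-burst realisations on a shared pulse.
    """
    if pulse_amp < 0:
        raise ValueError("pulse_amp must be >= 0")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    duration = truth.duration_s()
    n = int(np.floor(duration * fs))
    t = np.arange(n) / fs
    phi = truth.phase(t)
    pulse = np.sin(phi) + 0.3 * np.sin(2 * phi + 1.0)

    s = (
        noise.specular_amp * _smooth_noise(rng, n, fs)
        if noise.specular_amp > 0
        else np.zeros(n)
    )
    d = (
        noise.drift_amp * np.sin(2 * np.pi * noise.drift_freq * t)
        if noise.drift_amp > 0
        else np.zeros(n)
    )

    gains = np.asarray(channel_gains, dtype=float)
    base = np.asarray(base_rgb, dtype=float)
    data: dict[str, np.ndarray] = {}
    ids = (
        ["holistic"]
        if n_patches == 1
        else [f"patch_{i:02d}" for i in range(n_patches)]
    )
    for pid in ids:
        rel = (
            1.0
            + gains[None, :] * pulse_amp * pulse[:, None]
            + s[:, None]
            + d[:, None]
        )
        if noise.motion_burst_rate > 0 and noise.motion_burst_amp > 0:
            rel = rel + _motion_bursts(rng, n, fs, noise)
        arr = base[None, :] * rel
        if noise.sensor_noise_sd > 0:
            arr = arr + rng.normal(0.0, noise.sensor_noise_sd, size=(n, 3))
        data[pid] = arr
    return RGBTrace(t=t, data=data, fs=fs)


def _motion_bursts(rng, n, fs, noise: NoiseSpec, burst_s: float = 0.5) -> np.ndarray:
    """Non-common-mode burst disturbance: (n, 3) relative amplitude."""
    out = np.zeros((n, 3))
    n_bursts = rng.poisson(noise.motion_burst_rate * n / fs)
    width = max(2, int(round(burst_s * fs)))
    window = np.hanning(width)
    for _ in range(n_bursts):
        start = rng.integers(0, max(1, n - width))
        shape = rng.standard_normal((width, 3))
        # each channel moves differently -> POS cannot fully reject it
        out[start : start + width] += (
            noise.motion_burst_amp * window[:, None] * shape
        )
    return out


def generate_face_frames(
    rgb: RGBTrace,
    frame_hw: tuple[int, int] = (120, 160),
    face_box: tuple[int, int, int, int] = (20, 20, 100, 140),
    background_value: int = 10,
) -> FrameSequence:
    """Render a trace as uniform-fill 'face' frames (8-bit quantised).

    ``face_box`` is (row0, col0, row1, col1), half-open, inside the frame.
    Pixels inside the box follow the (single-patch) trace exactly up to
    rounding; the background is a constant below the skin threshold.
    """
    h, w = frame_hw
    r0, c0, r1, c1 = face_box
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError("face_box must lie inside the frame")
    trace = rgb.single()
    frames = np.full((rgb.n_frames, h, w, 3), background_value, dtype=np.uint8)
    quant = np.clip(np.rint(trace), 0, 255).astype(np.uint8)
    frames[:, r0:r1, c0:c1, :] = quant[:, None, None, :]
    return FrameSequence(frames=frames, fs=rgb.fs, timestamps=rgb.t.copy())
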