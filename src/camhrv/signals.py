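"""Domain containers shared by every stage of the rPPG/ECG processing chain.

Time is seconds (float) from recording start; all binning intervals are
half-open ``[lo, hi)``; arrays are 0-indexed.  Colour channels are always
stored in (R, G, B) order and carried by name to prevent order bugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNELS = ("R", "G", "B")

#: physiologically plausible inter-beat-interval range, ms
IBI_PLAUSIBLE_MS = (300.0, 2000.0)

#: hard instantaneous-heart-rate bounds, BPM
HR_HARD_BOUNDS_BPM = (20.0, 220.0)

HOLISTIC = "holistic"


class FormatError(ValueError):
    """A session file violates the documented layout (names the offending field)."""


class TooShortError(ValueError):
    """Recording shorter than one analysis window."""


def _uniform_grid(t: np.ndarray, tol: float = 1e-6) -> float:
    """Validate uniform sampling and return the step; raises FormatError."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise FormatError("timestamps: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError("timestamps: non-monotone or duplicated t_s")
    if np.ptp(dt) > tol:
        raise FormatError("timestamps: non-uniform sampling (gap detected)")
    return float(np.mean(dt))


@dataclass
class RGBTrace:
    """Per-frame mean colour values, optionally per patch.

    ``data`` maps patch id -> (n, 3) float array of (R, G, B) means in
    [0, 255]; the whole-face trace uses patch id ``"holistic"``.
    """

    t: np.ndarray
    data: dict[str, np.ndarray]
    fs: float
    frame_valid_fraction: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for pid, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.t.size, 3):
                raise FormatError(
                    f"patch {pid!r}: expected shape {(self.t.size, 3)}, got {arr.shape}"
                )
            self.data[pid] = arr

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def patch_ids(self) -> list[str]:
        return list(self.data)

    def single(self, patch_id: str | None = None) -> np.ndarray:
        """Return the (n, 3) array of one patch (the only one by default)."""
        if patch_id is None:
            if len(self.data) != 1:
                raise ValueError("trace has multiple patches; name one")
            patch_id = next(iter(self.data))
        return self.data[patch_id]

    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.fs


@dataclass
class BVPSignal:
    """Extracted blood-volume-pulse waveform (arbitrary units, zero mean)."""

    t: np.ndarray
    value: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape:
            raise ValueError("t and value length mismatch")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("BVP contains non-finite samples")


@dataclass
class ECGRecording:
    """Raw or filtered ECG trace at a uniform sampling rate (default 330 Hz)."""

    t: np.ndarray
    value: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape:
            raise ValueError("t and value length mismatch")


@dataclass
class RPeakSeries:
    """Detected/interpolated R-peak times with a record-level status.

    ``source`` holds ``"detected"`` or ``"interpolated"`` per beat;
    ``record_status`` is ``"ok"`` or ``"excluded"``.
    """

    times: np.ndarray
    source: np.ndarray
    record_status: str = "ok"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.source = np.asarray(self.source, dtype=object)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("R-peak times must be strictly increasing")


@dataclass
class IBISeries:
    """Inter-beat intervals (ms) anchored at the later beat of each interval."""

    onset_t: np.ndarray
    ibi_ms: np.ndarray
    flags: np.ndarray  # True where the interval is implausible

    def __post_init__(self) -> None:
        self.onset_t = np.asarray(self.onset_t, dtype=float)
        self.ibi_ms = np.asarray(self.ibi_ms, dtype=float)
        self.flags = np.asarray(self.flags, dtype=bool)
        if not (self.onset_t.shape == self.ibi_ms.shape == self.flags.shape):
            raise ValueError("IBISeries field length mismatch")
        if np.any(self.ibi_ms <= 0):
            raise ValueError("non-positive inter-beat interval")

    @classmethod
    def from_ibis(cls, onset_t, ibi_ms) -> "IBISeries":
        ibi_ms = np.asarray(ibi_ms, dtype=float)
        lo, hi = IBI_PLAUSIBLE_MS
        flags = (ibi_ms < lo) | (ibi_ms > hi)
        return cls(np.asarray(onset_t, dtype=float), ibi_ms, flags)

    def usable(self) -> np.ndarray:
        """IBI values with plausibility flags cleared."""
        return self.ibi_ms[~self.flags]


@dataclass
class InstHRSeries:
    """Instantaneous heart rate (BPM) on a uniform 30 Hz grid."""

    t: np.ndarray
    hr_bpm: np.ndarray
    valid: np.ndarray
    fs: float = 30.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.t.shape == self.hr_bpm.shape == self.valid.shape):
            raise ValueError("InstHRSeries field length mismatch")
        inbounds = (self.hr_bpm > HR_HARD_BOUNDS_BPM[0]) & (
            self.hr_bpm < HR_HARD_BOUNDS_BPM[1]
        )
        if np.any(self.valid & ~inbounds):
            raise ValueError("valid HR sample outside hard bounds (20, 220) BPM")


@dataclass
class FrameSequence:
    """A stack of H×W×3 8-bit frames with uniform timestamps."""

    frames: np.ndarray
    fs: float
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must be (n, H, W, 3)")
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be 8-bit")
        if self.frames.shape[0] != self.timestamps.size:
            raise ValueError("frame count != timestamp count")
        if self.timestamps.size >= 2:
            _uniform_grid(self.timestamps)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_hw(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]
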