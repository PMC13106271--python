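"""Session directory layout and readers/writers.

A session directory holds::

    rgb_trace.csv      t_s,patch_id,R,G,B   (patch_id "holistic" for whole-face)
    ecg.csv            t_s,ecg              (optional)
    meta.json          RecordingMeta fields
    ground_truth.json  synthetic sessions only
    frames/            optional PNG stack (frame_000000.png, ...)

Auxiliary schemas: ``bvp.csv`` (t_s,value), ``ibis.csv`` (t_s,ibi_ms,flag),
``inst_hr.csv`` (t_s,hr_bpm,valid), ``rpeaks.csv`` (t_s,source),
``noisy_segments.json`` (list of [start_s, end_s]).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RecordingMeta
from .signals import (
    BVPSignal,
    ECGRecording,
    FormatError,
    IBISeries,
    InstHRSeries,
    RGBTrace,
    _uniform_grid,
)
from .synthetic import GroundTruthPhysiology

__all__ = ["read_session", "write_session", "read_rgb_trace", "write_rgb_trace"]


def write_rgb_trace(path: Path, rgb: RGBTrace) -> None:
    rows = []
    for pid, arr in rgb.data.items():
        df = pd.DataFrame(
            {"t_s": rgb.t, "patch_id": pid, "R": arr[:, 0], "G": arr[:, 1],
             "B": arr[:, 2]}
        )
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format='%.17g')


def read_rgb_trace(path: Path) -> RGBTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t_s", "patch_id", "R", "G", "B"):
        if col not in df.columns:
            raise FormatError(f"rgb_trace.csv: missing column {col!r}")
    if df[["R", "G", "B"]].isna().any().any():
        raise FormatError("rgb_trace.csv: incomplete channel values")
    data: dict[str, np.ndarray] = {}
    t_ref = None
    for pid, sub in df.groupby("patch_id", sort=False):
        t = sub["t_s"].to_numpy(dtype=float)
        _uniform_grid(t)
        if t_ref is None:
            t_ref = t
        elif t.size != t_ref.size or np.max(np.abs(t - t_ref)) > 1e-9:
            raise FormatError(f"rgb_trace.csv: patch {pid!r} timestamps differ")
        data[str(pid)] = sub[["R", "G", "B"]].to_numpy(dtype=float)
    fs = 1.0 / float(np.mean(np.diff(t_ref)))
    return RGBTrace(t=t_ref, data=data, fs=fs)


def write_session(
    path: Path,
    rgb: RGBTrace,
    meta: RecordingMeta,
    ecg: ECGRecording | None = None,
    truth: GroundTruthPhysiology | None = None,
) -> None:
    """Write a full session directory (created if absent)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_rgb_trace(path / "rgb_trace.csv", rgb)
    meta_d = {
        "recording_id": meta.recording_id,
        "participant_id": meta.participant_id,
        "task_label": meta.task_label,
        "lighting_label": meta.lighting_label,
        "duration_s": meta.duration_s,
        "has_ecg": ecg is not None,
        "extra": meta.extra,
    }
    (path / "meta.json").write_text(json.dumps(meta_d, indent=2))
    if ecg is not None:
        pd.DataFrame({"t_s": ecg.t, "ecg": ecg.value}).to_csv(
            path / "ecg.csv", index=False, float_format='%.17g'
        )
    if truth is not None:
        gt = {
            "beat_times": truth.beat_times.tolist(),
            "rr_ms": truth.rr_ms.tolist(),
            "mean_hr_bpm": truth.mean_hr_bpm,
            "sdnn_true_ms": truth.sdnn_true_ms,
            "rmssd_true_ms": truth.rmssd_true_ms,
            "lf_freq": truth.lf_freq,
            "hf_freq": truth.hf_freq,
            "seed": truth.seed,
        }
        (path / "ground_truth.json").write_text(json.dumps(gt))


def read_session(
    path: Path,
) -> tuple[RGBTrace, ECGRecording | None, RecordingMeta]:
    """Read a session directory; the ECG slot is None when ecg.csv is absent
    (and ``meta.has_ecg`` is set accordingly)."""
    path = Path(path)
    rgb = read_rgb_trace(path / "rgb_trace.csv")
    meta_d = json.loads((path / "meta.json").read_text())
    extra = meta_d.pop("extra", {})
    has_ecg_flag = meta_d.pop("has_ecg", True)
    meta = RecordingMeta(**meta_d, extra=extra)
    ecg_path = path / "ecg.csv"
    ecg = None
    if ecg_path.exists():
        df = pd.read_csv(ecg_path, float_precision="round_trip")
        for col in ("t_s", "ecg"):
            if col not in df.columns:
                raise FormatError(f"ecg.csv: missing column {col!r}")
        t = df["t_s"].to_numpy(dtype=float)
        dt = _uniform_grid(t)
        ecg = ECGRecording(t=t, value=df["ecg"].to_numpy(dtype=float), fs=1.0 / dt)
    meta.has_ecg = ecg is not None and has_ecg_flag
    return rgb, ecg, meta


def read_ground_truth(path: Path) -> GroundTruthPhysiology:
    gt = json.loads((Path(path) / "ground_truth.json").read_text())
    return GroundTruthPhysiology(
        beat_times=np.asarray(gt["beat_times"]),
        rr_ms=np.asarray(gt["rr_ms"]),
        mean_hr_bpm=gt["mean_hr_bpm"],
        sdnn_true_ms=gt["sdnn_true_ms"],
        rmssd_true_ms=gt["rmssd_true_ms"],
        lf_freq=gt["lf_freq"],
        hf_freq=gt["hf_freq"],
        seed=gt["seed"],
    )


def write_bvp(path: Path, bvp: BVPSignal) -> None:
    pd.DataFrame({"t_s": bvp.t, "value": bvp.value}).to_csv(path, index=False, float_format='%.17g')


def write_ibis(path: Path, ibis: IBISeries) -> None:
    pd.DataFrame(
        {"t_s": ibis.onset_t, "ibi_ms": ibis.ibi_ms, "flag": ibis.flags.astype(int)}
    ).to_csv(path, index=False, float_format='%.17g')


def read_ibis(path: Path) -> IBISeries:
    df = pd.read_csv(path, float_precision="round_trip")
    return IBISeries(
        onset_t=df["t_s"].to_numpy(dtype=float),
        ibi_ms=df["ibi_ms"].to_numpy(dtype=float),
        flags=df["flag"].to_numpy(dtype=bool),
    )


def write_inst_hr(path: Path, series: InstHRSeries) -> None:
    pd.DataFrame(
        {"t_s": series.t, "hr_bpm": series.hr_bpm, "valid": series.valid.astype(int)}
    ).to_csv(path, index=False, float_format='%.17g')


def read_inst_hr(path: Path) -> InstHRSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["t_s"].to_numpy(dtype=float)
    dt = _uniform_grid(t)
    return InstHRSeries(
        t=t,
        hr_bpm=df["hr_bpm"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(dtype=bool),
        fs=1.0 / dt,
    )


def write_frames(path: Path, frames) -> None:
    """PNG stack for a FrameSequence (one file per frame)."""
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i in range(frames.n_frames):
        iio.imwrite(path / f"frame_{i:06d}.png", frames.frames[i])


def read_frames(path: Path, fs: float):
    import imageio.v3 as iio

    from .signals import FrameSequence

    files = sorted(Path(path).glob("frame_*.png"))
    if not files:
        raise FormatError("frames/: no frame_*.png files found")
    stack = np.stack([iio.imread(f) for f in files])
    t = np.arange(stack.shape[0]) / fs
    return FrameSequence(frames=stack.astype(np.uint8), fs=fs, timestamps=t)
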