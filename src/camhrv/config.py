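"""Session configuration: one flat document of every stage constant.

The four benchmark pipelines differ only in region-of-interest mode and
post-processing family:

====== ======== ============== ======================
id     ROI      post-process   patch combination
====== ======== ============== ======================
1      holistic time-domain    —
2      patches  time-domain    simple average
3      holistic freq-domain    —
4      patches  freq-domain    MRC-weighted average
====== ======== ============== ======================
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

PIPELINE_ROI = {1: "holistic", 2: "patches", 3: "holistic", 4: "patches"}
PIPELINE_DOMAIN = {1: "time", 2: "time", 3: "frequency", 4: "frequency"}


@dataclass
class SessionConfig:
    """All tunable constants of the processing chain, with study defaults."""

    pipeline_id: int = 3
    camera_fs: float = 30.0
    ecg_fs: float = 330.0
    alignment_shift_ms: float = 500.0
    rng_seed: int = 0

    # POS
    pos_window_s: float = 1.6
    # MRC
    mrc_wide_band: tuple[float, float] = (0.5, 5.0)
    mrc_narrow_halfwidth: float = 0.1
    # time-domain post-processing (pipelines 1-2)
    ma_win_frames: int = 6
    bp_low_hz: float = 0.5
    bp_high_hz: float = 2.5
    bp_order: int = 3
    upsample_fs: float = 330.0
    peak_w_peak_ms: float = 111.0
    peak_w_beat_ms: float = 667.0
    peak_offset_beta: float = 0.08
    peak_min_separation_s: float = 0.4
    # frequency-domain post-processing (pipelines 3-4)
    demod_window_s: float = 12.0
    demod_overlap_frac: float = 0.5
    demod_search_band: tuple[float, float] = (0.5, 2.5)
    demod_narrow_halfwidth: float = 0.1
    demod_bp_order: int = 8
    demod_b_min_hz: float = 0.2
    demod_b_max_hz: float = 0.8
    demod_snr_lo_db: float = 0.0
    demod_snr_hi_db: float = 10.0
    # ECG reference chain
    ecg_hp_hz: float = 0.5
    ecg_hp_order: int = 5
    ecg_notch_hz: float = 50.0
    ecg_notch_q: float = 30.0
    ecg_max_gap_s: float = 3.0
    # ROI
    skin_low: int = 40
    skin_high: int = 255
    patch_px: int = 40

    def __post_init__(self) -> None:
        if self.pipeline_id not in PIPELINE_ROI:
            raise ValueError(f"unknown pipeline_id {self.pipeline_id}; must be 1-4")
        if self.camera_fs <= 2 * self.bp_high_hz:
            raise ValueError("camera_fs must exceed twice the bandpass high cutoff")

    @property
    def roi_mode(self) -> str:
        return PIPELINE_ROI[self.pipeline_id]

    @property
    def hr_domain(self) -> str:
        return PIPELINE_DOMAIN[self.pipeline_id]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the full configuration (logged with every run)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("mrc_wide_band", "demod_search_band"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RecordingMeta:
    """Identity and context of one recording session."""

    recording_id: str
    participant_id: str
    task_label: str = ""
    lighting_label: str = "unknown"
    duration_s: float = 0.0
    has_ecg: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.recording_id or not self.participant_id:
            raise ValueError("recording_id and participant_id must be nonempty")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.lighting_label not in ("on", "off", "unknown"):
            raise ValueError("lighting_label must be one of: on, off, unknown")
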