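"""Frame stacks + face annotations -> holistic or patch-wise mean-RGB traces.

No face detector is bundled: :class:`FaceAnnotation` is an input contract
(binary masks and/or landmark-derived exclusion polygons may come from any
upstream detector or from the synthetic frame generator).  Non-skin pixels
are excluded by convex-hull masking of the eye/mouth polygons and by RGB
thresholding with every channel required to lie in [40, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .signals import FrameSequence, RGBTrace

__all__ = [
    "FaceAnnotation",
    "NoSkinPixelsError",
    "skin_mask",
    "holistic_trace",
    "patch_traces",
    "default_patch_anchors",
]


class NoSkinPixelsError(ValueError):
    """Skin mask came out empty for some frame."""

    def __init__(self, frame_index: int, message: str | None = None):
        self.frame_index = frame_index
        super().__init__(message or f"no skin pixels in frame {frame_index}")


@dataclass
class FaceAnnotation:
    """Per-frame (or static) face mask plus optional exclusions and patches.

    ``face_mask``: (H, W) or (n, H, W) boolean array.
    ``exclusion_polygons``: list of (k, 2) point arrays in (row, col) pixel
    coordinates (0-based, origin top-left); their convex hulls are removed.
    ``patch_anchors``: list of (cy, cx) patch centers in pixels.
    """

    face_mask: np.ndarray
    exclusion_polygons: list[np.ndarray] = field(default_factory=list)
    patch_anchors: list[tuple[float, float]] = field(default_factory=list)

    def mask_for(self, i: int, hw: tuple[int, int]) -> np.ndarray:
        m = np.asarray(self.face_mask, dtype=bool)
        m = m[i] if m.ndim == 3 else m
        if m.shape != hw:
            raise ValueError("face mask shape does not match frame shape")
        return m


def default_patch_anchors(
    face_box: tuple[int, int, int, int], patch_px: int = 40
) -> list[tuple[float, float]]:
    """Default forehead + cheek anchors on a normalized face box.

    Three patches across the forehead band and a 2×2 grid over each cheek
    region, expressed as fractions of the face box.  These are configurable
    stand-ins, not a claim about any particular landmark scheme.
    """
    r0, c0, r1, c1 = face_box
    h, w = r1 - r0, c1 - c0
    rel = [
        # forehead band
        (0.18, 0.30), (0.18, 0.50), (0.18, 0.70),
        # left cheek 2x2
        (0.55, 0.25), (0.55, 0.38), (0.68, 0.25), (0.68, 0.38),
        # right cheek 2x2
        (0.55, 0.62), (0.55, 0.75), (0.68, 0.62), (0.68, 0.75),
    ]
    return [(r0 + fr * h, c0 + fc * w) for fr, fc in rel]


def _hull_mask(hw: tuple[int, int], points: np.ndarray) -> np.ndarray:
    """Boolean mask of the convex hull of ``points`` ((row, col) coords)."""
    points = np.asarray(points, dtype=float)
    h, w = hw
    if points.shape[0] < 3:
        mask = np.zeros(hw, dtype=bool)
        rr = np.clip(np.rint(points[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.rint(points[:, 1]).astype(int), 0, w - 1)
        mask[rr, cc] = True
        return mask
    try:
        hull = ConvexHull(points)
    except QhullError:  # collinear points
        mask = np.zeros(hw, dtype=bool)
        rr = np.clip(np.rint(points[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.rint(points[:, 1]).astype(int), 0, w - 1)
        mask[rr, cc] = True
        return mask
    # half-plane test: a point is inside iff A @ p + b <= 0 for all facets
    eqs = hull.equations  # (n_facets, 3): a_r, a_c, offset
    rows, cols = np.mgrid[0:h, 0:w]
    pts = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)
    inside = np.all(pts @ eqs[:, :2].T + eqs[:, 2][None, :] <= 1e-9, axis=1)
    return inside.reshape(hw)


def skin_mask(
    frame: np.ndarray,
    face_mask: np.ndarray,
    exclusion_polygons: list[np.ndarray] | None = None,
    low: int = 40,
    high: int = 255,
    frame_index: int = 0,
) -> np.ndarray:
    """Keep pixels inside the face, outside exclusion hulls, with every
    channel in ``[low, high]``; raise :class:`NoSkinPixelsError` if empty."""
    face_mask = np.asarray(face_mask, dtype=bool)
    if not face_mask.any():
        raise NoSkinPixelsError(frame_index, f"empty face mask (frame {frame_index})")
    keep = face_mask.copy()
    for poly in exclusion_polygons or []:
        keep &= ~_hull_mask(face_mask.shape, poly)
    channels_ok = np.all((frame >= low) & (frame <= high), axis=-1)
    keep &= channels_ok
    if not keep.any():
        raise NoSkinPixelsError(frame_index)
    return keep


def holistic_trace(
    frames: FrameSequence,
    ann: FaceAnnotation,
    low: int = 40,
    high: int = 255,
) -> RGBTrace:
    """One (R, G, B) mean per frame over the skin mask of the whole face."""
    n = frames.n_frames
    hw = frames.frame_hw
    out = np.empty((n, 3))
    valid_frac = np.empty(n)
    for i in range(n):
        fmask = ann.mask_for(i, hw)
        smask = skin_mask(
            frames.frames[i], fmask, ann.exclusion_polygons, low, high, frame_index=i
        )
        pix = frames.frames[i][smask].astype(float)
        out[i] = pix.mean(axis=0)
        valid_frac[i] = smask.sum() / fmask.sum()
    return RGBTrace(
        t=frames.timestamps.copy(),
        data={"holistic": out},
        fs=frames.fs,
        frame_valid_fraction={"holistic": valid_frac},
    )


def patch_traces(
    frames: FrameSequence,
    ann: FaceAnnotation,
    patch_px: int = 40,
    low: int = 40,
    high: int = 255,
    max_gap_s: float = 0.5,
) -> RGBTrace:
    """One (R, G, B) series per 40×40 px patch over skin-masked pixels.

    A patch with no skin pixels in some frame is flagged invalid there
    (``frame_valid_fraction = 0``) and linearly interpolated over time when
    the gap is at most ``max_gap_s``; patches with longer gaps are dropped.
    """
    if not ann.patch_anchors:
        raise ValueError("annotation has no patch anchors")
    h, w = frames.frame_hw
    half = patch_px // 2
    boxes = []
    for cy, cx in ann.patch_anchors:
        r0, c0 = int(round(cy)) - half, int(round(cx)) - half
        r1, c1 = r0 + patch_px, c0 + patch_px
        if not (0 <= r0 and r1 <= h and 0 <= c0 and c1 <= w):
            raise ValueError(f"patch at ({cy}, {cx}) not fully inside frame")
        boxes.append((r0, c0, r1, c1))

    n = frames.n_frames
    data: dict[str, np.ndarray] = {}
    fracs: dict[str, np.ndarray] = {}
    for b, (r0, c0, r1, c1) in enumerate(boxes):
        pid = f"patch_{b:02d}"
        series = np.full((n, 3), np.nan)
        frac = np.zeros(n)
        for i in range(n):
            fmask = ann.mask_for(i, (h, w))
            try:
                smask = skin_mask(
                    frames.frames[i], fmask, ann.exclusion_polygons, low, high, i
                )
            except NoSkinPixelsError:
                continue
            box_mask = np.zeros((h, w), dtype=bool)
            box_mask[r0:r1, c0:c1] = True
            sel = smask & box_mask
            if sel.any():
                series[i] = frames.frames[i][sel].astype(float).mean(axis=0)
                frac[i] = sel.sum() / (patch_px * patch_px)
        series, keep = _fill_short_gaps(series, frames.fs, max_gap_s)
        if keep:
            data[pid] = series
            fracs[pid] = frac
    if not data:
        raise NoSkinPixelsError(0, "every patch invalid for the recording")
    return RGBTrace(
        t=frames.timestamps.copy(), data=data, fs=frames.fs, frame_valid_fraction=fracs
    )


def _fill_short_gaps(series: np.ndarray, fs: float, max_gap_s: float):
    """Linearly interpolate NaN runs of length <= max_gap_s; else drop patch."""
    bad = np.isnan(series[:, 0])
    if not bad.any():
        return series, True
    if bad.all():
        return series, False
    # boundary gaps or any gap longer than max_gap_s drop the patch
    idx = np.flatnonzero(bad)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    n = series.shape[0]
    for run in runs:
        if run[0] == 0 or run[-1] == n - 1 or run.size / fs > max_gap_s:
            return series, False
    good = ~bad
    xi = np.flatnonzero(good)
    for ch in range(3):
        series[bad, ch] = np.interp(np.flatnonzero(bad), xi, series[good, ch])
    return series, True
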