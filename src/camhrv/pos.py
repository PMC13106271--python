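"""Plane-orthogonal-to-the-skin (POS) pulse extraction and patch combination.

POS projects the temporally normalized RGB trace onto two fixed chrominance
axes, (0, 1, −1) and (−2, 1, 1), both orthogonal to the unit intensity
direction (their components sum to zero), then combines them with an
adaptive ratio α = σ(s1)/σ(s2).  Common-mode intensity variation (specular
reflection, global illumination flicker) is annihilated by construction;
per-channel static gains cancel in the window-mean normalization.

Patch signals are combined by a plain or MRC-weighted average, where the
maximum-ratio-combining weight of a patch is its spectral goodness: power
near the recording's center (pulse) frequency relative to total power in
the 0.5–5 Hz band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .signals import BVPSignal, RGBTrace, TooShortError

__all__ = ["POSParams", "pos", "mrc_goodness", "combine_patches"]

#: fixed projection rows over (R, G, B); both sum to zero
POS_PROJECTION = np.array([[0.0, 1.0, -1.0], [-2.0, 1.0, 1.0]])


@dataclass
class POSParams:
    """POS sliding-window settings (1.6 s window, hop of one frame)."""

    window_s: float = 1.6

    def window_frames(self, fs: float) -> int:
        w = int(round(self.window_s * fs))
        if w < 8:
            raise ValueError("POS window must span at least 8 samples")
        return w


def pos(
    rgb: RGBTrace,
    params: POSParams | None = None,
    patch_id: str | None = None,
) -> BVPSignal:
    """Extract the BVP from a single-patch RGB trace by sliding-window POS.

    Each window (hop = 1 frame) is normalized by its per-channel mean,
    projected onto the two chrominance axes, tuned (``h = s1 + α·s2`` with
    ``α = σ(s1)/σ(s2)``; α = 0 when σ(s2) = 0), mean-removed, and
    accumulated into the output by overlap-add.  Output has the input
    length and zero mean.
    """
    params = params or POSParams()
    x = rgb.single(patch_id)
    n = x.shape[0]
    w = params.window_frames(rgb.fs)
    if n < w:
        raise TooShortError(f"trace of {n} frames shorter than POS window ({w})")
    h = np.zeros(n)
    # sliding windows as a (n_windows, w, 3) view — hop is one frame
    windows = np.lib.stride_tricks.sliding_window_view(x, w, axis=0)  # (nw, 3, w)
    means = windows.mean(axis=2)  # (nw, 3)
    if np.any(means == 0):
        raise ValueError("degenerate channel: zero mean within a POS window")
    cn = windows / means[:, :, None]  # (nw, 3, w)
    s = np.einsum("pc,wct->wpt", POS_PROJECTION, cn)  # (nw, 2, w)
    s1, s2 = s[:, 0, :], s[:, 1, :]
    sd1 = s1.std(axis=1)
    sd2 = s2.std(axis=1)
    alpha = np.divide(sd1, sd2, out=np.zeros_like(sd1), where=sd2 > 0)
    hw = s1 + alpha[:, None] * s2
    hw = hw - hw.mean(axis=1, keepdims=True)
    for i in range(hw.shape[0]):
        h[i : i + w] += hw[i]
    h -= h.mean()
    return BVPSignal(t=rgb.t.copy(), value=h, fs=rgb.fs)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value whose cumulative weight reaches half the total."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def mrc_goodness(
    patch_bvps: dict[str, BVPSignal] | list[BVPSignal],
    fs: float | None = None,
    wide_band: tuple[float, float] = (0.5, 5.0),
    narrow_halfwidth: float = 0.1,
) -> np.ndarray:
    """Maximum-ratio-combining weights, one per patch, summing to one.

    The recording-level center frequency f_c is the median of the per-patch
    periodogram argmax within ``wide_band``, weighted by each patch's peak
    power (a plain median is degenerate for an even patch count, where it
    falls between the peaks of a strong and a junk patch); each patch's
    goodness is its power in f_c ± ``narrow_halfwidth`` divided by its
    total power in the wide band.  If every patch has zero power, uniform
    weights are returned (the degenerate case carries no information to
    weight by).
    """
    signals = list(patch_bvps.values()) if isinstance(patch_bvps, dict) else list(
        patch_bvps
    )
    if not signals:
        raise ValueError("need at least one patch")
    fs = fs or signals[0].fs
    freqs_list, psd_list, peaks, peak_powers = [], [], [], []
    for sig in signals:
        f, p = periodogram(sig.value, fs=fs, window="hann")
        band = (f >= wide_band[0]) & (f <= wide_band[1])
        freqs_list.append(f)
        psd_list.append(p)
        if p[band].max() > 0:
            peaks.append(f[band][np.argmax(p[band])])
            peak_powers.append(p[band].max())
    if not peaks:
        return np.full(len(signals), 1.0 / len(signals))
    f_c = _weighted_median(np.asarray(peaks), np.asarray(peak_powers))
    goodness = np.zeros(len(signals))
    for i, (f, p) in enumerate(zip(freqs_list, psd_list)):
        band = (f >= wide_band[0]) & (f <= wide_band[1])
        narrow = band & (np.abs(f - f_c) <= narrow_halfwidth)
        total = p[band].sum()
        goodness[i] = p[narrow].sum() / total if total > 0 else 0.0
    if goodness.sum() == 0:
        return np.full(len(signals), 1.0 / len(signals))
    return goodness / goodness.sum()


def combine_patches(
    patch_bvps: dict[str, BVPSignal] | list[BVPSignal],
    weights: np.ndarray | None = None,
) -> BVPSignal:
    """Pointwise (weighted) average of equal-length patch BVP signals."""
    signals = list(patch_bvps.values()) if isinstance(patch_bvps, dict) else list(
        patch_bvps
    )
    if not signals:
        raise ValueError("need at least one patch signal")
    n = signals[0].value.size
    for sig in signals:
        if sig.value.size != n:
            raise ValueError("patch signals have mismatched lengths")
    if weights is None:
        weights = np.full(len(signals), 1.0 / len(signals))
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(signals):
        raise ValueError("one weight per patch required")
    stack = np.stack([sig.value for sig in signals])
    value = weights @ stack
    return BVPSignal(t=signals[0].t.copy(), value=value, fs=signals[0].fs)
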