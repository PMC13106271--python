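"""Simple agreement diagnostics (matplotlib is imported lazily)."""

from __future__ import annotations

import numpy as np

from .evaluation import BlandAltman, bland_altman

__all__ = ["bland_altman_plot", "hr_overlay_plot"]


def bland_altman_plot(x_rppg, x_ecg, ax=None, label: str = ""):
    """Scatter of paired differences against means with bias and 95% LoA."""
    import matplotlib.pyplot as plt

    x_rppg = np.asarray(x_rppg, dtype=float)
    x_ecg = np.asarray(x_ecg, dtype=float)
    ba: BlandAltman = bland_altman(x_rppg, x_ecg)
    if ax is None:
        _, ax = plt.subplots()
    mean = (x_rppg + x_ecg) / 2.0
    ax.scatter(mean, x_rppg - x_ecg, s=12, alpha=0.6)
    ax.axhline(ba.bias, color="k", lw=1)
    for y in (ba.loa_lo, ba.loa_hi):
        ax.axhline(y, color="k", lw=1, ls=":")
    ax.set_xlabel(f"mean of methods {label}".strip())
    ax.set_ylabel(f"rPPG − ECG {label}".strip())
    return ax


def hr_overlay_plot(pair, ax=None):
    """Aligned instantaneous-HR trajectories of one recording pair."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(pair.ecg.t, pair.ecg.hr_bpm, label="ECG", lw=1)
    ax.plot(pair.rppg.t, pair.rppg.hr_bpm, label="rPPG", lw=1)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("instantaneous HR (BPM)")
    ax.legend()
    return ax
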