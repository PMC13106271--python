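"""Dispatch of the four benchmark pipeline configurations.

========  ========  =============  ==================  ==============
pipeline  ROI       combination    post-processing     pulse estimate
========  ========  =============  ==================  ==============
1         holistic  —              MA + fixed bandpass  peak-based
2         patches   plain average  MA + fixed bandpass  peak-based
3         holistic  —              adaptive bandpass    DESA-1
4         patches   MRC-weighted   adaptive bandpass    DESA-1
========  ========  =============  ==================  ==============

All four share POS extraction.  Pipelines 1–2 return the inter-beat series
of the detected systolic peaks; pipelines 3–4 reconstruct pseudo-beats
from the instantaneous-HR trajectory.
"""

from __future__ import annotations

import logging
from importlib.metadata import PackageNotFoundError, version

from .config import SessionConfig
from .ecg import ibi_to_inst_hr
from .evaluation import pseudo_ibis
from .freqdomain import DemodParams, hrvcam
from .pos import POSParams, combine_patches, mrc_goodness, pos
from .signals import BVPSignal, IBISeries, InstHRSeries, RGBTrace, RPeakSeries
from .timedomain import PeakDetectorParams, time_domain_chain

__all__ = ["run_pipeline", "extract_bvp"]

log = logging.getLogger("camhrv")


def _package_version() -> str:
    try:
        return version("camhrv")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def extract_bvp(config: SessionConfig, rgb: RGBTrace) -> BVPSignal:
    """POS extraction with the pipeline-appropriate patch combination."""
    params = POSParams(window_s=config.pos_window_s)
    if config.roi_mode == "holistic" or len(rgb.patch_ids) == 1:
        pid = rgb.patch_ids[0]
        return pos(rgb, params, patch_id=pid)
    patch_bvps = {pid: pos(rgb, params, patch_id=pid) for pid in rgb.patch_ids}
    if config.pipeline_id == 4:
        weights = mrc_goodness(
            patch_bvps,
            fs=rgb.fs,
            wide_band=config.mrc_wide_band,
            narrow_halfwidth=config.mrc_narrow_halfwidth,
        )
        return combine_patches(patch_bvps, weights)
    return combine_patches(patch_bvps)


def run_pipeline(
    config: SessionConfig, rgb: RGBTrace
) -> tuple[InstHRSeries, IBISeries | None]:
    """Run the configured pipeline: RGB trace -> (30 Hz HR series, IBIs).

    Deterministic for fixed input and config.  Raises
    :class:`~camhrv.signals.TooShortError` when the recording is shorter
    than one analysis window.
    """
    log.info(
        "run_pipeline id=%d config_hash=%s seed=%d version=%s",
        config.pipeline_id, config.config_hash(), config.rng_seed,
        _package_version(),
    )
    bvp = extract_bvp(config, rgb)
    if config.hr_domain == "time":
        peak_t, ibis = time_domain_chain(
            bvp,
            ma_win_frames=config.ma_win_frames,
            bp_low=config.bp_low_hz,
            bp_high=config.bp_high_hz,
            bp_order=config.bp_order,
            upsample_fs=config.upsample_fs,
            peak_params=PeakDetectorParams(
                w_peak_ms=config.peak_w_peak_ms,
                w_beat_ms=config.peak_w_beat_ms,
                offset_beta=config.peak_offset_beta,
                min_peak_separation_s=config.peak_min_separation_s,
            ),
        )
        if ibis is None:
            raise ValueError("too few peaks detected to derive an HR series")
        rpeaks = RPeakSeries(
            times=peak_t,
            source=["detected"] * peak_t.size,
        )
        inst = ibi_to_inst_hr(
            rpeaks, ecg_fs=config.upsample_fs, out_fs=config.camera_fs
        )
        return inst, ibis
    params = DemodParams(
        window_s=config.demod_window_s,
        overlap_frac=config.demod_overlap_frac,
        search_band=config.demod_search_band,
        narrow_halfwidth=config.demod_narrow_halfwidth,
        b_min=config.demod_b_min_hz,
        b_max=config.demod_b_max_hz,
        snr_lo=config.demod_snr_lo_db,
        snr_hi=config.demod_snr_hi_db,
        bp_order=config.demod_bp_order,
    )
    inst, _ = hrvcam(bvp, params)
    ibis = pseudo_ibis(inst)
    return inst, ibis
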