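"""High-level analysis pipeline: video stack -> summary metrics.

Thin composition of sigproc / metrics / conduction used by the command-line
interface and by end-to-end tests: build a mask, condition the mask-mean
trace, extract beats and global metrics, and optionally per-pixel maps,
conduction velocity and a pacing-capture report.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np

from . import conduction, metrics, sigproc
from .synthdata import PacingProtocol

__all__ = ["global_trace", "analyze_video"]


def global_trace(stack: sigproc.VideoStack, mask: sigproc.AnalysisMask) -> sigproc.Trace:
    """Mask-mean raw trace, conditioned with the stack's polarity setting."""
    rows, cols = np.nonzero(mask.valid)
    raw = stack.frames[:, rows, cols].mean(axis=1)
    return sigproc.condition_trace(
        raw, stack.frame_rate_hz, polarity=stack.polarity, source="mask-mean"
    )


def analyze_video(
    stack: sigproc.VideoStack,
    protocol: PacingProtocol | None = None,
    intensity_quantile: float = 0.5,
    snr_floor: float = 3.0,
    band_hz: tuple[float, float] = (0.2, 8.0),
    compute_maps: bool = False,
    compute_cv: bool = False,
    cv_window_s: tuple[float, float] | None = None,
    bin_factor: int = 2,
) -> dict:
    """Run the standard analysis chain and return a JSON-ready summary.

    Global metrics (dominant frequency, IBI, CaTD_p, upstroke) come from
    the mask-mean trace; ``compute_maps`` adds per-pixel maps (returned
    under ``maps`` as a :class:`~cardiomap.metrics.MetricMaps` plus their
    summaries), ``compute_cv`` a plane-fit conduction velocity (requires
    pixel size), and a ``protocol`` a stimulus-capture report.
    """
    mask = sigproc.build_mask(stack, intensity_quantile=intensity_quantile, snr_floor=snr_floor)
    trace = global_trace(stack, mask)
    beats = metrics.detect_beats(trace)
    out: dict = {
        "n_frames": stack.n_frames,
        "frame_rate_hz": stack.frame_rate_hz,
        "n_valid_pixels": mask.n_valid,
        "n_beats": len(beats),
        "df_hz": metrics.dominant_frequency(trace, band_hz=band_hz),
    }
    ibi = metrics.ibi_series(beats)
    out["ibi_s"] = None if ibi is None else {"mean": ibi[1], "sd": ibi[2]}
    for p in metrics.CATD_LEVELS:
        vals = [b.catd_ms[p] for b in beats if p in b.catd_ms]
        out[f"catd{p}_ms"] = float(np.median(vals)) if vals else None
    ups = [b.upstroke_s for b in beats if b.upstroke_s is not None]
    out["upstroke_s"] = float(np.median(ups)) if ups else None

    if compute_maps:
        maps = metrics.metric_maps(stack, bin_factor=bin_factor, snr_floor=snr_floor)
        out["maps"] = maps
        out["map_summary"] = maps.summary

    if compute_cv:
        if stack.pixel_size_mm is None:
            raise ValueError("conduction velocity requires pixel_size_mm")
        binned = sigproc.bin_stack(stack, bin_factor)
        dff = sigproc.condition_pixels(
            binned.frames, binned.frame_rate_hz, polarity=binned.polarity
        )
        if cv_window_s is None:
            if len(beats) < 2:
                raise ValueError("cannot infer a beat window for CV; pass cv_window_s")
            # bracket the second beat: the first may be clipped by onset
            mid = beats[1].activation_time_s
            gap = beats[1].activation_time_s - beats[0].activation_time_s
            cv_window_s = (mid - 0.2 * gap, mid + 0.8 * gap)
        h, w = binned.frames.shape[1:]
        act = conduction.activation_map(
            dff, binned.frame_rate_hz, np.ones((h, w), dtype=bool), cv_window_s
        )
        cv = conduction.conduction_velocity(act, binned.pixel_size_mm)
        out["cv"] = {
            "mean_mm_s": cv.mean_mm_s,
            "sd_mm_s": cv.sd_mm_s,
            "n_accepted": cv.n_accepted,
        }

    if protocol is not None:
        report = conduction.capture_report(beats, protocol)
        out["capture"] = {
            "segments": [asdict(s) for s in report.segments],
            "regularity_index": report.regularity_index,
            "any_refractory": report.any_refractory,
        }
    return out
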