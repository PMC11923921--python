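"""Per-trace and per-pixel calcium-handling metrics.

Beat detection, activation times (maximum-derivative convention with
sub-frame quadratic refinement), 10->90% upstroke duration, calcium
transient duration at 20/50/70/90% repolarization (CaTD_p, measured from
the activation time), inter-beat intervals, dominant frequency, and their
per-pixel maps over an analysis mask.

Undefined metrics propagate as flagged-missing (None / NaN), never as
zeros, so that map summaries are not corrupted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .sigproc import AnalysisMask, Trace, VideoStack, bin_stack, build_mask, condition_pixels

__all__ = [
    "Beat",
    "MetricMaps",
    "detect_beats",
    "upstroke_duration",
    "catd",
    "ibi_series",
    "dominant_frequency",
    "metric_maps",
]

CATD_LEVELS = (20, 50, 70, 90)


@dataclass
class Beat:
    """One detected transient.

    activation_time_s is the sub-frame time of maximum first derivative on
    the rising limb; catd_ms maps p -> duration where defined (a level the
    trace never recovers to before the next activation stays absent).
    """

    activation_time_s: float
    peak_time_s: float
    amplitude: float
    diastolic_level: float
    peak_index: int
    upstroke_s: float | None = None
    catd_ms: dict[int, float] = field(default_factory=dict)


def _quadratic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample offset of an extremum at index i from its neighbours."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def _cross_down(t: np.ndarray, y: np.ndarray, level: float, start: int, stop: int) -> float | None:
    """First interpolated downward crossing of ``level`` in [start, stop)."""
    for i in range(start, min(stop, len(y) - 1)):
        if y[i] >= level > y[i + 1]:
            frac = (y[i] - level) / (y[i] - y[i + 1])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def _cross_up_before(t: np.ndarray, y: np.ndarray, level: float, peak: int, floor: int) -> float | None:
    """Last interpolated upward crossing of ``level`` walking back from peak."""
    for i in range(peak - 1, max(floor - 1, -1), -1):
        if y[i] <= level < y[i + 1]:
            frac = (level - y[i]) / (y[i + 1] - y[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def detect_beats(
    trace: Trace,
    min_prominence_mads: float = 5.0,
    min_interval_s: float = 0.25,
) -> list[Beat]:
    """Detect beats on a conditioned trace.

    Peaks must rise ``min_prominence_mads`` robust SDs (MAD-based) above
    their surroundings and be spaced >= ``min_interval_s``.  Per beat the
    diastolic level is the median of the pre-activation window, the
    activation time the quadratic-refined maximum of the first derivative
    within the rise, and upstroke/CaTD are filled in where defined.
    """
    t = trace.time_s
    y = trace.values
    fs = trace.frame_rate_hz
    span = float(np.ptp(y))
    if span == 0:
        return []
    # noise floor from the first difference (transients are sparse and slow,
    # so the median absolute step is noise-dominated), plus a floor scaled to
    # the robust signal excursion so slow noise-free traces are not over-split
    noise_sd = 1.4826 * np.median(np.abs(np.diff(y))) / np.sqrt(2.0)
    excursion = float(np.percentile(y, 99) - np.median(y))
    # a true beat's prominence is never below its own excursion, so a 0.4
    # fraction rejects smoothed-noise peaks without touching real transients
    prominence = max(min_prominence_mads * noise_sd, 0.4 * excursion, 1e-3 * span)
    distance = max(1, int(round(min_interval_s * fs)))
    peaks, _ = find_peaks(y, prominence=prominence, distance=distance)
    if peaks.size == 0:
        return []

    dy = np.gradient(y)
    beats: list[Beat] = []
    for k, pk in enumerate(peaks):
        wstart = peaks[k - 1] if k > 0 else 0
        if pk - wstart < 2:
            continue
        seg = dy[wstart:pk + 1]
        rel = int(np.argmax(seg))
        act_idx = wstart + rel
        delta = _quadratic_refine(dy, act_idx)
        act_time = t[act_idx] + delta / fs
        # walk back from the max-derivative point to the upstroke foot, then
        # take a short pre-activation window: the per-beat diastole must sit
        # just before the rise (at fast rates the transient is still decaying
        # there, and a long window would reach into the previous decay limb)
        foot = act_idx
        slope_floor = 0.05 * dy[act_idx]
        while foot > wstart and dy[foot - 1] > slope_floor:
            foot -= 1
        pre_hi = max(wstart, foot - 1)
        pre_lo = max(wstart, pre_hi - max(3, int(0.12 * fs)))
        pre = y[pre_lo:pre_hi + 1]
        diastolic = float(np.median(pre)) if pre.size else float(y[wstart])
        # sub-frame peak value: the sampled maximum underestimates the true
        # peak by up to one frame of decay; a parabola through the peak and
        # its neighbours recovers most of it
        peak_val = float(y[pk])
        if 0 < pk < len(y) - 1:
            y0, y1, y2 = float(y[pk - 1]), float(y[pk]), float(y[pk + 1])
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:
                d = 0.5 * (y0 - y2) / denom
                if abs(d) <= 0.5:
                    peak_val = y1 - 0.25 * (y0 - y2) * d
        amplitude = peak_val - diastolic
        if amplitude <= 0:
            continue
        beats.append(
            Beat(
                activation_time_s=float(act_time),
                peak_time_s=float(t[pk]),
                amplitude=amplitude,
                diastolic_level=diastolic,
                peak_index=int(pk),
            )
        )

    for k, beat in enumerate(beats):
        beat.upstroke_s = upstroke_duration(beat, trace)
        next_act = beats[k + 1].activation_time_s if k + 1 < len(beats) else None
        for p in CATD_LEVELS:
            v = catd(beat, trace, p, next_activation_s=next_act)
            if v is not None:
                beat.catd_ms[p] = v
    return beats


def upstroke_duration(beat: Beat, trace: Trace) -> float | None:
    """10->90% rise time of the depolarization limb, linearly interpolated.

    None when the rise cannot bracket both level crossings (e.g. a
    single-frame rise corrupted by noise).
    """
    t, y = trace.time_s, trace.values
    pk = beat.peak_index
    floor = max(0, pk - int(2.0 * trace.frame_rate_hz))
    l10 = beat.diastolic_level + 0.1 * beat.amplitude
    l90 = beat.diastolic_level + 0.9 * beat.amplitude
    t90 = _cross_up_before(t, y, l90, pk, floor)
    if t90 is None:
        return None
    i90 = int(np.searchsorted(t, t90))
    t10 = _cross_up_before(t, y, l10, min(i90 + 1, pk), floor)
    if t10 is None or t90 <= t10:
        return None
    return t90 - t10


def catd(
    beat: Beat,
    trace: Trace,
    p: float,
    next_activation_s: float | None = None,
) -> float | None:
    """Calcium transient duration at p% repolarization, milliseconds.

    Time from the activation time to the first interpolated downward
    crossing of diastolic + (1 - p/100) * amplitude after the peak.  None
    (flagged undefined) when the next activation encroaches first or the
    trace ends unrecovered.
    """
    if not 0 < p < 100:
        raise ValueError(f"p must be in (0, 100), got {p}")
    t, y = trace.time_s, trace.values
    level = beat.diastolic_level + (1.0 - p / 100.0) * beat.amplitude
    stop = len(y)
    if next_activation_s is not None:
        stop = int(np.searchsorted(t, next_activation_s))
    tc = _cross_down(t, y, level, beat.peak_index, stop)
    if tc is None:
        return None
    if next_activation_s is not None and tc >= next_activation_s:
        return None
    return (tc - beat.activation_time_s) * 1000.0


def ibi_series(beats: list[Beat]) -> tuple[np.ndarray, float, float] | None:
    """Successive activation-time differences; (intervals, mean, population SD).

    None when fewer than 2 beats exist (undefined, not zero).
    """
    if len(beats) < 2:
        return None
    acts = np.array([b.activation_time_s for b in beats])
    intervals = np.diff(acts)
    return intervals, float(intervals.mean()), float(intervals.std())


def dominant_frequency(
    trace: Trace | tuple[np.ndarray, float],
    band_hz: tuple[float, float] = (0.2, 8.0),
    resolution_hz: float = 0.02,
) -> float:
    """Frequency of the periodogram maximum within ``band_hz``.

    The mean-removed trace is zero-padded so the FFT bin spacing is at most
    ``resolution_hz``; ties break toward the lower frequency.  Requires a
    duration of at least 2 / band_low.
    """
    if isinstance(trace, Trace):
        values, fs = trace.values, trace.frame_rate_hz
    else:
        values, fs = trace
        values = np.asarray(values, dtype=float)
    lo, hi = band_hz
    if lo <= 0 or hi <= lo:
        raise ValueError("band_hz must satisfy 0 < low < high")
    duration = values.size / fs
    if duration < 2.0 / lo:
        raise ValueError(
            f"trace of {duration:.2f} s too short for band low {lo} Hz (need >= {2.0 / lo:.2f} s)"
        )
    nfft = 1
    while fs / nfft > resolution_hz:
        nfft *= 2
    nfft = max(nfft, values.size)
    x = values - values.mean()
    spec = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        raise ValueError("frequency band contains no spectral bins")
    band_spec = spec[in_band]
    # argmax returns the first (lowest-frequency) maximum on ties
    return float(freqs[in_band][int(np.argmax(band_spec))])


# ---------------------------------------------------------------------------
# Maps


@dataclass
class MetricMaps:
    """Per-pixel metric maps plus mean +/- SD summaries over defined pixels."""

    df_hz: np.ndarray
    ibi_s: np.ndarray
    catd_ms: dict[int, np.ndarray]
    upstroke_s: np.ndarray
    mask: AnalysisMask
    summary: dict[str, dict[str, float]]

    def as_dict(self) -> dict[str, np.ndarray]:
        out = {"df_hz": self.df_hz, "ibi_s": self.ibi_s, "upstroke_s": self.upstroke_s}
        for p, m in self.catd_ms.items():
            out[f"catd{p}_ms"] = m
        return out


def _summarize(name: str, arr: np.ndarray) -> dict[str, float]:
    vals = arr[np.isfinite(arr)]
    return {
        "mean": float(vals.mean()) if vals.size else float("nan"),
        "sd": float(vals.std()) if vals.size else float("nan"),
        "n_defined": int(vals.size),
        "n_undefined": int(arr.size - vals.size),
    }


def metric_maps(
    stack: VideoStack,
    mask: AnalysisMask | None = None,
    segment_s: tuple[float, float] | None = None,
    bin_factor: int = 2,
    intensity_quantile: float = 0.5,
    snr_floor: float = 3.0,
    min_prominence_mads: float = 5.0,
    min_interval_s: float = 0.25,
    detrend_window_s: float = 4.0,
) -> MetricMaps:
    """Compute all per-pixel metric maps over the valid mask.

    The stack is spatially binned first; a mask is built from the binned
    stack when none is supplied (a supplied mask must match the binned
    shape).  ``segment_s`` restricts analysis to a time window, e.g. one
    pacing-protocol segment.  Statistics are over valid pixels with a
    defined value; undefined pixels are counted, not zero-filled.
    """
    binned = bin_stack(stack, bin_factor)
    if segment_s is not None:
        i0 = int(round(segment_s[0] * binned.frame_rate_hz))
        i1 = int(round(segment_s[1] * binned.frame_rate_hz))
        binned = VideoStack(
            frames=binned.frames[i0:i1],
            frame_rate_hz=binned.frame_rate_hz,
            pixel_size_mm=binned.pixel_size_mm,
            polarity=binned.polarity,
        )
    if mask is None:
        mask = build_mask(binned, intensity_quantile=intensity_quantile, snr_floor=snr_floor)
    if mask.valid.shape != binned.frames.shape[1:]:
        raise ValueError("mask shape does not match the (binned) stack")
    if not mask.valid.any():
        raise ValueError("empty analysis mask")

    fs = binned.frame_rate_hz
    dff = condition_pixels(
        binned.frames, fs, mask.valid, polarity=binned.polarity, detrend_window_s=detrend_window_s
    )
    h, w = mask.valid.shape
    shape = (h, w)
    df_map = np.full(shape, np.nan)
    ibi_map = np.full(shape, np.nan)
    ups_map = np.full(shape, np.nan)
    catd_maps = {p: np.full(shape, np.nan) for p in CATD_LEVELS}

    time_s = np.arange(binned.n_frames) / fs
    rows, cols = np.nonzero(mask.valid)
    # dominant frequency, vectorized over pixels
    flat = dff[:, rows, cols]
    x = flat - flat.mean(axis=0, keepdims=True)
    nfft = 1
    while fs / nfft > 0.02:
        nfft *= 2
    nfft = max(nfft, flat.shape[0])
    spec = np.abs(np.fft.rfft(x, n=nfft, axis=0)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    in_band = (freqs >= 0.2) & (freqs <= 8.0)
    band = spec[in_band]
    df_px = freqs[in_band][np.argmax(band, axis=0)]
    df_px[band.max(axis=0) <= 0] = np.nan  # spectrally silent pixel
    df_map[rows, cols] = df_px

    for r, c, vals in zip(rows, cols, flat.T):
        tr = Trace(time_s=time_s, values=vals, source=f"px({r},{c})")
        beats = detect_beats(tr, min_prominence_mads=min_prominence_mads, min_interval_s=min_interval_s)
        ibi = ibi_series(beats)
        if ibi is not None:
            ibi_map[r, c] = ibi[1]
        ups = [b.upstroke_s for b in beats if b.upstroke_s is not None]
        if ups:
            ups_map[r, c] = float(np.median(ups))
        for p in CATD_LEVELS:
            vv = [b.catd_ms[p] for b in beats if p in b.catd_ms]
            if vv:
                catd_maps[p][r, c] = float(np.median(vv))

    summary = {"df_hz": _summarize("df_hz", df_map[mask.valid]), "ibi_s": _summarize("ibi_s", ibi_map[mask.valid]), "upstroke_s": _summarize("upstroke_s", ups_map[mask.valid])}
    for p in CATD_LEVELS:
        summary[f"catd{p}_ms"] = _summarize(f"catd{p}_ms", catd_maps[p][mask.valid])
    return MetricMaps(
        df_hz=df_map, ibi_s=ibi_map, catd_ms=catd_maps, upstroke_s=ups_map, mask=mask, summary=summary
    )
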