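"""Activation maps, conduction velocity and pacing-capture accounting.

Conduction velocity uses the gradient method: a plane t(x, y) = ax + by + c
is fitted to the activation times in a local neighborhood of each pixel and
the local wave speed is 1/|grad t|.  Pacing capture compares detected beats
against delivered stimuli per protocol segment; persistent failure to
follow fast pacing flags a refractory (electrophysiologically immature)
preparation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import median_filter

from .metrics import Beat, ibi_series
from .sigproc import AnalysisMask
from .synthdata import PacingProtocol

__all__ = [
    "ActivationMap",
    "CVResult",
    "CaptureReport",
    "SegmentCapture",
    "activation_map",
    "conduction_velocity",
    "capture_report",
]


@dataclass
class ActivationMap:
    """Per-pixel activation times (ms) of a single beat, zero-referenced."""

    times_ms: np.ndarray
    valid: np.ndarray
    beat_index: int = 0

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.times_ms.shape != self.valid.shape:
            raise ValueError("times and validity mask must share shape")


@dataclass
class CVResult:
    speed_mm_s: np.ndarray
    r2: np.ndarray
    mean_mm_s: float
    sd_mm_s: float
    n_accepted: int


@dataclass
class SegmentCapture:
    segment: int
    mode: str
    freq_hz: float
    stimuli: int
    beats: int
    capture_ratio: float
    refractory: bool


@dataclass
class CaptureReport:
    segments: list[SegmentCapture]
    regularity_index: float | None  # SD(IBI)/mean(IBI) over basal segments

    @property
    def any_refractory(self) -> bool:
        return any(s.refractory for s in self.segments)


def activation_map(
    dff: np.ndarray,
    frame_rate_hz: float,
    mask: AnalysisMask | np.ndarray,
    window_s: tuple[float, float],
    min_amplitude_mads: float = 5.0,
    beat_index: int = 0,
) -> ActivationMap:
    """Per-pixel maximum-derivative times for one beat window.

    ``dff`` is a conditioned (T, H, W) array (NaN outside the mask).  Pixels
    whose in-window excursion is below ``min_amplitude_mads`` robust noise
    SDs carry no detectable beat and are invalidated; the map is rejected
    when fewer than half the valid pixels have one.
    """
    valid_in = mask.valid if isinstance(mask, AnalysisMask) else np.asarray(mask, dtype=bool)
    fs = frame_rate_hz
    i0 = max(0, int(round(window_s[0] * fs)))
    i1 = min(dff.shape[0], int(round(window_s[1] * fs)))
    if i1 - i0 < 3:
        raise ValueError("beat window spans fewer than 3 frames")
    seg = dff[i0:i1]

    rows, cols = np.nonzero(valid_in)
    traces = seg[:, rows, cols]
    # detectability: excursion above robust per-pixel noise, estimated from
    # the first difference (the transient is sparse and slow in time)
    med = np.median(traces, axis=0)
    noise = 1.4826 * np.median(np.abs(np.diff(traces, axis=0)), axis=0) / np.sqrt(2.0)
    excursion = traces.max(axis=0) - med
    has_beat = excursion >= np.maximum(min_amplitude_mads * noise, 1e-9)
    frac = has_beat.mean() if has_beat.size else 0.0
    if frac < 0.5:
        raise ValueError(
            f"beat detected in only {100 * frac:.0f}% of valid pixels; activation map rejected"
        )

    d = np.gradient(traces, axis=0)
    idx = np.argmax(d, axis=0)
    # quadratic sub-frame refinement of the derivative peak
    n = d.shape[0]
    i_lo = np.clip(idx - 1, 0, n - 1)
    i_hi = np.clip(idx + 1, 0, n - 1)
    cols_i = np.arange(d.shape[1])
    y0, y1, y2 = d[i_lo, cols_i], d[idx, cols_i], d[i_hi, cols_i]
    denom = y0 - 2.0 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom != 0, 0.5 * (y0 - y2) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    t_ms = (idx + delta) / fs * 1000.0

    times = np.full(valid_in.shape, np.nan)
    ok_rows, ok_cols = rows[has_beat], cols[has_beat]
    times[ok_rows, ok_cols] = t_ms[has_beat]
    valid_out = np.zeros_like(valid_in)
    valid_out[ok_rows, ok_cols] = True
    times[valid_out] -= np.nanmin(times[valid_out])
    return ActivationMap(times_ms=times, valid=valid_out, beat_index=beat_index)


def conduction_velocity(
    act_map: ActivationMap,
    pixel_size_mm: float,
    neighborhood_radius_px: int = 3,
    r2_floor: float = 0.9,
    min_accepted: int = 10,
    smooth_median_px: int = 3,
) -> CVResult:
    """Local plane-fit (gradient-method) conduction velocity, mm/s.

    Activation times are first denoised with a ``smooth_median_px`` median
    filter (order-statistic, so a locally planar wavefront is unchanged
    away from map edges).  For each pixel whose full disc neighborhood is
    valid, t(x, y) is fitted by least squares; speed = 1 / |(a, b)| with
    the gradient in ms/mm.  Pixels with fit R^2 below ``r2_floor`` (or a
    vanishing gradient, as in a synchronous preparation) are excluded.
    """
    if pixel_size_mm is None or pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be positive")
    r = int(neighborhood_radius_px)
    times = act_map.times_ms
    if smooth_median_px > 1:
        times = median_filter(times, size=smooth_median_px)
    h, w = times.shape
    size = 2 * r + 1
    if h < size or w < size:
        raise ValueError("activation map smaller than the fit neighborhood")

    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    disc = (dy**2 + dx**2) <= r * r + 1e-9
    npts = int(disc.sum())
    # design matrix in mm; constant across pixels -> one pseudo-inverse
    a_mat = np.column_stack(
        [dx[disc] * pixel_size_mm, dy[disc] * pixel_size_mm, np.ones(npts)]
    )
    pinv = np.linalg.pinv(a_mat)

    win_t = sliding_window_view(times, (size, size))  # (h-2r, w-2r, size, size)
    win_v = sliding_window_view(act_map.valid, (size, size))
    flat_t = win_t[..., disc]  # (..., npts)
    all_valid = win_v[..., disc].all(axis=-1)

    coef = flat_t @ pinv.T  # (..., 3)
    fitted = coef @ a_mat.T
    resid = flat_t - fitted
    ss_res = np.nansum(resid**2, axis=-1)
    ss_tot = np.nansum((flat_t - np.nanmean(flat_t, axis=-1, keepdims=True)) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        grad = np.hypot(coef[..., 0], coef[..., 1])  # ms / mm
        speed = np.where(grad > 0, 1000.0 / grad, np.inf)

    speed_map = np.full((h, w), np.nan)
    r2_map = np.full((h, w), np.nan)
    inner = (slice(r, h - r), slice(r, w - r))
    speed_map[inner] = np.where(all_valid, speed, np.nan)
    r2_map[inner] = np.where(all_valid, r2, np.nan)

    accepted = np.isfinite(speed_map) & (r2_map >= r2_floor)
    n_acc = int(accepted.sum())
    if n_acc < min_accepted:
        raise ValueError(
            f"only {n_acc} pixels accepted (R^2 >= {r2_floor}); conduction velocity undefined"
        )
    vals = speed_map[accepted]
    return CVResult(
        speed_mm_s=np.where(accepted, speed_map, np.nan),
        r2=r2_map,
        mean_mm_s=float(vals.mean()),
        sd_mm_s=float(vals.std()),
        n_accepted=n_acc,
    )


def capture_report(
    beats: list[Beat],
    protocol: PacingProtocol,
    refractory_flag_threshold: float = 0.8,
    latency_s: float = 0.0,
) -> CaptureReport:
    """Capture accounting of detected beats against the pacing protocol.

    Per paced segment: capture ratio = detected beats / delivered stimuli,
    with the refractory flag raised when the ratio falls below the
    threshold.  The regularity index SD(IBI)/mean(IBI) is computed over the
    basal segments (None with < 3 basal beats).
    """
    acts = np.array([b.activation_time_s for b in beats])
    segments = []
    basal_beats: list[Beat] = []
    for i, seg in enumerate(protocol.segments):
        n_stim = int(np.ceil(seg.duration_s * seg.freq_hz - 1e-9))
        in_seg = (acts >= seg.start_s + latency_s) & (acts < seg.end_s + latency_s)
        n_beats = int(in_seg.sum())
        ratio = n_beats / n_stim if n_stim else float("nan")
        segments.append(
            SegmentCapture(
                segment=i,
                mode=seg.mode,
                freq_hz=seg.freq_hz,
                stimuli=n_stim,
                beats=n_beats,
                capture_ratio=ratio,
                refractory=(seg.mode == "paced" and ratio < refractory_flag_threshold),
            )
        )
        if seg.mode == "basal":
            basal_beats.extend(b for b, ok in zip(beats, in_seg) if ok)

    regularity = None
    ibi = ibi_series(basal_beats)
    if ibi is not None and ibi[1] > 0:
        regularity = float(ibi[2] / ibi[1])
    return CaptureReport(segments=segments, regularity_index=regularity)
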