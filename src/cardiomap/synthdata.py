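"""Synthetic inputs with serialized ground truth.

Every downstream stage of the toolkit is testable without laboratory data:
this module renders calcium-transient movies of beating spheroids
(spatially synchronous) and monolayers (travelling wavefronts at a set
conduction velocity) under a basal + paced stimulation protocol, binary
aggregate images with known Feret diameters, and perfusion-culture
metabolite trajectories integrated from known specific rates.

All randomness flows from a single integer seed recorded in the ground
truth; with noise and bleaching off, regeneration with the same seed is
bit-identical.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.ndimage import gaussian_filter

from .bioprocess import PerfusionSeries
from .sigproc import VideoStack, write_stack

__all__ = [
    "WaveformParams",
    "PacingSegment",
    "PacingProtocol",
    "SceneConfig",
    "GroundTruth",
    "ShapeSpec",
    "waveform_kernel",
    "analytic_catd",
    "analytic_catd_periodic",
    "generate_video",
    "recovery_case",
    "save_video",
    "generate_aggregate_image",
    "simulate_perfusion",
]

# Fraction of the full cubic-smoothstep rise spanned by the 10->90% interval.
# smoothstep s(x) = 3x^2 - 2x^3; s^-1(y) = 1/2 - sin(asin(1-2y)/3), so
# x(0.9) - x(0.1) = 2*sin(asin(0.8)/3).
_SMOOTHSTEP_1090 = 2.0 * math.sin(math.asin(0.8) / 3.0)

CATD_LEVELS = (20, 50, 70, 90)


# ---------------------------------------------------------------------------
# Configuration types


@dataclass(frozen=True)
class WaveformParams:
    """Shape of a single calcium transient.

    upstroke_duration_s is the 10->90% rise time (the quantity reported by
    the metrics module); the full cubic-smoothstep rise lasts
    upstroke_duration_s / 0.6084.  After the peak the transient recovers as
    exp(-dt/decay_tau_s).  refractory_period_s is the minimum interval after
    an activation for the next stimulus to capture.
    """

    upstroke_duration_s: float = 0.05
    decay_tau_s: float = 0.35
    amplitude: float = 1000.0
    diastolic_level: float = 2000.0
    refractory_period_s: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "upstroke_duration_s",
            "decay_tau_s",
            "amplitude",
            "diastolic_level",
            "refractory_period_s",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.refractory_period_s < self.upstroke_duration_s:
            raise ValueError("refractory_period_s must be >= upstroke_duration_s")

    @property
    def rise_time_s(self) -> float:
        """Total rise (activation onset to peak) of the smoothstep limb."""
        return self.upstroke_duration_s / _SMOOTHSTEP_1090


@dataclass(frozen=True)
class PacingSegment:
    start_s: float
    duration_s: float
    freq_hz: float
    mode: str = "paced"  # 'basal' (spontaneous rate) or 'paced' (stimulated)

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.freq_hz <= 0:
            raise ValueError("duration_s and freq_hz must be positive")
        if self.mode not in ("basal", "paced"):
            raise ValueError(f"mode must be 'basal' or 'paced', got {self.mode!r}")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class PacingProtocol:
    """Ordered, non-overlapping acquisition segments."""

    segments: tuple[PacingSegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s - 1e-12:
                raise ValueError("segments must be ordered and non-overlapping")

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s

    @classmethod
    def standard(
        cls,
        basal_freq_hz: float = 1.0,
        paced_freqs_hz: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0),
        segment_s: float = 5.0,
    ) -> "PacingProtocol":
        """Basal stage then stimulation at increasing rates, 5 s each."""
        segs = [PacingSegment(0.0, segment_s, basal_freq_hz, "basal")]
        t = segment_s
        for f in paced_freqs_hz:
            segs.append(PacingSegment(t, segment_s, f, "paced"))
            t += segment_s
        return cls(tuple(segs))


@dataclass(frozen=True)
class SceneConfig:
    """Geometry/acquisition of a synthetic movie (128x128 EMCCD-style)."""

    mode: str = "aggregate"  # 'aggregate' or 'monolayer'
    height_px: int = 128
    width_px: int = 128
    frame_rate_hz: float = 50.0
    pixel_size_mm: float = 0.05
    cv_mm_s: float | None = None
    stim_origin_px: tuple[float, float] = (0.0, 0.0)  # (row, col)
    polarity: str = "up"
    noise_sd: float = 0.0  # fraction of transient amplitude
    bleach_tau_s: float = math.inf
    illumination_rel_range: float = 0.0
    aggregate_radius_frac: float = 0.35
    background_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("aggregate", "monolayer"):
            raise ValueError(f"mode must be 'aggregate' or 'monolayer', got {self.mode!r}")
        if self.height_px < 8 or self.width_px < 8:
            raise ValueError("dimensions must be >= 8 px")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.mode == "monolayer" and (self.cv_mm_s is None or self.cv_mm_s <= 0):
            raise ValueError("cv_mm_s must be positive in monolayer mode")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.polarity not in ("up", "down"):
            raise ValueError("polarity must be 'up' or 'down'")


# ---------------------------------------------------------------------------
# Waveform kernel


def _smoothstep(x: np.ndarray) -> np.ndarray:
    return x * x * (3.0 - 2.0 * x)


def kernel_values(params: WaveformParams, t: np.ndarray) -> np.ndarray:
    """Transient amplitude at times ``t`` relative to activation onset.

    0 before activation; cubic-smoothstep rise to ``amplitude`` over the
    full rise time; exponential recovery afterwards.
    """
    t = np.asarray(t, dtype=float)
    rise = params.rise_time_s
    out = np.zeros_like(t)
    rising = (t >= 0) & (t < rise)
    out[rising] = params.amplitude * _smoothstep(t[rising] / rise)
    decaying = t >= rise
    out[decaying] = params.amplitude * np.exp(-(t[decaying] - rise) / params.decay_tau_s)
    return out


def analytic_catd(params: WaveformParams, p: float, reference: str = "onset") -> float:
    """Closed-form CaTD_p (ms) of the kernel.

    Time from the activation reference until the recovery limb crosses
    (1 - p/100) of the amplitude: rise remainder + tau * ln(100/(100-p)).
    ``reference`` is 'onset' (start of rise) or 'upslope' (maximum-derivative
    time — the rise midpoint for a smoothstep), matching the activation-time
    convention of the mapping metrics.
    """
    if not 0 < p < 100:
        raise ValueError(f"p must be in (0, 100), got {p}")
    if reference == "onset":
        lead = params.rise_time_s
    elif reference == "upslope":
        lead = params.rise_time_s / 2.0
    else:
        raise ValueError("reference must be 'onset' or 'upslope'")
    return 1000.0 * (lead + params.decay_tau_s * math.log(100.0 / (100.0 - p)))


def analytic_catd_periodic(
    params: WaveformParams,
    p: float,
    period_s: float = math.inf,
    reference: str = "upslope",
) -> float | None:
    """Closed-form CaTD_p (ms) of a periodic transient train.

    At beat period T the exponential tails of earlier transients superpose:
    the peak sits at A / (1 - e^(-T/tau)) and the pre-upstroke diastole at
    A e^(-(T-R)/tau) / (1 - e^(-T/tau)) above true baseline (R = full rise
    time).  CaTD_p is measured against that *per-beat* diastole and
    amplitude, exactly as a beat-wise analysis sees it.  Returns None when
    the p% recovery is encroached by the next activation (undefined), and
    reduces to :func:`analytic_catd` as T -> infinity.
    """
    if not 0 < p < 100:
        raise ValueError(f"p must be in (0, 100), got {p}")
    rise = params.rise_time_s
    tau = params.decay_tau_s
    amp = params.amplitude
    if math.isinf(period_s):
        s_peak, d = amp, 0.0
    else:
        if period_s <= rise:
            return None
        f = math.exp(-period_s / tau)
        s_peak = amp / (1.0 - f)
        d = amp * math.exp(-(period_s - rise) / tau) / (1.0 - f)
    level = d + (1.0 - p / 100.0) * (s_peak - d)
    u = tau * math.log(s_peak / level)
    if math.isfinite(period_s) and u > period_s - rise + 1e-12:
        return None
    lead = rise if reference == "onset" else rise / 2.0
    return 1000.0 * (lead + u)


def waveform_kernel(params: WaveformParams, t: np.ndarray) -> tuple[np.ndarray, dict[int, float]]:
    """Kernel trace plus its analytic onset-referenced CaTD values (ms)."""
    if np.any(np.diff(np.asarray(t, dtype=float)) <= 0):
        raise ValueError("t must be strictly ascending")
    values = kernel_values(params, t)
    catd = {p: analytic_catd(params, p, reference="onset") for p in CATD_LEVELS}
    return values, catd


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    """Everything the generator knows about a rendered movie.

    ``catd_ms`` is referenced to the maximum-upslope time (the activation
    convention of the metrics module); the onset-referenced values are
    larger by half the rise time and available via :func:`analytic_catd`.
    ``df_hz`` per segment is the realized beat rate (captured beats /
    segment duration).
    """

    event_times_s: list[float]
    event_captured: list[bool]
    event_segment: list[int]
    df_hz: list[float]
    capture: list[dict]
    catd_ms: dict[int, float | None]
    catd_ms_by_segment: list[dict[int, float | None]]
    upstroke_s: float
    cv_mm_s: float | None
    seed: int
    pixel_delays_s: np.ndarray | None = None  # not serialized
    footprint: np.ndarray | None = None  # not serialized

    def to_dict(self) -> dict:
        return {
            "event_times_s": list(self.event_times_s),
            "event_captured": list(self.event_captured),
            "event_segment": list(self.event_segment),
            "df_hz": list(self.df_hz),
            "capture": self.capture,
            "catd_ms": {str(k): v for k, v in self.catd_ms.items()},
            "catd_ms_by_segment": [
                {str(k): v for k, v in d.items()} for d in self.catd_ms_by_segment
            ],
            "upstroke_s": self.upstroke_s,
            "cv_mm_s": self.cv_mm_s,
            "seed": self.seed,
        }


def _schedule_events(
    protocol: PacingProtocol, refractory_s: float
) -> tuple[list[float], list[bool], list[int]]:
    """Stimulus/spontaneous event times with capture flags.

    A stimulus captures only if the elapsed time since the last captured
    activation is >= the refractory period; blocked stimuli are skipped
    entirely (no partial response).
    """
    times: list[float] = []
    captured: list[bool] = []
    seg_idx: list[int] = []
    last = -math.inf
    for i, seg in enumerate(protocol.segments):
        n = int(math.ceil(seg.duration_s * seg.freq_hz - 1e-9))
        for k in range(n):
            t = seg.start_s + k / seg.freq_hz
            if t >= seg.end_s - 1e-12:
                break
            ok = (t - last) >= refractory_s - 1e-12
            if ok:
                last = t
            times.append(t)
            captured.append(ok)
            seg_idx.append(i)
    return times, captured, seg_idx


def generate_video(
    scene: SceneConfig,
    wave: WaveformParams,
    protocol: PacingProtocol,
    n_frames: int | None = None,
) -> tuple[VideoStack, GroundTruth]:
    """Render a synthetic calcium movie and its ground truth.

    Aggregate mode: all pixels inside a centred disc share every activation
    time.  Monolayer mode: each pixel's activation is delayed by its
    distance from the stimulation origin divided by the conduction velocity
    (delays are continuous, so the ground-truth CV is exact).  Noise,
    photobleaching and illumination heterogeneity are applied after
    composition.
    """
    fps = scene.frame_rate_hz
    if n_frames is None:
        n_frames = int(math.ceil(protocol.end_s * fps))
    duration = n_frames / fps
    if protocol.end_s > duration + 1e-9:
        raise ValueError(
            f"protocol ends at {protocol.end_s:.3f} s but video lasts {duration:.3f} s"
        )
    h, w = scene.height_px, scene.width_px
    rng = np.random.default_rng(scene.seed)

    # footprint & per-pixel delays
    yy, xx = np.mgrid[0:h, 0:w]
    if scene.mode == "aggregate":
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r = scene.aggregate_radius_frac * min(h, w)
        footprint = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        delays = np.zeros(int(footprint.sum()))
    else:
        footprint = np.ones((h, w), dtype=bool)
        oy, ox = scene.stim_origin_px
        dist_mm = np.hypot(yy - oy, xx - ox) * scene.pixel_size_mm
        delays = dist_mm.ravel() / scene.cv_mm_s

    times, captured, seg_idx = _schedule_events(protocol, wave.refractory_period_s)

    # composition
    t_grid = np.arange(n_frames) / fps
    n_pix = int(footprint.sum())
    support = wave.rise_time_s + 8.0 * wave.decay_tau_s
    dmin, dmax = (float(delays.min()), float(delays.max())) if n_pix else (0.0, 0.0)
    sig = np.zeros((n_frames, n_pix))
    for te, ok in zip(times, captured):
        if not ok:
            continue
        i0 = max(0, int(math.floor((te + dmin) * fps)))
        i1 = min(n_frames, int(math.ceil((te + dmax + support) * fps)) + 1)
        if i1 <= i0:
            continue
        rel = t_grid[i0:i1, None] - te - delays[None, :]
        sig[i0:i1] += kernel_values(wave, rel)

    frames = np.full((n_frames, h, w), scene.background_frac * wave.diastolic_level)
    body = wave.diastolic_level + sig
    if scene.polarity == "down":
        body = 2.0 * wave.diastolic_level - body
    frames.reshape(n_frames, -1)[:, footprint.ravel()] = body

    if scene.illumination_rel_range > 0:
        raw = rng.random((h, w))
        smooth = gaussian_filter(raw, sigma=min(h, w) / 6.0, mode="reflect")
        span = smooth.max() - smooth.min()
        norm = (smooth - smooth.min()) / span if span > 0 else np.zeros_like(smooth)
        illum = 1.0 + scene.illumination_rel_range * (norm - 0.5)
        frames *= illum[None, :, :]
    if np.isfinite(scene.bleach_tau_s):
        frames *= np.exp(-t_grid / scene.bleach_tau_s)[:, None, None]
    if scene.noise_sd > 0:
        frames = frames + rng.normal(0.0, scene.noise_sd * wave.amplitude, frames.shape)
    np.clip(frames, 0.0, None, out=frames)

    # ground truth
    df = []
    capture_records = []
    catd_by_seg = []
    for i, seg in enumerate(protocol.segments):
        delivered = sum(1 for j, s in enumerate(seg_idx) if s == i)
        cap_times = [times[j] for j, s in enumerate(seg_idx) if s == i and captured[j]]
        ncap = len(cap_times)
        # realized beat rate from the mean inter-activation spacing (the
        # spectrally visible frequency), not from counts over the window —
        # counts quantize the rate by 1/duration
        if ncap >= 2:
            df.append((ncap - 1) / (cap_times[-1] - cap_times[0]))
        else:
            df.append(ncap / seg.duration_s)
        capture_records.append(
            {
                "segment": i,
                "mode": seg.mode,
                "freq_hz": seg.freq_hz,
                "delivered": delivered,
                "captured": ncap,
                "ratio": ncap / delivered if delivered else float("nan"),
            }
        )
        period = 1.0 / df[-1] if ncap > 1 else math.inf
        catd_by_seg.append(
            {p: analytic_catd_periodic(wave, p, period_s=period) for p in CATD_LEVELS}
        )
    truth = GroundTruth(
        event_times_s=times,
        event_captured=captured,
        event_segment=seg_idx,
        df_hz=df,
        capture=capture_records,
        catd_ms=catd_by_seg[0],
        catd_ms_by_segment=catd_by_seg,
        upstroke_s=wave.upstroke_duration_s,
        cv_mm_s=scene.cv_mm_s if scene.mode == "monolayer" else None,
        seed=scene.seed,
        pixel_delays_s=delays if scene.mode == "monolayer" else None,
        footprint=footprint,
    )
    stack = VideoStack(
        frames=frames.astype(np.float32),
        frame_rate_hz=fps,
        pixel_size_mm=scene.pixel_size_mm,
        polarity=scene.polarity,
    )
    return stack, truth


def save_video(
    directory: str | Path,
    stack: VideoStack,
    truth: GroundTruth,
    scene: SceneConfig,
    wave: WaveformParams,
    protocol: PacingProtocol,
    stem: str = "video",
) -> Path:
    """Write the movie as 16-bit TIFF plus a JSON sidecar of configs + truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{stem}.tif"
    sidecar = {
        "scene": asdict(scene),
        "waveform": asdict(wave),
        "protocol": [asdict(s) for s in protocol.segments],
        "ground_truth": truth.to_dict(),
    }
    write_stack(path, stack, sidecar=sidecar)
    return path


def recovery_case(seed: int) -> tuple[SceneConfig, WaveformParams, PacingProtocol]:
    """One draw of the parameter-recovery benchmark conditions.

    Spontaneous rate uniform in [0.5, 3] Hz; target CaTD50 uniform in
    [200 ms, min(800 ms, 75% of the beat period)] — the upper cap is a
    restitution-style constraint, a transient longer than its cycle has no
    defined duration; 10->90% upstroke uniform in [30, 80] ms; SNR 8
    (noise SD = amplitude/8); 10-s, 128x128, 50-fps spheroid movie.
    """
    rng = np.random.default_rng(seed)
    df = rng.uniform(0.5, 3.0)
    c50 = rng.uniform(0.2, min(0.8, 0.75 / df))
    upstroke = rng.uniform(0.03, 0.08)
    rise = upstroke / _SMOOTHSTEP_1090
    tau = (c50 - rise / 2.0) / math.log(2.0)
    wave = WaveformParams(
        upstroke_duration_s=upstroke,
        decay_tau_s=tau,
        refractory_period_s=max(0.15, upstroke),
    )
    scene = SceneConfig(mode="aggregate", noise_sd=1.0 / 8.0, seed=seed)
    protocol = PacingProtocol((PacingSegment(0.0, 10.0, df, "basal"),))
    return scene, wave, protocol


# ---------------------------------------------------------------------------
# Aggregate images


@dataclass(frozen=True)
class ShapeSpec:
    """One foreground object: disc (size=radius), square (size=side) or
    ellipse (size=(major, minor) full axis lengths), rotated by angle_deg."""

    center: tuple[float, float]  # (row, col)
    kind: str
    size: float | tuple[float, float]
    angle_deg: float = 0.0

    def true_feret_px(self) -> float:
        if self.kind == "disc":
            return 2.0 * float(self.size)
        if self.kind == "square":
            return float(self.size) * math.sqrt(2.0)
        if self.kind == "ellipse":
            return float(max(self.size))
        raise ValueError(f"unknown shape kind {self.kind!r}")


def generate_aggregate_image(
    shapes: list[ShapeSpec],
    image_shape: tuple[int, int] = (512, 512),
    noise_sd: float = 0.0,
    fg_level: float = 200.0,
    bg_level: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[float]]:
    """Rasterize bright shapes on a dark background; return true max-Feret (px).

    Pixels whose centres fall inside the continuous shape are foreground.
    Overlapping shapes raise a warning — per-shape ground truth is then
    unreliable (touching objects segment as one).
    """
    h, w = image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    total = np.zeros((h, w), dtype=int)
    ferets = []
    for s in shapes:
        cy, cx = s.center
        dy, dx = yy - cy, xx - cx
        th = math.radians(s.angle_deg)
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        if s.kind == "disc":
            r = float(s.size)
            m = dy * dy + dx * dx <= r * r
        elif s.kind == "square":
            half = float(s.size) / 2.0
            m = (np.abs(u) <= half) & (np.abs(v) <= half)
        elif s.kind == "ellipse":
            a, b = float(s.size[0]) / 2.0, float(s.size[1]) / 2.0
            m = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        else:
            raise ValueError(f"unknown shape kind {s.kind!r}")
        if not m.any():
            raise ValueError(f"shape {s} is degenerate or out of bounds")
        total += m
        ferets.append(s.true_feret_px())
    if np.any(total > 1):
        warnings.warn("overlapping shapes: per-shape ground truth is unreliable", stacklevel=2)
    rng = np.random.default_rng(seed)
    image = np.where(total > 0, fg_level, bg_level).astype(float)
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd * (fg_level - bg_level), image.shape)
    return image, ferets


# ---------------------------------------------------------------------------
# Perfusion simulator


def simulate_perfusion(
    q_true_pmol_cell_day: float,
    x0_cells_per_ml: float,
    mu_per_day: float,
    dilution_per_day: float,
    cin_mM: float,
    c0_mM: float,
    t_grid_day: np.ndarray,
    noise_sd_mM: float = 0.0,
    seed: int = 0,
) -> PerfusionSeries:
    """Integrate dC/dt = q*X(t) + D*(Cin - C) with exponential cell growth.

    X(t) = X0 * exp(mu t); q in pmol/cell/day converts to mM/day via the
    factor 1e-6 (pmol/mL = 1e-6 mM).  Adaptive RK45 with tight tolerances;
    Gaussian noise (SD in mM) is added to the sampled concentrations.
    Raises if the concentration goes negative, naming the time.
    """
    t_grid = np.asarray(t_grid_day, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid_day must be an ascending 1-D array with >= 2 points")
    if dilution_per_day < 0:
        raise ValueError("dilution_per_day must be non-negative")
    if x0_cells_per_ml <= 0:
        raise ValueError("x0_cells_per_ml must be positive")

    def rhs(t, y):
        x = x0_cells_per_ml * math.exp(mu_per_day * t)
        return [q_true_pmol_cell_day * x * 1e-6 + dilution_per_day * (cin_mM - y[0])]

    def hits_zero(t, y):
        return y[0]

    hits_zero.terminal = True
    hits_zero.direction = -1

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [c0_mM],
        t_eval=t_grid,
        rtol=1e-10,
        atol=1e-12,
        events=hits_zero,
        max_step=np.diff(t_grid).min(),
    )
    if sol.t_events[0].size:
        raise RuntimeError(
            f"simulated concentration reached zero at t = {sol.t_events[0][0]:.4f} days"
        )
    if not sol.success:
        raise RuntimeError(f"perfusion integration failed: {sol.message}")
    conc = sol.y[0]
    if noise_sd_mM > 0:
        rng = np.random.default_rng(seed)
        conc = conc + rng.normal(0.0, noise_sd_mM, conc.shape)
    cells = x0_cells_per_ml * np.exp(mu_per_day * t_grid)
    return PerfusionSeries(
        time_day=t_grid,
        conc_mM=conc,
        cells_per_ml=cells,
        cin_mM=cin_mM,
        dilution_per_day=dilution_per_day,
    )
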