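# Methods

This note documents the models, measurement conventions, parameter
defaults and numerical choices behind `cardiomap`, and what the synthetic
benchmarks do and do not establish about real recordings.

## Transient model

A calcium transient is modelled as a cubic smoothstep rise followed by a
single-exponential recovery:

    s(t) = A · smoothstep(t / T_rise)            0 ≤ t < T_rise
    s(t) = A · exp(−(t − T_rise) / τ)            t ≥ T_rise

`WaveformParams.upstroke_duration_s` is the 10→90 % rise time; for the
smoothstep the full rise is that value divided by 2·sin(asin(0.8)/3) ≈
0.6084, so the 10–90 % time is analytically exact. The smoothstep was
chosen because it is C¹, has its maximum slope exactly at mid-rise (making
the max-derivative activation convention analytically tractable), and its
level crossings are in closed form.

Defaults (chosen as typical of immature hiPSC-CM preparations imaged at
50 fps): upstroke 50 ms, τ = 350 ms, amplitude 1000 counts on a diastolic
level of 2000 counts (ΔF/F ≈ 0.5), refractory period 250 ms.

### CaTD conventions

Activation time is the maximum-derivative time (mid-rise), the standard
optical-mapping convention; CaTD_p runs from activation to the recovery
of p % of the beat's amplitude above its own diastole. A configuration
switch in `catd()`/`detect_beats` is unnecessary because both endpoints
are explicit in `Beat`.

At physiological rates the exponential tail has not finished when the next
beat starts. For a regular rhythm of period T the superposed signal peaks
at A/(1 − e^(−T/τ)) and its pre-upstroke diastole sits at
A·e^(−(T−T_rise)/τ)/(1 − e^(−T/τ)) above true baseline. The generator's
ground-truth CaTD therefore uses this *periodic* closed form
(`analytic_catd_periodic`), which is what a correct beat-wise measurement
sees; it reduces to the isolated-kernel form (`analytic_catd`) as T → ∞.
A corollary of the pure-exponential recovery is that, against per-beat
references, every p < 100 crossing occurs before the next rise — undefined
CaTD values arise at recording ends (and under noise), not mid-train.

## Signal conditioning

Chain: polarity resolution → sliding-percentile baseline → ΔF/F →
residual-floor subtraction → zero-phase smoothing.

- **Polarity.** Single-wavelength Fura-2 (380 nm excitation) reports a
  calcium rise as a fluorescence *fall*; rhod-2 as a rise. Auto mode flips
  the trace when the skewness of the baseline-subtracted signal is
  negative (transients are sparse, hence skew-signed). An explicit
  up/down override exists. For stacks, polarity is resolved once on the
  mask-mean trace.
- **Baseline.** Sliding 10th percentile over a 4-s window (≥ 2 beat
  cycles at the slowest rates considered), evaluated on strided anchors
  and linearly interpolated — the baseline is slow by construction and the
  stride cuts cost by ~6×. Percentile tracking (rather than a polynomial
  fit) is robust to rate changes across protocol segments and removes
  multiplicative photobleaching exactly in ΔF/F. A second pass subtracts
  the sliding percentile of the ΔF/F itself: window truncation at the
  trace edges otherwise leaves a slow residual drift (verified < 1 % of
  amplitude under a 30-s bleach constant).
- **Smoothing.** Zero-phase centred moving average, default **3 frames**.
  At 50 fps a 5-frame (100 ms) window attenuates the transient peak enough
  to bias amplitude-referenced CaTD50 by tens of milliseconds — more than
  the pipeline's own sub-frame timing error — so the narrower default is
  used; the width is a parameter.
- **Masking.** A pixel is analyzable if its mean intensity reaches the
  intensity quantile (default 0.5) of the frame-mean image *and* the
  peak-to-noise ratio of its detrended trace reaches `snr_floor` (default
  3). Noise is estimated from the first difference, which is
  noise-dominated for slow sparse transients. Dead-flat pixels (zero
  excursion, zero noise) fail.

## Beat detection and timing

Peaks are found with `scipy.signal.find_peaks` using a prominence floor of
max(5 robust noise SDs, 0.4 × the trace's 99th-percentile excursion): a
true beat's prominence can never be below its own excursion, so the
fraction rejects smoothed-noise peaks without touching real transients
(calibrated only in the sense that it is a conservative bound, not fitted
to any benchmark outcome). Sub-frame timing uses quadratic interpolation
of the derivative peak (activation) and of the signal peak (amplitude) —
the sampled maximum underestimates the true peak by up to one frame of
decay, which would otherwise bias every CaTD late by the same amount.
Diastole is the median of a ~120-ms window ending just before the upstroke
foot (found by walking the derivative back from the activation point); at
fast rates a longer window would reach into the previous decay limb.

Undefined metrics (unrecovered CaTD, unbracketable upstroke, < 2 beats for
IBI) propagate as missing values and are counted, never zero-filled.

## Dominant frequency

Periodogram of the mean-removed conditioned trace, zero-padded to a
≤ 0.02 Hz grid, argmax within 0.2–8 Hz (ties to the lower frequency).
Because the exponential-decay envelope falls monotonically with frequency,
the fundamental always dominates its harmonics for this waveform class.
The 0.2 Hz band-low requires ≥ 10 s of trace; for 5-s paced acquisitions
callers pass a 0.4 Hz band-low.

## Conduction velocity

Gradient method: activation times from the per-pixel maximum derivative
within a one-beat window, 3×3 median-filtered (an order statistic leaves a
locally planar wavefront unchanged away from edges), then a least-squares
plane t(x,y) = ax + by + c over a disc neighborhood (radius 3 px) around
every pixel whose full neighborhood is valid; speed = 1/√(a² + b²).
Pixels with fit R² < 0.9, or vanishing gradient (synchronous preparations
have no defined speed), are excluded; < 10 accepted pixels is an error.
With 2×2 spatial binning this recovers a 20 mm/s wavefront to < 1 % at
SNR 8. No streamline tracking, phase mapping or anisotropy estimation is
attempted.

## Pacing capture

Stimuli are delivered from each paced segment's start at 1/f spacing; a
stimulus captures only if the time since the last captured activation is
at least the refractory period, and blocked stimuli are skipped entirely
(the simplest refractoriness model consistent with a binary
tolerated/refractory readout). The capture ratio is detected beats over
delivered stimuli; ratios below 0.8 (default) raise the refractory flag.
Rhythm regularity is summarized as SD(IBI)/mean(IBI) over basal segments
instead of any reentry/phase-singularity detection.

## Synthetic movies

Spheroid mode composes one transient train shared by all pixels of a
centred disc (35 % of the frame side); monolayer mode delays each pixel by
its distance from the stimulation origin divided by the set conduction
velocity — delays are continuous (computed before frame sampling), so the
ground-truth CV is exact, and the wavefront is locally planar everywhere
(|∇t| = 1/cv). After composition: optional smooth multiplicative
illumination field, exponential photobleaching, i.i.d. Gaussian noise
scaled to the transient amplitude, and clipping at zero. All randomness
derives from the single scene seed; with noise and bleach off,
regeneration is bit-identical.

Ground-truth DF per segment is the realized mean inter-activation rate
(N−1)/(t_N − t_1) — counting beats over the window would quantize the rate
by 1/duration.

What the generator does **not** emulate: motion, camera-specific noise
(shot noise, EMCCD excess factor), spatial heterogeneity of kinetics,
alternans, ectopy, reentry, ratiometric acquisition. Benchmarks passed on
these movies therefore establish estimator correctness and noise
robustness under the stated model, not performance on pathological or
motion-contaminated recordings.

### Parameter-recovery benchmark

`synthdata.recovery_case` draws: rate uniform on [0.5, 3] Hz, target
CaTD50 uniform on [200 ms, min(800 ms, 0.75/rate)] — the cap is a
restitution-style constraint, since a transient longer than its cycle has
no defined duration — upstroke uniform on [30, 80] ms, SNR 8, 10-s
128×128 movies at 50 fps. Measured on the mask-mean trace, median
absolute errors over 50 draws are ≈ 0.003 Hz (DF) and ≈ 10 ms (CaTD50 and
upstroke), inside half a frame.

## Perfusion model and inversion

Forward: dC/dt = q·X(t)·10⁻⁶ + D(C_in − C), X(t) = X₀e^{μt}, integrated
with adaptive RK45 (rtol 10⁻¹⁰); a terminal event reports the time if the
concentration hits zero. Inversion applies the mass balance per sampling
interval with arithmetic interval means for C_out and X_V; the bracket is
divided by X̄_V as a whole (the only dimensionally consistent reading).
Units: mM and cells/mL convert to pmol·cell⁻¹·day⁻¹ via the factor 10⁶.
The discrete inversion is exact for linear C (batch, constant X) and at
steady state; for growing cultures the error is first-order in the
sampling interval (≈ 1 % at daily sampling for μ = 0.2 day⁻¹).
A logarithmic-mean X̄_V would be marginally better for fast growth but the
arithmetic mean matches the plain reading of "average viable-cell
concentration" and its error is already below the assay noise floor.

## Scale-up and DO

P/V uses the turbulent-regime relation P = Np ρ N³ D_i⁵ with N in rev/s
internally and rpm at interfaces. The known 0.2 L → 2 L operating pair
(80 → 149 rpm) is not checkable without both impellers' Np and D_i, which
users must supply. The DO conversion fixes air at 21.0 % O₂ (not 20.95 %)
so the conventional 47.6/23.8/71.4 % air-saturation setpoints for
10/5/15 % O₂ are reproduced exactly at one decimal.

## Aggregate morphometry

Otsu threshold (override available) → hole filling → connected components
→ removal of objects under 40 µm equivalent diameter. Max-Feret is the
maximum pairwise distance between convex-hull vertices of the object's
pixel centres plus half a pixel — pixel centres systematically under-reach
the continuous outline, and the half-pixel caliper correction splits the
difference between the centre and boundary conventions, keeping
disc/square/ellipse fixtures within 1.2 % at every rotation. Touching
objects merge (no watershed; flagged by the generator's overlap warning
instead). Statistics carry two flags: size-risk when the mean or any
object exceeds 300 µm (diffusion-limited necrotic cores), and
undersampled when fewer than 200 objects back the estimate. Min-Feret and
angle are not computed.

## Degenerate inputs and tie-breaks

Flat traces yield zero beats (not an error); empty masks, noise-only
activation windows, and < 10 accepted CV pixels raise descriptive errors;
periodogram ties break toward the lower frequency; quadratic refinements
are clipped to ±half a frame; baseline ≤ 0 aborts ΔF/F with a
normalization error.

## Known limitations

- CaTD accuracy degrades if the decay deviates strongly from a single
  exponential (the peak-refinement correction assumes a locally smooth
  peak).
- The CV estimator assumes a single coherent wavefront per window;
  colliding wavefronts or focal breakthrough violate the local-plane
  assumption.
- The capture accounting assigns beats to segments by activation time
  with no stimulus-to-beat latency model beyond an optional constant.
- Feret values inherit ±~1 px discretization; objects under ~10 px across
  should be measured at higher magnification instead.
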