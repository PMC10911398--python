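"""Extraction of pool-model observables from patch-clamp current traces.

This module turns raw (or synthetic) current traces into the summary
numbers the kinetic model consumes:

* the *corrected baseline* during a sucrose application, found by
  variance-mean (shot-noise) analysis — hypertonic solutions shift the
  leak current, and the true zero-release current can only be recovered
  by extrapolating the linear variance-vs-mean relation of synaptic shot
  noise back to the instrument-noise variance;
* the *plateau current* and the *transient (RRP) charge* of the sucrose
  response;
* spontaneous *mini* events and their rate (threshold detector on a
  smoothed trace, with a non-paralyzable dead-time correction);
* *train summaries*: cumulative-charge back-extrapolation, priming rate,
  release probability, paired-pulse ratio;
* the synchronous/asynchronous split of a single evoked response.

Conventions: inward currents are negative in traces; all derived
charges are reported as positive magnitudes (pC).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .types import CurrentTrace, SucroseResponse, TrainSummary

__all__ = [
    "BaselineFit",
    "MiniDetection",
    "variance_mean_baseline",
    "sucrose_rrp_charge",
    "analyze_sucrose_trace",
    "plateau_rate_spectral",
    "plateau_rate_campbell",
    "detrended_kernel_power",
    "detect_minis",
    "effective_dead_time",
    "train_summary",
    "synchronous_fraction",
    "fit_cumulative_release",
    "release_probability_sucrose",
]


def _running_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d

    window_samples = max(1, int(window_samples))
    return uniform_filter1d(x, size=window_samples, mode="nearest")


def _detrend(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Subtract a local quadratic (Savitzky-Golay) trend.

    A quadratic local fit follows the steep release transient without
    leaking its curvature into the residual variance, which a plain
    running average does.
    """
    from scipy.signal import savgol_filter

    window_samples = max(5, int(window_samples)) | 1
    return x - savgol_filter(x, window_length=window_samples, polyorder=2,
                             mode="nearest")


def _censored_quiescent(
    samples: np.ndarray,
    detrended: np.ndarray,
    fs: float,
    pre_pad: float = 0.003,
    post_pad: float = 0.025,
) -> tuple[float, float]:
    """Baseline mean and instrument-noise variance of a quiescent segment.

    Spontaneous minis are present even in "quiescent" stretches; their
    shot noise would inflate the zero-release variance anchor (and their
    mean current would offset the baseline) by exactly the resting
    release rate.  Candidate events are therefore censored (3 ms before
    to 25 ms after each peak) before computing the statistics.  The
    censoring threshold is deliberately low (3x the smoothed noise SD):
    a false positive merely discards clean samples, whereas a missed
    event leaks shot power into the anchor.
    """
    smoothed = _running_average(samples, 0.001 * fs)
    med = float(np.median(smoothed))
    mad = float(np.median(np.abs(smoothed - med)))
    noise_sd = 1.4826 * mad
    mask = np.ones(samples.size, dtype=bool)
    if noise_sd > 0:
        peaks, _ = signal.find_peaks(
            -(smoothed - med), height=3.0 * noise_sd,
            distance=max(1, int(0.002 * fs)),
        )
        a = int(pre_pad * fs)
        b = int(post_pad * fs)
        for p in peaks:
            mask[max(0, p - a):p + b] = False
    if mask.sum() < 0.1 * samples.size:  # pathologically event-dense
        mask[:] = True
    return float(np.mean(samples[mask])), float(np.var(detrended[mask]))


def _window_slice(trace: CurrentTrace, window: tuple[float, float]) -> slice:
    fs = trace.sampling_rate
    a = max(0, int(round(window[0] * fs)))
    b = min(trace.n_samples, int(round(window[1] * fs)))
    if b <= a:
        raise ValueError(f"window {window} lies outside the trace")
    return slice(a, b)


@dataclass
class BaselineFit:
    """Result of the variance-mean baseline correction."""

    corrected_baseline: float
    slope: float
    intercept: float
    quiescent_variance: float
    quiescent_baseline: float
    fallback: bool
    p_value: float


def variance_mean_baseline(
    trace: CurrentTrace,
    application_window: tuple[float, float] | None = None,
    bin_width: float = 0.050,
    smoothing_window: float = 0.010,
    quiescent_duration: float = 0.5,
    exchange_time: float | None = None,
) -> BaselineFit:
    """Variance-mean (shot-noise) estimate of the true baseline current.

    The trace is detrended by subtracting a local quadratic fit
    (``smoothing_window``, default 10 ms), then the variance of the
    detrended current and the mean of the raw current are computed in
    ``bin_width`` intervals (default 50 ms) across the application.
    Linear regression of variance on inward-current magnitude is
    back-extrapolated to the variance of a quiescent pre-application
    segment; the crossing current is the corrected baseline.

    If the solution-exchange time constant is known (argument or trace
    annotation), the leak shift is allowed to ramp in with that time
    constant: the known ramp shape enters the regression as a second
    regressor, so bins recorded while the solution is still exchanging
    (which carry most of the release transient for fast-depleting
    cells) do not bias the extrapolation.

    If the regression slope is not significantly positive (no resolvable
    shot noise), the raw pre-application baseline is returned and
    ``fallback`` is set.
    """
    if application_window is None:
        application_window = trace.annotations.get("application_window")
        if application_window is None:
            raise ValueError("no application window given or annotated")
    if exchange_time is None:
        proto = trace.annotations.get("protocol")
        if proto is not None:
            exchange_time = proto.get("exchange_time")
    fs = trace.sampling_rate
    app = _window_slice(trace, application_window)
    n_bins = int((app.stop - app.start) / (bin_width * fs))
    if n_bins < 10:
        raise ValueError("application window must span at least 10 bins")

    detrended = _detrend(trace.samples, smoothing_window * fs)

    q_end = application_window[0]
    q_start = max(0.0, q_end - quiescent_duration)
    if q_end <= 0:
        raise ValueError("no pre-application quiescent segment available")
    quiet = _window_slice(trace, (q_start, q_end))
    quiescent_baseline, v0 = _censored_quiescent(
        trace.samples[quiet], detrended[quiet], fs
    )

    bin_samples = int(round(bin_width * fs))
    means = np.empty(n_bins)
    variances = np.empty(n_bins)
    ramp = np.ones(n_bins)
    for i in range(n_bins):
        seg = slice(app.start + i * bin_samples, app.start + (i + 1) * bin_samples)
        means[i] = np.mean(trace.samples[seg])
        variances[i] = np.var(detrended[seg])
        if exchange_time and exchange_time > 0:
            # mean of 1 - exp(-t/tau) across the bin, t from app onset
            ta = i * bin_width
            tb = (i + 1) * bin_width
            ramp[i] = 1.0 - exchange_time * (
                math.exp(-ta / exchange_time) - math.exp(-tb / exchange_time)
            ) / bin_width

    x = -means  # inward-current magnitude, so shot noise has positive slope
    use_ramp = exchange_time is not None and exchange_time > 0 and (
        ramp.max() - ramp.min() > 1e-3
    )
    if use_ramp:
        # var = a + c*x + d*ramp ; fully exchanged baseline solves
        # a + c*(-b) + d = v0
        design = np.column_stack([np.ones(n_bins), x, ramp])
    else:
        design = np.column_stack([np.ones(n_bins), x])

    # iteratively reweighted fit: the sampling error of a bin variance
    # scales with the variance itself, so weights 1/fitted^2 keep the
    # huge transient bins from swamping the extrapolation
    weights = np.ones(n_bins)
    coef = np.zeros(design.shape[1])
    for _ in range(3):
        w = np.sqrt(weights)[:, None]
        coef, *_ = np.linalg.lstsq(design * w, variances * np.sqrt(weights),
                                   rcond=None)
        fitted = design @ coef
        weights = 1.0 / np.maximum(fitted, max(v0, 1e-12) / 4.0) ** 2

    resid = (variances - design @ coef) * np.sqrt(weights)
    dof = n_bins - design.shape[1]
    sigma2 = float(resid @ resid) / max(dof, 1)
    xtx = (design * weights[:, None]).T @ design
    try:
        cov = sigma2 * np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        cov = np.full((design.shape[1],) * 2, np.inf)
    slope = float(coef[1])
    slope_se = math.sqrt(max(cov[1, 1], 0.0))
    t_stat = slope / slope_se if slope_se > 0 else 0.0
    p_value = float(stats.t.sf(t_stat, dof))  # one-sided: slope > 0

    intercept = float(coef[0] + (coef[2] if use_ramp else 0.0))
    significant = slope > 0 and p_value < 0.05
    if not significant:
        warnings.warn(
            "variance-mean slope not significantly positive; "
            "falling back to the raw pre-application baseline",
            stacklevel=2,
        )
        return BaselineFit(
            corrected_baseline=quiescent_baseline,
            slope=slope,
            intercept=intercept,
            quiescent_variance=v0,
            quiescent_baseline=quiescent_baseline,
            fallback=True,
            p_value=p_value,
        )
    x0 = (v0 - intercept) / slope
    return BaselineFit(
        corrected_baseline=float(-x0),
        slope=slope,
        intercept=intercept,
        quiescent_variance=v0,
        quiescent_baseline=quiescent_baseline,
        fallback=False,
        p_value=p_value,
    )


def sucrose_rrp_charge(
    trace: CurrentTrace,
    corrected_baseline: float,
    application_window: tuple[float, float] | None = None,
    plateau_fraction: float = 0.2,
    pre_baseline: float | None = None,
    exchange_time: float | None = None,
) -> tuple[float, float]:
    """Integrate the transient (RRP) charge and measure the plateau.

    The baseline-subtracted current is integrated over the application;
    the plateau is the mean baseline-subtracted current over the final
    ``plateau_fraction`` of the application (default 20%), and the
    transient (RRP) charge is the total integral minus the plateau
    contribution.  If ``exchange_time`` and ``pre_baseline`` are given,
    the subtracted baseline ramps from the pre-application to the
    corrected level with that time constant, mirroring the solution
    exchange.

    Returns ``(rrp_charge_pC, plateau_current_pA)``; the charge is a
    positive magnitude, the plateau keeps the inward (negative) sign.
    """
    if application_window is None:
        application_window = trace.annotations.get("application_window")
        if application_window is None:
            raise ValueError("no application window given or annotated")
    fs = trace.sampling_rate
    dt = 1.0 / fs
    app = _window_slice(trace, application_window)
    t0, t1 = application_window
    duration = t1 - t0

    if exchange_time is None:
        proto = trace.annotations.get("protocol")
        if proto is not None:
            exchange_time = proto.get("exchange_time")

    seg = trace.samples[app]
    if exchange_time and pre_baseline is not None and exchange_time > 0:
        t_rel = np.arange(seg.size) * dt
        base = pre_baseline + (corrected_baseline - pre_baseline) * (
            1.0 - np.exp(-t_rel / exchange_time)
        )
    else:
        base = corrected_baseline
    d = seg - base

    n_plateau = max(1, int(round(plateau_fraction * seg.size)))
    plateau_current = float(np.mean(d[-n_plateau:]))
    if plateau_current > 0:
        # outward "plateau" means no resolvable release; clamp to zero
        plateau_current = 0.0

    total_charge = -float(np.sum(d)) * dt  # pC, positive for inward
    rrp_charge = total_charge - (-plateau_current) * duration
    return max(rrp_charge, 0.0), plateau_current


def detrended_kernel_power(
    kernel, sampling_rate: float, smoothing_window: float = 0.010
) -> float:
    """Integrated squared unit-charge waveform after detrending (1/s).

    By Campbell's theorem the shot-noise variance of a filtered Poisson
    train is ``rate * q^2 * <a^2> * P`` with ``P`` the integral of the
    squared unitary waveform; the same detrend filter that is applied to
    the trace must be applied to the waveform.  Returned for a
    unit-charge kernel; multiply by ``unitary_charge**2`` and the
    amplitude second moment.
    """
    dt = 1.0 / sampling_rate
    pad = int(round(3 * smoothing_window / dt)) + 1
    klen = max(2, int(round(12.0 * kernel.decay_tau / dt)))
    kt = np.arange(klen) * dt
    shape = np.exp(-kt / kernel.decay_tau) - np.exp(-kt / kernel.rise_tau)
    shape /= shape.sum() * dt
    sig = np.zeros(pad + klen + pad)
    sig[pad:pad + klen] = shape
    d = _detrend(sig, smoothing_window / dt)
    return float(np.sum(d * d) * dt)


def plateau_rate_campbell(
    trace: CurrentTrace,
    kernel,
    application_window: tuple[float, float] | None = None,
    plateau_fraction: float = 0.2,
    smoothing_window: float = 0.010,
    quiescent_duration: float = 0.5,
) -> float:
    """Plateau release rate (events/s) from the shot-noise variance.

    The mean-based plateau is exquisitely sensitive to the corrected
    baseline when the plateau is only a few pA; the variance is not —
    the excess of the detrended plateau variance over the quiescent
    (event-censored) variance divided by the Campbell factor
    ``q^2 * (1+cv^2) * P`` gives a baseline-free rate estimate.
    Requires the unitary waveform parameters (kernel).
    """
    if application_window is None:
        application_window = trace.annotations.get("application_window")
        if application_window is None:
            raise ValueError("no application window given or annotated")
    fs = trace.sampling_rate
    detrended = _detrend(trace.samples, smoothing_window * fs)
    t0, t1 = application_window
    q_start = max(0.0, t0 - quiescent_duration)
    quiet = _window_slice(trace, (q_start, t0))
    _, v0 = _censored_quiescent(trace.samples[quiet], detrended[quiet], fs)
    plateau_start = t1 - plateau_fraction * (t1 - t0)
    seg = detrended[_window_slice(trace, (plateau_start, t1))]
    var_exc = float(np.var(seg)) - v0
    factor = (
        kernel.unitary_charge**2
        * (1.0 + kernel.amplitude_cv**2)
        * detrended_kernel_power(kernel, fs, smoothing_window)
    )
    return max(var_exc, 0.0) / factor


def plateau_rate_spectral(
    trace: CurrentTrace,
    kernel,
    application_window: tuple[float, float] | None = None,
    plateau_fraction: float = 0.6,
    f_min: float = 30.0,
    nperseg: int = 4096,
) -> float:
    """Plateau release rate (events/s) from the shot-noise spectrum.

    The power spectral density of the plateau current is a two-component
    mixture with known shapes: shot noise carries the squared Fourier
    magnitude of the unitary waveform scaled by the event rate
    (Campbell's theorem), and instrument noise is white.  A weighted
    linear fit of the measured Welch spectrum against these two shapes
    yields the rate without any baseline or quiescent-variance anchor —
    crucial when the plateau is only a few pA and resting minis
    contaminate every "quiescent" stretch.  Frequencies below ``f_min``
    are excluded to stay clear of drift.
    """
    if application_window is None:
        application_window = trace.annotations.get("application_window")
        if application_window is None:
            raise ValueError("no application window given or annotated")
    fs = trace.sampling_rate
    t0, t1 = application_window
    plateau_start = t1 - plateau_fraction * (t1 - t0)
    seg = trace.samples[_window_slice(trace, (plateau_start, t1))]
    nperseg = min(nperseg, seg.size // 4)
    freqs, pxx = signal.welch(seg - seg.mean(), fs=fs, nperseg=nperseg)

    # one-sided PSD shape of a unit-rate shot process with this kernel
    dt = 1.0 / fs
    klen = max(2, int(round(10.0 * kernel.decay_tau / dt)))
    kt = np.arange(klen) * dt
    shape = np.exp(-kt / kernel.decay_tau) - np.exp(-kt / kernel.rise_tau)
    shape /= shape.sum() * dt
    unit = np.zeros(nperseg)
    unit[: min(klen, nperseg)] = (kernel.unitary_charge * shape)[:nperseg]
    s_shot = 2.0 * (1.0 + kernel.amplitude_cv**2) * np.abs(
        np.fft.rfft(unit) * dt
    ) ** 2
    s_white = np.full_like(s_shot, 2.0 / fs)

    mask = freqs >= f_min
    y = pxx[mask]
    m1 = s_shot[mask]
    m2 = s_white[mask]
    design = np.column_stack([m1, m2])
    # periodogram errors scale with the spectrum itself -> IRLS
    weights = np.ones(y.size)
    coef = np.array([0.0, float(np.median(y)) * fs / 2.0])
    for _ in range(4):
        w = weights[:, None]
        coef, *_ = np.linalg.lstsq(design * w, y * weights.ravel(), rcond=None)
        fitted = np.maximum(design @ coef, 1e-30)
        weights = 1.0 / fitted
    return float(max(coef[0], 0.0))


def analyze_sucrose_trace(
    trace: CurrentTrace,
    application_window: tuple[float, float] | None = None,
    bin_width: float = 0.050,
    smoothing_window: float = 0.010,
    plateau_fraction: float = 0.2,
) -> SucroseResponse:
    """Full sucrose-trace summary: baseline fit, plateau, RRP charge."""
    fit = variance_mean_baseline(
        trace, application_window, bin_width=bin_width,
        smoothing_window=smoothing_window,
    )
    rrp_charge, plateau = sucrose_rrp_charge(
        trace,
        fit.corrected_baseline,
        application_window,
        plateau_fraction=plateau_fraction,
        pre_baseline=fit.quiescent_baseline,
    )
    return SucroseResponse(
        corrected_baseline=fit.corrected_baseline,
        plateau_current=plateau,
        rrp_charge=rrp_charge,
        regression_slope=fit.slope,
        regression_intercept=fit.intercept,
        baseline_fallback=fit.fallback,
    )


@dataclass
class MiniDetection:
    """Detected spontaneous events and the dead-time-corrected rate."""

    event_times: np.ndarray
    amplitudes: np.ndarray
    mini_rate: float
    raw_rate: float
    threshold: float
    noise_sd: float
    analyzed_duration: float
    params: dict = field(default_factory=dict)


_DEAD_TIME_CACHE: dict = {}


def effective_dead_time(
    kernel,
    sampling_rate: float,
    threshold: float,
    min_interval: float = 0.002,
    smoothing_window: float = 0.001,
    n_grid: int = 9,
) -> float:
    """Resolution limit of the mini detector for a given unitary kernel.

    Two overlapping events closer than the detector can resolve are
    counted once; the loss behaves like a counter dead time, but the
    effective dead time is set by the kernel width and the peak-finding
    rules, not by ``min_interval`` alone.  This probes the detector
    itself: noise-free pairs of unitary waveforms are laid down at a
    grid of separations and amplitude combinations (lognormal quantiles
    matching the kernel's CV) and passed through the identical
    smoothing/peak logic; the integral of the miss probability over
    separation is the effective dead time (s).
    """
    from scipy.ndimage import uniform_filter1d

    dt = 1.0 / sampling_rate
    pad = int(round(12 * kernel.decay_tau / dt))
    klen = max(2, int(round(10.0 * kernel.decay_tau / dt)))
    kt = np.arange(klen) * dt
    shape = np.exp(-kt / kernel.decay_tau) - np.exp(-kt / kernel.rise_tau)
    shape /= shape.sum() * dt
    unit = kernel.unitary_charge * shape  # pA, magnitude

    if kernel.amplitude_cv > 0:
        sigma = math.sqrt(math.log1p(kernel.amplitude_cv**2))
        qs = stats.norm.ppf((np.arange(n_grid) + 0.5) / n_grid)
        amps = np.exp(-sigma * sigma / 2.0 + sigma * qs)
    else:
        amps = np.array([1.0])

    smooth_n = max(1, int(round(smoothing_window * sampling_rate)))
    distance = max(1, int(round(min_interval * sampling_rate)))
    seps = np.arange(1, int(round(0.008 / dt)) + 1)  # up to 8 ms
    miss = np.zeros(seps.size)
    for i, sep in enumerate(seps):
        lost = 0
        total = 0
        for a1 in amps:
            for a2 in amps:
                sig = np.zeros(pad + sep + klen + pad)
                sig[pad:pad + klen] += a1 * unit
                sig[pad + sep:pad + sep + klen] += a2 * unit
                sm = uniform_filter1d(sig, size=smooth_n, mode="nearest")
                peaks, _ = signal.find_peaks(
                    sm, height=threshold, distance=distance,
                    prominence=threshold,
                )
                detectable = int(a1 * unit.max() >= threshold) + int(
                    a2 * unit.max() >= threshold
                )
                if detectable > 0:
                    total += 1
                    if peaks.size < detectable:
                        lost += 1
        miss[i] = lost / total if total else 0.0
    return float(np.sum(miss) * dt)


def detect_minis(
    trace: CurrentTrace,
    threshold: float | None = None,
    min_interval: float = 0.002,
    smoothing_window: float = 0.001,
    window: tuple[float, float] | None = None,
    kernel=None,
) -> MiniDetection:
    """Detect miniature (single-vesicle) inward events.

    The trace is boxcar-smoothed (default 1 ms), the noise level of the
    smoothed trace is estimated robustly (MAD about the median, immune
    to the sparse events themselves), and events are local minima
    exceeding ``threshold`` (default 5x the smoothed noise SD) below the
    median, separated by at least ``min_interval`` and with prominence
    at least ``threshold``.

    The reported ``mini_rate`` applies a non-paralyzable dead-time
    correction ``r = m / (1 - m * tau)`` for unresolvably close events;
    ``tau`` is ``min_interval``, or the detector's kernel-calibrated
    resolution limit (:func:`effective_dead_time`) when the unitary
    ``kernel`` is supplied.  ``raw_rate`` is the uncorrected count per
    analyzed second.
    """
    fs = trace.sampling_rate
    if window is None:
        samples = trace.samples
        duration = trace.duration
    else:
        sl = _window_slice(trace, window)
        samples = trace.samples[sl]
        duration = (sl.stop - sl.start) / fs

    smoothed = _running_average(samples, smoothing_window * fs)
    med = float(np.median(smoothed))
    mad = float(np.median(np.abs(smoothed - med)))
    noise_sd = 1.4826 * mad
    if threshold is None:
        threshold = 5.0 * noise_sd
    elif noise_sd > 0 and threshold < 3.0 * noise_sd:
        warnings.warn(
            "detection threshold below 3x the smoothed noise SD; "
            "expect false positives",
            stacklevel=2,
        )

    distance = max(1, int(round(min_interval * fs)))
    # prominence rejects noise wiggles riding on an event's decay tail
    # without imposing a long dead time on genuine overlapping events
    peaks, props = signal.find_peaks(
        -(smoothed - med), height=threshold, distance=distance,
        prominence=threshold,
    )
    times = peaks / fs
    amplitudes = props["peak_heights"]
    raw_rate = peaks.size / duration if duration > 0 else 0.0
    if kernel is not None:
        key = (
            round(kernel.unitary_charge, 6), round(kernel.rise_tau, 9),
            round(kernel.decay_tau, 9), round(kernel.amplitude_cv, 4),
            round(fs, 3), round(threshold, 1), min_interval, smoothing_window,
        )
        tau_dead = _DEAD_TIME_CACHE.get(key)
        if tau_dead is None:
            tau_dead = effective_dead_time(
                kernel, fs, threshold, min_interval, smoothing_window
            )
            _DEAD_TIME_CACHE[key] = tau_dead
    else:
        tau_dead = min_interval
    dead = raw_rate * tau_dead
    mini_rate = raw_rate / (1.0 - dead) if dead < 0.5 else raw_rate
    return MiniDetection(
        event_times=times,
        amplitudes=amplitudes,
        mini_rate=float(mini_rate),
        raw_rate=float(raw_rate),
        threshold=float(threshold),
        noise_sd=float(noise_sd),
        analyzed_duration=float(duration),
        params={
            "min_interval": min_interval,
            "smoothing_window": smoothing_window,
            "dead_time": tau_dead,
        },
    )


def train_summary(
    per_stim_charges: np.ndarray,
    frequency: float,
    fit_range: tuple[int, int] | None = None,
    ppr_pair: tuple[int, int] = (0, 1),
    amplitudes: np.ndarray | None = None,
) -> TrainSummary:
    """Back-extrapolation analysis of an AP train.

    ``per_stim_charges`` are positive evoked charges (pC) per stimulus.
    Cumulative charge is regressed on time over ``fit_range`` (0-based
    half-open stimulus indices; default the last 20 stimuli, mirroring
    the "last part of stimulation") and extrapolated to time zero, one
    inter-stimulus interval before the first stimulus.  The intercept is
    the train-probed RRP (``rrp_ev``), the slope the priming rate;
    release probability is the first charge over ``rrp_ev``; the
    paired-pulse ratio is charge (or amplitude, if given) of stimulus
    ``ppr_pair[1]`` over ``ppr_pair[0]``.

    A non-positive intercept means depletion was insufficient for
    back-extrapolation; the summary is flagged invalid.
    """
    charges = np.asarray(per_stim_charges, dtype=float)
    n = charges.size
    if n < 2:
        raise ValueError("need at least 2 stimuli")
    if fit_range is None:
        lo = max(0, n - 20)
        fit_range = (lo, n)
    lo, hi = fit_range
    if not (0 <= lo < hi <= n) or hi - lo < 2:
        raise ValueError(f"invalid fit_range {fit_range} for {n} stimuli")

    interval = 1.0 / frequency
    t = (np.arange(n) + 1) * interval
    cum = np.cumsum(charges)
    reg = stats.linregress(t[lo:hi], cum[lo:hi])
    rrp_ev = float(reg.intercept)
    priming_rate = float(reg.slope)

    valid = rrp_ev > 1e-12
    p_release = charges[0] / rrp_ev if valid else float("nan")
    if valid and p_release > 1:
        valid = False  # pathological: first response exceeds the pool

    series = amplitudes if amplitudes is not None else charges
    a, b = ppr_pair
    ppr = float(series[b] / series[a]) if series[a] > 0 else float("nan")

    return TrainSummary(
        per_stim_charges=charges,
        cumulative_charges=cum,
        rrp_ev=rrp_ev,
        priming_rate_ev=priming_rate,
        p_release_ev=float(p_release),
        paired_pulse_ratio=ppr,
        valid=valid,
    )


def _double_exp_cum(t, a_fast, tau_fast, a_slow, tau_slow):
    return a_fast * (1 - np.exp(-t / tau_fast)) + a_slow * (1 - np.exp(-t / tau_slow))


def fit_cumulative_release(
    t: np.ndarray, cumulative: np.ndarray
) -> tuple[float, float, float, bool]:
    """Fit a double-exponential to a cumulative-release curve.

    Returns ``(fraction_fast, tau_fast, tau_slow, fallback)`` with the
    components sorted so ``tau_fast < tau_slow``.  On non-convergence a
    single exponential is fitted instead and the fraction is 1.
    """
    from scipy.optimize import curve_fit

    t = np.asarray(t, dtype=float)
    cumulative = np.asarray(cumulative, dtype=float)
    total = cumulative[-1]
    if total <= 0:
        raise ValueError("cumulative release must end positive")
    span = t[-1] - t[0]
    try:
        popt, _ = curve_fit(
            _double_exp_cum,
            t,
            cumulative,
            p0=[0.7 * total, span / 50, 0.3 * total, span / 3],
            bounds=([0, 1e-6, 0, 1e-6], [5 * total, span * 10, 5 * total, span * 10]),
            maxfev=10000,
        )
        a1, tau1, a2, tau2 = popt
        if tau1 > tau2:
            a1, tau1, a2, tau2 = a2, tau2, a1, tau1
        if a1 + a2 <= 0:
            raise RuntimeError("degenerate fit")
        return float(a1 / (a1 + a2)), float(tau1), float(tau2), False
    except (RuntimeError, ValueError):
        def single(tt, a, tau):
            return a * (1 - np.exp(-tt / tau))

        popt, _ = curve_fit(single, t, cumulative, p0=[total, span / 5], maxfev=10000)
        return 1.0, float(popt[1]), float(popt[1]), True


def synchronous_fraction(
    trace: CurrentTrace,
    stimulus_time: float,
    window: float = 0.5,
    baseline_window: float = 0.05,
) -> tuple[float, float, float, bool]:
    """Fraction of an evoked response released synchronously.

    Integrates the baseline-subtracted current from ``stimulus_time``
    over ``window`` seconds and fits the cumulative charge with a double
    exponential; the fast-component amplitude share is the synchronous
    fraction.  Returns ``(fraction, fast_tau, slow_tau, fallback)``.
    """
    fs = trace.sampling_rate
    pre = _window_slice(trace, (max(0.0, stimulus_time - baseline_window), stimulus_time))
    baseline = float(np.mean(trace.samples[pre]))
    post = _window_slice(trace, (stimulus_time, stimulus_time + window))
    d = trace.samples[post] - baseline
    cum = -np.cumsum(d) / fs  # pC, positive for inward
    t = (np.arange(cum.size) + 1) / fs
    return fit_cumulative_release(t, cum)


def release_probability_sucrose(eepsc_charge: float, rrp_charge: float) -> float:
    """Release probability: evoked charge over the sucrose-probed RRP.

    No clamping is applied; values above 1 indicate inconsistent inputs
    and are the caller's to flag.
    """
    if rrp_charge <= 0:
        raise ValueError("rrp_charge must be > 0")
    if eepsc_charge < 0:
        raise ValueError("eepsc_charge must be >= 0")
    return eepsc_charge / rrp_charge
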