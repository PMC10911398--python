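"""Stochastic synthetic data: exact vesicle-pool trajectories and current traces.

The generator is the test bed for the whole pipeline: it produces exact
stochastic counterparts of the one-pool model (priming as a Poisson
source at ``k1``, depriming and fusion as independent per-vesicle
hazards) and renders the resulting fusion events as realistic
patch-clamp current traces (unitary waveforms, solution-exchange
baseline shifts, Gaussian instrument noise, 20 kHz sampling).

The continuous-time chain is simulated with the exact Gillespie
algorithm; during the sucrose-exchange ramp, where the fusion hazard is
time dependent, events are drawn by thinning against the ``n_suc``
upper bound, which keeps the simulation exact.
"""

from __future__ import annotations

import math

import numpy as np

from .types import (
    CurrentTrace,
    EventRecord,
    MiniKernel,
    RateTriple,
    SucroseProtocol,
    TrainProtocol,
)

__all__ = [
    "simulate_pool",
    "render_trace",
    "simulate_train",
    "steady_state_pool_draw",
]

DEFAULT_SAMPLING_RATE = 20_000.0
DEFAULT_NOISE_SD = 3.0


def steady_state_pool_draw(rates: RateTriple, rng: np.random.Generator) -> int:
    """Draw an initial pool size from the stationary law of the chain.

    The birth-death chain with constant immigration ``k1`` and
    per-vesicle exit ``k_minus1 + kf`` has a Poisson stationary
    distribution with mean ``k1 / (k_minus1 + kf)``; drawing from it
    avoids any burn-in.
    """
    rates.require_steady_state()
    mean = rates.k1 / rates.decay_rate
    return int(rng.poisson(mean))


class _Blocks:
    """Pre-drawn random number blocks (cuts per-step RNG call overhead)."""

    def __init__(self, rng: np.random.Generator, size: int = 16384):
        self._rng = rng
        self._size = size
        self._exp = rng.standard_exponential(size)
        self._uni = rng.random(size)
        self._ie = 0
        self._iu = 0

    def exp(self) -> float:
        if self._ie >= self._size:
            self._exp = self._rng.standard_exponential(self._size)
            self._ie = 0
        v = self._exp[self._ie]
        self._ie += 1
        return v

    def uniform(self) -> float:
        if self._iu >= self._size:
            self._uni = self._rng.random(self._size)
            self._iu = 0
        v = self._uni[self._iu]
        self._iu += 1
        return v


def _segments(protocol: SucroseProtocol | None, t_end: float):
    """Split [0, t_end] into (t0, t1, s_const_or_None) pieces.

    ``s`` is the fold-increase of ``kf``; ``None`` marks a ramp segment
    where the hazard is time varying and thinning is required.
    """
    if protocol is None or protocol.n_suc == 1.0:
        return [(0.0, t_end, 1.0)]
    tau = protocol.exchange_time
    ramp = 10.0 * tau
    pts: list[tuple[float, float, float | None]] = []
    on, off = protocol.onset_time, protocol.end_time

    def add(a: float, b: float, s):
        a, b = max(0.0, a), min(t_end, b)
        if b > a:
            pts.append((a, b, s))

    add(0.0, on, 1.0)
    if tau == 0:
        add(on, off, protocol.n_suc)
        add(off, t_end, 1.0)
    else:
        add(on, on + ramp, None)
        add(on + ramp, off, protocol.n_suc)
        add(off, off + ramp, None)
        add(off + ramp, t_end, 1.0)
    return pts


def simulate_pool(
    rates: RateTriple,
    protocol: SucroseProtocol | None = None,
    t_end: float = 1.0,
    initial_pool: int | str = "steady",
    seed: int | None = None,
) -> EventRecord:
    """Exact stochastic simulation of the one-pool model.

    Parameters
    ----------
    rates : RateTriple
        Priming/depriming/fusion rates at rest.
    protocol : SucroseProtocol, optional
        If given, the per-vesicle fusion hazard is multiplied by the
        (ramped) fold-increase during the application.
    t_end : float
        Simulation horizon in seconds.
    initial_pool : int or "steady"
        Starting occupancy; ``"steady"`` draws from the Poisson
        stationary distribution of the resting chain.
    seed : int, optional
        Seed for the dedicated random generator (never global state).

    Returns
    -------
    EventRecord
        Fusion event times and the piecewise-constant pool path.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    rng = np.random.default_rng(seed)
    if initial_pool == "steady":
        n = steady_state_pool_draw(rates, rng)
    else:
        n = int(initial_pool)
        if n < 0:
            raise ValueError("initial_pool must be >= 0")

    k1, km1, kf = rates.k1, rates.k_minus1, rates.kf
    blocks = _Blocks(rng)
    fusion_times: list[float] = []
    pool_times: list[float] = [0.0]
    pool_sizes: list[int] = [n]

    for t0, t1, s_const in _segments(protocol, t_end):
        t = t0
        if s_const is not None:
            # Homogeneous Gillespie within the segment.
            s = s_const
            while True:
                total = k1 + n * (km1 + kf * s)
                if total <= 0:
                    break
                t = t + blocks.exp() / total
                if t >= t1:
                    break
                u = blocks.uniform() * total
                if u < k1:
                    n += 1
                elif u < k1 + n * km1:
                    n -= 1
                else:
                    n -= 1
                    fusion_times.append(t)
                pool_times.append(t)
                pool_sizes.append(n)
        else:
            # Ramp: thin the fusion channel against the n_suc bound.
            s_max = protocol.n_suc
            while True:
                bound = k1 + n * (km1 + kf * s_max)
                if bound <= 0:
                    break
                t = t + blocks.exp() / bound
                if t >= t1:
                    break
                u = blocks.uniform() * bound
                if u < k1:
                    n += 1
                elif u < k1 + n * km1:
                    n -= 1
                else:
                    # candidate fusion; accept with s(t)/s_max
                    if blocks.uniform() * s_max <= protocol.fold_increase(t):
                        n -= 1
                        fusion_times.append(t)
                    else:
                        continue
                pool_times.append(t)
                pool_sizes.append(n)

    pool_times.append(t_end)
    pool_sizes.append(n)
    return EventRecord(
        fusion_times=np.asarray(fusion_times),
        pool_times=np.asarray(pool_times),
        pool_sizes=np.asarray(pool_sizes),
        rates_used=rates,
        t_end=float(t_end),
        seed=seed,
    )


def _amplitude_jitter(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Multiplicative amplitude jitter: lognormal, mean 1, given CV."""
    if cv == 0 or n == 0:
        return np.ones(n)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def render_trace(
    events: EventRecord,
    kernel: MiniKernel | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    noise_sd: float = DEFAULT_NOISE_SD,
    protocol: SucroseProtocol | None = None,
    seed: int | None = None,
    baseline: float = 0.0,
    duration: float | None = None,
) -> CurrentTrace:
    """Render fusion events as a sampled current trace.

    Each event contributes one unitary waveform (inward, negative),
    amplitude-jittered by the kernel's CV; the discrete kernel is
    normalised so the integrated synaptic charge equals the summed event
    charges exactly.  The protocol's baseline shift (ramped by the
    exchange time) and Gaussian instrument noise are added on top.
    """
    from scipy.signal import fftconvolve

    kernel = kernel or MiniKernel()
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    dt = 1.0 / sampling_rate
    if dt > kernel.rise_tau:
        raise ValueError(
            "sampling interval exceeds kernel rise_tau; waveform unresolvable"
        )
    rng = np.random.default_rng(seed)
    duration = events.t_end if duration is None else float(duration)
    n_samples = int(round(duration * sampling_rate))
    times = np.arange(n_samples) * dt

    # unit-area discrete kernel (1/s), truncated at 10 decay constants
    klen = max(2, int(round(10.0 * kernel.decay_tau / dt)))
    kt = np.arange(klen) * dt
    shape = np.exp(-kt / kernel.decay_tau) - np.exp(-kt / kernel.rise_tau)
    shape /= shape.sum() * dt

    impulses = np.zeros(n_samples)
    ft = events.fusion_times
    ft = ft[ft < duration]
    if ft.size:
        charges = kernel.unitary_charge * _amplitude_jitter(
            rng, ft.size, kernel.amplitude_cv
        )
        idx = np.minimum((ft * sampling_rate).astype(np.int64), n_samples - 1)
        np.add.at(impulses, idx, charges)
        synaptic = -fftconvolve(impulses, shape)[:n_samples]
    else:
        synaptic = np.zeros(n_samples)

    current = synaptic + baseline
    if protocol is not None and protocol.baseline_shift != 0.0:
        current = current + protocol.baseline_at(times)
    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, size=n_samples)

    annotations: dict = {
        "units": {"time": "s", "current": "pA"},
        "baseline": baseline,
        "noise_sd": noise_sd,
        "seed": seed,
        "unitary_charge": kernel.unitary_charge,
        "kernel": {
            "unitary_charge": kernel.unitary_charge,
            "rise_tau": kernel.rise_tau,
            "decay_tau": kernel.decay_tau,
            "amplitude_cv": kernel.amplitude_cv,
        },
        "rates": {
            "k1": events.rates_used.k1,
            "k_minus1": events.rates_used.k_minus1,
            "kf": events.rates_used.kf,
        },
        "n_fusions": events.n_fusions,
    }
    if protocol is not None:
        annotations["application_window"] = (protocol.onset_time, protocol.end_time)
        annotations["protocol"] = {
            "onset_time": protocol.onset_time,
            "duration": protocol.duration,
            "n_suc": protocol.n_suc,
            "baseline_shift": protocol.baseline_shift,
            "exchange_time": protocol.exchange_time,
        }
    return CurrentTrace(current, sampling_rate, annotations)


def simulate_train(
    rates: RateTriple,
    train: TrainProtocol,
    seed: int | None = None,
    initial_pool: int | str = "steady",
    unitary_charge: float = 0.05,
    tail: float | None = None,
) -> tuple[np.ndarray, EventRecord]:
    """Simulate evoked release during an AP train.

    At each stimulus every primed vesicle fuses independently with
    probability ``p_vr`` (binomial draw); between stimuli the pool
    evolves under the resting one-pool dynamics (exact Gillespie).
    Returns the per-stimulus evoked charges (pC, positive magnitudes,
    ``count * unitary_charge``) and the full event record (evoked
    fusions are stamped just after the stimulus time).

    Optional facilitation: the release probability gains
    ``facilitation_increment`` after each AP, decaying exponentially
    with ``facilitation_tau`` between APs.
    """
    rng = np.random.default_rng(seed)
    if initial_pool == "steady":
        n = steady_state_pool_draw(rates, rng)
    else:
        n = int(initial_pool)

    k1, km1, kf = rates.k1, rates.k_minus1, rates.kf
    blocks = _Blocks(rng)
    interval = 1.0 / train.frequency
    stim_times = train.stimulus_times
    tail = interval if tail is None else float(tail)
    t_end = float(stim_times[-1] + tail)

    fusion_times: list[float] = []
    pool_times: list[float] = [0.0]
    pool_sizes: list[int] = [n]
    counts = np.zeros(train.n_stimuli, dtype=int)
    facilitation = 0.0
    t_prev = 0.0

    def evolve(t0: float, t1: float) -> None:
        nonlocal n
        t = t0
        while True:
            total = k1 + n * (km1 + kf)
            if total <= 0:
                break
            t = t + blocks.exp() / total
            if t >= t1:
                break
            u = blocks.uniform() * total
            if u < k1:
                n += 1
            elif u < k1 + n * km1:
                n -= 1
            else:
                n -= 1
                fusion_times.append(t)
            pool_times.append(t)
            pool_sizes.append(n)

    for i, t_stim in enumerate(stim_times):
        evolve(t_prev, t_stim)
        if i > 0:
            facilitation *= math.exp(-interval / train.facilitation_tau)
        p_eff = min(1.0, train.p_vr + facilitation)
        released = int(rng.binomial(n, p_eff)) if n > 0 and p_eff > 0 else 0
        counts[i] = released
        for j in range(released):
            fusion_times.append(t_stim + (j + 1) * 1e-9)
        n -= released
        pool_times.append(t_stim)
        pool_sizes.append(n)
        facilitation += train.facilitation_increment
        t_prev = t_stim + released * 1e-9 + 1e-9

    evolve(t_prev, t_end)
    pool_times.append(t_end)
    pool_sizes.append(n)

    record = EventRecord(
        fusion_times=np.asarray(fusion_times),
        pool_times=np.asarray(pool_times),
        pool_sizes=np.asarray(pool_sizes),
        rates_used=rates,
        t_end=t_end,
        seed=seed,
    )
    return counts * float(unitary_charge), record
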