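"""Domain types for readily-releasable-pool (RRP) kinetics.

The one-pool model describes the RRP as a single compartment filled by
priming at rate ``k1`` (vesicles/s) from an effectively infinite upstream
pool, and drained by per-vesicle depriming (``k_minus1``, 1/s) and
per-vesicle spontaneous fusion (``kf``, 1/s)::

    dRRP/dt = k1 - (k_minus1 + kf) * RRP

Hypertonic sucrose multiplies ``kf`` by a large factor ``n_suc``, which
converts the plateau of the sucrose-evoked current into a readout of the
priming rate.  All remaining types describe protocols, waveforms, and the
derived summaries the analysis stages exchange.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateTriple",
    "SucroseProtocol",
    "TrainProtocol",
    "MiniKernel",
    "EventRecord",
    "CurrentTrace",
    "SucroseResponse",
    "TrainSummary",
    "PoolEstimate",
    "EnergyLandscape",
    "ChargeModelParams",
]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class RateTriple:
    """Kinetic parameters of the one-pool model.

    Parameters
    ----------
    k1 : float
        Priming rate in vesicles/s (zeroth-order source).
    k_minus1 : float
        Depriming rate in 1/s (per-vesicle hazard).
    kf : float
        Spontaneous fusion rate in 1/s (per-vesicle hazard at rest).
    """

    k1: float
    k_minus1: float
    kf: float

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "kf"):
            value = _require_finite(name, getattr(self, name))
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
            object.__setattr__(self, name, value)

    @property
    def decay_rate(self) -> float:
        """Total per-vesicle exit rate ``k_minus1 + kf`` (1/s)."""
        return self.k_minus1 + self.kf

    def require_steady_state(self) -> None:
        if self.decay_rate <= 0:
            raise ValueError(
                "steady state undefined: k_minus1 + kf must be > 0"
            )


@dataclass(frozen=True)
class SucroseProtocol:
    """Hypertonic sucrose application.

    ``n_suc`` is the fold-increase of the per-vesicle fusion rate during
    the application; ``baseline_shift`` is the additive leak-current
    change (pA, signed) caused by the solution; ``exchange_time`` is the
    solution-exchange time constant (s) with which both effects ramp in.
    """

    onset_time: float
    duration: float
    n_suc: float
    baseline_shift: float = 0.0
    exchange_time: float = 0.05

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_suc < 1:
            raise ValueError("n_suc must be >= 1")
        if self.exchange_time < 0:
            raise ValueError("exchange_time must be >= 0")
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")

    @property
    def end_time(self) -> float:
        return self.onset_time + self.duration

    def fold_increase(self, t: np.ndarray | float) -> np.ndarray | float:
        """Instantaneous fold-increase of ``kf`` at time ``t``.

        Exponential approach to ``n_suc`` after onset, back to 1 after
        washout (with the same exchange time constant).
        """
        t = np.asarray(t, dtype=float)
        s = np.ones_like(t)
        tau = self.exchange_time
        rising = t >= self.onset_time
        if tau == 0:
            s = np.where(rising, self.n_suc, 1.0)
            s = np.where(t >= self.end_time, 1.0, s)
        else:
            up = 1.0 + (self.n_suc - 1.0) * (
                1.0 - np.exp(-(t - self.onset_time) / tau)
            )
            s = np.where(rising, up, s)
            after = t >= self.end_time
            level_at_end = 1.0 + (self.n_suc - 1.0) * (
                1.0 - np.exp(-self.duration / tau)
            )
            down = 1.0 + (level_at_end - 1.0) * np.exp(
                -(t - self.end_time) / tau
            )
            s = np.where(after, down, s)
        if s.ndim == 0:
            return float(s)
        return s

    def baseline_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Leak-current shift (pA) at time ``t``, ramped like ``fold_increase``."""
        s = self.fold_increase(t)
        frac = (np.asarray(s) - 1.0) / (self.n_suc - 1.0) if self.n_suc > 1 else np.asarray(s) * 0.0
        out = self.baseline_shift * frac
        if np.ndim(out) == 0:
            return float(out)
        return out


@dataclass(frozen=True)
class TrainProtocol:
    """Action-potential train (e.g. 50 stimuli at 40 Hz).

    ``p_vr`` is the per-stimulus vesicular release probability.  Optional
    facilitation: after each stimulus ``p_vr`` is incremented by
    ``facilitation_increment`` and the increment decays with time
    constant ``facilitation_tau`` (s).
    """

    n_stimuli: int
    frequency: float
    p_vr: float
    facilitation_increment: float = 0.0
    facilitation_tau: float = 0.1
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be >= 1")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if not 0.0 <= self.p_vr <= 1.0:
            raise ValueError("p_vr must be in [0, 1]")
        if self.facilitation_tau <= 0:
            raise ValueError("facilitation_tau must be > 0")

    @property
    def stimulus_times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_stimuli) / self.frequency


@dataclass(frozen=True)
class MiniKernel:
    """Unitary (single-vesicle) current waveform.

    Difference of exponentials normalised so its time integral equals
    ``unitary_charge`` (pC).  Inward currents are rendered negative.
    """

    unitary_charge: float = 0.05
    rise_tau: float = 0.5e-3
    decay_tau: float = 3.0e-3
    amplitude_cv: float = 0.3

    def __post_init__(self) -> None:
        if self.unitary_charge <= 0:
            raise ValueError("unitary_charge must be > 0")
        if not self.decay_tau > self.rise_tau > 0:
            raise ValueError("need decay_tau > rise_tau > 0")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Kernel evaluated at times ``t`` (s), in pA for a 1-event charge.

        Normalised so that ``trapz(waveform, t) == -unitary_charge`` in
        pA*s = pC (inward convention) in the continuum limit.
        """
        t = np.asarray(t, dtype=float)
        h = np.where(
            t >= 0,
            (np.exp(-t / self.decay_tau) - np.exp(-t / self.rise_tau))
            / (self.decay_tau - self.rise_tau),
            0.0,
        )
        return -self.unitary_charge * h

    @property
    def peak_time(self) -> float:
        r, d = self.rise_tau, self.decay_tau
        return math.log(d / r) * r * d / (d - r)

    @property
    def peak_amplitude(self) -> float:
        """Peak inward current (pA, positive magnitude) of one unit event."""
        return float(-self.waveform(np.array([self.peak_time]))[0])


@dataclass(frozen=True)
class EventRecord:
    """Exact stochastic trajectory of the vesicle pool.

    ``fusion_times`` are the times of single-vesicle fusion events;
    ``pool_times``/``pool_sizes`` describe the piecewise-constant pool
    occupancy (size ``pool_sizes[i]`` holds on ``[pool_times[i],
    pool_times[i+1])``).
    """

    fusion_times: np.ndarray
    pool_times: np.ndarray
    pool_sizes: np.ndarray
    rates_used: RateTriple
    t_end: float
    seed: int | None = None

    def __post_init__(self) -> None:
        ft = np.asarray(self.fusion_times, dtype=float)
        if ft.size and np.any(np.diff(ft) <= 0):
            raise ValueError("fusion_times must be strictly increasing")
        sizes = np.asarray(self.pool_sizes)
        if sizes.size and sizes.min() < 0:
            raise ValueError("pool size must never be negative")
        object.__setattr__(self, "fusion_times", ft)
        object.__setattr__(self, "pool_times", np.asarray(self.pool_times, dtype=float))
        object.__setattr__(self, "pool_sizes", sizes)

    @property
    def n_fusions(self) -> int:
        return int(self.fusion_times.size)

    def final_pool(self) -> int:
        return int(self.pool_sizes[-1]) if self.pool_sizes.size else 0


@dataclass
class CurrentTrace:
    """Uniformly sampled membrane current.

    ``samples`` are in pA (inward negative); ``annotations`` carries
    protocol windows (e.g. ``application_window``) and generator
    metadata used by the analysis stages.
    """

    samples: np.ndarray
    sampling_rate: float
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class SucroseResponse:
    """Per-trace summary of a sucrose application."""

    corrected_baseline: float
    plateau_current: float
    rrp_charge: float
    regression_slope: float = float("nan")
    regression_intercept: float = float("nan")
    baseline_fallback: bool = False

    def __post_init__(self) -> None:
        if self.rrp_charge < 0:
            raise ValueError("rrp_charge must be >= 0")


@dataclass
class TrainSummary:
    """Back-extrapolation summary of an AP-train response."""

    per_stim_charges: np.ndarray
    cumulative_charges: np.ndarray
    rrp_ev: float
    priming_rate_ev: float
    p_release_ev: float
    paired_pulse_ratio: float
    valid: bool = True

    def __post_init__(self) -> None:
        cum = np.asarray(self.cumulative_charges, dtype=float)
        if cum.size and np.any(np.diff(cum) < -1e-9):
            raise ValueError("cumulative_charges must be nondecreasing")


@dataclass
class PoolEstimate:
    """Estimated kinetic parameters for one cell or condition."""

    rates: RateTriple
    rrp_vesicles: float
    normalized_mini_rate: float
    n_suc_assumed: float | str = "infinite"
    flags: tuple[str, ...] = ()


@dataclass
class EnergyLandscape:
    """Mutant-minus-reference energy offsets along the priming/fusion path.

    Offsets are in kBT per molecule (multiply by RT to get kJ/mol).  The
    pre-primed state is anchored at 0 for both conditions; only
    differences are meaningful because the Arrhenius prefactor is
    unknown.
    """

    d_priming_ts: float
    d_rrp_state: float
    d_fusion_ts: float
    temperature: float = 298.15
    reference_label: str = "WT"
    mutant_label: str = "mutant"
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class ChargeModelParams:
    """Saturating electrostatic charge-to-rate model parameters.

    ``rate_at_zero`` anchors the curve at Z=0, the ceiling is
    ``fraction_f * max_rate``, ``slope_beta`` (kBT/charge) is the
    log-linear sensitivity in the sub-saturated regime, and
    ``evoked_offset`` is the number of positive charges separating the
    evoked from the spontaneous curve.
    """

    rate_at_zero: float = 0.00029
    max_rate: float = 6000.0
    fraction_f: float = 0.030
    slope_beta: float = 0.55575
    evoked_offset: float = 35.0

    def __post_init__(self) -> None:
        if not 0 < self.fraction_f <= 1:
            raise ValueError("fraction_f must be in (0, 1]")
        if self.slope_beta <= 0:
            raise ValueError("slope_beta must be > 0")
        if self.evoked_offset < 0:
            raise ValueError("evoked_offset must be >= 0")
        if not 0 < self.rate_at_zero < self.ceiling:
            raise ValueError("need 0 < rate_at_zero < fraction_f * max_rate")

    @property
    def ceiling(self) -> float:
        """Maximum attainable rate ``fraction_f * max_rate`` (1/s)."""
        return self.fraction_f * self.max_rate
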