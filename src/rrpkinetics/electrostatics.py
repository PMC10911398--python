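"""Saturating electrostatic charge-to-release-rate model.

The per-vesicle fusion rate depends on the net charge ``Z`` on the
SNARE-complex surface: in the sub-saturated regime each added positive
charge multiplies the rate by ``exp(beta)``, and the rate saturates at a
ceiling ``K = fraction_f * max_rate``.  The implemented form is a
logistic in the rate domain,

    k(Z) = K * k0 * exp(beta*Z) / (K + k0 * (exp(beta*Z) - 1)),

anchored by ``k(0) = k0`` (the rate at zero charge), ``k(inf) = K``,
and with ``d ln k / dZ -> beta`` for ``k << K``.  Evoked release lives
on the same curve shifted by ``evoked_offset`` positive charges.

The model is strictly monotone, so rates can be interpolated back to
charge values exactly; charge separations between conditions are
differences of such interpolated charges.
"""

from __future__ import annotations

import math

import numpy as np

from .types import ChargeModelParams

__all__ = [
    "rate_at_charge",
    "charge_at_rate",
    "delta_charge",
    "downscale_peak_rate",
    "curve_table",
]


def _effective_z(params: ChargeModelParams, z, mode: str):
    if mode == "spontaneous":
        return z
    if mode == "evoked":
        return np.asarray(z, dtype=float) + params.evoked_offset
    raise ValueError(f"mode must be 'spontaneous' or 'evoked', got {mode!r}")


def rate_at_charge(
    params: ChargeModelParams, z, mode: str = "spontaneous"
):
    """Per-vesicle release rate (1/s) at surface charge ``z``.

    Overflow-safe for arbitrarily large ``|z|``; strictly increasing in
    ``z`` with ``rate_at_charge(0) == rate_at_zero`` and the ceiling
    ``fraction_f * max_rate`` at ``z -> +inf``.
    """
    z_eff = np.asarray(_effective_z(params, z, mode), dtype=float)
    k0 = params.rate_at_zero
    ceiling = params.ceiling
    # k = K k0 e^{bz} / (K + k0 (e^{bz} - 1)); rewrite with e^{-bz} for
    # large positive z to avoid overflow.
    bz = params.slope_beta * z_eff
    with np.errstate(over="ignore"):
        small = bz < 0
        e_pos = np.exp(np.where(small, bz, 0.0))
        e_neg = np.exp(np.where(small, 0.0, -bz))
        num_small = ceiling * k0 * e_pos
        den_small = ceiling + k0 * (e_pos - 1.0)
        num_large = ceiling * k0
        den_large = ceiling * e_neg + k0 * (1.0 - e_neg)
        out = np.where(small, num_small / den_small, num_large / den_large)
    if out.ndim == 0:
        return float(out)
    return out


def charge_at_rate(
    params: ChargeModelParams, rate: float, mode: str = "spontaneous"
) -> float:
    """Exact inverse of :func:`rate_at_charge` (charge units).

    Only defined on the open range ``(0, fraction_f * max_rate)``.
    """
    k0 = params.rate_at_zero
    ceiling = params.ceiling
    if not 0 < rate < ceiling:
        raise ValueError(
            f"rate must lie in (0, {ceiling}) 1/s for interpolation, got {rate}"
        )
    z = math.log(rate * (ceiling - k0) / (k0 * (ceiling - rate))) / params.slope_beta
    if mode == "evoked":
        z -= params.evoked_offset
    elif mode != "spontaneous":
        raise ValueError(f"mode must be 'spontaneous' or 'evoked', got {mode!r}")
    return z


def delta_charge(
    params: ChargeModelParams,
    rate_a: float,
    rate_b: float,
    mode: str = "spontaneous",
) -> float:
    """Charge separation between two conditions from their rates.

    ``charge_at_rate(rate_b) - charge_at_rate(rate_a)``: the number of
    elementary charges that would move condition *a* onto condition *b*
    along the model curve.
    """
    return charge_at_rate(params, rate_b, mode) - charge_at_rate(params, rate_a, mode)


def downscale_peak_rate(
    rate: float, amplitude_ref: float, amplitude_target: float
) -> float:
    """Rescale a peak release rate by an eEPSC amplitude ratio.

    Used when deconvolution of a small response is unreliable: the peak
    rate measured in a reference condition is scaled by
    ``amplitude_target / amplitude_ref``.
    """
    if amplitude_ref <= 0 or amplitude_target <= 0:
        raise ValueError("amplitudes must be > 0")
    return rate * (amplitude_target / amplitude_ref)


def curve_table(
    params: ChargeModelParams,
    z_min: float = -10.0,
    z_max: float = 45.0,
    n: int = 221,
) -> np.ndarray:
    """(Z, spontaneous rate, evoked rate) table for plotting/export."""
    z = np.linspace(z_min, z_max, n)
    return np.column_stack(
        [
            z,
            rate_at_charge(params, z, "spontaneous"),
            rate_at_charge(params, z, "evoked"),
        ]
    )
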