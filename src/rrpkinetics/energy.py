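"""Arrhenius conversion of rate-constant changes into energy offsets.

A rate constant ``k = A * exp(-Ea / RT)`` cannot yield an absolute
barrier height because the prefactor ``A`` is unknown, but comparing a
mutant to a reference under the assumption that ``A`` is unchanged gives
the *difference* in activation energy::

    dEa (mut - ref) = RT * (ln k_ref - ln k_mut)

Applying this sequentially to the priming, depriming, and fusion rates —
with the pre-primed state anchored at the same level for both conditions
— builds a comparative energy landscape over the states
``pre-primed -> priming TS -> RRP -> fusion TS``.

Energies are emitted both per molecule (kBT) and per mole (kJ/mol);
at 298.15 K, RT = 2.479 kJ/mol, so 1 kBT per molecule corresponds to
2.479 kJ/mol.
"""

from __future__ import annotations

import math

from .types import EnergyLandscape, RateTriple

__all__ = [
    "GAS_CONSTANT_KJ",
    "gas_constant_times_T",
    "delta_activation_energy",
    "build_landscape",
    "landscape_profile",
]

GAS_CONSTANT_KJ = 8.31446e-3  # kJ/(mol*K)

#: Caveat attached to priming-barrier outputs: the priming step may be
#: collision-limited, in which case the Arrhenius prefactor is not
#: guaranteed to be mutation independent and a priming-barrier offset
#: may partly reflect altered collision rates.
PRIMING_PREFACTOR_NOTE = (
    "priming transition-state offsets assume a mutation-independent "
    "Arrhenius prefactor; priming may involve collision rates, so this "
    "offset can partly reflect altered collision frequency"
)


def gas_constant_times_T(temperature: float = 298.15) -> float:
    """Thermal energy per mole, RT, in kJ/mol (2.479 at 298.15 K)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return GAS_CONSTANT_KJ * temperature


def delta_activation_energy(
    k_ref: float, k_mut: float, temperature: float = 298.15
) -> tuple[float, float]:
    """Activation-energy difference (mutant - reference) from two rates.

    Returns ``(kBT, kJ/mol)``.  Positive means the mutant's barrier is
    higher (its rate is slower).  Antisymmetric in its arguments.
    """
    if k_ref <= 0 or k_mut <= 0:
        raise ValueError("rates must be > 0")
    kbt = math.log(k_ref / k_mut)
    return kbt, kbt * gas_constant_times_T(temperature)


def build_landscape(
    rates_ref: RateTriple,
    rates_mut: RateTriple,
    temperature: float = 298.15,
    reference_label: str = "WT",
    mutant_label: str = "mutant",
) -> EnergyLandscape:
    """Comparative energy landscape (mutant minus reference), in kBT.

    With the pre-primed level anchored at 0 for both conditions:

    * ``d_priming_ts``  = ln(k1_ref / k1_mut)
    * ``d_rrp_state``   = d_priming_ts - ln(k-1_ref / k-1_mut)
    * ``d_fusion_ts``   = d_rrp_state + ln(kf_ref / kf_mut)

    so that each barrier *height* change equals the activation-energy
    difference of the corresponding rate.
    """
    for r in (rates_ref, rates_mut):
        if r.k1 <= 0 or r.k_minus1 <= 0 or r.kf <= 0:
            raise ValueError("all six rates must be > 0")
    d_priming = math.log(rates_ref.k1 / rates_mut.k1)
    d_rrp = d_priming - math.log(rates_ref.k_minus1 / rates_mut.k_minus1)
    d_fusion = d_rrp + math.log(rates_ref.kf / rates_mut.kf)
    return EnergyLandscape(
        d_priming_ts=d_priming,
        d_rrp_state=d_rrp,
        d_fusion_ts=d_fusion,
        temperature=temperature,
        reference_label=reference_label,
        mutant_label=mutant_label,
        notes=(PRIMING_PREFACTOR_NOTE,),
    )


def landscape_profile(landscape: EnergyLandscape) -> list[dict]:
    """Plot-ready state/energy sequence for reference and mutant.

    The reference profile is anchored at 0 for every state (only
    differences are physical); the mutant profile carries the offsets.
    The post-fusion level is unknown and marked as such rather than
    given a value.
    """
    states = [
        ("pre_primed", 0.0, 0.0, True),
        ("priming_ts", 0.0, landscape.d_priming_ts, True),
        ("rrp", 0.0, landscape.d_rrp_state, True),
        ("fusion_ts", 0.0, landscape.d_fusion_ts, True),
        ("post_fusion", float("nan"), float("nan"), False),
    ]
    rt = gas_constant_times_T(landscape.temperature)
    profile = []
    for name, ref_kbt, mut_kbt, known in states:
        profile.append(
            {
                "state": name,
                "reference_kbt": ref_kbt,
                "mutant_offset_kbt": mut_kbt,
                "mutant_offset_kj_per_mol": mut_kbt * rt if known else float("nan"),
                "known": known,
            }
        )
    return profile
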