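"""Reference kinetic parameter sets for autaptic glutamatergic neurons.

Published point estimates of the one-pool rates (k1 in vesicles/s,
k_minus1 and kf in 1/s) for SNAP25 wildtype-rescue and disease-mutant
conditions, and for the synaptotagmin-1 knockout and its wildtype
littermate control.  The two SNAP25 mutant sets were measured against
separate parallel wildtype controls, hence the two WT entries.

These values serve as generator inputs for synthetic cohorts and as
worked-example inputs for the energy-landscape stage; they are not
fitted by this package.
"""

from .types import RateTriple

__all__ = ["REFERENCE_RATES"]

REFERENCE_RATES: dict[str, RateTriple] = {
    # SNAP25 wildtype rescue measured in parallel with V48F
    "WT": RateTriple(k1=385.6, k_minus1=0.0903, kf=0.000844),
    "V48F": RateTriple(k1=79.87, k_minus1=0.0605, kf=0.0164),
    # wildtype rescue measured in parallel with D166Y
    "WT_D166Y_set": RateTriple(k1=457.4, k_minus1=0.1114, kf=0.000398),
    "D166Y": RateTriple(k1=37.68, k_minus1=0.0294, kf=0.03522),
    "Syt1_WT": RateTriple(k1=1227.0, k_minus1=0.140, kf=0.000235),
    "Syt1_KO": RateTriple(k1=646.0, k_minus1=0.114, kf=0.00286),
}
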