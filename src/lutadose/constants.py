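"""Physical constants and standardized tissue data for 177Lu dosimetry.

All values are overridable through function arguments or :class:`~lutadose.io.RunConfig`;
nothing in the pipeline hard-wires them beyond being the defaults.
"""
import math

#: Physical half-life of 177Lu in hours (6.647 d, standard decay data).
LU177_HALF_LIFE_H = 6.647 * 24.0  # 159.528 h

#: Physical decay constant of 177Lu, h^-1.
LU177_LAMBDA_PHYS_PER_H = math.log(2.0) / LU177_HALF_LIFE_H

#: Mean electron (beta + conversion + Auger) energy emitted per 177Lu decay, MeV.
#: Used by the default local-deposition dose model.
LU177_MEAN_ELECTRON_ENERGY_MEV = 0.1479

#: Number of decays per GBq·h of cumulated activity.
DECAYS_PER_GBQ_H = 3.6e12

#: Joules per MeV.
J_PER_MEV = 1.602176634e-13

# Linear attenuation coefficients at 208 keV (narrow-beam, cm^-1).
# Tests never depend on these exact values; they are physics defaults.
MU_WATER_208KEV_CM1 = 0.137
MU_LUNG_208KEV_CM1 = 0.04
MU_AIR_208KEV_CM1 = 0.0

#: Standardized organ densities, g·mL^-1. Tumour density is taken equal to liver.
ORGAN_DENSITY_G_ML = {
    "kidney": 1.05,
    "liver": 1.06,
    "spleen": 1.06,
    "lung": 0.26,
    "tumour": 1.06,
    "soft_tissue": 1.0,
}
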