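"""Physical constants shared across the model.

All potentials in the package are expressed in MPa (negative under tension),
water fluxes in m of water per unit ground area per second, and conductances
in m s-1 MPa-1 unless stated otherwise.
"""

RHO_W = 1000.0  # water density [kg m-3]
GRAV = 9.81  # gravitational acceleration [m s-2]
MW_H2O = 0.018  # molar mass of water [kg mol-1]
R_GAS = 8.314  # universal gas constant [J mol-1 K-1]
CP_AIR = 1005.0  # specific heat of dry air [J kg-1 K-1]
LAMBDA_VAP = 2.45e6  # latent heat of vaporisation [J kg-1]

# metres of hydraulic head per MPa: 1e6 Pa / (rho * g)
M_HEAD_PER_MPA = 1.0e6 / (RHO_W * GRAV)

# shortwave -> photosynthetically active radiation conversion:
# 45% of shortwave energy is PAR, 4.57 umol photons per J of PAR
PAR_FRACTION = 0.45
UMOL_PER_J_PAR = 4.57

SECONDS_PER_HOUR = 3600.0
HOURS_PER_DAY = 24

# 1 umol CO2 m-2 s-1 sustained for one day, as kg C m-2 day-1
KGC_PER_UMOLCO2_DAY = 12.0e-9 * 86400.0
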