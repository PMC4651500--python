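"""Physical constants and package-wide default parameter values.

Units convention (package-wide): conductances in mol m-2 s-1 (H2O basis
unless stated otherwise), CO2 as mole fractions in umol mol-1, O2 in
mmol mol-1, vapour pressure deficit and atmospheric pressure in kPa,
temperatures in degrees C externally and K internally, photosynthetic
rates in umol m-2 s-1, transpiration in mmol m-2 s-1 where reported.
"""

from __future__ import annotations

#: Universal gas constant (J mol-1 K-1)
GAS_CONSTANT = 8.314

#: Reference temperature for all rate parameters (degrees C / K)
TREF_C = 25.0
TREF_K = 298.15

#: Ratio of diffusivities H2O:CO2 through stomata
GS_CO2_RATIO = 1.6

#: Ratio of diffusivities H2O:CO2 through the leaf boundary layer
GBL_CO2_RATIO = 1.37

#: Molar mass of dry air / water (kg mol-1)
MOLAR_MASS_AIR = 0.028965
MOLAR_MASS_H2O = 0.018015

#: Specific heat of air (J kg-1 K-1)
CP_AIR = 1010.0

#: Default atmospheric pressure (kPa)
PRESSURE_KPA = 101.3

#: Default saturating PAR for A-Ci measurements (umol m-2 s-1)
PAR_SATURATING = 1800.0


def latent_heat_vaporisation(tair_c: float) -> float:
    """Latent heat of vaporisation of water (J kg-1) at air temperature."""
    return 2.501e6 - 2365.0 * tair_c


# Default FvCB kinetic constants at 25 C (conventional C3 values; every one
# of these is overridable through BiochemParams).
KC25 = 404.9          # Rubisco Michaelis constant for CO2 (umol mol-1)
KO25 = 278.4          # Rubisco Michaelis constant for O2 (mmol mol-1)
GAMMASTAR25 = 42.75   # CO2 compensation point without Rd (umol mol-1)
OI = 210.0            # Leaf internal O2 (mmol mol-1)
ALPHA_J = 0.24        # Quantum yield of electron transport (mol mol-1)
THETA_J = 0.85        # Curvature of the light response of J (-)
THETA_HMIN = 0.9999   # Hyperbolic-minimum shape parameter (-)

# Activation energies (J mol-1) and peaked-response constants
EA_KC = 79430.0
EA_KO = 36380.0
EA_GAMMASTAR = 37830.0
EA_RD = 46390.0
EA_VCMAX = 82620.87
HD_VCMAX = 200000.0
SV_VCMAX = 645.1013   # entropy term (J mol-1 K-1)
EA_JMAX = 39676.89
HD_JMAX = 200000.0
SV_JMAX = 641.3615


def defaults_table() -> dict[str, float]:
    """All default constants as a flat name -> value mapping."""
    return {
        "GAS_CONSTANT": GAS_CONSTANT,
        "TREF_C": TREF_C,
        "GS_CO2_RATIO": GS_CO2_RATIO,
        "GBL_CO2_RATIO": GBL_CO2_RATIO,
        "PRESSURE_KPA": PRESSURE_KPA,
        "PAR_SATURATING": PAR_SATURATING,
        "KC25": KC25,
        "KO25": KO25,
        "GAMMASTAR25": GAMMASTAR25,
        "OI": OI,
        "ALPHA_J": ALPHA_J,
        "THETA_J": THETA_J,
        "THETA_HMIN": THETA_HMIN,
        "EA_KC": EA_KC,
        "EA_KO": EA_KO,
        "EA_GAMMASTAR": EA_GAMMASTAR,
        "EA_RD": EA_RD,
        "EA_VCMAX": EA_VCMAX,
        "HD_VCMAX": HD_VCMAX,
        "SV_VCMAX": SV_VCMAX,
        "EA_JMAX": EA_JMAX,
        "HD_JMAX": HD_JMAX,
        "SV_JMAX": SV_JMAX,
    }
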