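"""Physical constants and default medium properties.

Electrokinetic quantities are computed in SI units throughout; ionic
strengths are accepted in mol/L and converted internally.
"""

from scipy import constants as _sc

ELEMENTARY_CHARGE = _sc.elementary_charge  # C
AVOGADRO = _sc.Avogadro  # 1/mol
BOLTZMANN = _sc.Boltzmann  # J/K
VACUUM_PERMITTIVITY = _sc.epsilon_0  # F/m
FARADAY = _sc.physical_constants["Faraday constant"][0]  # C/mol

# Aqueous NaCl at room temperature: the measurement medium.
DEFAULT_TEMPERATURE_K = 298.15
DEFAULT_RELATIVE_PERMITTIVITY = 78.5
DEFAULT_VISCOSITY_PA_S = 0.89e-3
DEFAULT_VALENCE = 1

# Fixed plate-reader fluorescence gain: RFU per blank-corrected OD unit.
FLUOR_GAIN_RFU_PER_OD = 1000.0
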