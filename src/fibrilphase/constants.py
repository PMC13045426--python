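"""Physical constants and shared defaults.

All lengths in the package are nanometres, energies thermal (kT), ionic
strengths mol/L, concentrations weight percent, unless a function says
otherwise. SI constants come from scipy (CODATA).
"""

from scipy import constants as _sc

ELEMENTARY_CHARGE = _sc.e  # C
BOLTZMANN = _sc.k  # J/K
VACUUM_PERMITTIVITY = _sc.epsilon_0  # F/m
AVOGADRO = _sc.N_A  # 1/mol
EULER_GAMMA = 0.5772156649015329

#: Default working temperature, 23 degC (the electrokinetic and phase
#: measurements this package models are all performed at this temperature).
DEFAULT_TEMPERATURE_K = 296.15

#: Relative permittivity of water at 23 degC.
DEFAULT_EPS_R = 78.4

#: Dynamic viscosity of water at 23 degC, Pa*s.
WATER_VISCOSITY_23C = 0.933e-3

#: Ion product of water. Held fixed (single working temperature).
WATER_ION_PRODUCT = 1e-14

NM_PER_M = 1e9
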