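"""Physical constants and shared defaults.

Energies are kJ/mol throughout the package; temperatures kelvin; wavenumbers
cm^-1.  The coupling-parameter schedule is the 13-point grid used for all
alchemical transformations in the HSP90 study this package analyses.
"""

from scipy import constants as _sc

#: Gas constant in kJ/mol/K.
R_GAS = 8.31446e-3

#: Default simulation temperature (K) for free-energy estimation.
DEFAULT_TEMPERATURE = 300.0

#: Default temperature (K) for thermochemical (quasi-RRHO) corrections.
THERMO_TEMPERATURE = 298.15

#: 13-point coupling schedule, denser near the endpoints.
LAMBDA_SCHEDULE = (
    0.00, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50,
    0.60, 0.70, 0.80, 0.90, 0.95, 1.00,
)

#: Free-rotor damping crossover (cm^-1) for the quasi-RRHO entropy.
OMEGA0_DEFAULT = 100.0

#: Average molecular moment of inertia (kg m^2) capping the effective
#: free-rotor moment in the quasi-RRHO model.
B_AV_DEFAULT = 1.0e-44

# SI constants used by the thermochemistry code.
PLANCK = _sc.h
BOLTZMANN = _sc.k
SPEED_OF_LIGHT_CM = _sc.c * 100.0  # cm/s
AVOGADRO = _sc.N_A


def kt_kj_per_mol(temperature: float) -> float:
    """Thermal energy kT in kJ/mol at ``temperature`` kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_GAS * temperature
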