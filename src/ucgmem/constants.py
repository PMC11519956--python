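"""Physical constants and unit conversions.

Internal unit system follows the GROMACS convention: length nm, time ps,
mass amu, energy kJ/mol, temperature K.  In these units 1 amu nm^2/ps^2
equals exactly 1 kJ/mol, so kinetic energies need no conversion factor.
"""

#: Boltzmann constant, kJ/(mol K)
KB = 0.0083144621

#: Pressure conversion: 1 kJ/(mol nm^3) in bar
PRESSURE_BAR = 16.6054

#: 1 bar * nm^2 expressed in pN (1 bar = 1e5 N/m^2; 1 nm^2 = 1e-18 m^2)
BAR_NM2_TO_PN = 0.1

#: Boltzmann constant in J/K (for estimators reported in SI-derived units)
KB_SI = 1.380649e-23


def kbt(temperature: float) -> float:
    """Thermal energy kB*T in kJ/mol at `temperature` (K)."""
    return KB * temperature


def kbt_to_kjmol(value_kbt: float, temperature: float) -> float:
    """Convert an energy given in units of kB*T at `temperature` to kJ/mol."""
    return value_kbt * KB * temperature


def kjmol_to_kbt(value_kjmol: float, temperature: float) -> float:
    """Convert an energy in kJ/mol to units of kB*T at `temperature`."""
    return value_kjmol / (KB * temperature)
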