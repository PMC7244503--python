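"""Physical constants and unit conversions shared across the package.

Free energies of landscape states are expressed in units of kB*T at the
working temperature (25 degC by default); nearest-neighbour tables are kept
in kcal/mol.  A single conversion lives here so every module agrees.
"""

GAS_CONSTANT_KCAL = 1.987204258640832e-3  # kcal / (mol K)
CELSIUS_OFFSET = 273.15


def kelvin(temperature_c: float) -> float:
    """Absolute temperature for a Celsius input."""
    return temperature_c + CELSIUS_OFFSET


def kcal_to_kbt(dg_kcal_mol: float, temperature_c: float = 25.0) -> float:
    """Convert a molar free energy (kcal/mol) to units of kB*T."""
    return dg_kcal_mol / (GAS_CONSTANT_KCAL * kelvin(temperature_c))


def kbt_to_kcal(dg_kbt: float, temperature_c: float = 25.0) -> float:
    """Convert a free energy in kB*T to kcal/mol."""
    return dg_kbt * GAS_CONSTANT_KCAL * kelvin(temperature_c)
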