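"""Physical constants and unit conventions.

Internal units throughout the package: length nm, time ps, charge e,
mass g/mol, temperature K.  Potentials are handled dimensionless
(psi = e Psi / kB T) and converted to mV only at the reporting surface.
"""

from scipy import constants as _sc

#: elementary charge (C)
E_CHARGE = _sc.elementary_charge
#: Boltzmann constant (J/K)
KB = _sc.Boltzmann
#: vacuum permittivity (F/m)
EPS0 = _sc.epsilon_0

NM_PER_M = 1e9


def thermal_voltage_mv(temperature: float) -> float:
    """kB*T/e in millivolts (26.7 mV at 310 K)."""
    return KB * temperature / E_CHARGE * 1e3
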