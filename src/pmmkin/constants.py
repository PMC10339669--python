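"""Physical constants in the package unit system.

Units used throughout: energy kJ/mol, time fs, length nm, charge e,
mass amu, dipole e*nm, electric field kJ mol^-1 e^-1 nm^-1,
electric potential kJ mol^-1 e^-1.  These are the MD (GROMACS-style)
conventions with time rescaled from ps to fs, which keeps the tabulated
magnitudes of condensed-phase transition energies and gap velocities
order-one.
"""

import math

#: Reduced Planck constant, kJ mol^-1 fs.
HBAR = 63.5078

#: Planck constant, kJ mol^-1 fs.
PLANCK = 2.0 * math.pi * HBAR

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 8.31446e-3

#: 1 eV expressed in kJ/mol.
EV_TO_KJMOL = 96.48533212

#: Conversion of amu nm^2 fs^-2 to kJ/mol (1 g/mol nm^2 fs^-2 = 1e6 kJ/mol).
AMU_NM2_FS2_TO_KJMOL = 1.0e6

#: 1 Debye expressed in e*nm.
DEBYE_TO_E_NM = 3.33564095e-30 / 1.602176634e-19 * 1.0e9

# SI values used only where a rate must leave the MD unit system
# (spontaneous-emission coefficients are naturally expressed in s^-1).
E_CHARGE_SI = 1.602176634e-19       # C
AVOGADRO = 6.02214076e23            # mol^-1
PLANCK_SI = 6.62607015e-34          # J s
EPSILON0_SI = 8.8541878128e-12      # F m^-1
C_LIGHT_SI = 2.99792458e8           # m s^-1

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0


def kjmol_to_hz(energy: float) -> float:
    """Convert a transition energy in kJ/mol to a frequency in Hz."""
    return energy * 1.0e3 / (AVOGADRO * PLANCK_SI)


def kjmol_to_angular_fs(energy: float) -> float:
    """Convert a transition energy in kJ/mol to an angular frequency in fs^-1."""
    return energy / HBAR
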