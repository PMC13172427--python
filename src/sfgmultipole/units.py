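"""Internal unit system and physical constants.

The package works in MD-native units throughout:

========  =========================
length    Å (angstrom)
time      fs
charge    e (elementary charge)
mass      amu
T         K
========  =========================

Electrostatics use the *reduced Coulomb* convention k_e = 1, i.e. the field
of a point charge q at distance r is q/r² (in e/Å²) and dipoles are e·Å.
In these units the vacuum permittivity is ε0 = 1/(4π), so a response that
carries an ε0⁻¹ prefactor in SI simply acquires a factor 4π here.  The
dielectric maps ε_zz = 1/(1−s_zz) and ε_xx = 1+s_xx hold verbatim when the
reduced polarization response is defined as s ≡ 4π P / F (P = dipole
density in e/Å², F = driving amplitude in e/Å²).

Frequencies are handled on a wavenumber axis (cm⁻¹); the angular frequency
in rad/fs of a line at ν̃ cm⁻¹ is 2π·C0_CM_FS·ν̃.
"""

import numpy as np

#: speed of light in cm/fs (converts cm⁻¹ to cycles/fs)
C0_CM_FS = 2.99792458e-5

#: Boltzmann constant in amu·Å²/fs²/K (kinetic / dynamics unit system)
KB_AMU = 8.314462618e-7

#: Boltzmann constant in e²/Å/K (reduced electrostatic energy unit,
#: 1 e²/Å = e²/(4πε0·1Å) = 2.3071e-18 J)
KB_EA = 1.380649e-23 / 2.307077548e-18

#: conversion: 1 e²/Å of energy expressed in amu·Å²/fs²
EA_TO_AMU = KB_AMU / KB_EA


def wavenumber_to_angular(nu_cm: np.ndarray | float) -> np.ndarray | float:
    """Convert wavenumber (cm⁻¹) to angular frequency (rad/fs)."""
    return 2.0 * np.pi * C0_CM_FS * np.asarray(nu_cm, dtype=float)


def angular_to_wavenumber(omega: np.ndarray | float) -> np.ndarray | float:
    """Convert angular frequency (rad/fs) to wavenumber (cm⁻¹)."""
    return np.asarray(omega, dtype=float) / (2.0 * np.pi * C0_CM_FS)
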