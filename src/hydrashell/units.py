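"""Physical constants and unit conversions.

Internal units throughout the package: Å (length), fs (time), Debye (dipole),
cm⁻¹ (wavenumber), kJ·mol⁻¹ (energy), degrees (dihedral/CV angles), K
(temperature).  File dialects declare their units in headers; converters here
are the single source of truth for the factors.
"""

from __future__ import annotations

import numpy as np

#: speed of light in cm/fs — converts wavenumber (cm⁻¹) to cycles/fs
C_CM_PER_FS: float = 2.99792458e-5

#: 1 e·Å in Debye
EA_TO_DEBYE: float = 4.80320425

#: 1 Hartree in kJ/mol
HARTREE_TO_KJMOL: float = 2625.4996

#: molar gas constant in kJ/(mol·K)
R_KJMOL: float = 8.314462618e-3

#: h·c·N_A in kJ/mol per cm⁻¹ (photon energy per wavenumber)
HC_KJMOL_PER_CM: float = 11.96266e-3

#: molar mass of water, g/mol
M_WATER: float = 18.015

#: Avogadro constant, 1/mol
N_AVOGADRO: float = 6.02214076e23

#: valence charge (in units of +e) carried by each nucleus under the
#: pseudopotential convention: core electrons are pseudized, so the nucleus
#: contributes its valence-electron count as positive charge.
VALENCE_CHARGE: dict[str, int] = {"H": 1, "C": 4, "N": 5, "O": 6}

#: formal charge of one Wannier center (closed shell), units of e
CENTER_CHARGE: float = -2.0


def wavenumber_to_angular_freq(nu: float | np.ndarray) -> float | np.ndarray:
    """cm⁻¹ → angular frequency in rad/fs."""
    return 2.0 * np.pi * C_CM_PER_FS * np.asarray(nu)


def nyquist_wavenumber(dt: float) -> float:
    """Highest representable wavenumber (cm⁻¹) for sampling interval ``dt`` fs."""
    return 1.0 / (2.0 * C_CM_PER_FS * dt)


def hartree_to_kjmol(x: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(x) * HARTREE_TO_KJMOL if np.ndim(x) else float(x) * HARTREE_TO_KJMOL


def kjmol_to_hartree(x: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(x) / HARTREE_TO_KJMOL if np.ndim(x) else float(x) / HARTREE_TO_KJMOL
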