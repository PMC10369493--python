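"""Physical constants and unit conversions.

Internal unit system: lengths in nm, volumes in nm^3, energies in kJ/mol,
temperatures in K, concentrations in molecules/nm^3.  Equilibrium constants
are dimensionless, made so by the standard concentration ``c_std``.
"""

from __future__ import annotations

#: Molar gas constant, kJ/(mol K).
GAS_CONSTANT = 0.0083144626

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: 1 mol/L expressed in molecules/nm^3.
MOLAR_IN_PER_NM3 = AVOGADRO / 1e24

#: Default standard concentration c⌀ = 1 M, in molecules/nm^3.
DEFAULT_C_STD = MOLAR_IN_PER_NM3


def molar_to_number_density(c_molar: float) -> float:
    """Convert a molar concentration (mol/L) to a number density (molecules/nm^3)."""
    if c_molar < 0:
        raise ValueError(f"concentration must be non-negative, got {c_molar}")
    return c_molar * MOLAR_IN_PER_NM3


def number_density_to_molar(c: float) -> float:
    """Convert a number density (molecules/nm^3) to mol/L."""
    if c < 0:
        raise ValueError(f"concentration must be non-negative, got {c}")
    return c / MOLAR_IN_PER_NM3


def derive_box_length(n_total: int, concentration: float) -> float:
    """Edge of the cubic box holding ``n_total`` particles at a number density.

    Parameters
    ----------
    n_total : int
        Number of particles.
    concentration : float
        Number density in molecules/nm^3.

    Returns
    -------
    float
        Box edge length in nm, ``(n_total / concentration) ** (1/3)``.
    """
    if n_total <= 0:
        raise ValueError(f"n_total must be positive, got {n_total}")
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    return (n_total / concentration) ** (1.0 / 3.0)
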