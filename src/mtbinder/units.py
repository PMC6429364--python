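"""Physical constants and unit helpers (Å, e, kcal/mol, kT/e)."""

import math

#: Coulomb constant in kcal·Å/(mol·e²): E = K_COULOMB * q1*q2 / (eps * r).
K_COULOMB = 332.0636

#: Boltzmann constant in kcal/(mol·K).
K_BOLTZMANN = 0.0019872041

#: Avogadro's number (1/mol).
N_AVOGADRO = 6.02214076e23


def kt_kcal(temperature: float = 300.0) -> float:
    """Thermal energy kT in kcal/mol at ``temperature`` (K)."""
    return K_BOLTZMANN * temperature


def coulomb_prefactor_kt_e(temperature: float = 300.0) -> float:
    """Coulomb prefactor so that phi(r) = C*q/(eps*r) is in kT/e.

    Equals e²/(4·pi·eps0·kB·T) expressed in Å; ~557 Å at 300 K.
    """
    return K_COULOMB / kt_kcal(temperature)


def bjerrum_length(eps: float = 80.0, temperature: float = 300.0) -> float:
    """Bjerrum length in Å for relative dielectric ``eps``."""
    return coulomb_prefactor_kt_e(temperature) / eps


def debye_kappa(ionic_strength: float, eps: float = 80.0,
                temperature: float = 300.0) -> float:
    """Inverse Debye length kappa (1/Å) for a 1:1 salt.

    Parameters
    ----------
    ionic_strength : molar ionic strength I (mol/L).
    eps : solvent relative dielectric constant.
    temperature : K.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0:
        return 0.0
    # number density of each ion species in 1/Å^3
    n = N_AVOGADRO * ionic_strength * 1e-27
    kappa_sq = 8.0 * math.pi * bjerrum_length(eps, temperature) * n
    return math.sqrt(kappa_sq)
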