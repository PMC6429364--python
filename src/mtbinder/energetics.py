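"""Molecular-mechanics / generalized-Born energies and the rigid-body
binding-energy protocol.

The MM/GB energy of a structure is ``E = E_elec + E_VDW`` where ``E_elec``
is the Coulomb term plus the GB polarization term (Still's pairwise
function with Debye-screened solvent) and ``E_VDW`` is a 12-6
Lennard-Jones sum.  Binding energies follow the rigid-body protocol:
``ΔE = E(complex) − E(part A) − E(part B)`` with all three evaluated at
identical, unrelaxed coordinates, so ΔE reflects interaction (including
the change in solvent descreening) only.

Effective Born radii use Hawkins–Cramer–Truhlar pairwise descreening with
a 12 Å interaction cutoff.  Absolute solvation energies are flavour-
dependent; the quantities of interest here are Eq-structure identities and
with-tails vs without-tails contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structures import Structure
from .synthetic import Ensemble
from .units import K_COULOMB, debye_kappa

__all__ = [
    "ForceFieldParams", "EnergyComponents", "EnergyBreakdown",
    "coulomb_energy", "born_radii", "gb_energy", "lj_energy",
    "mm_gb_energy", "binding_energy", "binding_energy_from_components",
    "ensemble_binding_energy",
]

_MIN_R = 1e-6


@dataclass(frozen=True)
class ForceFieldParams:
    """Nonbonded parameters for pseudo-atom systems.

    Per-atom charges and intrinsic (Born/vdW) radii come from the
    Structure; a single generic Lennard-Jones type is used unless per-atom
    tables are supplied externally.  ``eps_solute`` is the reference
    dielectric of the Coulomb and GB vacuum state (standard MM/GB uses 1);
    ``eps_solvent`` = 80; ``kappa`` is derived from the ionic strength.
    """

    eps_solute: float = 1.0
    eps_solvent: float = 80.0
    ionic_strength: float = 0.15     # mol/L
    temperature: float = 300.0       # K
    born_cutoff: float = 12.0        # Å, descreening interaction cutoff
    hct_screen: float = 0.72         # HCT screening factor on descreener radii
    lj_epsilon: float = 0.4          # kcal/mol, generic residue-bead type
    lj_rmin: float = 4.0             # Å, generic type (pair minimum = rmin)

    def __post_init__(self):
        if self.born_cutoff <= 0:
            raise ValueError("born_cutoff must be > 0")
        if self.eps_solute <= 0 or self.eps_solvent <= 0:
            raise ValueError("dielectrics must be > 0")

    @property
    def kappa(self) -> float:
        return debye_kappa(self.ionic_strength, self.eps_solvent,
                           self.temperature)


@dataclass(frozen=True)
class EnergyComponents:
    """MM/GB energy terms (kcal/mol); E_MM_GB = E_elec + E_VDW exactly."""

    E_elec: float
    E_VDW: float

    @property
    def E_MM_GB(self) -> float:
        return self.E_elec + self.E_VDW


@dataclass(frozen=True)
class EnergyBreakdown:
    """Rigid-body binding decomposition: ΔE = E_complex − E_MTBD − E_MT."""

    E_complex: float
    E_MTBD: float
    E_MT: float
    n_snapshots: int = 1
    sd: float = 0.0

    @property
    def dE_binding(self) -> float:
        return self.E_complex - self.E_MTBD - self.E_MT


def binding_energy_from_components(e_complex: float, e_mtbd: float,
                                   e_mt: float) -> float:
    """The binding-energy identity ΔE = E_complex − E_MTBD − E_MT."""
    return EnergyBreakdown(e_complex, e_mtbd, e_mt).dE_binding


# ---------------------------------------------------------------------------
# Pairwise terms
# ---------------------------------------------------------------------------

def _pair_arrays(s: Structure, group_a=None, group_b=None):
    """(i, j, r) arrays for all relevant pairs: i<j pairs of the whole
    structure, or cross pairs only when two groups are given."""
    coords = s.coords
    if group_a is None and group_b is None:
        i, j = np.triu_indices(s.n_atoms, k=1)
    elif group_a is not None and group_b is not None:
        ia = np.asarray(group_a, dtype=int)
        ib = np.asarray(group_b, dtype=int)
        if np.intersect1d(ia, ib).size:
            raise ValueError("groups overlap")
        i, j = np.meshgrid(ia, ib, indexing="ij")
        i, j = i.ravel(), j.ravel()
    else:
        raise ValueError("give both groups or neither")
    r = np.linalg.norm(coords[i] - coords[j], axis=1)
    return i, j, r


def coulomb_energy(s: Structure, params: ForceFieldParams | None = None,
                   group_a=None, group_b=None) -> float:
    """Σ k·q_i·q_j / (ε_solute·r_ij) over pairs, no distance cutoff."""
    if params is None:
        params = ForceFieldParams()
    i, j, r = _pair_arrays(s, group_a, group_b)
    if len(r) == 0:
        return 0.0
    if r.min() < _MIN_R:
        raise ValueError("overlapping atoms in Coulomb sum")
    q = s.charges
    return float(K_COULOMB * np.sum(q[i] * q[j] / r) / params.eps_solute)


def _hct_descreen(r: float, rho_i: float, rho_j: float) -> float:
    """HCT pairwise descreening integral of atom j on atom i.

    Equals (1/4π)∫ dV/s⁴ over the part of sphere j lying outside the
    intrinsic sphere of i; subtracting the sum over neighbours from 1/ρ_i
    gives the inverse effective Born radius.
    """
    if r + rho_j <= rho_i:
        return 0.0
    U = r + rho_j
    L = max(rho_i, abs(r - rho_j))
    term = ((1.0 / L - 1.0 / U)
            + (r / 4.0) * (1.0 / U ** 2 - 1.0 / L ** 2)
            + (1.0 / (2.0 * r)) * math.log(L / U)
            + (rho_j ** 2 / (4.0 * r)) * (1.0 / L ** 2 - 1.0 / U ** 2))
    if rho_i < rho_j - r:
        term += 2.0 * (1.0 / rho_i - 1.0 / L)
    return 0.5 * term


def born_radii(s: Structure, params: ForceFieldParams | None = None
               ) -> np.ndarray:
    """Per-atom effective Born radii (Å), HCT pairwise descreening.

    Pairs beyond the 12 Å cutoff are excluded.  An isolated atom keeps its
    intrinsic radius; burial only increases the effective radius.
    """
    if params is None:
        params = ForceFieldParams()
    inv = 1.0 / s.radii.copy()
    tree = cKDTree(s.coords)
    pairs = tree.query_pairs(r=params.born_cutoff, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        r = np.linalg.norm(s.coords[i] - s.coords[j], axis=1)
        sc = params.hct_screen
        np.subtract.at(inv, i,
                       _hct_descreen_vec(r, s.radii[i], sc * s.radii[j]))
        np.subtract.at(inv, j,
                       _hct_descreen_vec(r, s.radii[j], sc * s.radii[i]))
    # deeply buried atoms can overshoot; clamp to a large finite radius
    inv = np.maximum(inv, 1e-3)
    radii = 1.0 / inv
    return np.maximum(radii, s.radii)


def _hct_descreen_vec(r: np.ndarray, rho_i: np.ndarray,
                      rho_j: np.ndarray) -> np.ndarray:
    """Vectorised :func:`_hct_descreen` over pair arrays."""
    U = r + rho_j
    L = np.maximum(rho_i, np.abs(r - rho_j))
    term = ((1.0 / L - 1.0 / U)
            + (r / 4.0) * (1.0 / U ** 2 - 1.0 / L ** 2)
            + (1.0 / (2.0 * r)) * np.log(L / U)
            + (rho_j ** 2 / (4.0 * r)) * (1.0 / L ** 2 - 1.0 / U ** 2))
    term = term + np.where(rho_i < rho_j - r,
                           2.0 * (1.0 / rho_i - 1.0 / L), 0.0)
    return np.where(r + rho_j <= rho_i, 0.0, 0.5 * term)


def gb_energy(s: Structure, params: ForceFieldParams | None = None,
              radii: np.ndarray | None = None) -> float:
    """Generalized-Born polarization energy with Debye screening (kcal/mol).

    E = −(k/2)·Σ_{i,j} (1/ε_in − e^{−κ·f_ij}/ε_out)·q_i·q_j / f_ij with
    Still's f_ij = √(r² + R_i·R_j·e^{−r²/(4·R_i·R_j)}); the i = j self term
    (f = R_i) is included.
    """
    if params is None:
        params = ForceFieldParams()
    q = s.charges
    if not np.any(q):
        return 0.0
    if radii is None:
        radii = born_radii(s, params)
    r2 = ((s.coords[:, None] - s.coords[None]) ** 2).sum(axis=-1)
    RiRj = radii[:, None] * radii[None]
    f = np.sqrt(r2 + RiRj * np.exp(-r2 / (4.0 * RiRj)))
    screen = (1.0 / params.eps_solute
              - np.exp(-params.kappa * f) / params.eps_solvent)
    qq = q[:, None] * q[None]
    return float(-(K_COULOMB / 2.0) * np.sum(screen * qq / f))


def lj_energy(s: Structure, params: ForceFieldParams | None = None,
              group_a=None, group_b=None) -> float:
    """12-6 Lennard-Jones energy: Σ ε[(r_min/r)¹² − 2(r_min/r)⁶].

    With two groups given only cross-group pairs are summed
    (Lorentz–Berthelot combination reduces to the generic single type).
    """
    if params is None:
        params = ForceFieldParams()
    i, j, r = _pair_arrays(s, group_a, group_b)
    if len(r) == 0:
        return 0.0
    if r.min() < _MIN_R:
        raise ValueError("overlapping atoms in LJ sum")
    x = (params.lj_rmin / r) ** 6
    return float(params.lj_epsilon * np.sum(x * x - 2.0 * x))


def mm_gb_energy(s: Structure, params: ForceFieldParams | None = None
                 ) -> EnergyComponents:
    """Total MM/GB energy of a structure: (Coulomb + GB) + LJ."""
    if params is None:
        params = ForceFieldParams()
    e_coul = coulomb_energy(s, params)
    e_gb = gb_energy(s, params)
    e_lj = lj_energy(s, params)
    return EnergyComponents(E_elec=e_coul + e_gb, E_VDW=e_lj)


# ---------------------------------------------------------------------------
# Binding protocol
# ---------------------------------------------------------------------------

def binding_energy(complex_: Structure, part_a_group: str = "binder",
                   part_b_group=None,
                   params: ForceFieldParams | None = None) -> EnergyBreakdown:
    """Rigid-body ΔE = E(complex) − E(A) − E(B) at fixed coordinates.

    ``part_b_group`` defaults to the complement of part A.  The two parts
    must not overlap; Born radii are recomputed for each isolated part, so
    ΔE includes the descreening change on association.
    """
    if params is None:
        params = ForceFieldParams()
    ia = complex_.group_indices(part_a_group)
    if part_b_group is None:
        ib = np.setdiff1d(np.arange(complex_.n_atoms), ia)
    else:
        ib = complex_.group_indices(part_b_group)
    if np.intersect1d(ia, ib).size:
        raise ValueError("binding parts overlap")
    e_cplx = mm_gb_energy(complex_, params).E_MM_GB
    e_a = mm_gb_energy(complex_.select(ia), params).E_MM_GB
    e_b = mm_gb_energy(complex_.select(ib), params).E_MM_GB
    return EnergyBreakdown(E_complex=e_cplx, E_MTBD=e_a, E_MT=e_b)


def ensemble_binding_energy(e: Ensemble, contact_counts: np.ndarray,
                            params: ForceFieldParams | None = None,
                            strip_tails: bool = False,
                            part_a_group: str = "binder",
                            tails_group: str = "tails",
                            max_snapshots: int | None = None,
                            frame_indices: np.ndarray | None = None
                            ) -> EnergyBreakdown:
    """Mean ± SD rigid-body binding energy over contact-bearing snapshots.

    ``contact_counts`` gives the per-frame contact count for the frames in
    ``frame_indices`` (default: all frames of the ensemble); frames with at
    least one contact are selected.  With ``strip_tails`` the tail atoms are
    deleted from both the complex and the parts at fixed coordinates before
    the energies are evaluated.  The SD is the population SD over the
    selected snapshots.
    """
    if params is None:
        params = ForceFieldParams()
    if frame_indices is None:
        frame_indices = np.arange(e.n_frames)
    frame_indices = np.asarray(frame_indices, dtype=int)
    contact_counts = np.asarray(contact_counts)
    if len(contact_counts) != len(frame_indices):
        raise ValueError("contact_counts / frame_indices length mismatch")
    selected = frame_indices[contact_counts >= 1]
    if selected.size == 0:
        raise ValueError(
            f"no contact-bearing snapshots among {len(frame_indices)} frames "
            f"(max count {int(contact_counts.max()) if len(contact_counts) else 0})")
    if max_snapshots is not None and selected.size > max_snapshots:
        # deterministic even stride through the selected snapshots
        stride = np.linspace(0, selected.size - 1, max_snapshots).astype(int)
        selected = selected[np.unique(stride)]

    topo = e.topology
    keep = np.arange(topo.n_atoms)
    if strip_tails:
        keep = np.setdiff1d(keep, topo.group_indices(tails_group))
    sub = topo.select(keep)

    des = []
    e_c = e_a = e_b = 0.0
    for f in selected:
        sub.coords = e.frames[f][keep]
        bd = binding_energy(sub, part_a_group, None, params)
        des.append(bd.dE_binding)
        e_c += bd.E_complex
        e_a += bd.E_MTBD
        e_b += bd.E_MT
    n = len(des)
    return EnergyBreakdown(
        E_complex=e_c / n, E_MTBD=e_a / n, E_MT=e_b / n,
        n_snapshots=n, sd=float(np.std(des)),
    )
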