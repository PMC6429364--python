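"""Finite-difference linearized Poisson–Boltzmann electrostatics.

Solves ∇·(ε∇φ) − ε_out·κ²·φ = −4π·C·ρ on a cubic lattice with a
two-dielectric solute/solvent model (probe-inflated atom spheres define the
solute interior) and Debye ionic screening restricted to the solvent
region.  Potentials are reported in kT/e at 300 K; C = e²/(4πε₀kT)
(≈ 557 Å) makes the analytic point-charge solution φ = C·q·e^{−κr}/(ε·r).

Grid sizing follows the DelPhi conventions: ``scale`` grid points per Å and
``perfil``, the percentage of the grid's linear dimension occupied by the
solute's longest dimension.  Boundary potentials are assigned from a
Debye-screened Coulomb sum over all charges; the interior is solved with a
preconditioned conjugate-gradient iteration on the 7-point stencil.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg
from scipy.interpolate import RegularGridInterpolator

from .structures import Structure
from .units import coulomb_prefactor_kt_e, debye_kappa

__all__ = [
    "PBEParams", "PotentialGrid", "FieldLine",
    "solve_lpbe", "surface_potential", "trace_field_lines",
    "interface_charge_asymmetry",
]


@dataclass(frozen=True)
class PBEParams:
    """Solver parameters (DelPhi-style defaults: 2 grids/Å, perfil 70,
    ε 2/80, I = 0.15 M, 1.4 Å probe)."""

    scale: float = 2.0            # grid points per Å
    perfil: float = 70.0          # % of grid spanned by the solute
    eps_in: float = 2.0
    eps_out: float = 80.0
    ionic_strength: float = 0.15  # mol/L
    temperature: float = 300.0
    probe_radius: float = 1.4     # Å, dielectric-surface inflation
    max_iter: int = 2000
    tol: float = 1e-8             # relative residual target
    min_box: float = 0.0          # Å, optional lower bound on the box edge

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if not 0 < self.perfil <= 100:
            raise ValueError("perfil must be in (0, 100]")
        if self.eps_in <= 0 or self.eps_out <= 0:
            raise ValueError("dielectrics must be > 0")

    @property
    def kappa(self) -> float:
        return debye_kappa(self.ionic_strength, self.eps_out,
                           self.temperature)


@dataclass
class PotentialGrid:
    """Cubic lattice of electrostatic potential in kT/e."""

    origin: np.ndarray
    spacing: float
    phi: np.ndarray                  # (nx, ny, nz)
    eps: np.ndarray | None = None    # node dielectric map
    kappa_sq: np.ndarray | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("non-finite potential values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.phi.shape

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[d] + self.spacing * np.arange(self.dims[d])
                     for d in range(3))

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        lo = self.origin
        hi = self.origin + self.spacing * (np.array(self.dims) - 1)
        return np.all((points >= lo) & (points <= hi), axis=1)

    def interpolator(self, values: np.ndarray | None = None,
                     ) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            self.axes, self.phi if values is None else values,
            method="linear", bounds_error=True)

    def potential_at(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of φ at Cartesian points (kT/e)."""
        return self.interpolator()(np.atleast_2d(points))

    def field_interpolators(self) -> list[RegularGridInterpolator]:
        """Interpolators for E = −∇φ (kT/e/Å), centred differences."""
        grads = np.gradient(self.phi, self.spacing)
        return [RegularGridInterpolator(self.axes, -g, method="linear",
                                        bounds_error=True) for g in grads]


@dataclass
class FieldLine:
    """A traced electrostatic field line."""

    points: np.ndarray
    seed: np.ndarray
    termination: str  # "sink", "boundary", "low_field", or "max_steps"


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

def _grid_geometry(s: Structure, p: PBEParams):
    lo = (s.coords - s.radii[:, None]).min(axis=0)
    hi = (s.coords + s.radii[:, None]).max(axis=0)
    longest = float((hi - lo).max())
    box = max(longest / (p.perfil / 100.0), p.min_box)
    if p.min_box and p.min_box < longest:
        warnings.warn("requested box smaller than the solute; expanding")
    h = 1.0 / p.scale
    n = int(np.ceil(box / h)) + 1
    if n % 2 == 0:
        n += 1
    center = 0.5 * (lo + hi)
    origin = center - 0.5 * (n - 1) * h
    return origin, h, n


def _spread_charges(s: Structure, origin, h, n) -> np.ndarray:
    """Trilinear assignment of each charge to its 8 surrounding nodes."""
    q_grid = np.zeros((n, n, n))
    frac = (s.coords - origin) / h
    base = np.floor(frac).astype(int)
    if np.any(base < 0) or np.any(base >= n - 1):
        raise ValueError("charge outside grid")
    w = frac - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wt = (np.where(dx, w[:, 0], 1 - w[:, 0])
                      * np.where(dy, w[:, 1], 1 - w[:, 1])
                      * np.where(dz, w[:, 2], 1 - w[:, 2]))
                np.add.at(q_grid,
                          (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz),
                          s.charges * wt)
    return q_grid


def _dielectric_maps(s: Structure, p: PBEParams, origin, h, n):
    """Node ε map (solute interior ε_in) and solvent κ² map."""
    axes = [origin[d] + h * np.arange(n) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)
    solute = np.zeros((n, n, n), dtype=bool)
    inflate = s.radii + p.probe_radius
    for c, r in zip(s.coords, inflate):
        # only touch the subgrid around the atom
        i0 = np.maximum(((c - r - origin) / h).astype(int), 0)
        i1 = np.minimum(((c + r - origin) / h).astype(int) + 2, n)
        xs = axes[0][i0[0]:i1[0]][:, None, None]
        ys = axes[1][i0[1]:i1[1]][None, :, None]
        zs = axes[2][i0[2]:i1[2]][None, None, :]
        d2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2
        solute[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= r * r
    eps = np.where(solute, p.eps_in, p.eps_out)
    kappa_sq = np.where(solute, 0.0, p.eps_out * p.kappa ** 2)
    return eps, kappa_sq


def _boundary_phi(s: Structure, p: PBEParams, origin, h, n) -> np.ndarray:
    """Debye-screened Coulomb monopole sum on all six grid faces."""
    C = coulomb_prefactor_kt_e(p.temperature)
    phi = np.zeros((n, n, n))
    axes = [origin[d] + h * np.arange(n) for d in range(3)]
    mask = np.zeros((n, n, n), dtype=bool)
    mask[0], mask[-1] = True, True
    mask[:, 0], mask[:, -1] = True, True
    mask[:, :, 0], mask[:, :, -1] = True, True
    pts = np.argwhere(mask)
    coords = origin + pts * h
    charged = np.abs(s.charges) > 0
    vals = np.zeros(len(pts))
    for qc, q in zip(s.coords[charged], s.charges[charged]):
        r = np.linalg.norm(coords - qc, axis=1)
        r = np.maximum(r, 1e-9)
        vals += C * q * np.exp(-p.kappa * r) / (p.eps_out * r)
    phi[mask] = vals
    return phi


def solve_lpbe(s: Structure, params: PBEParams | None = None) -> PotentialGrid:
    """Solve the linearized PBE for a charged structure.

    Returns the potential grid in kT/e.  Raises if the conjugate-gradient
    iteration does not reach the residual tolerance within ``max_iter``.
    """
    if params is None:
        params = PBEParams()
    origin, h, n = _grid_geometry(s, params)
    eps, kappa_sq = _dielectric_maps(s, params, origin, h, n)
    q_grid = _spread_charges(s, origin, h, n)
    phi_b = _boundary_phi(s, params, origin, h, n)

    if not np.any(np.abs(s.charges) > 0):
        return PotentialGrid(origin=origin, spacing=h,
                             phi=np.zeros((n, n, n)),
                             eps=eps, kappa_sq=kappa_sq)

    C = coulomb_prefactor_kt_e(params.temperature)
    interior = np.zeros((n, n, n), dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    idx = -np.ones((n, n, n), dtype=np.int64)
    n_int = int(interior.sum())
    idx[interior] = np.arange(n_int)

    # face dielectrics (harmonic mean of adjacent nodes) along each axis
    faces = [2.0 * eps[:-1] * eps[1:] / (eps[:-1] + eps[1:]),
             2.0 * eps[:, :-1] * eps[:, 1:] / (eps[:, :-1] + eps[:, 1:]),
             2.0 * eps[:, :, :-1] * eps[:, :, 1:]
             / (eps[:, :, :-1] + eps[:, :, 1:])]

    rows, cols, vals = [], [], []
    rhs = 4.0 * np.pi * C * q_grid[interior] / h
    diag = kappa_sq[interior] * h * h
    offsets = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0),
               (0, 0, -1), (0, 0, 1)]
    ii, jj, kk = np.where(interior)
    my = idx[interior]
    for di, dj, dk in offsets:
        ni_, nj_, nk_ = ii + di, jj + dj, kk + dk
        axis = 0 if di else (1 if dj else 2)
        fi = np.minimum(ii, ni_) if axis == 0 else ii
        fj = np.minimum(jj, nj_) if axis == 1 else jj
        fk = np.minimum(kk, nk_) if axis == 2 else kk
        w = faces[axis][fi, fj, fk]
        diag += w
        nb = idx[ni_, nj_, nk_]
        inside = nb >= 0
        rows.append(my[inside])
        cols.append(nb[inside])
        vals.append(-w[inside])
        # boundary neighbours go to the RHS (Dirichlet condition)
        rhs[~inside] += w[~inside] * phi_b[ni_[~inside], nj_[~inside],
                                           nk_[~inside]]
    rows.append(my)
    cols.append(my)
    vals.append(diag)
    A = sparse.csr_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_int, n_int))
    M = sparse.diags(1.0 / A.diagonal())
    x, info = cg(A, rhs, rtol=params.tol, atol=0.0,
                 maxiter=params.max_iter, M=M)
    if info != 0:
        res = float(np.abs(A @ x - rhs).max())
        raise RuntimeError(f"LPBE solver did not converge in "
                           f"{params.max_iter} iterations "
                           f"(max residual {res:.3e})")
    phi = phi_b.copy()
    phi[interior] = x
    return PotentialGrid(origin=origin, spacing=h, phi=phi,
                         eps=eps, kappa_sq=kappa_sq)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

_SPHERE_CACHE: dict[int, np.ndarray] = {}


def _unit_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden
    spiral)."""
    if n_points not in _SPHERE_CACHE:
        k = np.arange(n_points) + 0.5
        phi_ang = np.arccos(1 - 2 * k / n_points)
        theta = np.pi * (1 + 5 ** 0.5) * k
        _SPHERE_CACHE[n_points] = np.stack([
            np.sin(phi_ang) * np.cos(theta),
            np.sin(phi_ang) * np.sin(theta),
            np.cos(phi_ang)], axis=1)
    return _SPHERE_CACHE[n_points]


def surface_potential(grid: PotentialGrid, s: Structure,
                      n_points: int = 42) -> np.ndarray:
    """Mean potential (kT/e) sampled on each atom's solvent-exposed surface.

    Points on each atom's sphere that fall inside another atom are
    discarded; buried atoms (no exposed points) get NaN.  Raises if any
    atom lies outside the grid.
    """
    if not np.all(grid.contains(s.coords)):
        raise ValueError("atom outside potential grid")
    interp = grid.interpolator()
    sphere = _unit_sphere(n_points)
    out = np.full(s.n_atoms, np.nan)
    for i in range(s.n_atoms):
        pts = s.coords[i] + s.radii[i] * sphere
        exposed = np.ones(len(pts), dtype=bool)
        for j in range(s.n_atoms):
            if j == i:
                continue
            d = np.linalg.norm(pts - s.coords[j], axis=1)
            exposed &= d > s.radii[j]
            if not exposed.any():
                break
        if not exposed.any():
            continue
        pts = pts[exposed]
        ok = grid.contains(pts)
        if ok.any():
            out[i] = float(interp(pts[ok]).mean())
    return out


def trace_field_lines(grid: PotentialGrid, seeds: np.ndarray,
                      step: float = 0.5, max_steps: int = 2000,
                      e_min: float = 1e-4,
                      sink_points: np.ndarray | None = None,
                      sink_radius: float = 1.5) -> list[FieldLine]:
    """Streamlines of E = −∇φ traced with 4th-order Runge–Kutta.

    Each seed is integrated in both field directions; lines terminate on
    the grid boundary, where |E| < ``e_min``, within ``sink_radius`` of a
    sink point (charge site), or after ``max_steps``.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if not np.all(grid.contains(seeds)):
        raise ValueError("seed outside potential grid")
    interps = grid.field_interpolators()

    def field(p):
        return np.array([f(p[None])[0] for f in interps])

    def near_sink(p):
        if sink_points is None or len(sink_points) == 0:
            return False
        return bool(np.min(np.linalg.norm(sink_points - p, axis=1))
                    <= sink_radius)

    lines: list[FieldLine] = []
    for seed in seeds:
        for sign in (+1.0, -1.0):
            pts = [seed.copy()]
            reason = "max_steps"
            p = seed.copy()
            for _ in range(max_steps):
                try:
                    k1 = field(p)
                    if np.linalg.norm(k1) < e_min:
                        reason = "low_field"
                        break
                    d1 = sign * k1 / np.linalg.norm(k1)
                    k2 = field(p + 0.5 * step * d1)
                    d2 = sign * k2 / max(np.linalg.norm(k2), 1e-30)
                    k3 = field(p + 0.5 * step * d2)
                    d3 = sign * k3 / max(np.linalg.norm(k3), 1e-30)
                    k4 = field(p + step * d3)
                    d4 = sign * k4 / max(np.linalg.norm(k4), 1e-30)
                    p = p + (step / 6.0) * (d1 + 2 * d2 + 2 * d3 + d4)
                except ValueError:
                    reason = "boundary"
                    break
                if not grid.contains(p[None])[0]:
                    reason = "boundary"
                    break
                pts.append(p.copy())
                if near_sink(p):
                    reason = "sink"
                    break
            lines.append(FieldLine(points=np.array(pts), seed=seed.copy(),
                                   termination=reason))
    return lines


def interface_charge_asymmetry(s: Structure,
                               plane_point,
                               plane_normal,
                               slab_half_width: float = 10.0) -> float:
    """Fraction of the positive charge lying within ``slab_half_width`` Å of
    the interface plane."""
    plane_point = np.asarray(plane_point, dtype=float)
    normal = np.asarray(plane_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    pos = s.charges > 0
    if not pos.any():
        raise ValueError("structure has no positive charges")
    dist = np.abs((s.coords[pos] - plane_point) @ normal)
    total = s.charges[pos].sum()
    return float(s.charges[pos][dist <= slab_half_width].sum() / total)
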