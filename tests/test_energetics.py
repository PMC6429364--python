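import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mtbinder.datasets import BINDING_ENERGY_ROWS
from mtbinder.energetics import (EnergyBreakdown, EnergyComponents,
                                 ForceFieldParams, binding_energy,
                                 binding_energy_from_components, born_radii,
                                 coulomb_energy, ensemble_binding_energy,
                                 gb_energy, lj_energy, mm_gb_energy)
from mtbinder.structures import apply_transform
from mtbinder.synthetic import (Ensemble, SyntheticSystemSpec,
                                generate_ensemble, generate_system)
from mtbinder.contacts import build_contact_table
from mtbinder.units import K_COULOMB

from conftest import make_structure

VACUUM = ForceFieldParams(eps_solute=1.0)


# ---------------------------------------------------------------------------
# Coulomb
# ---------------------------------------------------------------------------

def test_unit_charges_at_1A():
    s = make_structure([[0, 0, 0], [1, 0, 0]], charges=[1.0, 1.0])
    assert coulomb_energy(s, VACUUM) == pytest.approx(332.0636)


def test_coulomb_vanishes_at_large_separation():
    s = make_structure([[0, 0, 0], [1e6, 0, 0]], charges=[1.0, -1.0])
    assert abs(coulomb_energy(s, VACUUM)) < 1e-3


def test_coulomb_double_loop_oracle():
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 15, size=(20, 3))
    charges = rng.uniform(-1, 1, size=20)
    s = make_structure(coords, charges=charges)
    expected = 0.0
    for i in range(20):
        for j in range(i + 1, 20):
            r = np.linalg.norm(coords[i] - coords[j])
            expected += K_COULOMB * charges[i] * charges[j] / r
    assert coulomb_energy(s, VACUUM) == pytest.approx(expected, abs=1e-9)


def test_overlapping_atoms_error():
    s = make_structure([[0, 0, 0], [0, 0, 0]], charges=[1.0, 1.0])
    with pytest.raises(ValueError):
        coulomb_energy(s, VACUUM)


# ---------------------------------------------------------------------------
# Born radii (HCT descreening)
# ---------------------------------------------------------------------------

def _descreen_integral_oracle(r, rho_i, rho_j, n=400):
    """Numerical (1/4π)∫ dV/s⁴ over the descreener sphere, excluding the
    region inside the intrinsic sphere of atom i."""
    # spherical shells around atom j
    radii = np.linspace(1e-4, rho_j, n, endpoint=False) + rho_j / (2 * n)
    mu = np.linspace(-1, 1, n, endpoint=False) + 1.0 / n
    total = 0.0
    dr = rho_j / n
    dmu = 2.0 / n
    for a in radii:
        # distance from atom i to a point at shell radius a, cos angle mu
        s2 = r * r + a * a - 2 * r * a * mu
        inside_i = s2 < rho_i * rho_i
        integrand = np.where(inside_i, 0.0, 1.0 / np.maximum(s2, 1e-12) ** 2)
        total += (integrand.sum() * dmu) * a * a * dr
    return 0.5 * total  # (2π/4π) × ∫


def test_isolated_atom_keeps_intrinsic_radius():
    s = make_structure([[0, 0, 0]], charges=[1.0], radii=[2.0])
    np.testing.assert_allclose(born_radii(s), [2.0])


def test_two_atom_hct_matches_numerical_integral():
    params = ForceFieldParams(hct_screen=1.0)  # unscaled for the oracle
    r, rho = 4.0, 1.8
    s = make_structure([[0, 0, 0], [r, 0, 0]], radii=[2.0, rho])
    eff = born_radii(s, params)
    oracle = _descreen_integral_oracle(r, 2.0, rho)
    expected = 1.0 / (1.0 / 2.0 - oracle)
    assert eff[0] == pytest.approx(expected, rel=1e-3)


def test_burial_increases_effective_radius():
    centre = make_structure([[0, 0, 0]], radii=[2.0])
    assert born_radii(centre)[0] == pytest.approx(2.0)
    # surround with a shell of neighbours
    shell = [[5 * np.sin(t) * np.cos(p), 5 * np.sin(t) * np.sin(p),
              5 * np.cos(t)]
             for t in np.linspace(0.3, np.pi - 0.3, 4)
             for p in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
    s = make_structure([[0, 0, 0]] + shell)
    eff = born_radii(s)
    assert eff[0] > 2.0
    # a denser shell buries deeper
    shell2 = shell + [[7.0, 0, 0], [-7.0, 0, 0], [0, 7.0, 0]]
    eff2 = born_radii(make_structure([[0, 0, 0]] + shell2))
    assert eff2[0] > eff[0]


def test_pairs_beyond_cutoff_excluded():
    s = make_structure([[0, 0, 0], [12.5, 0, 0]], radii=[2.0, 2.0])
    np.testing.assert_allclose(born_radii(s), [2.0, 2.0])


# ---------------------------------------------------------------------------
# GB energy
# ---------------------------------------------------------------------------

def _born_ion(q, R, eps_out, kappa=0.0):
    return -(K_COULOMB / 2.0) * (1.0 - np.exp(-kappa * R) / eps_out) \
        * q * q / R


@pytest.mark.parametrize("q,R,eps_out", [
    (1.0, 2.0, 80.0), (-2.0, 1.5, 80.0), (1.0, 3.0, 4.0),
])
def test_single_ion_matches_born_closed_form(q, R, eps_out):
    s = make_structure([[0, 0, 0]], charges=[q], radii=[R])
    params = ForceFieldParams(eps_solute=1.0, eps_solvent=eps_out,
                              ionic_strength=0.0)
    expected = -(K_COULOMB / 2.0) * (1.0 - 1.0 / eps_out) * q * q / R
    assert gb_energy(s, params) == pytest.approx(expected, abs=1e-9)


def test_born_ion_worked_example():
    # q=1, R=2 Å, ε 1→80, κ=0:  −(332.0636/2)(1−1/80)/2 = −81.98 kcal/mol
    s = make_structure([[0, 0, 0]], charges=[1.0], radii=[2.0])
    params = ForceFieldParams(ionic_strength=0.0)
    assert gb_energy(s, params) == pytest.approx(-81.978, abs=1e-2)


def test_zero_charges_zero_energy():
    s = make_structure(np.random.default_rng(0).normal(size=(5, 3)))
    assert gb_energy(s) == 0.0


def test_two_charge_gb_formula_oracle():
    coords = np.array([[0, 0, 0], [4.0, 0, 0]])
    q = np.array([0.6, -0.9])
    s = make_structure(coords, charges=q, radii=[2.0, 1.7])
    params = ForceFieldParams(ionic_strength=0.15)
    R = born_radii(s, params)
    kappa = params.kappa
    # independent evaluation of Still's sum, spelled out term by term
    expected = 0.0
    for i in range(2):
        for j in range(2):
            r2 = np.sum((coords[i] - coords[j]) ** 2)
            f = np.sqrt(r2 + R[i] * R[j]
                        * np.exp(-r2 / (4 * R[i] * R[j])))
            expected += (-(K_COULOMB / 2.0)
                         * (1.0 - np.exp(-kappa * f) / 80.0)
                         * q[i] * q[j] / f)
    assert gb_energy(s, params) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# Lennard-Jones
# ---------------------------------------------------------------------------

def test_pair_at_rmin_gives_minus_epsilon():
    p = ForceFieldParams()
    s = make_structure([[0, 0, 0], [p.lj_rmin, 0, 0]])
    assert lj_energy(s, p) == pytest.approx(-p.lj_epsilon)


def test_lj_vanishes_at_infinity():
    s = make_structure([[0, 0, 0], [1e5, 0, 0]])
    assert abs(lj_energy(s)) < 1e-12


def test_lj_double_loop_oracle():
    rng = np.random.default_rng(1)
    coords = rng.uniform(0, 12, size=(15, 3))
    p = ForceFieldParams()
    s = make_structure(coords)
    expected = 0.0
    for i in range(15):
        for j in range(i + 1, 15):
            r = np.linalg.norm(coords[i] - coords[j])
            x = (p.lj_rmin / r) ** 6
            expected += p.lj_epsilon * (x * x - 2 * x)
    assert lj_energy(s, p) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# Binding protocol
# ---------------------------------------------------------------------------

def test_components_additivity_exact():
    c = EnergyComponents(E_elec=-12.5, E_VDW=3.25)
    assert c.E_MM_GB == c.E_elec + c.E_VDW


@pytest.mark.parametrize("label,row", list(BINDING_ENERGY_ROWS.items()))
def test_published_binding_energy_arithmetic(label, row):
    e_complex, e_mtbd, e_mt, de_published, _ = row
    de = binding_energy_from_components(e_complex, e_mtbd, e_mt)
    assert round(de, 2) == pytest.approx(de_published, abs=0.005)


def test_breakdown_identity_exact():
    bd = EnergyBreakdown(-100.0, -30.0, -65.0)
    assert bd.dE_binding == bd.E_complex - bd.E_MTBD - bd.E_MT


def test_noninteracting_limit():
    # two charge groups far beyond all cutoffs with screening off:
    # vacuum Coulomb cancels against the GB cross term, ΔE → 0
    coords = np.vstack([np.random.default_rng(2).normal(size=(4, 3)),
                        np.random.default_rng(3).normal(size=(4, 3)) + 500.0])
    charges = [1.0, -0.5, 0.25, 0.5, -1.0, 0.75, -0.25, 0.5]
    s = make_structure(coords, charges=charges)
    s.groups["a"] = np.arange(4)
    s.groups["b"] = np.arange(4, 8)
    params = ForceFieldParams(ionic_strength=1e6)  # κ → ∞
    bd = binding_energy(s, "a", "b", params)
    assert abs(bd.dE_binding) < 1e-6


def test_binding_energy_rigid_transform_invariant(base_system):
    params = ForceFieldParams()
    bd1 = binding_energy(base_system, "binder", None, params)
    rng = np.random.default_rng(4)
    R = Rotation.random(random_state=rng).as_matrix()
    moved = apply_transform(base_system, R, [5.0, -3.0, 11.0])
    bd2 = binding_energy(moved, "binder", None, params)
    assert bd2.dE_binding == pytest.approx(bd1.dE_binding, abs=1e-6)


def test_overlapping_parts_rejected(base_system):
    with pytest.raises(ValueError):
        binding_energy(base_system, "binder", "binder")


def test_identical_frames_have_zero_sd(base_system):
    frames = np.repeat(base_system.coords[None], 4, axis=0)
    ens = Ensemble(base_system, frames, np.zeros(4, dtype=int))
    bd = ensemble_binding_energy(ens, np.ones(4))
    assert bd.sd == pytest.approx(0.0, abs=1e-9)
    assert bd.n_snapshots == 4


def test_snapshot_selection_matches_brute_filter(base_system, small_spec):
    ens = generate_ensemble(base_system, small_spec, 0.0)
    counts = build_contact_table(ens, window=1.0).per_frame
    bd = ensemble_binding_energy(ens, counts)
    assert bd.n_snapshots == int((counts >= 1).sum())


def test_no_contact_snapshots_errors(base_system):
    frames = np.repeat(base_system.coords[None], 3, axis=0)
    ens = Ensemble(base_system, frames, np.zeros(3, dtype=int))
    with pytest.raises(ValueError, match="contact"):
        ensemble_binding_energy(ens, np.zeros(3))


def test_tail_mediated_binding_is_favorable():
    # stripping the tails removes the only favorable cross-group
    # interactions, so ΔE(with) < ΔE(without)
    spec = SyntheticSystemSpec(n_frames=40, n_runs=3, seed=13)
    base = generate_system(spec)
    ens = generate_ensemble(base, spec, 0.0)
    counts = build_contact_table(ens, window=1.0).per_frame
    with_tails = ensemble_binding_energy(ens, counts, strip_tails=False,
                                         max_snapshots=36)
    without = ensemble_binding_energy(ens, counts, strip_tails=True,
                                      max_snapshots=36)
    assert with_tails.dE_binding < without.dE_binding
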