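import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from mtbinder import structures as st
from mtbinder.structures import (OffsetProtocol, PDBParseError,
                                 apply_transform, assign_ionization,
                                 build_extended_tail, min_group_distance,
                                 net_charge, offset_binder, read_pqr,
                                 read_structure, remove_clashes,
                                 write_structure)

from conftest import make_structure

ALPHA = "VGVDSVEGEGEEEGEEY"
BETA = "DATADEQGEFEEEGEEDEA"


# ---------------------------------------------------------------------------
# PDB / PQR I/O
# ---------------------------------------------------------------------------

MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1      11.104  -6.000   2.500  1.00  0.00"
    "           C\n"
    "END\n"
)


def test_read_minimal_pdb(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(MINIMAL_PDB)
    s = read_structure(path)
    assert s.n_atoms == 1
    np.testing.assert_allclose(s.coords[0], [11.104, -6.0, 2.5])
    a = s.atom(0)
    assert a.residue_id == ("A", 1, "ALA") and a.element == "C" and a.is_heavy


def test_round_trip_preserves_coordinates(tmp_path, base_system):
    path = tmp_path / "sys.pdb"
    write_structure(base_system, path)
    back = read_structure(path)
    assert back.n_atoms == base_system.n_atoms
    np.testing.assert_allclose(back.coords, base_system.coords, atol=5.1e-4)
    assert list(back.names) == list(base_system.names)
    assert list(back.res_numbers) == list(base_system.res_numbers)


def test_two_chain_file_recovered_field_by_field(tmp_path):
    # build a 2-chain, 10-residue structure programmatically, write, re-read
    parts = []
    for chain, seq in (("A", "GAGAG"), ("B", "KDKDE")):
        parts.append(build_extended_tail(seq, anchor=(0, 0, 10 if chain == "B"
                                                      else 0),
                                         chain_id=chain))
    s = st.concat(parts)
    path = tmp_path / "two.pdb"
    write_structure(s, path)
    back = read_structure(path)
    assert set(back.chain_ids) == {"A", "B"}
    assert len(back.residue_ids()) == 10
    for i in range(s.n_atoms):
        a, b = s.atom(i), back.atom(i)
        assert a.name == b.name and a.residue_id == b.residue_id
        np.testing.assert_allclose(a.coord, b.coord, atol=5.1e-4)


def test_malformed_record_names_line_number(tmp_path):
    path = tmp_path / "bad.pdb"
    path.write_text("ATOM      1  CA  ALA A   1      xx.xxx   0.000   0.000\n")
    with pytest.raises(PDBParseError, match="line 1"):
        read_structure(path)


def test_empty_file_errors(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("")
    with pytest.raises(PDBParseError):
        read_structure(path)


def test_read_pqr_charges_and_radii(tmp_path):
    path = tmp_path / "a.pqr"
    path.write_text(
        "ATOM 1 CA ALA A 1 0.0 0.0 0.0 -0.500 1.900\n"
        "ATOM 2 CB ALA A 1 1.5 0.0 0.0 0.250 1.700\n")
    s = read_pqr(path)
    np.testing.assert_allclose(s.charges, [-0.5, 0.25])
    np.testing.assert_allclose(s.radii, [1.9, 1.7])


# ---------------------------------------------------------------------------
# Tail building
# ---------------------------------------------------------------------------

def test_alpha_tail_has_17_residues():
    tail = build_extended_tail(ALPHA)
    assert len(tail.residue_ids()) == 17


def test_beta_tail_residues_and_ionizable_count():
    tail = build_extended_tail(BETA)
    assert len(tail.residue_ids()) == 19
    # brute-force oracle: count D/E letters
    n_acidic = sum(c in "DE" for c in BETA)
    assert n_acidic == 11
    sc = [i for i in range(tail.n_atoms) if tail.names[i] == "SC"
          and tail.res_names[i] in ("ASP", "GLU")]
    assert len(sc) == n_acidic


def test_tail_ca_spacing():
    tail = build_extended_tail(ALPHA, anchor=(1, 2, 3), direction=(0, 1, 0))
    ca = tail.coords[tail.names == "CA"]
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    np.testing.assert_allclose(d, 3.8, atol=0.01)


def test_empty_sequence_gives_empty_structure():
    assert build_extended_tail("").n_atoms == 0


def test_unknown_letter_errors():
    with pytest.raises(ValueError, match="unknown"):
        build_extended_tail("AXZ")


# ---------------------------------------------------------------------------
# Transforms and offsets
# ---------------------------------------------------------------------------

def _random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=rng).as_matrix()


def test_identity_transform_is_identity(base_system):
    out = apply_transform(base_system, np.eye(3), np.zeros(3))
    np.testing.assert_array_equal(out.coords, base_system.coords)


def test_pure_translation_shifts_centroid(base_system):
    t = np.array([1.0, -2.0, 3.0])
    out = apply_transform(base_system, np.eye(3), t)
    np.testing.assert_allclose(out.coords.mean(0) - base_system.coords.mean(0),
                               t, atol=1e-12)


def test_transform_composition():
    rng = np.random.default_rng(0)
    s = make_structure(rng.normal(size=(20, 3)))
    R1, R2 = _random_rotation(rng), _random_rotation(rng)
    t1, t2 = rng.normal(size=3), rng.normal(size=3)
    two_step = apply_transform(apply_transform(s, R1, t1), R2, t2)
    composed = apply_transform(s, R2 @ R1, R2 @ t1 + t2)
    np.testing.assert_allclose(two_step.coords, composed.coords, atol=1e-9)


def test_non_rotation_matrix_rejected(base_system):
    with pytest.raises(ValueError):
        apply_transform(base_system, 2 * np.eye(3), np.zeros(3))
    refl = np.diag([1.0, 1.0, -1.0])
    with pytest.raises(ValueError):
        apply_transform(base_system, refl, np.zeros(3))


def test_offset_zero_is_identity(base_system):
    out = offset_binder(base_system, OffsetProtocol(), 0.0)
    np.testing.assert_array_equal(out.coords, base_system.coords)


def test_offset_35_displaces_binder_centroid_exactly(base_system):
    proto = OffsetProtocol()
    out = offset_binder(base_system, proto, 35.0)
    idx = base_system.group_indices("binder")
    shift = out.coords[idx].mean(0) - base_system.coords[idx].mean(0)
    np.testing.assert_allclose(shift, 35.0 * proto.axis_vector, atol=1e-12)
    others = np.setdiff1d(np.arange(base_system.n_atoms), idx)
    np.testing.assert_array_equal(out.coords[others],
                                  base_system.coords[others])


def test_offset_then_reverse_recovers_input(base_system):
    proto = OffsetProtocol(axis=(0, 0, 1))
    rev = OffsetProtocol(axis=(0, 0, -1))
    out = offset_binder(offset_binder(base_system, proto, 15.0), rev, 15.0)
    np.testing.assert_allclose(out.coords, base_system.coords, atol=1e-9)


def test_offset_increases_binder_filament_distance(base_system):
    proto = OffsetProtocol()
    d0 = min_group_distance(base_system, "binder", "filament")
    d1 = min_group_distance(offset_binder(base_system, proto, 15.0),
                            "binder", "filament")
    assert d1 > d0


def test_offset_commutes_with_rigid_transform(base_system):
    # offsetting then transforming equals transforming then offsetting
    # along the co-transformed axis
    rng = np.random.default_rng(3)
    R, t = _random_rotation(rng), rng.normal(size=3)
    proto = OffsetProtocol(axis=(0, 0, 1))
    a = apply_transform(offset_binder(base_system, proto, 25.0), R, t)
    axis2 = tuple(R @ np.array([0, 0, 1.0]))
    b = offset_binder(apply_transform(base_system, R, t),
                      OffsetProtocol(axis=axis2), 25.0)
    np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)


def test_missing_binder_group_errors():
    s = make_structure(np.zeros((2, 3)) + [[0, 0, 0], [5, 0, 0]])
    with pytest.raises(KeyError):
        offset_binder(s, OffsetProtocol(), 5.0)


def test_offset_protocol_validation():
    with pytest.raises(ValueError):
        OffsetProtocol(axis=(0, 0, 2.0))
    with pytest.raises(ValueError):
        OffsetProtocol(distances=(0.0, 5.0, 5.0))


# ---------------------------------------------------------------------------
# Clash removal
# ---------------------------------------------------------------------------

def _clashed_system(base, dz=8.0):
    s = base.copy()
    idx = s.groups["binder"]
    s.coords[idx] -= np.array([0.0, 0.0, dz])
    return s


def test_clash_free_input_unchanged(base_system):
    out, report = remove_clashes(base_system, cutoff=2.0)
    assert report.displacement == 0.0 and not report.initial_clash_pairs
    np.testing.assert_array_equal(out.coords, base_system.coords)


def test_clash_removal_reaches_cutoff(base_system):
    clashed = _clashed_system(base_system)
    assert min_group_distance(clashed, "binder", "filament") < 2.0
    out, report = remove_clashes(clashed, cutoff=2.0)
    assert report.initial_clash_pairs and report.displacement > 0
    # brute-force pair scan
    ia = out.group_indices("binder")
    ib = out.group_indices("filament")
    d = np.linalg.norm(out.coords[ia][:, None] - out.coords[ib][None],
                       axis=-1)
    assert d.min() >= 2.0


def test_clash_removal_never_moves_filament_or_tails(base_system):
    clashed = _clashed_system(base_system)
    out, _ = remove_clashes(clashed, cutoff=2.0)
    others = np.setdiff1d(np.arange(clashed.n_atoms),
                          clashed.groups["binder"])
    np.testing.assert_array_equal(out.coords[others], clashed.coords[others])


def test_clash_displacement_monotone_in_cutoff(base_system):
    clashed = _clashed_system(base_system)
    disp = [remove_clashes(clashed, cutoff=c)[1].displacement
            for c in (1.0, 2.0, 3.0, 4.0)]
    assert all(a <= b for a, b in zip(disp, disp[1:]))


# ---------------------------------------------------------------------------
# Ionization
# ---------------------------------------------------------------------------

def test_polyglycine_is_neutral():
    s = assign_ionization(build_extended_tail("GGGGG"))
    assert net_charge(s) == 0


@pytest.mark.parametrize("seq,expected", [
    (BETA, -11),   # 3 D + 8 E
    (ALPHA, -8),   # 1 D + 7 E
])
def test_tail_net_charges(seq, expected):
    # oracle: letter counting
    assert -(sum(c in "DE" for c in seq)) == expected
    s = assign_ionization(build_extended_tail(seq))
    assert net_charge(s) == expected


@settings(max_examples=40, deadline=None, derandomize=True)
@given(hst.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
def test_net_charge_matches_letter_count(seq):
    s = assign_ionization(build_extended_tail(seq))
    expected = (seq.count("K") + seq.count("R")
                - seq.count("D") - seq.count("E"))
    assert net_charge(s) == expected


def test_charges_are_integers_in_unit_range(base_system):
    s = assign_ionization(base_system)
    assert set(np.unique(s.charges)) <= {-1.0, 0.0, 1.0}
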