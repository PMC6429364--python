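"""Structure data model, PDB/PQR I/O, model building, and ionization.

The central container is :class:`Structure`, an array-backed collection of
atoms (coordinates, partial charge, intrinsic radius, residue identity,
segment annotation) plus named atom-index *groups* such as ``"binder"``,
``"filament"`` and ``"tail_B"``.  Model-building operations cover extended
Cα-trace construction of disordered tails, rigid transforms, the
perpendicular-offset protocol used to separate a binder domain from a
filament, deterministic clash relief, and fixed-pKa ionization at pH 7.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

__all__ = [
    "SEGMENT_TAGS",
    "Atom",
    "Structure",
    "OffsetProtocol",
    "IonizationRules",
    "ClashReport",
    "PDBParseError",
    "read_structure",
    "write_structure",
    "read_pqr",
    "build_extended_tail",
    "apply_transform",
    "offset_binder",
    "remove_clashes",
    "assign_ionization",
    "net_charge",
]

#: Recognised segment annotation tags: the six helices of a
#: microtubule-binding domain, the loop next to H1 (LH1), the loop next to
#: the flap (LF), the flap insertion, the coiled-coil stalk halves, the four
#: disordered tails, and catch-alls.
SEGMENT_TAGS = (
    "H1", "H2", "H3", "H4", "H5", "H6",
    "LH1", "LF", "FLAP", "CC1", "CC2",
    "TAIL_A", "TAIL_B", "TAIL_C", "TAIL_D",
    "BODY", "OTHER",
)

# van der Waals-ish intrinsic radii (Å) per element, used when no PQR-style
# radii are supplied.  Values follow the Bondi set, H reduced as usual for
# implicit-solvent work.
ELEMENT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
}
DEFAULT_RADIUS = 1.70

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

# Representative side-chain atom that carries the formal charge for
# all-atom inputs (Cα-trace models use the "SC" pseudo-atom instead).
CHARGE_BEARING_ATOM = {"ASP": "CG", "GLU": "CD", "LYS": "NZ", "ARG": "CZ",
                       "HIS": "NE2"}


class PDBParseError(ValueError):
    """Raised for malformed PDB/PQR records; carries the offending line."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class Atom:
    """A single atom view (immutable snapshot of one Structure row)."""

    name: str
    element: str
    coord: np.ndarray
    charge: float
    radius: float
    residue_id: tuple[str, int, str]  # (chain, residue number, residue name)
    segment: str

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Structure:
    """Array-backed atom collection with named index groups.

    All per-atom arrays have length ``n_atoms``; ``groups`` maps a group
    name (e.g. ``"binder"``) to a sorted integer index array.
    """

    names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    chain_ids: np.ndarray
    res_numbers: np.ndarray
    res_names: np.ndarray
    segments: np.ndarray
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.names)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.res_numbers = np.asarray(self.res_numbers, dtype=int)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        heavy = self.heavy_mask
        if np.any(self.radii[heavy] <= 0):
            raise ValueError("heavy atoms must have radius > 0")
        for gname, idx in self.groups.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"group {gname!r} indices out of bounds")
            self.groups[gname] = idx
        if "binder" in self.groups and "filament" in self.groups:
            if np.intersect1d(self.groups["binder"],
                              self.groups["filament"]).size:
                raise ValueError("'binder' and 'filament' groups overlap")

    # -- basic introspection -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.char.upper(self.elements.astype(str)) != "H"

    def atom(self, i: int) -> Atom:
        return Atom(
            name=str(self.names[i]), element=str(self.elements[i]),
            coord=self.coords[i].copy(), charge=float(self.charges[i]),
            radius=float(self.radii[i]),
            residue_id=(str(self.chain_ids[i]), int(self.res_numbers[i]),
                        str(self.res_names[i])),
            segment=str(self.segments[i]),
        )

    def __iter__(self) -> Iterable[Atom]:
        return (self.atom(i) for i in range(self.n_atoms))

    def __len__(self) -> int:
        return self.n_atoms

    def copy(self) -> "Structure":
        return Structure(
            names=self.names.copy(), elements=self.elements.copy(),
            coords=self.coords.copy(), charges=self.charges.copy(),
            radii=self.radii.copy(), chain_ids=self.chain_ids.copy(),
            res_numbers=self.res_numbers.copy(),
            res_names=self.res_names.copy(), segments=self.segments.copy(),
            groups={k: v.copy() for k, v in self.groups.items()},
        )

    def group_indices(self, name: str) -> np.ndarray:
        if name not in self.groups:
            raise KeyError(f"structure has no group {name!r}")
        return self.groups[name]

    def select(self, indices: np.ndarray) -> "Structure":
        """Sub-structure of ``indices`` (groups re-indexed; empty dropped)."""
        indices = np.asarray(indices, dtype=int)
        remap = -np.ones(self.n_atoms, dtype=int)
        remap[indices] = np.arange(indices.size)
        groups = {}
        for gname, idx in self.groups.items():
            new = remap[idx]
            new = new[new >= 0]
            if new.size:
                groups[gname] = np.sort(new)
        return Structure(
            names=self.names[indices], elements=self.elements[indices],
            coords=self.coords[indices], charges=self.charges[indices],
            radii=self.radii[indices], chain_ids=self.chain_ids[indices],
            res_numbers=self.res_numbers[indices],
            res_names=self.res_names[indices],
            segments=self.segments[indices], groups=groups,
        )

    def residue_ids(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resnum, resname) triples."""
        seen, out = set(), []
        for i in range(self.n_atoms):
            key = (str(self.chain_ids[i]), int(self.res_numbers[i]),
                   str(self.res_names[i]))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out


def concat(parts: Sequence[Structure],
           group_labels: Sequence[str | None] | None = None) -> Structure:
    """Concatenate structures; optionally tag each part as a new group."""
    offsets = np.cumsum([0] + [p.n_atoms for p in parts])
    groups: dict[str, np.ndarray] = {}
    for off, part in zip(offsets, parts):
        for gname, idx in part.groups.items():
            prev = groups.get(gname, np.empty(0, dtype=int))
            groups[gname] = np.concatenate([prev, idx + off])
    if group_labels is not None:
        for off, part, label in zip(offsets, parts, group_labels):
            if label is None:
                continue
            prev = groups.get(label, np.empty(0, dtype=int))
            groups[label] = np.concatenate(
                [prev, np.arange(part.n_atoms) + off])
    return Structure(
        names=np.concatenate([p.names for p in parts]),
        elements=np.concatenate([p.elements for p in parts]),
        coords=np.concatenate([p.coords for p in parts]),
        charges=np.concatenate([p.charges for p in parts]),
        radii=np.concatenate([p.radii for p in parts]),
        chain_ids=np.concatenate([p.chain_ids for p in parts]),
        res_numbers=np.concatenate([p.res_numbers for p in parts]),
        res_names=np.concatenate([p.res_names for p in parts]),
        segments=np.concatenate([p.segments for p in parts]),
        groups={k: np.sort(v) for k, v in groups.items()},
    )


@dataclass(frozen=True)
class OffsetProtocol:
    """Perpendicular-offset protocol: unit axis + increasing distances (Å)."""

    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    distances: tuple[float, ...] = (0.0, 5.0, 15.0, 25.0, 35.0, 45.0, 55.0)

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValueError("offset axis must be a unit vector")
        d = np.asarray(self.distances, dtype=float)
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("distances must be nonnegative and strictly "
                             "increasing")

    @property
    def axis_vector(self) -> np.ndarray:
        return np.asarray(self.axis, dtype=float)


@dataclass(frozen=True)
class IonizationRules:
    """Fixed-pKa ionization rules (integer side-chain charges).

    At the default pH 7 this yields ASP/GLU −1, LYS/ARG +1 and neutral HIS —
    the fully-ionized regime continuum-pKa calculations predict for these
    systems.  Termini are left uncharged by default (the disordered tails
    are internal fragments of tubulin).
    """

    pH: float = 7.0
    model_pKa: Mapping[str, float] = field(default_factory=lambda: {
        "ASP": 3.65, "GLU": 4.25, "LYS": 10.53, "ARG": 12.48,
        "HIS": 6.00, "CYS": 8.30, "TYR": 10.07,
    })
    acids: frozenset = frozenset({"ASP", "GLU", "CYS", "TYR"})
    bases: frozenset = frozenset({"LYS", "ARG", "HIS"})
    charge_termini: bool = False

    def side_chain_charge(self, res_name: str) -> int:
        pka = self.model_pKa.get(res_name)
        if pka is None:
            return 0
        if res_name in self.acids:
            return -1 if self.pH > pka else 0
        if res_name in self.bases:
            return +1 if self.pH < pka else 0
        return 0


@dataclass
class ClashReport:
    initial_clash_pairs: list[tuple[int, int, float]]
    displacement: float
    n_steps: int


# ---------------------------------------------------------------------------
# PDB / PQR I/O
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            # two-letter elements only when unambiguous from PDB naming
            if stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
                return stripped[:2].upper()
            return ch.upper()
    return "C"


def _validate_pdb_lines(path: Path) -> int:
    """Pre-scan ATOM/HETATM records; raise PDBParseError with line number."""
    n_atom_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            n_atom_records += 1
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError("truncated ATOM record", lineno)
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise PDBParseError("unparsable coordinate field", lineno)
    return n_atom_records


def read_structure(path: str | Path) -> Structure:
    """Read a Structure from a PDB file (first model of multi-model files).

    Atoms are kept in file order with chain/residue identity preserved;
    the element is inferred from the atom name when the element column is
    blank.  Charges are initialised to 0 and radii from the bundled
    per-element table; use :func:`read_pqr` for user-supplied values.
    """
    path = Path(path)
    if _validate_pdb_lines(path) == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    return _from_atom_array(arr)


def _from_atom_array(arr: bst.AtomArray) -> Structure:
    elements = np.array([
        e if e.strip() else _infer_element(n)
        for e, n in zip(arr.element, arr.atom_name)
    ], dtype="U2")
    radii = np.array([ELEMENT_RADII.get(e.upper(), DEFAULT_RADIUS)
                      for e in elements])
    charges = (np.asarray(arr.charge, dtype=float)
               if "charge" in arr.get_annotation_categories()
               else np.zeros(arr.array_length()))
    return Structure(
        names=np.asarray(arr.atom_name, dtype="U6"),
        elements=elements,
        coords=np.asarray(arr.coord, dtype=float),
        charges=charges,
        radii=radii,
        chain_ids=np.asarray(arr.chain_id, dtype="U4"),
        res_numbers=np.asarray(arr.res_id, dtype=int),
        res_names=np.asarray(arr.res_name, dtype="U4"),
        segments=np.full(arr.array_length(), "OTHER", dtype="U8"),
    )


def to_atom_array(s: Structure) -> bst.AtomArray:
    arr = bst.AtomArray(s.n_atoms)
    arr.coord = s.coords.astype(np.float32)
    arr.atom_name = s.names.astype("U6")
    arr.element = s.elements.astype("U2")
    arr.chain_id = s.chain_ids.astype("U4")
    arr.res_id = s.res_numbers
    arr.res_name = s.res_names.astype("U4")
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    return arr


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a Structure to a PDB file (coordinates to 3 decimals)."""
    pdb = PDBFile()
    pdb.set_structure(to_atom_array(s))
    pdb.write(str(path))


def read_pqr(path: str | Path) -> Structure:
    """Read a PQR-dialect file (whitespace-separated; charge and radius
    columns replace occupancy/B-factor)."""
    names, elements, coords, charges, radii = [], [], [], [], []
    chains, res_nums, res_names = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            tok = line.split()
            try:
                # tolerate both with- and without-chain-id dialects
                if len(tok) >= 11:
                    (_, _, name, rname, chain, rnum,
                     x, y, z, q, r) = tok[:11]
                elif len(tok) == 10:
                    _, _, name, rname, rnum, x, y, z, q, r = tok
                    chain = "A"
                else:
                    raise ValueError("too few columns")
                coords.append([float(x), float(y), float(z)])
                charges.append(float(q))
                radii.append(float(r))
                res_nums.append(int(rnum))
            except ValueError as exc:
                raise PDBParseError(f"bad PQR record ({exc})", lineno)
            names.append(name)
            elements.append(_infer_element(name))
            chains.append(chain)
            res_names.append(rname)
    if not names:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    return Structure(
        names=np.array(names, dtype="U6"),
        elements=np.array(elements, dtype="U2"),
        coords=np.array(coords), charges=np.array(charges),
        radii=np.array(radii), chain_ids=np.array(chains, dtype="U4"),
        res_numbers=np.array(res_nums),
        res_names=np.array(res_names, dtype="U4"),
        segments=np.full(len(names), "OTHER", dtype="U8"),
    )


# ---------------------------------------------------------------------------
# Model building
# ---------------------------------------------------------------------------

CA_CA_DISTANCE = 3.8  # Å, trans peptide Cα spacing
SC_OFFSET = 2.5       # Å, side-chain pseudo-atom offset from Cα

IONIZABLE = set("DEKRH")


def build_extended_tail(sequence: str,
                        anchor: Sequence[float] = (0.0, 0.0, 0.0),
                        direction: Sequence[float] = (1.0, 0.0, 0.0),
                        chain_id: str = "T",
                        segment: str = "TAIL_A",
                        start_res: int = 1,
                        rules: IonizationRules | None = None) -> Structure:
    """Build an extended (all-trans) Cα-trace model of a tail sequence.

    One Cα per residue at 3.8 Å spacing along ``direction`` from ``anchor``;
    ionizable residues additionally carry a single side-chain pseudo-atom
    ("SC") bearing the residue's formal charge, placed 2.5 Å off the trace
    on alternating sides.
    """
    if rules is None:
        rules = IonizationRules()
    sequence = sequence.strip().upper()
    for ch in sequence:
        if ch not in AA_1TO3:
            raise ValueError(f"unknown one-letter amino-acid code {ch!r}")
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ValueError("direction must be nonzero")
    direction = direction / nrm
    # any unit vector perpendicular to the chain direction
    ref = np.array([0.0, 0.0, 1.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = np.cross(direction, ref)
    perp /= np.linalg.norm(perp)
    anchor = np.asarray(anchor, dtype=float)

    names, elements, coords, charges, radii = [], [], [], [], []
    res_nums, res_names = [], []
    for i, letter in enumerate(sequence):
        res3 = AA_1TO3[letter]
        ca = anchor + i * CA_CA_DISTANCE * direction
        names.append("CA"); elements.append("C")
        coords.append(ca); charges.append(0.0)
        radii.append(ELEMENT_RADII["C"])
        res_nums.append(start_res + i); res_names.append(res3)
        if letter in IONIZABLE:
            side = perp if i % 2 == 0 else -perp
            names.append("SC"); elements.append("C")
            coords.append(ca + SC_OFFSET * side)
            charges.append(float(rules.side_chain_charge(res3)))
            radii.append(ELEMENT_RADII["C"])
            res_nums.append(start_res + i); res_names.append(res3)
    n = len(names)
    return Structure(
        names=np.array(names, dtype="U6"),
        elements=np.array(elements, dtype="U2"),
        coords=np.array(coords).reshape(n, 3),
        charges=np.array(charges), radii=np.array(radii),
        chain_ids=np.full(n, chain_id, dtype="U4"),
        res_numbers=np.array(res_nums, dtype=int),
        res_names=np.array(res_names, dtype="U4"),
        segments=np.full(n, segment, dtype="U8"),
    )


def apply_transform(s: Structure, rotation: np.ndarray,
                    translation: Sequence[float]) -> Structure:
    """Map every coordinate x → R·x + t; non-coordinate fields unchanged."""
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be 3×3")
    if (np.abs(rotation @ rotation.T - np.eye(3)).max() > 1e-6
            or abs(np.linalg.det(rotation) - 1.0) > 1e-6):
        raise ValueError("matrix is not a proper rotation")
    out = s.copy()
    out.coords = s.coords @ rotation.T + np.asarray(translation, dtype=float)
    return out


def offset_binder(complex_: Structure, protocol: OffsetProtocol,
                  d: float) -> Structure:
    """Translate the ``"binder"`` group by ``d`` Å along the protocol axis."""
    if d < 0:
        raise ValueError("offset distance must be >= 0")
    if "binder" not in complex_.groups:
        raise KeyError("structure has no 'binder' group")
    out = complex_.copy()
    idx = out.groups["binder"]
    out.coords[idx] = out.coords[idx] + d * protocol.axis_vector
    return out


def min_group_distance(s: Structure, group_a: str, group_b: str,
                       heavy_only: bool = True) -> float:
    """Minimum pairwise distance between two groups (heavy atoms only by
    default)."""
    ia, ib = s.group_indices(group_a), s.group_indices(group_b)
    if heavy_only:
        heavy = s.heavy_mask
        ia, ib = ia[heavy[ia]], ib[heavy[ib]]
    if ia.size == 0 or ib.size == 0:
        return np.inf
    tree = cKDTree(s.coords[ib])
    dmin, _ = tree.query(s.coords[ia], k=1)
    return float(dmin.min())


def remove_clashes(s: Structure, cutoff: float = 2.0,
                   axis: Sequence[float] = (0.0, 0.0, 1.0),
                   step: float = 0.5,
                   max_steps: int = 1000) -> tuple[Structure, ClashReport]:
    """Relieve binder–filament clashes by translating the binder along
    ``+axis`` in 0.5 Å steps until no heavy-atom pair is below ``cutoff``.

    Filament and tail atoms are never moved.  Returns the (possibly moved)
    structure and a report with the initial clash pairs and the total
    displacement applied.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ia = s.group_indices("binder")
    ib = s.group_indices("filament")
    heavy = s.heavy_mask
    ia, ib = ia[heavy[ia]], ib[heavy[ib]]

    tree = cKDTree(s.coords[ib])
    pairs = tree.query_ball_point(s.coords[ia], r=cutoff)
    initial = []
    for k, hits in enumerate(pairs):
        for j in hits:
            dist = float(np.linalg.norm(s.coords[ia[k]] - s.coords[ib[j]]))
            initial.append((int(ia[k]), int(ib[j]), dist))

    out = s.copy()
    n_steps = 0
    while (min_group_distance(out, "binder", "filament") < cutoff
           and n_steps < max_steps):
        idx = out.groups["binder"]
        out.coords[idx] = out.coords[idx] + step * axis
        n_steps += 1
    return out, ClashReport(initial_clash_pairs=initial,
                            displacement=n_steps * step, n_steps=n_steps)


def assign_ionization(s: Structure,
                      rules: IonizationRules | None = None) -> Structure:
    """Assign integer formal charges per the fixed-pKa rule table.

    The charge is placed on the residue's side-chain pseudo-atom ("SC") when
    present, otherwise on the standard charge-bearing side-chain atom, and
    as a fallback on the Cα.  All other atoms are set to 0.
    """
    if rules is None:
        rules = IonizationRules()
    out = s.copy()
    out.charges = np.zeros(s.n_atoms)
    # group atom indices by residue
    by_res: dict[tuple, list[int]] = {}
    for i in range(s.n_atoms):
        key = (str(s.chain_ids[i]), int(s.res_numbers[i]))
        by_res.setdefault(key, []).append(i)
    for idx in by_res.values():
        res_name = str(s.res_names[idx[0]])
        q = rules.side_chain_charge(res_name)
        if q == 0:
            continue
        names = [str(s.names[i]).strip() for i in idx]
        target = None
        if "SC" in names:
            target = idx[names.index("SC")]
        else:
            bearer = CHARGE_BEARING_ATOM.get(res_name)
            if bearer in names:
                target = idx[names.index(bearer)]
            elif "CA" in names:
                target = idx[names.index("CA")]
            else:
                target = idx[0]
        out.charges[target] = float(q)
    return out


def net_charge(s: Structure) -> float:
    return float(s.charges.sum())
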