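"""Synthetic binder–filament–tail systems and replicate ensembles.

These generators stand in for molecular-dynamics trajectories of a
microtubule-binding domain (the *binder*) near a microtubule segment (the
*filament*) carrying four disordered acidic C-terminal tails.  The
ensembles are Monte-Carlo perturbation chains, not dynamics: the filament
is position-restrained, the binder fluctuates with an amplitude that grows
linearly with its offset from the filament, and the tails are re-sampled
each frame as self-avoiding walks whose probability of reaching over and
touching the binder's positive patches decays exponentially with the
binder–filament gap.  The statistical structure the downstream analyses
assume — contact frequency falling with offset and vanishing beyond a
threshold, fluctuation amplitude rising linearly with offset — is therefore
planted with known parameters and can be recovered quantitatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

from . import structures as st
from .structures import Structure, build_extended_tail, concat

__all__ = [
    "ALPHA_TAIL_SEQUENCE", "BETA_TAIL_SEQUENCE",
    "SyntheticSystemSpec", "Ensemble",
    "generate_system", "generate_ensemble",
    "write_ensemble", "read_ensemble",
]

#: Disordered C-terminal tail sequences of Bos taurus α- and β-tubulin.
ALPHA_TAIL_SEQUENCE = "VGVDSVEGEGEEEGEEY"
BETA_TAIL_SEQUENCE = "DATADEQGEFEEEGEEDEA"

# fixed geometry of the toy system (Å); filament long axis = x, offset = z
_MONOMER_LEN = 20.0
_MONOMER_WIDTH = 15.0
_MONOMER_DEPTH = 10.0
_LATTICE = 5.0
_BINDER_RADIUS = 12.0
_BOUND_GAP = 4.0          # binder-bottom-to-filament-top gap at offset 0
_TAIL_EXCLUSION = 5.0     # tails may not come nearer the binder than this
                          # unless a planted contact event fires
_CONTACT_APPROACH = 3.8   # closest-approach distance during an event


@dataclass(frozen=True)
class SyntheticSystemSpec:
    """Parameters of the synthetic system and its planted statistics.

    ``contact_decay_length`` sets how fast the planted tail–binder contact
    probability falls with the anchor-to-binder gap; ``zero_contact_distance``
    is the offset at/beyond which no contacts are planted at all.  The
    per-atom binder fluctuation (3-D RMS displacement) is
    ``fluctuation_base + fluctuation_distance_gain · offset``.
    """

    binder_n_residues: int = 150
    charge_layout: str = "interface_clustered"  # or "scattered"
    binder_net_charge: int = 3
    binder_n_positive: int = 12
    tail_sequences: Mapping[str, str] = field(default_factory=lambda: {
        "A": ALPHA_TAIL_SEQUENCE, "B": BETA_TAIL_SEQUENCE,
        "C": ALPHA_TAIL_SEQUENCE, "D": BETA_TAIL_SEQUENCE,
    })
    n_frames: int = 500
    n_runs: int = 3
    seed: int = 0
    contact_decay_length: float = 15.0
    fluctuation_base: float = 1.0
    fluctuation_distance_gain: float = 0.02
    zero_contact_distance: float = 50.0

    def __post_init__(self):
        if self.binder_n_residues <= 0 or self.n_frames <= 0:
            raise ValueError("sizes must be > 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.charge_layout not in ("interface_clustered", "scattered"):
            raise ValueError(f"unknown charge layout {self.charge_layout!r}")
        if self.contact_decay_length <= 0 or self.zero_contact_distance <= 0:
            raise ValueError("lengths must be > 0")
        n_neg = self.binder_n_positive - self.binder_net_charge
        if n_neg < 0 or self.binder_n_positive + n_neg > self.binder_n_residues:
            raise ValueError("charge layout impossible for this net charge "
                             "and residue count")


@dataclass
class Ensemble:
    """Ordered conformational frames for a fixed atom roster.

    ``frames`` has shape (n_frames_total, n_atoms, 3); ``run_ids`` labels
    each frame with its replicate run (0-based).
    """

    topology: Structure
    frames: np.ndarray
    run_ids: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.run_ids = np.asarray(self.run_ids, dtype=int)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("frame shape does not match topology atom count")
        if len(self.run_ids) != len(self.frames):
            raise ValueError("run_ids length mismatch")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite frame coordinates")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run_ids)

    def frames_of_run(self, run: int) -> np.ndarray:
        return self.frames[self.run_ids == run]

    def run_lengths(self) -> dict[int, int]:
        return {int(r): int((self.run_ids == r).sum()) for r in self.runs}


# ---------------------------------------------------------------------------
# System construction
# ---------------------------------------------------------------------------

def _lattice_block(x0: float) -> np.ndarray:
    xs = np.arange(x0 + _LATTICE / 2, x0 + _MONOMER_LEN, _LATTICE)
    ys = np.arange(-_MONOMER_WIDTH / 2 + _LATTICE / 2, _MONOMER_WIDTH / 2,
                   _LATTICE)
    zs = np.arange(-_MONOMER_DEPTH, 0, _LATTICE) + _LATTICE / 2
    g = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    return g.reshape(-1, 3)


def _make_monomer(chain: str, x0: float, rng: np.random.Generator,
                  start_res: int) -> Structure:
    coords = _lattice_block(x0)
    n = len(coords)
    res_names = np.full(n, "ALA", dtype="U4")
    charges = np.zeros(n)
    # a few balanced surface charge pairs so the filament body is
    # polar but net-neutral
    surf = np.where(coords[:, 2] > -_LATTICE)[0]
    picked = rng.choice(surf, size=min(8, len(surf)), replace=False)
    for k, i in enumerate(picked):
        if k % 2 == 0:
            res_names[i] = "LYS"; charges[i] = 1.0
        else:
            res_names[i] = "GLU"; charges[i] = -1.0
    return Structure(
        names=np.full(n, "CA", dtype="U6"),
        elements=np.full(n, "C", dtype="U2"),
        coords=coords, charges=charges,
        radii=np.full(n, 2.0),
        chain_ids=np.full(n, chain, dtype="U4"),
        res_numbers=np.arange(start_res, start_res + n),
        res_names=res_names,
        segments=np.full(n, "BODY", dtype="U8"),
    )


# fractional slicing of the binder chain into annotated segments
_BINDER_SEGMENTS = (
    ("CC1", 0.03), ("H1", 0.10), ("LH1", 0.05), ("H2", 0.10),
    ("H3", 0.10), ("H4", 0.10), ("FLAP", 0.08), ("LF", 0.05),
    ("H5", 0.10), ("H6", 0.10), ("CC2", 0.19),
)


def _binder_segment_labels(n: int) -> np.ndarray:
    bounds = np.cumsum([f for _, f in _BINDER_SEGMENTS])
    bounds = np.round(bounds / bounds[-1] * n).astype(int)
    labels = np.empty(n, dtype="U8")
    start = 0
    for (tag, _), end in zip(_BINDER_SEGMENTS, bounds):
        labels[start:end] = tag
        start = end
    labels[start:] = _BINDER_SEGMENTS[-1][0]
    return labels


def _make_binder(spec: SyntheticSystemSpec, center: np.ndarray,
                 rng: np.random.Generator) -> Structure:
    """Compact blob of Cα pseudo-residues with configurable charge layout."""
    n = spec.binder_n_residues
    pts: list[np.ndarray] = []
    # rejection-sample a blob with ~3.2 Å minimum spacing
    while len(pts) < n:
        p = rng.uniform(-_BINDER_RADIUS, _BINDER_RADIUS, size=3)
        if np.linalg.norm(p) > _BINDER_RADIUS:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < 3.2:
            continue
        pts.append(p)
    coords = np.array(pts) + center

    n_pos = spec.binder_n_positive
    n_neg = n_pos - spec.binder_net_charge
    interface_z = center[2] - _BINDER_RADIUS  # bottom of the blob
    near = np.where(coords[:, 2] - interface_z <= 10.0)[0]
    far = np.setdiff1d(np.arange(n), near)
    if spec.charge_layout == "interface_clustered":
        n_near = max(int(math.ceil(0.8 * n_pos)), n_pos - len(far))
        if n_near > len(near):
            raise ValueError("impossible placement: not enough interface "
                             "sites for clustered layout")
        pos_idx = np.concatenate([
            rng.choice(near, size=n_near, replace=False),
            rng.choice(far, size=n_pos - n_near, replace=False),
        ])
    else:
        # uniform over the blob, redrawn until the layout honours the
        # scattered contract (< 50% of positives near the interface)
        for _ in range(200):
            pos_idx = rng.choice(n, size=n_pos, replace=False)
            frac = np.isin(pos_idx, near).sum() / n_pos
            if frac < 0.5:
                break
        else:
            raise ValueError("impossible placement: could not scatter "
                             "positive charges away from the interface")
    rest = np.setdiff1d(np.arange(n), pos_idx)
    neg_idx = rng.choice(rest, size=n_neg, replace=False)

    charges = np.zeros(n)
    res_names = np.full(n, "ALA", dtype="U4")
    charges[pos_idx] = 1.0
    res_names[pos_idx] = "LYS"
    charges[neg_idx] = -1.0
    res_names[neg_idx] = "GLU"
    return Structure(
        names=np.full(n, "CA", dtype="U6"),
        elements=np.full(n, "C", dtype="U2"),
        coords=coords, charges=charges,
        radii=np.full(n, 2.0),
        chain_ids=np.full(n, "M", dtype="U4"),
        res_numbers=np.arange(1, n + 1),
        res_names=res_names,
        segments=_binder_segment_labels(n),
    )


#: tail label → (anchor point on the filament top surface, chain id)
_TAIL_ANCHORS = {
    "A": (np.array([0.0, 10.0, 0.0]), "E"),
    "B": (np.array([38.0, 0.0, 0.0]), "F"),
    "C": (np.array([40.0, 10.0, 0.0]), "G"),
    "D": (np.array([62.0, 0.0, 0.0]), "H"),
}
_BINDER_CENTER_XY = np.array([50.0, 0.0])


def generate_system(spec: SyntheticSystemSpec) -> Structure:
    """Build the bound-pose complex: rigid two-dimer filament, four anchored
    tails (B and D proximal to the binder), and a ~150-residue binder blob.

    Groups ``"filament"``, ``"binder"``, ``"tail_A"``–``"tail_D"`` and
    ``"tails"`` are populated; charges are assigned (tails per the pH-7
    fixed-pKa rules, binder per its charge layout).  Deterministic for a
    fixed spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    monomers = [_make_monomer(ch, x0, rng, start_res=1)
                for ch, x0 in zip("ABCD", (0.0, 20.0, 40.0, 60.0))]
    filament = concat(monomers)
    filament.groups["filament"] = np.arange(filament.n_atoms)

    tails = []
    for label in "ABCD":
        seq = spec.tail_sequences[label]
        anchor, chain = _TAIL_ANCHORS[label]
        tail = build_extended_tail(seq, anchor=anchor, direction=(0, 0, 1),
                                   chain_id=chain, segment=f"TAIL_{label}",
                                   start_res=1001)
        tail = st.assign_ionization(tail)
        tail.groups[f"tail_{label}"] = np.arange(tail.n_atoms)
        tails.append(tail)

    binder_center = np.array([*_BINDER_CENTER_XY,
                              _BOUND_GAP + _BINDER_RADIUS])
    binder = _make_binder(spec, binder_center, rng)
    binder.groups["binder"] = np.arange(binder.n_atoms)

    system = concat([filament, *tails, binder],
                    group_labels=[None, "tails", "tails", "tails", "tails",
                                  None])
    return system


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------

def _sample_tail_walk(anchor: np.ndarray, n_res: int,
                      rng: np.random.Generator,
                      targets: list[np.ndarray] | None,
                      drift: np.ndarray | None = None) -> np.ndarray:
    """One self-avoiding Cα walk from ``anchor``.

    With ``targets`` (positive binder sites) the walk visits them in turn,
    parking one bead at the planted contact-approach distance from each —
    a disordered chain laying across a charged patch — and then heads back
    out.  Without targets it is a persistent random walk (exclusion from
    the binder is enforced afterwards).
    """
    step = st.CA_CA_DISTANCE
    beads = np.empty((n_res, 3))
    beads[0] = anchor
    direction = np.array([0.0, 0.0, 1.0])
    queue = list(targets) if targets else []
    last_target = None
    for i in range(1, n_res):
        pos = beads[i - 1]
        for _ in range(8):
            if queue:
                target = queue[0]
                to_t = target - pos
                dist_t = np.linalg.norm(to_t)
                if dist_t <= _CONTACT_APPROACH + step:
                    # park exactly at the approach distance from the target
                    new = target + _CONTACT_APPROACH * _unit(
                        pos - target, rng)
                    last_target = queue.pop(0)
                else:
                    d = _unit(to_t / dist_t + 0.35 * rng.normal(size=3), rng)
                    new = pos + step * d
            elif last_target is not None:
                # after the last touch the chain heads back out instead of
                # wrapping the binder surface
                away = _unit(pos - last_target, rng)
                d = _unit(0.8 * away + 0.4 * direction
                          + 0.6 * rng.normal(size=3), rng)
                new = pos + step * d
            else:
                bias = 0.0 if drift is None else 0.5 * drift
                d = _unit(0.6 * direction + bias + rng.normal(size=3), rng)
                new = pos + step * d
            # approximate self-avoidance
            if i >= 2 and np.min(
                    np.linalg.norm(beads[:i - 1] - new, axis=1)) < 2.8:
                continue
            break
        beads[i] = new
        direction = _unit(beads[i] - beads[i - 1], rng)
    return beads


def _unit(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _push_clear(pts: np.ndarray, tree: cKDTree, rmin: float,
                centroid: np.ndarray) -> np.ndarray:
    """Move points so none is nearer than ``rmin`` to any tree point."""
    for _ in range(4):
        d, j = tree.query(pts)
        bad = d < rmin
        if not bad.any():
            return pts
        u = pts[bad] - tree.data[j[bad]]
        norms = np.linalg.norm(u, axis=1, keepdims=True)
        norms[norms < 1e-9] = 1e-9
        pts[bad] = tree.data[j[bad]] + u / norms * rmin
    # radial escape for the rare unresolved point
    d, _ = tree.query(pts)
    bad = d < rmin
    while bad.any():
        u = pts[bad] - centroid
        norms = np.linalg.norm(u, axis=1, keepdims=True)
        norms[norms < 1e-9] = 1e-9
        pts[bad] = pts[bad] + u / norms
        d, _ = tree.query(pts)
        bad = d < rmin
    return pts


def _resolve_coincidences(coords: np.ndarray, rng: np.random.Generator,
                          dmin: float = 0.8) -> None:
    """Nudge apart any near-coincident atom pair (random chain geometry can
    very rarely stack two pseudo-atoms); keeps nonbonded energies finite."""
    for _ in range(5):
        pairs = cKDTree(coords).query_pairs(dmin, output_type="ndarray")
        if not len(pairs):
            return
        for i, j in pairs:
            sep = coords[j] - coords[i]
            coords[j] = coords[i] + 0.9 * _unit(sep, rng)


def generate_ensemble(base: Structure, spec: SyntheticSystemSpec,
                      offset_d: float) -> Ensemble:
    """Replicate ensembles around an (already offset) base complex.

    Filament atoms get 0.1 Å restrained jitter; binder atoms get isotropic
    jitter whose 3-D RMS equals ``fluctuation_base +
    fluctuation_distance_gain·offset_d``; tails are re-sampled each frame
    with the planted contact statistics (probability
    exp(−gap/contact_decay_length), zero at/beyond
    ``zero_contact_distance``).
    """
    fil_idx = base.group_indices("filament")
    bind_idx = base.group_indices("binder")
    sigma_axis = (spec.fluctuation_base
                  + spec.fluctuation_distance_gain * offset_d) / math.sqrt(3)

    binder_coords = base.coords[bind_idx]
    base_tree = cKDTree(binder_coords)
    pos_mask = base.charges[bind_idx] > 0

    tail_info = []
    for label in "ABCD":
        gname = f"tail_{label}"
        if gname not in base.groups:
            continue
        idx = base.group_indices(gname)
        ca_mask = np.char.strip(base.names[idx].astype(str)) == "CA"
        anchor = base.coords[idx[ca_mask][0]]
        gap, _ = base_tree.query(anchor)
        if offset_d >= spec.zero_contact_distance:
            p_contact = 0.0
        else:
            p_contact = math.exp(-gap / spec.contact_decay_length)
        tail_info.append((idx, ca_mask, anchor, p_contact))

    n_total = spec.n_frames * spec.n_runs
    frames = np.empty((n_total, base.n_atoms, 3))
    run_ids = np.empty(n_total, dtype=int)
    f = 0
    for run in range(spec.n_runs):
        rng = np.random.default_rng(
            [spec.seed, run, int(round(offset_d * 16))])
        for _ in range(spec.n_frames):
            coords = base.coords.copy()
            coords[fil_idx] += rng.normal(0.0, 0.1, size=(len(fil_idx), 3))
            coords[bind_idx] += rng.normal(0.0, sigma_axis,
                                           size=(len(bind_idx), 3))
            frame_binder = coords[bind_idx]
            frame_tree = cKDTree(frame_binder)
            frame_pos = frame_binder[pos_mask]
            centroid = frame_binder.mean(axis=0)
            for idx, ca_mask, anchor, p_contact in tail_info:
                biased = (p_contact > 0 and len(frame_pos)
                          and rng.random() < p_contact)
                targets = None
                if biased:
                    order = np.argsort(
                        np.linalg.norm(frame_pos - anchor, axis=1))
                    targets = [frame_pos[k] for k in order[:4]]
                # free tails drift up and away from the binder
                drift = _unit(np.append(anchor[:2] - centroid[:2], 0.0)
                              + np.array([0.0, 0.0, 1.5]), rng)
                beads = _sample_tail_walk(anchor, int(ca_mask.sum()), rng,
                                          targets, drift)
                tail_coords = np.empty((len(idx), 3))
                tail_coords[ca_mask] = beads
                # side-chain pseudo-atoms ride on their Cα; in a planted
                # contact event the charged side chains orient toward the
                # nearest positive binder site (guided soft binding)
                sc_pos = np.where(~ca_mask)[0]
                ca_pos = np.where(ca_mask)[0]
                placed = list(tail_coords[ca_mask])
                for s_i in sc_pos:
                    owner = ca_pos[ca_pos < s_i][-1]
                    ca_xyz = tail_coords[owner]
                    toward = None
                    if biased and len(frame_pos):
                        dpos = np.linalg.norm(frame_pos - ca_xyz, axis=1)
                        jmin = np.argmin(dpos)
                        if dpos[jmin] < 7.0:
                            toward = frame_pos[jmin] - ca_xyz
                    for _ in range(6):
                        if toward is not None:
                            off = st.SC_OFFSET * _unit(
                                toward + 0.2 * rng.normal(size=3), rng)
                        else:
                            off = st.SC_OFFSET * _unit(rng.normal(size=3),
                                                       rng)
                        cand = ca_xyz + off
                        d = np.linalg.norm(np.asarray(placed) - cand, axis=1)
                        d = d[d > 1e-12]  # skip the owner itself at 2.5 Å
                        if not len(d) or d.min() >= 2.0:
                            break
                    tail_coords[s_i] = cand
                    placed.append(cand)
                # keep tails clear of the (jittered) binder: just inside
                # contact range when a planted event fired, strictly outside
                # it otherwise
                rmin = _CONTACT_APPROACH - 0.3 if biased else _TAIL_EXCLUSION
                tail_coords = _push_clear(tail_coords, frame_tree, rmin,
                                          centroid)
                coords[idx] = tail_coords
            _resolve_coincidences(coords, rng)
            frames[f] = coords
            run_ids[f] = run
            f += 1
    return Ensemble(topology=base, frames=frames, run_ids=run_ids)


# ---------------------------------------------------------------------------
# Ensemble I/O
# ---------------------------------------------------------------------------

def write_ensemble(e: Ensemble, prefix: str | Path, fmt: str = "pdb") -> list[Path]:
    """Write one multi-model PDB per replicate run (``<prefix>_run<r>.pdb``).

    With ``fmt="dcd"`` a single DCD trajectory plus PDB topology pair is
    written instead (requires MDAnalysis).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "pdb":
        arr = st.to_atom_array(e.topology)
        for run in e.runs:
            import biotite.structure as bst
            stack = bst.AtomArrayStack(
                int((e.run_ids == run).sum()), e.topology.n_atoms)
            for cat in arr.get_annotation_categories():
                stack.set_annotation(cat, arr.get_annotation(cat))
            stack.coord = e.frames_of_run(run).astype(np.float32)
            pdb = PDBFile()
            pdb.set_structure(stack)
            path = prefix.parent / f"{prefix.name}_run{int(run)}.pdb"
            pdb.write(str(path))
            written.append(path)
    elif fmt == "dcd":
        import MDAnalysis as mda
        top_path = prefix.parent / f"{prefix.name}_top.pdb"
        st.write_structure(e.topology, top_path)
        u = mda.Universe(str(top_path))
        dcd_path = prefix.parent / f"{prefix.name}.dcd"
        with mda.Writer(str(dcd_path), e.topology.n_atoms) as w:
            for frame in e.frames:
                u.atoms.positions = frame
                w.write(u.atoms)
        written = [top_path, dcd_path]
    else:
        raise ValueError(f"unknown ensemble format {fmt!r}")
    return written


def read_ensemble(prefix: str | Path, topology: Structure) -> Ensemble:
    """Read per-run multi-model PDB files written by :func:`write_ensemble`."""
    prefix = Path(prefix)
    frames, run_ids = [], []
    run = 0
    while True:
        path = prefix.parent / f"{prefix.name}_run{run}.pdb"
        if not path.exists():
            break
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        frames.append(coords)
        run_ids.append(np.full(len(coords), run))
        run += 1
    if not frames:
        raise FileNotFoundError(f"no ensemble files at prefix {prefix}")
    return Ensemble(topology=topology,
                    frames=np.concatenate(frames),
                    run_ids=np.concatenate(run_ids))
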