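"""Superposition, RMSD, per-residue RMSF, and linear trend fits.

RMSF is computed per Cα about the ensemble-average structure after
superposing every frame onto that average (the mean → fit → mean cycle is
iterated once, which is enough for these ensembles); the scalar ensemble
RMSF is the arithmetic mean of the per-residue values.  Replicate runs are
averaged per residue before the scalar mean is taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

from .synthetic import Ensemble

__all__ = [
    "RMSFProfile", "LinearFit",
    "kabsch_superpose", "superpose", "rmsd", "rmsf", "fit_linear",
]


def _as_points(P) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    return P


def kabsch_superpose(P, Q, weights=None) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t mapping P onto Q.

    Minimises the weighted RMSD of ``R·p + t`` against ``Q``; reflections
    are excluded (det R = +1).  Returns (R, t, rmsd).
    """
    P, Q = _as_points(P), _as_points(Q)
    if P.shape != Q.shape:
        raise ValueError("point sets must have equal shapes")
    if len(P) < 3:
        raise ValueError("need at least 3 points")
    if weights is None:
        w = np.ones(len(P))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(P),) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("invalid weights")
    w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    P0, Q0 = P - pc, Q - qc
    # degenerate (collinear) sets have a covariance of rank < 2
    H = (w[:, None] * P0).T @ Q0
    if np.linalg.matrix_rank(H, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, _ = Rotation.align_vectors(Q0, P0, weights=w)
    R = rot.as_matrix()
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    val = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum()))
    return R, t, val


def superpose(P, Q, weights=None) -> np.ndarray:
    """P rigidly fitted onto Q."""
    R, t, _ = kabsch_superpose(P, Q, weights)
    return _as_points(P) @ R.T + t


def rmsd(P, Q, superpose_first: bool = True, weights=None) -> float:
    """Root-mean-square deviation between two conformations (Å),
    after optimal superposition unless ``superpose_first=False``."""
    P, Q = _as_points(P), _as_points(Q)
    if P.shape != Q.shape:
        raise ValueError("point sets must have equal shapes")
    if superpose_first:
        _, _, val = kabsch_superpose(P, Q, weights)
        return val
    return float(np.sqrt(((P - Q) ** 2).sum(axis=1).mean()))


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Å) plus its residue-average scalar."""

    per_residue_rmsf: np.ndarray
    residue_keys: list
    fit_frame: np.ndarray | None  # superposition reference (mean structure)

    def __post_init__(self):
        self.per_residue_rmsf = np.asarray(self.per_residue_rmsf, dtype=float)
        if np.any(self.per_residue_rmsf < 0):
            raise ValueError("RMSF values must be >= 0")

    @property
    def mean_rmsf(self) -> float:
        """Arithmetic mean of the per-residue RMSF values."""
        return float(self.per_residue_rmsf.mean())


def _run_rmsf(frames: np.ndarray, superpose_frames: bool) -> tuple[np.ndarray, np.ndarray]:
    if superpose_frames:
        mean = frames.mean(axis=0)
        fitted = np.empty_like(frames)
        for _ in range(2):  # mean → fit → mean, iterated once
            for i, fr in enumerate(frames):
                fitted[i] = superpose(fr, mean)
            mean = fitted.mean(axis=0)
        frames = fitted
    else:
        mean = frames.mean(axis=0)
    dev = frames - mean
    per_atom = np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))
    return per_atom, mean


def rmsf(e: Ensemble, selection: np.ndarray | None = None,
         superpose_frames: bool = True,
         average_runs: bool = True) -> RMSFProfile:
    """Per-residue Cα RMSF of an ensemble.

    ``selection`` defaults to all Cα atoms of the ``"binder"`` group (or of
    the whole topology when no such group exists).  With ``average_runs``
    the per-residue profile is the mean over replicate runs before the
    scalar ensemble average is formed.
    """
    s = e.topology
    if selection is None:
        base = (s.group_indices("binder") if "binder" in s.groups
                else np.arange(s.n_atoms))
        names = np.char.strip(s.names[base].astype(str))
        selection = base[names == "CA"]
    selection = np.asarray(selection, dtype=int)
    if e.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")

    keys = [(str(s.chain_ids[i]), int(s.res_numbers[i]),
             str(s.res_names[i])) for i in selection]
    if average_runs and len(e.runs) > 1:
        profiles = []
        ref = None
        for run in e.runs:
            per_atom, mean = _run_rmsf(e.frames_of_run(run)[:, selection],
                                       superpose_frames)
            profiles.append(per_atom)
            ref = mean
        per_atom = np.mean(profiles, axis=0)
        return RMSFProfile(per_atom, keys, ref)
    per_atom, mean = _run_rmsf(e.frames[:, selection], superpose_frames)
    return RMSFProfile(per_atom, keys, mean)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r: float


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares line with Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    r = 0.0 if np.isnan(res.rvalue) else float(res.rvalue)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r=r)
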