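"""Contact counting and aggregation between a tail group and a binder group.

A *contact* is a heavy-atom pair, one atom from each group, within the
cutoff (default 4.0 Å); each pair is counted once per frame, so totals over
a trajectory are pair-event counts.  Aggregation produces per-residue totals
(which residues of the binder the tails touch), per-segment counts and
percentages (which helices/loops carry the interface), and replicate-mean
time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import Structure
from .synthetic import Ensemble

__all__ = [
    "ContactTable", "ContactSeries",
    "count_contacts", "contact_pairs", "contact_series",
    "build_contact_table", "aggregate_by_segment", "top_contact_residues",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (matching printed-table conventions)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _check_groups(group_a: np.ndarray, group_b: np.ndarray) -> None:
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("contact groups must be disjoint")


def count_contacts(frame: np.ndarray, group_a: Sequence[int],
                   group_b: Sequence[int], cutoff: float = 4.0) -> int:
    """Number of atom pairs (a ∈ A, b ∈ B) with ‖a−b‖ ≤ cutoff.

    Computed with a spatial tree but exactly equal to the all-pairs
    definition.  Empty groups give 0.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    _check_groups(group_a, group_b)
    if group_a.size == 0 or group_b.size == 0:
        return 0
    frame = np.asarray(frame, dtype=float)
    ta = cKDTree(frame[group_a])
    tb = cKDTree(frame[group_b])
    return int(ta.count_neighbors(tb, r=cutoff))


def contact_pairs(frame: np.ndarray, group_a: Sequence[int],
                  group_b: Sequence[int],
                  cutoff: float = 4.0) -> list[tuple[int, int]]:
    """The contacting (a, b) atom-index pairs themselves."""
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    _check_groups(group_a, group_b)
    if group_a.size == 0 or group_b.size == 0:
        return []
    frame = np.asarray(frame, dtype=float)
    tb = cKDTree(frame[group_b])
    out = []
    for k, hits in enumerate(tb.query_ball_point(frame[group_a], r=cutoff)):
        for j in hits:
            out.append((int(group_a[k]), int(group_b[j])))
    return out


def heavy_group(s: Structure, group: str) -> np.ndarray:
    """Heavy-atom subset of a named group."""
    idx = s.group_indices(group)
    return idx[s.heavy_mask[idx]]


@dataclass
class ContactSeries:
    """Per-run contact-count time series and their replicate mean."""

    per_run: np.ndarray          # (n_runs, n_frames_per_run)
    run_labels: np.ndarray
    window: float                # trailing fraction analysed

    @property
    def mean(self) -> np.ndarray:
        """Arithmetic mean across runs at each frame index."""
        return self.per_run.mean(axis=0)

    @property
    def window_start(self) -> int:
        n = self.per_run.shape[1]
        return n - int(round(self.window * n))

    @property
    def windowed(self) -> np.ndarray:
        return self.per_run[:, self.window_start:]

    @property
    def windowed_mean(self) -> float:
        return float(self.windowed.mean())


def contact_series(e: Ensemble, group_a: Sequence[int],
                   group_b: Sequence[int], cutoff: float = 4.0,
                   window: float = 0.5) -> ContactSeries:
    """Contact counts per frame for every replicate run plus their mean.

    The analysis window is the trailing ``window`` fraction of each run
    (equilibrated portion); runs must have equal length.
    """
    if not 0 < window <= 1:
        raise ValueError("window must be in (0, 1]")
    lengths = set(e.run_lengths().values())
    if len(lengths) > 1:
        raise ValueError(f"unequal run lengths: {sorted(lengths)}")
    runs = e.runs
    series = np.empty((len(runs), lengths.pop()), dtype=float)
    for r, run in enumerate(runs):
        for t, frame in enumerate(e.frames_of_run(run)):
            series[r, t] = count_contacts(frame, group_a, group_b, cutoff)
    return ContactSeries(per_run=series, run_labels=runs, window=window)


@dataclass
class ContactTable:
    """Accumulated contact statistics for one (tail group, binder group).

    ``per_frame`` holds windowed per-frame pair counts; ``per_residue`` and
    ``per_segment`` accumulate totals over the analysed frames of all runs,
    keyed by the binder-side residue / segment.
    """

    per_frame: np.ndarray
    per_residue: dict = field(default_factory=dict)
    per_segment: dict = field(default_factory=dict)
    cutoff: float = 4.0
    groups: tuple[str, str] = ("tails", "binder")

    @property
    def total(self) -> int:
        return int(sum(self.per_segment.values())) if self.per_segment else 0

    def segment_percentages(self) -> dict[str, float]:
        total = sum(self.per_segment.values())
        if total == 0:
            return {k: 0.0 for k in self.per_segment}
        return {k: round_half_up(100.0 * v / total, 2)
                for k, v in self.per_segment.items()}


def build_contact_table(e: Ensemble, tail_group: str = "tails",
                        binder_group: str = "binder", cutoff: float = 4.0,
                        window: float = 0.5) -> ContactTable:
    """Count tail–binder heavy-atom contacts over the analysis window and
    aggregate them by binder residue and binder segment."""
    s = e.topology
    ia = heavy_group(s, tail_group)
    ib = heavy_group(s, binder_group)
    lengths = set(e.run_lengths().values())
    if len(lengths) > 1:
        raise ValueError("unequal run lengths")
    n = lengths.pop()
    start = n - int(round(window * n))

    per_frame = []
    per_residue: dict = {}
    per_segment: dict = {}
    for run in e.runs:
        frames = e.frames_of_run(run)[start:]
        for frame in frames:
            pairs = contact_pairs(frame, ia, ib, cutoff)
            per_frame.append(len(pairs))
            for _, b in pairs:
                rkey = (str(s.chain_ids[b]), int(s.res_numbers[b]),
                        str(s.res_names[b]))
                per_residue[rkey] = per_residue.get(rkey, 0) + 1
                seg = str(s.segments[b])
                per_segment[seg] = per_segment.get(seg, 0) + 1
    return ContactTable(per_frame=np.asarray(per_frame, dtype=int),
                        per_residue=per_residue, per_segment=per_segment,
                        cutoff=cutoff, groups=(tail_group, binder_group))


def aggregate_by_segment(counts: "ContactTable | Mapping[str, int]",
                         segment_order: Sequence[str] | None = None
                         ) -> pd.DataFrame:
    """Per-segment contact counts and percentages.

    ``percentage(seg) = 100 · count(seg) / Σ counts``, rounded half-up to two
    decimals.  Accepts a ContactTable or a plain segment → count mapping.
    """
    if isinstance(counts, ContactTable):
        counts = counts.per_segment
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative contact count")
    keys = list(segment_order) if segment_order else list(counts)
    missing = set(counts) - set(keys)
    if missing:
        raise ValueError(f"counts for unmapped segments: {sorted(missing)}")
    total = sum(counts.get(k, 0) for k in keys)
    rows = []
    for k in keys:
        c = counts.get(k, 0)
        pct = round_half_up(100.0 * c / total, 2) if total else 0.0
        rows.append((k, c, pct))
    return pd.DataFrame(rows, columns=["segment", "count", "percentage"])


def top_contact_residues(per_residue: "ContactTable | Mapping", k: int = 10
                         ) -> list[tuple[tuple, int]]:
    """Residues ranked by total contacts, descending; ties broken by
    ascending residue number.  Zero-count residues are dropped."""
    if isinstance(per_residue, ContactTable):
        per_residue = per_residue.per_residue
    items = [(key, int(v)) for key, v in per_residue.items() if v > 0]
    items.sort(key=lambda kv: (-kv[1], kv[0][1]))
    return items[:k]


def write_contact_tsv(table: ContactTable, path: str | Path) -> None:
    df = aggregate_by_segment(table)
    df.to_csv(path, sep="\t", index=False)
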