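"""Excess-proton identification and continuous track extraction.

Every hydrogen is assigned to its nearest oxygen (minimum image); an oxygen
carrying three hydrogens is a hydronium ion and all three hydrogens become
excess-proton candidates.  A candidate that later changes its assigned
oxygen -- i.e. actually transfers -- is selected as the excess proton for
the entire contiguous interval during which it belonged to any hydronium.
This dynamic criterion avoids the spurious identity switches of the
'special pair dance' that a largest-OH-distance rule would produce.

Selected protons are projected onto the special-pair coordinates: the
oxygen-oxygen distance R_OO of the two nearest water oxygens and the signed
proton offset d from their midplane along the O-O axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .traj_io import AtomicFrame, Trajectory, minimum_image


class GeometryError(ValueError):
    pass


@dataclass
class ProtonAssignment:
    """Per-frame hydrogen->oxygen map and resulting hydronium set."""

    h_indices: np.ndarray  # hydrogen atom indices, (n_H,)
    o_indices: np.ndarray  # oxygen atom indices, (n_O,)
    nearest_oxygen: np.ndarray  # for each hydrogen, index into the full atom list
    hydronium_oxygens: frozenset[int]


def assign_hydrogens(frame: AtomicFrame) -> ProtonAssignment:
    """Assign each hydrogen to its closest oxygen under periodic boundaries.

    Equidistant ties go to the lowest oxygen atom index (deterministic).
    """
    elems = np.asarray(frame.elements)
    h_idx = np.flatnonzero(elems == "H")
    o_idx = np.flatnonzero(elems == "O")
    if len(o_idx) == 0:
        raise ValueError("frame contains no oxygen atoms")
    # (n_H, n_O) minimum-image distances
    disp = minimum_image(
        frame.positions[h_idx][:, None, :],
        frame.positions[o_idx][None, :, :],
        frame.cell_edge,
    )
    dist = np.linalg.norm(disp, axis=-1)
    nearest = o_idx[np.argmin(dist, axis=1)]  # argmin takes first (lowest index) on ties
    counts: dict[int, int] = {}
    for o in nearest:
        counts[int(o)] = counts.get(int(o), 0) + 1
    hydronium = frozenset(o for o, n in counts.items() if n == 3)
    return ProtonAssignment(
        h_indices=h_idx, o_indices=o_idx, nearest_oxygen=nearest,
        hydronium_oxygens=hydronium,
    )


@dataclass
class ExcessProtonTrack:
    """One continuous excess-proton trajectory in special-pair coordinates."""

    proton_index: int
    first_frame: int
    dt: float  # fs
    d: np.ndarray  # signed offset from the O-O midplane, A
    roo: np.ndarray  # O-O distance, A
    flanking_oxygens: np.ndarray  # (T, 2) atom indices (ordered: positive-d side last)
    chloride_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.roo = np.asarray(self.roo, dtype=float)
        if self.chloride_flag is None:
            self.chloride_flag = np.zeros(len(self.d), dtype=bool)
        if np.any(self.roo <= 0):
            raise GeometryError("R_OO must be positive")
        if np.any(np.abs(self.d) >= self.roo / 2):
            raise GeometryError("|d| must stay below R_OO/2")

    def __len__(self) -> int:
        return len(self.d)

    @property
    def times(self) -> np.ndarray:
        return (self.first_frame + np.arange(len(self.d))) * self.dt

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: frame, time_fs, proton_idx, O1/O2, d, R_OO, cl flag."""
        frames = self.first_frame + np.arange(len(self.d))
        return pd.DataFrame(
            {
                "frame": frames,
                "time_fs": frames * self.dt,
                "proton_idx": self.proton_index,
                "O1_idx": self.flanking_oxygens[:, 0],
                "O2_idx": self.flanking_oxygens[:, 1],
                "d_A": self.d,
                "Roo_A": self.roo,
                "cl_flag": self.chloride_flag,
            }
        )


def pair_coordinates(
    o_a: np.ndarray, o_b: np.ndarray, h: np.ndarray, cell_edge: float
) -> tuple[float, float]:
    """(d, R_OO) of a proton relative to the ordered oxygen pair (o_a, o_b).

    R_OO is the minimum-image |o_b - o_a|; d is the projection of the proton
    offset from the O-O midpoint onto the unit axis from o_a to o_b, so
    d > 0 means the proton sits on the o_b side of the midplane.
    """
    axis = minimum_image(o_a, o_b, cell_edge)
    roo = float(np.linalg.norm(axis))
    if roo <= 0:
        raise GeometryError("coincident oxygen positions")
    # proton relative to midpoint, built from minimum images w.r.t. o_a
    h_rel = minimum_image(o_a, h, cell_edge) - axis / 2.0
    d = float(np.dot(h_rel, axis) / roo)
    return d, roo


def special_pair_coordinates(
    frame: AtomicFrame,
    proton: int,
    prev_pair: Optional[tuple[int, int]] = None,
    prev_d: Optional[float] = None,
) -> tuple[float, float, tuple[int, int]]:
    """Project one proton onto its transient H5O2+ special-pair coordinates.

    The flanking pair is the proton's two nearest water oxygens (chloride is
    never a flanking partner).  Ordering -- and hence the sign of d -- is
    inherited from ``prev_pair`` whenever both oxygens persist; when the
    partner changes, the new ordering is chosen to keep the sign of d
    continuous with ``prev_d``.

    Returns ``(d, R_OO, (o_neg, o_pos))`` where ``o_pos`` is the oxygen on
    the positive-d side.
    """
    elems = np.asarray(frame.elements)
    o_idx = np.flatnonzero(elems == "O")
    if len(o_idx) < 2:
        raise GeometryError("need at least two water oxygens")
    disp = minimum_image(frame.positions[proton], frame.positions[o_idx], frame.cell_edge)
    dist = np.linalg.norm(disp, axis=-1)
    order = np.argsort(dist, kind="stable")
    nearest_two = {int(o_idx[order[0]]), int(o_idx[order[1]])}

    if prev_pair is not None and set(prev_pair) == nearest_two:
        pair = prev_pair
    else:
        a, b = sorted(nearest_two)
        pair = (a, b)
    d, roo = pair_coordinates(
        frame.positions[pair[0]], frame.positions[pair[1]],
        frame.positions[proton], frame.cell_edge,
    )
    if prev_pair is not None and set(prev_pair) == nearest_two:
        return d, roo, pair
    # re-anchor sign: keep continuity with the previous d, or start positive
    ref = prev_d if prev_d is not None and prev_d != 0.0 else None
    if (ref is not None and d * ref < 0) or (ref is None and d < 0):
        pair = (pair[1], pair[0])
        d = -d
    return d, roo, pair


def flag_chloride_coordination(
    track: ExcessProtonTrack, traj: Trajectory
) -> ExcessProtonTrack:
    """Flag frames where the proton's second-nearest heavy neighbor is Cl-.

    Such chloride-coordinated configurations are excluded from free-energy
    and spectral statistics downstream (the flag is set here; exclusion
    happens at histogram/spectrum assembly).
    """
    elems = np.asarray(traj.elements)
    heavy = np.flatnonzero((elems == "O") | (elems == "Cl"))
    if not np.any(elems == "Cl"):
        return track
    flags = np.zeros(len(track), dtype=bool)
    for k in range(len(track)):
        fr = traj.frames[track.first_frame + k]
        disp = minimum_image(
            fr.positions[track.proton_index], fr.positions[heavy], fr.cell_edge
        )
        dist = np.linalg.norm(disp, axis=-1)
        second = heavy[np.argsort(dist, kind="stable")[1]]
        flags[k] = elems[second] == "Cl"
    track.chloride_flag = flags
    return track


def extract_excess_tracks(traj: Trajectory) -> list[ExcessProtonTrack]:
    """Extract continuous excess-proton tracks from a trajectory.

    A track is emitted for every (proton, hydronium-membership episode)
    that contains at least one change of the proton's assigned oxygen.
    Protons that never transfer are not selected.
    """
    assignments = [assign_hydrogens(fr) for fr in traj.frames]
    n_frames = len(traj)
    h_idx = assignments[0].h_indices
    # membership[t, i]: hydrogen i belongs to a hydronium at frame t
    assigned = np.stack([a.nearest_oxygen for a in assignments])  # (T, n_H)
    member = np.zeros((n_frames, len(h_idx)), dtype=bool)
    for t, a in enumerate(assignments):
        hyd = a.hydronium_oxygens
        member[t] = np.fromiter((int(o) in hyd for o in a.nearest_oxygen),
                                dtype=bool, count=len(h_idx))

    tracks: list[ExcessProtonTrack] = []
    for i, proton in enumerate(h_idx):
        m = member[:, i]
        if not m.any():
            continue
        # maximal contiguous membership episodes
        edges = np.flatnonzero(np.diff(m.astype(int)))
        starts = [0] if m[0] else []
        starts += [int(e) + 1 for e in edges if m[e + 1]]
        ends = [int(e) + 1 for e in edges if m[e]]  # exclusive
        if m[-1]:
            ends.append(n_frames)
        for s, e in zip(starts, ends):
            changes = np.flatnonzero(np.diff(assigned[s:e, i]) != 0)
            if len(changes) == 0:
                continue  # candidate never transferred in this episode
            tracks.append(_build_track(traj, int(proton), s, e))
    return tracks


def _build_track(
    traj: Trajectory, proton: int, start: int, stop: int
) -> ExcessProtonTrack:
    d = np.empty(stop - start)
    roo = np.empty(stop - start)
    pairs = np.empty((stop - start, 2), dtype=int)
    pair: Optional[tuple[int, int]] = None
    prev_d: Optional[float] = None
    for k, t in enumerate(range(start, stop)):
        d[k], roo[k], pair = special_pair_coordinates(
            traj.frames[t], proton, prev_pair=pair, prev_d=prev_d
        )
        pairs[k] = pair
        prev_d = d[k]
    return ExcessProtonTrack(
        proton_index=proton, first_frame=start, dt=traj.dt,
        d=d, roo=roo, flanking_oxygens=pairs,
    )


def tracks_to_table(tracks: list[ExcessProtonTrack]) -> pd.DataFrame:
    """Concatenate track tables (one row per frame per track)."""
    if not tracks:
        return pd.DataFrame(
            columns=["frame", "time_fs", "proton_idx", "O1_idx", "O2_idx",
                     "d_A", "Roo_A", "cl_flag"]
        )
    return pd.concat([t.to_frame() for t in tracks], ignore_index=True)
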