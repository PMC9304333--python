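"""Trajectory containers, extended-XYZ input/output and periodic geometry.

The on-disk format is plain (extended-)XYZ with a cubic cell.  The comment
line may carry ``time=<fs>`` and ``cell=<A>`` tokens (either ``key=value``
style or inside an ASE-style ``Lattice="..."`` entry is not supported --
the dialect is deliberately small).  Wannier centers are stored as
pseudo-element ``X`` records so one reader handles both nuclei-only and
electronic trajectories.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .constants import KNOWN_ELEMENTS


class TrajectoryFormatError(ValueError):
    """Raised for malformed or inconsistent trajectory files."""


class AlignmentError(ValueError):
    """Raised when two trajectories cannot be merged on a common time grid."""


@dataclass
class TrajectoryMeta:
    """Run-level metadata: thermodynamic state and sampling intervals."""

    temperature: float = 300.0  # K
    volume: Optional[float] = None  # A^3
    c_w: Optional[float] = None  # mol/L, water concentration
    c_hcl: Optional[float] = None  # mol/L
    dt_wc: Optional[float] = None  # fs, Wannier-center sampling interval

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.volume is not None and self.volume <= 0:
            raise ValueError("volume must be positive")
        for c in (self.c_w, self.c_hcl):
            if c is not None and c < 0:
                raise ValueError("concentrations must be nonnegative")


@dataclass
class AtomicFrame:
    """One snapshot: element labels plus positions in a cubic periodic cell."""

    time: float  # fs
    cell_edge: float  # A
    elements: tuple[str, ...]
    positions: np.ndarray  # (N, 3) A
    wannier_positions: Optional[np.ndarray] = None  # (M, 3) A

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.elements) != len(self.positions):
            raise ValueError("element and position counts differ")
        if self.cell_edge <= 0:
            raise ValueError("cell_edge must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.wannier_positions is not None:
            self.wannier_positions = np.asarray(self.wannier_positions, dtype=float)
            if not np.all(np.isfinite(self.wannier_positions)):
                raise ValueError("non-finite Wannier coordinates")

    def indices_of(self, element: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.elements) == element)


@dataclass
class Trajectory:
    """Uniformly sampled sequence of frames with identical element lists."""

    frames: list[AtomicFrame]
    dt: float  # fs
    meta: TrajectoryMeta = field(default_factory=TrajectoryMeta)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        ref = self.frames[0].elements
        for fr in self.frames[1:]:
            if fr.elements != ref:
                raise TrajectoryFormatError("element lists differ between frames")
        times = np.array([fr.time for fr in self.frames])
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0) or not np.allclose(steps, self.dt, atol=1e-6):
                raise TrajectoryFormatError(
                    "frame times must increase uniformly by dt"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def elements(self) -> tuple[str, ...]:
        return self.frames[0].elements

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def positions_array(self) -> np.ndarray:
        """All nuclei positions as one (T, N, 3) array."""
        return np.stack([fr.positions for fr in self.frames])


# ---------------------------------------------------------------------------
# periodic geometry


def minimum_image(a: np.ndarray, b: np.ndarray, cell_edge: float) -> np.ndarray:
    """Displacement b - a wrapped componentwise into [-L/2, L/2).

    Works on single vectors or broadcastable arrays of positions.
    """
    if cell_edge <= 0:
        raise ValueError("cell_edge must be positive")
    delta = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return delta - cell_edge * np.floor(delta / cell_edge + 0.5)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, cell_edge: float) -> np.ndarray:
    return np.linalg.norm(minimum_image(a, b, cell_edge), axis=-1)


def unwrap_series(positions: np.ndarray, cell_edge: float) -> np.ndarray:
    """Remove periodic jumps from a (T, ..., 3) position time series.

    Consecutive displacements are replaced by their minimum images and
    cumulatively summed, which keeps molecular trajectories continuous.
    """
    pos = np.asarray(positions, dtype=float)
    steps = minimum_image(pos[:-1], pos[1:], cell_edge)
    out = np.empty_like(pos)
    out[0] = pos[0]
    np.cumsum(steps, axis=0, out=out[1:])
    out[1:] += pos[0]
    return out


# ---------------------------------------------------------------------------
# extended-XYZ reading and writing

_TIME_RE = re.compile(r"(?:^|\s)time=([-+0-9.eE]+)")
_CELL_RE = re.compile(r"(?:^|\s)cell=([-+0-9.eE]+)")


def read_xyz_trajectory(
    path: str | Path,
    cell_edge: Optional[float] = None,
    dt: float = 0.5,
    meta: Optional[TrajectoryMeta] = None,
) -> Trajectory:
    """Read an (extended-)XYZ file into a :class:`Trajectory`.

    Comment-line ``time=`` stamps are used when parseable and uniform,
    otherwise times are synthesized from ``dt``.  ``cell=`` on the comment
    line supplies the cubic cell edge unless ``cell_edge`` overrides it.
    Pseudo-element ``X`` records become Wannier-center positions.
    """
    lines = Path(path).read_text().splitlines()
    frames_raw: list[tuple[Optional[float], Optional[float], list[str], np.ndarray]] = []
    i = 0
    natoms_ref: Optional[int] = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"expected atom count at line {i + 1}"
            ) from exc
        if natoms_ref is None:
            natoms_ref = natoms
        elif natoms != natoms_ref:
            raise TrajectoryFormatError(
                f"inconsistent atom count at line {i + 1}: {natoms} != {natoms_ref}"
            )
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            raise TrajectoryFormatError("truncated frame at end of file")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t_match = _TIME_RE.search(comment)
        c_match = _CELL_RE.search(comment)
        t_val = float(t_match.group(1)) if t_match else None
        c_val = float(c_match.group(1)) if c_match else None
        elems: list[str] = []
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(f"short atom line at {i + 3 + k}")
            if parts[0] not in KNOWN_ELEMENTS:
                raise TrajectoryFormatError(f"unknown element symbol {parts[0]!r}")
            elems.append(parts[0])
            coords[k] = [float(x) for x in parts[1:4]]
        frames_raw.append((t_val, c_val, elems, coords))
        i += 2 + natoms

    if not frames_raw:
        raise TrajectoryFormatError(f"no frames found in {path}")

    times = [t for t, _, _, _ in frames_raw]
    use_stamps = all(t is not None for t in times)
    if use_stamps and len(times) > 1:
        steps = np.diff(np.array(times, dtype=float))
        use_stamps = bool(np.all(steps > 0) and np.allclose(steps, steps[0], atol=1e-9))
        if use_stamps:
            dt = float(steps[0])

    frames: list[AtomicFrame] = []
    for k, (t_val, c_val, elems, coords) in enumerate(frames_raw):
        edge = cell_edge if cell_edge is not None else c_val
        if edge is None:
            raise TrajectoryFormatError(
                "no cell edge: pass cell_edge or put cell=<A> on the comment line"
            )
        nuc_mask = np.array([e != "X" for e in elems])
        wc = coords[~nuc_mask] if not nuc_mask.all() else None
        frames.append(
            AtomicFrame(
                time=float(t_val) if use_stamps else k * dt,
                cell_edge=float(edge),
                elements=tuple(e for e in elems if e != "X"),
                positions=coords[nuc_mask],
                wannier_positions=wc,
            )
        )
    return Trajectory(frames=frames, dt=dt, meta=meta or TrajectoryMeta())


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as extended-XYZ (Wannier centers as element X)."""
    out: list[str] = []
    for fr in traj.frames:
        nwc = 0 if fr.wannier_positions is None else len(fr.wannier_positions)
        out.append(str(len(fr.elements) + nwc))
        out.append(f"time={fr.time:.6f} cell={fr.cell_edge:.8f}")
        for el, (x, y, z) in zip(fr.elements, fr.positions):
            out.append(f"{el} {x:.10f} {y:.10f} {z:.10f}")
        if fr.wannier_positions is not None:
            for x, y, z in fr.wannier_positions:
                out.append(f"X {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(out) + "\n")


def merge_wannier(nuclei: Trajectory, wannier: Trajectory) -> Trajectory:
    """Attach Wannier-center positions to the matching nuclei frames.

    The electronic trajectory is sampled more coarsely than the nuclei
    (every 2-4 fs vs 0.5 fs); the merged trajectory lives on the Wannier
    time grid while the high-resolution nuclei source remains available for
    kinetics.  Non-commensurate rates or misaligned grids raise
    :class:`AlignmentError`.
    """
    ratio = wannier.dt / nuclei.dt
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise AlignmentError(
            f"Wannier dt {wannier.dt} is not an integer multiple of nuclei dt {nuclei.dt}"
        )
    nuc_times = nuclei.times
    lookup = {round(t / nuclei.dt): idx for idx, t in enumerate(nuc_times)}
    merged: list[AtomicFrame] = []
    for wfr in wannier.frames:
        key = wfr.time / nuclei.dt
        if abs(key - round(key)) > 1e-6 or round(key) not in lookup:
            raise AlignmentError(
                f"Wannier frame at t={wfr.time} fs has no matching nuclei frame"
            )
        nfr = nuclei.frames[lookup[round(key)]]
        wc = wfr.wannier_positions
        if wc is None and "X" not in wfr.elements:
            # nuclei-style file used as Wannier source: all positions are centers
            wc = wfr.positions
        merged.append(replace(nfr, wannier_positions=wc))
    if not merged:
        raise AlignmentError("no overlapping frames")
    meta = replace(nuclei.meta, dt_wc=wannier.dt)
    return Trajectory(frames=merged, dt=wannier.dt, meta=meta)
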