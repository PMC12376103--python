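"""Extended-XYZ trajectory I/O and periodic-boundary geometry primitives.

The on-disk format is the ase/OVITO-compatible extended XYZ flavour: each
frame is ``natoms`` / comment / ``natoms`` atom lines, with the orthorhombic
cell carried on the comment line as ``Lattice="lx 0 0 0 ly 0 0 0 lz"`` and
``Properties=species:S:1:pos:R:3``.  Wannier centers are stored as
pseudo-atoms with element symbol ``"X"`` (the CP2K convention).  Path-integral
bead trajectories are written either as one file per bead
(``<stem>.bead-<k>.xyz``) or interleaved with a ``bead=<k>`` comment key;
the reader handles both.

Coordinates are Cartesian angstrom and are never wrapped on read; all
analyses apply the minimum-image convention themselves.  Only orthorhombic
cells are supported; triclinic input is rejected.
"""

from __future__ import annotations

import glob
import os
import re
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence

import numpy as np

__all__ = [
    "SimulationCell",
    "Frame",
    "Trajectory",
    "ExtXYZParseError",
    "UnsupportedCellError",
    "read_extxyz",
    "write_extxyz",
    "mic_displacement",
    "distance",
]


class ExtXYZParseError(ValueError):
    """Malformed extended-XYZ input; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnsupportedCellError(ValueError):
    """Non-orthorhombic (or otherwise invalid) simulation cell."""


@dataclass(frozen=True)
class SimulationCell:
    """Orthorhombic simulation cell with edge lengths in angstrom."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self):
        if not (self.lx > 0 and self.ly > 0 and self.lz > 0):
            raise UnsupportedCellError(
                f"cell lengths must be positive, got ({self.lx}, {self.ly}, {self.lz})"
            )

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)

    @property
    def volume(self) -> float:
        return float(self.lx * self.ly * self.lz)

    def lattice_string(self) -> str:
        return f'Lattice="{self.lx:.10g} 0 0 0 {self.ly:.10g} 0 0 0 {self.lz:.10g}"'


@dataclass
class Frame:
    """One trajectory frame: species, Cartesian positions (A), cell.

    Wannier-center pseudo-atoms appear as species ``"X"``.  ``bead_index``
    is set for path-integral bead frames and ``None`` for classical ones.
    """

    species: Sequence[str]
    positions: np.ndarray
    cell: SimulationCell
    frame_index: int = 0
    bead_index: Optional[int] = None
    time_fs: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.species), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.species)} species"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def indices_of(self, element: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.species) if s == element], dtype=int)

    def without_wannier(self) -> "Frame":
        keep = [i for i, s in enumerate(self.species) if s != "X"]
        return Frame(
            species=[self.species[i] for i in keep],
            positions=self.positions[keep],
            cell=self.cell,
            frame_index=self.frame_index,
            bead_index=self.bead_index,
            time_fs=self.time_fs,
            meta=dict(self.meta),
        )


class Trajectory:
    """Ordered collection of frames sharing one species list and cell.

    Positions are stored as a single ``(n_frames, n_atoms, 3)`` array so that
    per-frame observables can be computed vectorized; indexing returns a
    :class:`Frame` view.  For a path-integral trajectory with ``n_beads = P``,
    frames with equal ``frame_index`` and bead indices ``0..P-1`` form one
    complete bead set.
    """

    def __init__(
        self,
        species: Sequence[str],
        positions: np.ndarray,
        cell: SimulationCell,
        frame_index: Optional[np.ndarray] = None,
        bead_index: Optional[np.ndarray] = None,
        time_fs: Optional[np.ndarray] = None,
        n_beads: int = 1,
        dt_fs: float = 0.5,
        temperature_K: float = 300.0,
        meta: Optional[dict] = None,
    ):
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 3 or positions.shape[1] != len(species) or positions.shape[2] != 3:
            raise ValueError(f"positions must be (n_frames, {len(species)}, 3), got {positions.shape}")
        if n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        n = positions.shape[0]
        self.species = list(species)
        self.positions = positions
        self.cell = cell
        self.n_beads = int(n_beads)
        self.dt_fs = float(dt_fs)
        self.temperature_K = float(temperature_K)
        self.meta = dict(meta) if meta else {}
        if frame_index is None:
            if n_beads > 1:
                if n % n_beads:
                    raise ValueError("frame count not divisible by n_beads")
                frame_index = np.repeat(np.arange(n // n_beads), n_beads)
            else:
                frame_index = np.arange(n)
        self.frame_index = np.asarray(frame_index, dtype=int)
        if bead_index is None and n_beads > 1:
            bead_index = np.tile(np.arange(n_beads), n // n_beads)
        self.bead_index = None if bead_index is None else np.asarray(bead_index, dtype=int)
        if self.bead_index is not None and (
            self.bead_index.min() < 0 or self.bead_index.max() >= self.n_beads
        ):
            raise ValueError("bead_index out of range [0, P-1]")
        self.time_fs = None if time_fs is None else np.asarray(time_fs, dtype=float)

    # -- sequence protocol ------------------------------------------------

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __getitem__(self, i: int) -> Frame:
        return Frame(
            species=self.species,
            positions=self.positions[i],
            cell=self.cell,
            frame_index=int(self.frame_index[i]),
            bead_index=None if self.bead_index is None else int(self.bead_index[i]),
            time_fs=None if self.time_fs is None else float(self.time_fs[i]),
        )

    def __iter__(self) -> Iterator[Frame]:
        for i in range(len(self)):
            yield self[i]

    @property
    def n_frame_sets(self) -> int:
        """Number of distinct frame indices (bead sets for quantum runs)."""
        return len(np.unique(self.frame_index))

    def bead(self, k: int) -> "Trajectory":
        """Sub-trajectory of a single bead, preserving frame order."""
        if self.bead_index is None:
            if k != 0:
                raise IndexError("classical trajectory has only bead 0")
            return self
        mask = self.bead_index == k
        if not mask.any():
            raise IndexError(f"no frames with bead_index {k}")
        return Trajectory(
            self.species,
            self.positions[mask],
            self.cell,
            frame_index=self.frame_index[mask],
            bead_index=None,
            time_fs=None if self.time_fs is None else self.time_fs[mask],
            n_beads=1,
            dt_fs=self.dt_fs,
            temperature_K=self.temperature_K,
            meta=self.meta,
        )

    @classmethod
    def from_frames(
        cls,
        frames: Sequence[Frame],
        n_beads: int = 1,
        dt_fs: float = 0.5,
        temperature_K: float = 300.0,
        meta: Optional[dict] = None,
    ) -> "Trajectory":
        if not frames:
            raise ValueError("cannot build a trajectory from zero frames")
        first = frames[0]
        for f in frames[1:]:
            if list(f.species) != list(first.species):
                raise ValueError("all frames must share atom count and species order")
        has_beads = any(f.bead_index is not None for f in frames)
        return cls(
            species=first.species,
            positions=np.stack([f.positions for f in frames]),
            cell=first.cell,
            frame_index=np.array([f.frame_index for f in frames]),
            bead_index=np.array([f.bead_index or 0 for f in frames]) if has_beads else None,
            time_fs=(
                np.array([f.time_fs for f in frames])
                if all(f.time_fs is not None for f in frames)
                else None
            ),
            n_beads=n_beads if not has_beads else max(
                n_beads, max(f.bead_index or 0 for f in frames) + 1
            ),
            dt_fs=dt_fs,
            temperature_K=temperature_K,
            meta=meta,
        )

    def distances(self, i: int, j: int) -> np.ndarray:
        """Minimum-image distance between atoms i and j for every frame."""
        d = self.positions[:, j] - self.positions[:, i]
        L = self.cell.lengths
        d = d - L * np.floor(d / L + 0.5)
        return np.linalg.norm(d, axis=1)


# -- geometry primitives --------------------------------------------------


def mic_displacement(a: np.ndarray, b: np.ndarray, cell: SimulationCell) -> np.ndarray:
    """Minimum-image displacement b - a; each component lies in (-L/2, L/2].

    The boundary tie at exactly half a cell length resolves to +L/2.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    L = cell.lengths
    d = d - L * np.floor(d / L + 0.5)
    # floor maps the exact +L/2 tie to -L/2; push it back to the +L/2 side
    tie = d <= -L / 2
    d = np.where(tie, d + L, d)
    return d


def distance(frame: Frame, i: int, j: int) -> float:
    """Minimum-image distance between atoms i and j of a frame, in angstrom."""
    n = frame.n_atoms
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range: ({i}, {j}) for {n} atoms")
    return float(np.linalg.norm(mic_displacement(frame.positions[i], frame.positions[j], frame.cell)))


# -- extended XYZ parsing -------------------------------------------------

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(comment: str, lineno: int):
    kv = {}
    for m in _KV_RE.finditer(comment):
        kv[m.group(1)] = m.group(2) if m.group(2) is not None else m.group(3)
    lattice = None
    for key in ("Lattice", "lattice"):
        if key in kv:
            lattice = kv[key]
            break
    if lattice is None:
        raise ExtXYZParseError("comment line carries no Lattice= cell", lineno)
    try:
        nums = [float(t) for t in lattice.split()]
    except ValueError:
        raise ExtXYZParseError(f"cannot parse Lattice entries: {lattice!r}", lineno)
    if len(nums) != 9:
        raise ExtXYZParseError(f"Lattice must contain nine numbers, got {len(nums)}", lineno)
    mat = np.array(nums).reshape(3, 3)
    off = mat - np.diag(np.diag(mat))
    if np.abs(off).max() > 1e-8 * max(1.0, np.abs(mat).max()):
        raise UnsupportedCellError(
            f"non-orthorhombic cell at line {lineno}: off-diagonal terms {off.ravel().tolist()}"
        )
    cell = SimulationCell(mat[0, 0], mat[1, 1], mat[2, 2])
    return cell, kv


def _read_extxyz_file(path: str, keep_wannier: bool = True) -> List[Frame]:
    frames: List[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    default_index = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ExtXYZParseError(f"expected atom count, got {lines[i]!r}", i + 1)
        if natoms <= 0:
            raise ExtXYZParseError(f"non-positive atom count {natoms}", i + 1)
        if i + 1 >= len(lines):
            raise ExtXYZParseError("missing comment line after atom count", i + 2)
        cell, kv = _parse_comment(lines[i + 1], i + 2)
        species: List[str] = []
        pos = np.empty((natoms, 3))
        for a in range(natoms):
            ln = i + 2 + a
            if ln >= len(lines):
                raise ExtXYZParseError(
                    f"truncated frame: expected {natoms} atom lines, file ends early", ln + 1
                )
            toks = lines[ln].split()
            if len(toks) < 4:
                raise ExtXYZParseError(f"atom line has {len(toks)} fields, need >= 4", ln + 1)
            species.append(toks[0])
            try:
                pos[a] = [float(toks[1]), float(toks[2]), float(toks[3])]
            except ValueError:
                raise ExtXYZParseError(f"cannot parse coordinates: {lines[ln]!r}", ln + 1)
        meta = {}
        for key in ("dt_fs", "temperature_K"):
            if key in kv:
                meta[key] = float(kv[key])
        if "n_beads" in kv:
            meta["n_beads"] = int(kv["n_beads"])
        frame = Frame(
            species=species,
            positions=pos,
            cell=cell,
            frame_index=int(kv.get("frame", default_index)),
            bead_index=int(kv["bead"]) if "bead" in kv else None,
            time_fs=float(kv["time"]) if "time" in kv else None,
            meta=meta,
        )
        if not keep_wannier:
            frame = frame.without_wannier()
        frames.append(frame)
        default_index += 1
        i += 2 + natoms
    if not frames:
        raise ExtXYZParseError(f"no frames found in {path}", None)
    return frames


def _bead_siblings(path: str) -> List[str]:
    stem, ext = os.path.splitext(path)
    found = sorted(
        glob.glob(f"{glob.escape(stem)}.bead-*{ext}"),
        key=lambda p: int(re.search(r"\.bead-(\d+)", p).group(1)),
    )
    return found


def read_extxyz(path: str, keep_wannier: bool = True) -> Trajectory:
    """Read an extended-XYZ trajectory (single file or per-bead file family).

    If ``path`` itself does not exist but sibling files ``<stem>.bead-<k>.xyz``
    do, the bead family is read and merged into a single multi-bead
    trajectory.  Set ``keep_wannier=False`` to drop Wannier-center ("X")
    records on read.
    """
    if os.path.exists(path):
        frames = _read_extxyz_file(path, keep_wannier)
        beads = sorted({f.bead_index for f in frames if f.bead_index is not None})
        n_beads = frames[0].meta.get("n_beads", (beads[-1] + 1) if beads else 1)
    else:
        siblings = _bead_siblings(path)
        if not siblings:
            raise FileNotFoundError(path)
        frames = []
        for p in siblings:
            k = int(re.search(r"\.bead-(\d+)", p).group(1))
            for f in _read_extxyz_file(p, keep_wannier):
                if f.bead_index is None:
                    f.bead_index = k
                frames.append(f)
        # interleave by (frame_index, bead_index) so bead sets are contiguous
        frames.sort(key=lambda f: (f.frame_index, f.bead_index))
        n_beads = len(siblings)
    meta = frames[0].meta
    return Trajectory.from_frames(
        frames,
        n_beads=n_beads,
        dt_fs=meta.get("dt_fs", 0.5),
        temperature_K=meta.get("temperature_K", 300.0),
    )


def _write_frames(frames: Sequence[Frame], traj: Trajectory, path: str) -> None:
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f"{f.n_atoms}\n")
            comment = (
                f.cell.lattice_string()
                + ' Properties=species:S:1:pos:R:3'
                + f" frame={f.frame_index}"
            )
            if f.bead_index is not None:
                comment += f" bead={f.bead_index}"
            if f.time_fs is not None:
                comment += f" time={f.time_fs:.6g}"
            comment += (
                f" n_beads={traj.n_beads} dt_fs={traj.dt_fs:.10g}"
                f" temperature_K={traj.temperature_K:.10g}"
            )
            fh.write(comment + "\n")
            for s, p in zip(f.species, f.positions):
                fh.write(f"{s} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")


def write_extxyz(traj: Trajectory, path: str, split_beads: Optional[bool] = None) -> None:
    """Write a trajectory as extended XYZ.

    For multi-bead trajectories the default is one file per bead with the
    suffix convention ``<stem>.bead-<k>.xyz``; pass ``split_beads=False`` to
    interleave all beads into one file with ``bead=`` comment keys.
    """
    if len(traj) == 0:
        raise ValueError("refusing to write an empty trajectory")
    if split_beads is None:
        split_beads = traj.n_beads > 1
    if split_beads and traj.n_beads > 1:
        stem, ext = os.path.splitext(path)
        for k in range(traj.n_beads):
            mask = traj.bead_index == k
            frames = [traj[i] for i in np.nonzero(mask)[0]]
            _write_frames(frames, traj, f"{stem}.bead-{k}{ext}")
    else:
        _write_frames(list(traj), traj, path)
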