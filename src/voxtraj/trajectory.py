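"""Trajectory loading, frame slicing, and subsystem querying.

A trajectory is a topology shared by an ordered sequence of coordinate
frames.  Dynamic features operate on *frame slices*: runs of ``W``
consecutive frames sharing the topology, the unit of time-window
aggregation.  A static structure is simply a trajectory with one frame.

Built-in readers cover PDB (single- and multi-MODEL, via mdtraj) and a
plain-text XYZ-per-frame format (count line, comment line, then
``element x y z`` per atom; frames concatenated).  Other dialects
(NetCDF/XTC/DCD, ...) enter through :func:`register_reader`: a reader is
any callable ``(topology_source, coordinate_source) -> (Topology,
iterator of Frame)``.

Coordinates are Å throughout.  Periodic boundary conditions are not
handled and no superposition/alignment is performed: inputs are assumed
imaged, whole, and pre-aligned (a preprocessing responsibility).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .errors import (
    CorruptInputError,
    InvalidArgumentError,
    UnsupportedFormatError,
)
from .grid import GridSpec

__all__ = [
    "Topology",
    "Frame",
    "FrameSlice",
    "load_trajectory",
    "register_reader",
    "slice_frames",
    "query_subsystem",
    "PART_RECEPTOR",
    "PART_LIGAND",
    "PART_SOLVENT",
]

logger = logging.getLogger(__name__)

# part_annotation codes
PART_RECEPTOR = 0
PART_LIGAND = 1
PART_SOLVENT = 2

#: residue names recognized as water/solvent
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SOL", "H2O", "SPC"})
#: residue names recognized as ligand-like small molecules
LIGAND_RESNAMES = frozenset({"LIG", "UNL", "UNK", "DRG", "INH", "MOL"})


@dataclass
class Topology:
    """Per-atom static records shared by all frames of a trajectory.

    Arrays are aligned by 0-based atom index.  ``part_annotation`` codes a
    coarse partition of the system: 0 = receptor, 1 = ligand, 2 = solvent.
    """

    element: np.ndarray  # str array, element symbols
    atom_name: np.ndarray  # str array
    residue_name: np.ndarray  # str array
    residue_index: np.ndarray  # int array
    part_annotation: np.ndarray  # int array

    def __post_init__(self) -> None:
        self.element = np.asarray(self.element, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.part_annotation = np.asarray(self.part_annotation, dtype=int)
        n = len(self.element)
        for name in ("atom_name", "residue_name", "residue_index", "part_annotation"):
            if len(getattr(self, name)) != n:
                raise InvalidArgumentError(f"topology field {name!r} length != atom count {n}")

    @property
    def n_atoms(self) -> int:
        return len(self.element)

    def subset(self, indices: np.ndarray) -> "Topology":
        """Topology restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return Topology(
            element=self.element[idx],
            atom_name=self.atom_name[idx],
            residue_name=self.residue_name[idx],
            residue_index=self.residue_index[idx],
            part_annotation=self.part_annotation[idx],
        )


@dataclass
class Frame:
    """One coordinate snapshot: ``(n_atoms, 3)`` Å, plus its time index."""

    coordinates: np.ndarray
    time_index: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise InvalidArgumentError(
                f"coordinates must have shape (n, 3), got {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise CorruptInputError("frame contains non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class FrameSlice:
    """A run of ``W`` time-ordered frames sharing one topology.

    ``source_indices``, when set, maps this slice's atoms back to the
    atom indices of the unreduced topology it was queried from.
    """

    topology: Topology
    frames: list[Frame]
    slice_index: int = 0
    source_indices: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise InvalidArgumentError("FrameSlice requires at least one frame")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.n_atoms != n:
                raise CorruptInputError(
                    f"frame atom count {f.n_atoms} != topology atom count {n}"
                )
        times = [f.time_index for f in self.frames]
        if any(b < a for a, b in zip(times, times[1:])):
            raise InvalidArgumentError("frames must be time-ordered")

    @property
    def window(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms


# ---------------------------------------------------------------------------
# readers

ReaderFn = Callable[[str, "str | None"], tuple[Topology, Iterator[Frame]]]
_READERS: dict[str, ReaderFn] = {}


def register_reader(format_tag: str, reader: ReaderFn) -> None:
    """Register a trajectory reader plugin under ``format_tag``."""
    _READERS[format_tag.lower()] = reader


def _part_from_resname(resname: str) -> int:
    up = resname.upper()
    if up in WATER_RESNAMES:
        return PART_SOLVENT
    if up in LIGAND_RESNAMES:
        return PART_LIGAND
    return PART_RECEPTOR


def _read_pdb(topology_source: str, coordinate_source: "str | None"):
    import mdtraj

    path = coordinate_source or topology_source
    traj = mdtraj.load_pdb(str(path), standard_names=False, no_boxchk=True)
    top = traj.topology
    elements, names, resnames, resids, parts = [], [], [], [], []
    for atom in top.atoms:
        sym = atom.element.symbol if atom.element is not None else "X"
        elements.append(sym)
        names.append(atom.name)
        resnames.append(atom.residue.name)
        resids.append(atom.residue.resSeq)
        parts.append(_part_from_resname(atom.residue.name))
    topology = Topology(
        element=np.array(elements, dtype=object),
        atom_name=np.array(names, dtype=object),
        residue_name=np.array(resnames, dtype=object),
        residue_index=np.array(resids, dtype=int),
        part_annotation=np.array(parts, dtype=int),
    )
    coords_ang = traj.xyz * 10.0  # mdtraj uses nm internally

    def frames() -> Iterator[Frame]:
        for t in range(coords_ang.shape[0]):
            yield Frame(coordinates=np.array(coords_ang[t], dtype=float), time_index=t)

    return topology, frames()


def _parse_xyz_frames(path: str, expected_atoms: "int | None") -> Iterator[tuple[list[str], np.ndarray]]:
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.strip()
            if not header:
                continue
            try:
                n = int(header)
            except ValueError as exc:
                raise CorruptInputError(f"XYZ count line is not an integer: {header!r}") from exc
            fh.readline()  # comment line
            elements: list[str] = []
            coords = np.empty((n, 3), dtype=float)
            for i in range(n):
                line = fh.readline()
                if not line:
                    raise CorruptInputError(f"XYZ frame truncated at atom {i} of {n}")
                parts = line.split()
                if len(parts) < 4:
                    raise CorruptInputError(f"XYZ atom line malformed: {line!r}")
                elements.append(parts[0])
                try:
                    coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
                except ValueError as exc:
                    raise CorruptInputError(f"XYZ atom line malformed: {line!r}") from exc
            if expected_atoms is not None and n != expected_atoms:
                raise CorruptInputError(
                    f"frame with {n} coordinates against {expected_atoms}-atom topology"
                )
            yield elements, coords


def _read_xyz(topology_source: "str | None", coordinate_source: str):
    if topology_source and str(topology_source) != str(coordinate_source):
        topology, _ = _read_pdb(topology_source, None)
    else:
        # build a placeholder topology from the first frame's element column
        first = next(_parse_xyz_frames(str(coordinate_source), None), None)
        if first is None:
            raise CorruptInputError(f"XYZ file {coordinate_source} contains no frames")
        elements, _ = first
        n = len(elements)
        topology = Topology(
            element=np.array(elements, dtype=object),
            atom_name=np.array(elements, dtype=object),
            residue_name=np.array(["DUM"] * n, dtype=object),
            residue_index=np.zeros(n, dtype=int),
            part_annotation=np.zeros(n, dtype=int),
        )

    n_atoms = topology.n_atoms

    def frames() -> Iterator[Frame]:
        for t, (_, coords) in enumerate(_parse_xyz_frames(str(coordinate_source), n_atoms)):
            yield Frame(coordinates=coords, time_index=t)

    return topology, frames()


register_reader("pdb", _read_pdb)
register_reader("xyz", _read_xyz)


def load_trajectory(
    topology_source: "str | None",
    coordinate_source: "str | None" = None,
    format_tag: str = "pdb",
) -> tuple[Topology, Iterator[Frame]]:
    """Load a trajectory, yielding frames lazily in file order.

    A single static structure (1-MODEL PDB) yields exactly one frame: a
    static structure is a trajectory with one frame.

    Parameters
    ----------
    topology_source
        Path of the topology file (PDB).  For the ``xyz`` dialect it may be
        omitted, in which case a placeholder topology is built from the
        element column of the first frame.
    coordinate_source
        Path of the coordinate file; defaults to ``topology_source``.
    format_tag
        Registered reader name (built-in: ``pdb``, ``xyz``).
    """
    tag = format_tag.lower()
    if tag not in _READERS:
        raise UnsupportedFormatError(
            f"unknown format {format_tag!r}; registered: {sorted(_READERS)}"
        )
    return _READERS[tag](topology_source, coordinate_source)


# ---------------------------------------------------------------------------
# slicing and querying


def slice_frames(frames: Iterable[Frame], window: int, topology: Topology) -> list[FrameSlice]:
    """Split ``frames`` into ``floor(T/W)`` nonoverlapping slices of length
    ``window``; the trailing ``T mod W`` frames are dropped (logged at INFO).
    """
    if window < 1:
        raise InvalidArgumentError(f"window must be >= 1, got {window}")
    frames = list(frames)
    n_slices = len(frames) // window
    dropped = len(frames) - n_slices * window
    if dropped:
        logger.info("dropping %d trailing frame(s) not filling a window of %d", dropped, window)
    return [
        FrameSlice(
            topology=topology,
            frames=frames[s * window : (s + 1) * window],
            slice_index=s,
        )
        for s in range(n_slices)
    ]


def _distance_to_box(points: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to an axis-aligned box (0 inside)."""
    clamped = np.clip(points, lower, upper)
    return np.linalg.norm(points - clamped, axis=1)


def query_subsystem(
    slice_: FrameSlice,
    focus,
    spec: GridSpec,
    include_environment: float = 0.0,
) -> FrameSlice:
    """Restrict a frame slice to the focus atoms plus their environment.

    Keeps the union, over all frames of the slice, of atoms that are in the
    focus selection or within ``include_environment`` Å of the grid's
    *padded* box.  The atom set is fixed across the whole slice so every
    frame shares one reduced topology; atom ordering is preserved.

    ``focus`` may be a resolved :class:`~voxtraj.selection.FocusSelection`
    or a selection expression string (resolved against the slice topology),
    which makes the operation idempotent under re-querying.

    Because the padded box already extends beyond the central region by the
    feature reach, ``include_environment=0`` (membership = inside the padded
    box in at least one frame) is lossless for the central-region outputs.
    """
    from .selection import FocusSelection, select_focus

    if isinstance(focus, str):
        focus = select_focus(focus, slice_.topology)
    elif not isinstance(focus, FocusSelection):
        raise InvalidArgumentError("focus must be a FocusSelection or expression string")

    n = slice_.topology.n_atoms
    keep = np.zeros(n, dtype=bool)
    keep[np.asarray(focus.resolved_indices, dtype=int)] = True
    lower, upper = spec.box_bounds(padded=True)
    for frame in slice_.frames:
        keep |= _distance_to_box(frame.coordinates, lower, upper) <= include_environment
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        logger.warning("query produced an empty subsystem; downstream features will be zero")
    sub_top = slice_.topology.subset(kept)
    sub_frames = [
        Frame(coordinates=f.coordinates[kept], time_index=f.time_index) for f in slice_.frames
    ]
    if slice_.source_indices is not None:
        kept_source = np.asarray(slice_.source_indices)[kept]
    else:
        kept_source = kept
    return FrameSlice(
        topology=sub_top,
        frames=sub_frames,
        slice_index=slice_.slice_index,
        source_indices=kept_source,
    )
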