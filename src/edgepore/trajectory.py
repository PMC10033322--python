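"""Topology/coordinate data model, file dialects, and the atom-selection layer.

Two on-disk dialects are supported:

* multi-MODEL PDB (standard fixed columns, coordinates in Å on disk, nm in
  memory);
* ``frame_table`` — a tab-separated text format with one atom per row
  (atom_index, name, residue_name, residue_number, chain, role, subrole,
  x, y, z in nm) and one header line per frame::

      #FRAME t=<ps> box=<lx> <ly> <lz>

  Coordinates are written with shortest round-trip ``repr`` so a write/read
  cycle is bit exact.

By convention the membrane normal is the third box axis.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .roles import Role, Subrole, assign_role, element_mass, guess_element, validate_role

logger = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0


class FormatError(ValueError):
    """A file could not be parsed under the named dialect."""


class TopologyMismatchError(ValueError):
    """Replicates of one trajectory set do not share a topology."""


class EmptyReplicateError(ValueError):
    """Discard/stride filtering left a replicate without frames."""


@dataclass(frozen=True)
class AtomRecord:
    atom_index: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    role: Role
    subrole: Subrole

    def __post_init__(self) -> None:
        if self.atom_index < 0:
            raise ValueError("atom_index must be >= 0")
        validate_role(self.role, self.subrole)


class Topology:
    """Column-oriented store of :class:`AtomRecord` fields for fast selection."""

    def __init__(self, records: Sequence[AtomRecord]):
        if len({r.atom_index for r in records}) != len(records):
            raise ValueError("atom_index values must be unique within a topology")
        self._records = tuple(records)
        self.atom_index = np.array([r.atom_index for r in records], dtype=np.int64)
        self.name = np.array([r.name for r in records], dtype=object)
        self.element = np.array([r.element for r in records], dtype=object)
        self.residue_number = np.array([r.residue_number for r in records], dtype=np.int64)
        self.residue_name = np.array([r.residue_name for r in records], dtype=object)
        self.chain_id = np.array([r.chain_id for r in records], dtype=object)
        self.role = np.array([r.role.value for r in records], dtype=object)
        self.subrole = np.array([r.subrole.value for r in records], dtype=object)

    def __len__(self) -> int:
        return len(self._records)

    @property
    def n_atoms(self) -> int:
        return len(self._records)

    @property
    def records(self) -> tuple[AtomRecord, ...]:
        return self._records

    def record(self, i: int) -> AtomRecord:
        return self._records[i]

    @property
    def masses(self) -> np.ndarray:
        return np.array([element_mass(e) for e in self.element], dtype=float)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.element], dtype=bool)

    def subset(self, indices: np.ndarray) -> "Topology":
        return Topology([self._records[int(i)] for i in indices])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self._records == other._records

    def __hash__(self) -> int:  # pragma: no cover - not used as dict key in hot paths
        return hash(self._records)

    def first_difference(self, other: "Topology") -> str | None:
        """Human-readable description of the first differing atom, or None."""
        if len(self) != len(other):
            return f"atom counts differ ({len(self)} vs {len(other)})"
        for a, b in zip(self._records, other._records):
            if a != b:
                return f"atom {a.atom_index}: {a} != {b}"
        return None


@dataclass
class FrameSnapshot:
    """One time point: coordinates (nm), orthorhombic box lengths (nm), time (ps)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def validate_against(self, topology: Topology) -> None:
        if self.n_atoms != topology.n_atoms:
            raise ValueError(
                f"frame has {self.n_atoms} coordinates but topology has "
                f"{topology.n_atoms} atoms"
            )


@dataclass
class TrajectorySet:
    """Replicate trajectories sharing one topology."""

    topology: Topology
    replicates: list[list[FrameSnapshot]]
    stride: float = 100.0
    discard: float = 500_000.0

    def __post_init__(self) -> None:
        for rep in self.replicates:
            times = [f.time for f in rep]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError("frames within a replicate must be time-ordered")
            for f in rep:
                f.validate_against(self.topology)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def n_frames(self) -> int:
        return sum(len(r) for r in self.replicates)

    def iter_frames(self) -> Iterable[tuple[int, FrameSnapshot]]:
        for i, rep in enumerate(self.replicates):
            for frame in rep:
                yield i, frame


@dataclass(frozen=True)
class RoleSelection:
    """Deterministic, order-preserving predicate over AtomRecord fields."""

    role: Role | None = None
    subrole: Subrole | None = None
    residue_min: int | None = None
    residue_max: int | None = None
    residue_names: frozenset[str] | None = None
    chain: str | None = None
    names: frozenset[str] | None = None
    elements: frozenset[str] | None = None
    heavy_only: bool = False

    def mask(self, topology: Topology) -> np.ndarray:
        m = np.ones(topology.n_atoms, dtype=bool)
        if self.role is not None:
            m &= topology.role == self.role.value
        if self.subrole is not None:
            m &= topology.subrole == self.subrole.value
        if self.residue_min is not None:
            m &= topology.residue_number >= self.residue_min
        if self.residue_max is not None:
            m &= topology.residue_number <= self.residue_max
        if self.residue_names is not None:
            m &= np.isin(topology.residue_name, list(self.residue_names))
        if self.chain is not None:
            m &= topology.chain_id == self.chain
        if self.names is not None:
            m &= np.isin(topology.name, list(self.names))
        if self.elements is not None:
            wanted = {e.upper() for e in self.elements}
            m &= np.array([e.upper() in wanted for e in topology.element], dtype=bool)
        if self.heavy_only:
            m &= topology.heavy_mask
        return m


def select_atoms(topology: Topology, selection: RoleSelection) -> np.ndarray:
    """Strictly increasing atom indices matching ``selection`` (possibly empty)."""
    if topology.n_atoms == 0:
        raise ValueError("cannot select from an empty topology")
    return np.flatnonzero(selection.mask(topology))


def intersect_indices(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.intersect1d(a, b)


def union_indices(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.union1d(a, b)


def polar_oxygen_selection(topology: Topology) -> np.ndarray:
    """Lipid oxygens plus water oxygens — the polar atoms of the defect coordinate."""
    lipid_o = select_atoms(
        topology, RoleSelection(role=Role.LIPID, elements=frozenset({"O"}))
    )
    water_o = select_atoms(topology, RoleSelection(role=Role.WATER, subrole=Subrole.WATER_O))
    return union_indices(lipid_o, water_o)


# ---------------------------------------------------------------------------
# frame_table dialect
# ---------------------------------------------------------------------------

_FT_COLUMNS = (
    "atom_index name residue_name residue_number chain role subrole x y z".split()
)


def write_frame_table(
    path: str | Path, topology: Topology, frames: Sequence[FrameSnapshot]
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for frame in frames:
            frame.validate_against(topology)
            fh.write(
                f"#FRAME t={float(frame.time)!r} box={float(frame.box[0])!r} "
                f"{float(frame.box[1])!r} {float(frame.box[2])!r}\n"
            )
            for rec, xyz in zip(topology.records, frame.coordinates):
                fh.write(
                    "\t".join(
                        [
                            str(rec.atom_index),
                            rec.name,
                            rec.residue_name,
                            str(rec.residue_number),
                            rec.chain_id,
                            rec.role.value,
                            rec.subrole.value,
                            repr(float(xyz[0])),
                            repr(float(xyz[1])),
                            repr(float(xyz[2])),
                        ]
                    )
                    + "\n"
                )


def read_frame_table(path: str | Path) -> tuple[Topology, list[FrameSnapshot]]:
    path = Path(path)
    topology: Topology | None = None
    frames: list[FrameSnapshot] = []
    records: list[AtomRecord] = []
    coords: list[list[float]] = []
    header: tuple[float, np.ndarray] | None = None

    def flush(lineno: int) -> None:
        nonlocal topology, records, coords, header
        if header is None:
            return
        time, box = header
        frame_top = Topology(records)
        if topology is None:
            topology = frame_top
        else:
            diff = topology.first_difference(frame_top)
            if diff is not None:
                raise TopologyMismatchError(
                    f"{path}: frame topologies differ near line {lineno}: {diff}"
                )
        frames.append(FrameSnapshot(np.array(coords, dtype=float), box, time))
        records, coords = [], []

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#FRAME"):
                flush(lineno)
                try:
                    fields = dict(
                        part.split("=", 1) for part in line.split() if "=" in part
                    )
                    time = float(fields["t"])
                    bx = fields["box"]
                    rest = line.split("box=", 1)[1].split()
                    box = np.array([float(bx), float(rest[1]), float(rest[2])])
                except (KeyError, IndexError, ValueError) as exc:
                    raise FormatError(f"{path}:{lineno}: bad frame header: {line!r}") from exc
                header = (time, box)
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_FT_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_FT_COLUMNS)} tab-separated "
                    f"fields, got {len(parts)}"
                )
            try:
                rec = AtomRecord(
                    atom_index=int(parts[0]),
                    name=parts[1],
                    element=guess_element(parts[1], parts[2]),
                    residue_number=int(parts[3]),
                    residue_name=parts[2],
                    chain_id=parts[4],
                    role=Role(parts[5]),
                    subrole=Subrole(parts[6]),
                )
                xyz = [float(parts[7]), float(parts[8]), float(parts[9])]
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{lineno}: unparseable row: {line!r}") from exc
            records.append(rec)
            coords.append(xyz)
    flush(-1)
    if topology is None:
        raise FormatError(f"{path}: no frames found")
    return topology, frames


# ---------------------------------------------------------------------------
# PDB dialect
# ---------------------------------------------------------------------------


def _parse_pdb_atom(line: str, lineno: int, path: Path, index: int) -> tuple[AtomRecord, list[float]]:
    try:
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}:{lineno}: unparseable ATOM record") from exc
    if not element:
        element = guess_element(name, residue_name)
    role, subrole = assign_role(name, residue_name)
    rec = AtomRecord(
        atom_index=index,
        name=name,
        element=element,
        residue_number=residue_number,
        residue_name=residue_name,
        chain_id=chain,
        role=role,
        subrole=subrole,
    )
    return rec, [x / ANGSTROM_PER_NM, y / ANGSTROM_PER_NM, z / ANGSTROM_PER_NM]


def read_pdb(
    path: str | Path, frame_spacing: float = 100.0
) -> tuple[Topology, list[FrameSnapshot]]:
    """Read a (possibly multi-MODEL) PDB file; MODEL k gets time (k-1)*frame_spacing."""
    path = Path(path)
    box = np.array([100.0, 100.0, 100.0])
    topology: Topology | None = None
    frames: list[FrameSnapshot] = []
    records: list[AtomRecord] = []
    coords: list[list[float]] = []
    saw_model = False

    def flush(lineno: int) -> None:
        nonlocal topology, records, coords
        if not records:
            return
        frame_top = Topology(records)
        if topology is None:
            topology = frame_top
        else:
            diff = topology.first_difference(frame_top)
            if diff is not None:
                raise TopologyMismatchError(
                    f"{path}: MODEL topologies differ near line {lineno}: {diff}"
                )
        frames.append(
            FrameSnapshot(np.array(coords), box.copy(), time=len(frames) * frame_spacing)
        )
        records, coords = [], []

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag == "CRYST1":
                try:
                    box = (
                        np.array(
                            [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                        )
                        / ANGSTROM_PER_NM
                    )
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: unparseable CRYST1 record") from exc
            elif tag == "MODEL":
                saw_model = True
            elif tag == "ENDMDL":
                flush(lineno)
            elif tag in ("ATOM", "HETATM"):
                rec, xyz = _parse_pdb_atom(line, lineno, path, index=len(records))
                records.append(rec)
                coords.append(xyz)
    flush(-1)
    if topology is None:
        raise FormatError(f"{path}: no ATOM records found")
    if saw_model and not frames:
        raise FormatError(f"{path}: MODEL without ENDMDL")
    return topology, frames


def write_pdb(path: str | Path, topology: Topology, frames: Sequence[FrameSnapshot]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        box = frames[0].box * ANGSTROM_PER_NM
        fh.write(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        multi = len(frames) > 1
        for imodel, frame in enumerate(frames, start=1):
            frame.validate_against(topology)
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            for rec, xyz in zip(topology.records, frame.coordinates):
                name = rec.name if len(rec.name) == 4 else f" {rec.name:<3s}"
                serial = (rec.atom_index + 1) % 100000
                resname = rec.residue_name[:3]  # PDB column limit; POPC -> POP
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s}{'':1s}{resname:>3s} "
                    f"{rec.chain_id:1s}{rec.residue_number:4d}    "
                    f"{xyz[0] * 10:8.3f}{xyz[1] * 10:8.3f}{xyz[2] * 10:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {rec.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# public readers
# ---------------------------------------------------------------------------


def read_structure(
    path: str | Path, dialect: str = "pdb"
) -> tuple[Topology, FrameSnapshot]:
    """Read a single structure; for multi-frame files the first frame is returned."""
    topology, frames = _read_any(path, dialect)
    return topology, frames[0]


def _read_any(path: str | Path, dialect: str) -> tuple[Topology, list[FrameSnapshot]]:
    if dialect == "pdb":
        return read_pdb(path)
    if dialect == "frame_table":
        return read_frame_table(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def detect_dialect(path: str | Path) -> str:
    p = Path(path)
    if p.suffix.lower() == ".pdb":
        return "pdb"
    return "frame_table"


def read_trajectory(
    paths: Sequence[str | Path],
    stride: float = 100.0,
    discard: float = 500_000.0,
    dialect: str | None = None,
) -> TrajectorySet:
    """Load replicate trajectories, drop the first ``discard`` ps, subsample to ``stride``.

    Replicate order follows path order.  All files must share an identical
    topology; the first differing atom is reported otherwise.
    """
    if not paths:
        raise ValueError("need at least one trajectory path")
    topology: Topology | None = None
    replicates: list[list[FrameSnapshot]] = []
    for path in paths:
        dia = dialect or detect_dialect(path)
        top, frames = _read_any(path, dia)
        if topology is None:
            topology = top
        else:
            diff = topology.first_difference(top)
            if diff is not None:
                raise TopologyMismatchError(f"{path}: topology mismatch: {diff}")
        kept = subsample_frames(frames, stride=stride, discard=discard)
        if not kept:
            raise EmptyReplicateError(
                f"{path}: no frames remain after discarding the first {discard} ps"
            )
        replicates.append(kept)
    assert topology is not None
    return TrajectorySet(topology, replicates, stride=stride, discard=discard)


def subsample_frames(
    frames: Sequence[FrameSnapshot], stride: float, discard: float
) -> list[FrameSnapshot]:
    retained = [f for f in frames if f.time >= discard]
    if not retained or stride <= 0:
        return list(retained)
    t0 = retained[0].time
    kept = []
    for f in retained:
        k = (f.time - t0) / stride
        if abs(k - round(k)) < 1e-6:
            kept.append(f)
    return kept


def trajectory_from_frames(
    topology: Topology,
    frames_by_replicate: Sequence[Sequence[FrameSnapshot]],
    stride: float = 100.0,
    discard: float = 0.0,
) -> TrajectorySet:
    """Wrap in-memory frames as a TrajectorySet without any filtering."""
    return TrajectorySet(topology, [list(r) for r in frames_by_replicate], stride, discard)


def replace(obj, **changes):
    """dataclasses.replace re-export (convenience for frozen selections)."""
    return dataclasses.replace(obj, **changes)
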