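"""Synthetic membrane / protein / solvent systems with planted ground truth.

Nothing here is simulated: coordinates are scripted so that every analysis
statistic (ξ per frame, per-edge ξ, contact frequencies, shell counts,
crossing counts, RMSD of transformed copies) has an exactly known value.
Pseudo-lipids are coarse stand-ins — a handful of role-tagged heavy atoms per
molecule — because all analyses depend only on role tags and coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .builder import (
    STRAND_SPANS,
    OligomerModel,
    Strand,
    compute_edges,
    derive_model_id,
)
from .defects import EdgeDefinition, SliceGrid, bilayer_center
from .geometry import minimum_image_distance, place_atom, rotation_about_axis
from .roles import Role, Subrole
from .trajectory import (
    AtomRecord,
    FrameSnapshot,
    Topology,
    TrajectorySet,
    trajectory_from_frames,
)

#: ions per nm^3 per mol/L
_IONS_PER_NM3_PER_MOLAR = 0.6022


def ion_counts_for_strength(ionic_strength_mM: float, water_volume_nm3: float) -> int:
    """Ions of each species for a 1:1 salt at the given ionic strength."""
    return int(round(ionic_strength_mM / 1000.0 * _IONS_PER_NM3_PER_MOLAR * water_volume_nm3))


@dataclass
class SyntheticSpec:
    """Recipe for a planted bilayer system."""

    n_lipids_per_leaflet: int = 36
    leaflet_z: float = 2.0
    box: tuple[float, float, float] = (5.0, 5.0, 9.0)
    n_waters: int = 150
    ionic_strength_mM: float = 600.0
    n_ions: int | None = None  # overrides the ionic-strength formula when set
    seed: int = 0
    corridor_xy: tuple[float, float] | None = None
    corridor_radius: float = 0.5

    def ion_pairs(self) -> int:
        if self.n_ions is not None:
            return self.n_ions
        lx, ly, lz = self.box
        slab = max(lz / 2 - self.leaflet_z - 0.4, 0.5)
        return ion_counts_for_strength(self.ionic_strength_mM, lx * ly * 2 * slab)


@dataclass
class SyntheticSystem:
    """A topology + single frame bundle produced by the generators."""

    topology: Topology
    frame: FrameSnapshot
    spec: SyntheticSpec

    @property
    def center(self) -> float:
        return bilayer_center(self.topology, self.frame)


class PackingError(ValueError):
    """The requested particle counts do not fit the box."""


def _grid_xy(n: int, lx: float, ly: float, rng: np.random.Generator, jitter: float,
             corridor: tuple[float, float] | None, corridor_radius: float) -> np.ndarray:
    """Jittered grid positions in the xy-plane, avoiding an optional corridor."""
    side = math.ceil(math.sqrt(n * 2))
    if lx / side < 0.1 or ly / side < 0.1:
        raise PackingError(f"cannot place {n} molecules in a {lx} x {ly} nm plane")
    xs = (np.arange(side) + 0.5) * (lx / side) - lx / 2
    ys = (np.arange(side) + 0.5) * (ly / side) - ly / 2
    pts = np.array([(x, y) for x in xs for y in ys])
    if corridor is not None:
        d = np.hypot(pts[:, 0] - corridor[0], pts[:, 1] - corridor[1])
        pts = pts[d > corridor_radius]
    if len(pts) < n:
        raise PackingError(f"cannot place {n} molecules in a {lx} x {ly} nm plane")
    pts = pts[rng.permutation(len(pts))[:n]]
    return pts + rng.uniform(-jitter, jitter, size=pts.shape)


def make_bilayer_system(spec: SyntheticSpec) -> SyntheticSystem:
    """Planar pseudo-lipid bilayer with water slabs and K+/Cl- ions.

    Head-group (phosphate/choline) atoms sit near ±leaflet_z, carbonyl and
    ester oxygens just outside the hydrophobic core, acyl pseudo-carbons fill
    the core, and all polar atoms stay clear of the central 2.8 nm slab.  The
    two leaflets are exact mirror images, so the lipid center of mass is at
    z = 0.  Identical seeds give identical coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.box
    records: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    resnum = 0

    def add(name: str, resname: str, chain: str, xyz: tuple[float, float, float]) -> None:
        records.append(
            AtomRecord(
                atom_index=len(records),
                name=name,
                element=_ELEMENT_OF.get(name, name[0]),
                residue_number=resnum,
                residue_name=resname,
                chain_id=chain,
                role=_ROLE_OF[(resname, name)][0],
                subrole=_ROLE_OF[(resname, name)][1],
            )
        )
        coords.append(xyz)

    lipid_xy = _grid_xy(
        spec.n_lipids_per_leaflet, lx, ly, rng, 0.04, spec.corridor_xy, spec.corridor_radius
    )
    for x, y in lipid_xy:
        hz = spec.leaflet_z + rng.uniform(-0.15, 0.15)
        oz = 1.55 + rng.uniform(0.0, 0.1)
        for sign in (+1.0, -1.0):  # mirrored leaflets -> lipid center exactly 0
            resnum += 1
            add("P", "POPC", "L", (x, y, sign * hz))
            add("O13", "POPC", "L", (x + 0.1, y, sign * (hz + 0.05)))
            add("C13", "POPC", "L", (x - 0.1, y + 0.1, sign * (hz + 0.1)))
            add("O22", "POPC", "L", (x + 0.05, y - 0.1, sign * oz))
            add("O21", "POPC", "L", (x - 0.05, y + 0.05, sign * (oz + 0.02)))
            add("C2A", "POPC", "L", (x, y + 0.05, sign * 1.0))
            add("C2B", "POPC", "L", (x + 0.05, y, sign * 0.5))

    water_lo, water_hi = spec.leaflet_z + 0.4, lz / 2 - 0.1
    if water_hi <= water_lo:
        raise PackingError("box too thin for a water slab above the leaflets")
    water_xy = _grid_xy(spec.n_waters, lx, ly, rng, 0.03, spec.corridor_xy, spec.corridor_radius)
    for i, (x, y) in enumerate(water_xy):
        resnum += 1
        sign = 1.0 if i % 2 == 0 else -1.0
        z = sign * rng.uniform(water_lo, water_hi)
        add("OW", "SOL", "W", (x, y, z))

    n_pairs = spec.ion_pairs()
    if n_pairs:
        ion_xy = _grid_xy(2 * n_pairs, lx, ly, rng, 0.02, spec.corridor_xy, spec.corridor_radius)
        for i, (x, y) in enumerate(ion_xy):
            resnum += 1
            sign = 1.0 if i % 2 == 0 else -1.0
            z = sign * rng.uniform(water_lo, water_hi)
            if i < n_pairs:
                add("K", "K", "I", (x, y, z))
            else:
                add("CL", "CL", "I", (x, y, z))

    frame = FrameSnapshot(np.array(coords), np.array(spec.box), time=0.0)
    return SyntheticSystem(Topology(records), frame, spec)


_ELEMENT_OF = {
    "P": "P",
    "O13": "O",
    "C13": "C",
    "O22": "O",
    "O21": "O",
    "C2A": "C",
    "C2B": "C",
    "OW": "O",
    "K": "K",
    "CL": "CL",
}

_ROLE_OF = {
    ("POPC", "P"): (Role.LIPID, Subrole.PHOSPHATE),
    ("POPC", "O13"): (Role.LIPID, Subrole.PHOSPHATE),
    ("POPC", "C13"): (Role.LIPID, Subrole.CHOLINE),
    ("POPC", "O22"): (Role.LIPID, Subrole.CARBONYL_O),
    ("POPC", "O21"): (Role.LIPID, Subrole.ESTER_O),
    ("POPC", "C2A"): (Role.LIPID, Subrole.OTHER),
    ("POPC", "C2B"): (Role.LIPID, Subrole.OTHER),
    ("SOL", "OW"): (Role.WATER, Subrole.WATER_O),
    ("K", "K"): (Role.ION, Subrole.K),
    ("CL", "CL"): (Role.ION, Subrole.CL),
}


class PlacementError(ValueError):
    """A planted atom could not be placed without collisions."""


def _append_atoms(
    system: SyntheticSystem, new_records: list[AtomRecord], new_coords: np.ndarray
) -> SyntheticSystem:
    top = system.topology
    base = top.n_atoms
    records = list(top.records) + [
        replace(r, atom_index=base + i) for i, r in enumerate(new_records)
    ]
    coords = np.vstack([system.frame.coordinates, new_coords])
    frame = FrameSnapshot(coords, system.frame.box.copy(), system.frame.time)
    return SyntheticSystem(Topology(records), frame, system.spec)


def _check_collisions(
    system: SyntheticSystem, new_coords: np.ndarray, min_dist: float = 0.05
) -> bool:
    if system.topology.n_atoms == 0:
        return True
    d = minimum_image_distance(new_coords, system.frame.coordinates, system.frame.box)
    return bool(d.min() >= min_dist)


def _planted_water_records(n: int, start_resnum: int) -> list[AtomRecord]:
    return [
        AtomRecord(
            atom_index=i,  # reindexed on append
            name="OW",
            element="O",
            residue_number=start_resnum + i,
            residue_name="SOL",
            chain_id="D",
            role=Role.WATER,
            subrole=Subrole.WATER_O,
        )
        for i in range(n)
    ]


def plant_polar_column(
    system: SyntheticSystem,
    grid: SliceGrid,
    filled_slices: list[int] | np.ndarray,
    xy: tuple[float, float],
    rng: np.random.Generator | None = None,
) -> SyntheticSystem:
    """Plant one water oxygen at the z-center of every listed slice, at fixed xy."""
    filled = sorted(set(int(i) for i in filled_slices))
    if any(i < 0 or i >= grid.n_slices for i in filled):
        raise ValueError("slice index outside the grid")
    center = system.center
    zc = grid.slice_centers(center)
    coords = np.array([[xy[0], xy[1], zc[i]] for i in filled]).reshape(-1, 3)
    if coords.size and not _check_collisions(system, coords):
        rng = rng or np.random.default_rng(0)
        for _ in range(20):
            jittered = coords + np.concatenate(
                [rng.uniform(-0.03, 0.03, (len(coords), 2)), np.zeros((len(coords), 1))],
                axis=1,
            )
            if _check_collisions(system, jittered):
                coords = jittered
                break
        else:
            raise PlacementError("could not place defect column without collisions")
    start = int(system.topology.residue_number.max(initial=0)) + 1
    return _append_atoms(system, _planted_water_records(len(filled), start), coords)


def plant_edge_defect(
    system: SyntheticSystem,
    edge: EdgeDefinition,
    filled_slices: list[int] | np.ndarray,
    grid: SliceGrid,
    offset: float = 0.15,
) -> SyntheticSystem:
    """Plant a water column laterally within 0.3 nm of the edge strands.

    Each listed slice receives one water oxygen at its z-center; the resulting
    total and edge ξ both equal |filled| / n_slices exactly on a pristine slab.
    """
    filled = sorted(set(int(i) for i in filled_slices))
    if any(i < 0 or i >= grid.n_slices for i in filled):
        raise ValueError("slice index outside the grid")
    center = system.center
    zc = grid.slice_centers(center)
    edge_coords = system.frame.coordinates[np.asarray(edge.strand_atom_indices)]
    # candidate lateral offsets, all within 0.3 nm of the anchoring edge atom
    candidates = [
        (offset, 0.0), (-offset, 0.0), (0.0, offset), (0.0, -offset),
        (0.21, 0.0), (-0.21, 0.0), (0.0, 0.21), (0.0, -0.21),
        (0.15, 0.15), (-0.15, -0.15), (0.29, 0.0), (0.0, 0.29),
    ]
    coords = []
    for i in filled:
        nearest = edge_coords[np.argmin(np.abs(edge_coords[:, 2] - zc[i]))]
        for dx, dy in candidates:
            cand = np.array([[nearest[0] + dx, nearest[1] + dy, zc[i]]])
            others = np.array(coords).reshape(-1, 3)
            clear = _check_collisions(system, cand) and (
                others.size == 0
                or minimum_image_distance(cand, others, system.frame.box).min() >= 0.05
            )
            if clear:
                coords.append(cand[0])
                break
        else:
            raise PlacementError(
                f"could not place defect water in slice {i} without collisions"
            )
    coords = np.array(coords).reshape(-1, 3)
    start = int(system.topology.residue_number.max(initial=0)) + 1
    return _append_atoms(system, _planted_water_records(len(filled), start), coords)


# ---------------------------------------------------------------------------
# idealized β-sheets
# ---------------------------------------------------------------------------

_BB = {  # bond lengths (nm) and angles (deg) of an idealized backbone
    "n_ca": 0.1458,
    "ca_c": 0.1525,
    "c_n": 0.1329,
    "c_o": 0.1229,
    "ca_cb": 0.1521,
    "ang_n_ca_c": 111.0,
    "ang_ca_c_n": 116.2,
    "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.5,
    "ang_n_ca_cb": 110.4,
}

BETA_PHI_DEG = -139.0
BETA_PSI_DEG = 135.0


def _build_strand_backbone(n_res: int, phi: float, psi: float) -> dict[str, np.ndarray]:
    """Backbone + Cβ coordinates (nm) of one extended strand via NeRF."""
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_BB["n_ca"], 0.0, 0.0])]
    C = [place_atom([0.0, -1.0, 0.0], N[0], CA[0], _BB["ca_c"], _BB["ang_n_ca_c"], 180.0)]
    for _ in range(1, n_res):
        n_next = place_atom(N[-1], CA[-1], C[-1], _BB["c_n"], _BB["ang_ca_c_n"], psi)
        ca_next = place_atom(CA[-1], C[-1], n_next, _BB["n_ca"], _BB["ang_c_n_ca"], 180.0)
        c_next = place_atom(C[-1], n_next, ca_next, _BB["ca_c"], _BB["ang_n_ca_c"], phi)
        N.append(n_next)
        CA.append(ca_next)
        C.append(c_next)
    O = [
        place_atom(N[i], CA[i], C[i], _BB["c_o"], _BB["ang_ca_c_o"], psi + 180.0)
        for i in range(n_res)
    ]
    CB = [
        place_atom(C[i], N[i], CA[i], _BB["ca_cb"], _BB["ang_n_ca_cb"], 122.55)
        for i in range(n_res)
    ]
    return {"N": np.array(N), "CA": np.array(CA), "C": np.array(C), "O": np.array(O), "CB": np.array(CB)}


def _default_labels(n_strands: int) -> list[str]:
    if n_strands == 6:
        return ["beta1", "beta2", "beta3", "beta3", "beta2", "beta1"]
    return [f"beta{(i % 3) + 1}" for i in range(n_strands)]


def _default_chains(labels: list[str]) -> list[str]:
    # hairpin grouping for the 6-strand tetramer template; otherwise one
    # chain per strand
    if labels == ["beta1", "beta2", "beta3", "beta3", "beta2", "beta1"]:
        return ["A", "A", "B", "C", "D", "D"]
    return [chr(ord("A") + i) for i in range(len(labels))]


def _residue_name(label: str, resnum: int) -> str:
    if label == "beta1":
        return {13: "HIS", 14: "HIS", 15: "GLN", 16: "LYS"}.get(resnum, "ALA")
    return "ALA"


def make_ideal_sheet(
    n_strands: int,
    residues_per_strand: int = 13,
    rise: float = 0.34,
    strand_spacing: float = 0.48,
    antiparallel: bool = True,
    labels: list[str] | None = None,
    chains: list[str] | None = None,
    box: tuple[float, float, float] = (6.0, 6.0, 9.0),
) -> tuple[OligomerModel, Topology, FrameSnapshot]:
    """Idealized membrane-spanning β-sheet (backbone N, Cα, C, O + Cβ).

    All residues carry extended-β dihedrals, strands run along z and stack
    along y.  β1 strands get HHQK residue names at positions 13-16 so contact
    and coordination selections resolve on synthetic models.
    """
    if n_strands < 2:
        raise ValueError("a sheet needs at least two strands")
    labels = list(labels) if labels is not None else _default_labels(n_strands)
    if len(labels) != n_strands:
        raise ValueError("labels length must equal n_strands")
    chains = list(chains) if chains is not None else _default_chains(labels)
    if len(chains) != n_strands:
        raise ValueError("chains length must equal n_strands")

    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    strands: list[Strand] = []
    flip = rotation_about_axis([0.0, 1.0, 0.0], 180.0)
    for si, (label, chain) in enumerate(zip(labels, chains)):
        span_lo, span_hi = STRAND_SPANS[label]
        n_res = min(residues_per_strand, span_hi - span_lo + 1)
        bb = _build_strand_backbone(n_res, BETA_PHI_DEG, BETA_PSI_DEG)
        # align the Cα axis with z and center the strand
        v = bb["CA"][-1] - bb["CA"][0]
        v /= np.linalg.norm(v)
        z_axis = np.array([0.0, 0.0, 1.0])
        axis = np.cross(v, z_axis)
        if np.linalg.norm(axis) < 1e-12:
            rot = np.eye(3)
        else:
            angle = math.degrees(math.acos(np.clip(np.dot(v, z_axis), -1, 1)))
            rot = rotation_about_axis(axis, angle)
        stacked = {k: a @ rot.T for k, a in bb.items()}
        center = stacked["CA"].mean(axis=0)
        for k in stacked:
            stacked[k] = stacked[k] - center
        if antiparallel and si % 2 == 1:
            for k in stacked:
                stacked[k] = stacked[k] @ flip.T
        shift = np.array([0.0, si * strand_spacing, (si % 2) * rise / 2])
        resnums = list(range(span_lo, span_lo + n_res))
        for ri, rn in enumerate(resnums):
            resname = _residue_name(label, rn)
            for atom in ("N", "CA", "C", "O", "CB"):
                records.append(
                    AtomRecord(
                        atom_index=len(records),
                        name=atom,
                        element=atom[0],
                        residue_number=rn,
                        residue_name=resname,
                        chain_id=chain,
                        role=Role.PROTEIN,
                        subrole=Subrole.BACKBONE if atom != "CB" else Subrole.SIDECHAIN,
                    )
                )
                coords.append(stacked[atom][ri] + shift)
        strands.append(Strand(label, chain, resnums[0], resnums[-1]))

    frame = FrameSnapshot(np.array(coords), np.array(box), time=0.0)
    topology = Topology(records)
    seen: list[str] = []
    for c in chains:
        if c not in seen:
            seen.append(c)
    model = OligomerModel(chains=seen, strands=strands)
    model.edges = compute_edges(strands, topology, frame)
    model.identifier = derive_model_id(model)
    return model, topology, frame


def make_tetramer_template() -> tuple[OligomerModel, Topology, FrameSnapshot]:
    """The 6-strand, 4-chain single-sheet tetramer template (β1 β2 β3 β3 β2 β1)."""
    return make_ideal_sheet(6)


def merge_into_bilayer(
    system: SyntheticSystem, sheet_top: Topology, sheet_frame: FrameSnapshot
) -> tuple[SyntheticSystem, int]:
    """Embed a sheet into a bilayer system; returns the merged system and the
    atom-index offset of the sheet atoms within it."""
    offset = system.topology.n_atoms
    new_sys = _append_atoms(system, list(sheet_top.records), sheet_frame.coordinates)
    return new_sys, offset


# ---------------------------------------------------------------------------
# scripted ion trajectories
# ---------------------------------------------------------------------------


@dataclass
class IonPath:
    """A scripted ion: fixed xy, per-frame z values, and a co-moving shell."""

    xy: tuple[float, float]
    z_path: np.ndarray
    shell: dict[str, int] = field(default_factory=dict)
    shell_radius: float = 0.25


_SHELL_TEMPLATES = {
    "water_O": ("OW", "SOL", "W", Role.WATER, Subrole.WATER_O, "O"),
    "lipid_O": ("O22", "POPC", "L", Role.LIPID, Subrole.CARBONYL_O, "O"),
    "Q15_sidechain": ("OE1", "GLN", "Z", Role.PROTEIN, Subrole.SIDECHAIN, "O"),
    "H13_sidechain": ("ND1", "HIS", "Z", Role.PROTEIN, Subrole.SIDECHAIN, "N"),
    "H14_sidechain": ("ND1", "HIS", "Z", Role.PROTEIN, Subrole.SIDECHAIN, "N"),
    "backbone_carbonyl_O_res9_21": ("O", "ALA", "Z", Role.PROTEIN, Subrole.BACKBONE, "O"),
}

_SHELL_RESNUM = {
    "Q15_sidechain": 15,
    "H13_sidechain": 13,
    "H14_sidechain": 14,
    "backbone_carbonyl_O_res9_21": 10,
}


def _sphere_directions(k: int) -> np.ndarray:
    """k well-separated unit vectors (golden spiral)."""
    i = np.arange(k) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / k
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_permeation_series(
    system: SyntheticSystem,
    plan: list[IonPath],
    stride: float = 100.0,
    n_replicates: int = 1,
) -> TrajectorySet:
    """Scripted trajectory: planned ions traverse their z-paths with their
    prescribed first shells co-moving; everything else stays frozen.

    The same plan plays in every replicate.  Crossing detection and the
    coordination profile recover the plan exactly.
    """
    if not plan:
        base = [
            FrameSnapshot(system.frame.coordinates.copy(), system.frame.box.copy(), t * stride)
            for t in range(1)
        ]
        top = system.topology
        return trajectory_from_frames(top, [base] * n_replicates, stride=stride)

    n_frames = len(plan[0].z_path)
    if any(len(p.z_path) != n_frames for p in plan):
        raise ValueError("all ion paths must have the same number of frames")

    records = list(system.topology.records)
    base_n = len(records)
    resnum = int(system.topology.residue_number.max(initial=0)) + 1
    ion_atom: list[int] = []
    shell_atoms: list[list[tuple[int, np.ndarray]]] = []
    for p in plan:
        records.append(
            AtomRecord(
                atom_index=len(records),
                name="K",
                element="K",
                residue_number=resnum,
                residue_name="K",
                chain_id="I",
                role=Role.ION,
                subrole=Subrole.K,
            )
        )
        ion_atom.append(len(records) - 1)
        resnum += 1
        n_shell = sum(p.shell.values())
        if n_shell > 24:
            raise PlacementError("shell too crowded")
        dirs = _sphere_directions(max(n_shell, 1)) * p.shell_radius
        if n_shell > 1:
            dmin = minimum_image_distance(dirs, dirs, np.array([99.0, 99.0, 99.0]))
            np.fill_diagonal(dmin, np.inf)
            if dmin.min() < 0.05:
                raise PlacementError("shell partners collide")
        offsets: list[tuple[int, np.ndarray]] = []
        k = 0
        for cat, count in p.shell.items():
            if cat not in _SHELL_TEMPLATES:
                raise ValueError(f"unknown shell category {cat!r}")
            name, resname, chain, role, subrole, element = _SHELL_TEMPLATES[cat]
            for _ in range(count):
                rn = _SHELL_RESNUM.get(cat, resnum)
                records.append(
                    AtomRecord(
                        atom_index=len(records),
                        name=name,
                        element=element,
                        residue_number=rn,
                        residue_name=resname,
                        chain_id=chain,
                        role=role,
                        subrole=subrole,
                    )
                )
                offsets.append((len(records) - 1, dirs[k]))
                k += 1
                if cat not in _SHELL_RESNUM:
                    resnum += 1
        shell_atoms.append(offsets)

    topology = Topology(records)
    frames: list[FrameSnapshot] = []
    n_total = len(records)
    for fi in range(n_frames):
        coords = np.zeros((n_total, 3))
        coords[:base_n] = system.frame.coordinates
        for pi, p in enumerate(plan):
            pos = np.array([p.xy[0], p.xy[1], float(p.z_path[fi])])
            coords[ion_atom[pi]] = pos
            for ai, off in shell_atoms[pi]:
                coords[ai] = pos + off
        frames.append(FrameSnapshot(coords, system.frame.box.copy(), time=fi * stride))
        planted = coords[base_n:]
        if base_n and planted.size:
            d = minimum_image_distance(planted, coords[:base_n], system.frame.box)
            if d.min() < 0.05:
                raise PlacementError(
                    f"scripted atoms collide with the base system in frame {fi}"
                )
    return trajectory_from_frames(topology, [frames] * n_replicates, stride=stride)
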