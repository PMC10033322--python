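"""Polar transmembrane defect reaction coordinate.

The membrane-spanning hydrophobic slab is discretized into equal slices along
the membrane normal (third axis).  Per frame, the coordinate ξ is the fraction
of slices that contain at least one polar (lipid-oxygen or water-oxygen) atom:
ξ = 1 marks a continuous polar defect, ξ = 0 an intact slab.  The ensemble
distribution p(ξ) is turned into a free-energy profile −RT·ln p.

Per-edge variants restrict the occupancy count to polar atoms laterally close
to the heavy atoms of a β-strand edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, GAS_CONSTANT_KJ_PER_MOL_K
from .geometry import minimum_image_distance
from .trajectory import FrameSnapshot, Topology, TrajectorySet, polar_oxygen_selection


class ConfigurationError(ValueError):
    """Inconsistent analysis configuration (e.g. non-commensurate slice grid)."""


@dataclass(frozen=True)
class SliceGrid:
    """Discretization of the transmembrane slab into occupancy slices."""

    slab_thickness: float = 2.8
    increment: float = 0.1
    n_slices: int = 28

    def __post_init__(self) -> None:
        if abs(self.n_slices * self.increment - self.slab_thickness) > 1e-9:
            raise ConfigurationError(
                f"n_slices ({self.n_slices}) x increment ({self.increment}) "
                f"!= slab_thickness ({self.slab_thickness})"
            )

    def slice_centers(self, center: float = 0.0) -> np.ndarray:
        z0 = center - self.slab_thickness / 2
        return z0 + (np.arange(self.n_slices) + 0.5) * self.increment


def build_slice_grid(slab_thickness: float = 2.8, increment: float = 0.1) -> SliceGrid:
    """Construct a slice grid, refusing non-commensurate thickness/increment pairs."""
    if slab_thickness <= 0 or increment <= 0:
        raise ConfigurationError("slab thickness and increment must be positive")
    ratio = slab_thickness / increment
    n = round(ratio)
    if n < 1 or abs(ratio - n) * increment > 1e-6:
        raise ConfigurationError(
            f"slab thickness {slab_thickness} nm is not an integer multiple of "
            f"the increment {increment} nm"
        )
    return SliceGrid(slab_thickness=slab_thickness, increment=increment, n_slices=n)


def bilayer_center(
    topology: Topology, frame: FrameSnapshot, mode: str = "mass"
) -> float:
    """z of the bilayer center from all lipid atoms (mass-weighted by default).

    Falls back to 0.0 for systems without lipid atoms (e.g. bare sheets).
    """
    lipid = topology.role == "lipid"
    if not lipid.any():
        return 0.0
    z = frame.coordinates[lipid, 2]
    if mode == "geometric":
        return float(z.mean())
    if mode == "mass":
        w = topology.masses[lipid]
        return float(np.average(z, weights=w))
    raise ValueError(f"unknown center mode {mode!r}")


def slice_indices(z: np.ndarray, center: float, grid: SliceGrid) -> np.ndarray:
    """Slice membership of z values; -1 marks atoms outside the slab.

    Slices tile the slab contiguously; interior boundaries belong to the lower
    slice, and both slab faces are inside.
    """
    z = np.asarray(z, dtype=float)
    z0 = center - grid.slab_thickness / 2
    t = (z - z0) / grid.increment
    # ceil(t) - 1 implements "boundary belongs to the lower slice"
    idx = np.ceil(t).astype(np.int64) - 1
    idx[t == 0.0] = 0  # the bottom slab face is inside slice 0
    idx[(t < 0) | (t > grid.n_slices)] = -1
    return idx


def occupied_slices(
    z: np.ndarray, center: float, grid: SliceGrid
) -> np.ndarray:
    """Boolean occupancy per slice for the given polar-atom z coordinates."""
    occ = np.zeros(grid.n_slices, dtype=bool)
    idx = slice_indices(z, center, grid)
    occ[idx[idx >= 0]] = True
    return occ


def frame_xi(
    topology: Topology,
    frame: FrameSnapshot,
    grid: SliceGrid,
    polar: np.ndarray | None = None,
    center: float | None = None,
    center_mode: str = "mass",
) -> float:
    """ξ for one frame: occupied-slice fraction over the transmembrane slab."""
    if polar is None:
        polar = polar_oxygen_selection(topology)
    polar = np.asarray(polar, dtype=np.int64)
    if polar.size == 0:
        raise ValueError(
            "polar selection is empty; a dry slab must still be probed with "
            "a non-empty polar atom set"
        )
    if center is None:
        center = bilayer_center(topology, frame, mode=center_mode)
    occ = occupied_slices(frame.coordinates[polar, 2], center, grid)
    return float(occ.sum()) / grid.n_slices


@dataclass(frozen=True)
class EdgeDefinition:
    """A β-strand edge: its heavy-atom indices and the lateral capture cutoff."""

    label: str
    strand_atom_indices: tuple[int, ...]
    lateral_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if len(self.strand_atom_indices) == 0:
            raise ValueError(f"edge {self.label!r} has no atoms")
        if self.lateral_cutoff <= 0:
            raise ValueError("lateral cutoff must be positive")


def edge_xi(
    topology: Topology,
    frame: FrameSnapshot,
    grid: SliceGrid,
    edge: EdgeDefinition,
    polar: np.ndarray | None = None,
    center: float | None = None,
    center_mode: str = "mass",
) -> float:
    """ξ restricted to polar atoms within the edge's lateral (xy) cutoff.

    An atom may count toward several edges; per-edge ξ never exceeds total ξ.
    """
    if polar is None:
        polar = polar_oxygen_selection(topology)
    polar = np.asarray(polar, dtype=np.int64)
    if polar.size == 0:
        raise ValueError("polar selection is empty")
    if center is None:
        center = bilayer_center(topology, frame, mode=center_mode)
    pz = frame.coordinates[polar, 2]
    in_slab = slice_indices(pz, center, grid) >= 0
    if not in_slab.any():
        return 0.0
    pxy = frame.coordinates[polar][in_slab][:, :2]
    exy = frame.coordinates[np.asarray(edge.strand_atom_indices), :2]
    lateral = minimum_image_distance(pxy, exy, frame.box[:2]).min(axis=1)
    near = lateral <= edge.lateral_cutoff
    if not near.any():
        return 0.0
    occ = occupied_slices(pz[in_slab][near], center, grid)
    return float(occ.sum()) / grid.n_slices


@dataclass
class DefectSeries:
    """Per-frame ξ (total and per edge) for every replicate."""

    grid: SliceGrid
    times: list[np.ndarray]
    xi: list[np.ndarray]
    per_edge_xi: dict[str, list[np.ndarray]] = field(default_factory=dict)
    temperature: float = DEFAULT_TEMPERATURE_K

    @property
    def n_replicates(self) -> int:
        return len(self.xi)

    def all_xi(self) -> np.ndarray:
        return np.concatenate(self.xi) if self.xi else np.empty(0)


def compute_defect_series(
    trajset: TrajectorySet,
    grid: SliceGrid,
    edges: tuple[EdgeDefinition, ...] | list[EdgeDefinition] = (),
    center_mode: str = "mass",
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> DefectSeries:
    polar = polar_oxygen_selection(trajset.topology)
    times, xi_all = [], []
    per_edge: dict[str, list[np.ndarray]] = {e.label: [] for e in edges}
    for rep in trajset.replicates:
        t = np.array([f.time for f in rep])
        xi_rep = np.empty(len(rep))
        edge_rep = {e.label: np.empty(len(rep)) for e in edges}
        for i, frame in enumerate(rep):
            center = bilayer_center(trajset.topology, frame, mode=center_mode)
            xi_rep[i] = frame_xi(trajset.topology, frame, grid, polar, center)
            for e in edges:
                edge_rep[e.label][i] = edge_xi(
                    trajset.topology, frame, grid, e, polar, center
                )
        times.append(t)
        xi_all.append(xi_rep)
        for e in edges:
            per_edge[e.label].append(edge_rep[e.label])
    return DefectSeries(grid, times, xi_all, per_edge, temperature)


@dataclass
class XiDistribution:
    """Histogram of ξ over its attainable values k/n_slices."""

    bins: np.ndarray  # bin values k/n_slices, k = 0..n_slices
    p: np.ndarray  # combined probabilities, sum 1 over occupied bins
    sem: np.ndarray  # standard error across replicates
    counts: np.ndarray  # combined frame counts per bin
    per_replicate_p: np.ndarray  # (n_rep, n_bins)


def xi_distribution(
    xi_by_replicate: list[np.ndarray] | list[list[float]], n_slices: int
) -> XiDistribution:
    """Exact counting distribution of ξ with one bin per attainable value.

    ξ is intrinsically discrete (k/n_slices), so probabilities are exact
    frequencies, not density estimates.  SEM is computed across replicates.
    """
    reps = [np.asarray(x, dtype=float) for x in xi_by_replicate]
    total = sum(len(r) for r in reps)
    if total == 0:
        raise ValueError("cannot build a distribution from zero frames")
    bins = np.arange(n_slices + 1) / n_slices
    counts = np.zeros(n_slices + 1, dtype=np.int64)
    per_rep = np.zeros((len(reps), n_slices + 1))
    for ri, r in enumerate(reps):
        k = np.round(r * n_slices).astype(np.int64)
        if np.any(np.abs(r * n_slices - k) > 1e-9) or k.min(initial=0) < 0 or k.max(initial=0) > n_slices:
            raise ValueError("xi values must be multiples of 1/n_slices in [0, 1]")
        c = np.bincount(k, minlength=n_slices + 1)
        counts += c
        if len(r):
            per_rep[ri] = c / len(r)
    p = counts / total
    if len(reps) > 1:
        sem = per_rep.std(axis=0, ddof=1) / math.sqrt(len(reps))
    else:
        sem = np.zeros(n_slices + 1)
    return XiDistribution(bins, p, sem, counts, per_rep)


def xi_free_energy(
    p: np.ndarray, temperature: float = DEFAULT_TEMPERATURE_K
) -> tuple[np.ndarray, np.ndarray]:
    """ΔG_i = −RT·ln p_i in kJ/mol.

    Returns (dG, defined) where bins with p = 0 are flagged undefined and hold
    NaN — never 0 or ±inf silently.
    """
    p = np.asarray(p, dtype=float)
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    defined = p > 0
    dg = np.full(p.shape, np.nan)
    dg[defined] = -GAS_CONSTANT_KJ_PER_MOL_K * temperature * np.log(p[defined])
    return dg, defined
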