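"""Partial density profiles along the membrane normal.

Atoms are binned by their z offset from the per-frame bilayer center (wrapped
into the box by minimum image, so nothing is ever lost to the histogram range)
and normalised by bin volume.  Frames are averaged per replicate, then the
replicate means carry a standard error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .defects import bilayer_center
from .trajectory import RoleSelection, TrajectorySet, select_atoms

logger = logging.getLogger(__name__)


@dataclass
class AxialProfile:
    """A quantity binned along the membrane normal, with replicate SEM."""

    bin_centers: np.ndarray
    values: np.ndarray
    sem: np.ndarray
    quantity: str = "number_density"
    missing: np.ndarray | None = None  # bins with zero observations (coordination)

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


def _bin_edges(box_z: float, bin_width: float) -> np.ndarray:
    """Uniform bins symmetric about 0 that cover the whole wrapped z range."""
    n_half = math.ceil(box_z / 2 / bin_width)
    return np.arange(-n_half, n_half + 1) * bin_width


def wrapped_dz(z: np.ndarray, center: float, box_z: float) -> np.ndarray:
    dz = z - center
    return dz - box_z * np.round(dz / box_z)


def partial_density(
    trajset: TrajectorySet,
    selection: RoleSelection | np.ndarray,
    bin_width: float = 0.1,
    weighting: str = "number",
    center_mode: str = "mass",
) -> AxialProfile:
    """Replicate-averaged density of the selected atoms vs. distance from the
    bilayer center.

    ``weighting='number'`` yields number density (atoms/nm³); ``'mass'``
    multiplies each atom by its element mass (u/nm³).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if weighting not in ("number", "mass"):
        raise ValueError(f"unknown weighting {weighting!r}")
    top = trajset.topology
    if isinstance(selection, RoleSelection):
        sel = select_atoms(top, selection)
    else:
        sel = np.asarray(selection, dtype=np.int64)
    if sel.size == 0:
        logger.warning("partial_density: empty selection, profile is all zero")
    weights = top.masses[sel] if weighting == "mass" else np.ones(sel.size)

    box_z = max(f.box[2] for _, f in trajset.iter_frames())
    edges = _bin_edges(box_z, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    rep_means = []
    for rep in trajset.replicates:
        acc = np.zeros(len(centers))
        for frame in rep:
            center = bilayer_center(top, frame, mode=center_mode)
            dz = wrapped_dz(frame.coordinates[sel, 2], center, frame.box[2])
            hist, _ = np.histogram(dz, bins=edges, weights=weights)
            area = frame.box[0] * frame.box[1]
            acc += hist / (bin_width * area)
        rep_means.append(acc / max(len(rep), 1))
    rep_means = np.array(rep_means)
    values = rep_means.mean(axis=0)
    if len(rep_means) > 1:
        sem = rep_means.std(axis=0, ddof=1) / math.sqrt(len(rep_means))
    else:
        sem = np.zeros_like(values)
    quantity = "mass_density" if weighting == "mass" else "number_density"
    return AxialProfile(centers, values, sem, quantity=quantity)


def residue_axial_density(
    trajset: TrajectorySet,
    residue_min: int,
    residue_max: int,
    representative: str = "all_heavy",
    bin_width: float = 0.1,
    center_mode: str = "mass",
) -> AxialProfile:
    """Density profile of a protein residue range (e.g. the HHQK domain)."""
    from .roles import Role, Subrole

    if representative == "all_heavy":
        sel = RoleSelection(
            role=Role.PROTEIN,
            residue_min=residue_min,
            residue_max=residue_max,
            heavy_only=True,
        )
    elif representative == "sidechain":
        sel = RoleSelection(
            role=Role.PROTEIN,
            subrole=Subrole.SIDECHAIN,
            residue_min=residue_min,
            residue_max=residue_max,
            heavy_only=True,
        )
    else:
        raise ValueError(f"unknown representative {representative!r}")
    if select_atoms(trajset.topology, sel).size == 0:
        logger.warning(
            "residue_axial_density: residues %d-%d select no atoms",
            residue_min,
            residue_max,
        )
    return partial_density(trajset, sel, bin_width=bin_width, center_mode=center_mode)
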