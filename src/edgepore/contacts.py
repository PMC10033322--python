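"""Residue-resolved short-range contact analysis.

A residue is "in contact" with a partner group in a frame iff at least one
heavy-atom pair (residue atom, partner atom) lies within the cutoff under the
minimum-image convention (default 0.5 nm).  Contact frequency is the fraction
of frames in contact, averaged per replicate and reported with the standard
error across replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .neighbors import cross_pairs
from .roles import Role
from .trajectory import (
    FrameSnapshot,
    RoleSelection,
    Topology,
    TrajectorySet,
    select_atoms,
)

DEFAULT_CONTACT_CUTOFF = 0.5


@dataclass
class ContactMap:
    """Per-residue contact frequencies for one partner category."""

    residue_numbers: np.ndarray
    residue_names: list[str]
    partner_category: str
    frequency: np.ndarray  # mean over replicates, in [0, 1]
    sem: np.ndarray
    per_replicate: np.ndarray  # (n_rep, n_residues)


def _residue_atoms(
    topology: Topology, residue_min: int, residue_max: int
) -> tuple[np.ndarray, list[str], list[np.ndarray]]:
    """Residue numbers, names and heavy-atom index groups for a protein range."""
    sel = select_atoms(
        topology,
        RoleSelection(
            role=Role.PROTEIN,
            residue_min=residue_min,
            residue_max=residue_max,
            heavy_only=True,
        ),
    )
    resnums = np.unique(topology.residue_number[sel])
    groups, names = [], []
    for rn in resnums:
        idx = sel[topology.residue_number[sel] == rn]
        groups.append(idx)
        names.append(str(topology.residue_name[idx[0]]))
    return resnums, names, groups


def frame_contacts(
    topology: Topology,
    frame: FrameSnapshot,
    residue_min: int,
    residue_max: int,
    partner: RoleSelection | np.ndarray,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    method: str = "kdtree",
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean in-contact flag per residue for one frame.

    Returns (residue_numbers, contact flags).  Hydrogens are excluded on both
    sides; an empty partner selection yields all-false.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    resnums, _, groups = _residue_atoms(topology, residue_min, residue_max)
    if isinstance(partner, RoleSelection):
        pidx = select_atoms(topology, partner)
    else:
        pidx = np.asarray(partner, dtype=np.int64)
    pidx = pidx[topology.heavy_mask[pidx]]
    flags = np.zeros(len(resnums), dtype=bool)
    if pidx.size == 0 or len(resnums) == 0:
        return resnums, flags
    res_atoms = np.concatenate(groups)
    owner = np.concatenate(
        [np.full(len(g), i, dtype=np.int64) for i, g in enumerate(groups)]
    )
    pairs = cross_pairs(
        frame.coordinates[res_atoms],
        frame.coordinates[pidx],
        frame.box,
        cutoff,
        method=method,
    )
    flags[np.unique(owner[pairs[:, 0]])] = True
    return resnums, flags


def contact_frequency(
    trajset: TrajectorySet,
    residue_min: int,
    residue_max: int,
    partner: RoleSelection | np.ndarray,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    partner_category: str = "partner",
    method: str = "kdtree",
) -> ContactMap:
    """Fraction of frames each residue contacts the partner group.

    Replicates are weighted equally regardless of frame count.
    """
    top = trajset.topology
    resnums, names, _ = _residue_atoms(top, residue_min, residue_max)
    per_rep = np.zeros((trajset.n_replicates, len(resnums)))
    for ri, rep in enumerate(trajset.replicates):
        hits = np.zeros(len(resnums))
        for frame in rep:
            _, flags = frame_contacts(
                top, frame, residue_min, residue_max, partner, cutoff, method
            )
            hits += flags
        per_rep[ri] = hits / max(len(rep), 1)
    freq = per_rep.mean(axis=0)
    if trajset.n_replicates > 1:
        sem = per_rep.std(axis=0, ddof=1) / math.sqrt(trajset.n_replicates)
    else:
        sem = np.zeros_like(freq)
    return ContactMap(resnums, names, partner_category, freq, sem, per_rep)


#: partner categories of the standard contact map
def partner_selections() -> dict[str, RoleSelection]:
    from .roles import Subrole

    return {
        "phosphate": RoleSelection(role=Role.LIPID, subrole=Subrole.PHOSPHATE, heavy_only=True),
        "choline": RoleSelection(role=Role.LIPID, subrole=Subrole.CHOLINE, heavy_only=True),
        "carbonyl_O": RoleSelection(role=Role.LIPID, subrole=Subrole.CARBONYL_O),
        "ester_O": RoleSelection(role=Role.LIPID, subrole=Subrole.ESTER_O),
        "water": RoleSelection(role=Role.WATER, heavy_only=True),
        "K": RoleSelection(role=Role.ION, subrole=Subrole.K),
        "Cl": RoleSelection(role=Role.ION, subrole=Subrole.CL),
    }
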