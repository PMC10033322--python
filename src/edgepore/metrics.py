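"""Aggregate stability metrics: fitted RMSD, β-structure content, and
RMSD-based conformational pooling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import dihedral, superpose
from .roles import Role, Subrole
from .trajectory import FrameSnapshot, RoleSelection, Topology, select_atoms

MAINCHAIN_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class FitMask:
    """Atom indices used for superposition: mainchain (N, Cα, C, O) plus Cβ."""

    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.atom_indices) < 3:
            raise ValueError("a fit mask needs at least 3 atoms")


def mainchain_cb_mask(
    topology: Topology, residue_min: int, residue_max: int, chains: set[str] | None = None
) -> FitMask:
    """Mainchain + Cβ mask over a residue range (optionally limited to chains)."""
    sel = RoleSelection(
        role=Role.PROTEIN,
        residue_min=residue_min,
        residue_max=residue_max,
        names=frozenset(MAINCHAIN_NAMES + ("CB",)),
    )
    idx = select_atoms(topology, sel)
    if chains is not None:
        idx = idx[np.isin(topology.chain_id[idx], list(chains))]
    return FitMask(tuple(int(i) for i in idx))


def superpose_rmsd(
    frame_coords: np.ndarray,
    reference_coords: np.ndarray,
    mask: FitMask | np.ndarray | None = None,
) -> float:
    """RMSD (nm) over the mask after optimal rigid-body least-squares fit.

    The rotation is proper (no reflections).  Degenerate (collinear) masks
    raise instead of returning a meaningless fit.
    """
    frame_coords = np.asarray(frame_coords, dtype=float)
    reference_coords = np.asarray(reference_coords, dtype=float)
    if mask is not None:
        idx = np.asarray(
            mask.atom_indices if isinstance(mask, FitMask) else mask, dtype=np.int64
        )
        mobile = frame_coords[idx]
        ref = reference_coords[idx]
    else:
        mobile, ref = frame_coords, reference_coords
    if mobile.shape != ref.shape:
        raise ValueError("fit mask selects different atom counts in the two structures")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) fit mask")
    _, _, fitted = superpose(mobile, ref)
    return float(np.sqrt(((fitted - ref) ** 2).sum(axis=1).mean()))


#: extended-β region bounds in degrees: φ ∈ [-180, -45], ψ ∈ [45, 180] ∪ [-180, -150]
BETA_PHI = (-180.0, -45.0)
BETA_PSI_UPPER = (45.0, 180.0)
BETA_PSI_LOWER = (-180.0, -150.0)


def _is_beta(phi: float, psi: float) -> bool:
    in_phi = BETA_PHI[0] <= phi <= BETA_PHI[1]
    in_psi = (BETA_PSI_UPPER[0] <= psi <= BETA_PSI_UPPER[1]) or (
        BETA_PSI_LOWER[0] <= psi <= BETA_PSI_LOWER[1]
    )
    return in_phi and in_psi


def backbone_dihedrals(
    topology: Topology, frame: FrameSnapshot, residue_min: int, residue_max: int
) -> list[tuple[str, int, float, float]]:
    """(chain, residue, φ, ψ) for every residue in range with computable dihedrals."""
    out: list[tuple[str, int, float, float]] = []
    coords = frame.coordinates
    bb = select_atoms(
        topology,
        RoleSelection(role=Role.PROTEIN, subrole=Subrole.BACKBONE, names=frozenset(MAINCHAIN_NAMES)),
    )
    for chain in sorted(set(topology.chain_id[bb])):
        cidx = bb[topology.chain_id[bb] == chain]
        resnums = np.unique(topology.residue_number[cidx])
        atom_of: dict[tuple[int, str], int] = {}
        for i in cidx:
            atom_of[(int(topology.residue_number[i]), str(topology.name[i]))] = int(i)
        for rn in resnums:
            rn = int(rn)
            if not (residue_min <= rn <= residue_max):
                continue
            needed = [
                (rn - 1, "C"),
                (rn, "N"),
                (rn, "CA"),
                (rn, "C"),
                (rn + 1, "N"),
            ]
            if any(key not in atom_of for key in needed):
                continue  # chain termini excluded from the denominator
            c_prev, n, ca, c, n_next = (coords[atom_of[k]] for k in needed)
            phi = dihedral(c_prev, n, ca, c)
            psi = dihedral(n, ca, c, n_next)
            out.append((chain, rn, phi, psi))
    return out


def beta_content(
    topology: Topology, frame: FrameSnapshot, residue_min: int, residue_max: int
) -> float:
    """Fraction of residues (with defined φ/ψ) in the extended-β dihedral region."""
    dihedrals = backbone_dihedrals(topology, frame, residue_min, residue_max)
    if not dihedrals:
        raise ValueError("no residue in range has computable backbone dihedrals")
    hits = sum(1 for _, _, phi, psi in dihedrals if _is_beta(phi, psi))
    return hits / len(dihedrals)


@dataclass
class PoolAssignment:
    """RMSD-based conformational pools: I (< t1), II ([t1, t2)), III (≥ t2)."""

    labels: list[str]
    thresholds: tuple[float, float]


def pool_by_rmsd(
    rmsd_values: np.ndarray | list[float], thresholds: tuple[float, float] = (0.3, 0.6)
) -> PoolAssignment:
    """Assign per-trajectory mean RMSDs to pools I/II/III.

    Pool III (RMSD ≥ upper threshold, default 0.6 nm) is the non-conducting
    class.  Boundaries are left-closed for the upper pools.
    """
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValueError("thresholds must be strictly increasing")
    labels = []
    for v in np.asarray(rmsd_values, dtype=float):
        if v < t1:
            labels.append("I")
        elif v < t2:
            labels.append("II")
        else:
            labels.append("III")
    return PoolAssignment(labels, (t1, t2))
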