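"""Ion first-hydration-shell composition, membrane crossing events, and
permeation free-energy profiles.

Shell composition counts heavy atoms of fixed partner categories within a
cutoff (default 0.35 nm) of an ion.  Crossing events come from a hysteretic
three-state machine (bulk above / slab / bulk below) on the ion z track.
Permeation free energy is the Boltzmann inversion of an axial ion number
density relative to a bulk window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, GAS_CONSTANT_KJ_PER_MOL_K
from .defects import bilayer_center
from .density import AxialProfile, _bin_edges, wrapped_dz
from .neighbors import indices_within
from .roles import Role, Subrole
from .trajectory import (
    FrameSnapshot,
    RoleSelection,
    Topology,
    TrajectorySet,
    select_atoms,
)

DEFAULT_SHELL_CUTOFF = 0.35

#: shell partner categories: protein subcategories follow the β1-edge groups
#: (backbone carbonyl O of residues 9-21, H13/H14 imidazole N, Q15 side-chain O)
def shell_category_indices(topology: Topology) -> dict[str, np.ndarray]:
    heavy = topology.heavy_mask
    cats: dict[str, np.ndarray] = {}
    cats["water_O"] = select_atoms(
        topology, RoleSelection(role=Role.WATER, subrole=Subrole.WATER_O)
    )
    cats["lipid_O"] = select_atoms(
        topology, RoleSelection(role=Role.LIPID, elements=frozenset({"O"}))
    )
    cats["protein_total"] = select_atoms(
        topology, RoleSelection(role=Role.PROTEIN, heavy_only=True)
    )
    cats["backbone_carbonyl_O_res9_21"] = select_atoms(
        topology,
        RoleSelection(
            role=Role.PROTEIN,
            subrole=Subrole.BACKBONE,
            residue_min=9,
            residue_max=21,
            names=frozenset({"O"}),
        ),
    )
    cats["H13_sidechain"] = select_atoms(
        topology,
        RoleSelection(
            role=Role.PROTEIN,
            subrole=Subrole.SIDECHAIN,
            residue_min=13,
            residue_max=13,
            elements=frozenset({"N"}),
        ),
    )
    cats["H14_sidechain"] = select_atoms(
        topology,
        RoleSelection(
            role=Role.PROTEIN,
            subrole=Subrole.SIDECHAIN,
            residue_min=14,
            residue_max=14,
            elements=frozenset({"N"}),
        ),
    )
    cats["Q15_sidechain"] = select_atoms(
        topology,
        RoleSelection(
            role=Role.PROTEIN,
            subrole=Subrole.SIDECHAIN,
            residue_min=15,
            residue_max=15,
            elements=frozenset({"O"}),
        ),
    )
    return {k: v[heavy[v]] for k, v in cats.items()}


SHELL_CATEGORIES = (
    "water_O",
    "lipid_O",
    "protein_total",
    "backbone_carbonyl_O_res9_21",
    "H13_sidechain",
    "H14_sidechain",
    "Q15_sidechain",
)


@dataclass
class ShellComposition:
    """First-shell partner counts around one ion in one frame."""

    counts: dict[str, int]
    cutoff: float = DEFAULT_SHELL_CUTOFF

    def __post_init__(self) -> None:
        for k, v in self.counts.items():
            if v < 0:
                raise ValueError(f"negative count for {k}")
        total = self.counts.get("protein_total", 0)
        for k in (
            "backbone_carbonyl_O_res9_21",
            "H13_sidechain",
            "H14_sidechain",
            "Q15_sidechain",
        ):
            if self.counts.get(k, 0) > total:
                raise ValueError(f"protein subcategory {k} exceeds protein_total")


def shell_composition(
    topology: Topology,
    frame: FrameSnapshot,
    ion_index: int,
    cutoff: float = DEFAULT_SHELL_CUTOFF,
    categories: dict[str, np.ndarray] | None = None,
    method: str = "kdtree",
) -> ShellComposition:
    """Count heavy partner atoms of each category within ``cutoff`` of the ion."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not (0 <= ion_index < topology.n_atoms):
        raise IndexError(f"ion index {ion_index} out of range")
    if categories is None:
        categories = shell_category_indices(topology)
    pos = frame.coordinates[ion_index]
    counts: dict[str, int] = {}
    for cat, idx in categories.items():
        idx = idx[idx != ion_index]
        if idx.size == 0:
            counts[cat] = 0
            continue
        within = indices_within(pos, frame.coordinates[idx], frame.box, cutoff, method)
        counts[cat] = int(within.size)
    return ShellComposition(counts, cutoff)


def coordination_profile(
    trajset: TrajectorySet,
    ion_selection: RoleSelection | np.ndarray | None = None,
    bin_width: float = 0.1,
    cutoff: float = DEFAULT_SHELL_CUTOFF,
    center_mode: str = "mass",
    method: str = "kdtree",
) -> dict[str, AxialProfile]:
    """Mean first-shell composition vs. ion depth, one profile per category.

    Every (ion, frame) observation is binned by z − z_center; bins without any
    observation are flagged missing.  SEM runs across replicates that sampled
    the bin.
    """
    top = trajset.topology
    if ion_selection is None:
        ion_selection = RoleSelection(role=Role.ION, subrole=Subrole.K)
    if isinstance(ion_selection, RoleSelection):
        ions = select_atoms(top, ion_selection)
    else:
        ions = np.asarray(ion_selection, dtype=np.int64)
    if ions.size == 0:
        raise ValueError("ion selection is empty")
    categories = shell_category_indices(top)

    box_z = max(f.box[2] for _, f in trajset.iter_frames())
    edges = _bin_edges(box_z, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nb = len(centers)
    n_rep = trajset.n_replicates

    sums = {c: np.zeros((n_rep, nb)) for c in categories}
    nobs = np.zeros((n_rep, nb))
    for ri, rep in enumerate(trajset.replicates):
        for frame in rep:
            zc = bilayer_center(top, frame, mode=center_mode)
            for ion in ions:
                dz = wrapped_dz(frame.coordinates[ion, 2], zc, frame.box[2])
                b = int(np.clip(np.digitize(dz, edges) - 1, 0, nb - 1))
                comp = shell_composition(top, frame, int(ion), cutoff, categories, method)
                nobs[ri, b] += 1
                for c in categories:
                    sums[c][ri, b] += comp.counts[c]

    profiles: dict[str, AxialProfile] = {}
    missing = nobs.sum(axis=0) == 0
    for c in categories:
        with np.errstate(invalid="ignore", divide="ignore"):
            rep_mean = np.where(nobs > 0, sums[c] / nobs, np.nan)
        values = np.full(nb, np.nan)
        sem = np.full(nb, np.nan)
        for b in range(nb):
            col = rep_mean[:, b]
            ok = ~np.isnan(col)
            if ok.sum() == 0:
                continue
            values[b] = col[ok].mean()
            sem[b] = (
                col[ok].std(ddof=1) / math.sqrt(ok.sum()) if ok.sum() > 1 else 0.0
            )
        profiles[c] = AxialProfile(centers, values, sem, quantity="coordination", missing=missing)
    return profiles


@dataclass
class CrossingEvent:
    ion_index: int
    replicate: int
    entry_time: float
    exit_time: float
    direction: str  # "up" or "down"

    def __post_init__(self) -> None:
        if self.exit_time <= self.entry_time:
            raise ValueError("exit_time must be after entry_time")
        if self.direction not in ("up", "down"):
            raise ValueError(f"bad direction {self.direction!r}")


def crossing_events(
    trajset: TrajectorySet,
    ion_selection: RoleSelection | np.ndarray | None = None,
    slab_halfwidth: float = 1.4,
    bulk_margin: float = 0.4,
    center_mode: str = "mass",
) -> list[CrossingEvent]:
    """Detect complete membrane traversals of ions.

    Per ion, a three-state machine with hysteresis classifies z − z_center as
    bulk above (> +h+m), slab (|z| ≤ h) or bulk below (< −h−m).  A crossing is
    emitted when an ion moves bulk → slab → opposite bulk without revisiting
    the origin-side bulk.
    """
    top = trajset.topology
    if ion_selection is None:
        ion_selection = RoleSelection(role=Role.ION, subrole=Subrole.K)
    if isinstance(ion_selection, RoleSelection):
        ions = select_atoms(top, ion_selection)
    else:
        ions = np.asarray(ion_selection, dtype=np.int64)
    h, m = slab_halfwidth, bulk_margin
    events: list[CrossingEvent] = []
    for ri, rep in enumerate(trajset.replicates):
        times = np.array([f.time for f in rep])
        centers = np.array([bilayer_center(top, f, mode=center_mode) for f in rep])
        for ion in ions:
            z = np.array([f.coordinates[ion, 2] for f in rep]) - centers
            origin: str | None = None  # bulk side the ion came from
            entry: float | None = None
            for t, zi in zip(times, z):
                if zi > h + m:
                    side = "above"
                elif zi < -h - m:
                    side = "below"
                elif abs(zi) <= h:
                    side = "slab"
                else:
                    side = "margin"
                if side in ("above", "below"):
                    if origin is not None and side != origin and entry is not None:
                        events.append(
                            CrossingEvent(
                                ion_index=int(ion),
                                replicate=ri,
                                entry_time=float(entry),
                                exit_time=float(t),
                                direction="down" if side == "below" else "up",
                            )
                        )
                    origin = side
                    entry = None
                elif side == "slab" and origin is not None and entry is None:
                    entry = t
    return events


def permeation_free_energy(
    profile: AxialProfile,
    bulk_window: tuple[float, float] = (2.5, 3.5),
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> AxialProfile:
    """Boltzmann inversion ΔG(z) = −RT·ln(ρ(z)/ρ_bulk) of an ion density profile.

    ρ_bulk is the mean density over bins with |z| inside ``bulk_window``.
    Bins with zero density are flagged undefined (NaN), not ±inf.
    """
    lo, hi = bulk_window
    z = profile.bin_centers
    bulk = (np.abs(z) >= lo) & (np.abs(z) <= hi)
    if not bulk.any():
        raise ValueError("bulk window selects no bins")
    rho = np.asarray(profile.values, dtype=float)
    rho_bulk = rho[bulk].mean()
    if not rho_bulk > 0:
        raise ValueError("bulk density is zero; cannot normalise")
    if np.any(rho[bulk] <= 0):
        raise ValueError("density profile must be strictly positive in the bulk window")
    defined = rho > 0
    dg = np.full(rho.shape, np.nan)
    dg[defined] = -GAS_CONSTANT_KJ_PER_MOL_K * temperature * np.log(rho[defined] / rho_bulk)
    return AxialProfile(
        z, dg, np.zeros_like(dg), quantity="free_energy", missing=~defined
    )
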