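"""β-sheet oligomer model construction and transformation.

Covers the model-identifier grammar (``<SizeWord>-<k>pe-<composition>``),
rigid-body assembly of β-sandwich models from a single-sheet template, strand
deletion to derive truncation isoforms, and the strand/edge sidecar consumed
by the defect analysis.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .defects import EdgeDefinition
from .geometry import rotation_about_axis
from .neighbors import min_cross_distance
from .roles import Role
from .trajectory import (
    AtomRecord,
    FrameSnapshot,
    RoleSelection,
    Topology,
    select_atoms,
)

STRAND_LABELS = ("beta1", "beta2", "beta3")

#: template residue spans per strand class (β1 / β2 / β3)
STRAND_SPANS = {"beta1": (9, 21), "beta2": (29, 40), "beta3": (29, 41)}

SIZE_WORDS = {"Di": 2, "Tri": 3, "Tetra": 4, "Penta": 5, "Hexa": 6, "Octa": 8}
_WORD_OF_SIZE = {v: k for k, v in SIZE_WORDS.items()}


class ModelIDError(ValueError):
    """Malformed model identifier."""


class AssemblyError(ValueError):
    """Rigid-body assembly failed (steric clash)."""


@dataclass(frozen=True)
class ModelID:
    """Parsed model identifier, e.g. ``Penta-1pe-3.3.2`` or ``Tetra-0pe-2OTK``."""

    size_word: str
    pair_edges: int
    composition: tuple[int, ...] | None = None
    template: str | None = None

    @property
    def size(self) -> int:
        return SIZE_WORDS[self.size_word]

    def __str__(self) -> str:
        return format_model_id(self)


_ID_RE = re.compile(r"^(?P<word>[A-Za-z]+)-(?P<k>\d+)pe-(?P<comp>.+)$")


def parse_model_id(text: str) -> ModelID:
    """Parse ``<SizeWord>-<k>pe-<composition>``; composition is either a
    dot-separated integer list or a template code kept verbatim."""
    m = _ID_RE.match(text.strip())
    if not m:
        raise ModelIDError(f"identifier {text!r} does not match <SizeWord>-<k>pe-<composition>")
    word = m.group("word")
    if word not in SIZE_WORDS:
        raise ModelIDError(f"unknown size word {word!r} in {text!r}")
    k = int(m.group("k"))
    comp = m.group("comp")
    parts = comp.split(".")
    if all(p.isdigit() for p in parts):
        return ModelID(word, k, composition=tuple(int(p) for p in parts))
    if "." in comp:
        raise ModelIDError(f"mixed composition token {comp!r} in {text!r}")
    return ModelID(word, k, template=comp)


def format_model_id(mid: ModelID) -> str:
    if mid.composition is not None:
        comp = ".".join(str(c) for c in mid.composition)
    elif mid.template is not None:
        comp = mid.template
    else:
        raise ModelIDError("model id needs a composition or template")
    return f"{mid.size_word}-{mid.pair_edges}pe-{comp}"


@dataclass(frozen=True)
class Strand:
    """One β-strand: class label, owning chain and residue span."""

    label: str
    chain: str
    residue_min: int
    residue_max: int

    def __post_init__(self) -> None:
        if self.label not in STRAND_LABELS:
            raise ValueError(f"unknown strand label {self.label!r}")
        lo, hi = STRAND_SPANS[self.label]
        if self.residue_min < lo or self.residue_max > hi:
            raise ValueError(
                f"{self.label} span {self.residue_min}-{self.residue_max} outside "
                f"template bounds {lo}-{hi}"
            )


def strand_atom_indices(topology: Topology, strand: Strand, heavy_only: bool = True) -> np.ndarray:
    sel = RoleSelection(
        role=Role.PROTEIN,
        residue_min=strand.residue_min,
        residue_max=strand.residue_max,
        chain=strand.chain,
        heavy_only=heavy_only,
    )
    return select_atoms(topology, sel)


@dataclass
class EdgeInfo:
    """A sheet edge: the strand(s) forming it plus the resolved EdgeDefinition."""

    label: str
    strands: list[Strand]
    definition: EdgeDefinition

    @property
    def is_pair_edge(self) -> bool:
        return len(self.strands) >= 2

    @property
    def is_beta1_pair_edge(self) -> bool:
        return self.is_pair_edge and all(s.label == "beta1" for s in self.strands)


@dataclass
class OligomerModel:
    """A labeled β-sheet assembly: chains, strand classes, and edge metadata."""

    chains: list[str]
    strands: list[Strand]
    edges: list[EdgeInfo] = field(default_factory=list)
    identifier: ModelID | None = None

    @property
    def n_strands(self) -> int:
        return len(self.strands)

    def beta1_pair_edge_count(self) -> int:
        return sum(e.is_beta1_pair_edge for e in self.edges)

    def strand_counts(self) -> tuple[int, int, int]:
        return tuple(
            sum(1 for s in self.strands if s.label == lab) for lab in STRAND_LABELS
        )


def _strand_centroid(topology: Topology, frame: FrameSnapshot, strand: Strand) -> np.ndarray:
    idx = strand_atom_indices(topology, strand)
    return frame.coordinates[idx].mean(axis=0)


def compute_edges(
    strands: list[Strand],
    topology: Topology,
    frame: FrameSnapshot,
    lateral_cutoff: float = 1.0,
    layer_gap: float = 0.45,
) -> list[EdgeInfo]:
    """Edges from the outermost strands of each sheet layer.

    Strands are clustered into layers by their mean position along the sheet
    separation axis (x); within each layer the strands at both extremes of the
    stacking axis (y) are the edge strands.  The two edges collect one strand
    per layer, so a sandwich yields side-by-side pair edges.
    """
    if not strands:
        return []
    cx = np.array([_strand_centroid(topology, frame, s)[0] for s in strands])
    cy = np.array([_strand_centroid(topology, frame, s)[1] for s in strands])
    order = np.argsort(cx, kind="stable")
    layers: list[list[int]] = [[int(order[0])]]
    for i in order[1:]:
        if cx[i] - cx[layers[-1][-1]] > layer_gap:
            layers.append([int(i)])
        else:
            layers[-1].append(int(i))
    lo_strands, hi_strands = [], []
    for layer in layers:
        ys = cy[layer]
        lo_strands.append(strands[layer[int(np.argmin(ys))]])
        hi_strands.append(strands[layer[int(np.argmax(ys))]])
    edges = []
    for label, members in (("edge_A", lo_strands), ("edge_B", hi_strands)):
        idx = np.concatenate([strand_atom_indices(topology, s) for s in members])
        edges.append(
            EdgeInfo(
                label,
                members,
                EdgeDefinition(label, tuple(int(i) for i in np.sort(idx)), lateral_cutoff),
            )
        )
    return edges


def derive_model_id(model: OligomerModel) -> ModelID | None:
    size = len(model.chains)
    if size not in _WORD_OF_SIZE:
        return None
    return ModelID(
        _WORD_OF_SIZE[size],
        model.beta1_pair_edge_count(),
        composition=model.strand_counts(),
    )


def _next_chain_ids(existing: list[str], n: int) -> list[str]:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    fresh = [c for c in alphabet if c not in existing]
    if len(fresh) < n:
        raise AssemblyError("ran out of chain identifiers")
    return fresh[:n]


def assemble_sandwich(
    model: OligomerModel,
    topology: Topology,
    frame: FrameSnapshot,
    packing: str = "face_to_face_AP",
    offset: float = 1.0,
    clash_min: float = 0.25,
    lateral_cutoff: float = 1.0,
) -> tuple[OligomerModel, Topology, FrameSnapshot]:
    """Duplicate a single-sheet template into a β-sandwich by a rigid transform.

    ``face_to_face_AP``: 180° rotation about the membrane normal (about the
    sheet centroid) followed by a lateral translation by ``offset`` along x.
    ``face_to_back_P``: lateral translation only (strand directions preserved).
    """
    if offset <= 0:
        raise AssemblyError("offset must be positive")
    prot = select_atoms(topology, RoleSelection(role=Role.PROTEIN))
    if prot.size != topology.n_atoms:
        raise AssemblyError("template must contain only the protein sheet")
    coords = frame.coordinates
    centroid = coords.mean(axis=0)
    if packing == "face_to_face_AP":
        rot = rotation_about_axis([0.0, 0.0, 1.0], 180.0)
        copy = (coords - centroid) @ rot.T + centroid
    elif packing == "face_to_back_P":
        copy = coords.copy()
    else:
        raise ValueError(f"unknown packing {packing!r}")
    copy = copy + np.array([offset, 0.0, 0.0])

    heavy = topology.heavy_mask
    dmin = min_cross_distance(coords[heavy], copy[heavy], frame.box)
    if dmin < clash_min:
        hidx = np.flatnonzero(heavy)
        from .geometry import minimum_image_distance

        dist = minimum_image_distance(coords[hidx], copy[hidx], frame.box)
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        rec_a, rec_b = topology.record(int(hidx[i])), topology.record(int(hidx[j]))
        raise AssemblyError(
            f"inter-copy clash: {dist[i, j]:.3f} nm < {clash_min} nm between "
            f"{rec_a.chain_id}/{rec_a.residue_number}/{rec_a.name} and copy "
            f"{rec_b.chain_id}/{rec_b.residue_number}/{rec_b.name}"
        )

    chain_map = dict(zip(model.chains, _next_chain_ids(model.chains, len(model.chains))))
    n = topology.n_atoms
    new_records = list(topology.records) + [
        replace(
            r,
            atom_index=r.atom_index + n,
            chain_id=chain_map[r.chain_id],
        )
        for r in topology.records
    ]
    new_top = Topology(new_records)
    new_frame = FrameSnapshot(
        np.vstack([coords, copy]), frame.box.copy(), frame.time
    )
    new_strands = list(model.strands) + [
        replace(s, chain=chain_map[s.chain]) for s in model.strands
    ]
    new_model = OligomerModel(
        chains=model.chains + [chain_map[c] for c in model.chains],
        strands=new_strands,
    )
    new_model.edges = compute_edges(new_strands, new_top, new_frame, lateral_cutoff)
    new_model.identifier = derive_model_id(new_model)
    return new_model, new_top, new_frame


def delete_strands(
    model: OligomerModel,
    topology: Topology,
    frame: FrameSnapshot,
    which: list[int | str | Strand],
    lateral_cutoff: float = 1.0,
) -> tuple[OligomerModel, Topology, FrameSnapshot]:
    """Remove strands by index, class label (all matching), or Strand object.

    Atoms of deleted strands are removed, chains left without strands vanish,
    edges and the identifier are recomputed.  Requesting a strand that does
    not exist raises — a second deletion never silently no-ops.
    """
    doomed: set[Strand] = set()
    for item in which:
        if isinstance(item, Strand):
            if item not in model.strands:
                raise ValueError(f"strand {item} not in model")
            doomed.add(item)
        elif isinstance(item, int):
            try:
                doomed.add(model.strands[item])
            except IndexError as exc:
                raise ValueError(f"strand index {item} out of range") from exc
        elif isinstance(item, str):
            matches = [s for s in model.strands if s.label == item]
            if not matches:
                raise ValueError(f"no strand labeled {item!r} in model")
            doomed.update(matches)
        else:
            raise TypeError(f"cannot interpret strand selector {item!r}")
    survivors = [s for s in model.strands if s not in doomed]
    if not survivors:
        raise ValueError("cannot delete every strand of a model")

    keep = np.ones(topology.n_atoms, dtype=bool)
    for s in doomed:
        idx = strand_atom_indices(topology, s, heavy_only=False)
        keep[idx] = False
    surviving_chains = sorted(
        {s.chain for s in survivors}, key=model.chains.index
    )
    # drop whole chains that lost all their strands
    keep &= np.isin(topology.chain_id, surviving_chains)

    kept_idx = np.flatnonzero(keep)
    new_records = [
        replace(topology.record(int(i)), atom_index=k) for k, i in enumerate(kept_idx)
    ]
    new_top = Topology(new_records)
    new_frame = FrameSnapshot(
        frame.coordinates[kept_idx], frame.box.copy(), frame.time
    )
    new_model = OligomerModel(chains=surviving_chains, strands=survivors)
    new_model.edges = compute_edges(survivors, new_top, new_frame, lateral_cutoff)
    new_model.identifier = derive_model_id(new_model)
    return new_model, new_top, new_frame


# ---------------------------------------------------------------------------
# sidecar
# ---------------------------------------------------------------------------


def model_to_dict(model: OligomerModel) -> dict:
    return {
        "identifier": str(model.identifier) if model.identifier else None,
        "chains": model.chains,
        "strands": [
            {
                "label": s.label,
                "chain": s.chain,
                "residue_min": s.residue_min,
                "residue_max": s.residue_max,
            }
            for s in model.strands
        ],
        "edges": [
            {
                "label": e.label,
                "strands": [model.strands.index(s) for s in e.strands],
                "lateral_cutoff": e.definition.lateral_cutoff,
            }
            for e in model.edges
        ],
    }


def model_from_dict(data: dict, topology: Topology) -> OligomerModel:
    strands = [
        Strand(d["label"], d["chain"], d["residue_min"], d["residue_max"])
        for d in data["strands"]
    ]
    model = OligomerModel(chains=list(data["chains"]), strands=strands)
    edges = []
    for ed in data.get("edges", []):
        members = [strands[i] for i in ed["strands"]]
        idx = np.concatenate([strand_atom_indices(topology, s) for s in members])
        edges.append(
            EdgeInfo(
                ed["label"],
                members,
                EdgeDefinition(
                    ed["label"],
                    tuple(int(i) for i in np.sort(idx)),
                    ed.get("lateral_cutoff", 1.0),
                ),
            )
        )
    model.edges = edges
    ident = data.get("identifier")
    model.identifier = parse_model_id(ident) if ident else None
    return model


def write_model_sidecar(path: str | Path, model: OligomerModel) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")


def read_model_sidecar(path: str | Path, topology: Topology) -> OligomerModel:
    return model_from_dict(json.loads(Path(path).read_text()), topology)
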