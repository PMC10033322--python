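"""Atom role/subrole vocabulary and the name-based assignment rule table.

Every atom in a topology carries a coarse ``role`` (protein / lipid / water /
ion / other) and a finer ``subrole`` used by the analysis selections
(phosphate, choline, carbonyl oxygen, water oxygen, ...).  Assignment is
purely rule based on residue and atom names so that both real PDB files and
synthetic toy systems load through the same path.
"""

from __future__ import annotations

import logging
from enum import Enum

logger = logging.getLogger(__name__)


class Role(str, Enum):
    PROTEIN = "protein"
    LIPID = "lipid"
    WATER = "water"
    ION = "ion"
    OTHER = "other"


class Subrole(str, Enum):
    BACKBONE = "backbone"
    SIDECHAIN = "sidechain"
    CARBONYL_O = "carbonyl_O"
    PHOSPHATE = "phosphate"
    CHOLINE = "choline"
    ESTER_O = "ester_O"
    WATER_O = "water_O"
    K = "K"
    CL = "Cl"
    OTHER = "other"


#: legal subroles under each role
ROLE_COMPAT: dict[Role, frozenset[Subrole]] = {
    Role.PROTEIN: frozenset({Subrole.BACKBONE, Subrole.SIDECHAIN, Subrole.OTHER}),
    Role.LIPID: frozenset(
        {
            Subrole.PHOSPHATE,
            Subrole.CHOLINE,
            Subrole.CARBONYL_O,
            Subrole.ESTER_O,
            Subrole.OTHER,
        }
    ),
    Role.WATER: frozenset({Subrole.WATER_O, Subrole.OTHER}),
    Role.ION: frozenset({Subrole.K, Subrole.CL, Subrole.OTHER}),
    Role.OTHER: frozenset({Subrole.OTHER}),
}


AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL HSD HSE HSP HID HIE HIP ACE NME""".split()
)

WATER_RESIDUES = frozenset({"HOH", "SOL", "WAT", "TIP3", "TIP", "SPC", "W"})

K_RESIDUES = frozenset({"K", "K+", "POT"})
CL_RESIDUES = frozenset({"CL", "CL-", "CLA"})

LIPID_RESIDUES = frozenset({"POPC", "POPE", "DOPC", "DPPC", "LIP", "PC", "POP", "DOP", "DPP"})

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA", "HN"})

# POPC-style atom name map (CHARMM / Slipids conventions)
_LIPID_PHOSPHATE = frozenset({"P", "P8", "O11", "O12", "O13", "O14", "OP1", "OP2", "OP3", "OP4"})
_LIPID_CHOLINE = frozenset({"N", "N4", "C11", "C12", "C13", "C14", "C15", "C5", "C6", "C7"})
_LIPID_ESTER_O = frozenset({"O21", "O31", "OS1", "OS2"})
_LIPID_CARBONYL_O = frozenset({"O22", "O32", "OC1", "OC2"})

#: atomic masses (u) for the elements that occur in these systems
MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "K": 39.098,
    "CL": 35.45,
    "NA": 22.990,
}


def element_mass(element: str) -> float:
    return MASSES.get(element.upper(), 12.011)


def guess_element(atom_name: str, residue_name: str) -> str:
    """Infer an element symbol from an atom name when none is given."""
    res = residue_name.strip().upper()
    if res in K_RESIDUES:
        return "K"
    if res in CL_RESIDUES:
        return "CL"
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    if stripped[:2].upper() in ("CL", "NA") and len(atom_name.strip()) <= 2:
        return stripped[:2].upper()
    return stripped[0].upper()


def assign_role(atom_name: str, residue_name: str) -> tuple[Role, Subrole]:
    """Map (atom name, residue name) to (role, subrole) via the rule table.

    Unknown combinations are tagged ``(other, other)`` with a warning so toy
    systems always load; nothing is ever dropped.
    """
    name = atom_name.strip().upper()
    res = residue_name.strip().upper()

    if res in WATER_RESIDUES:
        if name.startswith("O"):
            return Role.WATER, Subrole.WATER_O
        return Role.WATER, Subrole.OTHER
    if res in K_RESIDUES:
        return Role.ION, Subrole.K
    if res in CL_RESIDUES:
        return Role.ION, Subrole.CL
    if res in LIPID_RESIDUES:
        if name in _LIPID_PHOSPHATE:
            return Role.LIPID, Subrole.PHOSPHATE
        if name in _LIPID_CHOLINE:
            return Role.LIPID, Subrole.CHOLINE
        if name in _LIPID_ESTER_O:
            return Role.LIPID, Subrole.ESTER_O
        if name in _LIPID_CARBONYL_O:
            return Role.LIPID, Subrole.CARBONYL_O
        return Role.LIPID, Subrole.OTHER
    if res in AMINO_ACIDS:
        if name in BACKBONE_NAMES:
            return Role.PROTEIN, Subrole.BACKBONE
        return Role.PROTEIN, Subrole.SIDECHAIN

    logger.warning("unknown residue/atom name %r/%r tagged role=other", residue_name, atom_name)
    return Role.OTHER, Subrole.OTHER


def validate_role(role: Role, subrole: Subrole) -> None:
    if subrole not in ROLE_COMPAT[role]:
        raise ValueError(f"subrole {subrole.value!r} is not legal under role {role.value!r}")
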