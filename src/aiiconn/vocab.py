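"""Controlled vocabularies shared across the package.

Cell types form a closed vocabulary with a shallow subtype hierarchy:
subtype labels (e.g. ``ON_CB6``) collapse onto their parent (``ON_CB``)
in connectivity tallies via :func:`effective_type`.
"""
from __future__ import annotations

from enum import Enum


class CellType(str, Enum):
    AII = "AII"
    RB = "RB"
    ON_CB = "ON_CB"
    ON_CB5 = "ON_CB5"
    ON_CB6 = "ON_CB6"
    ON_CB7 = "ON_CB7"
    ON_CB8 = "ON_CB8"
    OFF_CB = "OFF_CB"
    AC = "AC"
    NOS1_AC = "NOS1_AC"
    A17 = "A17"
    DAC = "DAC"
    SAC_ON = "SAC_ON"
    SAC_OFF = "SAC_OFF"
    GC = "GC"
    UNIDENTIFIED = "UNIDENTIFIED"


#: subtype -> parent used when tallying connectivity
_PARENT: dict[CellType, CellType] = {
    CellType.ON_CB5: CellType.ON_CB,
    CellType.ON_CB6: CellType.ON_CB,
    CellType.ON_CB7: CellType.ON_CB,
    CellType.ON_CB8: CellType.ON_CB,
    CellType.NOS1_AC: CellType.AC,
    CellType.DAC: CellType.AC,
}

#: presynaptic types allowed to carry ribbon synapses
BIPOLAR_TYPES: frozenset[CellType] = frozenset(
    {
        CellType.RB,
        CellType.ON_CB,
        CellType.ON_CB5,
        CellType.ON_CB6,
        CellType.ON_CB7,
        CellType.ON_CB8,
        CellType.OFF_CB,
    }
)


def effective_type(t: CellType) -> CellType:
    """Collapse a subtype label onto its tally parent (identity otherwise)."""
    return _PARENT.get(t, t)


def parse_cell_type(token: str) -> CellType | None:
    """Case-insensitive lookup of a cell-type token; ``None`` if unknown."""
    key = token.strip().upper().replace("-", "_")
    try:
        return CellType[key]
    except KeyError:
        return None


class SynKind(str, Enum):
    RIBBON = "ribbon"
    CONVENTIONAL = "conventional"


class Direction(str, Enum):
    INPUT = "input"
    OUTPUT = "output"


class Compartment(str, Enum):
    DISTAL_DENDRITE = "distal_dendrite"
    PROXIMAL_DENDRITE = "proximal_dendrite"
    SOMA = "soma"
    UNASSIGNED = "unassigned"


class LaminarZone(str, Enum):
    OUTER_OFF = "outer_OFF"
    BETWEEN_SAC = "between_SAC"
    INNER_ON = "inner_ON"
    SUB_ON = "sub_ON"
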