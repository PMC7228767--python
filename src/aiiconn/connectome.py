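"""Typed synapse tables and connectivity accounting.

Builds directed synapse records from node annotations (two-sided when a
pre/post annotation pair can be matched by partner id or proximity),
then derives input/output tallies by partner type and compartment,
cross-cell mean ± SD summaries, axon→target convergence, and the
composition of ribbon dyads.

Percentage convention: shares are stored as raw fractions; display
rounds to one decimal and drops a trailing ``.0`` (so 85, 63.5, 9.5 all
occur); integer accessors round half-up.
"""
from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._cluster import single_linkage
from .geometry import IPLFrame, ipl_depth
from .skeleton_io import (
    AnnotationRecord,
    Skeleton,
    SkeletonForest,
    path_distance,
    to_physical,
    VoxelScale,
)
from .vocab import (
    BIPOLAR_TYPES,
    CellType,
    Compartment,
    Direction,
    SynKind,
    effective_type,
)

log = logging.getLogger(__name__)

__all__ = [
    "SynapseRecord",
    "PairingConfig",
    "PairingConflictError",
    "TallyRow",
    "TallyTable",
    "SummaryRow",
    "ConvergenceTable",
    "DyadComposition",
    "round_half_up",
    "percent_display",
    "build_synapse_table",
    "assign_compartment",
    "tally_inputs",
    "tally_outputs",
    "aggregate_summary",
    "convergence",
    "dyad_composition",
    "records_to_frame",
    "write_synapse_tsv",
    "read_synapse_tsv",
]


# --------------------------------------------------------------------------
# rounding conventions

def round_half_up(x: float) -> int:
    """Round half away from zero (the tables' integer convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent_display(fraction: float) -> str:
    """Percent at one decimal; the decimal is dropped when it is .0."""
    pct = round(fraction * 100.0, 1)
    if pct == int(pct):
        return str(int(pct))
    return f"{pct:g}"


# --------------------------------------------------------------------------
# synapse records

@dataclass(frozen=True)
class SynapseRecord:
    """One directed chemical synapse."""

    synapse_id: int
    pre_id: int | None
    pre_type: CellType
    post_id: int | None
    post_type: CellType
    kind: SynKind
    position: tuple[float, float, float] = (math.nan,) * 3  # physical nm
    depth: float = math.nan
    compartment: Compartment = Compartment.UNASSIGNED
    provenance: str = "constructed"
    pre_node: int | None = None
    post_node: int | None = None
    dyad_site: int | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pre_id is not None and self.pre_id == self.post_id:
            raise ValueError(f"synapse {self.synapse_id}: pre and post cell identical")


@dataclass(frozen=True)
class PairingConfig:
    epsilon_nm: float = 500.0   # proximity-pairing radius
    dyad_radius_nm: float = 300.0  # ribbon records within this share a dyad site
    soma_radius_um: float = 5.0
    distal_depth_threshold: float = 0.9  # depth at/after which dendrites count as distal

    def __post_init__(self) -> None:
        if self.epsilon_nm <= 0 or self.dyad_radius_nm <= 0 or self.soma_radius_um <= 0:
            raise ValueError("pairing thresholds must be positive")


class PairingConflictError(ValueError):
    """Mutually id-matched annotations whose kinds cannot be reconciled."""


def assign_compartment(
    depth: float,
    post_skeleton: Skeleton | None,
    post_node: int | None,
    scale: VoxelScale | None,
    config: PairingConfig = PairingConfig(),
) -> Compartment:
    """Compartment of a synapse on its postsynaptic cell.

    Soma wins when the synapse-bearing node lies within ``soma_radius_um``
    (geodesic) of a declared soma node; otherwise distal vs proximal is
    decided by normalized depth; with neither available: unassigned.
    """
    if (
        post_skeleton is not None
        and post_skeleton.soma_node is not None
        and post_node is not None
        and scale is not None
    ):
        d = path_distance(post_skeleton, post_node, post_skeleton.soma_node, scale)
        if d <= config.soma_radius_um:
            return Compartment.SOMA
    if not math.isnan(depth):
        if depth >= config.distal_depth_threshold:
            return Compartment.DISTAL_DENDRITE
        return Compartment.PROXIMAL_DENDRITE
    return Compartment.UNASSIGNED


def _ann_position(forest: SkeletonForest, ann: AnnotationRecord) -> tuple[float, float, float]:
    return to_physical(forest.node(ann.skeleton_id, ann.node_id).position, forest.scale)


def build_synapse_table(
    forest: SkeletonForest,
    frame: IPLFrame | None,
    types: Mapping[int, CellType],
    pairing: PairingConfig = PairingConfig(),
) -> list[SynapseRecord]:
    """Form directed synapse records from the forest's annotations.

    Pairing precedence: (a) mutual partner-id matches; (b) greedy
    proximity pairing of an output and an input annotation of the same
    kind on different cells within ``epsilon_nm``, each annotation used
    at most once.  Unpaired annotations yield one-sided records whose
    opposite cell comes from the annotation's own partner fields.
    """

    def cell_type(sid: int | None) -> CellType:
        if sid is None:
            return CellType.UNIDENTIFIED
        t = types.get(sid)
        if t is None:
            log.warning("skeleton %d has no type entry; treating as UNIDENTIFIED", sid)
            return CellType.UNIDENTIFIED
        return t

    anns = list(forest.annotations)
    pos = {id(a): _ann_position(forest, a) for a in anns}
    outs = [a for a in anns if a.direction is Direction.OUTPUT]
    ins = [a for a in anns if a.direction is Direction.INPUT]
    used: set[int] = set()
    pairs: list[tuple[AnnotationRecord, AnnotationRecord, str]] = []

    # (a) mutual id matches, grouped per ordered (pre, post) cell pair
    by_pair_out: dict[tuple[int, int], list[AnnotationRecord]] = defaultdict(list)
    by_pair_in: dict[tuple[int, int], list[AnnotationRecord]] = defaultdict(list)
    for a in outs:
        if a.partner_cell_id is not None:
            by_pair_out[(a.skeleton_id, a.partner_cell_id)].append(a)
    for a in ins:
        if a.partner_cell_id is not None:
            by_pair_in[(a.partner_cell_id, a.skeleton_id)].append(a)
    for key in sorted(set(by_pair_out) & set(by_pair_in)):
        os_, is_ = by_pair_out[key], by_pair_in[key]
        for kind in (SynKind.RIBBON, SynKind.CONVENTIONAL):
            ok = [a for a in os_ if a.syn_kind is kind and id(a) not in used]
            ik = [a for a in is_ if a.syn_kind is kind and id(a) not in used]
            cand = sorted(
                ((math.dist(pos[id(o)], pos[id(i)]), o, i) for o in ok for i in ik),
                key=lambda t: t[0],
            )
            for d, o, i in cand:
                if id(o) in used or id(i) in used:
                    continue
                used.add(id(o)); used.add(id(i))
                pairs.append((o, i, "paired:id"))
        rem_out = [a for a in os_ if id(a) not in used]
        rem_in = [a for a in is_ if id(a) not in used]
        if rem_out and rem_in:
            # both sides still claim this cell pair but kinds disagree
            raise PairingConflictError(
                f"cell pair {key}: unreconciled annotations of incompatible kinds "
                f"(out nodes {[a.node_id for a in rem_out]}, "
                f"in nodes {[a.node_id for a in rem_in]})"
            )

    # (b) proximity pairing among the rest
    free_out = [a for a in outs if id(a) not in used]
    free_in = [a for a in ins if id(a) not in used]
    cand = []
    for o in free_out:
        for i in free_in:
            if o.skeleton_id == i.skeleton_id or o.syn_kind is not i.syn_kind:
                continue
            d = math.dist(pos[id(o)], pos[id(i)])
            if d <= pairing.epsilon_nm:
                cand.append((d, o.skeleton_id, o.node_id, i.skeleton_id, i.node_id, o, i))
    cand.sort(key=lambda t: t[:5])
    for d, *_ids, o, i in cand:
        if id(o) in used or id(i) in used:
            continue
        used.add(id(o)); used.add(id(i))
        pairs.append((o, i, "paired:proximity"))

    # assemble records
    records: list[SynapseRecord] = []
    next_id = 0

    def depth_of(p: tuple[float, float, float]) -> float:
        return ipl_depth(p, frame) if frame is not None else math.nan

    def finish(
        pre_id, post_id, kind, p, pre_node, post_node, provenance
    ) -> SynapseRecord:
        nonlocal next_id
        pre_t, post_t = cell_type(pre_id), cell_type(post_id)
        dep = depth_of(p)
        post_sk = forest.skeletons.get(post_id) if post_id is not None else None
        comp = assign_compartment(dep, post_sk, post_node, forest.scale, pairing)
        flags: tuple[str, ...] = ()
        if kind is SynKind.RIBBON and pre_t not in BIPOLAR_TYPES:
            flags = ("ribbon-from-nonbipolar",)
            log.warning(
                "synapse %d: ribbon synapse with non-bipolar presynaptic type %s",
                next_id, pre_t.value,
            )
        rec = SynapseRecord(
            synapse_id=next_id,
            pre_id=pre_id, pre_type=pre_t,
            post_id=post_id, post_type=post_t,
            kind=kind, position=p, depth=dep, compartment=comp,
            provenance=provenance, pre_node=pre_node, post_node=post_node,
            flags=flags,
        )
        next_id += 1
        return rec

    for o, i, prov in sorted(
        pairs, key=lambda t: (t[0].skeleton_id, t[0].node_id, t[1].skeleton_id, t[1].node_id)
    ):
        po, pi = pos[id(o)], pos[id(i)]
        mid = tuple((a + b) / 2.0 for a, b in zip(po, pi))
        records.append(
            finish(o.skeleton_id, i.skeleton_id, o.syn_kind, mid, o.node_id, i.node_id, prov)
        )
    for a in sorted(outs, key=lambda a: (a.skeleton_id, a.node_id)):
        if id(a) in used:
            continue
        rec = finish(
            a.skeleton_id, a.partner_cell_id, a.syn_kind, pos[id(a)], a.node_id, None,
            "pre-only",
        )
        if a.partner_cell_id is None:
            rec = replace(rec, post_type=a.partner_type)
        records.append(rec)
    for a in sorted(ins, key=lambda a: (a.skeleton_id, a.node_id)):
        if id(a) in used:
            continue
        rec = finish(
            a.partner_cell_id, a.skeleton_id, a.syn_kind, pos[id(a)], None, a.node_id,
            "post-only",
        )
        if a.partner_cell_id is None:
            rec = replace(rec, pre_type=a.partner_type)
        records.append(rec)

    _assign_dyad_sites(records, pairing.dyad_radius_nm)
    return records


def _assign_dyad_sites(records: list[SynapseRecord], radius_nm: float) -> None:
    """Group ribbon records per presynaptic cell into release sites."""
    by_pre: dict[int, list[int]] = defaultdict(list)
    for idx, r in enumerate(records):
        if r.kind is SynKind.RIBBON and r.pre_id is not None:
            by_pre[r.pre_id].append(idx)
    site = 0
    for pre in sorted(by_pre):
        idxs = by_pre[pre]
        labels = single_linkage([records[i].position for i in idxs], radius_nm)
        remap: dict[int, int] = {}
        for i, lab in zip(idxs, labels):
            if lab not in remap:
                remap[lab] = site
                site += 1
            records[i] = replace(records[i], dyad_site=remap[lab])


# --------------------------------------------------------------------------
# tallies

@dataclass(frozen=True)
class TallyRow:
    key: tuple[str, str | None]  # (partner type label, compartment or None)
    count: int
    share: float | None  # fraction of this row's base (None when base is 0)

    @property
    def percent_int(self) -> int | None:
        return None if self.share is None else round_half_up(self.share * 100.0)

    @property
    def percent(self) -> str | None:
        return None if self.share is None else percent_display(self.share)


@dataclass
class TallyTable:
    focal: tuple[int, ...]
    direction: Direction
    rows: dict[tuple[str, str | None], TallyRow]
    total: int

    def count(self, ptype: str, compartment: str | None = None) -> int:
        row = self.rows.get((ptype, compartment))
        return 0 if row is None else row.count

    def percent_int(self, ptype: str, compartment: str | None = None) -> int | None:
        row = self.rows.get((ptype, compartment))
        return None if row is None else row.percent_int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "partner_type": k[0],
                    "compartment": k[1] or "",
                    "count": r.count,
                    "percent": r.percent or "",
                }
                for k, r in self.rows.items()
            ]
        )


def _tally(
    records: Sequence[SynapseRecord],
    focal: tuple[int, ...],
    direction: Direction,
    partner_of,
    split_compartment_for: frozenset[CellType],
) -> TallyTable:
    by_type: dict[CellType, list[SynapseRecord]] = defaultdict(list)
    for r in records:
        by_type[effective_type(partner_of(r))].append(r)
    total = len(records)
    rows: dict[tuple[str, str | None], TallyRow] = {}
    for t in sorted(by_type, key=lambda t: t.value):
        recs = by_type[t]
        share = len(recs) / total if total else None
        rows[(t.value, None)] = TallyRow((t.value, None), len(recs), share)
        if t in split_compartment_for:
            by_comp: dict[Compartment, int] = defaultdict(int)
            for r in recs:
                by_comp[r.compartment] += 1
            for comp in Compartment:
                if comp in by_comp:
                    sub_share = by_comp[comp] / len(recs) if recs else None
                    rows[(t.value, comp.value)] = TallyRow(
                        (t.value, comp.value), by_comp[comp], sub_share
                    )
    return TallyTable(focal=focal, direction=direction, rows=rows, total=total)


def tally_inputs(
    cell: int,
    table: Sequence[SynapseRecord],
    split_compartment_for: frozenset[CellType] = frozenset({CellType.AC}),
) -> TallyTable:
    """Inputs to one cell grouped by presynaptic type.

    AC inputs (by default) are additionally split by compartment; the
    compartment sub-rows' shares are of that type's own total, matching
    the printed-table convention.
    """
    recs = [r for r in table if r.post_id == cell]
    return _tally(
        recs, (cell,), Direction.INPUT, lambda r: r.pre_type, split_compartment_for
    )


def tally_outputs(
    cells: Iterable[int],
    table: Sequence[SynapseRecord],
    split_compartment_for: frozenset[CellType] = frozenset(),
) -> TallyTable:
    """Pooled outputs of a set of cells grouped by postsynaptic type."""
    cellset = frozenset(cells)
    recs = [r for r in table if r.pre_id in cellset]
    return _tally(
        recs,
        tuple(sorted(cellset)),
        Direction.OUTPUT,
        lambda r: r.post_type,
        split_compartment_for,
    )


@dataclass(frozen=True)
class SummaryRow:
    key: tuple[str, str | None]
    counts: tuple[int, ...]
    mean: float
    sd: float

    @property
    def mean_int(self) -> int:
        return round_half_up(self.mean)

    @property
    def sd_int(self) -> int:
        return round_half_up(self.sd)


def aggregate_summary(tables: Sequence[TallyTable]) -> dict[tuple[str, str | None], SummaryRow]:
    """Per-row mean ± sample SD across cells (display rounds half-up)."""
    if len(tables) < 2:
        raise ValueError("aggregate_summary needs at least 2 tables")
    keys = set(tables[0].rows)
    for t in tables[1:]:
        if set(t.rows) != keys:
            diff = set(t.rows) ^ keys
            raise ValueError(
                "tables have mismatched row keys: "
                f"{sorted(diff, key=lambda k: (k[0], k[1] or ''))}"
            )
    out: dict[tuple[str, str | None], SummaryRow] = {}
    for k in sorted(keys, key=lambda k: (k[0], k[1] or "")):
        counts = tuple(t.rows[k].count for t in tables)
        arr = np.asarray(counts, dtype=float)
        out[k] = SummaryRow(
            key=k,
            counts=counts,
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)),
        )
    return out


# --------------------------------------------------------------------------
# convergence

@dataclass
class ConvergenceTable:
    pair_counts: dict[tuple[int, int], int]
    n_pre: int
    n_post: int
    total_synapses: int
    mean_per_presynaptic: float  # total / |pre group|  (the printed convention)
    mean_per_connected_pair: float  # total / #pairs with >= 1 synapse

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"pre_id": a, "post_id": b, "n_synapses": c}
                for (a, b), c in sorted(self.pair_counts.items())
            ]
        )


def convergence(
    pre_group: Iterable[int],
    post_group: Iterable[int],
    table: Sequence[SynapseRecord],
) -> ConvergenceTable:
    """Per-pair synapse counts between two skeleton groups.

    Two summary means are reported: total synapses divided by the size
    of the presynaptic group (the printed "~2 inputs" convention), and
    divided by the number of connected pairs.
    """
    pre = frozenset(pre_group)
    post = frozenset(post_group)
    pair_counts: dict[tuple[int, int], int] = defaultdict(int)
    for r in table:
        if r.pre_id in pre and r.post_id in post:
            pair_counts[(r.pre_id, r.post_id)] += 1
    total = sum(pair_counts.values())
    n_connected = len(pair_counts)
    return ConvergenceTable(
        pair_counts=dict(pair_counts),
        n_pre=len(pre),
        n_post=len(post),
        total_synapses=total,
        mean_per_presynaptic=total / len(pre) if pre else math.nan,
        mean_per_connected_pair=total / n_connected if n_connected else math.nan,
    )


# --------------------------------------------------------------------------
# dyads

#: canonical dyad categories for a focal-AC dyad analysis
DYAD_AC_AII = "AC+AII"   # the AC replaced the A17
DYAD_AC_A17 = "AC+A17"   # the AC replaced the AII
DYAD_AC_UNID = "AC+UNIDENTIFIED"


@dataclass
class DyadComposition:
    dyads: dict[str, int]          # pair label -> count (exactly 2 partners)
    monads: int                    # ribbon sites with a single recorded partner
    triads: int                    # sites with > 2 partners (excluded from %)
    shares: dict[str, float]       # over AC-containing dyads

    @property
    def n_dyads(self) -> int:
        return sum(self.dyads.values())


def dyad_composition(
    rb_cells: Iterable[int],
    table: Sequence[SynapseRecord],
    dyad_radius_um: float = 0.3,
) -> DyadComposition:
    """Composition of ribbon dyads made by a set of bipolar cells.

    Ribbon records sharing a ``dyad_site`` id (or, failing that, lying
    within ``dyad_radius_um`` of each other on the same presynaptic
    cell) are grouped into release sites; two-partner sites are
    classified by the sorted pair of postsynaptic types.  Shares are
    computed over dyads that include an AC partner.
    """
    rb = frozenset(rb_cells)
    recs = [r for r in table if r.kind is SynKind.RIBBON and r.pre_id in rb]
    by_pre: dict[int, list[SynapseRecord]] = defaultdict(list)
    for r in recs:
        by_pre[r.pre_id].append(r)

    groups: list[list[SynapseRecord]] = []
    for pre in sorted(by_pre):
        cell_recs = by_pre[pre]
        if all(r.dyad_site is not None for r in cell_recs):
            sites: dict[int, list[SynapseRecord]] = defaultdict(list)
            for r in cell_recs:
                sites[r.dyad_site].append(r)
            groups.extend(sites[s] for s in sorted(sites))
        else:
            labels = single_linkage(
                [r.position for r in cell_recs], dyad_radius_um * 1000.0
            )
            sites = defaultdict(list)
            for r, lab in zip(cell_recs, labels):
                sites[lab].append(r)
            groups.extend(sites[s] for s in sorted(sites))

    dyads: dict[str, int] = defaultdict(int)
    monads = triads = 0
    for g in groups:
        if len(g) == 1:
            monads += 1
        elif len(g) > 2:
            triads += 1
            log.warning(
                "ribbon site with %d postsynaptic partners flagged as triad "
                "(pre cell %s); excluded from dyad percentages", len(g), g[0].pre_id,
            )
        else:
            labels = sorted(effective_type(r.post_type).value for r in g)
            if "AC" in labels:
                labels.remove("AC")
                label = "AC+" + labels[0]  # canonical AC-first form
            else:
                label = "+".join(labels)
            dyads[label] += 1

    ac_dyads = {k: v for k, v in dyads.items() if "AC" in k.split("+")}
    denom = sum(ac_dyads.values())
    shares = {k: v / denom for k, v in ac_dyads.items()} if denom else {}
    return DyadComposition(dyads=dict(dyads), monads=monads, triads=triads, shares=shares)


# --------------------------------------------------------------------------
# TSV round trip

_TSV_COLUMNS = [
    "synapse_id", "pre_id", "pre_type", "post_id", "post_type", "kind",
    "x_nm", "y_nm", "z_nm", "depth", "compartment", "provenance",
]


def records_to_frame(records: Sequence[SynapseRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "synapse_id": r.synapse_id,
                "pre_id": r.pre_id if r.pre_id is not None else "",
                "pre_type": r.pre_type.value,
                "post_id": r.post_id if r.post_id is not None else "",
                "post_type": r.post_type.value,
                "kind": r.kind.value,
                "x_nm": r.position[0],
                "y_nm": r.position[1],
                "z_nm": r.position[2],
                "depth": r.depth,
                "compartment": r.compartment.value,
                "provenance": r.provenance,
            }
        )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_synapse_tsv(records: Sequence[SynapseRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_synapse_tsv(path: str | Path) -> list[SynapseRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    out: list[SynapseRecord] = []
    for row in df.itertuples(index=False):
        out.append(
            SynapseRecord(
                synapse_id=int(row.synapse_id),
                pre_id=int(row.pre_id) if str(row.pre_id) != "" else None,
                pre_type=CellType(row.pre_type),
                post_id=int(row.post_id) if str(row.post_id) != "" else None,
                post_type=CellType(row.post_type),
                kind=SynKind(row.kind),
                position=(float(row.x_nm), float(row.y_nm), float(row.z_nm)),
                depth=float(row.depth) if str(row.depth) not in ("", "nan") else math.nan,
                compartment=Compartment(row.compartment),
                provenance=str(row.provenance),
            )
        )
    return out
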