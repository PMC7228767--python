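"""Read, validate and write NML skeleton/annotation files.

The NML dialect handled here is the Knossos/webKnossos XML skeleton
format: a ``<things>`` root whose ``<thing id name>`` children carry
``<nodes>`` (``<node id x y z radius .../>``), ``<edges>``
(``<edge source target/>``) and optionally a ``<comments>`` block
(``<comment node content/>``).  Comments may alternatively appear as a
``comment`` attribute directly on ``<node>``.  Unknown attributes are
preserved opaquely through a read/write round trip.

Synapse annotations live in node comments and follow the grammar

    syn:<kind>:<dir>:<ptype>[:<pid>]

with ``kind`` in {ribbon, conv}, ``dir`` in {in, out}, ``ptype`` a
cell-type label from the controlled vocabulary and ``pid`` an optional
partner skeleton id (a bare integer or ``cell<int>``).  Matching is
case-insensitive; comments that do not match are preserved as raw text
and logged, never dropped.
"""
from __future__ import annotations

import logging
import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx

from .vocab import CellType, Direction, SynKind, parse_cell_type

log = logging.getLogger(__name__)

__all__ = [
    "VoxelScale",
    "SkeletonNode",
    "Skeleton",
    "AnnotationRecord",
    "SkeletonForest",
    "NMLError",
    "NMLParseError",
    "NMLValidationError",
    "K0725_SCALE",
    "parse_annotation",
    "read_nml",
    "write_nml",
    "to_physical",
    "cable_length",
    "path_distance",
    "write_swc",
]


class NMLError(Exception):
    """Base class for NML I/O failures."""


class NMLParseError(NMLError):
    """Malformed XML; carries the offending line where available."""


class NMLValidationError(NMLError):
    """Structurally valid XML violating a skeleton invariant."""


@dataclass(frozen=True)
class VoxelScale:
    """Physical size of one voxel, nm per voxel along x, y, z.

    Anisotropy is permitted (``sz != sx``); all components must be
    strictly positive.
    """

    sx: float
    sy: float
    sz: float

    def __post_init__(self) -> None:
        if not (self.sx > 0 and self.sy > 0 and self.sz > 0):
            raise ValueError(f"voxel scale must be strictly positive, got {self}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sx, self.sy, self.sz)


#: scale of the SBEM volume the reference skeletons were traced in
K0725_SCALE = VoxelScale(13.2, 13.2, 26.0)


@dataclass(frozen=True)
class SkeletonNode:
    node_id: int
    position: tuple[float, float, float]  # voxel coordinates
    radius: float | None = None
    comment: str | None = None
    attrs: tuple[tuple[str, str], ...] = ()  # unknown XML attributes, preserved

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.position):
            raise ValueError(
                f"node {self.node_id}: voxel position must be non-negative, got {self.position}"
            )


@dataclass
class Skeleton:
    """A tree-structured (forest-structured) neurite skeleton.

    Edges are stored as normalized ``(min_id, max_id)`` tuples.  Cycles
    are rejected at validation; disconnected components are tolerated
    with a warning since manual tracings commonly contain gaps.
    """

    skeleton_id: int
    name: str = ""
    nodes: dict[int, SkeletonNode] = field(default_factory=dict)
    edges: set[tuple[int, int]] = field(default_factory=set)
    soma_node: int | None = None
    attrs: tuple[tuple[str, str], ...] = ()

    def add_node(self, node: SkeletonNode) -> None:
        if node.node_id in self.nodes:
            raise NMLValidationError(
                f"skeleton {self.skeleton_id}: duplicate node id {node.node_id}"
            )
        self.nodes[node.node_id] = node

    def add_edge(self, a: int, b: int) -> None:
        if a == b:
            raise NMLValidationError(
                f"skeleton {self.skeleton_id}: self-loop at node {a}"
            )
        self.edges.add((a, b) if a < b else (b, a))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def validate(self) -> list[str]:
        """Check invariants; raise on hard violations, return warnings."""
        missing = sorted(
            {n for e in self.edges for n in e if n not in self.nodes}
        )
        if missing:
            raise NMLValidationError(
                f"skeleton {self.skeleton_id}: edges reference missing node ids {missing}"
            )
        g = self.graph()
        if len(self.edges) > 0 and not nx.is_forest(g):
            raise NMLValidationError(
                f"skeleton {self.skeleton_id} contains a cycle (not a tree)"
            )
        warnings: list[str] = []
        if len(self.nodes) > 0:
            n_comp = nx.number_connected_components(g)
            if n_comp > 1:
                warnings.append(
                    f"skeleton {self.skeleton_id} has {n_comp} connected components"
                )
        if self.soma_node is not None and self.soma_node not in self.nodes:
            raise NMLValidationError(
                f"skeleton {self.skeleton_id}: soma node {self.soma_node} missing"
            )
        return warnings

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Skeleton):
            return NotImplemented
        return (
            self.skeleton_id == other.skeleton_id
            and self.name == other.name
            and self.nodes == other.nodes
            and self.edges == other.edges
            and self.soma_node == other.soma_node
            and dict(self.attrs) == dict(other.attrs)
        )


@dataclass(frozen=True)
class AnnotationRecord:
    """One parsed synapse annotation, traced to exactly one node."""

    node_id: int
    skeleton_id: int
    syn_kind: SynKind
    direction: Direction
    partner_type: CellType
    partner_cell_id: int | None
    raw_comment: str


@dataclass
class SkeletonForest:
    scale: VoxelScale
    skeletons: dict[int, Skeleton] = field(default_factory=dict)
    annotations: list[AnnotationRecord] = field(default_factory=list)
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] | None = None
    unparsed_comments: list[tuple[int, int, str]] = field(default_factory=list)
    attrs: tuple[tuple[str, str], ...] = ()

    def add_skeleton(self, skeleton: Skeleton) -> None:
        if skeleton.skeleton_id in self.skeletons:
            raise NMLValidationError(f"duplicate skeleton id {skeleton.skeleton_id}")
        self.skeletons[skeleton.skeleton_id] = skeleton

    def node(self, skeleton_id: int, node_id: int) -> SkeletonNode:
        return self.skeletons[skeleton_id].nodes[node_id]

    def validate(self) -> list[str]:
        warnings: list[str] = []
        for sk in self.skeletons.values():
            warnings.extend(sk.validate())
        for ann in self.annotations:
            if ann.skeleton_id not in self.skeletons:
                raise NMLValidationError(
                    f"annotation references missing skeleton {ann.skeleton_id}"
                )
            if ann.node_id not in self.skeletons[ann.skeleton_id].nodes:
                raise NMLValidationError(
                    f"annotation references missing node {ann.node_id} "
                    f"in skeleton {ann.skeleton_id}"
                )
        if self.bounds is not None:
            for sk in self.skeletons.values():
                for node in sk.nodes.values():
                    for c, (lo, hi) in zip(node.position, self.bounds):
                        if not (lo <= c <= hi):
                            raise NMLValidationError(
                                f"skeleton {sk.skeleton_id} node {node.node_id} "
                                f"position {node.position} outside bounds {self.bounds}"
                            )
        return warnings

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SkeletonForest):
            return NotImplemented
        return (
            self.scale == other.scale
            and self.skeletons == other.skeletons
            and sorted(self.annotations, key=lambda a: (a.skeleton_id, a.node_id))
            == sorted(other.annotations, key=lambda a: (a.skeleton_id, a.node_id))
            and self.bounds == other.bounds
        )


# --------------------------------------------------------------------------
# annotation grammar

_KIND_TOKENS = {"ribbon": SynKind.RIBBON, "conv": SynKind.CONVENTIONAL}
_DIR_TOKENS = {"in": Direction.INPUT, "out": Direction.OUTPUT}

_ANNOT_RE = re.compile(
    r"^\s*syn:(?P<kind>ribbon|conv):(?P<dir>in|out):(?P<ptype>[A-Za-z0-9_\-]+)"
    r"(?::(?:cell)?(?P<pid>\d+))?\s*$",
    re.IGNORECASE,
)


def parse_annotation(comment: str) -> dict | None:
    """Parse a node comment against the synapse grammar.

    Returns a dict with keys ``syn_kind``, ``direction``,
    ``partner_type``, ``partner_cell_id`` on a match, ``None``
    otherwise.  Never raises: a no-match is a value, not an error.
    """
    if not isinstance(comment, str):
        return None
    m = _ANNOT_RE.match(comment)
    if m is None:
        return None
    ptype = parse_cell_type(m.group("ptype"))
    if ptype is None:
        return None
    pid = m.group("pid")
    return {
        "syn_kind": _KIND_TOKENS[m.group("kind").lower()],
        "direction": _DIR_TOKENS[m.group("dir").lower()],
        "partner_type": ptype,
        "partner_cell_id": int(pid) if pid is not None else None,
    }


def format_annotation(
    syn_kind: SynKind,
    direction: Direction,
    partner_type: CellType,
    partner_cell_id: int | None = None,
) -> str:
    """Inverse of :func:`parse_annotation` for canonical comments."""
    kind = "ribbon" if syn_kind is SynKind.RIBBON else "conv"
    dirn = "in" if direction is Direction.INPUT else "out"
    s = f"syn:{kind}:{dirn}:{partner_type.value}"
    if partner_cell_id is not None:
        s += f":{partner_cell_id}"
    return s


# --------------------------------------------------------------------------
# NML reading

_NODE_CORE_ATTRS = {"id", "x", "y", "z", "radius", "comment"}
_THING_CORE_ATTRS = {"id", "name"}

_SOMA_RE = re.compile(r"^\s*soma\s*$", re.IGNORECASE)


def _parse_float(value: str, context: str) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise NMLParseError(f"{context}: not a number: {value!r}") from exc


def read_nml(path: str | Path, scale: VoxelScale) -> SkeletonForest:
    """Read an NML file into a validated :class:`SkeletonForest`.

    Every ``<thing>`` becomes one skeleton; node comments matching the
    annotation grammar become :class:`AnnotationRecord` entries;
    non-matching comments stay on their node and are itemized in
    ``forest.unparsed_comments``.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise NMLParseError(f"{path}: malformed XML at line {exc.position[0]}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "things":
        raise NMLParseError(f"{path}: expected <things> root, got <{root.tag}>")

    forest = SkeletonForest(scale=scale, attrs=tuple(sorted(root.attrib.items())))

    # root-level comments (webKnossos style): node ids assumed globally unique
    root_comments: dict[int, str] = {}
    for cblock in root.findall("comments"):
        for c in cblock.findall("comment"):
            root_comments[int(c.attrib["node"])] = c.attrib.get("content", "")

    for thing in root.findall("thing"):
        sid = int(thing.attrib["id"])
        sk = Skeleton(
            skeleton_id=sid,
            name=thing.attrib.get("name", ""),
            attrs=tuple(
                sorted((k, v) for k, v in thing.attrib.items() if k not in _THING_CORE_ATTRS)
            ),
        )
        comments: dict[int, str] = {}
        for cblock in thing.findall("comments"):
            for c in cblock.findall("comment"):
                comments[int(c.attrib["node"])] = c.attrib.get("content", "")

        for nodes_el in thing.findall("nodes"):
            for n in nodes_el.findall("node"):
                nid = int(n.attrib["id"])
                ctx = f"{path} skeleton {sid} node {nid}"
                comment = n.attrib.get("comment") or comments.get(nid) or root_comments.get(nid)
                node = SkeletonNode(
                    node_id=nid,
                    position=(
                        _parse_float(n.attrib["x"], ctx),
                        _parse_float(n.attrib["y"], ctx),
                        _parse_float(n.attrib["z"], ctx),
                    ),
                    radius=_parse_float(n.attrib["radius"], ctx) if "radius" in n.attrib else None,
                    comment=comment,
                    attrs=tuple(
                        sorted((k, v) for k, v in n.attrib.items() if k not in _NODE_CORE_ATTRS)
                    ),
                )
                sk.add_node(node)

        for edges_el in thing.findall("edges"):
            for e in edges_el.findall("edge"):
                sk.add_edge(int(e.attrib["source"]), int(e.attrib["target"]))

        forest.add_skeleton(sk)

    extract_annotations(forest)

    for w in forest.validate():
        log.warning("%s: %s", path, w)
    return forest


def extract_annotations(forest: SkeletonForest) -> None:
    """(Re)build annotation records from node comments in place.

    Comments matching the synapse grammar become records; a bare "soma"
    comment marks the skeleton's soma node; anything else is itemized in
    ``forest.unparsed_comments`` and logged, never dropped.
    """
    forest.annotations.clear()
    forest.unparsed_comments.clear()
    for sid in sorted(forest.skeletons):
        sk = forest.skeletons[sid]
        for nid in sorted(sk.nodes):
            node = sk.nodes[nid]
            if node.comment is None:
                continue
            parsed = parse_annotation(node.comment)
            if parsed is not None:
                forest.annotations.append(
                    AnnotationRecord(
                        node_id=nid,
                        skeleton_id=sid,
                        raw_comment=node.comment,
                        **parsed,
                    )
                )
            elif _SOMA_RE.match(node.comment):
                sk.soma_node = nid
            else:
                forest.unparsed_comments.append((sid, nid, node.comment))
                log.info(
                    "skeleton %d node %d: comment %r does not match annotation "
                    "grammar; kept as raw text", sid, nid, node.comment,
                )


# --------------------------------------------------------------------------
# NML writing

def _fmt(x: float) -> str:
    """Shortest exact decimal representation (deterministic output)."""
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def write_nml(forest: SkeletonForest, path: str | Path) -> None:
    """Write ``forest`` to NML; output is byte-stable for equal input.

    Refuses to write a forest violating its invariants.
    """
    forest.validate()
    path = Path(path)
    lines: list[str] = ['<?xml version="1.0" encoding="utf-8"?>']
    extra_root = "".join(f' {k}="{v}"' for k, v in sorted(forest.attrs))
    lines.append(f"<things{extra_root}>")
    for sid in sorted(forest.skeletons):
        sk = forest.skeletons[sid]
        extra = "".join(f' {k}="{v}"' for k, v in sorted(sk.attrs))
        lines.append(f'  <thing id="{sid}" name="{_xml_escape(sk.name)}"{extra}>')
        lines.append("    <nodes>")
        for nid in sorted(sk.nodes):
            node = sk.nodes[nid]
            x, y, z = node.position
            parts = [f'id="{nid}"', f'x="{_fmt(x)}"', f'y="{_fmt(y)}"', f'z="{_fmt(z)}"']
            if node.radius is not None:
                parts.append(f'radius="{_fmt(node.radius)}"')
            parts.extend(f'{k}="{_xml_escape(v)}"' for k, v in sorted(node.attrs))
            lines.append(f'      <node {" ".join(parts)}/>')
        lines.append("    </nodes>")
        lines.append("    <edges>")
        for a, b in sorted(sk.edges):
            lines.append(f'      <edge source="{a}" target="{b}"/>')
        lines.append("    </edges>")
        comments = [
            (nid, sk.nodes[nid].comment)
            for nid in sorted(sk.nodes)
            if sk.nodes[nid].comment is not None
        ]
        if sk.soma_node is not None and sk.nodes[sk.soma_node].comment is None:
            comments.append((sk.soma_node, "soma"))
            comments.sort()
        if comments:
            lines.append("    <comments>")
            for nid, content in comments:
                lines.append(f'      <comment node="{nid}" content="{_xml_escape(content)}"/>')
            lines.append("    </comments>")
        lines.append("  </thing>")
    lines.append("</things>")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _xml_escape(s: str) -> str:
    return (
        s.replace("&", "&amp;")
        .replace("<", "&lt;")
        .replace(">", "&gt;")
        .replace('"', "&quot;")
    )


# --------------------------------------------------------------------------
# morphometrics

def to_physical(
    position: Sequence[float], scale: VoxelScale
) -> tuple[float, float, float]:
    """Voxel position -> physical nm (componentwise product, no offset)."""
    return (position[0] * scale.sx, position[1] * scale.sy, position[2] * scale.sz)


def _edge_length_nm(sk: Skeleton, a: int, b: int, scale: VoxelScale) -> float:
    pa = to_physical(sk.nodes[a].position, scale)
    pb = to_physical(sk.nodes[b].position, scale)
    return math.dist(pa, pb)


def cable_length(skeleton: Skeleton, scale: VoxelScale) -> float:
    """Total cable length in µm: sum of physical edge lengths."""
    total_nm = sum(_edge_length_nm(skeleton, a, b, scale) for a, b in skeleton.edges)
    return total_nm / 1000.0


def path_distance(
    skeleton: Skeleton, a: int, b: int, scale: VoxelScale
) -> float:
    """Geodesic distance in µm along the unique tree path between nodes."""
    if a not in skeleton.nodes or b not in skeleton.nodes:
        missing = [n for n in (a, b) if n not in skeleton.nodes]
        raise KeyError(f"skeleton {skeleton.skeleton_id}: unknown node ids {missing}")
    if a == b:
        return 0.0
    g = skeleton.graph()
    try:
        path = nx.shortest_path(g, a, b)  # unique on a forest
    except nx.NetworkXNoPath as exc:
        raise NMLValidationError(
            f"skeleton {skeleton.skeleton_id}: nodes {a} and {b} lie in "
            f"different connected components"
        ) from exc
    total_nm = sum(
        _edge_length_nm(skeleton, u, v, scale) for u, v in zip(path[:-1], path[1:])
    )
    return total_nm / 1000.0


def write_swc(skeleton: Skeleton, scale: VoxelScale, path: str | Path) -> None:
    """Export one skeleton as standard 7-column SWC in physical µm.

    Type column is 0 (undefined) except the soma node (1) when declared.
    Parent structure comes from a BFS rooted at the soma node, else the
    smallest node id per component.
    """
    skeleton.validate()
    path = Path(path)
    g = skeleton.graph()
    parent: dict[int, int] = {}
    for comp in nx.connected_components(g):
        root = (
            skeleton.soma_node
            if skeleton.soma_node in comp
            else min(comp)
        )
        for u, v in nx.bfs_edges(g, root):
            parent[v] = u
    lines = ["# generated by aiiconn; coordinates in µm"]
    for nid in sorted(skeleton.nodes):
        node = skeleton.nodes[nid]
        x, y, z = (c / 1000.0 for c in to_physical(node.position, scale))
        r = (node.radius or 0.0) / 1000.0
        t = 1 if nid == skeleton.soma_node else 0
        lines.append(
            f"{nid} {t} {x:.6f} {y:.6f} {z:.6f} {r:.6f} {parent.get(nid, -1)}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
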