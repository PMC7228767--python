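"""Seeded synthetic skeleton volumes with known ground truth.

The generator emits a stylized but structurally faithful volume: two
tilted near-parallel SAC planes, AII skeletons (soma above the OFF
plane, trunk, distal tuft below the ON plane), rod-bipolar skeletons
with ribbon outputs onto the AII tufts, and a population of presynaptic
axons whose output targets follow a configurable mixture.  Every
synapse annotation is two-sided with matching partner ids (optionally
stripped to exercise proximity pairing), and a ground-truth record of
types, pairings, planes and mixtures accompanies the forest.

Geometry is built in an axis-aligned frame (depth along +z), rotated
rigidly by the requested tilt, translated to non-negative coordinates,
and converted to voxels; all randomness flows from one seeded
``numpy`` generator, so identical seeds give byte-identical NML.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .skeleton_io import (
    K0725_SCALE,
    Skeleton,
    SkeletonForest,
    SkeletonNode,
    VoxelScale,
    extract_annotations,
    format_annotation,
)
from .vocab import CellType, Compartment, Direction, SynKind
from .connectome import SynapseRecord

__all__ = [
    "SynthParams",
    "GroundTruth",
    "PerturbConfig",
    "largest_remainder",
    "generate",
    "perturb",
    "aii_inputs_fixture",
    "axon_outputs_fixture",
    "focal_cell_fixture",
    "soma_basket_fixture",
    "dyad_fixture",
]


def largest_remainder(probs: Sequence[float], n: int) -> list[int]:
    """Integer allocation of n items to categories by largest remainder.

    Ties between equal remainders are broken by listed category order.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    quotas = [p * n for p in probs]
    counts = [int(math.floor(q)) for q in quotas]
    short = n - sum(counts)
    order = sorted(range(len(probs)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


@dataclass(frozen=True)
class SynthParams:
    n_aii: int = 3
    n_rb: int = 10
    n_axons: int = 61
    n_on_cb: int = 4
    n_other_aii: int = 6       # extra AII targets beyond the reconstructed ones
    n_unidentified: int = 3
    n_a17: int = 2
    n_focal_ac: int = 1        # postsynaptic AC(s) at ribbon dyads
    n_dyad_rb: int = 10        # dedicated RBs carrying the dyad sites
    output_mixture: tuple[tuple[str, float], ...] = (
        ("AII", 0.85), ("RB", 0.12), ("ON_CB", 0.02), ("UNIDENTIFIED", 0.01)
    )
    n_output_synapses: int = 1425
    ribbons_per_aii_mean: float = 173.0
    ac_offset_scale_um: float = 3.0  # exponential distance of AC synapse from nearest ribbon
    dyad_mixture: tuple[tuple[str, float], ...] = (
        ("AII", 0.75), ("A17", 0.18), ("UNIDENTIFIED", 0.07)
    )
    n_dyads: int = 100
    sac_tilt_deg: float = 5.0
    depth_noise_sigma_nm: float = 50.0
    allocation: str = "quota"  # "quota" | "multinomial"
    annotate_partner_ids: bool = True
    tuft_halfspan_um: float = 8.0
    seed: int = 0
    scale: VoxelScale = K0725_SCALE

    def validate(self) -> None:
        problems = []
        for name in ("n_aii", "n_rb", "n_axons", "n_on_cb", "n_other_aii",
                     "n_unidentified", "n_a17", "n_focal_ac", "n_dyad_rb",
                     "n_output_synapses", "n_dyads"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be non-negative")
        for name in ("output_mixture", "dyad_mixture"):
            probs = [p for _, p in getattr(self, name)]
            if any(p < 0 for p in probs):
                problems.append(f"{name} has negative probabilities")
            if abs(sum(probs) - 1.0) > 1e-9:
                problems.append(f"{name} probabilities sum to {sum(probs)}, not 1")
        if self.allocation not in ("quota", "multinomial"):
            problems.append(f"unknown allocation mode {self.allocation!r}")
        if self.ribbons_per_aii_mean < 0:
            problems.append("ribbons_per_aii_mean must be non-negative")
        if self.ac_offset_scale_um <= 0:
            problems.append("ac_offset_scale_um must be positive")
        if problems:
            raise ValueError("invalid SynthParams: " + "; ".join(problems))


@dataclass
class GroundTruth:
    types: dict[int, str] = field(default_factory=dict)
    pairs: list[tuple[int, int, int, int]] = field(default_factory=list)  # pre_sid, pre_node, post_sid, post_node
    plane_off: tuple[tuple[float, float, float], float] | None = None  # (normal, offset nm)
    plane_on: tuple[tuple[float, float, float], float] | None = None
    orientation_ref: tuple[float, float, float] | None = None
    tilt_deg: float = 0.0
    output_mixture_counts: dict[str, int] = field(default_factory=dict)
    dyad_counts: dict[str, int] = field(default_factory=dict)
    ribbons_per_aii: dict[int, int] = field(default_factory=dict)
    ac_offsets_um: list[float] = field(default_factory=list)
    aii_ids: list[int] = field(default_factory=list)
    axon_ids: list[int] = field(default_factory=list)
    rb_ids: list[int] = field(default_factory=list)
    dyad_rb_ids: list[int] = field(default_factory=list)
    sac_ids: dict[str, int] = field(default_factory=dict)
    dropped_annotations: list[tuple[int, int]] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "types": {str(k): v for k, v in sorted(self.types.items())},
            "pairs": self.pairs,
            "plane_off": self.plane_off,
            "plane_on": self.plane_on,
            "orientation_ref": self.orientation_ref,
            "tilt_deg": self.tilt_deg,
            "output_mixture_counts": self.output_mixture_counts,
            "dyad_counts": self.dyad_counts,
            "ribbons_per_aii": {str(k): v for k, v in sorted(self.ribbons_per_aii.items())},
            "aii_ids": self.aii_ids,
            "axon_ids": self.axon_ids,
            "rb_ids": self.rb_ids,
            "dyad_rb_ids": self.dyad_rb_ids,
            "sac_ids": self.sac_ids,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


# physical layout constants (nm), axis-aligned frame
_Z_OFF = 12000.0
_Z_ON = 20000.0
_SEP = _Z_ON - _Z_OFF
_LATERAL = 50000.0


def _depth_to_z(depth: float) -> float:
    return _Z_OFF + depth * _SEP


class _Builder:
    """Accumulates skeletons in physical nm; voxelizes at the end."""

    def __init__(self, params: SynthParams) -> None:
        self.params = params
        self.skeletons: list[tuple[int, str, dict, list]] = []  # sid, name, nodes, edges
        self._next_sid = 1
        self._next_nid = 1

    def new_skeleton(self, name: str) -> tuple[int, dict, list]:
        sid = self._next_sid
        self._next_sid += 1
        nodes: dict[int, tuple[np.ndarray, str | None]] = {}
        edges: list[tuple[int, int]] = []
        self.skeletons.append((sid, name, nodes, edges))
        return sid, nodes, edges

    def add_node(self, nodes: dict, pos, comment: str | None = None) -> int:
        nid = self._next_nid
        self._next_nid += 1
        nodes[nid] = (np.asarray(pos, dtype=float), comment)
        return nid

    def chain(self, nodes: dict, edges: list, points) -> list[int]:
        ids = [self.add_node(nodes, p) for p in points]
        edges.extend((a, b) for a, b in zip(ids[:-1], ids[1:]))
        return ids

    def finalize(self, tilt_deg: float, truth: GroundTruth) -> SkeletonForest:
        """Rotate about the volume centroid, shift non-negative, voxelize."""
        theta = math.radians(tilt_deg)
        rot = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, math.cos(theta), -math.sin(theta)],
                [0.0, math.sin(theta), math.cos(theta)],
            ]
        )
        all_pos = [p for _, _, nodes, _ in self.skeletons for p, _ in nodes.values()]
        center = np.mean(all_pos, axis=0) if all_pos else np.zeros(3)

        def xform(p: np.ndarray) -> np.ndarray:
            return rot @ (p - center) + center

        rotated = {
            sid: {nid: (xform(p), c) for nid, (p, c) in nodes.items()}
            for sid, _, nodes, _ in self.skeletons
        }
        mins = np.zeros(3)
        if all_pos:
            mins = np.min(
                [p for nd in rotated.values() for p, _ in nd.values()], axis=0
            )
        shift = np.where(mins < 0, -mins, 0.0)

        scale = np.asarray(self.params.scale.as_tuple())
        forest = SkeletonForest(scale=self.params.scale)
        for sid, name, _, edges in self.skeletons:
            sk = Skeleton(skeleton_id=sid, name=name)
            for nid, (p, comment) in rotated[sid].items():
                vox = (p + shift) / scale
                sk.add_node(
                    SkeletonNode(
                        node_id=nid,
                        position=(
                            round(float(vox[0]), 4),
                            round(float(vox[1]), 4),
                            round(float(vox[2]), 4),
                        ),
                        comment=comment,
                    )
                )
                if comment is not None and comment.strip().lower() == "soma":
                    sk.soma_node = nid
            for a, b in edges:
                sk.add_edge(a, b)
            forest.add_skeleton(sk)

        normal = tuple(float(x) for x in rot @ np.array([0.0, 0.0, 1.0]))
        p_off = xform(np.array([0.0, 0.0, _Z_OFF])) + shift
        p_on = xform(np.array([0.0, 0.0, _Z_ON])) + shift
        ref = xform(np.array([_LATERAL / 2, _LATERAL / 2, _depth_to_z(2.0)])) + shift
        truth.plane_off = (normal, float(np.dot(normal, p_off)))
        truth.plane_on = (normal, float(np.dot(normal, p_on)))
        truth.orientation_ref = tuple(float(x) for x in ref)
        truth.tilt_deg = tilt_deg
        extract_annotations(forest)
        return forest


def _allocate(rng: np.random.Generator, mixture, n: int, mode: str) -> dict[str, int]:
    labels = [k for k, _ in mixture]
    probs = [p for _, p in mixture]
    if mode == "quota":
        counts = largest_remainder(probs, n)
    else:
        counts = list(rng.multinomial(n, probs))
    return dict(zip(labels, (int(c) for c in counts)))


def generate(params: SynthParams) -> tuple[SkeletonForest, GroundTruth]:
    """Generate a seeded synthetic volume and its ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    b = _Builder(params)
    truth = GroundTruth()
    pid = params.annotate_partner_ids

    def ann(kind: SynKind, direction: Direction, ptype: CellType, partner: int | None) -> str:
        return format_annotation(kind, direction, ptype, partner if pid else None)

    # --- SAC planes ------------------------------------------------------
    grid = np.linspace(4000.0, _LATERAL - 4000.0, 8)
    for label, z0 in (("SAC_OFF", _Z_OFF), ("SAC_ON", _Z_ON)):
        sid, nodes, edges = b.new_skeleton(label)
        pts = []
        for i, gx in enumerate(grid):
            ys = grid if i % 2 == 0 else grid[::-1]  # serpentine chain
            for gy in ys:
                z = z0 + rng.normal(0.0, params.depth_noise_sigma_nm)
                pts.append((gx, gy, z))
        b.chain(nodes, edges, pts)
        truth.types[sid] = label
        truth.sac_ids[label] = sid

    # --- AII skeletons ---------------------------------------------------
    tuft_half = params.tuft_halfspan_um * 1000.0
    aii_tuft: dict[int, tuple[list[int], dict, list]] = {}
    aii_ribbon_sites: dict[int, list[tuple[np.ndarray, int]]] = {}
    for i in range(params.n_aii):
        sid, nodes, edges = b.new_skeleton(f"AII_{i + 1}")
        truth.types[sid] = CellType.AII.value
        truth.aii_ids.append(sid)
        cx = _LATERAL * (i + 1) / (params.n_aii + 1)
        cy = _LATERAL / 2.0
        soma = b.add_node(nodes, (cx, cy, _depth_to_z(-0.25)), comment="soma")
        trunk_z = np.arange(_depth_to_z(-0.25) + 1000.0, _depth_to_z(1.2), 1000.0)
        trunk = b.chain(nodes, edges, [(cx, cy, z) for z in trunk_z])
        edges.append((soma, trunk[0]))
        tuft_x = np.arange(cx - tuft_half, cx + tuft_half + 1.0, 500.0)
        tuft = b.chain(nodes, edges, [(x, cy, _depth_to_z(1.2)) for x in tuft_x])
        edges.append((trunk[-1], tuft[len(tuft) // 2]))
        aii_tuft[sid] = (tuft, nodes, edges)
        aii_ribbon_sites[sid] = []

    # extra (non-reconstructed) AII targets
    other_aii: list[tuple[int, dict, list, int]] = []
    for i in range(params.n_other_aii):
        sid, nodes, edges = b.new_skeleton(f"AII_other_{i + 1}")
        truth.types[sid] = CellType.AII.value
        cx = _LATERAL * (i + 1) / (params.n_other_aii + 1)
        ids = b.chain(
            nodes, edges,
            [(cx, _LATERAL * 0.25, _depth_to_z(1.15) + k * 400.0) for k in range(4)],
        )
        other_aii.append((sid, nodes, edges, ids[0]))

    # --- RB skeletons ----------------------------------------------------
    rbs: list[tuple[int, dict, list, int]] = []  # sid, nodes, edges, terminal node
    for j in range(params.n_rb):
        sid, nodes, edges = b.new_skeleton(f"RB_{j + 1}")
        truth.types[sid] = CellType.RB.value
        truth.rb_ids.append(sid)
        rx = _LATERAL * (j + 0.5) / params.n_rb
        ry = _LATERAL * 0.35
        ids = b.chain(
            nodes, edges,
            [(rx, ry, _depth_to_z(-0.5)), (rx, ry, _depth_to_z(0.5)), (rx, ry, _depth_to_z(1.1))],
        )
        rbs.append((sid, nodes, edges, ids[-1]))

    # --- ribbon inputs RB -> AII tufts -----------------------------------
    rb_cursor = 0
    for sid in truth.aii_ids:
        tuft, nodes, edges = aii_tuft[sid]
        if params.allocation == "quota":
            n_ribbons = int(round(params.ribbons_per_aii_mean))
        else:
            n_ribbons = int(rng.poisson(params.ribbons_per_aii_mean))
        truth.ribbons_per_aii[sid] = n_ribbons
        # uniform positions along the tuft chain
        ts = np.sort(rng.uniform(0.0, 1.0, size=n_ribbons))
        tuft_pos = np.asarray([nodes[n][0] for n in tuft])
        seg_len = np.linalg.norm(np.diff(tuft_pos, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        for t in ts:
            s = t * cum[-1]
            k = min(int(np.searchsorted(cum, s, side="right")) - 1, len(seg_len) - 1)
            frac = (s - cum[k]) / seg_len[k] if seg_len[k] > 0 else 0.0
            p = tuft_pos[k] + frac * (tuft_pos[k + 1] - tuft_pos[k])
            rb_sid, rb_nodes, rb_edges, rb_term = rbs[rb_cursor % len(rbs)]
            rb_cursor += 1
            out_node = b.add_node(
                rb_nodes, p + np.array([0.0, 0.0, -100.0]),
                comment=ann(SynKind.RIBBON, Direction.OUTPUT, CellType.AII, sid),
            )
            rb_edges.append((rb_term, out_node))
            in_node = b.add_node(
                nodes, p,
                comment=ann(SynKind.RIBBON, Direction.INPUT, CellType.RB, rb_sid),
            )
            edges.append((tuft[k], in_node))
            truth.pairs.append((rb_sid, out_node, sid, in_node))
            aii_ribbon_sites[sid].append((p, in_node))

    # --- presynaptic axons and their output mixture ----------------------
    axons: list[tuple[int, dict, list, list[int]]] = []
    for k in range(params.n_axons):
        sid, nodes, edges = b.new_skeleton(f"axon_{k + 1}")
        truth.types[sid] = CellType.AC.value
        truth.axon_ids.append(sid)
        ay = _LATERAL * (k + 0.5) / max(params.n_axons, 1)
        ids = b.chain(
            nodes, edges,
            [(x, ay, _depth_to_z(1.15)) for x in np.linspace(2000.0, _LATERAL - 2000.0, 6)],
        )
        axons.append((sid, nodes, edges, ids))

    on_cbs: list[tuple[int, dict, list, int]] = []
    for i in range(params.n_on_cb):
        sid, nodes, edges = b.new_skeleton(f"ON_CB_{i + 1}")
        truth.types[sid] = CellType.ON_CB.value
        cx = _LATERAL * (i + 0.5) / max(params.n_on_cb, 1)
        ids = b.chain(
            nodes, edges,
            [(cx, _LATERAL * 0.6, _depth_to_z(0.2)), (cx, _LATERAL * 0.6, _depth_to_z(1.05))],
        )
        on_cbs.append((sid, nodes, edges, ids[-1]))

    unids: list[tuple[int, dict, list, int]] = []
    for i in range(params.n_unidentified):
        sid, nodes, edges = b.new_skeleton(f"unidentified_{i + 1}")
        truth.types[sid] = CellType.UNIDENTIFIED.value
        cx = _LATERAL * (i + 0.5) / max(params.n_unidentified, 1)
        ids = b.chain(
            nodes, edges,
            [(cx, _LATERAL * 0.7, _depth_to_z(1.1)), (cx, _LATERAL * 0.7, _depth_to_z(1.3))],
        )
        unids.append((sid, nodes, edges, ids[-1]))

    mixture_counts = _allocate(rng, params.output_mixture, params.n_output_synapses, params.allocation)
    truth.output_mixture_counts = mixture_counts
    target_events: list[str] = []
    for label, _ in params.output_mixture:
        target_events.extend([label] * mixture_counts.get(label, 0))
    rng.shuffle(target_events)

    def attach_output(axon_idx: int, target_label: str, event_idx: int) -> None:
        ax_sid, ax_nodes, ax_edges, ax_chain = axons[axon_idx]
        if target_label == "AII" and truth.aii_ids:
            # AC synapses sit at an exponential offset from a ribbon site
            tgt = truth.aii_ids[event_idx % len(truth.aii_ids)]
            sites = aii_ribbon_sites[tgt]
            base_p, _ = sites[int(rng.integers(len(sites)))] if sites else (
                np.array([_LATERAL / 2, _LATERAL / 2, _depth_to_z(1.2)]), None)
            r_um = float(rng.exponential(params.ac_offset_scale_um))
            truth.ac_offsets_um.append(r_um)
            # offset perpendicular to the tuft axis: the source ribbon is
            # then the nearest one at exactly r_um, so the placement
            # model's distance distribution is recoverable from NN stats
            phi = float(rng.uniform(0.0, 2.0 * math.pi))
            v = np.array([0.0, math.cos(phi), math.sin(phi)])
            p = base_p + v * r_um * 1000.0
            tuft, t_nodes, t_edges = aii_tuft[tgt]
            anchor = tuft[len(tuft) // 2]
            ttype = CellType.AII
        elif target_label == "AII":
            return
        else:
            pool = {"RB": rbs, "ON_CB": on_cbs, "UNIDENTIFIED": unids}[target_label]
            tgt, t_nodes, t_edges, anchor = pool[event_idx % len(pool)]
            p = b.skeletons[tgt - 1][2][anchor][0] + np.array(
                [float(rng.uniform(200.0, 2000.0)), 0.0, 0.0]
            )
            ttype = CellType(target_label)
        out_node = b.add_node(
            ax_nodes, p + np.array([0.0, 100.0, 0.0]),
            comment=ann(SynKind.CONVENTIONAL, Direction.OUTPUT, ttype, tgt),
        )
        ax_edges.append((ax_chain[event_idx % len(ax_chain)], out_node))
        in_node = b.add_node(
            t_nodes, p,
            comment=ann(SynKind.CONVENTIONAL, Direction.INPUT, CellType.AC, ax_sid),
        )
        t_edges.append((anchor, in_node))
        truth.pairs.append((ax_sid, out_node, tgt, in_node))

    if params.n_axons > 0:
        for idx, label in enumerate(target_events):
            if label == "AII" and not truth.aii_ids:
                continue
            if label == "RB" and not rbs:
                continue
            if label == "ON_CB" and not on_cbs:
                continue
            if label == "UNIDENTIFIED" and not unids:
                continue
            attach_output(int(rng.integers(params.n_axons)), label, idx)

    # --- ribbon dyads onto focal AC(s) -----------------------------------
    focal_acs: list[tuple[int, dict, list, int]] = []
    for i in range(params.n_focal_ac):
        sid, nodes, edges = b.new_skeleton(f"AC_focal_{i + 1}")
        truth.types[sid] = CellType.AC.value
        ids = b.chain(
            nodes, edges,
            [(x, _LATERAL * 0.45, _depth_to_z(1.1)) for x in np.linspace(3000.0, _LATERAL - 3000.0, 5)],
        )
        focal_acs.append((sid, nodes, edges, ids[0]))
    a17s: list[tuple[int, dict, list, int]] = []
    for i in range(params.n_a17):
        sid, nodes, edges = b.new_skeleton(f"A17_{i + 1}")
        truth.types[sid] = CellType.A17.value
        ids = b.chain(
            nodes, edges,
            [(_LATERAL * 0.3, _LATERAL * (0.3 + 0.1 * i), _depth_to_z(1.05) + 300.0 * k)
             for k in range(3)],
        )
        a17s.append((sid, nodes, edges, ids[0]))

    if params.n_dyads > 0 and focal_acs:
        # dedicated RBs carry the dyads so ribbon-mass RBs cannot blur sites
        dyad_rbs: list[tuple[int, dict, list, int]] = []
        for j in range(params.n_dyad_rb):
            sid, nodes, edges = b.new_skeleton(f"RB_dyad_{j + 1}")
            truth.types[sid] = CellType.RB.value
            truth.dyad_rb_ids.append(sid)
            rx = _LATERAL * (j + 0.5) / params.n_dyad_rb
            ry = _LATERAL * 0.55
            ids = b.chain(
                nodes, edges,
                [(rx, ry, _depth_to_z(-0.5)), (rx, ry, _depth_to_z(1.1))],
            )
            dyad_rbs.append((sid, nodes, edges, ids[-1]))
        dyad_counts = _allocate(rng, params.dyad_mixture, params.n_dyads, params.allocation)
        truth.dyad_counts = {f"AC+{k}": v for k, v in dyad_counts.items()}
        partner_events: list[str] = []
        for label, _ in params.dyad_mixture:
            partner_events.extend([label] * dyad_counts.get(label, 0))
        rng.shuffle(partner_events)
        per_rb_count: dict[int, int] = {}
        for m, partner_label in enumerate(partner_events):
            rb_sid, rb_nodes, rb_edges, rb_term = dyad_rbs[m % len(dyad_rbs)]
            k = per_rb_count.get(rb_sid, 0)
            per_rb_count[rb_sid] = k + 1
            # sites of one RB spaced 1 µm apart (>> dyad radius)
            base = b.skeletons[rb_sid - 1][2][rb_term][0]
            site = base + np.array([1000.0 * (k + 1), 500.0, 0.0])
            ac_sid, ac_nodes, ac_edges, ac_anchor = focal_acs[m % len(focal_acs)]
            if partner_label == "AII" and truth.aii_ids:
                p_sid = truth.aii_ids[m % len(truth.aii_ids)]
                tuft, p_nodes, p_edges = aii_tuft[p_sid]
                p_anchor = tuft[0]
                p_type = CellType.AII
            elif partner_label == "A17" and a17s:
                p_sid, p_nodes, p_edges, p_anchor = a17s[m % len(a17s)]
                p_type = CellType.A17
            else:
                p_sid, p_nodes, p_edges, p_anchor = unids[m % len(unids)]
                p_type = CellType.UNIDENTIFIED
            out1 = b.add_node(
                rb_nodes, site,
                comment=ann(SynKind.RIBBON, Direction.OUTPUT, CellType.AC, ac_sid),
            )
            out2 = b.add_node(
                rb_nodes, site + np.array([60.0, 0.0, 0.0]),
                comment=ann(SynKind.RIBBON, Direction.OUTPUT, p_type, p_sid),
            )
            rb_edges.extend([(rb_term, out1), (out1, out2)])
            in1 = b.add_node(
                ac_nodes, site + np.array([0.0, 120.0, 0.0]),
                comment=ann(SynKind.RIBBON, Direction.INPUT, CellType.RB, rb_sid),
            )
            ac_edges.append((ac_anchor, in1))
            in2 = b.add_node(
                p_nodes, site + np.array([60.0, 120.0, 0.0]),
                comment=ann(SynKind.RIBBON, Direction.INPUT, CellType.RB, rb_sid),
            )
            p_edges.append((p_anchor, in2))
            truth.pairs.append((rb_sid, out1, ac_sid, in1))
            truth.pairs.append((rb_sid, out2, p_sid, in2))

    forest = b.finalize(params.sac_tilt_deg, truth)
    return forest, truth


@dataclass(frozen=True)
class PerturbConfig:
    jitter_sigma_nm: float = 0.0
    annotation_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma_nm < 0:
            raise ValueError("jitter_sigma_nm must be non-negative")
        if not (0.0 <= self.annotation_dropout <= 1.0):
            raise ValueError("annotation_dropout must be in [0, 1]")


def perturb(
    forest: SkeletonForest, truth: GroundTruth, noise: PerturbConfig
) -> tuple[SkeletonForest, GroundTruth]:
    """Apply reproducible position jitter and annotation dropout.

    Dropped annotation records are recorded in the returned truth's
    ``dropped_annotations`` so recovery curves can score against them.
    """
    rng = np.random.default_rng(noise.seed)
    scale = np.asarray(forest.scale.as_tuple())
    new_forest = SkeletonForest(scale=forest.scale, attrs=forest.attrs)
    dropped: set[tuple[int, int]] = set()
    for ann in forest.annotations:
        if noise.annotation_dropout > 0 and rng.random() < noise.annotation_dropout:
            dropped.add((ann.skeleton_id, ann.node_id))

    for sid in sorted(forest.skeletons):
        sk = forest.skeletons[sid]
        new_sk = Skeleton(skeleton_id=sid, name=sk.name, attrs=sk.attrs, soma_node=sk.soma_node)
        for nid in sorted(sk.nodes):
            node = sk.nodes[nid]
            pos = np.asarray(node.position)
            if noise.jitter_sigma_nm > 0:
                pos = pos + rng.normal(0.0, noise.jitter_sigma_nm, size=3) / scale
                pos = np.maximum(pos, 0.0)
            comment = node.comment
            if (sid, nid) in dropped:
                comment = None
            new_sk.add_node(
                SkeletonNode(
                    node_id=nid,
                    position=tuple(pos),
                    radius=node.radius,
                    comment=comment,
                    attrs=node.attrs,
                )
            )
        new_sk.edges = set(sk.edges)
        new_forest.add_skeleton(new_sk)
    new_forest.annotations = [
        a for a in forest.annotations if (a.skeleton_id, a.node_id) not in dropped
    ]
    new_truth = replace_truth_dropped(truth, sorted(dropped))
    return new_forest, new_truth


def replace_truth_dropped(truth: GroundTruth, dropped: list[tuple[int, int]]) -> GroundTruth:
    out = GroundTruth(**{k: getattr(truth, k) for k in truth.__dataclass_fields__})
    out.dropped_annotations = list(dropped)
    return out


# --------------------------------------------------------------------------
# printed-table fixtures
#
# These encode the per-cell synapse counts of the reference tables as
# in-memory synapse records so the tally/summary/convergence operations
# can be exercised (and their printed integers reproduced) without any
# download.  Ids: reconstructed AIIs 101-103, RB pool 201+, axons 401+,
# focal cells 71-72, soma-basket neurites 801+.

AII_FIXTURE_IDS = (101, 102, 103)
CELL1_ID, CELL2_ID = 71, 72


def _mk(i: int, pre: int, pre_t: CellType, post: int | None, post_t: CellType,
        kind: SynKind, comp: Compartment = Compartment.UNASSIGNED,
        pos=(0.0, 0.0, 0.0), dyad_site: int | None = None) -> SynapseRecord:
    return SynapseRecord(
        synapse_id=i, pre_id=pre, pre_type=pre_t, post_id=post, post_type=post_t,
        kind=kind, position=tuple(pos), compartment=comp, provenance="fixture",
        dyad_site=dyad_site,
    )


def aii_inputs_fixture() -> list[SynapseRecord]:
    """Per-cell inputs to the three reconstructed AIIs.

    RB ribbon inputs 173/171/176; AC conventional inputs split into
    ON-layer (distal) 161/157/161 and soma 17/20/15.
    """
    rb_counts = dict(zip(AII_FIXTURE_IDS, (173, 171, 176)))
    ac_on = dict(zip(AII_FIXTURE_IDS, (161, 157, 161)))
    ac_soma = dict(zip(AII_FIXTURE_IDS, (17, 20, 15)))
    records: list[SynapseRecord] = []
    i = 0
    pre = 20000
    for aii in AII_FIXTURE_IDS:
        for _ in range(rb_counts[aii]):
            records.append(_mk(i, 201 + (i % 30), CellType.RB, aii, CellType.AII,
                               SynKind.RIBBON, Compartment.DISTAL_DENDRITE))
            i += 1
        for _ in range(ac_on[aii]):
            pre += 1
            records.append(_mk(i, pre, CellType.AC, aii, CellType.AII,
                               SynKind.CONVENTIONAL, Compartment.DISTAL_DENDRITE))
            i += 1
        for _ in range(ac_soma[aii]):
            pre += 1
            records.append(_mk(i, pre, CellType.AC, aii, CellType.AII,
                               SynKind.CONVENTIONAL, Compartment.SOMA))
            i += 1
    return records


AXON_FIXTURE_IDS = tuple(range(401, 462))


def axon_outputs_fixture() -> list[SynapseRecord]:
    """Pooled outputs of the 61 presynaptic axons.

    1425 output synapses: 1212 to AIIs (130 of them onto the three
    reconstructed AIIs), 173 to RBs, 35 to ON CBs, 5 unidentified.
    """
    records: list[SynapseRecord] = []
    i = 0

    def add(post: int, post_t: CellType, n: int) -> None:
        nonlocal i
        for _ in range(n):
            axon = AXON_FIXTURE_IDS[i % len(AXON_FIXTURE_IDS)]
            records.append(_mk(i, axon, CellType.AC, post, post_t, SynKind.CONVENTIONAL,
                               Compartment.DISTAL_DENDRITE))
            i += 1

    # 130 synapses onto the three reconstructed AIIs (convergence arithmetic)
    for k in range(130):
        axon = AXON_FIXTURE_IDS[k % len(AXON_FIXTURE_IDS)]
        records.append(_mk(i, axon, CellType.AC, AII_FIXTURE_IDS[k % 3], CellType.AII,
                           SynKind.CONVENTIONAL, Compartment.DISTAL_DENDRITE))
        i += 1
    add(510, CellType.AII, 1212 - 130)   # other AIIs in the volume
    add(220, CellType.RB, 173)
    add(230, CellType.ON_CB, 35)
    add(240, CellType.UNIDENTIFIED, 5)
    return records


def focal_cell_fixture(cell: int) -> list[SynapseRecord]:
    """Inputs and outputs of focal cell 1 or 2.

    Cell 1: inputs AC 200 / RB 47 / ON CB 66 / unidentified 2 (total 315
    as itemized; the printed total is 314); outputs AII 93 / RB 11 /
    ON CB 11.  Cell 2: inputs AC 183 / RB 56 / ON CB 55 / unidentified 3;
    outputs AII 86 / RB 18 / ON CB 2.
    """
    if cell == 1:
        sid = CELL1_ID
        inputs = ((CellType.AC, 200), (CellType.RB, 47), (CellType.ON_CB, 66),
                  (CellType.UNIDENTIFIED, 2))
        outputs = ((CellType.AII, 93), (CellType.RB, 11), (CellType.ON_CB, 11))
    elif cell == 2:
        sid = CELL2_ID
        inputs = ((CellType.AC, 183), (CellType.RB, 56), (CellType.ON_CB, 55),
                  (CellType.UNIDENTIFIED, 3))
        outputs = ((CellType.AII, 86), (CellType.RB, 18), (CellType.ON_CB, 2))
    else:
        raise ValueError("cell must be 1 or 2")
    records: list[SynapseRecord] = []
    i = 0
    partner = 30000
    for ptype, n in inputs:
        kind = SynKind.RIBBON if ptype in (CellType.RB, CellType.ON_CB) else SynKind.CONVENTIONAL
        for _ in range(n):
            partner += 1
            records.append(_mk(i, partner, ptype, sid, CellType.AC, kind,
                               Compartment.PROXIMAL_DENDRITE))
            i += 1
    for ptype, n in outputs:
        for _ in range(n):
            partner += 1
            records.append(_mk(i, sid, CellType.AC, partner, ptype, SynKind.CONVENTIONAL))
            i += 1
    return records


SOMA_NEURITE_IDS = tuple(range(801, 809))


def soma_basket_fixture() -> list[SynapseRecord]:
    """Outputs of the eight soma-targeting neurites: 113 synapses,
    90 onto AIIs and 23 onto other (unidentified) cells."""
    records: list[SynapseRecord] = []
    i = 0
    for k in range(90):
        records.append(_mk(i, SOMA_NEURITE_IDS[k % 8], CellType.AC, 520 + (k % 5),
                           CellType.AII, SynKind.CONVENTIONAL, Compartment.SOMA))
        i += 1
    for k in range(23):
        records.append(_mk(i, SOMA_NEURITE_IDS[k % 8], CellType.AC, 530 + (k % 5),
                           CellType.UNIDENTIFIED, SynKind.CONVENTIONAL))
        i += 1
    return records


def dyad_fixture(
    n: int = 100,
    mixture: tuple[tuple[str, float], ...] = (("AII", 0.75), ("A17", 0.18), ("UNIDENTIFIED", 0.07)),
    focal_ac: int = CELL1_ID,
) -> list[SynapseRecord]:
    """Ribbon dyads at RB terminals with the focal AC as one partner."""
    counts = largest_remainder([p for _, p in mixture], n)
    records: list[SynapseRecord] = []
    i = 0
    site = 0
    for (label, _), c in zip(mixture, counts):
        ptype = CellType(label)
        for _ in range(c):
            rb = 201 + (site % 40)
            pos = (site * 10000.0, 0.0, 0.0)
            records.append(_mk(i, rb, CellType.RB, focal_ac, CellType.AC,
                               SynKind.RIBBON, Compartment.PROXIMAL_DENDRITE,
                               pos=pos, dyad_site=site))
            i += 1
            partner = 40000 + site
            records.append(_mk(i, rb, CellType.RB,
                               partner if ptype is not CellType.UNIDENTIFIED else None,
                               ptype, SynKind.RIBBON, Compartment.UNASSIGNED,
                               pos=pos, dyad_site=site))
            i += 1
            site += 1
    return records
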