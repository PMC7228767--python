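"""Nearest-neighbor synapse statistics, stratification profiles, and the
depth-based ON-CB subtype classifier."""
from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._cluster import single_linkage
from .connectome import SynapseRecord
from .geometry import IPLFrame, ipl_depth
from .skeleton_io import Skeleton, SkeletonForest, VoxelScale, path_distance, to_physical
from .vocab import CellType

log = logging.getLogger(__name__)

__all__ = [
    "DistanceSample",
    "StratificationProfile",
    "ClassifierConfig",
    "ClassifierDecision",
    "nn_distances",
    "ecdf",
    "fraction_within",
    "median",
    "stratification_profile",
    "classify_on_cb",
    "en_passant_cluster_stat",
]


@dataclass(frozen=True)
class DistanceSample:
    """Per-query nearest-neighbor distances in µm."""

    distances: tuple[float, ...]
    metric: str  # "euclidean" | "geodesic_on_post_arbor"
    n_queries: int
    n_excluded: int  # queries with an empty admissible reference set
    query_desc: str = ""
    reference_desc: str = ""

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.distances):
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_um": self.distances})


def nn_distances(
    query: Sequence[SynapseRecord],
    reference: Sequence[SynapseRecord],
    metric: str = "euclidean",
    group_by_post: bool = True,
    forest: SkeletonForest | None = None,
) -> DistanceSample:
    """Minimum distance from each query synapse to the reference set.

    With ``group_by_post`` (the default) queries are compared only
    against references on the same postsynaptic cell.  ``euclidean``
    uses physical positions; ``geodesic_on_post_arbor`` measures along
    the shared postsynaptic arbor between the synapse-bearing nodes and
    requires ``forest`` plus grouping by postsynaptic cell.
    """
    if metric not in ("euclidean", "geodesic_on_post_arbor"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "geodesic_on_post_arbor":
        if not group_by_post:
            raise ValueError("geodesic metric requires group_by_post=True")
        if forest is None:
            raise ValueError("geodesic metric requires the skeleton forest")

    groups: dict[object, tuple[list[SynapseRecord], list[SynapseRecord]]]
    if group_by_post:
        groups = defaultdict(lambda: ([], []))
        for r in query:
            groups[r.post_id][0].append(r)
        for r in reference:
            groups[r.post_id][1].append(r)
    else:
        groups = {None: (list(query), list(reference))}

    distances: list[float] = []
    n_excluded = 0
    for key in sorted(groups, key=lambda k: (k is None, k)):
        qs, rs = groups[key]
        if not qs:
            continue
        if not rs:
            n_excluded += len(qs)
            continue
        if metric == "euclidean":
            tree = cKDTree(np.asarray([r.position for r in rs], dtype=float))
            d_nm, _ = tree.query(np.asarray([q.position for q in qs], dtype=float))
            distances.extend(float(d) / 1000.0 for d in np.atleast_1d(d_nm))
        else:
            sk = forest.skeletons[key]
            for q in qs:
                if q.post_node is None:
                    n_excluded += 1
                    continue
                best = math.inf
                for r in rs:
                    if r.post_node is None:
                        continue
                    best = min(best, path_distance(sk, q.post_node, r.post_node, forest.scale))
                if math.isinf(best):
                    n_excluded += 1
                else:
                    distances.append(best)
    return DistanceSample(
        distances=tuple(distances),
        metric=metric,
        n_queries=len(query),
        n_excluded=n_excluded,
    )


def ecdf(sample: DistanceSample) -> Callable[[float], float]:
    """Right-continuous empirical CDF of the sample (closed at the point)."""
    if not sample.distances:
        raise ValueError("empty distance sample")
    xs = np.sort(np.asarray(sample.distances))

    def F(r: float) -> float:
        return float(np.searchsorted(xs, r, side="right")) / len(xs)

    return F


def fraction_within(sample: DistanceSample, r: float) -> float:
    """Fraction of distances <= r (closed boundary)."""
    return ecdf(sample)(r)


def median(sample: DistanceSample) -> float:
    """Sample median; at even n the lower of the two middle order statistics."""
    if not sample.distances:
        raise ValueError("empty distance sample")
    xs = sorted(sample.distances)
    return xs[(len(xs) - 1) // 2]


# --------------------------------------------------------------------------
# stratification profiles

@dataclass(frozen=True)
class StratificationProfile:
    bin_edges: tuple[float, ...]       # half-open [lo, hi) depth bins
    length_um: tuple[float, ...]       # cable length apportioned per bin
    total_length_um: float

    @property
    def density(self) -> tuple[float, ...]:
        if self.total_length_um == 0:
            return tuple(0.0 for _ in self.length_um)
        return tuple(l / self.total_length_um for l in self.length_um)

    def peak_depth(self) -> float:
        """Midpoint of the densest bin."""
        i = int(np.argmax(self.length_um))
        return (self.bin_edges[i] + self.bin_edges[i + 1]) / 2.0

    def fraction_at_or_beyond(self, depth: float) -> float:
        """Fraction of cable in bins whose midpoint is >= depth."""
        if self.total_length_um == 0:
            return 0.0
        total = 0.0
        for i, l in enumerate(self.length_um):
            mid = (self.bin_edges[i] + self.bin_edges[i + 1]) / 2.0
            if mid >= depth:
                total += l
        return total / self.total_length_um

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "length_um": self.length_um,
                "density": self.density,
            }
        )


def stratification_profile(
    skeleton: Skeleton,
    frame: IPLFrame,
    scale: VoxelScale,
    bin_width: float = 0.1,
) -> StratificationProfile:
    """Cable length per normalized-depth bin.

    Each edge's physical length is apportioned to bins by linear
    interpolation of its endpoints' depths; an edge spanning a boundary
    splits proportionally, so total binned mass equals cable length.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    depths = {
        nid: ipl_depth(to_physical(node.position, scale), frame)
        for nid, node in skeleton.nodes.items()
    }
    if not depths:
        return StratificationProfile((0.0, bin_width), (0.0,), 0.0)
    lo_bin = math.floor(min(depths.values()) / bin_width)
    hi_bin = math.floor(max(depths.values()) / bin_width) + 1
    n_bins = max(hi_bin - lo_bin, 1)
    edges = [(lo_bin + i) * bin_width for i in range(n_bins + 1)]
    mass = [0.0] * n_bins

    def bin_of(d: float) -> int:
        return min(max(int(math.floor(d / bin_width)) - lo_bin, 0), n_bins - 1)

    for a, b in skeleton.edges:
        pa = to_physical(skeleton.nodes[a].position, scale)
        pb = to_physical(skeleton.nodes[b].position, scale)
        length = math.dist(pa, pb) / 1000.0
        da, db = depths[a], depths[b]
        if da > db:
            da, db = db, da
        if length == 0.0:
            continue
        if da == db:
            mass[bin_of(da)] += length
            continue
        # walk the depth interval [da, db), splitting at bin boundaries
        span = db - da
        d = da
        while d < db - 1e-15:
            k = bin_of(d)
            bin_hi = edges[k + 1]
            d_next = min(db, bin_hi if bin_hi > d + 1e-15 else bin_hi + bin_width)
            mass[k] += length * (d_next - d) / span
            d = d_next
    total = sum(mass)
    return StratificationProfile(tuple(edges), tuple(mass), total)


# --------------------------------------------------------------------------
# ON-CB subtype classifier

@dataclass(frozen=True)
class ClassifierConfig:
    """Depth windows for the rule-based ON-CB subtype decision.

    Windows refer to the peak-density depth of the axonal
    stratification profile in SAC-relative units (ON SAC plane = 1).
    Shipped defaults place type 6 peaking just vitreal to the ON SAC
    plane and types 7/8 progressively deeper; they are configuration,
    not claims.
    """

    inner_margin: float = 0.8          # profiles peaking short of this are not ON-CB terminals
    min_inner_fraction: float = 0.3    # minimum cable fraction at/beyond inner_margin
    window_cb5: tuple[float, float] = (0.8, 0.95)
    window_cb6: tuple[float, float] = (0.95, 1.15)
    window_cb7: tuple[float, float] = (1.15, 1.35)
    window_cb8: tuple[float, float] = (1.35, math.inf)


@dataclass(frozen=True)
class ClassifierDecision:
    cell_type: CellType
    fired_rule: str
    peak_depth: float
    inner_fraction: float
    branch_count: int | None = None

    def to_dict(self) -> dict:
        return {
            "cell_type": self.cell_type.value,
            "fired_rule": self.fired_rule,
            "peak_depth": self.peak_depth,
            "inner_fraction": self.inner_fraction,
            "branch_count": self.branch_count,
        }


def classify_on_cb(
    profile: StratificationProfile,
    branch_count: int | None = None,
    rules: ClassifierConfig = ClassifierConfig(),
) -> ClassifierDecision:
    """Assign an ON-CB subtype from a stratification profile.

    Decision inputs: peak-density depth, fraction of cable at or beyond
    the inner margin, and (recorded, not currently decisive) branch
    count.  Every decision reports the rule that fired.
    """
    if profile.total_length_um == 0:
        return ClassifierDecision(
            CellType.UNIDENTIFIED, "empty-profile", math.nan, 0.0, branch_count
        )
    peak = profile.peak_depth()
    inner_frac = profile.fraction_at_or_beyond(rules.inner_margin)
    if peak < rules.inner_margin or inner_frac < rules.min_inner_fraction:
        return ClassifierDecision(
            CellType.UNIDENTIFIED,
            f"no-inner-terminal(peak={peak:.3f}<{rules.inner_margin} "
            f"or inner_fraction={inner_frac:.3f}<{rules.min_inner_fraction})",
            peak, inner_frac, branch_count,
        )
    for ctype, (lo, hi) in (
        (CellType.ON_CB5, rules.window_cb5),
        (CellType.ON_CB6, rules.window_cb6),
        (CellType.ON_CB7, rules.window_cb7),
        (CellType.ON_CB8, rules.window_cb8),
    ):
        if lo <= peak < hi:
            return ClassifierDecision(
                ctype, f"peak-depth-window[{lo},{hi})", peak, inner_frac, branch_count
            )
    return ClassifierDecision(
        CellType.UNIDENTIFIED, "no-window-matched", peak, inner_frac, branch_count
    )


# --------------------------------------------------------------------------
# en passant ribbon clusters

@dataclass(frozen=True)
class RibbonCluster:
    size: int
    single_target: bool
    post_ids: tuple[object, ...]
    member_synapse_ids: tuple[int, ...]


def en_passant_cluster_stat(
    records: Sequence[SynapseRecord],
    linking_radius_um: float = 1.0,
) -> list[RibbonCluster]:
    """Single-linkage clusters of ribbon positions along one axon shaft.

    All records must share one presynaptic skeleton.  Each cluster
    reports its size and whether all member ribbons are apposed to the
    same postsynaptic cell.
    """
    if not records:
        return []
    pres = {r.pre_id for r in records}
    if len(pres) != 1:
        raise ValueError(f"records span multiple presynaptic cells: {sorted(map(str, pres))}")
    labels = single_linkage([r.position for r in records], linking_radius_um * 1000.0)
    by_label: dict[int, list[SynapseRecord]] = defaultdict(list)
    for r, lab in zip(records, labels):
        by_label[lab].append(r)
    out = []
    for lab in sorted(by_label):
        members = by_label[lab]
        posts = tuple(sorted({str(m.post_id) for m in members}))
        out.append(
            RibbonCluster(
                size=len(members),
                single_target=len(posts) == 1,
                post_ids=posts,
                member_synapse_ids=tuple(m.synapse_id for m in members),
            )
        )
    return out
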