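"""SAC-plane fitting, tilt correction, and normalized IPL depth.

Depth convention: the fitted OFF-SAC plane maps to depth 0 and the
ON-SAC plane to depth 1 (SAC-relative units); depth increases toward
the ganglion-cell layer, whose side must be declared explicitly via an
orientation reference point — no silent sign guessing.  An affine
re-expression to other unit systems (e.g. percent IPL) is available by
choosing different ``depth_at_off``/``depth_at_on`` anchors.
"""
from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .skeleton_io import Skeleton, SkeletonForest, SkeletonNode, to_physical
from .vocab import LaminarZone

log = logging.getLogger(__name__)

__all__ = [
    "Plane",
    "PlaneFit",
    "IPLFrame",
    "ZoneConfig",
    "DegenerateInputError",
    "fit_plane",
    "frame_from_sac_skeletons",
    "tilt_correct",
    "ipl_depth",
    "assign_laminar_zone",
]


class DegenerateInputError(ValueError):
    """Point cloud too small or rank-deficient for a plane fit."""


@dataclass(frozen=True)
class Plane:
    """Plane {x : normal·x = offset}; normal is unit, offset in nm."""

    normal: tuple[float, float, float]
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError(f"plane normal must be unit length, got {self.normal}")

    def signed_distance(self, point: Sequence[float]) -> float:
        return float(np.dot(self.normal, point) - self.offset)


@dataclass(frozen=True)
class PlaneFit:
    plane: Plane
    rms_residual: float  # RMS perpendicular distance, nm
    n_points: int


def _canonical_normal(n: np.ndarray) -> np.ndarray:
    """Fix the sign ambiguity deterministically (largest component > 0)."""
    i = int(np.argmax(np.abs(n)))
    return -n if n[i] < 0 else n


def fit_plane(points: Sequence[Sequence[float]]) -> PlaneFit:
    """Total-least-squares plane through a 3-D point cloud.

    The normal is the direction of smallest variance of the centered
    cloud (smallest singular vector); the offset places the plane
    through the centroid.  Raises :class:`DegenerateInputError` for
    fewer than 3 points or a (near-)collinear cloud.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateInputError(
            f"plane fit needs >= 3 points of dimension 3, got shape {pts.shape}"
        )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # rank: two in-plane directions must carry variance
    scale = s[0] if s[0] > 0 else 1.0
    if s[1] / scale < 1e-12 or s[0] == 0:
        raise DegenerateInputError("points are collinear or coincident; plane undefined")
    normal = _canonical_normal(vt[2])
    rms = float(s[2] / math.sqrt(pts.shape[0]))
    plane = Plane(tuple(normal), float(np.dot(normal, centroid)))
    return PlaneFit(plane=plane, rms_residual=rms, n_points=pts.shape[0])


@dataclass(frozen=True)
class IPLFrame:
    """Two fitted SAC planes plus the depth-normalization convention."""

    plane_off: Plane
    plane_on: Plane
    orientation_ref: tuple[float, float, float]  # physical point on the GCL side
    depth_at_off: float = 0.0
    depth_at_on: float = 1.0
    max_normal_angle_deg: float = 15.0

    def __post_init__(self) -> None:
        if self.depth_at_off == self.depth_at_on:
            raise ValueError("depth_at_off and depth_at_on must differ")
        ang = self.normal_angle_deg()
        if ang > self.max_normal_angle_deg:
            raise ValueError(
                f"SAC plane normals disagree by {ang:.2f} deg "
                f"(limit {self.max_normal_angle_deg} deg)"
            )
        if ang > 5.0:
            warnings.warn(
                f"SAC plane normals disagree by {ang:.2f} deg; depth uses the mean normal",
                stacklevel=2,
            )
        if self.separation_nm() <= 0:
            raise ValueError("SAC planes are coincident; separation must be positive")
        # the GCL-side reference must sit strictly beyond the ON plane:
        # with both normals oriented toward it, the OFF half-space must
        # contain the ON plane and not vice versa
        d_off_ref = self.plane_off.signed_distance(self.orientation_ref)
        d_on_ref = self.plane_on.signed_distance(self.orientation_ref)
        if d_off_ref == 0.0 or d_on_ref == 0.0:
            raise ValueError("orientation_ref lies on a SAC plane; GCL side ambiguous")
        anchor_on = np.asarray(self.plane_on.normal) * self.plane_on.offset
        anchor_off = np.asarray(self.plane_off.normal) * self.plane_off.offset
        s_off = self.plane_off.signed_distance(anchor_on) * math.copysign(1.0, d_off_ref)
        s_on = self.plane_on.signed_distance(anchor_off) * math.copysign(1.0, d_on_ref)
        if s_off <= 0 or s_on >= 0:
            raise ValueError(
                "orientation_ref must lie on the GCL side, beyond the ON SAC plane"
            )

    def normal_angle_deg(self) -> float:
        c = abs(float(np.dot(self.plane_off.normal, self.plane_on.normal)))
        return math.degrees(math.acos(min(1.0, c)))

    def axis(self) -> np.ndarray:
        """Unit depth axis: mean of the sign-aligned plane normals,
        oriented so the orientation reference lies at larger depth."""
        n_off = np.asarray(self.plane_off.normal)
        n_on = np.asarray(self.plane_on.normal)
        if np.dot(n_off, n_on) < 0:
            n_on = -n_on
        u = n_off + n_on
        u = u / np.linalg.norm(u)
        s_off = self._plane_coord(u, self.plane_off)
        if float(np.dot(u, self.orientation_ref)) < s_off:
            u = -u
        return u

    @staticmethod
    def _plane_coord(u: np.ndarray, plane: Plane) -> float:
        """Coordinate of ``plane`` along axis ``u`` (exact when parallel)."""
        anchor = np.asarray(plane.normal) * plane.offset
        return float(np.dot(u, anchor))

    def separation_nm(self) -> float:
        u = np.asarray(self.plane_off.normal)
        return abs(self._plane_coord(u, self.plane_on) - self._plane_coord(u, self.plane_off))

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "plane_off": {"normal": list(self.plane_off.normal), "offset_nm": self.plane_off.offset},
            "plane_on": {"normal": list(self.plane_on.normal), "offset_nm": self.plane_on.offset},
            "orientation_ref_nm": list(self.orientation_ref),
            "depth_at_off": self.depth_at_off,
            "depth_at_on": self.depth_at_on,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "IPLFrame":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            plane_off=Plane(tuple(doc["plane_off"]["normal"]), doc["plane_off"]["offset_nm"]),
            plane_on=Plane(tuple(doc["plane_on"]["normal"]), doc["plane_on"]["offset_nm"]),
            orientation_ref=tuple(doc["orientation_ref_nm"]),
            depth_at_off=doc.get("depth_at_off", 0.0),
            depth_at_on=doc.get("depth_at_on", 1.0),
        )


def ipl_depth(point: Sequence[float], frame: IPLFrame) -> float:
    """Normalized IPL depth of a physical (nm) point.

    Computed from the signed perpendicular distances to the two planes,
    each oriented so the declared GCL-side reference is positive:
    ``t = d_off / (d_off - d_on)``, then affinely mapped so the OFF
    plane sits at ``depth_at_off`` and the ON plane at ``depth_at_on``.
    For parallel planes this is the signed distance to the OFF plane
    over the separation; it is exact at both planes and invariant under
    rigid motion even when the fitted planes are slightly non-parallel.
    """
    ref = frame.orientation_ref
    d_off = frame.plane_off.signed_distance(point)
    if frame.plane_off.signed_distance(ref) < 0:
        d_off = -d_off
    d_on = frame.plane_on.signed_distance(point)
    if frame.plane_on.signed_distance(ref) < 0:
        d_on = -d_on
    denom = d_off - d_on
    if denom == 0.0:
        raise ValueError("point is equidistant from both planes; depth undefined")
    t = d_off / denom
    return frame.depth_at_off + t * (frame.depth_at_on - frame.depth_at_off)


def frame_from_sac_skeletons(
    forest: SkeletonForest,
    sac_off_id: int,
    sac_on_id: int,
    orientation_ref: Sequence[float] | None = None,
) -> IPLFrame:
    """Fit both SAC planes from traced skeletons and assemble a frame.

    When no orientation reference is given, the GCL side is taken to lie
    beyond the ON plane on the side away from the OFF plane (i.e. the
    ON cloud is trusted to be the ON SAC).
    """
    def pts(sid: int) -> list[tuple[float, float, float]]:
        sk = forest.skeletons[sid]
        return [to_physical(n.position, forest.scale) for n in sk.nodes.values()]

    fit_off = fit_plane(pts(sac_off_id))
    fit_on = fit_plane(pts(sac_on_id))
    if orientation_ref is None:
        anchor_off = np.asarray(fit_off.plane.normal) * fit_off.plane.offset
        anchor_on = np.asarray(fit_on.plane.normal) * fit_on.plane.offset
        orientation_ref = tuple(anchor_on + (anchor_on - anchor_off))
    return IPLFrame(
        plane_off=fit_off.plane,
        plane_on=fit_on.plane,
        orientation_ref=tuple(float(c) for c in orientation_ref),
    )


# --------------------------------------------------------------------------
# tilt correction

def _rotation_to_z(u: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector u onto +z (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(u, z))
    if c > 1.0 - 1e-15:
        return np.eye(3)
    if c < -1.0 + 1e-15:
        return np.diag([1.0, -1.0, -1.0])  # 180 deg about x
    v = np.cross(u, z)
    vx = np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _transform_plane(
    plane: Plane, rot: np.ndarray, center: np.ndarray, shift: np.ndarray
) -> Plane:
    n_new = rot @ np.asarray(plane.normal)
    n_new = n_new / np.linalg.norm(n_new)
    # x' = R(x - c) + c + s  =>  n'·x' = offset - n·c + n'·(c + s)
    offset_new = (
        plane.offset
        - float(np.dot(plane.normal, center))
        + float(np.dot(n_new, center + shift))
    )
    return Plane(tuple(float(c) for c in n_new), offset_new)


def tilt_correct(
    forest: SkeletonForest, frame: IPLFrame
) -> tuple[SkeletonForest, IPLFrame, float]:
    """Rigidly rotate the volume so the mean SAC normal becomes (0,0,1).

    The rotation is about the centroid of all node positions (physical
    coordinates); pairwise distances are preserved exactly up to
    floating point.  Returns the rotated forest, the rotated frame, and
    the applied rotation angle in degrees.
    """
    u = frame.axis()
    rot = _rotation_to_z(u)
    angle_deg = math.degrees(
        math.acos(max(-1.0, min(1.0, (np.trace(rot) - 1.0) / 2.0)))
    )

    scale = np.array(forest.scale.as_tuple())
    all_phys = [
        np.asarray(node.position) * scale
        for sk in forest.skeletons.values()
        for node in sk.nodes.values()
    ]
    center = np.mean(all_phys, axis=0) if all_phys else np.zeros(3)

    # translate afterwards so voxel coordinates stay non-negative
    rotated_nm = {
        (sid, nid): rot @ (np.asarray(node.position) * scale - center) + center
        for sid, sk in forest.skeletons.items()
        for nid, node in sk.nodes.items()
    }
    mins = np.min(list(rotated_nm.values()), axis=0) if rotated_nm else np.zeros(3)
    shift = np.where(mins < 0, -mins, 0.0)

    def xform(p_nm: np.ndarray) -> np.ndarray:
        return rot @ (p_nm - center) + center + shift

    new_skeletons: dict[int, Skeleton] = {}
    for sid, sk in forest.skeletons.items():
        new_nodes: dict[int, SkeletonNode] = {}
        for nid, node in sk.nodes.items():
            p_new = (rotated_nm[(sid, nid)] + shift) / scale
            new_nodes[nid] = replace(node, position=tuple(float(c) for c in p_new))
        new_skeletons[sid] = Skeleton(
            skeleton_id=sid,
            name=sk.name,
            nodes=new_nodes,
            edges=set(sk.edges),
            soma_node=sk.soma_node,
            attrs=sk.attrs,
        )
    new_forest = SkeletonForest(
        scale=forest.scale,
        skeletons=new_skeletons,
        annotations=list(forest.annotations),
        bounds=None,  # bounds do not survive rotation
        unparsed_comments=list(forest.unparsed_comments),
        attrs=forest.attrs,
    )
    new_frame = IPLFrame(
        plane_off=_transform_plane(frame.plane_off, rot, center, shift),
        plane_on=_transform_plane(frame.plane_on, rot, center, shift),
        orientation_ref=tuple(xform(np.asarray(frame.orientation_ref, dtype=float))),
        depth_at_off=frame.depth_at_off,
        depth_at_on=frame.depth_at_on,
        max_normal_angle_deg=frame.max_normal_angle_deg,
    )
    return new_forest, new_frame, angle_deg


# --------------------------------------------------------------------------
# laminar zones

@dataclass(frozen=True)
class ZoneConfig:
    """Half-open [lo, hi) depth boundaries for laminar zones."""

    off_boundary: float = 0.0   # below -> outer_OFF
    on_boundary: float = 1.0    # at/above -> inner_ON
    sub_on_boundary: float = 1.5  # at/above -> sub_ON

    def __post_init__(self) -> None:
        if not (self.off_boundary < self.on_boundary < self.sub_on_boundary):
            raise ValueError("zone thresholds must be strictly increasing")


def assign_laminar_zone(depth: float, thresholds: ZoneConfig | None = None) -> LaminarZone:
    """Map a normalized depth to its laminar zone (half-open bins)."""
    t = thresholds or ZoneConfig()
    if depth < t.off_boundary:
        return LaminarZone.OUTER_OFF
    if depth < t.on_boundary:
        return LaminarZone.BETWEEN_SAC
    if depth < t.sub_on_boundary:
        return LaminarZone.INNER_ON
    return LaminarZone.SUB_ON
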