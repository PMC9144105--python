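"""Domain model for a microdissected coronary resistance-artery network.

A :class:`VascularNetwork` is a rooted planar tree. The root is the
orifice, where the network leaves the aorta; the coordinate frame puts
the orifice at (0, 0) with +X pointing toward the cardiac apex and +Y
toward the left ventricle. Vessels are :class:`Segment` polylines that
run between bifurcations (or from a bifurcation to the ~80 um
visibility endpoint), each carrying outer and inner diameters measured
at three points along its axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, NamedTuple

import numpy as np

from .geometry import as_axis, angle_of_deg, rotate_deg

__all__ = [
    "Point2D",
    "NetworkNode",
    "Segment",
    "VascularNetwork",
    "ValidationIssue",
    "ValidationReport",
    "validate_network",
    "to_coordinate_frame",
]

NodeRole = Literal["orifice", "bifurcation", "endpoint", "waypoint"]


class Point2D(NamedTuple):
    """A point in the orifice-anchored frame (micrometres)."""

    x: float
    y: float


@dataclass
class NetworkNode:
    id: int
    position: Point2D
    role: NodeRole


@dataclass
class Segment:
    """One vessel segment between consecutive branch points.

    ``axis`` is the digitized centreline, first vertex at the upstream
    node. ``outer_diams``/``inner_diams`` are the three diameter
    measurements (um) taken at the start, middle and end of the axis.
    """

    id: int
    axis: np.ndarray
    outer_diams: np.ndarray
    inner_diams: np.ndarray
    parent: int | None = None
    branch_order: int | None = None

    def __post_init__(self) -> None:
        self.axis = as_axis(self.axis)
        self.outer_diams = np.asarray(self.outer_diams, dtype=float)
        self.inner_diams = np.asarray(self.inner_diams, dtype=float)

    @property
    def mean_outer(self) -> float:
        return float(np.mean(self.outer_diams))

    @property
    def mean_inner(self) -> float:
        return float(np.mean(self.inner_diams))

    @property
    def start(self) -> np.ndarray:
        return self.axis[0]

    @property
    def end(self) -> np.ndarray:
        return self.axis[-1]


@dataclass
class VascularNetwork:
    """Rooted tree of segments with derived node bookkeeping.

    ``segments`` maps segment id -> :class:`Segment`; topology lives in
    the segments' ``parent`` fields. ``meta`` carries provenance (for
    synthetic networks, the generation parameters and injected-defect
    ground truth).
    """

    segments: dict[int, Segment]
    meta: dict = field(default_factory=dict)

    @property
    def root_id(self) -> int:
        roots = [s.id for s in self.segments.values() if s.parent is None]
        if len(roots) != 1:
            raise ValueError(f"network must have exactly one root, found {len(roots)}")
        return roots[0]

    @property
    def root(self) -> Segment:
        return self.segments[self.root_id]

    def children(self, seg_id: int) -> list[int]:
        return sorted(s.id for s in self.segments.values() if s.parent == seg_id)

    @property
    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {sid: [] for sid in self.segments}
        for s in self.segments.values():
            if s.parent is not None and s.parent in adj:
                adj[s.parent].append(s.id)
        return {k: sorted(v) for k, v in adj.items()}

    @property
    def orifice_position(self) -> np.ndarray:
        return self.root.axis[0]

    def depth_first_ids(self) -> list[int]:
        """Segment ids in canonical depth-first order.

        Daughters are visited largest mean outer diameter first, ties
        broken by departure angle; this ordering makes serialization
        byte-stable.
        """
        adj = self.adjacency
        order: list[int] = []

        def key(sid: int):
            s = self.segments[sid]
            v = s.axis[min(1, len(s.axis) - 1)] - s.axis[0]
            ang = angle_of_deg(v) if np.any(v) else 0.0
            return (-s.mean_outer, ang, sid)

        stack = [self.root_id]
        while stack:
            sid = stack.pop()
            order.append(sid)
            stack.extend(sorted(adj[sid], key=key, reverse=True))
        return order

    def nodes(self, coincidence_tol: float = 1.0) -> dict[int, NetworkNode]:
        """Derive the node table: orifice, bifurcations, endpoints,
        waypoints (nodes continuing into exactly one daughter)."""
        adj = self.adjacency
        nodes: dict[int, NetworkNode] = {}
        root = self.root
        nodes[0] = NetworkNode(0, Point2D(*root.axis[0]), "orifice")
        for i, sid in enumerate(self.depth_first_ids(), start=1):
            seg = self.segments[sid]
            n_child = len(adj[sid])
            role: NodeRole = (
                "endpoint" if n_child == 0 else "waypoint" if n_child == 1 else "bifurcation"
            )
            nodes[i] = NetworkNode(i, Point2D(*seg.axis[-1]), role)
        return nodes

    def transformed(self, func) -> "VascularNetwork":
        """Return a copy with ``func`` applied to every axis."""
        segs = {
            sid: replace(s, axis=func(s.axis)) for sid, s in self.segments.items()
        }
        return VascularNetwork(segments=segs, meta=dict(self.meta))


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class ValidationIssue:
    severity: Literal["error", "warning"]
    code: str
    message: str
    entity: int | None = None


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, severity, code, message, entity=None) -> None:
        self.issues.append(ValidationIssue(severity, code, message, entity))

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self) -> bool:  # truthy when clean, like a passing check
        return self.ok


def validate_network(
    network: VascularNetwork, coincidence_tol: float = 1.0
) -> ValidationReport:
    """Sweep every structural invariant and report all violations.

    Checks: single root; acyclic parent links; parents resolvable;
    finite coordinates; >=2 distinct consecutive axis vertices;
    positive diameters with inner < outer at each of the three points;
    every daughter's first axis vertex coinciding with its mother's
    last vertex within ``coincidence_tol`` um.
    """
    rep = ValidationReport()
    segs = network.segments
    roots = [s.id for s in segs.values() if s.parent is None]
    if len(roots) != 1:
        rep.add("error", "root-count", f"expected 1 root segment, found {len(roots)}")
    for s in segs.values():
        if s.parent is not None and s.parent not in segs:
            rep.add("error", "orphan", f"parent {s.parent} of segment {s.id} missing", s.id)
        if s.parent == s.id:
            rep.add("error", "self-parent", "segment is its own parent", s.id)
        if not np.all(np.isfinite(s.axis)):
            rep.add("error", "nonfinite-axis", "axis has non-finite coordinates", s.id)
            continue
        if len(s.axis) < 2:
            rep.add("error", "short-axis", "axis needs at least 2 points", s.id)
        elif np.any(np.all(np.diff(s.axis, axis=0) == 0.0, axis=1)):
            rep.add("error", "repeated-vertex", "consecutive axis points coincide", s.id)
        if len(s.outer_diams) != 3 or len(s.inner_diams) != 3:
            rep.add("error", "diam-count", "three diameter points required", s.id)
            continue
        if np.any(s.outer_diams <= 0) or np.any(s.inner_diams <= 0):
            rep.add("error", "nonpositive-diam", "diameters must be positive", s.id)
        if np.any(s.inner_diams >= s.outer_diams):
            rep.add("error", "inner-ge-outer", "inner diameter >= outer diameter", s.id)
    # cycle sweep over parent links
    for s in segs.values():
        seen = set()
        cur: int | None = s.id
        while cur is not None and cur in segs:
            if cur in seen:
                if cur == s.id:
                    rep.add("error", "cycle", "parent links form a cycle", s.id)
                break
            seen.add(cur)
            cur = segs[cur].parent
    for s in segs.values():
        if s.parent is not None and s.parent in segs and len(s.axis) >= 1:
            gap = float(np.hypot(*(s.axis[0] - segs[s.parent].axis[-1])))
            if gap > coincidence_tol:
                rep.add(
                    "error",
                    "detached",
                    f"start is {gap:.2f} um from mother end (tol {coincidence_tol})",
                    s.id,
                )
    return rep


# ---------------------------------------------------------------------------
# coordinate frame


def to_coordinate_frame(
    network: VascularNetwork,
    orifice: Iterable[float] | None = None,
    apex_point: Iterable[float] | None = None,
    lv_point: Iterable[float] | None = None,
) -> VascularNetwork:
    """Rigidly move the network into the orifice-anchored frame.

    The orifice (default: the root segment's first vertex) goes to
    (0, 0) and the orifice->apex direction becomes +X. If ``lv_point``
    (a point on the left-ventricle side) is given and lands at negative
    Y, the Y axis is mirrored so the left ventricle is at positive Y.
    Distances between all points are preserved.
    """
    orifice = np.asarray(
        network.orifice_position if orifice is None else list(orifice), dtype=float
    )
    if apex_point is None:
        apex = orifice + np.array([1.0, 0.0])
    else:
        apex = np.asarray(list(apex_point), dtype=float)
    if np.allclose(apex, orifice):
        raise ValueError("apex direction point coincides with the orifice")
    ang = angle_of_deg(apex - orifice)

    flip = 1.0
    if lv_point is not None:
        lv = rotate_deg(np.asarray(list(lv_point), dtype=float) - orifice, -ang)
        if lv[1] < 0:
            flip = -1.0

    def move(axis: np.ndarray) -> np.ndarray:
        out = rotate_deg(axis - orifice, -ang)
        out[:, 1] *= flip
        return out

    return network.transformed(move)
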