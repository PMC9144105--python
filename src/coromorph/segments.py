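"""Per-segment morphometry.

Each vessel segment gets a branch order, a flow length (arc length of
its possibly curved axis), a direct length (chord), a tortuosity index

    T(%) = 100 - direct * 100 / flow,

mean outer/inner diameters from the three measurement points, wall
thickness per side, a lumen cross-section area pi * r_i^2, and flow
and direct distances from the orifice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import angle_between_deg, arc_length, chord_length, points_at_arclength
from .model import Segment, VascularNetwork

__all__ = [
    "SegmentMetrics",
    "flow_length",
    "direct_length",
    "tortuosity_pct",
    "lumen_area",
    "assign_branch_orders",
    "summarize_segment",
    "compute_segment_metrics",
]

METRIC_COLUMNS = [
    "segment_id",
    "branch_order",
    "flow_length_um",
    "direct_length_um",
    "tortuosity_pct",
    "mean_outer_diam_um",
    "mean_inner_diam_um",
    "wall_thickness_um",
    "lumen_area_um2",
    "flow_distance_um",
    "direct_distance_um",
]


@dataclass(frozen=True)
class SegmentMetrics:
    segment_id: int
    branch_order: int
    flow_length: float
    direct_length: float
    tortuosity_pct: float
    mean_outer_diam: float
    mean_inner_diam: float
    wall_thickness: float
    lumen_area: float
    flow_distance_from_orifice: float
    direct_distance_from_orifice: float


def flow_length(segment: Segment) -> float:
    """Arc length of the segment axis, um."""
    if len(segment.axis) < 2:
        raise ValueError(f"segment {segment.id}: axis needs >= 2 points")
    return arc_length(segment.axis)


def direct_length(segment: Segment) -> float:
    """Chord between the first and last axis points, um."""
    d = chord_length(segment.axis)
    if d == 0.0:
        warnings.warn(
            f"segment {segment.id}: start and end coincide (closed loop axis)",
            stacklevel=2,
        )
    return d


def tortuosity_pct(segment: Segment) -> float:
    """Tortuosity T(%) = 100 - direct*100/flow; 0 for a straight axis."""
    flow = flow_length(segment)
    if flow <= 0:
        raise ValueError(f"segment {segment.id}: zero flow length")
    return 100.0 - chord_length(segment.axis) * 100.0 / flow


def lumen_area(inner_radius: float) -> float:
    """Lumen cross-section area pi * r_i^2 (um^2) from the inner radius."""
    if inner_radius < 0:
        raise ValueError("inner radius must be non-negative")
    return math.pi * inner_radius**2


def _departure_direction(seg: Segment, chord: float = 100.0) -> np.ndarray:
    tip = points_at_arclength(seg.axis, min(chord, arc_length(seg.axis)))
    return tip - seg.axis[0]


def assign_branch_orders(network: VascularNetwork, scheme: str = "generation") -> VascularNetwork:
    """Assign branch orders in place (and return the network).

    ``generation``: the root is order 1 and every daughter increments
    its mother's order.  ``trunk-following``: at each bifurcation the
    daughter that continues the trunk (smallest deviation from the
    mother axis, ties to the larger diameter) keeps the mother's
    order; the rest increment.
    """
    if scheme not in ("generation", "trunk-following"):
        raise ValueError(f"unknown ordering scheme {scheme!r}")
    adj = network.adjacency
    root = network.root_id
    network.segments[root].branch_order = 1
    stack = [root]
    while stack:
        sid = stack.pop()
        seg = network.segments[sid]
        kids = adj[sid]
        if not kids:
            continue
        trunk_kid = None
        if scheme == "trunk-following":
            mother_dir = seg.axis[-1] - points_at_arclength(
                seg.axis, max(0.0, arc_length(seg.axis) - 100.0)
            )
            if not np.any(mother_dir):
                mother_dir = seg.axis[-1] - seg.axis[0]

            def dev_key(k: int):
                child = network.segments[k]
                dev = angle_between_deg(mother_dir, _departure_direction(child))
                return (round(dev, 6), -child.mean_outer)

            trunk_kid = min(kids, key=dev_key)
        for k in kids:
            keep = scheme == "trunk-following" and k == trunk_kid
            network.segments[k].branch_order = seg.branch_order + (0 if keep else 1)
            stack.append(k)
    return network


def summarize_segment(
    segment: Segment,
    upstream_flow_distance: float = 0.0,
    orifice=(0.0, 0.0),
    diam_agg: str = "mean",
    direct_anchor: str = "midpoint",
) -> SegmentMetrics:
    """Collect every per-segment metric into one record.

    ``direct_anchor`` selects the point whose chord distance from the
    orifice is reported: the segment's arc midpoint (default) or its
    downstream endpoint.
    """
    agg = np.mean if diam_agg == "mean" else np.median
    if diam_agg not in ("mean", "median"):
        raise ValueError(f"unknown diameter aggregate {diam_agg!r}")
    mean_outer = float(agg(segment.outer_diams))
    mean_inner = float(agg(segment.inner_diams))
    flow = flow_length(segment)
    if direct_anchor == "midpoint":
        anchor = points_at_arclength(segment.axis, flow / 2.0)
    elif direct_anchor == "endpoint":
        anchor = segment.axis[-1]
    else:
        raise ValueError(f"unknown direct anchor {direct_anchor!r}")
    return SegmentMetrics(
        segment_id=segment.id,
        branch_order=segment.branch_order if segment.branch_order is not None else -1,
        flow_length=flow,
        direct_length=direct_length(segment),
        tortuosity_pct=tortuosity_pct(segment),
        mean_outer_diam=mean_outer,
        mean_inner_diam=mean_inner,
        wall_thickness=(mean_outer - mean_inner) / 2.0,
        lumen_area=lumen_area(mean_inner / 2.0),
        flow_distance_from_orifice=upstream_flow_distance + flow,
        direct_distance_from_orifice=float(np.hypot(*(anchor - np.asarray(orifice, float)))),
    )


def compute_segment_metrics(
    network: VascularNetwork,
    scheme: str = "generation",
    diam_agg: str = "mean",
    direct_anchor: str = "midpoint",
) -> pd.DataFrame:
    """One row per segment, orders assigned, distances accumulated
    root-to-tip. Columns are ``METRIC_COLUMNS``."""
    assign_branch_orders(network, scheme)
    adj = network.adjacency
    orifice = network.orifice_position
    upstream: dict[int, float] = {network.root_id: 0.0}
    rows = []
    stack = [network.root_id]
    while stack:
        sid = stack.pop()
        seg = network.segments[sid]
        m = summarize_segment(seg, upstream[sid], orifice, diam_agg, direct_anchor)
        rows.append(
            (
                m.segment_id,
                m.branch_order,
                m.flow_length,
                m.direct_length,
                m.tortuosity_pct,
                m.mean_outer_diam,
                m.mean_inner_diam,
                m.wall_thickness,
                m.lumen_area,
                m.flow_distance_from_orifice,
                m.direct_distance_from_orifice,
            )
        )
        for k in adj[sid]:
            upstream[k] = m.flow_distance_from_orifice
            stack.append(k)
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS).sort_values("segment_id")
    return df.reset_index(drop=True)


def per_order_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-branch-order segment counts, mean lengths and lumen areas
    (one row per observed order)."""
    g = metrics.groupby("branch_order")
    out = g.agg(
        n_segments=("segment_id", "size"),
        mean_flow_length_um=("flow_length_um", "mean"),
        mean_lumen_area_um2=("lumen_area_um2", "mean"),
        mean_outer_diam_um=("mean_outer_diam_um", "mean"),
    )
    return out.reset_index()
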