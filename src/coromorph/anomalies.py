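"""Hemodynamically disadvantageous network deformities.

Four classes are counted per network and pooled per cohort: branches
running in parallel, broken (kinked) vessel courses, multiple (>= 3
daughter) branching, and segments with tortuosity above 8%. Courses
that deviate from the energy-optimal pattern force the network to
spend more mechanical energy on perfusion, which is why they are
tallied. The study design never defines the parallel/broken criteria
numerically, so the thresholds here are explicit, documented config
keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .geometry import points_at_arclength
from .model import VascularNetwork
from .rings import decompose_network
from .segments import flow_length, tortuosity_pct

__all__ = [
    "AnomalyInstance",
    "AnomalyReport",
    "ANOMALY_CLASSES",
    "detect_multiple_branching",
    "count_tortuous_segments",
    "detect_parallel_running",
    "detect_broken_course",
    "detect_all",
    "anomaly_report",
]

ANOMALY_CLASSES = (
    "parallel_running",
    "broken_course",
    "multiple_branching",
    "tortuosity_gt_threshold",
)


@dataclass(frozen=True)
class AnomalyInstance:
    anomaly_class: str
    entities: tuple[int, ...]  # segment ids involved
    value: float  # arity / kink angle / overlap length / tortuosity


@dataclass
class AnomalyReport:
    """Pooled, normalized deformity counts for one cohort."""

    counts: dict[str, float]
    n_networks: int
    normalize_to_n: int
    evidence: list[AnomalyInstance] = field(default_factory=list)

    @property
    def sum_of_all(self) -> float:
        return float(sum(self.counts.values()))


def detect_multiple_branching(network: VascularNetwork) -> list[AnomalyInstance]:
    """One instance per node with three or more daughter segments
    (arity recorded as the value)."""
    out = []
    for sid, kids in sorted(network.adjacency.items()):
        if len(kids) >= 3:
            out.append(AnomalyInstance("multiple_branching", (sid, *kids), float(len(kids))))
    return out


def count_tortuous_segments(
    network: VascularNetwork, threshold: float = 8.0
) -> list[AnomalyInstance]:
    """Segments whose tortuosity strictly exceeds ``threshold`` %."""
    out = []
    for sid in sorted(network.segments):
        t = tortuosity_pct(network.segments[sid])
        if t > threshold:
            out.append(AnomalyInstance("tortuosity_gt_threshold", (sid,), t))
    return out


def detect_broken_course(
    network: VascularNetwork,
    angle_threshold: float = 60.0,
    chord: float = 50.0,
) -> list[AnomalyInstance]:
    """Kinks inside segments: direction changes between consecutive
    ``chord``-um chords exceeding ``angle_threshold``. Direction
    changes at bifurcation nodes are branching, not broken courses,
    and are never counted."""
    out = []
    for sid in sorted(network.segments):
        seg = network.segments[sid]
        total = flow_length(seg)
        n = int(total // chord)
        if n < 2:
            continue
        pts = points_at_arclength(seg.axis, np.arange(n + 1) * chord)
        vecs = np.diff(pts, axis=0)
        headings = np.degrees(np.arctan2(vecs[:, 1], vecs[:, 0]))
        turns = np.abs((np.diff(headings) + 180.0) % 360.0 - 180.0)
        for t in turns[turns > angle_threshold]:
            out.append(AnomalyInstance("broken_course", (sid,), float(t)))
    return out


def detect_parallel_running(
    network: VascularNetwork,
    max_gap: float = 200.0,
    max_angle: float = 15.0,
    min_overlap: float = 250.0,
    units=None,
    unit_length: float = 50.0,
) -> list[AnomalyInstance]:
    """Pairs of segments whose ring units run side by side.

    Two segments qualify when their ring units stay within ``max_gap``
    um of each other with local axis directions differing by less than
    ``max_angle`` degrees (mod 180) over at least ``min_overlap`` um of
    arc. Mother-daughter pairs are excluded: a daughter necessarily
    starts on its mother. Each unordered pair is reported once.
    """
    if units is None:
        units = decompose_network(network, unit_length=unit_length)
    out = []
    by_seg = {
        int(sid): (
            g[["center_x_um", "center_y_um"]].to_numpy(),
            g["axis_angle_deg"].to_numpy(),
        )
        for sid, g in units.groupby("segment_id")
    }
    parents = {sid: s.parent for sid, s in network.segments.items()}
    for a, b in combinations(sorted(by_seg), 2):
        if parents.get(a) == b or parents.get(b) == a:
            continue
        ca, aa = by_seg[a]
        cb, ab = by_seg[b]
        gap = np.hypot(
            ca[:, 0][:, None] - cb[:, 0][None, :], ca[:, 1][:, None] - cb[:, 1][None, :]
        )
        dang = np.abs(aa[:, None] - ab[None, :])
        dang = np.minimum(dang, 180.0 - dang)
        ok = (gap <= max_gap) & (dang < max_angle)
        overlap = unit_length * min(ok.any(axis=1).sum(), ok.any(axis=0).sum())
        if overlap >= min_overlap:
            out.append(AnomalyInstance("parallel_running", (a, b), float(overlap)))
    return out


def detect_all(
    network: VascularNetwork,
    tortuosity_threshold: float = 8.0,
    parallel_max_gap: float = 200.0,
    parallel_max_angle: float = 15.0,
    parallel_min_overlap: float = 250.0,
    broken_angle_threshold: float = 60.0,
    units=None,
) -> list[AnomalyInstance]:
    """Run every detector on one network."""
    return (
        detect_parallel_running(
            network, parallel_max_gap, parallel_max_angle, parallel_min_overlap, units
        )
        + detect_broken_course(network, broken_angle_threshold)
        + detect_multiple_branching(network)
        + count_tortuous_segments(network, tortuosity_threshold)
    )


def anomaly_report(
    networks: list[VascularNetwork],
    normalize_to_n: int = 8,
    **detector_kwargs,
) -> AnomalyReport:
    """Pool deformity counts across a cohort and normalize to a
    reference cohort size (counts * normalize_to_n / n_networks)."""
    if not networks:
        raise ValueError("empty network group")
    evidence: list[AnomalyInstance] = []
    raw = dict.fromkeys(ANOMALY_CLASSES, 0.0)
    for net in networks:
        for inst in detect_all(net, **detector_kwargs):
            evidence.append(inst)
            raw[inst.anomaly_class] += 1.0
    scale = normalize_to_n / len(networks)
    counts = {k: v * scale for k, v in raw.items()}
    return AnomalyReport(counts, len(networks), normalize_to_n, evidence)
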