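"""Readers and writers for digitized network geometry.

Two text dialects are supported:

* ``swc`` — the standard 7-column morphology format (id, type, x, y,
  z, radius, parent), one sample per axis vertex. SWC carries a single
  radius, which maps to the *outer* radius; the three-point outer and
  inner diameters travel in a companion ``<stem>.segments.csv`` that is
  written automatically and picked up on read when present. Without
  the companion, inner diameters are reconstructed from a default wall
  thickness and the network is flagged.
* ``csv`` — a documented pair ``<stem>.nodes.csv`` (node_id, x_um,
  y_um, role) + ``<stem>.segments.csv`` (segment_id, parent_segment,
  node_path, outer_d1..3, inner_d1..3) with a units header line.

The network is planar: SWC ``z`` is read, and a warning is recorded if
it is non-zero anywhere.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .geometry import cumulative_arclength
from .model import Segment, VascularNetwork, validate_network

__all__ = ["read_network", "write_network", "FormatError", "TopologyError"]

_SEG_HEADER = [
    "segment_id",
    "parent_segment",
    "node_path",
    "outer_d1",
    "outer_d2",
    "outer_d3",
    "inner_d1",
    "inner_d2",
    "inner_d3",
]


class FormatError(ValueError):
    """The file does not parse in the named dialect."""


class TopologyError(ValueError):
    """Parsed geometry does not form a single rooted tree."""


def _three_point_radii(axis: np.ndarray, outer_diams: np.ndarray) -> np.ndarray:
    """Outer radius at every axis vertex, interpolating the three
    measurements placed at arc fractions 0, 1/2 and 1."""
    cum = cumulative_arclength(axis)
    frac = cum / cum[-1] if cum[-1] > 0 else np.linspace(0, 1, len(cum))
    return np.interp(frac, [0.0, 0.5, 1.0], np.asarray(outer_diams, float) / 2.0)


def _companion_path(path: Path) -> Path:
    return path.with_suffix(".segments.csv")


# ---------------------------------------------------------------------------
# writing


def write_network(network: VascularNetwork, path, format: str = "swc") -> None:
    """Serialize a network; byte-stable for a fixed input.

    Segments are written in canonical depth-first order (daughters by
    descending diameter, ties by angle), so writing the same network
    twice produces identical bytes.
    """
    if not network.segments:
        raise ValueError("refusing to write a network with no segments")
    path = Path(path)
    if format == "swc":
        _write_swc(network, path)
    elif format == "csv":
        _write_csv_pair(network, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_swc(network: VascularNetwork, path: Path) -> None:
    order = network.depth_first_ids()
    lines = ["# SWC export; units um; planar network (z = 0)"]
    sample_of_end: dict[int, int] = {}  # segment id -> sample id of its last vertex
    paths: dict[int, list[int]] = {}
    next_id = 1

    root = network.segments[order[0]]
    rows: list[tuple[int, int, float, float, float, int]] = []
    # sample rows: (id, type, x, y, radius, parent)
    radii = _three_point_radii(root.axis, root.outer_diams)
    rows.append((next_id, 1, root.axis[0, 0], root.axis[0, 1], radii[0], -1))
    root_start = next_id
    next_id += 1
    for sid in order:
        seg = network.segments[sid]
        radii = _three_point_radii(seg.axis, seg.outer_diams)
        start_sample = root_start if seg.parent is None else sample_of_end[seg.parent]
        sample_path = [start_sample]
        parent_sample = start_sample
        for k in range(1, len(seg.axis)):
            rows.append((next_id, 2, seg.axis[k, 0], seg.axis[k, 1], radii[k], parent_sample))
            sample_path.append(next_id)
            parent_sample = next_id
            next_id += 1
        sample_of_end[sid] = parent_sample
        paths[sid] = sample_path

    for rid, rtype, x, y, r, parent in rows:
        lines.append(f"{rid} {rtype} {x:.6f} {y:.6f} 0.000000 {r:.6f} {parent}")
    path.write_text("\n".join(lines) + "\n")
    _write_segment_table(network, order, paths, _companion_path(path))


def _write_segment_table(network, order, paths, table_path: Path) -> None:
    lines = [",".join(_SEG_HEADER)]
    for sid in order:
        seg = network.segments[sid]
        parent = "" if seg.parent is None else str(seg.parent)
        node_path = "|".join(str(i) for i in paths[sid])
        diams = [f"{d:.6f}" for d in (*seg.outer_diams, *seg.inner_diams)]
        lines.append(",".join([str(sid), parent, node_path, *diams]))
    table_path.write_text("\n".join(lines) + "\n")


def _write_csv_pair(network: VascularNetwork, path: Path) -> None:
    stem = Path(path)
    order = network.depth_first_ids()
    node_rows: list[str] = ["# units: um", "node_id,x_um,y_um,role"]
    paths: dict[int, list[int]] = {}
    adj = network.adjacency
    next_id = 1
    end_node: dict[int, int] = {}
    root = network.segments[order[0]]
    node_rows.append(f"1,{root.axis[0, 0]:.6f},{root.axis[0, 1]:.6f},orifice")
    root_node = 1
    next_id = 2
    for sid in order:
        seg = network.segments[sid]
        start = root_node if seg.parent is None else end_node[seg.parent]
        node_path = [start]
        for k in range(1, len(seg.axis)):
            last = k == len(seg.axis) - 1
            if last:
                n_child = len(adj[sid])
                role = "endpoint" if n_child == 0 else ("waypoint" if n_child == 1 else "bifurcation")
            else:
                role = "waypoint"
            node_rows.append(f"{next_id},{seg.axis[k, 0]:.6f},{seg.axis[k, 1]:.6f},{role}")
            node_path.append(next_id)
            next_id += 1
        end_node[sid] = node_path[-1]
        paths[sid] = node_path
    stem.with_suffix(".nodes.csv").write_text("\n".join(node_rows) + "\n")
    _write_segment_table(network, order, paths, stem.with_suffix(".segments.csv"))


# ---------------------------------------------------------------------------
# reading


def read_network(
    path,
    format: str = "swc",
    default_wall_thickness: float = 15.0,
    validate: bool = True,
) -> VascularNetwork:
    """Parse a network file and validate its structure.

    ``default_wall_thickness`` (um, per side) reconstructs inner
    diameters when only SWC radii are available; networks so completed
    carry a ``"reconstructed_inner"`` warning in ``meta``.
    """
    path = Path(path)
    if format == "swc" and not path.exists():
        raise FileNotFoundError(path)
    if format == "swc":
        net = _read_swc(path, default_wall_thickness)
    elif format == "csv":
        net = _read_csv_pair(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if validate:
        report = validate_network(net)
        if report.errors:
            first = report.errors[0]
            raise TopologyError(
                f"{path}: invalid network ({len(report.errors)} errors; "
                f"first: {first.code} on entity {first.entity}: {first.message})"
            )
    return net


def _read_swc(path: Path, default_wall: float):
    samples: dict[int, tuple[float, float, float, float, int]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise FormatError(f"{path}:{lineno}: expected 7 SWC columns, got {len(parts)}")
        try:
            sid = int(parts[0])
            x, y, z, r = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        if sid == parent:
            raise TopologyError(f"{path}:{lineno}: sample {sid} is its own parent")
        if sid in samples:
            raise FormatError(f"{path}:{lineno}: duplicate sample id {sid}")
        samples[sid] = (x, y, z, r, parent)
    if not samples:
        raise FormatError(f"{path}: no SWC samples")

    warnings: list[str] = []
    if any(abs(s[2]) > 1e-9 for s in samples.values()):
        warnings.append("nonplanar: SWC z coordinates are non-zero and were ignored")

    roots = [sid for sid, s in samples.items() if s[4] == -1]
    if len(roots) != 1:
        raise TopologyError(f"{path}: expected one root sample, found {len(roots)}")
    children: dict[int, list[int]] = {sid: [] for sid in samples}
    for sid, s in samples.items():
        if s[4] != -1:
            if s[4] not in samples:
                raise TopologyError(f"{path}: sample {sid} has unknown parent {s[4]}")
            children[s[4]].append(sid)
    _check_acyclic(samples, roots[0], path)

    companion = _companion_path(path)
    pos = {sid: np.array([s[0], s[1]]) for sid, s in samples.items()}
    radius = {sid: s[3] for sid, s in samples.items()}
    if companion.exists():
        segments = _segments_from_table(companion, pos)
    else:
        segments = _segments_from_branch_points(children, roots[0], pos, radius, default_wall)
        warnings.append("reconstructed_inner: inner diameters from default wall thickness")
    net = VascularNetwork(segments=segments)
    if warnings:
        net.meta["warnings"] = warnings
    return net


def _check_acyclic(samples, root, path):
    state: dict[int, int] = {}
    for start in samples:
        chain = []
        cur = start
        while cur != -1 and state.get(cur, 0) == 0:
            chain.append(cur)
            state[cur] = 1
            cur = samples[cur][4]
        if cur != -1 and state.get(cur) == 1 and cur in chain:
            raise TopologyError(f"{path}: parent links contain a cycle through sample {cur}")
        for c in chain:
            state[c] = 2


def _segments_from_table(table_path: Path, pos: dict[int, np.ndarray]) -> dict[int, Segment]:
    segments: dict[int, Segment] = {}
    with open(table_path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_SEG_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{table_path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                sid = int(row["segment_id"])
                parent = row["parent_segment"].strip()
                node_ids = [int(t) for t in row["node_path"].split("|")]
                outer = [float(row[f"outer_d{k}"]) for k in (1, 2, 3)]
                inner = [float(row[f"inner_d{k}"]) for k in (1, 2, 3)]
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{table_path}:{lineno}: {exc}") from None
            unknown = [n for n in node_ids if n not in pos]
            if unknown:
                raise FormatError(f"{table_path}:{lineno}: unknown node ids {unknown}")
            segments[sid] = Segment(
                id=sid,
                axis=np.array([pos[n] for n in node_ids]),
                outer_diams=outer,
                inner_diams=inner,
                parent=None if parent == "" else int(parent),
            )
    if not segments:
        raise FormatError(f"{table_path}: no segments")
    return segments


def _segments_from_branch_points(children, root, pos, radius, default_wall):
    """Cut the SWC sample tree into segments at branch points."""
    segments: dict[int, Segment] = {}
    next_seg = 1
    # (start sample, first child on this branch, parent segment id)
    stack: list[tuple[int, int, int | None]] = [
        (root, c, None) for c in sorted(children[root], reverse=True)
    ]
    if not stack and len(children[root]) == 0:
        raise TopologyError("SWC tree has a single sample and no segments")
    while stack:
        start, cur, parent_seg = stack.pop()
        chain = [start]
        while True:
            chain.append(cur)
            kids = children[cur]
            if len(kids) != 1:
                break
            cur = kids[0]
        axis = np.array([pos[n] for n in chain])
        cum = cumulative_arclength(axis)
        frac = cum / cum[-1] if cum[-1] > 0 else np.linspace(0, 1, len(cum))
        rr = np.array([radius[n] for n in chain])
        outer = 2.0 * np.interp([0.0, 0.5, 1.0], frac, rr)
        inner = np.maximum(outer - 2.0 * default_wall, 0.2 * outer)
        sid = next_seg
        next_seg += 1
        segments[sid] = Segment(sid, axis, outer, inner, parent=parent_seg)
        for c in sorted(children[cur], reverse=True):
            stack.append((cur, c, sid))
    return segments


def _read_csv_pair(path: Path):
    stem = Path(path)
    nodes_path = stem.with_suffix(".nodes.csv")
    seg_path = stem.with_suffix(".segments.csv")
    if stem.is_dir():
        nodes_path = stem / "nodes.csv"
        seg_path = stem / "segments.csv"
    for p in (nodes_path, seg_path):
        if not p.exists():
            raise FileNotFoundError(p)
    pos: dict[int, np.ndarray] = {}
    with open(nodes_path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    body = [ln for ln in lines if not ln.startswith("#")]
    header = body[0].split(",")
    if header[:3] != ["node_id", "x_um", "y_um"]:
        raise FormatError(f"{nodes_path}: unexpected header {body[0]!r}")
    for lineno, ln in enumerate(body[1:], start=2):
        parts = ln.split(",")
        try:
            pos[int(parts[0])] = np.array([float(parts[1]), float(parts[2])])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{nodes_path}:{lineno}: {exc}") from None
    return VascularNetwork(segments=_segments_from_table(seg_path, pos))
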