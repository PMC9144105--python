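"""Planar polyline geometry shared by the morphometry modules.

All coordinates are micrometres in the orifice-anchored frame (X toward
the apex, Y toward the left ventricle). Axes are (N, 2) float arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_axis",
    "cumulative_arclength",
    "arc_length",
    "chord_length",
    "points_at_arclength",
    "angle_of_deg",
    "angle_between_deg",
    "rotate_deg",
]


def as_axis(points) -> np.ndarray:
    """Coerce a point sequence to an (N, 2) float64 array."""
    axis = np.asarray(points, dtype=float)
    if axis.ndim != 2 or axis.shape[1] != 2:
        raise ValueError(f"axis must be (N, 2), got shape {axis.shape}")
    return axis


def cumulative_arclength(axis: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each vertex, starting at 0."""
    axis = as_axis(axis)
    steps = np.hypot(*np.diff(axis, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(steps)])


def arc_length(axis: np.ndarray) -> float:
    """Total length along the polyline (the 'flow' length)."""
    return float(cumulative_arclength(axis)[-1])


def chord_length(axis: np.ndarray) -> float:
    """Straight-line distance between the first and last vertex."""
    axis = as_axis(axis)
    return float(np.hypot(*(axis[-1] - axis[0])))


def points_at_arclength(axis: np.ndarray, s) -> np.ndarray:
    """Interpolate points on the polyline at arc-length positions ``s``.

    Positions are clipped to [0, total length]. Returns (len(s), 2) for
    array input, (2,) for a scalar.
    """
    axis = as_axis(axis)
    cum = cumulative_arclength(axis)
    s_arr = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, cum[-1])
    out = np.column_stack(
        [np.interp(s_arr, cum, axis[:, 0]), np.interp(s_arr, cum, axis[:, 1])]
    )
    return out[0] if np.isscalar(s) or np.ndim(s) == 0 else out


def angle_of_deg(v) -> float:
    """Angle of a 2-vector versus the +X axis, in degrees in (-180, 180]."""
    v = np.asarray(v, dtype=float)
    if not np.any(v):
        raise ValueError("zero vector has no direction")
    return float(np.degrees(np.arctan2(v[1], v[0])))


def angle_between_deg(u, v) -> float:
    """Unsigned planar angle between two vectors, degrees in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length direction vector")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def rotate_deg(points: np.ndarray, deg: float, about=(0.0, 0.0)) -> np.ndarray:
    """Rotate points counter-clockwise by ``deg`` about a pivot."""
    about = np.asarray(about, dtype=float)
    t = np.radians(deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return (np.asarray(points, dtype=float) - about) @ rot.T + about
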