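"""Planar geometric primitives shared by the simulator and the analysis stages.

All coordinates are in micrometres (um). Networks are collections of straight
segments, so every operation here reduces to exact line/circle or line/grid
intersection arithmetic, vectorised over segments.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotate",
    "unit",
    "signed_angle_deg",
    "clip_segments_to_disk",
    "point_segment_distance",
]


def rotate(v: np.ndarray, theta: float) -> np.ndarray:
    """Rotate 2-vector(s) ``v`` by ``theta`` radians (counter-clockwise)."""
    c, s = np.cos(theta), np.sin(theta)
    v = np.asarray(v, dtype=float)
    return np.stack([c * v[..., 0] - s * v[..., 1], s * v[..., 0] + c * v[..., 1]], axis=-1)


def unit(v: np.ndarray) -> np.ndarray:
    """Normalise a 2-vector; raises on zero input."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def signed_angle_deg(ref: np.ndarray, v: np.ndarray) -> float:
    """Signed angle (degrees, in (-180, 180]) from ``ref`` to ``v``."""
    cross = ref[0] * v[1] - ref[1] * v[0]
    dot = ref[0] * v[0] + ref[1] * v[1]
    ang = np.degrees(np.arctan2(cross, dot))
    # atan2 returns -180 for the antipodal direction; map to +180
    if ang <= -180.0:
        ang = 180.0
    return float(ang)


def clip_segments_to_disk(p0: np.ndarray, p1: np.ndarray, center, radius: float):
    """Exactly clip segments ``p0->p1`` to the disk of ``radius`` around ``center``.

    Returns ``(lengths, t0, t1)`` where ``lengths[i]`` is the arclength of
    segment ``i`` inside the disk and ``(t0, t1)`` the clipped parameter range
    (``t0 >= t1`` meaning no intersection).
    """
    p0 = np.atleast_2d(p0).astype(float)
    p1 = np.atleast_2d(p1).astype(float)
    c = np.asarray(center, dtype=float)
    d = p1 - p0
    f = p0 - c
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", f, d)
    cc = np.einsum("ij,ij->i", f, f) - radius * radius
    disc = b * b - 4.0 * a * cc
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = np.sqrt(np.maximum(disc, 0.0))
        t0 = np.clip((-b - sq) / (2.0 * a), 0.0, 1.0)
        t1 = np.clip((-b + sq) / (2.0 * a), 0.0, 1.0)
    ok = (disc > 0) & (a > 0)
    seglen = np.sqrt(a)
    lengths = np.where(ok, (t1 - t0) * seglen, 0.0)
    lengths = np.maximum(lengths, 0.0)
    return lengths, np.where(ok, t0, 0.0), np.where(ok, t1, 0.0)


def point_segment_distance(p, a: np.ndarray, b: np.ndarray):
    """Distance from point ``p`` to each segment ``a[i]->b[i]``.

    Returns ``(distances, nearest_points)``.
    """
    p = np.asarray(p, dtype=float)
    a = np.atleast_2d(a).astype(float)
    b = np.atleast_2d(b).astype(float)
    d = b - a
    denom = np.einsum("ij,ij->i", d, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("ij,j->i", d, p) - np.einsum("ij,ij->i", d, a)
        t = np.where(denom > 0, t / np.where(denom > 0, denom, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    nearest = a + t[:, None] * d
    dist = np.linalg.norm(nearest - p, axis=1)
    return dist, nearest
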