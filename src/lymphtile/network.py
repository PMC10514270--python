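"""Core domain types: vessel networks, growing tips, the tissue domain.

A :class:`VesselNetwork` is a planar geometric graph: nodes carry coordinates
in micrometres, segments are straight edges between nodes.  The simulator
builds networks one elongation step at a time; the analysis path constructs
them from skeleton files.  Segments are never deleted -- pruning marks them
dead (``alive=False``), mirroring the empty basement-membrane "sleeves" that
regressed vessels leave behind.

Cell-level bookkeeping for lineage tracing lives in :class:`ParticleTable`:
particles are cells positioned along segments (stored as a fraction of the
segment so that uniform tissue dilation moves them for free), each with a
parent pointer that records its full genealogy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import clip_segments_to_disk

__all__ = [
    "VesselNetwork",
    "Tip",
    "DomainGeometry",
    "ParticleTable",
    "segment_length",
    "local_density",
]


@dataclass
class Tip:
    """An active growing end of a vessel.

    ``state`` is 'active' or 'terminated'; ``fate`` records why a terminated
    tip stopped ('annihilated', 'boundary', 'branched', or None while active).
    ``particle`` is the id of the leading cell (the most recently deposited
    particle of this tip), used for clonal label inheritance.  ``n_steps``
    counts elongation steps taken since birth.
    """

    id: int
    node: int
    heading: np.ndarray
    speed: float
    birth_time: float
    state: str = "active"
    fate: str | None = None
    particle: int = -1
    tree: int = 0
    n_steps: int = 0
    parent_tip: int = -1  # tip this one split off from (-1 for seeds/sprouts)

    def __post_init__(self):
        self.heading = np.asarray(self.heading, dtype=float)
        n = np.linalg.norm(self.heading)
        if not np.isfinite(n) or n == 0:
            raise ValueError("tip heading must be a finite nonzero vector")
        self.heading = self.heading / n


@dataclass
class DomainGeometry:
    """Half-disk tissue domain growing linearly in time.

    The flat edge lies on y = 0 with the stalk base at the origin; tissue
    occupies y >= 0.  The radius grows as R(t) = radius0 + growth_rate * t,
    emulating the linear expansion of the ear pinna over the developmental
    window (t = 0 corresponds to P4).
    """

    radius0: float = 2000.0
    growth_rate: float = 180.0

    def radius(self, t: float) -> float:
        return self.radius0 + self.growth_rate * t

    def area(self, t: float) -> float:
        r = self.radius(t)
        return 0.5 * np.pi * r * r

    def contains(self, points: np.ndarray, t: float, margin: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside the half-disk at time ``t``."""
        pts = np.atleast_2d(points)
        r = self.radius(t) - margin
        inside = (pts[:, 1] >= -1e-9) & (np.einsum("ij,ij->i", pts, pts) <= r * r)
        return inside if points is not pts or pts.ndim > 1 else inside


class ParticleTable:
    """Cells along ducts: position (segment + fraction), label, genealogy."""

    def __init__(self):
        self.seg: list[int] = []
        self.frac: list[float] = []
        self.parent: list[int] = []
        self.birth: list[float] = []
        self.clone: list[int] = []  # id of founding labeled particle, -1 unlabeled
        self.color: list[int] = []  # -1 unlabeled

    def __len__(self) -> int:
        return len(self.seg)

    def add(self, seg: int, frac: float, parent: int, birth: float,
            clone: int = -1, color: int = -1) -> int:
        pid = len(self.seg)
        self.seg.append(seg)
        self.frac.append(float(frac))
        self.parent.append(parent)
        self.birth.append(float(birth))
        self.clone.append(clone)
        self.color.append(color)
        return pid


class _Buf:
    """Amortised-growth numpy buffer."""

    def __init__(self, shape_tail=(), dtype=float, cap=64):
        self._arr = np.empty((cap,) + shape_tail, dtype=dtype)
        self.n = 0

    def append(self, value) -> int:
        if self.n == len(self._arr):
            grown = np.empty((2 * len(self._arr),) + self._arr.shape[1:], self._arr.dtype)
            grown[: self.n] = self._arr
            self._arr = grown
        self._arr[self.n] = value
        self.n += 1
        return self.n - 1

    @property
    def view(self) -> np.ndarray:
        return self._arr[: self.n]


class VesselNetwork:
    """Planar geometric graph of vessel nodes and segments.

    Node coordinates are um; segments carry a creation time (days), an alive
    flag, the id of the tree (connected component seeded at t = 0) and the id
    of the tip that laid them down (-1 for file-loaded networks).
    """

    def __init__(self):
        self._xy = _Buf((2,), float)
        self._seg = _Buf((2,), np.int64)
        self._seg_birth = _Buf((), float)
        self._seg_alive = _Buf((), bool)
        self._seg_tree = _Buf((), np.int64)
        self._seg_tip = _Buf((), np.int64)
        self._seg_len = _Buf((), float)  # cached lengths, synced on dilation
        self.tips: list[Tip] = []
        self.particles = ParticleTable()
        self.seg_particles: list[list[int]] = []
        # adjacency: node -> [(segment id, neighbor node), ...]
        self.node_segments: list[list[tuple[int, int]]] = []

    # -- construction -------------------------------------------------------

    @classmethod
    def from_arrays(cls, coords, edges, alive=None, tree=None, birth=None) -> "VesselNetwork":
        net = cls()
        coords = np.asarray(coords, dtype=float)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite node coordinate")
        for xy in coords:
            net.add_node(xy)
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        seen = set()
        for i, (a, b) in enumerate(edges):
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError(f"duplicate edge {a}-{b}")
            seen.add(key)
            net.add_segment(
                int(a), int(b),
                birth=0.0 if birth is None else float(birth[i]),
                tree=0 if tree is None else int(tree[i]),
                alive=True if alive is None else bool(alive[i]),
            )
        return net

    def add_node(self, xy) -> int:
        xy = np.asarray(xy, dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("non-finite node coordinate")
        self.node_segments.append([])
        return self._xy.append(xy)

    def add_segment(self, a: int, b: int, birth: float = 0.0, tree: int = 0,
                    tip: int = -1, alive: bool = True) -> int:
        n = self.n_nodes
        if not (0 <= a < n and 0 <= b < n):
            raise KeyError(f"segment references unknown node ({a}, {b})")
        if a == b:
            raise ValueError("segment endpoints must differ")
        ca, cb = self.coords[a], self.coords[b]
        length = float(np.hypot(ca[0] - cb[0], ca[1] - cb[1]))
        if length < 1e-9:
            raise ValueError("zero-length segment rejected")
        sid = self._seg.append((a, b))
        self._seg_len.append(length)
        self._seg_birth.append(birth)
        self._seg_alive.append(alive)
        self._seg_tree.append(tree)
        self._seg_tip.append(tip)
        self.seg_particles.append([])
        self.node_segments[a].append((sid, b))
        self.node_segments[b].append((sid, a))
        return sid

    def split_segment(self, sid: int, frac: float) -> tuple[int, int, int]:
        """Split segment ``sid`` at parameter ``frac`` in (0, 1).

        Returns ``(new_node, left_sid, right_sid)``; ``left_sid == sid`` keeps
        the original id for the half adjacent to the original first endpoint.
        Particles on the segment are reassigned to the proper half.
        """
        if not 0.0 < frac < 1.0:
            raise ValueError("split fraction must be in (0, 1)")
        a, b = self._seg.view[sid]
        pa, pb = self.coords[a], self.coords[b]
        a, b = int(a), int(b)
        new_node = self.add_node(pa + frac * (pb - pa))
        self._seg.view[sid] = (a, new_node)
        self._seg_len.view[sid] *= frac
        self.node_segments[a] = [
            (s, new_node if s == sid else n) for s, n in self.node_segments[a]
        ]
        self.node_segments[b] = [
            (s, n) for s, n in self.node_segments[b] if s != sid
        ]
        self.node_segments[new_node].append((sid, a))
        right = self.add_segment(
            new_node, int(b),
            birth=float(self._seg_birth.view[sid]),
            tree=int(self._seg_tree.view[sid]),
            tip=int(self._seg_tip.view[sid]),
            alive=bool(self._seg_alive.view[sid]),
        )
        old = self.seg_particles[sid]
        left_list, right_list = [], []
        P = self.particles
        for pid in old:
            f = P.frac[pid]
            if f <= frac:
                P.frac[pid] = f / frac
                left_list.append(pid)
            else:
                P.seg[pid] = right
                P.frac[pid] = (f - frac) / (1.0 - frac)
                right_list.append(pid)
        self.seg_particles[sid] = left_list
        self.seg_particles[right] = right_list
        return new_node, sid, right

    def copy(self, with_particles: bool = False) -> "VesselNetwork":
        net = VesselNetwork.__new__(VesselNetwork)
        for name in ("_xy", "_seg", "_seg_birth", "_seg_alive", "_seg_tree",
                     "_seg_tip", "_seg_len"):
            src = getattr(self, name)
            buf = _Buf.__new__(_Buf)
            buf._arr = src.view.copy()
            buf.n = src.n
            setattr(net, name, buf)
        net.tips = []
        net.particles = ParticleTable()
        net.seg_particles = [[] for _ in range(self.n_segments)]
        net.node_segments = [list(l) for l in self.node_segments]
        if with_particles:
            import copy as _copy

            net.particles = _copy.deepcopy(self.particles)
            net.seg_particles = [list(l) for l in self.seg_particles]
        return net

    # -- views --------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self._xy.n

    @property
    def n_segments(self) -> int:
        return self._seg.n

    @property
    def coords(self) -> np.ndarray:
        return self._xy.view

    @property
    def segments(self) -> np.ndarray:
        return self._seg.view

    @property
    def seg_birth(self) -> np.ndarray:
        return self._seg_birth.view

    @property
    def seg_alive(self) -> np.ndarray:
        return self._seg_alive.view

    @property
    def seg_tree(self) -> np.ndarray:
        return self._seg_tree.view

    @property
    def seg_tip(self) -> np.ndarray:
        return self._seg_tip.view

    def endpoints(self, alive_only: bool = True):
        seg = self.segments
        if alive_only:
            seg = seg[self.seg_alive]
        return self.coords[seg[:, 0]], self.coords[seg[:, 1]]

    def segment_lengths(self, alive_only: bool = True) -> np.ndarray:
        p0, p1 = self.endpoints(alive_only)
        return np.linalg.norm(p1 - p0, axis=1)

    def total_length(self, alive_only: bool = True) -> float:
        return float(self.segment_lengths(alive_only).sum())

    def degrees(self, alive_only: bool = True) -> np.ndarray:
        seg = self.segments
        if alive_only:
            seg = seg[self.seg_alive]
        return np.bincount(seg.ravel(), minlength=self.n_nodes)

    def segment_length(self, sid: int) -> float:
        if not 0 <= sid < self.n_segments:
            raise KeyError(f"unknown segment id {sid}")
        return float(self._seg_len.view[sid])

    # -- geometry -----------------------------------------------------------

    def local_density(self, point, radius: float, alive_only: bool = True,
                      exclude_segments=None) -> float:
        """Vessel length per unit area inside the disk of ``radius`` at ``point``.

        Segments are clipped exactly to the disk (line/circle intersection);
        ``exclude_segments`` is an optional set/array of segment ids left out
        (used, e.g., to exclude a sprout's own segments).
        """
        if radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_segments == 0:
            return 0.0
        mask = self.seg_alive.copy() if alive_only else np.ones(self.n_segments, bool)
        if exclude_segments is not None:
            mask[np.fromiter(exclude_segments, dtype=np.int64, count=-1)] = False
        seg = self.segments[mask]
        if seg.size == 0:
            return 0.0
        p0, p1 = self.coords[seg[:, 0]], self.coords[seg[:, 1]]
        lengths, _, _ = clip_segments_to_disk(p0, p1, point, radius)
        return float(lengths.sum() / (np.pi * radius * radius))


def segment_length(network: VesselNetwork, segment_id: int) -> float:
    """Euclidean length (um) of one segment."""
    return network.segment_length(segment_id)


def local_density(network: VesselNetwork, point, radius: float, **kw) -> float:
    """Vessel arclength per um^2 within the disk of ``radius`` around ``point``."""
    return network.local_density(point, radius, **kw)
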