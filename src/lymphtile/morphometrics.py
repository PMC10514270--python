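"""Network statistics: density fluctuations, branch lengths, alignment, angles.

The central quantity is the spatial density-fluctuation exponent alpha: the
plane is tiled with non-overlapping square windows of side L, the vessel
arclength ("mass") inside each fully interior window is measured exactly, and
alpha is the least-squares slope of log SD(mass) against log mean(mass)
across window scales.  alpha = 0.5 is the equilibrium (Poisson) value,
alpha = 1 the maximum; values above 0.5 signal "giant" density fluctuations,
i.e., poor space-filling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .network import DomainGeometry, VesselNetwork

__all__ = [
    "FluctuationResult",
    "branches",
    "segment_statistics",
    "window_masses",
    "fluctuation_exponent",
    "fit_fluctuation_exponent",
    "branch_length_distribution",
    "nematic_order",
    "classify_branch_nodes",
]


# ---------------------------------------------------------------------------
# degree-2 contraction: branches = maximal paths between nodes of degree != 2


def branches(network: VesselNetwork, alive_only: bool = True):
    """Maximal paths between nodes of degree != 2 ("branches"/"segments"
    in the morphological sense, after contracting polyline vertices).

    Returns a list of dicts with keys ``nodes`` (node-id path), ``length``
    (um) and ``segments`` (underlying segment ids).
    """
    net = network
    seg_ids = np.flatnonzero(net.seg_alive) if alive_only else np.arange(net.n_segments)
    if len(seg_ids) == 0:
        return []
    deg = np.zeros(net.n_nodes, dtype=np.int64)
    adj: dict[int, list[int]] = {}
    for sid in seg_ids:
        a, b = (int(v) for v in net.segments[sid])
        deg[a] += 1
        deg[b] += 1
        adj.setdefault(a, []).append(sid)
        adj.setdefault(b, []).append(sid)
    coords = net.coords
    seen = np.zeros(net.n_segments, dtype=bool)
    out = []

    def walk(start_node: int, sid: int):
        path = [start_node]
        segs = []
        node = start_node
        while True:
            seen[sid] = True
            segs.append(sid)
            a, b = (int(v) for v in net.segments[sid])
            node = b if a == node else a
            path.append(node)
            if deg[node] != 2:
                break
            nxt = [s for s in adj[node] if not seen[s]]
            if not nxt:
                break
            sid = nxt[0]
        pts = coords[path]
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        out.append({"nodes": path, "segments": segs, "length": length})

    for v in np.flatnonzero(deg != 2):
        for sid in adj.get(int(v), []):
            if not seen[sid]:
                walk(int(v), sid)
    # isolated cycles (degree-2 everywhere) -- not produced by the simulator
    for sid in seg_ids:
        if not seen[sid]:
            walk(int(net.segments[sid][0]), sid)
    return out


def segment_statistics(network: VesselNetwork) -> dict:
    """Counts and lengths of morphological segments (degree-2 contracted)."""
    br = branches(network)
    if not br:
        return {"empty": True, "segment_count": 0, "mean_length": np.nan,
                "median_length": np.nan, "total_length": 0.0}
    lengths = np.array([b["length"] for b in br])
    return {
        "empty": False,
        "segment_count": len(lengths),
        "mean_length": float(lengths.mean()),
        "median_length": float(np.median(lengths)),
        "total_length": float(lengths.sum()),
    }


# ---------------------------------------------------------------------------
# windowed masses and the fluctuation exponent


def _grid_masses(p0: np.ndarray, p1: np.ndarray, L: float, x0: float, y0: float,
                 nx: int, ny: int) -> np.ndarray:
    """Exact arclength of each segment apportioned to cells of an L-grid."""
    masses = np.zeros((nx, ny))
    for a, b in zip(p0, p1):
        d = b - a
        seglen = float(np.hypot(*d))
        if seglen == 0:
            continue
        ts = [0.0, 1.0]
        for axis, lo, n in ((0, x0, nx), (1, y0, ny)):
            if d[axis] != 0.0:
                k0 = int(np.floor((min(a[axis], b[axis]) - lo) / L)) + 1
                k1 = int(np.floor((max(a[axis], b[axis]) - lo) / L))
                for k in range(k0, k1 + 1):
                    t = (lo + k * L - a[axis]) / d[axis]
                    if 0.0 < t < 1.0:
                        ts.append(float(t))
        ts = sorted(set(ts))
        for t_lo, t_hi in zip(ts[:-1], ts[1:]):
            mid = a + 0.5 * (t_lo + t_hi) * d
            ix = int(np.floor((mid[0] - x0) / L))
            iy = int(np.floor((mid[1] - y0) / L))
            if 0 <= ix < nx and 0 <= iy < ny:
                masses[ix, iy] += (t_hi - t_lo) * seglen
    return masses


def window_masses(network: VesselNetwork, domain: DomainGeometry | None, L: float,
                  t: float = 0.0) -> np.ndarray:
    """Vessel mass (um) per fully interior non-overlapping square window.

    The plane is tiled with axis-aligned squares of side ``L`` anchored at the
    domain origin; windows not entirely inside the domain are discarded (no
    boundary renormalisation).  With ``domain=None`` the network bounding box
    is used as the domain.
    """
    if L <= 0:
        raise ValueError("window side L must be positive")
    p0, p1 = network.endpoints(alive_only=True)
    if domain is None:
        if len(p0) == 0:
            return np.empty(0)
        allpts = np.vstack([p0, p1])
        xmin, ymin = allpts.min(axis=0)
        xmax, ymax = allpts.max(axis=0)
        x0, y0 = xmin, ymin
        nx = max(int(np.floor((xmax - xmin) / L)), 0)
        ny = max(int(np.floor((ymax - ymin) / L)), 0)
        if nx == 0 or ny == 0:
            return np.empty(0)
        interior = np.ones((nx, ny), dtype=bool)
    else:
        R = domain.radius(t)
        x0, y0 = -R, 0.0
        nx = ny = int(np.ceil(2 * R / L))
        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        cx = x0 + ix * L
        cy = y0 + iy * L
        # half-disk is convex: a window is interior iff its 4 corners are
        corners_ok = np.ones((nx, ny), dtype=bool)
        for dx in (0.0, L):
            for dy in (0.0, L):
                px, py = cx + dx, cy + dy
                corners_ok &= (py >= -1e-9) & (px * px + py * py <= R * R + 1e-6)
        interior = corners_ok
    if len(p0) == 0:
        return np.zeros(int(interior.sum()))
    masses = _grid_masses(p0, p1, L, x0, y0, nx, ny)
    return masses[interior]


@dataclass
class FluctuationResult:
    """Density-fluctuation exponent alpha with its fit diagnostics."""

    window_sides: np.ndarray     # L (um)
    means: np.ndarray            # mean window mass per L (um)
    sds: np.ndarray              # SD of window mass per L (um)
    n_windows: np.ndarray
    alpha: float                 # slope of log SD vs log mean
    stderr: float

    def __repr__(self):
        return (f"FluctuationResult(alpha={self.alpha:.3f} +/- {self.stderr:.3f}, "
                f"scales={len(self.window_sides)})")


def fit_fluctuation_exponent(masses_by_L: dict) -> FluctuationResult:
    """Fit alpha from per-scale window-mass tables.

    ``masses_by_L`` maps window side L to the array of window masses at that
    scale.  Scales with zero mean or zero SD are rejected.
    """
    Ls, means, sds, ns = [], [], [], []
    for L in sorted(masses_by_L):
        m = np.asarray(masses_by_L[L], dtype=float)
        mu, sd = m.mean(), m.std()
        if mu <= 0 or sd <= 0:
            raise ValueError(f"degenerate window masses at L={L}")
        Ls.append(L)
        means.append(mu)
        sds.append(sd)
        ns.append(len(m))
    if len(Ls) < 3:
        raise ValueError("need at least 3 window scales to fit the exponent")
    fit = stats.linregress(np.log(means), np.log(sds))
    return FluctuationResult(
        window_sides=np.array(Ls), means=np.array(means), sds=np.array(sds),
        n_windows=np.array(ns), alpha=float(fit.slope), stderr=float(fit.stderr),
    )


def fluctuation_exponent(network: VesselNetwork, domain: DomainGeometry | None,
                         L_list, t: float = 0.0,
                         min_windows: int = 20) -> FluctuationResult:
    """Density-fluctuation exponent of a network over window sides ``L_list``."""
    masses = {}
    for L in L_list:
        m = window_masses(network, domain, L, t=t)
        if len(m) < min_windows:
            raise ValueError(
                f"only {len(m)} fully interior windows at L={L} "
                f"(need >= {min_windows})"
            )
        masses[L] = m
    return fit_fluctuation_exponent(masses)


# ---------------------------------------------------------------------------
# branch-length distribution


@dataclass
class BranchLengthFit:
    lengths: np.ndarray
    threshold: float
    rate: float                  # exponential tail rate lambda (um^-1)
    rate_ci: tuple
    n_tail: int
    gof_pvalue: float
    degenerate: bool
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def branch_length_distribution(network_or_lengths, threshold: float | None = None,
                               bins: int = 30) -> BranchLengthFit:
    """Empirical branch-length distribution and ML exponential-tail fit.

    The tail rate is fitted by maximum likelihood over lengths above
    ``threshold`` (default: the median), lambda = 1 / mean(x - threshold).
    A Kolmogorov-Smirnov statistic against the fitted exponential provides a
    goodness-of-fit p-value; constant lengths are flagged degenerate.
    """
    if isinstance(network_or_lengths, VesselNetwork):
        lengths = np.array([b["length"] for b in branches(network_or_lengths)])
    else:
        lengths = np.asarray(network_or_lengths, dtype=float)
    if len(lengths) < 50:
        raise ValueError(f"need >= 50 branch lengths, got {len(lengths)}")
    if threshold is None:
        threshold = float(np.median(lengths))
    tail = lengths[lengths > threshold] - threshold
    counts, edges = np.histogram(lengths, bins=bins)
    if len(tail) < 10 or tail.std() == 0:
        return BranchLengthFit(lengths, threshold, np.nan, (np.nan, np.nan),
                               len(tail), np.nan, True, counts, edges)
    rate = 1.0 / tail.mean()
    half = 1.96 / np.sqrt(len(tail))
    ci = (rate * (1 - half), rate * (1 + half))
    gof = stats.kstest(tail, "expon", args=(0, 1.0 / rate)).pvalue
    return BranchLengthFit(lengths, threshold, float(rate), ci, len(tail),
                           float(gof), False, counts, edges)


# ---------------------------------------------------------------------------
# nematic order


def nematic_order(network: VesselNetwork, r: float) -> float | None:
    """Nematic order parameter S(r) = <cos 2(theta_i - theta_j)> over segment
    pairs whose midpoints lie within distance ``r``.

    Orientations are taken mod 180 deg.  Returns None when no pair is in
    range.  S = 1 for perfectly aligned networks, 0 for isotropic ones.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    p0, p1 = network.endpoints(alive_only=True)
    if len(p0) < 2:
        return None
    mid = 0.5 * (p0 + p1)
    theta = np.arctan2(p1[:, 1] - p0[:, 1], p1[:, 0] - p0[:, 0])
    tree = cKDTree(mid)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if len(pairs) == 0:
        return None
    dtheta = theta[pairs[:, 0]] - theta[pairs[:, 1]]
    return float(np.cos(2.0 * dtheta).mean())


# ---------------------------------------------------------------------------
# lateral vs fork classification of branch nodes


def _arm_direction(net: VesselNetwork, adj: dict, deg: np.ndarray, node: int,
                   first_sid: int, arm_length: float) -> np.ndarray:
    """Length-weighted mean tangent over the first ``arm_length`` um of an arm."""
    coords = net.coords
    acc = np.zeros(2)
    remaining = arm_length
    cur = node
    sid = first_sid
    visited = set()
    while remaining > 0 and sid not in visited:
        visited.add(sid)
        a, b = (int(v) for v in net.segments[sid])
        nxt = b if a == cur else a
        vec = coords[nxt] - coords[cur]
        seglen = float(np.linalg.norm(vec))
        if seglen == 0:
            break
        use = min(seglen, remaining)
        acc += vec / seglen * use
        remaining -= use
        cur = nxt
        if deg[cur] != 2 or remaining <= 0:
            break
        cand = [s for s in adj[cur] if s != sid and net.seg_alive[s]]
        if len(cand) != 1:
            break
        sid = cand[0]
    n = np.linalg.norm(acc)
    return acc / n if n > 0 else acc


def classify_branch_nodes(network: VesselNetwork, arm_length: float = 20.0,
                          lateral_threshold: float = 165.0):
    """Classify degree-3 branch nodes as lateral (side-branch-like) or fork.

    At each degree-3 node the three outgoing tangent directions, each averaged
    over ``arm_length`` um of arc, define three pairwise angles; the largest
    ("through" angle) is compared with ``lateral_threshold`` (degrees): a
    nearly straight through-path (large angle) indicates a lateral branch off
    a continuing duct, a symmetric splay indicates a fork-like bifurcation.

    Returns ``(records, fraction_lateral)`` where ``records`` is a list of
    dicts with node id, through angle (deg) and class.  Nodes of alive degree
    other than 3 are skipped.
    """
    if arm_length <= 0:
        raise ValueError("arm_length must be positive")
    net = network
    deg = net.degrees(alive_only=True)
    adj: dict[int, list[int]] = {}
    for sid in np.flatnonzero(net.seg_alive):
        a, b = (int(v) for v in net.segments[sid])
        adj.setdefault(a, []).append(sid)
        adj.setdefault(b, []).append(sid)
    records = []
    for v in np.flatnonzero(deg == 3):
        v = int(v)
        arms = [_arm_direction(net, adj, deg, v, sid, arm_length) for sid in adj[v]]
        if any(np.linalg.norm(a) == 0 for a in arms):
            continue
        angles = []
        for i in range(3):
            for j in range(i + 1, 3):
                c = float(np.clip(arms[i] @ arms[j], -1.0, 1.0))
                angles.append(np.degrees(np.arccos(c)))
        theta_through = max(angles)
        records.append({
            "node": v,
            "theta_through": float(theta_through),
            "class": "lateral" if theta_through >= lateral_threshold else "fork",
        })
    frac = (np.mean([r["class"] == "lateral" for r in records])
            if records else np.nan)
    return records, float(frac)
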