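"""Density-sensing signatures around nascent side branches.

A nascent sprout is summarised by its root (on the parent duct) and the unit
vector u from the root to its terminal tip.  Three metrics quantify whether
sprouts target low-density territory:

* the ratio of the isotropic vessel density rho_s around sprout roots to the
  density rho_r around random points on the network, as a function of the
  probe radius R;
* the distribution of signed angles psi between neighboring segments
  (position relative to the root) and u;
* the front/back ratio P(|psi| < 45 deg) / P(|psi| > 135 deg).

Neighboring vessel material is weighted by the exact arclength of each
segment clipped to the probe disk, and positions are taken at the midpoint of
the clipped portion, which makes all metrics invariant to re-sampling of
polylines.  A sprout's own segments (root to terminal tip) are excluded from
its neighborhood; the parent duct is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import clip_segments_to_disk, signed_angle_deg
from .network import VesselNetwork
from .simulator import SimResult

__all__ = [
    "Sprout",
    "sprout_vector",
    "sprouts_from_events",
    "sprouts_from_annotations",
    "isotropic_density_ratio",
    "angle_distribution",
    "front_back_ratio",
    "random_network_points",
]


@dataclass
class Sprout:
    """A nascent side branch: root on the parent duct, terminal tip."""

    root_node: int
    tip_node: int
    root: np.ndarray = None
    direction: np.ndarray = None          # unit vector root -> tip
    own_segments: frozenset = field(default_factory=frozenset)


def sprout_vector(network: VesselNetwork, root_node: int, tip_node: int) -> np.ndarray:
    """Unit vector from the sprout root to its terminal tip."""
    for nid in (root_node, tip_node):
        if not 0 <= nid < network.n_nodes:
            raise KeyError(f"unknown node id {nid}")
    v = network.coords[tip_node] - network.coords[root_node]
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("sprout root and tip coincide")
    return v / n


def sprouts_from_events(result: SimResult, window: float | None = None,
                        min_steps: int = 2, at_time: float | None = None,
                        network: VesselNetwork | None = None) -> list[Sprout]:
    """Collect nascent sprouts from a simulation's event log.

    ``window`` keeps only side branches created within the last ``window``
    days before the observation time (None keeps all); sprouts whose tip laid
    fewer than ``min_steps`` segments are dropped (no direction yet).  The
    sprout's own segments are those created by its tip.

    With ``at_time``/``network`` (a snapshot time and the matching snapshot)
    sprouts are reconstructed as they existed at that time -- the natural
    analog of annotating nascent sprouts in an image taken mid-development.
    """
    net = network if network is not None else result.network
    t_ref = result.final_time if at_time is None else at_time
    n_seg = net.n_segments
    seg_tip = net.seg_tip
    # tip genealogy (from the full run; tip ids are stable across snapshots)
    children: dict[int, list[int]] = {}
    for tp in result.network.tips:
        if tp.parent_tip >= 0:
            children.setdefault(tp.parent_tip, []).append(tp.id)
    out = []
    for (time, event, tip_id, node, _x, _y) in result.events:
        if event != "side_branch":
            continue
        if time > t_ref or (window is not None and time < t_ref - window):
            continue
        # the sprout comprises its tip and all descendant tips (a nascent
        # sprout that has already split still counts once, root to the
        # farthest terminal tip)
        own_tips = {tip_id}
        frontier = [tip_id]
        while frontier:
            tid = frontier.pop()
            for ch in children.get(tid, []):
                if ch not in own_tips:
                    own_tips.add(ch)
                    frontier.append(ch)
        own = np.flatnonzero(np.isin(seg_tip[:n_seg], list(own_tips)))
        if len(own) < min_steps:
            continue
        # terminal tip = the endpoint of the sprout's own subgraph that is
        # farthest from the root among nodes of own-degree 1
        ends, counts = np.unique(net.segments[own].ravel(), return_counts=True)
        leaves = [int(v) for v, c in zip(ends, counts) if c == 1 and v != node]
        if not leaves:
            continue
        root_xy = net.coords[node]
        tip_node = max(leaves, key=lambda v: np.linalg.norm(net.coords[v] - root_xy))
        try:
            u = sprout_vector(net, node, tip_node)
        except ValueError:
            continue
        out.append(Sprout(
            root_node=node, tip_node=tip_node, root=root_xy.copy(),
            direction=u, own_segments=frozenset(int(s) for s in own),
        ))
    return out


def nascent_sprout_density_timecourse(result: SimResult, R: float,
                                      window: float = 1.0,
                                      n_random: int = 300, rng=None,
                                      n_boot: int = 200,
                                      min_sprouts: int = 1) -> dict:
    """Pool rho_s / rho_r over snapshots, scoring each nascent sprout in the
    network state in which it is nascent.

    For every stored snapshot, sprouts created within the last ``window``
    days are measured against that snapshot (own segments excluded) together
    with ``n_random`` arclength-uniform reference points; densities are
    pooled over snapshots and the ratio of means is bootstrapped over
    sprouts.  This mirrors annotating fresh side branches in each image of a
    developmental series.
    """
    if not result.snapshots:
        raise ValueError("run has no snapshots; set snapshot_times in the config")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    area = np.pi * R * R
    rho_s, rho_r = [], []
    n_sprouts = 0
    for tk in sorted(result.snapshots):
        snap = result.snapshots[tk]
        sprouts = sprouts_from_events(result, window=window, at_time=tk,
                                      network=snap)
        if len(sprouts) < min_sprouts:
            continue
        n_sprouts += len(sprouts)
        for s in sprouts:
            rho_s.append(
                _neighbor_weights(snap, s.root, R, s.own_segments)[1].sum() / area
            )
        for p in random_network_points(snap, n_random, rng):
            rho_r.append(_neighbor_weights(snap, p, R)[1].sum() / area)
    if not rho_s:
        raise ValueError("no nascent sprouts found in any snapshot")
    rho_s = np.asarray(rho_s)
    rho_r = np.asarray(rho_r)
    ratio = rho_s.mean() / rho_r.mean()
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bs = rng.integers(0, len(rho_s), len(rho_s))
        br = rng.integers(0, len(rho_r), len(rho_r))
        boots[i] = rho_s[bs].mean() / rho_r[br].mean()
    return {"ratio": float(ratio), "boot_sd": float(boots.std()),
            "n_sprouts": n_sprouts, "R": R,
            "rho_s": rho_s, "rho_r": rho_r}


def sprouts_from_annotations(network: VesselNetwork, table) -> list[Sprout]:
    """Build sprouts from an annotation table of (root_node_id, tip_node_id).

    The own-segment set is the path from root to tip in the alive graph.
    """
    import networkx as nx

    g = nx.Graph()
    for sid in np.flatnonzero(network.seg_alive):
        a, b = (int(v) for v in network.segments[sid])
        g.add_edge(a, b, sid=int(sid))
    out = []
    for root, tipn in table:
        u = sprout_vector(network, int(root), int(tipn))
        path = nx.shortest_path(g, int(root), int(tipn))
        own = frozenset(
            g.edges[a, b]["sid"] for a, b in zip(path[:-1], path[1:])
        )
        out.append(Sprout(
            root_node=int(root), tip_node=int(tipn),
            root=network.coords[int(root)].copy(), direction=u,
            own_segments=own,
        ))
    return out


# ---------------------------------------------------------------------------


def random_network_points(network: VesselNetwork, n: int, rng) -> np.ndarray:
    """Points sampled uniformly by arclength on the alive network."""
    p0, p1 = network.endpoints(alive_only=True)
    lens = np.linalg.norm(p1 - p0, axis=1)
    total = lens.sum()
    if total == 0:
        raise ValueError("empty network")
    u = rng.uniform(0.0, total, n)
    cum = np.cumsum(lens)
    j = np.minimum(np.searchsorted(cum, u), len(lens) - 1)
    frac = (u - (cum[j] - lens[j])) / lens[j]
    return p0[j] + frac[:, None] * (p1[j] - p0[j])


def _neighbor_weights(network: VesselNetwork, point, R: float,
                      exclude: frozenset = frozenset()):
    """Clipped-midpoint positions and clipped-length weights of neighbors."""
    alive = network.seg_alive.copy()
    if exclude:
        alive[list(exclude)] = False
    seg = network.segments[alive]
    if len(seg) == 0:
        return np.empty((0, 2)), np.empty(0)
    p0 = network.coords[seg[:, 0]]
    p1 = network.coords[seg[:, 1]]
    lengths, t0, t1 = clip_segments_to_disk(p0, p1, point, R)
    keep = lengths > 0
    tm = 0.5 * (t0[keep] + t1[keep])
    mids = p0[keep] + tm[:, None] * (p1[keep] - p0[keep])
    return mids, lengths[keep]


def isotropic_density_ratio(network: VesselNetwork, sprouts: list[Sprout],
                            R: float, n_random: int = 1000, rng=None,
                            n_boot: int = 200) -> dict:
    """mean rho_s / mean rho_r with a bootstrap SD over sprouts.

    rho_s is the vessel density (um arclength per um^2, exact clipping) in
    the disk of radius ``R`` around each sprout root, excluding the sprout's
    own segments; rho_r is the density around ``n_random`` points sampled
    uniformly by arclength on the network (nothing excluded).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if not sprouts:
        raise ValueError("empty sprout list")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    area = np.pi * R * R
    rho_s = np.array([
        _neighbor_weights(network, s.root, R, s.own_segments)[1].sum() / area
        for s in sprouts
    ])
    pts = random_network_points(network, n_random, rng)
    rho_r = np.array([
        _neighbor_weights(network, p, R)[1].sum() / area for p in pts
    ])
    ratio = rho_s.mean() / rho_r.mean()
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bs = rng.integers(0, len(rho_s), len(rho_s))
        br = rng.integers(0, len(rho_r), len(rho_r))
        boots[i] = rho_s[bs].mean() / rho_r[br].mean()
    return {
        "ratio": float(ratio),
        "boot_sd": float(boots.std()),
        "rho_s": rho_s,
        "rho_r": rho_r,
        "R": R,
        "n_sprouts": len(sprouts),
    }


def _psi_masses(network: VesselNetwork, point, direction, R: float,
                exclude: frozenset = frozenset()):
    """Signed angles psi (deg) and arclength weights of neighbors in the disk."""
    mids, weights = _neighbor_weights(network, point, R, exclude)
    psis = np.array([
        signed_angle_deg(direction, m - point) for m in mids
    ]) if len(mids) else np.empty(0)
    return psis, weights


def angle_distribution(network: VesselNetwork, sprouts: list[Sprout], R: float,
                       bin_width: float = 30.0, n_null: int = 0, rng=None) -> dict:
    """Length-weighted relative frequencies of psi in ``bin_width``-deg bins.

    With ``n_null > 0`` a matched null is computed at random network points
    with reference directions drawn uniformly on the circle.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    edges = np.arange(-180.0, 180.0 + 0.5 * bin_width, bin_width)
    psis, ws = [], []
    for s in sprouts:
        p, w = _psi_masses(network, s.root, s.direction, R, s.own_segments)
        psis.append(p)
        ws.append(w)
    psis = np.concatenate(psis) if psis else np.empty(0)
    ws = np.concatenate(ws) if ws else np.empty(0)
    out = {"edges": edges, "R": R, "empty": len(psis) == 0}
    if len(psis):
        h, _ = np.histogram(psis, bins=edges, weights=ws)
        out["freq"] = h / h.sum()
    else:
        out["freq"] = np.zeros(len(edges) - 1)
    if n_null > 0:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        pts = random_network_points(network, n_null, rng)
        angs = rng.uniform(0.0, 2.0 * np.pi, n_null)
        dirs = np.stack([np.cos(angs), np.sin(angs)], axis=1)
        np_psis, np_ws = [], []
        for p, d in zip(pts, dirs):
            a, w = _psi_masses(network, p, d, R)
            np_psis.append(a)
            np_ws.append(w)
        np_psis = np.concatenate(np_psis)
        np_ws = np.concatenate(np_ws)
        hn, _ = np.histogram(np_psis, bins=edges, weights=np_ws)
        out["null_freq"] = hn / hn.sum()
        out["null_psis"] = np_psis
        out["null_weights"] = np_ws
    return out


def front_back_ratio(network: VesselNetwork, points_with_directions, R: float,
                     n_boot: int = 200, rng=None,
                     exclusions: list | None = None) -> dict:
    """P(|psi| < 45 deg) / P(|psi| > 135 deg), pooled over reference points.

    ``points_with_directions`` is a sequence of (point, unit direction).
    The probability mass is the clipped arclength of neighboring segments in
    the front cone versus the back cone; the SD is a bootstrap over points.
    A zero back mass flags the ratio infinite.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fronts, backs = [], []
    for i, (p, d) in enumerate(points_with_directions):
        excl = exclusions[i] if exclusions else frozenset()
        psis, ws = _psi_masses(network, p, d, R, excl)
        a = np.abs(psis)
        fronts.append(float(ws[a < 45.0].sum()))
        backs.append(float(ws[a > 135.0].sum()))
    fronts = np.array(fronts)
    backs = np.array(backs)
    tot_f, tot_b = fronts.sum(), backs.sum()
    out = {"front_mass": float(tot_f), "back_mass": float(tot_b), "R": R,
           "n_points": len(fronts)}
    if tot_b == 0:
        out["ratio"] = np.inf
        out["infinite"] = True
        lo = []
        for _ in range(n_boot):
            bi = rng.integers(0, len(fronts), len(fronts))
            lo.append(fronts[bi].sum())
        out["boot_front_lower"] = float(np.percentile(lo, 2.5))
        out["boot_sd"] = np.nan
        return out
    out["infinite"] = False
    out["ratio"] = float(tot_f / tot_b)
    boots = []
    for _ in range(n_boot):
        bi = rng.integers(0, len(fronts), len(fronts))
        bf, bb = fronts[bi].sum(), backs[bi].sum()
        if bb > 0:
            boots.append(bf / bb)
    out["boot_sd"] = float(np.std(boots)) if boots else np.nan
    return out
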