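"""Branching-and-annihilating random walk on a uniformly growing half-disk.

The model: active tips elongate in steps of fixed physical length with
Gaussian angular noise and a short-range repulsive bias away from nearby
ducts; each step they may split into two daughters (tip-branching); they
terminate irreversibly when they come within an annihilation radius of a
foreign duct or when they reach the tissue boundary.  Ducts may re-activate
growth anywhere along their length (side-branching), either uniformly at
random or modulated by the locally sensed vessel density (isotropic and/or
directional sensing).  The tissue grows uniformly, dilating the established
network, and duct cells proliferate to restore cell spacing.  Terminal
branches can regress stochastically (pruning), leaving dead segments behind.

Update order within a time step is fixed for determinism:
dilation -> elongation (with repulsion) -> tip-branching -> annihilation ->
side-branching -> pruning, with scheduled perturbation factors applied to
the rates at the current time.

Randomness is split into independent substreams per mechanism, so switching
one mechanism off does not shift the draws of another (clean ablations), and
a fixed seed gives bit-identical event logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import point_segment_distance, rotate
from .network import DomainGeometry, Tip, VesselNetwork
from .params import SimParams

__all__ = ["Simulation", "SimResult", "run_simulation"]

_DEG = np.pi / 180.0


class _SpatialIndex:
    """KD-tree over alive segment midpoints with exact distance refinement."""

    def __init__(self, net: VesselNetwork):
        self.ids = np.flatnonzero(net.seg_alive)
        seg = net.segments[self.ids]
        coords = net.coords
        self.p0 = coords[seg[:, 0]]
        self.p1 = coords[seg[:, 1]]
        self.mid = 0.5 * (self.p0 + self.p1)
        self.length = np.linalg.norm(self.p1 - self.p0, axis=1)
        self.total_length = float(self.length.sum())
        if len(self.ids):
            self.pad = 0.5 * float(self.length.max())
            self.tree = cKDTree(self.mid)
        else:
            self.pad = 0.0
            self.tree = None

    def near(self, point, r: float):
        """Segments within exact distance ``r`` of ``point``.

        Returns ``(segment_ids, distances, nearest_points)``.
        """
        if self.tree is None:
            return (np.empty(0, np.int64), np.empty(0), np.empty((0, 2)))
        loc = self.tree.query_ball_point(point, r + self.pad)
        if not loc:
            return (np.empty(0, np.int64), np.empty(0), np.empty((0, 2)))
        loc = np.asarray(loc, dtype=np.int64)
        d, npts = point_segment_distance(point, self.p0[loc], self.p1[loc])
        keep = d <= r
        return self.ids[loc[keep]], d[keep], npts[keep]

    def mass_in_disk(self, point, r: float) -> float:
        """Approximate vessel length in a disk (midpoint membership)."""
        if self.tree is None:
            return 0.0
        loc = self.tree.query_ball_point(point, r)
        return float(self.length[loc].sum())

    def mass_in_half_disk(self, point, r: float, direction) -> float:
        if self.tree is None:
            return 0.0
        loc = np.asarray(self.tree.query_ball_point(point, r), dtype=np.int64)
        if not len(loc):
            return 0.0
        rel = self.mid[loc] - np.asarray(point)
        mask = rel @ np.asarray(direction) > 0
        return float(self.length[loc[mask]].sum())


@dataclass
class SimResult:
    """Outcome of a run: final network, event log, snapshots, provenance."""

    network: VesselNetwork
    domain: DomainGeometry
    params: SimParams
    seed: int
    final_time: float
    events: list = field(default_factory=list)
    snapshots: dict = field(default_factory=dict)

    @property
    def event_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.events, columns=["time", "event", "tip", "node", "x", "y"]
        )

    def event_counts(self) -> dict:
        from collections import Counter

        return dict(Counter(e[1] for e in self.events))


class Simulation:
    """Mutable simulation state; use :func:`run_simulation` for one-shot runs."""

    def __init__(self, params: SimParams, seed: int):
        params.validate()
        self.params = params
        self.seed = int(seed)
        streams = np.random.SeedSequence(self.seed).spawn(8)
        (self.rng_init, self.rng_elong, self.rng_branch, self.rng_side,
         self.rng_prune, self.rng_dilate, self.rng_label, self.rng_annih) = (
            np.random.default_rng(s) for s in streams
        )
        self.net = VesselNetwork()
        self.domain = DomainGeometry(params.radius0, params.growth_rate)
        self.t = 0.0
        self.events: list = []
        self.snapshots: dict = {}
        self.root_nodes: set[int] = set()
        self._tip_trees_seeded = params.n_tip_trees == 0
        self._labeled = False
        self._next_tree = 0
        self._seed_stalk_trees()

    # -- seeding ------------------------------------------------------------

    def _new_tip(self, node: int, heading, tree: int, particle: int = -1,
                 parent_tip: int = -1) -> Tip:
        tip = Tip(
            id=len(self.net.tips), node=node, heading=heading,
            speed=self.params.tip_speed, birth_time=self.t,
            particle=particle, tree=tree, parent_tip=parent_tip,
        )
        self.net.tips.append(tip)
        return tip

    def _seed_stalk_trees(self):
        p = self.params
        xs = np.sort(self.rng_init.uniform(-0.85, 0.85, p.n_trees)) * p.radius0
        for x in xs:
            node = self.net.add_node((x, 0.0))
            self.root_nodes.add(node)
            ang = 0.5 * np.pi + self.rng_init.normal(0.0, 0.1)
            tip = self._new_tip(node, (np.cos(ang), np.sin(ang)), self._next_tree)
            self._next_tree += 1
            self._log("seed", tip.id, node)

    def _seed_tip_trees(self):
        p = self.params
        r = 0.98 * self.domain.radius(self.t)
        angs = np.clip(
            self.rng_init.normal(90.0, 20.0, p.n_tip_trees), 30.0, 150.0
        ) * _DEG
        for a in np.sort(angs):
            node = self.net.add_node((r * np.cos(a), r * np.sin(a)))
            self.root_nodes.add(node)
            jitter = self.rng_init.normal(0.0, 0.1)
            heading = rotate((-np.cos(a), -np.sin(a)), jitter)
            tip = self._new_tip(node, heading, self._next_tree)
            self._next_tree += 1
            self._log("seed", tip.id, node)

    # -- bookkeeping --------------------------------------------------------

    def _log(self, event: str, tip: int, node: int):
        xy = self.net.coords[node]
        self.events.append((self.t, event, tip, node, float(xy[0]), float(xy[1])))

    def active_tips(self) -> list[Tip]:
        return [tp for tp in self.net.tips if tp.state == "active"]

    def _terminate(self, tip: Tip, fate: str):
        tip.state = "terminated"
        tip.fate = fate
        self._log(fate, tip.id, tip.node)

    def _exclusion_set(self, node: int) -> set[int]:
        """Segments within graph-arc distance n_self * step of ``node``.

        The duct continuum a tip just emerged from -- its own trail, the
        parent duct around its branch point, a sibling's or uncle's young
        branches -- is invisible to that tip's annihilation and repulsion;
        "too close to neighboring ducts" refers to vessel that is near in
        space but far along the network.  A breadth-first walk bounded by the
        arc length n_self * step (um) captures exactly that set.
        """
        net = self.net
        limit = self.params.n_self * self.params.step + self.params.step
        alive = net.seg_alive
        lens = net._seg_len.view
        node_segments = net.node_segments
        best = {node: 0.0}
        out: set[int] = set()
        stack = [(node, 0.0)]
        while stack:
            u, du = stack.pop()
            for sid, v in node_segments[u]:
                if sid in out or not alive[sid]:
                    continue
                out.add(sid)
                dv = du + lens[sid]
                if dv < limit and best.get(v, np.inf) > dv:
                    best[v] = dv
                    stack.append((v, dv))
        return out

    def _excluded(self, excl_set: set[int], seg_ids: np.ndarray) -> np.ndarray:
        if not excl_set:
            return np.zeros(len(seg_ids), dtype=bool)
        return np.fromiter((int(s) in excl_set for s in seg_ids), dtype=bool,
                           count=len(seg_ids))

    def _deposit(self, tip: Tip, sid: int, frac: float = 0.5) -> int:
        P = self.net.particles
        if tip.particle >= 0:
            clone, color = P.clone[tip.particle], P.color[tip.particle]
        else:
            clone = color = -1
        pid = P.add(sid, frac, parent=tip.particle, birth=self.t,
                    clone=clone, color=color)
        self.net.seg_particles[sid].append(pid)
        tip.particle = pid
        return pid

    # -- per-step operations (fixed order) ----------------------------------

    def dilate(self, t_new: float):
        """Uniform tissue growth: scale coordinates, restore cell spacing."""
        factor = self.domain.radius(t_new) / self.domain.radius(self.t)
        if factor != 1.0:
            self.net._xy.view[:] *= factor
            self.net._seg_len.view[:] *= factor
        self.t = t_new
        if factor <= 1.0 or len(self.net.particles) == 0:
            return
        # tissue growth drives duct-cell proliferation: each cell divides
        # independently with probability equal to the relative stretch, so
        # cell spacing is restored in expectation and every lineage grows as
        # a Yule process -- which is what gives the duct-cell clones their
        # exponential (geometric) size distribution.
        net = self.net
        P = net.particles
        n = len(P)
        hits = np.flatnonzero(self.rng_dilate.random(n) < (factor - 1.0))
        alive = net.seg_alive
        for q in hits:
            sid = P.seg[q]
            if not alive[sid]:
                continue
            # daughter stays adjacent on the same duct segment
            f = min(1.0, max(0.0, P.frac[q] + self.rng_dilate.uniform(-0.3, 0.3)))
            pid = P.add(sid, f, parent=int(q), birth=self.t,
                        clone=P.clone[q], color=P.color[q])
            net.seg_particles[sid].append(pid)

    def elongate_tips(self, index: _SpatialIndex):
        p = self.params
        for tip in self.net.tips:
            if tip.state != "active":
                continue
            pos = self.net.coords[tip.node]
            bias = 0.0
            if p.k_repulsion > 0 and p.r_repulsion > 0:
                ids, dists, npts = index.near(pos, p.r_repulsion)
                if len(ids):
                    # the exclusion cached by last step's annihilation phase is
                    # one step stale, which only softens repulsion marginally
                    excl = getattr(tip, "_excl", None)
                    if excl is None:
                        excl = self._exclusion_set(tip.node)
                    keep = ~self._excluded(excl, ids)
                    if keep.any():
                        j = np.argmin(np.where(keep, dists, np.inf))
                        d = dists[j]
                        away = pos - npts[j]
                        norm = np.linalg.norm(away)
                        if norm > 1e-12 and d < p.r_repulsion:
                            toward = -away / norm
                            ang = np.arctan2(
                                tip.heading[0] * toward[1] - tip.heading[1] * toward[0],
                                tip.heading @ toward,
                            )
                            bias = -np.sign(ang) * p.k_repulsion * (1.0 - d / p.r_repulsion)
            theta = bias + self.rng_elong.normal(0.0, p.sigma_theta)
            tip.heading = rotate(tip.heading, theta)
            newpos = pos + p.step * tip.heading
            if not self.domain.contains(newpos[None, :], self.t)[0]:
                self._terminate(tip, "boundary")
                continue
            nid = self.net.add_node(newpos)
            sid = self.net.add_segment(tip.node, nid, birth=self.t,
                                       tree=tip.tree, tip=tip.id)
            tip.node = nid
            tip.n_steps += 1
            self._deposit(tip, sid)

    def attempt_tip_branch(self, pb_eff: float):
        p = self.params
        for tip in list(self.net.tips):
            if tip.state != "active":
                continue
            if self.rng_branch.random() >= pb_eff:
                continue
            phi = np.clip(
                self.rng_branch.normal(p.daughter_angle_mean, p.daughter_angle_sd),
                20.0, 160.0,
            ) * _DEG
            for sign in (+1.0, -1.0):
                self._new_tip(
                    tip.node, rotate(tip.heading, sign * 0.5 * phi),
                    tree=tip.tree, particle=tip.particle, parent_tip=tip.id,
                )
            tip.state = "terminated"
            tip.fate = "branched"
            self._log("tip_branch", tip.id, tip.node)

    def check_annihilation(self, index: _SpatialIndex):
        p = self.params
        for tip in self.net.tips:
            if tip.state != "active" or tip.n_steps == 0:
                continue  # tips that have not laid a segment yet get one step of grace
            pos = self.net.coords[tip.node]
            if p.annihilation_mode == "hard":
                ids, dists, _ = index.near(pos, p.r_annihilation)
                # exclusion is evaluated on the post-elongation network so the
                # whole family's segments from this step are accounted for;
                # the set is kept for next step's repulsion
                tip._excl = self._exclusion_set(tip.node)
                if len(ids) and (~self._excluded(tip._excl, ids)).any():
                    self._terminate(tip, "annihilated")
            else:
                rho = index.mass_in_disk(pos, p.r_annihilation) / (
                    np.pi * p.r_annihilation ** 2
                )
                if self.rng_annih.random() < min(1.0, rho / p.rho_star):
                    self._terminate(tip, "annihilated")

    def attempt_side_branching(self, index: _SpatialIndex, ps_eff: float):
        p = self.params
        if ps_eff <= 0 or index.total_length == 0:
            return
        lam = ps_eff * index.total_length * p.dt
        n = self.rng_side.poisson(lam)
        if n == 0:
            return
        cum = np.cumsum(index.length)
        split_done: set[int] = set()
        for u in self.rng_side.uniform(0.0, index.total_length, n):
            j = int(np.searchsorted(cum, u))
            j = min(j, len(cum) - 1)
            sid = int(index.ids[j])
            if sid in split_done or not self.net.seg_alive[sid]:
                continue
            seglen = index.length[j]
            if seglen < 2.0:
                continue
            frac = (u - (cum[j - 1] if j else 0.0)) / seglen
            frac = float(np.clip(frac, 0.5 / seglen, 1.0 - 0.5 / seglen))
            site = index.p0[j] + frac * (index.p1[j] - index.p0[j])
            tangent = (index.p1[j] - index.p0[j]) / seglen
            heading = self._sprout_heading(index, site, tangent)
            if heading is None:
                continue
            split_done.add(sid)
            self._create_sprout(sid, frac, heading)

    def _sprout_heading(self, index, site, tangent):
        """Pick the sprout direction per side-branching mode; None = rejected."""
        p = self.params
        mode = p.side_branch_mode
        perp = np.array([-tangent[1], tangent[0]])
        if mode in ("isotropic", "combined"):
            rho = index.mass_in_disk(site, p.r_sense) / (np.pi * p.r_sense ** 2)
            accept = max(0.0, 1.0 - rho / p.rho_star)
            if self.rng_side.random() >= accept:
                return None
        if mode in ("random", "isotropic"):
            sign = 1.0 if self.rng_side.random() < 0.5 else -1.0
            return sign * perp
        # directional / combined: sample perpendicular-biased candidate
        # directions on both sides, keep the one seeing the least density
        # in its half-disk of radius R_sense
        offsets = self.rng_side.uniform(-60.0, 60.0, p.n_dir) * _DEG
        best, best_mass = None, np.inf
        for i, off in enumerate(offsets):
            base = perp if i % 2 == 0 else -perp
            cand = rotate(base, off)
            mass = index.mass_in_half_disk(site, p.r_sense, cand)
            if mass < best_mass:
                best, best_mass = cand, mass
        return best

    def _create_sprout(self, sid: int, frac: float, heading):
        p = self.params
        root, left, right = self.net.split_segment(sid, frac)
        tip = self._new_tip(root, heading, tree=int(self.net.seg_tree[sid]))
        # the sprout is the reactivation of a duct cell: inherit the label of
        # the nearest particle on the parent duct
        P = self.net.particles
        cands = []
        for half, pick in ((left, max), (right, min)):
            plist = self.net.seg_particles[half]
            if plist:
                cands.append(pick(plist, key=lambda q: P.frac[q]))
        if cands:
            pos = self.net.coords[root]

            def _dist(q):
                a, b = self.net.segments[P.seg[q]]
                pt = self.net.coords[a] + P.frac[q] * (self.net.coords[b] - self.net.coords[a])
                return float(np.linalg.norm(pt - pos))

            tip.particle = min(cands, key=_dist)
        self._log("side_branch", tip.id, root)

    def apply_pruning(self, prune_eff: float):
        p = self.params
        if prune_eff <= 0:
            return
        net = self.net
        deg = net.degrees(alive_only=True)
        active_nodes = {tp.node for tp in net.tips if tp.state == "active"}
        terminals = [
            int(v) for v in np.flatnonzero(deg == 1)
            if v not in active_nodes and v not in self.root_nodes
        ]
        for v in terminals:
            if self.rng_prune.random() >= prune_eff * p.dt:
                continue
            node = v
            while True:
                nxt = [(s, n) for s, n in net.node_segments[node]
                       if net.seg_alive[s]]
                if len(nxt) != 1:
                    break
                sid, node = nxt[0]
                net.seg_alive[sid] = False
                if deg[node] != 2:
                    break
            self._log("prune", -1, v)

    def label_clones(self, fraction: float, color_count: int = 4):
        """Irreversibly label each particle with probability ``fraction``."""
        P = self.net.particles
        if len(P) == 0:
            raise ValueError("cannot label before any particles exist")
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        hits = self.rng_label.random(len(P)) < fraction
        colors = self.rng_label.integers(0, max(color_count, 1), len(P))
        for pid in np.flatnonzero(hits):
            if P.clone[pid] == -1:
                P.clone[pid] = int(pid)
                P.color[pid] = int(colors[pid])
        self._labeled = True
        self.events.append((self.t, "label", -1, -1, np.nan, np.nan))

    # -- main loop -----------------------------------------------------------

    def step(self):
        p = self.params
        t_new = self.t + p.dt
        self.dilate(t_new)
        if not self._tip_trees_seeded and self.t >= p.tip_tree_time:
            self._seed_tip_trees()
            self._tip_trees_seeded = True
        fb, fs, fp = p.factors_at(self.t)
        pre = _SpatialIndex(self.net)
        self.elongate_tips(pre)
        self.attempt_tip_branch(p.p_branch * fb)
        post = _SpatialIndex(self.net)
        self.check_annihilation(post)
        self.attempt_side_branching(post, p.p_side * fs)
        self.apply_pruning(p.pruning_rate * fp)
        if (p.label_time is not None and not self._labeled
                and self.t >= p.label_time and len(self.net.particles)):
            self.label_clones(p.label_fraction, p.color_count)

    def run(self, stop_when_quiescent: bool = False) -> "SimResult":
        p = self.params
        n_steps = int(np.floor(p.duration / p.dt + 1e-9))
        snap_iter = sorted(p.snapshot_times)
        si = 0
        for _ in range(n_steps):
            self.step()
            while si < len(snap_iter) and self.t >= snap_iter[si] - 1e-9:
                self.snapshots[snap_iter[si]] = self.net.copy()
                si += 1
            if stop_when_quiescent and not any(
                tp.state == "active" for tp in self.net.tips
            ):
                break
        return self.result()

    def result(self) -> SimResult:
        return SimResult(
            network=self.net, domain=self.domain, params=self.params,
            seed=self.seed, final_time=self.t, events=self.events,
            snapshots=self.snapshots,
        )


def run_simulation(params: SimParams, seed: int,
                   stop_when_quiescent: bool = False) -> SimResult:
    """Run the full model and return the final state, snapshots and event log.

    Bit-reproducible for a fixed ``seed``: all stochastic mechanisms draw from
    independent substreams spawned from it.
    """
    sim = Simulation(params, seed)
    return sim.run(stop_when_quiescent)
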