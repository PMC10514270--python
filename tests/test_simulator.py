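"""Engine mechanics: elongation, branching, annihilation, dilation,
side-branching, pruning, perturbations, labeling, determinism."""

import numpy as np
import pytest

import lymphtile as lt
from lymphtile.simulator import Simulation, _SpatialIndex


def quiet_params(**kw):
    """A minimal, mechanism-free parameter set for op-level tests."""
    defaults = dict(
        radius0=5000.0, growth_rate=0.0, duration=2.0, tip_speed=450.0,
        sigma_theta=0.0, p_branch=0.0, p_side=0.0, k_repulsion=0.0,
        n_trees=1, n_tip_trees=0, pruning_rate=0.0,
    )
    defaults.update(kw)
    p = lt.SimParams(**defaults)
    p.validate()
    return p


def single_tip_sim(heading=(0.0, 1.0), pos=(0.0, 0.0), **kw):
    """Simulation with exactly one tip at a controlled position/heading."""
    sim = Simulation(quiet_params(**kw), seed=0)
    tip = sim.net.tips[0]
    sim.net._xy.view[tip.node] = pos
    tip.heading = np.asarray(heading, dtype=float)
    return sim, tip


class TestElongation:
    def test_noise_free_step_is_straight(self):
        sim, tip = single_tip_sim(heading=(1.0, 0.0), pos=(0.0, 100.0))
        sim.elongate_tips(_SpatialIndex(sim.net))
        assert np.allclose(sim.net.coords[tip.node], (10.0, 100.0))

    def test_heading_diffusion_matches_sigma(self):
        """Mean squared heading deviation after n steps ~ n sigma^2."""
        sigma, n = 0.12, 25
        devs = []
        for seed in range(300):
            p = quiet_params(sigma_theta=sigma, duration=n * 10.0 / 450.0)
            sim = Simulation(p, seed=seed)
            tip = sim.net.tips[0]
            sim.net._xy.view[tip.node] = (0.0, 1000.0)
            theta0 = np.arctan2(*tip.heading[::-1])
            sim.run()
            theta = np.arctan2(*tip.heading[::-1])
            devs.append((theta - theta0) ** 2)
        msd = np.mean(devs)
        expect = n * sigma**2
        assert msd == pytest.approx(expect, rel=0.25)

    def test_repulsion_steers_away_from_parallel_duct(self):
        """A tip running parallel to a duct inside r_rep veers away."""
        sim, tip = single_tip_sim(heading=(1.0, 0.0), pos=(0.0, 1000.0),
                                  k_repulsion=0.4)
        a = sim.net.add_node((-500.0, 1030.0))
        b = sim.net.add_node((1500.0, 1030.0))
        sim.net.add_segment(a, b)  # foreign duct 30 um above, within r_rep=60
        ys = []
        for _ in range(12):
            idx = _SpatialIndex(sim.net)
            sim.elongate_tips(idx)
            ys.append(sim.net.coords[tip.node][1])
        assert tip.state == "active"
        assert ys[-1] < 1000.0  # driven downward, away from the duct
        assert all(np.diff(ys) <= 1e-9)

    def test_boundary_terminates(self):
        sim, tip = single_tip_sim(heading=(0.0, 1.0), pos=(0.0, 4995.0))
        sim.elongate_tips(_SpatialIndex(sim.net))
        assert tip.state == "terminated" and tip.fate == "boundary"


class TestTipBranching:
    def test_pb_zero_never_branches(self, wt_sim):
        p = quiet_params(duration=5.0)
        res = lt.run_simulation(p, seed=3)
        assert res.event_counts().get("tip_branch", 0) == 0

    def test_pb_one_doubles_each_step(self):
        sim, _ = single_tip_sim(pos=(0.0, 2000.0))
        for expected in (2, 4, 8):
            sim.attempt_tip_branch(1.0)
            active = [tp for tp in sim.net.tips if tp.state == "active"]
            assert len(active) == expected

    def test_empirical_branch_rate(self):
        """Branch frequency over many tip-steps matches p_b binomially."""
        pb, n_steps, n_rep = 0.07, 20, 120
        events = trials = 0
        for seed in range(n_rep):
            p = quiet_params(p_branch=pb, duration=n_steps * 10.0 / 450.0,
                             radius0=50000.0)
            sim = Simulation(p, seed=seed)
            sim.net._xy.view[sim.net.tips[0].node] = (0.0, 25000.0)
            res = sim.run()
            ev = res.event_counts()
            events += ev.get("tip_branch", 0)
            # each active tip-step is one Bernoulli trial
            trials += sum(tp.n_steps for tp in sim.net.tips)
        rate = events / trials
        se = np.sqrt(pb * (1 - pb) / trials)
        assert abs(rate - pb) < 3 * se + 0.005

    def test_daughter_angle_split(self):
        sim, tip = single_tip_sim(heading=(0.0, 1.0), pos=(0.0, 2000.0))
        sim.attempt_tip_branch(1.0)
        d1, d2 = [tp for tp in sim.net.tips if tp.state == "active"]
        # daughters open symmetrically about the parent heading
        assert d1.heading @ d2.heading < 1.0
        cross1 = d1.heading[0] * 1.0 - d1.heading[1] * 0.0
        cross2 = d2.heading[0] * 1.0 - d2.heading[1] * 0.0
        assert cross1 == pytest.approx(-cross2, abs=1e-9)


class TestAnnihilation:
    def test_straight_tip_never_self_annihilates(self):
        p = quiet_params(duration=4.0)
        res = lt.run_simulation(p, seed=1)
        assert res.event_counts().get("annihilated", 0) == 0

    def test_foreign_duct_within_half_radius_kills(self):
        sim, tip = single_tip_sim(heading=(1.0, 0.0), pos=(0.0, 1000.0))
        a = sim.net.add_node((-100.0, 1020.0))
        b = sim.net.add_node((200.0, 1020.0))
        sim.net.add_segment(a, b)  # 20 um = r_a/2 away
        sim.elongate_tips(_SpatialIndex(sim.net))  # lay one own segment
        sim.check_annihilation(_SpatialIndex(sim.net))
        assert tip.state == "terminated" and tip.fate == "annihilated"

    def test_head_on_tips_terminate_near_r_a(self):
        """Antiparallel tips approaching head-on stop at ~r_a separation."""
        p = quiet_params(n_trees=2, radius0=5000.0)
        sim = Simulation(p, seed=0)
        t1, t2 = sim.net.tips
        sim.net._xy.view[t1.node] = (0.0, 1000.0)
        sim.net._xy.view[t2.node] = (400.0, 1000.0)
        t1.heading = np.array([1.0, 0.0])
        t2.heading = np.array([-1.0, 0.0])
        while any(tp.state == "active" for tp in (t1, t2)):
            idx = _SpatialIndex(sim.net)
            sim.elongate_tips(idx)
            sim.check_annihilation(_SpatialIndex(sim.net))
            sim.t += p.dt
        gap = abs(sim.net.coords[t1.node][0] - sim.net.coords[t2.node][0])
        ra, step = p.r_annihilation, p.step
        assert ra - 2 * step < gap <= ra + 2 * step

    def test_annihilated_tips_lie_close_to_foreign_duct(self, wt_sim):
        """Across a full run, every annihilated tip sits within r_a + step
        of some foreign duct segment."""
        p = wt_sim.params
        net = wt_sim.network
        idx = _SpatialIndex(net)
        checked = 0
        for tip in net.tips:
            if tip.fate != "annihilated":
                continue
            ids, dists, _ = idx.near(net.coords[tip.node],
                                     p.r_annihilation + p.step)
            assert len(ids) > 0
            checked += 1
        assert checked > 50


class TestDilation:
    def test_scaling_doubles_lengths_preserves_topology(self):
        net = lt.VesselNetwork.from_arrays(
            [(0, 0), (100, 0), (200, 50)], [(0, 1), (1, 2)])
        p = quiet_params()
        sim = Simulation(p, seed=0)
        sim.net = net
        sim.domain = lt.DomainGeometry(1000.0, 1000.0)  # doubles in 1 day
        deg_before = net.degrees().copy()
        sim.t = 0.0
        sim.dilate(1.0)
        assert np.allclose(net.coords[1], (200, 0))
        assert net.segment_length(0) == pytest.approx(200.0)
        assert np.array_equal(net.degrees(), deg_before)

    def test_particle_count_roughly_doubles(self):
        """Uniformly seeded duct particles are replenished under 2x dilation."""
        p = quiet_params(duration=40 * 10.0 / 450.0)
        sim = Simulation(p, seed=4)
        sim.net._xy.view[sim.net.tips[0].node] = (0.0, 2000.0)
        sim.run()  # lays ~40 segments with 1 particle each
        n0 = len(sim.net.particles)
        # restart the clock with a domain that doubles over one day
        sim.t = 0.0
        sim.domain = lt.DomainGeometry(sim.domain.radius(sim.params.duration),
                                       0.0)
        sim.domain.growth_rate = sim.domain.radius0
        for k in range(1, 51):
            sim.dilate(k * 0.02)
        n1 = len(sim.net.particles)
        assert n1 == pytest.approx(2 * n0, rel=0.20)


class TestSideBranching:
    def straight_duct_sim(self, mode, **kw):
        sim = Simulation(quiet_params(p_side=kw.pop("p_side", 1e-3),
                                      side_branch_mode=mode, **kw), seed=9)
        nodes = [sim.net.add_node((x, 2000.0)) for x in range(-1000, 1001, 10)]
        for a, b in zip(nodes[:-1], nodes[1:]):
            sid = sim.net.add_segment(a, b)
            sim.net.particles.add(sid, 0.5, parent=-1, birth=0.0)
            sim.net.seg_particles[sid].append(len(sim.net.particles) - 1)
        sim.net.tips[0].state = "terminated"  # only the duct remains
        return sim

    def test_ps_zero_no_sprouts(self):
        res = lt.run_simulation(quiet_params(duration=5.0, p_side=0.0), seed=2)
        assert res.event_counts().get("side_branch", 0) == 0

    def test_random_mode_poisson_rate(self):
        """Sprout count over one step matches p_s * L * dt on average."""
        counts = []
        ps = 2e-3
        for seed in range(150):
            sim = self.straight_duct_sim("random", p_side=ps)
            sim.rng_side = np.random.default_rng(seed)
            L = sim.net.total_length()
            idx = _SpatialIndex(sim.net)
            sim.attempt_side_branching(idx, ps)
            counts.append(sum(1 for e in sim.events if e[1] == "side_branch"))
        lam = ps * 2000.0 * sim.params.dt
        mean = np.mean(counts)
        se = np.sqrt(lam / len(counts))
        assert abs(mean - lam) < 3 * se

    def test_sprout_heading_perpendicular_in_random_mode(self):
        sim = self.straight_duct_sim("random", p_side=0.05)
        idx = _SpatialIndex(sim.net)
        sim.attempt_side_branching(idx, 0.05)
        sprouts = [tp for tp in sim.net.tips if tp.state == "active"]
        assert len(sprouts) > 0
        for tp in sprouts:
            assert abs(tp.heading[0]) < 1e-9
            assert abs(abs(tp.heading[1]) - 1.0) < 1e-9

    def test_directional_mode_targets_empty_half_plane(self):
        """With all other vessel mass above the duct, sprouts point down."""
        headings = []
        for seed in range(80):
            sim = self.straight_duct_sim("directional", p_side=0.02)
            # dense parallel ducts above (y > 2000), short segments so their
            # mass is spatially resolved
            for y in (2060.0, 2100.0, 2140.0):
                prev = sim.net.add_node((-1000.0, y))
                for x in range(-990, 1001, 10):
                    nxt = sim.net.add_node((float(x), y))
                    sim.net.add_segment(prev, nxt)
                    prev = nxt
            sim.rng_side = np.random.default_rng(seed)
            idx = _SpatialIndex(sim.net)
            sim.attempt_side_branching(idx, 0.02)
            # keep sprouts rooted on the lower duct (y = 2000); for them the
            # low-density half-plane is below
            headings += [tp.heading for tp in sim.net.tips
                         if tp.state == "active" and tp.n_steps == 0
                         and sim.net.coords[tp.node][1] < 2010.0]
        headings = np.array(headings)
        assert len(headings) >= 40
        assert np.mean(headings[:, 1] < 0) >= 0.95

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            quiet_params(side_branch_mode="telepathic")


class TestPruning:
    def test_rate_zero_keeps_network(self, small_sim):
        assert small_sim.params.pruning_rate == 0.0
        assert small_sim.network.seg_alive.all()

    def test_huge_rate_collapses_single_tree(self):
        p = quiet_params(duration=30 * 10.0 / 450.0)
        sim = Simulation(p, seed=5)
        sim.net._xy.view[sim.net.tips[0].node] = (0.0, 2000.0)
        sim.run()
        sim.net.tips[0].state = "terminated"
        for _ in range(200):
            sim.apply_pruning(1.0 / sim.params.dt)  # certain pruning per step
        assert sim.net.seg_alive.sum() == 0

    def test_pruned_segments_flagged_not_deleted(self):
        p = quiet_params(duration=20 * 10.0 / 450.0)
        sim = Simulation(p, seed=5)
        sim.net._xy.view[sim.net.tips[0].node] = (0.0, 2000.0)
        sim.run()
        n_seg = sim.net.n_segments
        sim.net.tips[0].state = "terminated"
        sim.apply_pruning(1.0 / sim.params.dt)
        assert sim.net.n_segments == n_seg
        assert not sim.net.seg_alive.all()


class TestPerturbations:
    def test_empty_schedule_identity(self):
        p = quiet_params()
        assert p.factors_at(0.0) == (1.0, 1.0, 1.0)
        assert p.factors_at(17.0) == (1.0, 1.0, 1.0)

    def test_svegfr3_abolishes_branching_after_day7(self):
        p = lt.preset("svegfr3", scale=0.25)
        res = lt.run_simulation(p, seed=3)
        log = res.event_log
        late = log[(log.time > 7.0 + p.dt) & log.event.isin(["tip_branch", "side_branch"])]
        assert len(late) == 0
        early = log[(log.time <= 7.0) & (log.event == "tip_branch")]
        assert len(early) > 0

    def test_vegfc_het_has_no_side_branches(self):
        p = lt.preset("vegfc-het", scale=0.25)
        res = lt.run_simulation(p, seed=3)
        assert res.event_counts().get("side_branch", 0) == 0

    def test_schedule_outside_run_rejected(self):
        with pytest.raises(ValueError):
            quiet_params(perturbations=[lt.Perturbation(time=99.0)])


class TestLabeling:
    def test_label_before_particles_errors(self):
        sim = Simulation(quiet_params(), seed=0)
        with pytest.raises(ValueError):
            sim.label_clones(0.5)

    def test_fraction_zero_and_one(self):
        p = quiet_params(duration=30 * 10.0 / 450.0)
        sim = Simulation(p, seed=8)
        sim.net._xy.view[sim.net.tips[0].node] = (0.0, 2000.0)
        sim.run()
        sim.label_clones(0.0)
        assert all(c == -1 for c in sim.net.particles.clone)
        sim.label_clones(1.0)
        assert all(c >= 0 for c in sim.net.particles.clone)

    def test_binomial_label_count(self, wt_sim):
        P = wt_sim.network.particles
        n = len(P)
        frac = 0.01
        rng = np.random.default_rng(1)
        clone, _ = lt.retrospective_label(wt_sim, wt_sim.final_time, frac, rng)
        founders = sum(1 for q in range(n) if clone[q] == q)
        expect = n * frac
        assert abs(founders - expect) < 4 * np.sqrt(expect)


class TestRunSimulation:
    def test_zero_trees_empty_network(self):
        p = quiet_params(n_trees=0)
        res = lt.run_simulation(p, seed=0)
        assert res.network.n_segments == 0

    def test_fixed_seed_bit_determinism(self):
        p = lt.preset("wt", scale=0.2, duration=6.0)
        r1 = lt.run_simulation(p, seed=77)
        r2 = lt.run_simulation(p, seed=77)
        assert r1.events == r2.events
        assert np.array_equal(r1.network.coords, r2.network.coords)

    def test_total_length_nondecreasing_without_pruning(self):
        p = lt.preset("wt", scale=0.2, duration=8.0,
                      snapshot_times=[2.0, 4.0, 6.0, 8.0])
        res = lt.run_simulation(p, seed=13)
        lengths = [res.snapshots[t].total_length() for t in sorted(res.snapshots)]
        assert all(np.diff(lengths) >= -1e-6)

    def test_branch_nodes_match_event_log(self, wt_sim):
        """Every alive degree-3 node was created by exactly one logged
        tip-branch or side-branch event."""
        net = wt_sim.network
        deg = net.degrees(alive_only=True)
        branch_nodes = set(np.flatnonzero(deg == 3))
        event_nodes = {e[3] for e in wt_sim.events
                       if e[1] in ("tip_branch", "side_branch")}
        assert branch_nodes <= event_nodes

    def test_node_degrees_at_most_three(self, wt_sim):
        assert wt_sim.network.degrees().max() <= 3

    def test_nodes_inside_domain(self, wt_sim):
        net, dom = wt_sim.network, wt_sim.domain
        used = np.unique(net.segments)
        inside = dom.contains(net.coords[used], wt_sim.final_time, margin=-1e-6)
        assert inside.all()
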