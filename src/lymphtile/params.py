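"""Simulation parameters, perturbation schedules, and named presets.

Units: lengths um, time days, rates per day.  The developmental window is
mapped as P4 -> t = 0 and P21 -> t = 17 d, so e.g. a perturbation applied at
P11 acts from t = 7 d.

The kinetic defaults were chosen to reproduce the qualitative growth regimes
of the wild-type network: stalk-seeded trees reach the distal edge of the
pinna around t = 9 d (P13), branch lengths are broadly distributed with a
~10^2-um scale, and side-branch events over a full run are of the same order
as tip-branch events.  Every value is exposed in the configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Perturbation", "SimParams", "preset"]


@dataclass(frozen=True)
class Perturbation:
    """Multiplicative rate change switched on at ``time`` (days).

    From ``time`` onward, the tip-branching probability, side-branching rate
    and pruning rate are multiplied by the given factors (factors from
    multiple events compound).
    """

    time: float
    pb_factor: float = 1.0
    ps_factor: float = 1.0
    prune_factor: float = 1.0


@dataclass
class SimParams:
    """All rates and kernels of the branching-and-annihilating random walk."""

    # geometry / growth
    radius0: float = 2000.0          # initial half-disk radius R0 (um)
    growth_rate: float = 180.0       # g, radius growth (um/day)
    duration: float = 17.0           # days (P4 -> P21)

    # tip kinetics
    tip_speed: float = 450.0         # v (um/day)
    step: float = 10.0               # elongation step delta (um)
    sigma_theta: float = 0.15        # angular noise (rad per sqrt(step))
    p_branch: float = 0.10           # p_b, tip-branching probability per step
    daughter_angle_mean: float = 70.0  # branch opening angle phi (deg)
    daughter_angle_sd: float = 15.0

    # interactions
    r_annihilation: float = 40.0     # r_a (um)
    annihilation_mode: str = "hard"  # 'hard' | 'probabilistic'
    # ducts within n_self * step um of a tip ALONG THE NETWORK (graph-arc
    # distance: own trail, parent duct at the branch point, sibling's young
    # branch) are invisible to its annihilation/repulsion
    n_self: int = 12
    r_repulsion: float = 60.0        # r_rep (um)
    k_repulsion: float = 0.3         # max repulsive turn (rad) at contact

    # side-branching
    p_side: float = 2.0e-3           # p_s, sprout rate per um of duct per day
    side_branch_mode: str = "random"  # random | isotropic | directional | combined
    r_sense: float = 150.0           # density sensing radius (um)
    rho_star: float = 0.020          # density cap rho* (um^-1), ~ the
                                     # wild-type steady-state network density
    n_dir: int = 8                   # candidate directions for directional mode

    # pruning
    pruning_rate: float = 0.0        # per terminal branch per day

    # initial condition
    n_trees: int = 12                # stalk-seeded trees at t = 0
    n_tip_trees: int = 5             # distal-edge trees appearing at t = 2 d (P6)
    tip_tree_time: float = 2.0

    # clonal labeling (optional; retrospective labeling is also available)
    label_time: float | None = None
    label_fraction: float = 0.01
    color_count: int = 4

    # schedule and bookkeeping
    perturbations: list[Perturbation] = field(default_factory=list)
    particle_spacing: float | None = None  # defaults to `step`
    snapshot_times: list[float] = field(default_factory=list)

    # -- derived ------------------------------------------------------------

    @property
    def dt(self) -> float:
        """Time step (days): one elongation step per dt."""
        return self.step / self.tip_speed

    @property
    def spacing(self) -> float:
        return self.step if self.particle_spacing is None else self.particle_spacing

    def validate(self) -> None:
        numeric = [
            self.radius0, self.growth_rate, self.duration, self.tip_speed,
            self.step, self.sigma_theta, self.p_branch, self.r_annihilation,
            self.r_repulsion, self.k_repulsion, self.p_side, self.r_sense,
            self.rho_star, self.pruning_rate,
        ]
        if not all(np.isfinite(v) for v in numeric):
            raise ValueError("non-finite simulation parameter")
        if min(self.growth_rate, self.p_side, self.pruning_rate,
               self.r_annihilation, self.r_repulsion, self.r_sense) < 0:
            raise ValueError("rates and radii must be non-negative")
        if not 0.0 <= self.p_branch <= 1.0:
            raise ValueError("p_branch must lie in [0, 1]")
        if self.step <= 0 or self.tip_speed <= 0:
            raise ValueError("step and tip_speed must be positive")
        if self.side_branch_mode not in ("random", "isotropic", "directional", "combined"):
            raise ValueError(f"unknown side_branch_mode {self.side_branch_mode!r}")
        if self.annihilation_mode not in ("hard", "probabilistic"):
            raise ValueError(f"unknown annihilation_mode {self.annihilation_mode!r}")
        if not 0.0 <= self.label_fraction <= 1.0:
            raise ValueError("label_fraction must lie in [0, 1]")
        for p in self.perturbations:
            if not 0.0 <= p.time <= self.duration:
                raise ValueError(f"perturbation time {p.time} outside [0, {self.duration}]")

    def factors_at(self, t: float) -> tuple[float, float, float]:
        """Compounded (p_b, p_s, pruning) multipliers active at time ``t``."""
        fb = fs = fp = 1.0
        for p in self.perturbations:
            if t >= p.time:
                fb *= p.pb_factor
                fs *= p.ps_factor
                fp *= p.prune_factor
        return fb, fs, fp

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["perturbations"] = [dataclasses.asdict(p) for p in self.perturbations]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        d["perturbations"] = [Perturbation(**p) for p in d.get("perturbations", [])]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def preset(name: str, scale: float = 1.0, **overrides) -> SimParams:
    """Named parameter sets for the study conditions.

    ``scale`` shrinks the domain (radius0, growth_rate and seed counts) while
    keeping the interaction scales (step, r_a, r_rep, R_sense) physical, for
    cheaper runs with the same local statistics.

    Presets
    -------
    wt                  : full model with combined isotropic+directional
                          density-sensed side-branching (the mechanism the
                          sprout-targeting metrics support in vivo)
    wt-random           : wild-type kinetics with location-blind (random)
                          side-branching
    no-side             : p_s = 0, invasion only (giant-fluctuation regime)
    svegfr3             : VEGF-C/D ligand trap -- all branching off from t = 7 d (P11)
    vegfc-het           : Vegfc+/- -- side-branching off, tip-branching at 25%
    clp24               : Clp24 endothelial deletion at P8 -- branching at 150%
    """
    base = SimParams()
    if name in ("wt", "wild-type"):
        base.side_branch_mode = "combined"
    elif name == "wt-random":
        base.side_branch_mode = "random"
    elif name == "no-side":
        base.p_side = 0.0
    elif name == "svegfr3":
        base.perturbations = [Perturbation(time=7.0, pb_factor=0.0, ps_factor=0.0)]
    elif name == "vegfc-het":
        base.perturbations = [Perturbation(time=0.0, pb_factor=0.25, ps_factor=0.0)]
    elif name == "clp24":
        base.perturbations = [Perturbation(time=4.0, pb_factor=1.5, ps_factor=1.5)]
    else:
        raise ValueError(f"unknown preset {name!r}")
    if scale != 1.0:
        # shrink the domain while keeping the interaction scales (step, r_a,
        # r_rep, R_sense) physical; tip speed scales with the domain so the
        # invasion still crosses the pinna in the same number of days and the
        # dilation-to-elongation ratio g/v is preserved
        base.radius0 *= scale
        base.growth_rate *= scale
        base.tip_speed *= scale
        base.n_trees = max(2, int(round(base.n_trees * scale)))
        base.n_tip_trees = max(1, int(round(base.n_tip_trees * scale))) if base.n_tip_trees else 0
    for k, v in overrides.items():
        if not hasattr(base, k):
            raise ValueError(f"unknown parameter {k!r}")
        setattr(base, k, v)
    base.validate()
    return base
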