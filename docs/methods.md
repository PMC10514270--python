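# Methods

## Model

The simulator implements a branching-and-annihilating random walk (BARW)
for the growth of a planar vessel network in a uniformly expanding tissue.
The domain is a half-disk of radius R(t) = R₀ + g·t with its flat edge on
y = 0 (the stalk of the ear pinna) and tissue at y ≥ 0; the developmental
window maps P4 → t = 0 and P21 → t = 17 d.

Each time step dt = δ/v (one elongation step per tip) applies, in fixed
order:

1. **Dilation.** Coordinates are scaled about the origin by
   R(t+dt)/R(t). Duct cells ("particles", one per cell, nominal spacing
   one step length) proliferate stochastically: each cell divides
   independently with probability equal to the relative stretch of the
   step, the daughter staying adjacent on the same duct and inheriting
   the mother's label. Cell spacing is thereby restored in expectation,
   and every labeled lineage grows as a Yule process — which is exactly
   what gives the duct-cell clone population its exponential (geometric)
   size distribution. Deterministic gap-triggered insertion would restore
   spacing too, but duplicates each cell quasi-deterministically and
   destroys that distribution.
2. **Elongation.** Each active tip turns by N(0, σ_θ²) plus a repulsive
   bias k_rep·(1 − d/r_rep) away from the nearest visible duct point
   within r_rep, then advances by δ. Tips stepping outside the domain
   terminate (boundary fate).
3. **Tip-branching.** With probability p_b per step a tip is replaced by
   two daughters whose headings open by φ ~ N(70°, 15°) (clipped to
   [20°, 160°]) symmetrically about the parent heading.
4. **Annihilation.** A tip that has laid at least one segment terminates
   when any *visible* duct segment lies within r_a of it. Visibility is
   the crux: a tip ignores all vessel within graph-arc distance
   n_self·δ of its current node (breadth-first walk on the network). This
   single rule excludes the tip's own trail, the parent duct around its
   branch point, and a sibling's or uncle's newborn branches — the duct
   continuum the tip just emerged from — while leaving genuinely foreign
   vessel lethal at r_a (two head-on tips stop at ≈ r_a separation). A
   trailing-window exclusion of the tip's own recent steps cannot do this:
   newborn daughters sit directly on the family's ducts and annihilate at
   birth, which makes branching effectively lethal and extinguishes the
   invasion. An optional probabilistic mode terminates tips at a rate
   proportional to the locally sensed density instead of a hard radius.
5. **Side-branching.** Candidate sprout sites arrive as a Poisson process
   along alive duct arclength with rate p_s·dt. Four modes:
   *random* (all candidates accepted, heading perpendicular with random
   sign); *isotropic* (accepted with probability max(0, 1 − ρ/ρ*), where ρ
   is the vessel density in the disk of radius R_sense around the site);
   *directional* (always accepted, heading chosen among n_dir
   perpendicular-biased candidate directions — uniform within ±60° of the
   two perpendiculars — minimizing the vessel mass in the half-disk of
   radius R_sense it faces); *combined* (isotropic acceptance and
   directional heading). The in-simulation density uses segment-midpoint
   membership for throughput; all analysis densities use exact
   line–circle clipping.
6. **Pruning.** Terminal (degree-1, non-growing) branches regress with a
   configured rate per branch per day, back to the nearest branch node;
   removed segments are flagged dead, not deleted, so regressed "sleeves"
   remain inspectable. Off by default.

Rate multipliers from a perturbation schedule apply to p_b, p_s and the
pruning rate from their switch-on times; presets cover the ligand-trap
(all branching off from t = 7 d), the heterozygote (side-branching off,
tip-branching at 25%) and the overactive (both rates at 150% from t = 4 d)
conditions.

Randomness is split into independent substreams per mechanism (seeding,
elongation, tip-branching, side-branching, pruning, dilation insertions,
labeling, annihilation), so ablating one mechanism does not shift
another's draws, and a fixed seed reproduces the event log bit for bit.

## Parameters

| parameter | default | meaning |
|---|---|---|
| R₀ | 2000 µm | initial half-disk radius |
| g | 180 µm/day | radius growth rate |
| v | 450 µm/day | tip speed (stalk trees reach the distal edge ≈ t = 9 d) |
| δ | 10 µm | elongation step |
| σ_θ | 0.15 rad/√step | angular noise |
| p_b | 0.10 /step | tip-branching probability |
| φ | N(70°, 15°) | daughter opening angle |
| r_a | 40 µm | annihilation radius |
| n_self | 12 steps | self-exclusion arc (n_self·δ = 120 µm along the network) |
| r_rep, k_rep | 60 µm, 0.3 rad | repulsion range and maximal turn |
| p_s | 2×10⁻³ /µm/day | side-branching rate |
| R_sense | 150 µm | density-sensing radius |
| ρ* | 0.020 µm⁻¹ | density cap for isotropic acceptance (≈ the wild-type steady-state density) |
| n_trees, n_tip_trees | 12, 5 | stalk seeds at t = 0, distal seeds at t = 2 d |
| duration | 17 d | P4 → P21 |

The interaction scales (δ, r_a, r_rep, R_sense) and the noise are treated
as physical. The kinetic parameters p_b, p_s, k_rep and ρ* are not
directly measurable from printed data; they were calibrated once, by
parameter sweeps, to reproduce the wild-type regimes — a supercritical
invasion that covers the pinna by t ≈ 9 d with broadly distributed branch
lengths, giant density fluctuations (α ≈ 0.7) when side-branching is
disabled, and relaxation to the equilibrium exponent α ≈ 0.5 in the full
wild-type model — and then frozen. ρ* is tied to the wild-type
steady-state density, which makes the isotropic acceptance self-limiting.
n_self was set by the geometry of sibling separation: daughters opening at
70° are ≈ 0.57·a apart after each has grown an arc a, so the exclusion arc
must comfortably exceed r_a/0.57 ≈ 70 µm; 120 µm leaves margin for angular
noise. The `wt` preset uses combined (isotropic + directional) sensing,
the mechanism the sprout-targeting metrics support; `wt-random` keeps the
same kinetics with location-blind side-branching and is used for the clone
analyses, where the choice of side-branching mode has little consequence.

## Reduced-scale runs

Tests and the acceptance script run the model on a desk scale: R₀, g and v
are multiplied by s = 0.3 (clone analyses: 0.25) while δ, r_a, r_rep and
R_sense stay physical. Scaling the speed with the domain preserves the
crossing time of the invasion (≈ 9 d) and the dilation-to-elongation ratio
g/v, so the local statistics (branch lengths, spacings, angles) and the
developmental sequence are unchanged; only the number of ducts shrinks
with the domain area. Window sides for the exponent are reduced
accordingly (60–240 µm in six logarithmic steps against a final radius of
≈ 1.5 mm, keeping ≥ 20 fully interior windows per scale). The clone-size
threshold separating the large population scales with domain area
(10⁵ µm² × s²). Labeling-time comparisons are stage-matched rather than
day-matched: in the reduced system the earliest days contain
proportionally more growing tips per cell than the corresponding in-vivo
stages, so "early" induction is taken at t = 5 d (invasion ongoing,
coverage incomplete) and "late" at t = 8–12 d.

## Analysis choices

- **Fluctuation exponent.** α is the least-squares slope of log SD versus
  log mean of window masses across window sides; windows are
  non-overlapping, axis-aligned and fully interior (boundary-clipped
  windows are discarded, not renormalized); masses are exact clipped
  arclengths. The estimator is validated on homogeneous Poisson segment
  fields (α = 0.5 within fit error) and on the maximally clustered
  all-or-nothing construction (α = 1 exactly).
- **Branches.** Morphological segments are maximal paths between nodes of
  degree ≠ 2. The exponential-tail rate is the ML estimator
  λ = 1/mean(x − x₀) over lengths above a threshold (default: the
  median), with a Kolmogorov–Smirnov goodness-of-fit check.
- **Lateral vs fork.** At each degree-3 node the three outgoing tangent
  directions are averaged over 20 µm of arc; the node is lateral if the
  largest pairwise angle (the "through" angle) is ≥ 165°. The threshold
  was calibrated against simulation event-log ground truth (side-branch
  roots vs tip-splitting nodes): with daughters opening at φ ~ N(70°, 15°)
  a fork's through angle is ≈ 180° − φ/2 ~ N(145°, 7.5°), so thresholds
  near 150° misclassify a quarter of forks; 165° classifies ≥ 85% of both
  classes correctly.
- **Sprout metrics.** Neighboring vessel around a point is weighted by the
  exact arclength of each segment clipped to the probe disk, positioned at
  the midpoint of the clipped portion. A sprout's own segments — its tip's
  ducts and those of all descendant tips — are excluded from its
  neighborhood; the parent duct is not. Nascent sprouts are scored in the
  snapshot in which they are nascent (created within the last 1–1.5 d
  before the snapshot), mirroring annotation of fresh sprouts in an image
  series; scoring old sprouts against the final network dilutes the
  density deficit because a successful sprout fills the very gap it
  targeted. Null references use points sampled uniformly by arclength
  with directions uniform on the circle.
- **Clones.** A clone is the set of particles descending from one labeled
  founder (lineage, not spatial contiguity). Labels never influence the
  dynamics, so induction at time t is applied retrospectively through the
  recorded genealogy: a particle belongs to the clone of its unique
  ancestor alive at t. This makes labeling-time sweeps exactly equivalent
  to matched runs sharing the growth seed, at the cost of a single
  simulation. Areas are particle count × spacing × nominal width
  (10 µm); the conversion sets only the scale of the size axis.

## What the generator does and does not emulate

Simulated networks reproduce the in-vivo phenomenology this model family
is built around: stochastic invasion with density-limited termination,
broad branch-length distributions with exponential tails, giant density
fluctuations after invasion, their relaxation by side-branching,
bimodal clone-size distributions from tip versus duct labeling, and
density-targeted sprout initiation. They do not emulate image-derived
properties of real data — segmentation noise, vessel calibers, loops
formed by anastomosis (the model's networks are trees with terminations),
the deep collector network, or 3D tissue curvature — so passing tests
validates the algorithms and the model's internal consistency, not
image-analysis robustness.

## Numerical notes and limitations

- Degenerate inputs: zero-length segments are rejected at construction;
  splitting clamps sprout sites ≥ 0.5 µm from segment ends; window scales
  with fewer than 20 interior windows raise errors naming the scale;
  nematic order with no pairs and front/back ratios with zero back-mass
  return flagged results rather than numbers.
- The in-loop density sensing uses segment midpoints (adequate because
  simulator segments are ≤ ~25 µm); all reported metrics use exact
  clipping.
- Segment lengths are cached and rescaled on dilation; analysis paths
  recompute from coordinates.
- The graph-arc exclusion makes vessel within 120 µm of network distance
  mutually invisible; at very high side-branching rates with no density
  cap (random or directional-only modes pushed hard) this permits locally
  dense brush-like growth that the hard annihilation radius would
  otherwise forbid. The isotropic acceptance (wild-type preset) caps this
  by construction.
- Event-log determinism holds per (seed, parameter set, package version);
  floating-point reproducibility across platforms is expected for the
  numpy operations used but not formally guaranteed.
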