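# Methods

`mtcortex` simulates the self-organization of the plant cortical microtubule
array on the unrolled surface of a cylindrical cell, with the protoxylem
band/gap scenario and the analytic geometry of array–ROP-pattern
co-alignment. This note documents the model, the numerical choices, the
parameterization, and what the shipped tests do and do not demonstrate.

## Model

### Geometry

The cell cortex is the rectangle `[0, W) × [0, H]` with `W = 2πR`; `x` is
periodic (circumferential), `z` is bounded by the cell edges. Directed
growth headings ψ are measured from the long axis, so transverse growth is
ψ = 90°. Internally, `x` is kept *unwrapped* so polylines remain continuous
across the seam; periodicity enters only through exact periodic-image
handling in intersection queries and through canonicalization on export.
Growing tips insert plain "wrap" vertices so that no single segment exceeds
`W/2`; this bounds the number of periodic images any query must consider
and makes minimal-image reconstruction of exported snapshots exact.

### Microtubules and dynamic instability

A microtubule is a polyline from its treadmilling minus end to its dynamic
plus end. The plus end switches stochastically between growth (speed
`v_plus`) and shrinkage (`v_minus`) with catastrophe rate `r_cat` and
rescue rate `r_res`; the minus end retracts at constant `v_tm`. Shrinkage
retraces the stored polyline exactly; a rescued tip resumes along the local
polyline direction. A tip reaching either cell edge (z = 0 or H) is clamped
there and undergoes a catastrophe.

### Collisions, bundling, severing

A growing tip colliding with another microtubule at angle α:

- α < θ_bundle (default 40°): **bundling** — the tip is entrained along the
  co-aligned sense of the obstructing trajectory. Bundles are co-incident
  trajectories with no lateral spacing, so membership at a point is a
  geometric recount of collinear coverage.
- α ≥ θ_bundle: **induced catastrophe** with probability `p_cat`
  (default 0.09), otherwise a **crossover**. Each live crossover carries an
  independent exponential katanin clock at rate `r_sever`; on firing, the
  later-arriving (cytoplasmic-side) microtubule is severed at the crossing:
  the minus-side fragment gets a new shrinking plus end, the plus-side
  fragment a new treadmilling minus end, conserving total length. Zero-length
  fragments (cuts exactly at an endpoint) are discarded immediately.
  Crossovers disappear when either polyline retracts past the point, which
  invalidates pending severing events.

### Flexibility

Semiflexible growth uses discrete deflections: straight runs of exponential
length (mean `delta_d`, default 0.3 µm) followed by a turn drawn uniformly
from `[-m, m]`, with sub-threshold turns (|angle| < 1e-3 rad) snapped to
zero. The calibration `m = sqrt(3·delta_d/L_p)` equates the per-step
variance `m²/3` with `delta_d/L_p`, giving the 2D worm-like-chain law
`⟨θ²(s)⟩ = s/L_p` (tangent correlation `exp(-s/2L_p)` in 2D). `L_p = ∞`
recovers rigid microtubules with exactly straight free trajectories. The
estimator/generator round trip (recovery within a few percent for
L_p ∈ {50, 300, 2000} µm from 300 paths of 50 µm) is the arbiter of this
convention; halving `delta_d` (with recalibrated `m`) leaves the recovered
L_p unchanged within scatter, so the step size is immaterial.

Inside a bundle of `n` other members, a deflection attempt is executed with
probability `1/(n+1)` (the rejected fraction `n/(n+1)` approximates that
only the outermost member has room to bend away); an executed deflection
makes the microtubule leave the bundle. Bundled tips follow their bundle
around polyline bends smaller than the tracking angle (default 10°; bends
created by bundling events can reach 40° and are not tracked); at a split
below the tracking angle the continuation is chosen with probability
proportional to branch occupancy. When the host trajectory ends or
diverges, the follower simply continues straight and leaves the bundle.

### Nucleation

Two modes. *Isotropic* (legacy): Poisson events at rate `r_iso` with
uniform position and direction. *Local density-dependent*: appearance
events at rate `r_app` draw a uniform appearance point; `n_dir` rays
("metatrajectories", default 24) in equally spaced directions with one
shared uniform angular offset stand in for complex diffusion. A ray whose
first microtubule crossing lies at distance `d ≤ d_max` contributes
bound-nucleation weight

    P_j = (1/n_dir) · exp(-d_j · sqrt(r_u / D)),

the 1D diffusion-with-killing splitting probability for a complex with
membrane diffusion coefficient `D` and free-nucleation rate `r_u`; the
remaining mass `1 − ΣP_j` is an unbound nucleation at the appearance point.
The functional form is isolated in `nucleation.metatrajectory_weight` so it
can be swapped. `d_max` (default 10 µm) is chosen so the survival factor at
the cutoff is below 1e-4 for the default `sqrt(D/r_u)` = 1 µm. A bound
candidate is then accepted with probability `p_acc_mt` (default 0.62), an
unbound one with `p_acc_free` (default 0.02) — the complements of the
empirical dissociation frequencies of lattice-bound and freely diffusing
complexes. Accepted nucleations occupy one of `N_c` complexes (default 200)
for `t_occ` (default 90 s, the katanin-mediated release time), and each
appearance event is rejected outright with probability
`occupied/N_c` — this couples the global nucleation rate to the pool and
shifts nucleations toward regions that retain microtubules.

Bound daughters are parallel (fraction 0.31), antiparallel (0.07) or
branched (0.62) to the parent, the branch angle drawn from a normal
distribution with mode 35° (spread 15°) truncated to (0°, 180°), side
chosen equiprobably. Parallel/antiparallel daughters are entrained as
bundle members from birth.

### Protoxylem scenario

The banded ROP/MIDD1 prepattern is static: `n_bands` axial bands of width
`w_b` (half-open intervals, first band starting at z = 0) separated by gaps
of width `w_g`; after the activation time `t_band` the catastrophe rate in
gaps is multiplied by `f_cat` (default 3), bands keep baseline dynamics.
Initiation is two-phase: until `t_bias_end` all nucleations are placed
uniformly with directions drawn normal around the bias angle (σ default
0.018 rad ≈ 1°), then the configured nucleation mode runs under uniform
dynamics until activation. Bias-phase appearances pass the pool-occupancy
rejection but not the dissociation thinning: the phase exists to firmly
establish a transverse array, which the 2% free-complex acceptance could
not do at any sensible appearance rate.

### Co-alignment analytics

A banded or spiral ROP pattern with intrinsic band spacing `b` must close
around the cylinder: one trip around the circumference advances an n-start
spiral by n band spacings, so admissible orientations (from transverse) are
`θ_n = arctan(n·b/W)`, n = 0 (rings), 1, 2, … Assuming the pattern adopts
the admissible orientation nearest the array's, the worst-case mismatch is
the largest half-gap, `θ_1/2` (gaps shrink with n because arctan is
concave). For R = 7.5 µm and b = 6 µm this is 3.63° → 3.6° at one decimal.
Two straight-line limits quantify band confinement: a microtubule spans the
circumference within one band only below `arctan(w_b/W)` (≈1.22° at
defaults), and at mismatch α it fits `w_b/sin α` inside a band.

## Event engine

The simulation is exactly event-driven: between events all endpoints move
linearly, so every next state change has a closed form. Stochastic events
(catastrophe, rescue, severing, appearance) carry exponential waiting
times; geometric events (collision, edge arrival, deflection point,
band/gap boundary crossing, vertex passages, death, bundle-vertex arrival,
wrap subdivision) are computed exactly. Events execute in non-decreasing
time, deterministic before stochastic at ties, then by subject id — runs
are bit-reproducible from the seed. Randomness flows through three named
substreams (dynamics, nucleation, flexibility) so adding events in one
subsystem does not perturb another's draws.

Collision scheduling treats obstructing segments as *moving extents*: each
segment lies on a fixed carrier line and only its terminal arc coordinates
move, so the crossing time of a growing tip with any segment solves a
linear equation. Scheduled events carry per-subject sequence numbers (plus
the obstacle's geometry version for collisions and bundle tracking) and are
lazily recomputed on mismatch at pop time; whenever a tip starts covering
new ground (nucleation, rescue, deflection, bundling) every other growing
tip is probed against the new moving segment so no earlier collision can be
missed. The position-dependent catastrophe rate is handled exactly for the
piecewise-constant band/gap profile by re-drawing the waiting time at
deterministic boundary-crossing events and at the activation instant
(memorylessness makes the re-draw statistically exact).

Validation hooks: a conservation audit records, at every event, the total
length and the growing/shrinking/total counts and checks
`dL/dt = n_grow·v_plus − n_shrink·v_minus − n_mt·v_tm` on each inter-event
interval to 1e-6 µm; a collision audit re-derives every first-collision
search with an independent scalar all-pairs brute force (periodic images
and moving extents included) and requires identical hit identity and time
to 1e-9 s. Coincident bundled trajectories make hit identity degenerate, so
equal-point equal-time hits count as agreement.

Numerical choices: crossings closer than 1e-9 µm along a path are treated
as coincident with the collision just resolved and skipped; directions
within 1e-12 of parallel never intersect transversally; collinear coverage
("same trajectory") uses a 1e-7 µm tolerance, which is safe because
entrained geometry is copied exactly, not re-derived.

## Parameterization

Speeds and rates are deliberately required configuration fields with no
built-in defaults. The shipped example configurations use values
representative of measured protoxylem microtubule dynamics in the
literature: `v_plus = 0.058`, `v_minus = 0.085`, `v_tm = 0.005` µm/s,
`r_cat = 0.0048`, `r_res = 0.0063` /s (bounded-growth regime),
`r_sever = 0.001` /s per crossover, `p_cat = 0.09`, θ_bundle = 40°. The
nucleation defaults (`D = 0.013` µm²/s, `r_u = 0.013` /s, n_dir = 24,
acceptance 0.62/0.02, pool 200 × 90 s) give a bound-nucleation length scale
of 1 µm and bound-dominated nucleation in a developed array. These are the
package's own choices where a single published value was not available to
it, and they are stated in the configs, not hard-coded.

## Scaled-down study conditions

The full-scale protoxylem ensembles (R = 7.5 µm, 10 bands, 7 simulated
hours, 100 replicates) are out of scope for the test suite; the shipped
band-formation checks run R = 2 µm with 4 bands (H = 24 µm), appearance
rate 0.3 /s, a shortened schedule (30 min bias, activation at 60 min,
90 min of banding) and 5 seeds per condition. Under these conditions the
fraction of microtubule length in bands rises from the ~16.7% area share to
well above it after activation with a transverse (zero-mismatch) initial
array, and a 3.6° initial mismatch loses band density over the first hour
of banding relative to zero mismatch — the directional behaviour of the
full-scale system. What these scaled runs do *not* show: quantitative
densities or populated-band counts of the full geometry, long-run
steady-state maintenance (the small domain loses total density during
banding), or flexibility–nucleation interaction effects, which require
larger ensembles.

The persistence-length estimator fits the tangent-variance line
`⟨θ²(s)⟩ = s/L_p` by pooling squared tangent-angle increments over an
arc-length grid — the efficient estimator of that slope, since the squared
angle grows linearly with independent increments; the tangent angle of a
polyline is sampled exactly as a step function in arc length. Straight
paths report `L_p = ∞`.

## Known limitations

- Bundles have no lateral structure; occupancy is a collinear recount, and
  the deflection-rejection rule `n/(n+1)` is an approximation.
- A follower whose host is severed behind it simply leaves the bundle
  rather than re-attaching to the fragment.
- Minus ends only retract (no pause, no minus-end dynamics); there is no
  tubulin-pool limitation and no pausing state.
- The ROP pattern is a static prepattern; reaction–diffusion ROP dynamics,
  mechanical stress cues, and metaxylem pit patterning are out of scope.
- The band/gap catastrophe profile is a step function; gradual profiles are
  not implemented.
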