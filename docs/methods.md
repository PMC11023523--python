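# Methods

## The model

`polarweave` simulates a quiescent epithelial monolayer that re-activates
into collective migration, as an **active elastic solid (AES)**: N
self-propelled particles ("cells") permanently connected to their
Voronoi neighbours by nonlinear springs. Each cell i carries a position
R_i and a unit polarity P_i (its propulsion direction) and obeys the
overdamped equations

    Ṙ_i = V_c P_i + F_i / ζ
    Ṗ_i = γ (P_i × Ṙ_i) × P_i ,

where F_i = −∂/∂R_i Σ U(r_ij) with the pair energy

    U(r_ij) = (K/2)(d_ij − r_ij)² + B (d_ij − r_ij)⁴ .

The polarity equation turns the propulsion direction toward the actual
velocity: a cell that is pushed sideways by its neighbours steers with
the push ("force synchronisation"). The quartic term stiffens the spring
at large strain, suppressing compressional collapse and overstretching.

Two reduced parameters control the physics: the rigidity
**K̃ = K d / (ζ V_c)** and the turning rate **γ̃**. We quote γ per
micrometre of displacement — γ = γ̃ μm⁻¹ — so γ̃ = 1.5 means the polarity
turns by 1.5 rad per μm moved when perpendicular to the velocity. We
verified the alternative convention γ = γ̃/d (turning ~20× slower): it
destroys the hallmark phenomenology — the confined monolayer then ends
in a rim-orbiting polarized blob instead of retaining a persistent
central +1 vortex — so the per-μm convention is the one used throughout.

### Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| V_c | 35 | μm/h | propulsion speed of an unobstructed cell |
| d | 22.5 | μm | mean cell spacing / rest length |
| ζ | 1 | — | substrate friction; defines the force unit |
| K̃ | 40 | — | reduced rigidity (moderate-deformation regime is 10–50) |
| γ̃ | 1.5 | 1/μm | turning per μm of displacement; ≳ 1 gives polar ordering |
| B̃ = B d³/(ζ V_c) | K̃/4 | — | quartic term equals the harmonic one at 50% strain, negligible below ~20% |
| R | 3500·√(N/10⁵) | μm | domain radius at the reference density (10⁵ cells per 3.5-mm well) |

B is a free choice (only its order matters); B̃ = K̃/4 keeps the spring
essentially harmonic at moderate deformations while preventing
overcompression.

### Lattice construction

Points are packed by random sequential insertion of polydisperse disks
(diameters uniform on [0.8d, 1.2d]) started at 60% of target size, grown
stepwise with deterministic overlap push-apart sweeps (the
zero-temperature limit of Metropolis moves on the overlap energy) under
confinement to the disk. Springs are the Delaunay edges (equivalently
Voronoi adjacencies); hull slivers longer than 1.5d are pruned, and if
pruning would disconnect the graph the shortest pruned edges are
restored. Rest lengths d_ij are drawn i.i.d. uniform on [0.8d, 1.2d]
(mean d), which builds in microscopic disorder and gives globally
isotropic elasticity; `rest_length_mode="distance"` instead inherits the
packed distances (clamped to the interval), giving a stress-free initial
state — useful when a property of the alignment dynamics should be
isolated from the residual packing pre-stress.

Note the reference geometry (10⁵ cells, R = 3.5 mm, d ≈ 22.5 μm) is
slightly denser than a hexagonal packing at spacing d, so packed
nearest-neighbour distances average 10–20% below d; the rest-length
statistics are unaffected (mean d by construction).

### Boundary condition

Cells outside the domain feel a linear inward spring force (stiffness K
by default). The polarity "turns away from the boundary": by default a
**slip** rule cancels the outward radial polarity component for cells
within 2d of the rim, leaving rim polarity tangential or inward; a
rate-based alternative (`boundary_mode="turn"`, default 5 h⁻¹) rotates
the polarity toward the inward normal. Slip in a 2d shell is the
default because the rate rule in a thin d/2 shell is too weak at desk
scale: the sheet then presses into the wall and collapses into an
orbiting polarized blob instead of coarsening to a vortex.

### Integration

Explicit Euler. The default step satisfies three bounds: advective
(V_c·dt ≤ 0.05 d), spring stability (dt ≤ 0.25 ζ/(K·deg_max)), and
polarity rotation (γ V_c dt ≤ 0.2). For K̃ = 40 the spring bound is
tightest (dt ≈ 5·10⁻⁴ h). The step is shrunk so snapshot times are hit
exactly; a compiled (numba) kernel applies the identical update for long
runs, agreeing with the pure-numpy reference step to ~10⁻¹³ (tested). A
guard aborts if any particle moves more than d/2 in a step. Halving dt
changes the final polar order by < 2% (tested).

## Velocity-field analysis

**Gridding.** Particle velocities are averaged in 165-μm square windows
on a 66-μm grid (matching the PIV settings of the experiments this
emulates: 165-μm interrogation windows with 99-μm overlap); empty
windows are masked. Mathematical axes (x right, y up) — winding signs
depend on this convention.

**Winding number.** At each grid point the velocity directions of the 8
surrounding nodes, traversed anticlockwise from the top-left, are
range-adjusted and their folded differences summed; the result divided
by 2π is the local winding number ω: +1 at a vortex (either spin), −1 at
a saddle. A brute-force loop-winding oracle (direction sum along any
closed rectangle) cross-checks charge additivity in the tests.

**Defect filtering.** A defect core straddles a grid cell, so winding
fires on the few adjacent nodes enclosing it; contiguous same-charge
nodes (within 1.5 grid spacings) are collapsed into one localized core
first, and cores of the same charge strictly closer than 165 μm are
then merged (size-weighted centroid). Merging raw winding nodes instead
would inflate the effective merge separation by the core's plaquette
extent. Opposite charges are never merged — that would erase imminent
annihilation pairs. Defects must persist ≥ 2 consecutive frames
(same-charge match within a link radius).

The persistence/link radius defaults to the merge radius (165 μm), which
suits slow experimental defect motion; in the desk-scale simulations the
lone vortex core wanders 200–350 μm between 15-min frames (measured
median 209 μm, p95 355 μm), so the simulation studies use a 400-μm link
radius. With the default the persistence filter deletes a perfectly
detected core in ~70% of frames.

**Correlation length.** The spatial correlation function is the
cosine-weighted inner product of velocity fluctuations at x-axis lags,

    C(r) = 1/(Nx·Ny·(Nx−r)) ΣΣ [δu δu′ + δv δv′] cos(θ − θ′),

with fluctuations about the frame's spatial mean. Beware a structural
property of this estimator: for uncorrelated directions at constant
speed the summand reduces to |v|² cos²Δθ, so the normalized curve decays
to a baseline of 0.5, not 0. The exponential fit a·exp(−r/b) is
therefore restricted to lags before the curve first drops below 0.15
(at least 5 lags), and ξ solves a·exp(−ξ/b) = 0.5. If the fitted
amplitude ends ≤ 0.5 the 0.5 crossing of the data itself is
interpolated; if the curve never reaches 0.5, ξ is right-censored at the
maximum lag and flagged (a spatially constant field is maximally
ordered by convention). On synthetic direction-noise fields with
exponential autocorrelation exp(−r/λ), the estimator recovers
ξ = λ·ln 2 with < 10% bias for λ ∈ [150, 600] μm on 64×64 grids.

**Vorticity.** ω = ∂v/∂x − ∂u/∂y by central differences (one-sided at
edges); rigid rotation at rate Ω gives 2Ω exactly on the interior.

## Defect tracking and annihilation calling

Per-frame defects are linked by greedy mutual-nearest-neighbour matching
(same charge, within the link radius; candidates accepted in order of
distance). Defect speed is path length divided by the number of time
points, for stable tracks of ≥ 25 points only. An annihilation is a
(+1, −1) track pair dying within one frame of each other with final
positions within 165 μm; proliferation is the mirrored condition on
births. Tracks ending at the observation border (margin one PIV window)
or at the last frame are not event candidates — leaving the field of
view is not annihilation.

**Corridor reversal.** For each annihilation the circular-mean velocity
direction in the rectangle between the pair's final positions is
compared one frame before death versus one frame after. Two details
matter and were validated on an analytic pair-annihilation fixture
(which yields exactly 180°): the rectangle is shortened by 25% of the
segment at each end, because the swirling flow at the cores otherwise
dilutes the corridor direction (the direction field of a pair rotates by
tens of degrees within half a grid spacing of the axis, and only
symmetric sampling about the axis cancels this); and corridors covering
fewer than 2 grid points are discarded as unresolved. Events in the
first simulated hour are discarded — the velocity field is still
developing from the noise-dominated quiescent state, mirroring the
experiments, where imaging starts 1 h after stimulation.

## Trajectory kinematics

**Relative motility** registers all trajectories so a chosen anchor cell
is stationary (pure translation per frame), then reports each other
cell's summed per-frame step lengths divided by the window duration —
the standard window is 101 frames at 4-min intervals (6.7 h). It is
invariant under any global rigid translation (tested) and zero for rigid
co-movement.

**Pair diffusion**: for track pairs within 23 μm at the first frame and
complete over the window, the mean squared inter-pair distance per frame
is regressed linearly on time; the slope (μm²/h) reads out solid
(slope ≈ 0) versus fluidised (positive slope) behaviour. Fewer than 30
qualifying pairs triggers a warning (the reference protocol analyses at
least 30 pairs per sample). No categorical solid/liquid call is made —
only the slope is reported.
For independent 2D random walks with per-axis step std σ the slope is
4σ²/frame-interval (verified against a Monte-Carlo oracle).

## The synthetic-data generators

`compose_defect_field` superposes point defects by angle addition
(θ = Σ q_k atan2(y−y_k, x−x_k) + ψ), so planted charge, position and
spin are exact ground truth for the detector. `correlated_noise_field`
perturbs a uniform direction with a Gaussian field of exponential
autocorrelation built by circulant spectral filtering on a 2× padded
grid (exact target correlation on the torus); the default direction
noise σ_θ = 0.4 rad keeps the cosine-weighted correlation estimator in
its small-angle regime. `synth_trajectories` produces rigid, diffusive
or mixed tracks with known drift and step statistics. What these
fixtures do **not** emulate: PIV measurement noise and window-correlated
errors, cell division and death, density inhomogeneity, and image
registration artifacts — tests passing on them validate the estimators'
mathematics, not robustness to every property of microscope data.

## Desk-scale study conditions and their limits

The simulation studies use N = 5,000 cells (R ≈ 783 μm at the reference
density), K̃ = 40, γ̃ = 1.5, random initial polarity, 40-h observation
with 15-min snapshots — a ~20× linear scale-down of the reference
system (10⁵ cells in a 3.5-mm well, imaged 30–50 h). Consequences
observed and accounted for in the tests:

- Coarsening is fast (minutes–hours) and yields few annihilation events
  per run (~1–3 measurable ones); statistics therefore pool ≥ 5 seeds.
- The terminal single +1 vortex persists for the whole window, but its
  core wanders through the domain interior rather than sitting at the
  geometric centre (at 10⁵ particles the core is reported stationary at
  the centre); "central" is tested as the core staying inside the
  domain interior (radius < 0.8R) rather than at the origin.
- Defect counts at a single late frame flicker (the core occasionally
  crosses regions where the 8-neighbour winding stencil is masked near
  the rim), so final-state statistics use the modal count over the last
  10 h, not one frame.
- The measured corridor reversal across annihilations comes out at
  ~140–155° rather than the ideal 180°. The estimator itself returns
  exactly 180° on the analytic pair fixture; in the scaled-down runs the
  pair separation at annihilation is only 1–2 PIV windows, so defect
  localization error (±half a grid step) and window smoothing mix
  unreversed surrounding flow into the corridor — biases that all act
  toward smaller angles. The reported value is therefore a lower bound
  on the physical reversal.
- The defect-count/ν and defect-count/ξ anticorrelations are evaluated
  on frame-wise seed-averaged curves over the coarsening window (first
  10 h), mirroring how the reference curves average n = 8 monolayers;
  per-seed ξ series are sign-unstable because the correlation structure
  of a single-vortex field moves with the wandering core.

## Numerical conventions

- Units: μm, hours, μm/h everywhere; forces in units of ζV_c.
- Every random stage draws from `numpy.random.default_rng` seeded with a
  namespaced tuple (seed, stage), so packing, rest lengths and initial
  polarity are independent streams even for equal seeds.
- Cocircular Voronoi ties are broken by a 10⁻⁶ d jitter applied only for
  the tessellation.
- Degenerate inputs fail loudly: coincident bonded particles, infeasible
  packing densities, anchor-track gaps, zero-charge defect rows, and
  non-monotone frames all raise with diagnostics.
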