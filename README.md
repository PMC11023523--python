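# polarweave

Simulation and velocity-field topology analysis of collective cell
migration in epithelial monolayers.

When a quiescent (serum-starved) keratinocyte monolayer is re-activated,
initially immobile cells with random polarity self-organise into
large-scale coherent migration. The ordering is *topology-guided*: the
emerging velocity field first fills with ±1 topological defects —
vortices (winding number +1) and saddles (−1) — and long-range polar
order spreads through the mutual attraction and annihilation of
oppositely charged defect pairs, until a confined circular monolayer
retains a single +1 vortex. `polarweave` implements both sides of that
story at desk scale:

- an **active-elastic-solid (AES) simulator** — N self-propelled cells
  connected by nonlinear springs on a disordered Voronoi lattice,

      Ṙ_i = V_c P_i + F_i/ζ ,
      Ṗ_i = γ (P_i × Ṙ_i) × P_i ,
      U(r_ij) = (K/2)(d_ij − r_ij)² + B(d_ij − r_ij)⁴ ,

  with reduced rigidity K̃ = K d/(ζ V_c) and turning rate γ̃ (per μm of
  displacement), under circular confinement; and

- a **PIV-style analysis chain** for gridded velocity fields: ±1 defect
  detection by the eight-neighbour winding number, 165-μm same-charge
  merging, two-frame persistence, defect tracking and
  annihilation/proliferation calling, the corridor-direction reversal
  across annihilations, mean speed ν, the cosine-weighted spatial
  correlation function and its 0.5-crossing length ξ, vorticity, and
  trajectory kinematics (anchor-registered relative motility, pair
  mean-squared-separation slopes).

Synthetic generators (planted defect fields, direction noise with known
correlation length, rigid/diffusive/mixed trajectories) provide exact
ground truth for every estimator.

## Worked example

Build a monolayer, run the confined AES model, and read out the
topology:

```python
import polarweave as pw

n = 5000
R = pw.scaled_domain_radius(n)          # 783 um at reference density
cfg = pw.RunConfig(
    lattice=pw.LatticeSpec(domain_radius=R, target_cell_count=n,
                           mean_spacing=22.5, rng_seed=0),
    sim=pw.SimParams.from_dimensionless(40, 1.5, domain_radius=R,
                                        rng_seed=0),
    detection=pw.DetectionParams(link_radius=400.0),
    duration_h=10.0, snapshot_interval_h=0.25, seed=0)
res = pw.run_pipeline(cfg, outdir="results/demo")
print(res.timeseries[["t_h", "n_total", "nu_umph", "xi_um", "phi"]]
      .iloc[::8].round(1))
```

prints (seed 0):

```
     t_h  n_total  nu_umph  xi_um  phi
0    0.0       38      4.9   51.8  0.0
8    2.0        4     29.6  537.0  0.5
16   4.0        3     32.2  481.2  0.2
24   6.0        1     33.1  337.2  0.6
32   8.0        1     33.2  666.2  0.7
40  10.0        0     33.2    4.0  0.7
```

Read it as the self-ordering storyline: ~38 defects in the barely moving
post-activation field collapse within hours, by pair annihilation, to a
single persistent +1 vortex; meanwhile the mean speed ν climbs from ~5
to ~33 μm/h (V_c = 35) and the velocity correlation length ξ grows from
one grid spacing to several hundred μm — defect count anticorrelates
with both, the signature of annihilation-driven coarsening. (The last
row shows two desk-scale artifacts worth knowing: the lone wandering
vortex core occasionally escapes the detectable grid region for a frame,
and when the field is momentarily near-uniform the fluctuation-based ξ
collapses, because fluctuations about the mean flow are then tiny and
short-ranged.)

`analysis/01_build_lattice.py` … `04_kinematics.py` run the full study
(lattice statistics, multi-seed ordering curves, annihilation-reversal
measurement, solid-vs-fluid kinematics) and print what they find.

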