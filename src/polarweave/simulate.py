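"""Active-elastic-solid (AES) dynamics of a confined cell monolayer.

Each cell i is an overdamped self-propelled particle permanently connected
to its neighbours by nonlinear springs:

    Ṙ_i = V_c P_i + F_i / ζ
    Ṗ_i = γ (P_i × Ṙ_i) × P_i

with unit polarity P_i, propulsion speed V_c, substrate friction ζ, and
elastic force F_i derived from the pair energy

    U(r_ij) = (K/2)(d_ij − r_ij)² + B (d_ij − r_ij)⁴ .

The polarity equation turns the propulsion direction toward the actual
velocity at rate γ |Ṙ| — "force synchronisation": a cell senses the net
force its neighbours transmit and steers with it. The quartic term
stiffens the springs at large strain, suppressing compressional collapse
and overstretching. Two dimensionless groups control the physics:
K̃ = K d / (ζ V_c) (rigidity) and γ̃ = γ d (turning rate).

Confinement: cells outside the circular domain feel a linear inward
radial spring force, and near the rim the polarity turns toward the
inward normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import SpringNetwork


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Physical and numerical parameters of the AES integration.

    Units: lengths μm, times hours, forces in units of ζ·V_c (ζ = 1 by
    default defines the force scale).
    """

    V_c: float = 35.0                 # propulsion speed, μm/h
    zeta: float = 1.0                 # substrate friction
    K: float = 0.0                    # spring constant, force/μm
    B: float = 0.0                    # quartic coefficient, force/μm³
    gamma: float = 0.0                # turning rate, 1/μm
    d: float = 22.5                   # mean cell spacing, μm (scales only)
    dt: float | None = None           # time step, h (None = auto)
    domain_radius: float | None = None    # None = unconfined
    boundary_stiffness: float | None = None   # default: K (or 1 if K = 0)
    boundary_turn_rate: float = 5.0   # 1/h (mode "turn")
    boundary_mode: str = "slip"       # "slip" | "turn"
    boundary_shell: float = 2.0       # shell thickness, units of d
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.V_c < 0 or self.zeta <= 0 or self.K < 0 or self.B < 0 \
                or self.gamma < 0:
            raise ValueError("invalid sign in SimParams")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")

    @classmethod
    def from_dimensionless(cls, K_tilde: float, gamma_tilde: float,
                           V_c: float = 35.0, d: float = 22.5,
                           zeta: float = 1.0, B_tilde: float | None = None,
                           **kwargs) -> "SimParams":
        """Build parameters from the reduced rigidity and turning rate.

        K = K̃ ζ V_c / d and B = B̃ ζ V_c / d³ with B̃ = K̃/4 by default
        (quartic equals harmonic term at 50% strain, negligible below
        ~20%). The turning rate is quoted per micrometre of displacement:
        γ = γ̃ μm⁻¹ (the polarity turns by γ̃ radians per μm moved when
        perpendicular to the velocity). Only with this reading does the
        confined monolayer retain the persistent central +1 vortex;
        turning ~20× slower leaves the vortex a short transient.
        """
        if B_tilde is None:
            B_tilde = K_tilde / 4.0
        return cls(V_c=V_c, zeta=zeta, d=d,
                   K=K_tilde * zeta * V_c / d,
                   B=B_tilde * zeta * V_c / d**3,
                   gamma=gamma_tilde, **kwargs)

    @property
    def K_tilde(self) -> float:
        return self.K * self.d / (self.zeta * self.V_c)

    @property
    def gamma_tilde(self) -> float:
        return self.gamma

    @property
    def B_tilde(self) -> float:
        return self.B * self.d**3 / (self.zeta * self.V_c)

    def resolved_dt(self, max_degree: int = 8) -> float:
        """Stable explicit-Euler step: advective and spring-stability bounds."""
        if self.dt is not None:
            return self.dt
        bounds = []
        if self.V_c > 0:
            bounds.append(0.05 * self.d / self.V_c)
        if self.K > 0:
            bounds.append(0.25 * self.zeta / (self.K * max_degree))
        if self.gamma > 0 and self.V_c > 0:
            # polarity rotation per step stays well below a radian
            bounds.append(0.2 / (self.gamma * self.V_c))
        if not bounds:
            raise ValueError("cannot choose dt automatically; set dt")
        return min(bounds)


@dataclass
class ParticleState:
    """Positions, unit polarities and last-step velocities at one time."""

    time: float
    positions: np.ndarray    # (N, 2) μm
    polarities: np.ndarray   # (N, 2) unit vectors
    velocities: np.ndarray   # (N, 2) μm/h

    @property
    def n(self) -> int:
        return len(self.positions)

    def polar_order(self) -> float:
        """φ = |Σ P_i| / N, the polar order parameter."""
        return float(np.linalg.norm(self.polarities.mean(axis=0)))


def initial_state(net: SpringNetwork, p: SimParams,
                  initial_polarity: str = "random") -> ParticleState:
    n = net.n_points
    if initial_polarity == "random":
        rng = np.random.default_rng((p.rng_seed, 2))
        ang = rng.uniform(0, 2 * np.pi, n)
    elif initial_polarity == "uniform":
        ang = np.zeros(n)
    else:
        raise ValueError(f"unknown initial_polarity {initial_polarity!r}")
    pol = np.column_stack([np.cos(ang), np.sin(ang)])
    return ParticleState(time=0.0, positions=net.points.copy(),
                         polarities=pol,
                         velocities=p.V_c * pol)


def elastic_forces(state: ParticleState, net: SpringNetwork,
                   p: SimParams) -> np.ndarray:
    """F_i = −∂U_total/∂R_i for the harmonic + quartic pair energy.

    With s = d_ij − r_ij, the force on i along the unit bond vector
    (R_j − R_i)/r_ij has magnitude −(K s + 4 B s³): attractive when the
    bond is stretched, repulsive when compressed.
    """
    i, j = net.edges[:, 0], net.edges[:, 1]
    dvec = state.positions[j] - state.positions[i]
    r = np.hypot(dvec[:, 0], dvec[:, 1])
    bad = r <= 0
    if bad.any():
        k = int(np.argmax(bad))
        raise SimulationError(
            f"coincident bonded particles on edge ({i[k]}, {j[k]})")
    s = net.rest_lengths - r
    fmag = -(p.K * s + 4.0 * p.B * s**3) / r   # per unit bond vector
    fvec = fmag[:, None] * dvec
    forces = np.zeros_like(state.positions)
    n = state.n
    forces[:, 0] = np.bincount(i, weights=fvec[:, 0], minlength=n) \
        - np.bincount(j, weights=fvec[:, 0], minlength=n)
    forces[:, 1] = np.bincount(i, weights=fvec[:, 1], minlength=n) \
        - np.bincount(j, weights=fvec[:, 1], minlength=n)
    return forces


def boundary_terms(state: ParticleState, p: SimParams
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Confinement: inward radial force and polarity turning near the rim.

    Returns (force increment (N,2), signed polarity angular rate (N,)).
    Particles strictly outside radius R feel force k_b (|R_i| − R) toward
    the centre. The polarity turns away from the boundary for particles
    beyond R − shell·d, in one of two modes:

    - "turn": rotate toward the inward normal at rate
      ``boundary_turn_rate · sin(angle to the normal)``;
    - "slip" (default): cancel the outward radial polarity component,
      i.e. an effectively instantaneous version of the same turning that
      leaves rim polarity tangential.

    In both cases the angular rate returned here is applied by ``step``;
    for "slip" it is the rate that removes the outward component within
    one step.
    """
    n = state.n
    forces = np.zeros((n, 2))
    omega = np.zeros(n)
    if p.domain_radius is None:
        return forces, omega
    R = p.domain_radius
    k_b = p.boundary_stiffness
    if k_b is None:
        k_b = p.K if p.K > 0 else 1.0
    rad = np.hypot(state.positions[:, 0], state.positions[:, 1])
    out = rad > R
    if out.any():
        unit_in = -state.positions[out] / rad[out, None]
        forces[out] = k_b * (rad[out] - R)[:, None] * unit_in
    near = rad > R - p.boundary_shell * p.d
    if near.any():
        r_safe = np.maximum(rad[near], 1e-12)
        n_in = -state.positions[near] / r_safe[:, None]
        pol = state.polarities[near]
        if p.boundary_mode == "turn":
            # (P × n̂)_z = sin(signed angle from P to the inward normal)
            cross = pol[:, 0] * n_in[:, 1] - pol[:, 1] * n_in[:, 0]
            omega[near] = p.boundary_turn_rate * cross
        elif p.boundary_mode != "slip":
            raise ValueError(f"unknown boundary_mode {p.boundary_mode!r}")
    return forces, omega


def _slip_polarity(positions: np.ndarray, polarities: np.ndarray,
                   p: SimParams) -> np.ndarray:
    """Remove the outward radial polarity component near the rim (in place).

    Applied after the alignment update when ``boundary_mode == "slip"``:
    particles beyond R − shell·d whose polarity points outward have that
    component cancelled, leaving the tangential part (renormalised by the
    caller). Inward-pointing polarity is untouched.
    """
    R = p.domain_radius
    rad = np.hypot(positions[:, 0], positions[:, 1])
    near = rad > R - p.boundary_shell * p.d
    if near.any():
        r_hat = positions[near] / np.maximum(rad[near], 1e-12)[:, None]
        dot = (polarities[near] * r_hat).sum(axis=1)
        outward = np.maximum(dot, 0.0)
        newp = polarities[near] - outward[:, None] * r_hat
        # exactly radial outward polarity: turn fully inward
        tiny = np.hypot(newp[:, 0], newp[:, 1]) < 1e-12
        newp[tiny] = -r_hat[tiny]
        polarities[near] = newp
    return polarities


def step(state: ParticleState, net: SpringNetwork | None,
         p: SimParams, dt: float | None = None) -> ParticleState:
    """One explicit Euler step of the coupled position/polarity dynamics.

    The polarity turning term γ (P × Ṙ) × P is evaluated through the
    identity (P × Ṙ) × P = Ṙ − (P·Ṙ) P, exact for unit P; the polarity is
    renormalised after the update.
    """
    if dt is None:
        dt = p.resolved_dt()
    pos, pol = state.positions, state.polarities
    forces = np.zeros_like(pos)
    if net is not None and net.n_edges:
        forces = elastic_forces(state, net, p)
    bforce, bomega = boundary_terms(state, p)
    vel = p.V_c * pol + (forces + bforce) / p.zeta
    new_pos = pos + vel * dt
    pdotv = np.sum(pol * vel, axis=1, keepdims=True)
    dpol = p.gamma * (vel - pdotv * pol) * dt
    # boundary rotation: angular rate bomega about z, i.e. along perp(P)
    perp = np.column_stack([-pol[:, 1], pol[:, 0]])
    new_pol = pol + dpol + (bomega * dt)[:, None] * perp
    if p.domain_radius is not None and p.boundary_mode == "slip":
        new_pol = _slip_polarity(pos, new_pol, p)
    norm = np.hypot(new_pol[:, 0], new_pol[:, 1])
    if not np.all(np.isfinite(new_pos)) or not np.all(norm > 0):
        raise SimulationError(
            f"non-finite state at t={state.time + dt:.4f} h; reduce dt")
    new_pol = new_pol / norm[:, None]
    return ParticleState(time=state.time + dt, positions=new_pos,
                         polarities=new_pol, velocities=vel)


def run(net: SpringNetwork, p: SimParams, duration: float,
        snapshot_interval: float, initial_polarity: str = "random",
        state: ParticleState | None = None,
        use_compiled: bool = True) -> list[ParticleState]:
    """Integrate for ``duration`` hours, returning snapshots.

    Snapshots are taken every ``snapshot_interval`` (the initial state is
    included when starting fresh); the step size is shrunk so snapshot
    times are hit exactly. Deterministic for a fixed seed. Raises if any
    particle moves more than d/2 in one step. A compiled kernel is used
    when available; it applies the same update (see ``_kernels``).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt0 = p.resolved_dt(max_degree=max(int(net.degree().max()), 1)
                        if net.n_edges else 1)
    n_sub = max(int(np.ceil(snapshot_interval / dt0 - 1e-12)), 1)
    dt = snapshot_interval / n_sub
    if state is None:
        state = initial_state(net, p, initial_polarity)
        snaps = [state]
    else:
        snaps = []
    n_chunks = int(np.floor(duration / snapshot_interval + 1e-9))
    guard = 0.5 * p.d

    from ._kernels import HAVE_NUMBA, euler_steps
    compiled = use_compiled and HAVE_NUMBA

    for _ in range(n_chunks):
        if compiled:
            pos = state.positions.copy()
            pol = state.polarities.copy()
            edges = net.edges if net.n_edges else np.empty((0, 2), dtype=np.int64)
            k_b = p.boundary_stiffness
            if k_b is None:
                k_b = p.K if p.K > 0 else 1.0
            vel, max_disp = euler_steps(
                pos, pol, np.ascontiguousarray(edges[:, 0]),
                np.ascontiguousarray(edges[:, 1]),
                np.asarray(net.rest_lengths, dtype=float), n_sub, dt,
                p.V_c, p.zeta, p.K, p.B, p.gamma,
                p.domain_radius if p.domain_radius is not None else 0.0,
                k_b, p.boundary_turn_rate, p.boundary_shell * p.d,
                p.domain_radius is not None, p.boundary_mode == "slip")
            if max_disp < 0:
                raise SimulationError(
                    f"non-finite or coincident-particle state near "
                    f"t={state.time:.4f} h; reduce dt")
            state = ParticleState(time=state.time + snapshot_interval,
                                  positions=pos, polarities=pol,
                                  velocities=vel)
        else:
            max_disp = 0.0
            for _ in range(n_sub):
                prev_pos = state.positions
                state = step(state, net, p, dt=dt)
                max_disp = max(max_disp, float(np.max(np.hypot(
                    *(state.positions - prev_pos).T))) if state.n else 0.0)
        if max_disp > guard:
            raise SimulationError(
                f"instability: displacement {max_disp:.2f} μm > d/2 in one "
                f"step at t={state.time:.4f} h; reduce dt")
        snaps.append(state)
    return snaps


def run_metadata(p: SimParams) -> dict:
    return {"K_tilde": p.K_tilde, "gamma_tilde": p.gamma_tilde,
            "B_tilde": p.B_tilde, "V_c": p.V_c, "d": p.d,
            "zeta": p.zeta, "dt": p.dt, "seed": p.rng_seed,
            "domain_radius": p.domain_radius}
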