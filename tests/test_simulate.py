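import numpy as np
import pytest

import polarweave as pw
from polarweave.lattice import SpringNetwork
from polarweave.simulate import (SimParams, SimulationError, boundary_terms,
                                 elastic_forces, initial_state, run, step)


def _free_particle_net():
    return SpringNetwork(points=np.zeros((1, 2)),
                         edges=np.empty((0, 2), dtype=int),
                         rest_lengths=np.empty(0))


def _two_particle_net(separation, rest):
    return SpringNetwork(points=np.array([[0.0, 0.0], [separation, 0.0]]),
                         edges=np.array([[0, 1]]),
                         rest_lengths=np.array([rest], dtype=float))


class TestElasticForces:
    def test_zero_at_rest_length(self, small_lattice):
        p = SimParams.from_dimensionless(40, 1.5)
        net = _two_particle_net(10.0, 10.0)
        st = initial_state(net, p, "uniform")
        assert np.allclose(elastic_forces(st, net, p), 0.0)

    def test_stretched_harmonic_pair(self):
        # K=1, B=0, d_ij=10, r_ij=12: |F| = K*(r-d) = 2, attractive
        p = SimParams(V_c=0.0, K=1.0, B=0.0, d=22.5, dt=0.01)
        net = _two_particle_net(12.0, 10.0)
        st = initial_state(net, p, "uniform")
        F = elastic_forces(st, net, p)
        assert F[0] == pytest.approx([2.0, 0.0])
        assert F[1] == pytest.approx([-2.0, 0.0])

    def test_matches_numerical_gradient(self, small_lattice):
        net = small_lattice
        p = SimParams.from_dimensionless(40, 1.5)
        st = initial_state(net, p, "random")
        rng = np.random.default_rng(2)
        st.positions = st.positions + rng.normal(scale=2.0,
                                                 size=st.positions.shape)
        F = elastic_forces(st, net, p)

        def U(pos):
            dv = pos[net.edges[:, 1]] - pos[net.edges[:, 0]]
            r = np.hypot(dv[:, 0], dv[:, 1])
            s = net.rest_lengths - r
            return (p.K / 2 * s**2 + p.B * s**4).sum()

        eps = 1e-5
        idx = rng.choice(net.n_points, size=25, replace=False)
        for i in idx:
            for c in range(2):
                pp = st.positions.copy()
                pp[i, c] += eps
                up = U(pp)
                pp[i, c] -= 2 * eps
                um = U(pp)
                grad = -(up - um) / (2 * eps)
                assert F[i, c] == pytest.approx(grad, rel=1e-5, abs=1e-6)

    def test_newtons_third_law(self, small_lattice):
        p = SimParams.from_dimensionless(40, 1.5)
        st = initial_state(small_lattice, p, "random")
        st.positions = st.positions + np.random.default_rng(0).normal(
            scale=3.0, size=st.positions.shape)
        F = elastic_forces(st, small_lattice, p)
        scale = np.abs(F).max()
        assert np.abs(F.sum(axis=0)).max() < 1e-9 * max(scale, 1.0)

    def test_coincident_particles_rejected(self):
        p = SimParams(K=1.0, dt=0.01)
        net = _two_particle_net(0.0, 10.0)
        st = initial_state(net, p, "uniform")
        with pytest.raises(SimulationError, match="edge"):
            elastic_forces(st, net, p)


class TestBoundary:
    def test_interior_particle_unaffected(self):
        p = SimParams(domain_radius=100.0, boundary_stiffness=1.0, d=22.5,
                      dt=0.01)
        net = _free_particle_net()
        st = initial_state(net, p, "uniform")
        st.positions[0] = [100.0 - 22.5, 0.0]
        f, w = boundary_terms(st, p)
        assert np.all(f == 0) and np.all(w == 0)

    def test_outside_particle_pushed_inward(self):
        p = SimParams(domain_radius=100.0, boundary_stiffness=1.0, dt=0.01)
        st = initial_state(_free_particle_net(), p, "uniform")
        st.positions[0] = [105.0, 0.0]
        f, _ = boundary_terms(st, p)
        assert f[0] == pytest.approx([-5.0, 0.0])

    def test_exactly_on_rim_no_force(self):
        p = SimParams(domain_radius=100.0, boundary_stiffness=1.0, dt=0.01)
        st = initial_state(_free_particle_net(), p, "uniform")
        st.positions[0] = [100.0, 0.0]
        f, _ = boundary_terms(st, p)
        assert np.all(f == 0)

    def test_turn_mode_rotates_toward_inward_normal(self):
        p = SimParams(domain_radius=100.0, boundary_mode="turn",
                      boundary_turn_rate=2.0, d=22.5, dt=0.01)
        st = initial_state(_free_particle_net(), p, "uniform")
        st.positions[0] = [99.0, 0.0]        # inside shell
        st.polarities[0] = [0.0, 1.0]        # tangential; normal is -x
        _, w = boundary_terms(st, p)
        # rotating +y toward -x is a counterclockwise (positive) rotation
        assert w[0] == pytest.approx(2.0)

    def test_slip_mode_cancels_outward_component(self):
        p = SimParams(V_c=0.0, domain_radius=100.0, boundary_mode="slip",
                      d=22.5, dt=0.01)
        st = initial_state(_free_particle_net(), p, "uniform")
        st.positions[0] = [99.0, 0.0]
        st.polarities[0] = np.array([1.0, 1.0]) / np.sqrt(2)
        out = step(st, None, p)
        assert out.polarities[0] == pytest.approx([0.0, 1.0])


class TestStep:
    def test_free_particle_travels_at_propulsion_speed(self):
        p = SimParams(V_c=35.0, dt=0.01)
        states = run(_free_particle_net(), p, duration=1.0,
                     snapshot_interval=1.0, initial_polarity="uniform")
        disp = np.hypot(*states[-1].positions[0])
        assert disp / states[-1].time == pytest.approx(35.0)

    def test_gamma_zero_keeps_polarity(self, small_lattice):
        p = SimParams.from_dimensionless(40, 0.0, rng_seed=4)
        st = initial_state(small_lattice, p, "random")
        pol0 = st.polarities.copy()
        for _ in range(20):
            st = step(st, small_lattice, p, dt=0.001)
        assert np.allclose(st.polarities, pol0)

    def test_aligned_polarity_is_fixed_point(self):
        # P parallel to velocity: (P x R') x P = 0
        p = SimParams(V_c=35.0, gamma=0.1, dt=0.01)
        st = initial_state(_free_particle_net(), p, "uniform")
        out = step(st, None, p)
        assert out.polarities[0] == pytest.approx([1.0, 0.0])

    def test_polarity_stays_unit(self, small_lattice):
        p = SimParams.from_dimensionless(40, 1.5, rng_seed=3)
        st = initial_state(small_lattice, p, "random")
        for _ in range(50):
            st = step(st, small_lattice, p, dt=0.002)
            norms = np.hypot(*st.polarities.T)
            assert np.abs(norms - 1.0).max() < 1e-9

    def test_gradient_descent_decreases_energy(self, small_lattice):
        # V_c = 0, gamma = 0: overdamped relaxation of the spring energy
        net = small_lattice
        p = SimParams(V_c=0.0, K=10.0, B=0.0, gamma=0.0, dt=1e-4)
        st = initial_state(net, p, "uniform")
        st.positions = st.positions + np.random.default_rng(1).normal(
            scale=1.0, size=st.positions.shape)

        def U(pos):
            dv = pos[net.edges[:, 1]] - pos[net.edges[:, 0]]
            r = np.hypot(dv[:, 0], dv[:, 1])
            return (p.K / 2 * (net.rest_lengths - r)**2).sum()

        energies = [U(st.positions)]
        for _ in range(30):
            st = step(st, net, p)
            energies.append(U(st.positions))
        assert np.all(np.diff(energies) <= 1e-9)


class TestRun:
    def test_compiled_matches_reference(self, small_lattice):
        p = SimParams.from_dimensionless(
            40, 1.5, domain_radius=small_lattice.spec.domain_radius,
            rng_seed=9)
        a = run(small_lattice, p, duration=0.2, snapshot_interval=0.1,
                use_compiled=True)
        b = run(small_lattice, p, duration=0.2, snapshot_interval=0.1,
                use_compiled=False)
        for sa, sb in zip(a, b):
            assert np.allclose(sa.positions, sb.positions, atol=1e-10)
            assert np.allclose(sa.polarities, sb.polarities, atol=1e-10)

    def test_deterministic_for_seed(self, small_lattice):
        p = SimParams.from_dimensionless(
            40, 1.5, domain_radius=small_lattice.spec.domain_radius,
            rng_seed=2)
        a = run(small_lattice, p, duration=0.5, snapshot_interval=0.25)
        b = run(small_lattice, p, duration=0.5, snapshot_interval=0.25)
        assert np.array_equal(a[-1].positions, b[-1].positions)

    def test_uniform_polarity_no_boundary_stays_uniform(self):
        # stress-free rest lengths: forces vanish, rigid translation is an
        # exact fixed point of the polarity dynamics
        n = 300
        spec = pw.LatticeSpec(domain_radius=pw.scaled_domain_radius(n),
                              target_cell_count=n, mean_spacing=22.5,
                              rng_seed=7)
        net = pw.build_network(pw.pack_disks(spec), spec,
                               rest_length_mode="distance")
        p = SimParams.from_dimensionless(40, 1.5, rng_seed=0)
        states = run(net, p, duration=1.0, snapshot_interval=0.5,
                     initial_polarity="uniform")
        # clamping of out-of-interval rest lengths leaves a little residual
        # stress, so the fixed point is near-exact rather than exact
        assert states[-1].polar_order() > 0.99
        assert np.hypot(*states[-1].velocities.T).mean() == pytest.approx(
            35.0, rel=1e-2)

    def test_instability_detected(self, small_lattice):
        p = SimParams.from_dimensionless(40, 1.5, dt=0.05)   # way too large
        with pytest.raises(SimulationError):
            run(small_lattice, p, duration=0.5, snapshot_interval=0.05)


def test_polar_ordering_develops_unconfined():
    """With gamma_tilde = 1.5 the unconfined sheet orders within ~10 h."""
    n = 2000
    spec = pw.LatticeSpec(domain_radius=pw.scaled_domain_radius(n),
                          target_cell_count=n, mean_spacing=22.5, rng_seed=0)
    # stress-free start isolates the alignment dynamics from the residual
    # packing pre-stress
    net = pw.build_network(pw.pack_disks(spec), spec,
                           rest_length_mode="distance")
    p = SimParams.from_dimensionless(40, 1.5, rng_seed=0)
    states = run(net, p, duration=10.0, snapshot_interval=2.0)
    assert states[0].polar_order() < 0.15
    assert states[-1].polar_order() > 0.7


def test_timestep_convergence():
    """Halving dt changes the final polar order by < 2%."""
    n = 300
    spec = pw.LatticeSpec(domain_radius=pw.scaled_domain_radius(n),
                          target_cell_count=n, mean_spacing=22.5, rng_seed=2)
    net = pw.build_lattice(spec)
    dt0 = SimParams.from_dimensionless(40, 1.5).resolved_dt(
        max_degree=int(net.degree().max()))
    phis = []
    for dt in (dt0, dt0 / 2):
        p = SimParams.from_dimensionless(40, 1.5, rng_seed=2, dt=dt)
        states = run(net, p, duration=4.0, snapshot_interval=4.0)
        phis.append(states[-1].polar_order())
    assert abs(phis[1] - phis[0]) / phis[0] < 0.02
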