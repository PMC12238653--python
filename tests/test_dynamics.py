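"""Plant-dynamics validation against independent oracles.

The forward dynamics are checked against a symbolic Euler-Lagrange
derivation built from scratch with sympy; the centre of pressure against a
whole-body angular-momentum balance; the linearisation against central
finite differences; and the integrator against energy conservation and its
theoretical order.
"""

import numpy as np
import pytest

from balancempc import dynamics as dyn
from balancempc.dynamics import ControlInput, PlantState

from _oracles import alphadd_from_model

_S = np.tril(np.ones((3, 3)))
_D = np.array([[1.0, 0, 0], [-1.0, 1.0, 0], [0, -1.0, 1.0]])


def test_upright_unforced_equilibrium(model):
    acc = dyn.forward_dynamics(model, PlantState.upright(), ControlInput(np.zeros(3)))
    assert np.allclose(acc, 0.0, atol=1e-14)


def test_forward_dynamics_matches_symbolic_lagrangian(model, lagrangian_oracle):
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(1000):
        phi = rng.uniform(-0.6, 0.6, 3)
        phid = rng.uniform(-6.0, 6.0, 3)
        tau = rng.uniform(-200.0, 200.0, 3)
        ap = rng.uniform(-5.0, 5.0)
        mine = dyn.joint_accelerations(model, phi, phid, tau, ap)
        ref = alphadd_from_model(model, phi, phid, tau, ap, lagrangian_oracle)
        worst = max(worst, np.max(np.abs(mine - ref) / (1.0 + np.abs(ref))))
    assert worst < 1e-8


def test_forward_dynamics_batched_matches_scalar(model):
    rng = np.random.default_rng(3)
    phi = rng.uniform(-0.4, 0.4, (8, 3))
    phid = rng.uniform(-3.0, 3.0, (8, 3))
    tau = rng.uniform(-50.0, 50.0, (8, 3))
    ap = rng.uniform(-2.0, 2.0, 8)
    batched = dyn.joint_accelerations(model, phi, phid, tau, ap)
    for i in range(8):
        single = dyn.joint_accelerations(model, phi[i], phid[i], tau[i], ap[i])
        assert np.allclose(batched[i], single, atol=1e-12)


def test_mass_matrix_positive_definite_over_joint_range(model):
    grid = np.linspace(-0.6, 0.6, 5)
    for pa in grid:
        for pk in grid:
            for ph in grid:
                M = dyn.mass_matrix(model, np.array([pa, pk, ph]))
                assert np.allclose(M, M.T)
                assert np.linalg.eigvalsh(M).min() > 0.0


def test_linearize_matches_central_finite_differences(model):
    rng = np.random.default_rng(7)
    eps = 1e-6
    for _ in range(20):
        st = PlantState(rng.uniform(-0.5, 0.5, 3), rng.uniform(-3, 3, 3))
        u = ControlInput(rng.uniform(-100, 100, 3))
        ap = rng.uniform(-5, 5)
        A, B = dyn.linearize(model, st, u, ap)

        def f(x, tau):
            return np.concatenate(
                [x[3:], dyn.joint_accelerations(model, x[:3], x[3:], tau, ap)]
            )

        for i in range(6):
            dx = np.zeros(6)
            dx[i] = eps
            col = (f(st.x + dx, u.tau) - f(st.x - dx, u.tau)) / (2 * eps)
            assert np.all(np.abs(A[:, i] - col) / (1.0 + np.abs(col)) < 1e-6)
        for i in range(3):
            dt_ = np.zeros(3)
            dt_[i] = eps
            col = (f(st.x, u.tau + dt_) - f(st.x, u.tau - dt_)) / (2 * eps)
            assert np.all(np.abs(B[:, i] - col) / (1.0 + np.abs(col)) < 1e-6)


def test_linearize_structure_at_upright(model):
    A, B = dyn.linearize(model, PlantState.upright(), ControlInput(np.zeros(3)))
    # inverted pendulum: at least one unstable continuous eigenvalue
    assert np.max(np.linalg.eigvals(A).real) > 0.0
    # second-order structure: angle rows of B are zero, velocity block is I
    assert np.allclose(B[:3], 0.0)
    assert np.allclose(A[:3, 3:], np.eye(3))
    assert np.allclose(A[:3, :3], 0.0)


def test_forward_dynamics_consistent_with_linearization(model):
    st0 = PlantState.upright()
    u0 = ControlInput(np.zeros(3))
    A, B = dyn.linearize(model, st0, u0, 0.0)
    eps = 1e-7
    rng = np.random.default_rng(11)
    dx = rng.normal(size=6)
    du = rng.normal(size=3)
    st = PlantState(eps * dx[:3], eps * dx[3:])
    acc = dyn.joint_accelerations(model, st.phi, st.phidot, eps * du, 0.0)
    pred = (A @ (eps * dx) + B @ (eps * du))[3:]
    assert np.allclose(acc, pred, atol=1e-9)


def test_step_state_fixed_point_and_blowup_flag(model):
    st = dyn.step_state(model, PlantState.upright(), ControlInput(np.zeros(3)), 0.0, 0.01)
    assert np.allclose(st.x, 0.0)
    assert st.t == pytest.approx(0.01)
    with pytest.raises(ValueError):
        dyn.step_state(model, PlantState.upright(), ControlInput(np.zeros(3)), 0.0, -1.0)


def test_passive_energy_conservation(model):
    # unforced swing from a lean; fixed-step RK4 at 0.1 ms over 10 s
    state = PlantState(np.array([0.12, -0.06, 0.09]), np.zeros(3))
    u = ControlInput(np.zeros(3))
    e0 = dyn.total_energy(model, state)
    assert e0 != 0.0
    x = state.x
    t = 0.0
    dt = 1e-4
    for _ in range(100_000):
        x = dyn.rk4_step(model, x, u.tau, lambda _t: 0.0, t, dt)
        t += dt
    e1 = dyn.total_energy(model, PlantState(x[:3], x[3:], t))
    assert abs(e1 - e0) / abs(e0) < 1e-6


def test_rk4_local_error_shrinks_sixteenfold(model):
    state = PlantState(np.array([0.2, -0.1, 0.15]), np.array([0.3, 0.1, -0.2]))
    u = ControlInput(np.zeros(3))

    def integrate(dt, t_end=0.08):
        x = state.x
        t = 0.0
        while t < t_end - 1e-12:
            x = dyn.rk4_step(model, x, u.tau, lambda _t: 0.0, t, dt)
            t += dt
        return x

    ref = integrate(1e-5)
    err_coarse = np.abs(integrate(2e-3) - ref).max()
    err_fine = np.abs(integrate(1e-3) - ref).max()
    assert err_coarse / err_fine == pytest.approx(16.0, rel=0.35)


def test_total_energy_properties(model):
    assert dyn.total_energy(model, PlantState.upright()) == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(5)
    for _ in range(20):
        st = PlantState(rng.uniform(-0.5, 0.5, 3), rng.uniform(-4, 4, 3))
        still = PlantState(st.phi, np.zeros(3))
        kinetic = dyn.total_energy(model, st) - dyn.total_energy(model, still)
        assert kinetic >= 0.0


def test_total_com_matches_forward_kinematics_oracle(model):
    rng = np.random.default_rng(9)
    la = model.link_arrays
    for _ in range(30):
        phi = rng.uniform(-0.5, 0.5, 3)
        phid = rng.uniform(-3, 3, 3)
        xp, vp = rng.uniform(-0.01, 0.01), rng.uniform(-0.1, 0.1)
        st = PlantState(phi, phid)
        com_x, com_z, com_vx = dyn.total_com(model, st, xp, vp)
        # independent per-segment kinematics: explicit joint chain
        alpha = np.cumsum(phi)
        alphad = np.cumsum(phid)
        h = model.ankle_height
        jx, jz, jvx = xp, h, vp
        tot_x = model.foot.mass * (xp + model.foot_com_forward)
        tot_z = model.foot.mass * (0.5 * h)
        tot_vx = model.foot.mass * vp
        for k, seg in enumerate(model.links):
            cx = jx + seg.com_distance * np.sin(alpha[k])
            cz = jz + seg.com_distance * np.cos(alpha[k])
            cvx = jvx + seg.com_distance * np.cos(alpha[k]) * alphad[k]
            tot_x += seg.mass * cx
            tot_z += seg.mass * cz
            tot_vx += seg.mass * cvx
            jx += seg.length * np.sin(alpha[k])
            jz += seg.length * np.cos(alpha[k])
            jvx += seg.length * np.cos(alpha[k]) * alphad[k]
        M = model.total_mass
        assert com_x == pytest.approx(tot_x / M, abs=1e-12)
        assert com_z == pytest.approx(tot_z / M, abs=1e-12)
        assert com_vx == pytest.approx(tot_vx / M, abs=1e-12)
        assert la["m"].sum() + model.foot.mass == pytest.approx(M)


def test_small_ankle_lean_com_shift(model):
    la = model.link_arrays
    phi_a = 1e-4
    st = PlantState(np.array([phi_a, 0.0, 0.0]), np.zeros(3))
    com_x, _, _ = dyn.total_com(model, st)
    com0_x, _, _ = dyn.total_com(model, PlantState.upright())
    expected = la["P"].sum() * phi_a / model.total_mass
    assert com_x - com0_x == pytest.approx(expected, rel=1e-6)


def _equilibrium_torque(model, phi):
    la = model.link_arrays
    alpha = _S @ phi
    return np.linalg.solve(_D.T, -model.gravity * la["P"] * np.sin(alpha))


def test_static_cop_equals_com(model):
    for phi in (np.zeros(3), np.array([0.05, -0.02, 0.03]), np.array([-0.1, 0.04, 0.02])):
        st = PlantState(phi, np.zeros(3))
        tau = _equilibrium_torque(model, phi)
        acc = dyn.forward_dynamics(model, st, ControlInput(tau))
        assert np.allclose(acc, 0.0, atol=1e-10)
        gr = dyn.cop_position(model, st, acc, ControlInput(tau))
        com_x, _, _ = dyn.total_com(model, st)
        assert gr.cop_x == pytest.approx(com_x, abs=1e-12)
        assert gr.fz == pytest.approx(model.total_mass * model.gravity)
        assert not gr.lift_off


def test_quasi_static_cop_moment_balance(model):
    # small lean held by ankle torque: COP offset ~ -tau_a/(M g) plus the
    # gravity moments of the leaning segments and foot geometry
    phi = np.array([0.02, 0.0, 0.0])
    st = PlantState(phi, np.zeros(3))
    tau = _equilibrium_torque(model, phi)
    acc = dyn.forward_dynamics(model, st, ControlInput(tau))
    gr = dyn.cop_position(model, st, acc, ControlInput(tau))
    mg = model.total_mass * model.gravity
    links_moment = model.gravity * (model.link_arrays["P"] * np.sin(np.cumsum(phi))).sum()
    expected = (-tau[0] + model.foot_com_forward * model.foot.mass * model.gravity) / mg
    # -tau_a equals the links' gravity moment at equilibrium
    assert -tau[0] == pytest.approx(links_moment, rel=1e-12)
    assert gr.cop_x == pytest.approx(expected, rel=1e-9)


def test_dynamic_cop_whole_body_momentum_oracle(model):
    # external moment about the ankle equals the rate of change of angular
    # momentum computed segment by segment (independent of the foot
    # free-body route used by cop_position)
    rng = np.random.default_rng(2)
    la = model.link_arrays
    m, Ic = la["m"], la["Ic"]
    g, h = model.gravity, model.ankle_height
    for _ in range(50):
        phi = rng.uniform(-0.3, 0.3, 3)
        phid = rng.uniform(-2, 2, 3)
        tau = rng.uniform(-80, 80, 3)
        ap = rng.uniform(-4, 4)
        st = PlantState(phi, phid)
        u = ControlInput(tau)
        acc = dyn.forward_dynamics(model, st, u, ap)
        gr = dyn.cop_position(model, st, acc, u, ap)
        if gr.lift_off:  # fz <= 0: no support, COP undefined by construction
            assert np.isnan(gr.cop_x)
            continue
        alpha, alphad, alphadd = _S @ phi, _S @ phid, _S @ acc
        xdd, zdd = dyn._link_com_accelerations(model, alpha, alphad, alphadd, ap)
        cx, cz = dyn._link_com_positions(model, alpha, 0.0)
        lhs = np.sum((cz - h) * m * xdd - cx * m * zdd) + np.sum(Ic * alphadd)
        mf, x_fc, z_fc = model.foot.mass, model.foot_com_forward, 0.5 * h
        lhs += (z_fc - h) * mf * ap
        rhs = np.sum(cx * m * g) + x_fc * mf * g + (-h) * gr.fx - gr.cop_x * gr.fz
        assert lhs == pytest.approx(rhs, abs=1e-9)
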