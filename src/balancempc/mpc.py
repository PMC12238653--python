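"""Receding-horizon balance controller and closed-loop simulation driver.

At every control period (10 ms) the controller minimises the quadratic cost

    J = (Rs - Y)' Qbar (Rs - Y) + (dGamma)' Rbar (dGamma)

over a sequence of joint-torque increments dGamma (move-blocked to the
control horizon Nc), where Y stacks the predicted states (joint deviations
and velocities) over the prediction horizon Np and Rs is the upright-stance
reference (zero).  Predictions roll the nonlinear plant forward with the
true platform-acceleration preview; biomechanical bounds on torques,
torque increments, joint angles and velocities are enforced in the solve.
The first increment is applied and the horizon recedes.

Two solver modes are provided:

``"sqp"`` (default)
    Gauss-Newton sequential quadratic programming written for this
    6-variable problem: nonlinear nominal rollout, linearised sensitivity
    (RK4-consistent discretisation of the analytic Jacobians), exact
    solution of the resulting least-squares step, iterated.  Bounds are
    enforced by a projected re-solve and are inactive at the 2 mm
    perturbation scale.

``"nlp"``
    scipy SLSQP on the full nonlinear rollout with explicit bound and
    state constraints.  Slower; used as the reference formulation.

With no scheduling, switching logic or time-varying weights, any change of
coordination strategy during a run is an emergent property of this single
optimisation problem interacting with the plant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .anthropometry import AnthropometricModel
from .dynamics import (
    ControlInput,
    PlantState,
    SimulationBlowupError,
    cop_position,
    joint_accelerations,
    linearize,
    rk4_step,
    total_com,
)
from .platform import PlatformSpec, _eval, acceleration_fn  # noqa: F401

__all__ = [
    "MPCConfig",
    "MPCSolution",
    "SimulationResult",
    "predict_outputs",
    "cost_J",
    "solve_step",
    "closed_loop_simulate",
    "RESULT_COLUMNS",
]

# solver_status codes recorded per sample
STATUS_OK = 0
STATUS_CLIPPED = 1
STATUS_FALLBACK = 2


@dataclass
class MPCConfig:
    """Controller configuration.

    ``q_diag`` weights the six states (three joint deviations, three joint
    velocities) at every prediction step; ``r_diag`` weights the three
    torque increments at every control move.  Increments enter the cost as
    dimensionless effort, i.e. divided by the characteristic joint torque
    capacity ``tau_scale``, so ``r_diag`` ratios act exactly as written
    while states stay in radians.  Bounds are symmetric about zero
    (upright): joint range (rad), joint velocity (rad/s), torque (N m, per
    joint) and per-step torque increment (N m).
    """

    np_horizon: int = 4
    nc_horizon: int = 2
    q_diag: np.ndarray = field(default_factory=lambda: 10.0 * np.ones(6))
    r_diag: np.ndarray = field(default_factory=lambda: np.array([10.0, 10.0, 80.0]))
    dt: float = 0.01
    tau_scale: float = 150.0
    phi_bound: float = 0.6
    phidot_bound: float = 6.0
    tau_bounds: np.ndarray = field(default_factory=lambda: np.array([150.0, 150.0, 200.0]))
    dtau_bound: float = 50.0
    solver: str = "sqp"
    prediction: str = "nonlinear"
    sqp_iters: int = 2
    nlp_maxiter: int = 100
    nlp_tol: float = 1e-12

    def __post_init__(self) -> None:
        self.q_diag = np.asarray(self.q_diag, dtype=float)
        self.r_diag = np.asarray(self.r_diag, dtype=float)
        self.tau_bounds = np.asarray(self.tau_bounds, dtype=float)
        if not (self.np_horizon >= self.nc_horizon >= 1):
            raise ValueError("need Np >= Nc >= 1")
        if self.q_diag.shape != (6,) or self.r_diag.shape != (3,):
            raise ValueError("q_diag must have 6 entries, r_diag 3")
        if (self.q_diag < 0).any() or (self.r_diag < 0).any():
            raise ValueError("weights must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_scale <= 0:
            raise ValueError("tau_scale must be positive")
        if self.solver not in ("sqp", "nlp"):
            raise ValueError("solver must be 'sqp' or 'nlp'")
        if self.prediction not in ("nonlinear", "linear"):
            raise ValueError("prediction must be 'nonlinear' or 'linear'")

    @property
    def r_effective(self) -> np.ndarray:
        """Increment weights acting on torques in N m (effort-normalised)."""
        return self.r_diag / self.tau_scale**2


@dataclass
class MPCSolution:
    """One receding-horizon solve."""

    delta_tau_sequence: np.ndarray  # (3*Nc,)
    applied: ControlInput
    predicted_outputs: np.ndarray  # (6*Np,)
    cost: float
    status: int
    iterations: int


@dataclass
class SimulationResult:
    """Closed-loop run: per-sample table plus outcome metadata."""

    frame: pd.DataFrame
    config_echo: dict
    failed: bool = False
    failure_time: float | None = None
    failure_frequency: float | None = None


RESULT_COLUMNS = [
    "t",
    "phi_ankle", "phi_knee", "phi_hip",
    "phidot_ankle", "phidot_knee", "phidot_hip",
    "tau_ankle", "tau_knee", "tau_hip",
    "com_x", "cop_x", "platform_x",
    "f_inst", "cost", "solver_status",
]


def _move_schedule(delta_seq: np.ndarray, prev_tau: np.ndarray, np_horizon: int, nc_horizon: int) -> np.ndarray:
    """Torque applied at each of the Np prediction steps (move blocking)."""
    moves = delta_seq.reshape(nc_horizon, 3)
    taus = np.empty((np_horizon, 3))
    tau = prev_tau.astype(float).copy()
    for i in range(np_horizon):
        if i < nc_horizon:
            tau = tau + moves[i]
        taus[i] = tau
    return taus


def predict_outputs(
    model: AnthropometricModel,
    config: MPCConfig,
    state: PlantState,
    prev_tau: np.ndarray,
    delta_seq: np.ndarray,
    platform_acc: Callable[[float], float],
) -> np.ndarray:
    """Stacked predicted states Y (6*Np,) from a nonlinear rollout.

    The plant is integrated with the same RK4 step as the simulator; the
    torque is updated by ``delta_seq`` over the first Nc steps and held
    constant thereafter.  Non-finite predictions raise
    :class:`SimulationBlowupError` (infeasible for the solver).
    """
    delta_seq = np.asarray(delta_seq, dtype=float)
    if delta_seq.shape != (3 * config.nc_horizon,):
        raise ValueError("delta_seq must have length 3*Nc")
    taus = _move_schedule(delta_seq, np.asarray(prev_tau, float), config.np_horizon, config.nc_horizon)
    x = state.x
    t = state.t
    out = np.empty(6 * config.np_horizon)
    for i in range(config.np_horizon):
        x = rk4_step(model, x, taus[i], platform_acc, t, config.dt)
        t += config.dt
        out[6 * i : 6 * i + 6] = x
    if not np.all(np.isfinite(out)):
        raise SimulationBlowupError("prediction rollout diverged")
    return out


def cost_J(
    Y: np.ndarray,
    Rs: np.ndarray,
    delta_seq: np.ndarray,
    q_diag: np.ndarray,
    r_diag: np.ndarray,
) -> float:
    """Quadratic tracking-plus-effort cost with block-diagonal weights.

    The per-step state weights ``q_diag`` tile over the prediction horizon
    and the per-move increment weights ``r_diag`` over the control horizon.
    """
    Y = np.asarray(Y, float)
    Rs = np.asarray(Rs, float)
    delta_seq = np.asarray(delta_seq, float)
    if Y.shape != Rs.shape or Y.size % 6 or delta_seq.size % 3:
        raise ValueError("nonconformable cost arguments")
    qw = np.tile(np.asarray(q_diag, float), Y.size // 6)
    rw = np.tile(np.asarray(r_diag, float), delta_seq.size // 3)
    e = Rs - Y
    return float(e @ (qw * e) + delta_seq @ (rw * delta_seq))


def _discretize_rk4(
    A: np.ndarray, B: np.ndarray, h: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact one-RK4-step maps of an affine system with held input.

    Returns (Ad, Bd, S) with x+ = Ad x + Bd u + S c for xdot = A x + B u + c;
    S is the truncated integral of the matrix exponential that RK4 realises.
    """
    A2 = A @ A
    A3 = A2 @ A
    Ad = np.eye(6) + h * A + (h**2 / 2) * A2 + (h**3 / 6) * A3 + (h**4 / 24) * A3 @ A
    S = h * np.eye(6) + (h**2 / 2) * A + (h**3 / 6) * A2 + (h**4 / 24) * A3
    return Ad, S @ B, S


def _predict_linear(
    model: AnthropometricModel,
    config: MPCConfig,
    state: PlantState,
    prev_tau: np.ndarray,
    delta_seq: np.ndarray,
    platform_acc: Callable[[float], float],
) -> np.ndarray:
    """Rollout of the plant linearised (affine-exactly) at the current state.

    Used when ``config.prediction == "linear"``: the prediction model is the
    first-order expansion of the dynamics about (state, prev_tau) with the
    platform forcing evaluated per prediction step, discretised by the same
    operator the RK4 integrator realises for an affine system.
    """
    prev_tau = np.asarray(prev_tau, float)
    u = ControlInput(prev_tau)
    A, B = linearize(model, state, u, platform_acc(state.t))
    Ad, Bd, S = _discretize_rk4(A, B, config.dt)
    x_star = state.x
    taus = _move_schedule(
        np.asarray(delta_seq, float), prev_tau, config.np_horizon, config.nc_horizon
    )
    x = x_star.copy()
    t = state.t
    out = np.empty(6 * config.np_horizon)
    for i in range(config.np_horizon):
        ap = platform_acc(t)
        f0 = np.concatenate(
            [x_star[3:], joint_accelerations(model, x_star[:3], x_star[3:], prev_tau, ap)]
        )
        c = f0 - A @ x_star - B @ prev_tau
        x = Ad @ x + Bd @ taus[i] + S @ c
        t += config.dt
        out[6 * i : 6 * i + 6] = x
    return out


def _rollout(model, config, state, prev_tau, delta_seq, platform_acc) -> np.ndarray:
    if config.prediction == "linear":
        return _predict_linear(model, config, state, prev_tau, delta_seq, platform_acc)
    return predict_outputs(model, config, state, prev_tau, delta_seq, platform_acc)


def _prediction_matrix(Ad: np.ndarray, Bd: np.ndarray, np_h: int, nc_h: int) -> np.ndarray:
    """Phi: sensitivity of stacked predictions to the move sequence."""
    # impulse[l] = Ad^(i-1-l) Bd contributions
    powers = [np.eye(6)]
    for _ in range(np_h - 1):
        powers.append(Ad @ powers[-1])
    Phi = np.zeros((6 * np_h, 3 * nc_h))
    for i in range(1, np_h + 1):  # prediction step i uses inputs l = 0..i-1
        for j in range(nc_h):
            # delta_j affects input steps l >= j
            blk = np.zeros((6, 3))
            for l in range(j, i):
                blk += powers[i - 1 - l] @ Bd
            Phi[6 * (i - 1) : 6 * i, 3 * j : 3 * j + 3] = blk
    return Phi


def _solve_sqp(model, config, state, prev_tau, platform_acc) -> MPCSolution:
    np_h, nc_h = config.np_horizon, config.nc_horizon
    qw = np.tile(config.q_diag, np_h)
    rw = np.tile(config.r_effective, nc_h)
    A, B = linearize(model, state, ControlInput(np.asarray(prev_tau, float)), platform_acc(state.t))
    Ad, Bd, _ = _discretize_rk4(A, B, config.dt)
    Phi = _prediction_matrix(Ad, Bd, np_h, nc_h)
    H = Phi.T @ (qw[:, None] * Phi) + np.diag(rw)
    delta = np.zeros(3 * nc_h)
    status = STATUS_OK
    for _ in range(max(1, config.sqp_iters)):
        y = _rollout(model, config, state, prev_tau, delta, platform_acc)
        grad = Phi.T @ (qw * y) + rw * delta
        delta = delta - np.linalg.solve(H, grad)
    # enforce bounds (inactive at nominal perturbation scale)
    lo, hi = _delta_bounds(config, np.asarray(prev_tau, float))
    clipped = np.clip(delta, lo, hi)
    if not np.allclose(clipped, delta):
        status = STATUS_CLIPPED
        delta = clipped
    y = _rollout(model, config, state, prev_tau, delta, platform_acc)
    cost = cost_J(y, np.zeros_like(y), delta, config.q_diag, config.r_effective)
    tau = np.asarray(prev_tau, float) + delta[:3]
    return MPCSolution(delta, ControlInput(tau), y, cost, status, config.sqp_iters)


def _delta_bounds(config: MPCConfig, prev_tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-move bounds on increments implied by dtau and torque limits.

    Conservative box form: each move is limited so that every partial sum
    stays within the torque bounds when the other moves are at extremes is
    not enforced here; instead the first move (the applied one) respects
    the torque bound exactly and later moves the increment bound.
    """
    nc = config.nc_horizon
    lo = np.full(3 * nc, -config.dtau_bound)
    hi = np.full(3 * nc, config.dtau_bound)
    lo[:3] = np.maximum(lo[:3], -config.tau_bounds - prev_tau)
    hi[:3] = np.minimum(hi[:3], config.tau_bounds - prev_tau)
    return lo, hi


def _solve_nlp(model, config, state, prev_tau, platform_acc, warm=None) -> MPCSolution:
    np_h, nc_h = config.np_horizon, config.nc_horizon
    prev_tau = np.asarray(prev_tau, float)
    Rs = np.zeros(6 * np_h)

    def raw_cost(delta):
        y = _rollout(model, config, state, prev_tau, delta, platform_acc)
        return cost_J(y, Rs, delta, config.q_diag, config.r_effective)

    lo, hi = _delta_bounds(config, prev_tau)
    cons = []
    # cumulative torque within bounds for every move
    cum = np.kron(np.tril(np.ones((nc_h, nc_h))), np.eye(3))
    cons.append({
        "type": "ineq",
        "fun": lambda d: np.concatenate([
            np.tile(config.tau_bounds, nc_h) - (np.tile(prev_tau, nc_h) + cum @ d),
            np.tile(config.tau_bounds, nc_h) + (np.tile(prev_tau, nc_h) + cum @ d),
        ]),
    })

    def state_margin(delta):
        y = _rollout(model, config, state, prev_tau, delta, platform_acc)
        ys = y.reshape(np_h, 6)
        return np.concatenate([
            config.phi_bound - np.abs(ys[:, :3]).ravel(),
            config.phidot_bound - np.abs(ys[:, 3:]).ravel(),
        ])

    cons.append({"type": "ineq", "fun": state_margin})
    x0 = np.zeros(3 * nc_h) if warm is None else np.asarray(warm, float)
    x0 = np.clip(x0, lo, hi)
    # scale the objective to O(1) so SLSQP's ftol acts as a relative tolerance
    scale = max(raw_cost(x0), raw_cost(np.zeros(3 * nc_h)))
    scale = scale if scale > 0 else 1.0
    if config.prediction == "linear":
        # the cost is exactly quadratic in the moves: supply its gradient
        qw = np.tile(config.q_diag, np_h)
        rw = np.tile(config.r_effective, nc_h)
        y0 = _rollout(model, config, state, prev_tau, np.zeros(3 * nc_h), platform_acc)
        A, B = linearize(model, state, ControlInput(prev_tau), platform_acc(state.t))
        Ad, Bd, _ = _discretize_rk4(A, B, config.dt)
        Phi = _prediction_matrix(Ad, Bd, np_h, nc_h)

        def jac(d):
            return 2.0 * (Phi.T @ (qw * (y0 + Phi @ d)) + rw * d) / scale

    else:
        jac = "3-point"
    # SLSQP can stall short of the optimum on this ill-conditioned
    # quadratic (adjacent moves are nearly collinear at dt = 10 ms);
    # restarting from the incumbent reliably polishes the solution.
    res = None
    nit = 0
    for _ in range(3):
        res = minimize(
            lambda d: raw_cost(d) / scale,
            x0,
            method="SLSQP",
            jac=jac,
            bounds=list(zip(lo, hi)),
            constraints=cons,
            options={"maxiter": config.nlp_maxiter, "ftol": config.nlp_tol},
        )
        nit += res.nit
        moved = np.abs(res.x - x0).max()
        x0 = res.x
        if not np.all(np.isfinite(x0)) or moved < 1e-12:
            break
    res.nit = nit
    if not res.success and not np.all(np.isfinite(res.x)):
        # fall back to holding the previous torque
        delta = np.zeros(3 * nc_h)
        status = STATUS_FALLBACK
    else:
        delta = res.x
        status = STATUS_OK if res.success else STATUS_FALLBACK
    y = _rollout(model, config, state, prev_tau, delta, platform_acc)
    cost = cost_J(y, Rs, delta, config.q_diag, config.r_effective)
    return MPCSolution(delta, ControlInput(prev_tau + delta[:3]), y, cost, status, res.nit)


def solve_step(
    model: AnthropometricModel,
    config: MPCConfig,
    state: PlantState,
    prev_tau: np.ndarray,
    platform_acc: Callable[[float], float],
    warm: np.ndarray | None = None,
) -> MPCSolution:
    """One receding-horizon optimisation; returns the move sequence and the
    torque to apply (previous torque plus first increment)."""
    if config.solver == "nlp":
        return _solve_nlp(model, config, state, prev_tau, platform_acc, warm)
    return _solve_sqp(model, config, state, prev_tau, platform_acc)


def closed_loop_simulate(
    model: AnthropometricModel,
    config: MPCConfig,
    spec: PlatformSpec,
    preview: bool = True,
    progress: bool = False,
) -> SimulationResult:
    """Run the full closed loop over the platform sweep at 100 Hz.

    Alternates :func:`solve_step` and one RK4 plant step per control period,
    recording state, torque, whole-body COM, COP, platform kinematics and
    instantaneous frequency at every sample (duration/dt + 1 rows).  With
    ``preview=False`` the controller holds the current platform
    acceleration constant over the horizon instead of using the true chirp.
    """
    dt = config.dt
    n = int(round(spec.duration / dt))
    acc_true = acceleration_fn(spec)
    state = PlantState.upright()
    prev_tau = np.zeros(3)
    warm = np.zeros(3 * config.nc_horizon)
    rows = np.empty((n + 1, len(RESULT_COLUMNS) - 1))
    status_col = np.zeros(n + 1, dtype=int)
    failed = False
    fail_t = fail_f = None

    k_end = n
    for k in range(n + 1):
        t = k * dt
        pos, vel, ap, f_inst = _eval(spec, t)
        if k < n:
            if preview:
                horizon_acc = acc_true
            else:
                a_now = ap
                horizon_acc = lambda _t, a=a_now: a  # noqa: E731
            sol = solve_step(model, config, state, prev_tau, horizon_acc, warm)
            tau = sol.applied.tau
            cost = sol.cost
            status = sol.status
            # shift warm start by one move
            warm = np.concatenate([sol.delta_tau_sequence[3:], np.zeros(3)])
        else:
            tau = prev_tau
            cost = np.nan
            status = STATUS_OK
        phidd = joint_accelerations(model, state.phi, state.phidot, tau, ap)
        gr = cop_position(model, state, phidd, ControlInput(tau), ap)
        com_x, _, _ = total_com(model, state, pos, vel)
        # torques are recorded as internal joint moments, restoring-positive
        # (negative of the CCW generalized torque), so quiet-stance joint
        # quasi-stiffness is positive; pairwise coordination is unaffected.
        rows[k] = [
            t, *state.phi, *state.phidot, *(-tau),
            com_x, pos + gr.cop_x, pos, f_inst, cost,
        ]
        status_col[k] = status
        if np.abs(state.phi).max() > config.phi_bound or np.abs(state.phidot).max() > config.phidot_bound:
            failed, fail_t, fail_f = True, t, f_inst
            k_end = k
            break
        if k < n:
            try:
                x = rk4_step(model, state.x, tau, acc_true, t, dt)
            except FloatingPointError:
                failed, fail_t, fail_f = True, t, f_inst
                k_end = k
                break
            if not np.all(np.isfinite(x)):
                failed, fail_t, fail_f = True, t, f_inst
                k_end = k
                break
            state = PlantState(x[:3], x[3:], t + dt)
            prev_tau = tau
        if progress and k % 1000 == 0:
            print(f"t={t:7.2f} s  f={f_inst:5.2f} Hz  |phi|max={np.abs(state.phi).max():.2e}")

    frame = pd.DataFrame(rows[: k_end + 1], columns=RESULT_COLUMNS[:-1])
    frame["solver_status"] = status_col[: k_end + 1]
    echo = {
        "mpc": {
            "np_horizon": config.np_horizon,
            "nc_horizon": config.nc_horizon,
            "q_diag": config.q_diag.tolist(),
            "r_diag": config.r_diag.tolist(),
            "dt": config.dt,
            "solver": config.solver,
            "preview": preview,
        },
        "platform": {
            "amplitude": spec.amplitude,
            "f_start": spec.f_start,
            "f_end": spec.f_end,
            "duration": spec.duration,
        },
        "body": {"total_mass": model.total_mass, "total_height": model.total_height},
    }
    return SimulationResult(frame, echo, failed, fail_t, fail_f)
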