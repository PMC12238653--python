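"""Rigid-body dynamics of the three-link chain on a translating platform.

The foot is bolted to a platform that translates horizontally (anterior-
posterior, x positive forward, z up).  The shank, thigh and HAT segments
form a triple inverted pendulum articulated at ankle, knee and hip, driven
by joint torques.  Generalized coordinates used internally are the absolute
segment angles from vertical, alpha_i; the public state uses joint
deviations from upright phi = (phi_ankle, phi_knee, phi_hip) with
alpha = cumsum(phi) and phi = 0 the upright equilibrium.

Equations of motion (derived by Euler-Lagrange for a chain with a
prescribed horizontal base motion x_p(t)):

    sum_j M_ij(alpha) dd(alpha_j) + sum_j b_ij sin(alpha_i - alpha_j) d(alpha_j)^2
        - g P_i sin(alpha_i) + P_i cos(alpha_i) dd(x_p) = Q_i

with M_ij = b_ij cos(alpha_i - alpha_j) + delta_ij I_i, the constant
coefficients b and first moments P precomputed from the anthropometry, and
Q = D^T tau the generalized torques (D maps absolute-angle variations to
joint-angle variations).  Base excitation enters purely through the
inertial coupling term P_i cos(alpha_i) * platform acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .anthropometry import AnthropometricModel

__all__ = [
    "PlantState",
    "ControlInput",
    "GroundReaction",
    "mass_matrix",
    "joint_accelerations",
    "forward_dynamics",
    "step_state",
    "rk4_step",
    "total_com",
    "cop_position",
    "linearize",
    "total_energy",
    "SimulationBlowupError",
]

# alpha = S @ phi;  phi = D @ alpha
_S = np.tril(np.ones((3, 3)))
_D = np.array([[1.0, 0.0, 0.0], [-1.0, 1.0, 0.0], [0.0, -1.0, 1.0]])


class SimulationBlowupError(RuntimeError):
    """State left the finite range during integration."""


@dataclass
class PlantState:
    """Joint-space state: deviations from upright (rad, rad/s) and time."""

    phi: np.ndarray
    phidot: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.phidot = np.asarray(self.phidot, dtype=float)
        if self.phi.shape != (3,) or self.phidot.shape != (3,):
            raise ValueError("phi and phidot must be 3-vectors")

    @property
    def x(self) -> np.ndarray:
        """Stacked state vector (phi, phidot)."""
        return np.concatenate([self.phi, self.phidot])

    @classmethod
    def upright(cls, t: float = 0.0) -> "PlantState":
        return cls(np.zeros(3), np.zeros(3), t)


@dataclass
class ControlInput:
    """Joint torques (N m): ankle, knee, hip."""

    tau: np.ndarray

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.shape != (3,):
            raise ValueError("tau must be a 3-vector")


@dataclass
class GroundReaction:
    """Ground reaction under the foot.

    ``cop_x`` is in the platform frame, relative to the ankle projection.
    ``within_foot`` is False when the COP falls outside the heel-toe
    extent (the fixed-support model is then invalid); ``lift_off`` flags
    a non-positive vertical force.
    """

    fz: float
    fx: float
    cop_x: float
    within_foot: bool = True
    lift_off: bool = False


def mass_matrix(model: AnthropometricModel, phi: np.ndarray) -> np.ndarray:
    """Configuration-dependent inertia matrix in absolute-angle coordinates."""
    la = model.link_arrays
    alpha = _S @ np.asarray(phi, dtype=float)
    diff = alpha[:, None] - alpha[None, :]
    return la["b"] * np.cos(diff) + np.diag(la["Ic"])


def joint_accelerations(
    model: AnthropometricModel,
    phi: np.ndarray,
    phidot: np.ndarray,
    tau: np.ndarray,
    platform_acc: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Joint angular accelerations phidd (rad/s^2); batched over leading axes.

    Solves M(alpha) alpha_dd = Q + g P sin(alpha) - C(alpha, alphadot)
    - P cos(alpha) a_p and maps back to joint coordinates.  Raises
    LinAlgError if the inertia matrix is singular (cannot occur for
    physical parameters).
    """
    la = model.link_arrays
    b, P, Ic, g = la["b"], la["P"], la["Ic"], model.gravity
    phi = np.asarray(phi, dtype=float)
    phidot = np.asarray(phidot, dtype=float)
    alpha = phi @ _S.T
    alphadot = phidot @ _S.T
    ap = np.asarray(platform_acc, dtype=float)

    diff = alpha[..., :, None] - alpha[..., None, :]
    M = b * np.cos(diff)
    M[..., np.arange(3), np.arange(3)] += Ic
    W = b * np.sin(diff)
    sa = np.sin(alpha)
    ca = np.cos(alpha)
    Q = tau @ _D  # D^T tau, batched
    rhs = (
        Q
        + g * P * sa
        - np.einsum("...ij,...j->...i", W, alphadot**2)
        - P * ca * ap[..., None]
    )
    alphadd = np.linalg.solve(M, rhs[..., None])[..., 0]
    return alphadd @ _D.T


def forward_dynamics(
    model: AnthropometricModel,
    state: PlantState,
    u: ControlInput,
    platform_acc: float = 0.0,
) -> np.ndarray:
    """Joint angular accelerations for a single state (rad/s^2)."""
    return joint_accelerations(model, state.phi, state.phidot, u.tau, platform_acc)


def _state_derivative(
    model: AnthropometricModel,
    x: np.ndarray,
    tau: np.ndarray,
    ap: float,
) -> np.ndarray:
    phidd = joint_accelerations(model, x[:3], x[3:], tau, ap)
    return np.concatenate([x[3:], phidd])


def rk4_step(
    model: AnthropometricModel,
    x: np.ndarray,
    tau: np.ndarray,
    acc_fn: Callable[[float], float],
    t: float,
    dt: float,
) -> np.ndarray:
    """One classical Runge-Kutta step of the stacked state with held torque."""
    k1 = _state_derivative(model, x, tau, acc_fn(t))
    a_mid = acc_fn(t + 0.5 * dt)
    k2 = _state_derivative(model, x + 0.5 * dt * k1, tau, a_mid)
    k3 = _state_derivative(model, x + 0.5 * dt * k2, tau, a_mid)
    k4 = _state_derivative(model, x + dt * k3, tau, acc_fn(t + dt))
    return x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def step_state(
    model: AnthropometricModel,
    state: PlantState,
    u: ControlInput,
    platform_motion_at_t: Callable[[float], float] | float = 0.0,
    dt: float = 0.01,
    substeps: int = 1,
) -> PlantState:
    """Advance the plant one control period by fixed-step RK4.

    ``platform_motion_at_t`` is the platform horizontal acceleration as a
    callable of time (or a constant); torque is held constant over the
    step.  Raises :class:`SimulationBlowupError` if the state leaves the
    finite range.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if callable(platform_motion_at_t):
        acc_fn = platform_motion_at_t
    else:
        a_const = float(platform_motion_at_t)
        acc_fn = lambda t: a_const  # noqa: E731
    x = state.x
    h = dt / substeps
    t = state.t
    for _ in range(substeps):
        x = rk4_step(model, x, u.tau, acc_fn, t, h)
        t += h
    if not np.all(np.isfinite(x)):
        raise SimulationBlowupError(f"non-finite state at t={state.t + dt:.3f} s")
    return PlantState(x[:3], x[3:], state.t + dt)


def _lever_matrix(model: AnthropometricModel) -> np.ndarray:
    """c[k, i]: moment arm of absolute angle i in link-k COM kinematics."""
    la = model.link_arrays
    L, d = la["L"], la["d"]
    c = np.zeros((3, 3))
    for k in range(3):
        c[k, :k] = L[:k]
        c[k, k] = d[k]
    return c


def _link_com_positions(
    model: AnthropometricModel, alpha: np.ndarray, platform_pos: float
) -> tuple[np.ndarray, np.ndarray]:
    """Lab-frame (x, z) of the three link COMs; ankle at (platform_pos, h)."""
    la = model.link_arrays
    L, d = la["L"], la["d"]
    sa, ca = np.sin(alpha), np.cos(alpha)
    joint_x = platform_pos + np.concatenate([[0.0], np.cumsum(L * sa)])[:3]
    joint_z = model.ankle_height + np.concatenate([[0.0], np.cumsum(L * ca)])[:3]
    return joint_x + d * sa, joint_z + d * ca


def total_com(
    model: AnthropometricModel,
    state: PlantState,
    platform_pos: float = 0.0,
    platform_vel: float = 0.0,
) -> tuple[float, float, float]:
    """Whole-body centre of mass (x, z) and its horizontal velocity, lab frame.

    Includes the foot, which translates rigidly with the platform.
    """
    la = model.link_arrays
    m, L, d = la["m"], la["L"], la["d"]
    alpha = _S @ state.phi
    alphadot = _S @ state.phidot
    cx, cz = _link_com_positions(model, alpha, platform_pos)
    ca = np.cos(alpha)
    # d/dt of each link COM x: platform_vel + sum over supporting angles
    c = _lever_matrix(model)
    cxdot = platform_vel + (c * (ca * alphadot)).sum(axis=1)
    mf = model.foot.mass
    foot_x = platform_pos + model.foot_com_forward
    foot_z = 0.5 * model.ankle_height
    M = model.total_mass
    com_x = (mf * foot_x + (m * cx).sum()) / M
    com_z = (mf * foot_z + (m * cz).sum()) / M
    com_xdot = (mf * platform_vel + (m * cxdot).sum()) / M
    return float(com_x), float(com_z), float(com_xdot)


def _link_com_accelerations(
    model: AnthropometricModel,
    alpha: np.ndarray,
    alphadot: np.ndarray,
    alphadd: np.ndarray,
    platform_acc: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Lab-frame (xdd, zdd) of the three link COMs."""
    sa, ca = np.sin(alpha), np.cos(alpha)
    c = _lever_matrix(model)
    xdd = platform_acc + (c * (ca * alphadd - sa * alphadot**2)).sum(axis=1)
    zdd = (c * (-sa * alphadd - ca * alphadot**2)).sum(axis=1)
    return xdd, zdd


def cop_position(
    model: AnthropometricModel,
    state: PlantState,
    accelerations: np.ndarray,
    u: ControlInput,
    platform_acc: float = 0.0,
) -> GroundReaction:
    """Centre of pressure from the foot free-body (foot fixed to platform).

    The ankle reaction force follows from Newton's law applied to the
    three supported links; the foot free-body (reaction force and ankle
    torque, foot weight, foot inertia under platform acceleration) then
    yields the ground reaction components and the COP x-coordinate.
    """
    alpha = _S @ state.phi
    alphadot = _S @ state.phidot
    alphadd = _S @ np.asarray(accelerations, dtype=float)
    la = model.link_arrays
    m = la["m"]
    g = model.gravity
    xdd, zdd = _link_com_accelerations(model, alpha, alphadot, alphadd, platform_acc)
    # force the foot exerts on the link chain at the ankle
    f_ax = (m * xdd).sum()
    f_az = (m * (zdd + g)).sum()
    mf = model.foot.mass
    fx = mf * platform_acc + f_ax
    fz = mf * g + f_az
    lift_off = fz <= 0.0
    h = model.ankle_height
    x_fc = model.foot_com_forward  # foot COM relative to ankle
    z_fc = 0.5 * h
    tau_a = float(u.tau[0])
    if lift_off:
        cop = np.nan
    else:
        # moment balance about the ankle, forward-tipping positive
        cop = (x_fc * mf * g - tau_a - h * fx - mf * (z_fc - h) * platform_acc) / fz
    within = bool(not lift_off and model.heel_x <= cop <= model.toe_x)
    return GroundReaction(
        fz=float(fz), fx=float(fx), cop_x=float(cop), within_foot=within, lift_off=lift_off
    )


def linearize(
    model: AnthropometricModel,
    state: PlantState,
    u: ControlInput,
    platform_acc: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous-time Jacobians (A, B) of xdot = f(x, u, a_p) at a point.

    x = (phi, phidot).  The partials are assembled analytically from the
    closed-form equations of motion (matrix calculus on M(alpha) and the
    right-hand side), not by finite differences.
    """
    la = model.link_arrays
    b, P, Ic, g = la["b"], la["P"], la["Ic"], model.gravity
    alpha = _S @ state.phi
    alphadot = _S @ state.phidot
    sa, ca = np.sin(alpha), np.cos(alpha)
    diff = alpha[:, None] - alpha[None, :]
    M = b * np.cos(diff) + np.diag(Ic)
    W = b * np.sin(diff)
    V = b * np.cos(diff)
    Q = _D.T @ u.tau
    rhs = Q + g * P * sa - W @ alphadot**2 - P * ca * platform_acc
    Minv = np.linalg.inv(M)
    alphadd = Minv @ rhs

    Ja = np.zeros((3, 3))  # d(alphadd)/d(alpha_k)
    v2 = alphadot**2
    Vv2 = V @ v2
    Wa = W @ alphadd
    for k in range(3):
        dr = np.zeros(3)
        dr[k] += g * P[k] * ca[k] + P[k] * sa[k] * platform_acc - Vv2[k]
        dr += V[:, k] * v2[k]
        dMa = np.zeros(3)  # (dM/dalpha_k) @ alphadd
        dMa[k] -= Wa[k]
        dMa += W[:, k] * alphadd[k]
        Ja[:, k] = Minv @ (dr - dMa)
    Jv = Minv @ (-2.0 * W * alphadot[None, :])  # d(alphadd)/d(alphadot_k)

    A = np.zeros((6, 6))
    A[:3, 3:] = np.eye(3)
    A[3:, :3] = _D @ Ja @ _S
    A[3:, 3:] = _D @ Jv @ _S
    B = np.zeros((6, 3))
    B[3:, :] = _D @ Minv @ _D.T
    return A, B


def total_energy(
    model: AnthropometricModel,
    state: PlantState,
    platform_pos: float = 0.0,
    platform_vel: float = 0.0,
) -> float:
    """Total mechanical energy (J) in the lab frame, zero at rest upright.

    Kinetic plus gravitational potential energy of all four segments, with
    the potential reference chosen so the upright configuration at rest
    (platform at the origin) has zero energy.
    """
    la = model.link_arrays
    m, L, d, Ic = la["m"], la["L"], la["d"], la["Ic"]
    g = model.gravity
    alpha = _S @ state.phi
    alphadot = _S @ state.phidot
    ca, sa = np.cos(alpha), np.sin(alpha)
    c = _lever_matrix(model)
    vx = platform_vel + (c * (ca * alphadot)).sum(axis=1)
    vz = (c * (-sa * alphadot)).sum(axis=1)
    ke = 0.5 * ((m * (vx**2 + vz**2)).sum() + (Ic * alphadot**2).sum())
    ke += 0.5 * model.foot.mass * platform_vel**2
    _, cz = _link_com_positions(model, alpha, platform_pos)
    pe = g * (m * cz).sum()
    # upright reference heights
    cz0 = model.ankle_height + np.concatenate([[0.0], np.cumsum(L)])[:3] + d
    pe0 = g * (m * cz0).sum()
    return float(ke + pe - pe0)
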