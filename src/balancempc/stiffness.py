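"""Quasi-stiffness: per-cycle linear fits of joint torque against angle.

Quasi-stiffness is the slope of the best linear fit on the torque-angle
graph over a movement cycle.  Unlike true (perturbation-based) joint
stiffness it may be negative: a positive slope is spring-like, resisting
motion; a negative slope marks torque assisting motion (anti-phase
torque-angle coordination).  Cycles are delimited by upward zero-crossings
of the platform position so all joints share identical segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QuasiStiffnessResult", "quasi_stiffness_cycles", "sign_transition"]


@dataclass
class QuasiStiffnessResult:
    """Per-cycle OLS slope/intercept/R^2 with cycle timing and frequency."""

    slope: np.ndarray
    intercept: np.ndarray
    r_squared: np.ndarray
    t_start: np.ndarray
    t_end: np.ndarray
    f_centre: np.ndarray
    valid: np.ndarray
    joint: str = ""

    def __len__(self) -> int:
        return len(self.slope)


def _cycle_bounds(platform_pos: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges between consecutive upward zero-crossings."""
    p = np.asarray(platform_pos, dtype=float)
    up = np.flatnonzero((p[:-1] < 0.0) & (p[1:] >= 0.0)) + 1
    return [(up[i], up[i + 1]) for i in range(len(up) - 1)]


def quasi_stiffness_cycles(
    torque: np.ndarray,
    angle: np.ndarray,
    platform_pos: np.ndarray,
    freq_stamps: np.ndarray,
    t: np.ndarray | None = None,
    min_samples: int = 5,
    joint: str = "",
) -> QuasiStiffnessResult:
    """OLS fit tau = a*phi + b within each platform-period cycle.

    Cycles with fewer than ``min_samples`` samples or zero angle variance
    are flagged invalid (NaN slope).
    """
    torque = np.asarray(torque, dtype=float)
    angle = np.asarray(angle, dtype=float)
    freq_stamps = np.asarray(freq_stamps, dtype=float)
    if not (torque.shape == angle.shape == freq_stamps.shape):
        raise ValueError("torque, angle and freq_stamps must have equal shapes")
    if np.any(np.diff(freq_stamps) < 0):
        raise ValueError("freq_stamps must be monotone non-decreasing")
    if t is None:
        t = np.arange(len(torque), dtype=float)
    bounds = _cycle_bounds(platform_pos)
    n = len(bounds)
    slope = np.full(n, np.nan)
    intercept = np.full(n, np.nan)
    r2 = np.full(n, np.nan)
    ts = np.full(n, np.nan)
    te = np.full(n, np.nan)
    fc = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, (a, b) in enumerate(bounds):
        ts[i], te[i] = t[a], t[b - 1]
        fc[i] = freq_stamps[a:b].mean()
        if b - a < min_samples:
            continue
        phi = angle[a:b]
        tau = torque[a:b]
        if np.ptp(phi) == 0.0:
            continue
        coef = np.polyfit(phi, tau, 1)
        fitted = np.polyval(coef, phi)
        ss_res = np.sum((tau - fitted) ** 2)
        ss_tot = np.sum((tau - tau.mean()) ** 2)
        slope[i], intercept[i] = coef
        r2[i] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        valid[i] = True
    return QuasiStiffnessResult(slope, intercept, r2, ts, te, fc, valid, joint)


def sign_transition(result: QuasiStiffnessResult, persistence: int = 3) -> float | None:
    """Frequency of the first persistent slope sign change, or None.

    Scans valid cycles in order; a change counts when the new sign holds
    for at least ``persistence`` consecutive valid cycles.  Returns the
    cycle-centre frequency of the first cycle of the persistent run.
    """
    idx = np.flatnonzero(result.valid & (result.slope != 0.0))
    if len(idx) < persistence + 1:
        raise ValueError("need at least persistence+1 valid cycles")
    signs = np.sign(result.slope[idx])
    for k in range(1, len(idx) - persistence + 1):
        if signs[k] != signs[k - 1] and np.all(signs[k : k + persistence] == signs[k]):
            return float(result.f_centre[idx[k]])
    return None
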