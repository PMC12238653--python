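"""Anterior-posterior sinusoidal chirp of the support platform.

The platform translates as x(t) = A sin(psi(t)) with a linearly increasing
instantaneous frequency f(t) = f_start + k t, k = (f_end - f_start)/T, so
psi(t) = 2 pi (f_start t + k t^2 / 2) + phase0.  Velocity and acceleration
are the exact analytic derivatives.  Defaults follow the experimental
protocol the simulator emulates: amplitude 2 mm, 0.4 -> 6 Hz sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["PlatformSpec", "PlatformSample", "platform_sample", "platform_series", "acceleration_fn"]


@dataclass(frozen=True)
class PlatformSpec:
    """Chirp parameters: amplitude (m), frequency endpoints (Hz), duration (s)."""

    amplitude: float = 0.002
    f_start: float = 0.4
    f_end: float = 6.0
    duration: float = 280.0
    phase0: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if not (0 < self.f_start <= self.f_end):
            raise ValueError("need 0 < f_start <= f_end")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def ramp_rate(self) -> float:
        """Frequency sweep rate k (Hz/s)."""
        return (self.f_end - self.f_start) / self.duration


@dataclass(frozen=True)
class PlatformSample:
    """Platform kinematics at one instant."""

    position: float
    velocity: float
    acceleration: float
    frequency: float
    t: float


def _eval(spec: PlatformSpec, t):
    """Chirp kinematics without range checks (used for horizon previews)."""
    k = spec.ramp_rate
    f = spec.f_start + k * t
    psi = 2.0 * np.pi * (spec.f_start * t + 0.5 * k * t * t) + spec.phase0
    w = 2.0 * np.pi * f
    A = spec.amplitude
    s, c = np.sin(psi), np.cos(psi)
    pos = A * s
    vel = A * c * w
    acc = -A * s * w * w + A * c * 2.0 * np.pi * k
    return pos, vel, acc, f


def platform_sample(spec: PlatformSpec, t: float) -> PlatformSample:
    """Exact platform kinematics at time ``t`` in [0, duration]."""
    if not (0.0 <= t <= spec.duration + 1e-9):
        raise ValueError(f"t={t} outside [0, {spec.duration}]")
    pos, vel, acc, f = _eval(spec, t)
    return PlatformSample(float(pos), float(vel), float(acc), float(f), float(t))


def platform_series(spec: PlatformSpec, dt: float = 0.01) -> dict[str, np.ndarray]:
    """Sampled trajectory on the uniform grid t = 0, dt, ..., duration."""
    n = int(round(spec.duration / dt))
    t = np.arange(n + 1) * dt
    pos, vel, acc, f = _eval(spec, t)
    return {"t": t, "position": pos, "velocity": vel, "acceleration": acc, "frequency": f}


def acceleration_fn(spec: PlatformSpec) -> Callable[[float], float]:
    """Platform acceleration as a plain callable of time (preview-safe:
    evaluates the analytic chirp slightly beyond the nominal duration so a
    prediction horizon that overhangs the end of the sweep stays defined)."""

    def acc(t: float) -> float:
        return _eval(spec, t)[2]

    return acc
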