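"""Coordination analysis: vector coding, relative phase rate, transitions.

Coordination between two signals (adjacent joint torques, or COP and COM
displacement) is quantified by the vector-coding coupling angle: the angle
of the displacement vector between consecutive samples in the signal-pair
plane, gamma_i = atan2(y_{i+1}-y_i, x_{i+1}-x_i) in [0, 360) degrees.
Angles near the 45/225 degree diagonal indicate in-phase motion, near
135/315 anti-phase.  Per 1-s window the proportions of in- vs anti-phase
samples form the relative phase rate (RPR); a logistic fit of the
anti-phase proportion against the window-centre platform frequency locates
the coordination transition.  Postural strategies follow from the phase of
the two adjacent torque pairs: ankle strategy when both are in-phase, knee
when ankle-knee is anti-phase but knee-hip in-phase, hip for the reverse,
combined when both are anti-phase.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Phase",
    "StrategyLabel",
    "CouplingSeries",
    "RPRSeries",
    "TransitionEstimate",
    "coupling_angle",
    "classify_phase",
    "rpr",
    "windowed_rpr",
    "fit_sigmoid",
    "label_strategy",
    "compare_series",
]


class Phase(enum.Enum):
    IN_PHASE = "in_phase"
    ANTI_PHASE = "anti_phase"


class StrategyLabel(enum.Enum):
    ANKLE = "ankle"
    KNEE = "knee"
    HIP = "hip"
    COMBINED = "combined"


@dataclass
class CouplingSeries:
    """Coupling angles (degrees, [0, 360)) per consecutive sample pair.

    ``valid`` marks pairs with nonzero displacement; undefined angles are
    excluded from window denominators.  ``t`` / ``f`` stamp each pair at
    the midpoint of its two samples.
    """

    angles: np.ndarray
    valid: np.ndarray
    t: np.ndarray | None = None
    f: np.ndarray | None = None
    pair: str = ""

    def __len__(self) -> int:
        return len(self.angles)


@dataclass
class RPRSeries:
    """Windowed in-/anti-phase proportions (relative phase rate)."""

    in_phase: np.ndarray
    anti_phase: np.ndarray
    t_start: np.ndarray
    t_end: np.ndarray
    f_centre: np.ndarray
    window_samples: int
    defined: np.ndarray = field(default=None)  # False where all samples excluded

    def __post_init__(self) -> None:
        if self.defined is None:
            self.defined = np.isfinite(self.in_phase)

    def __len__(self) -> int:
        return len(self.in_phase)


@dataclass
class TransitionEstimate:
    """Logistic transition fit: midpoint frequency and slope scale (Hz)."""

    frequency: float
    slope: float
    residual_rms: float
    detected: bool
    message: str = ""


def coupling_angle(
    x: np.ndarray,
    y: np.ndarray,
    t: np.ndarray | None = None,
    f: np.ndarray | None = None,
    pair: str = "",
) -> CouplingSeries:
    """Vector-coding coupling angles between two equal-length series.

    Pairs where both consecutive differences are exactly zero have no
    defined direction; they are marked invalid and excluded downstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d series of length >= 2")
    dx = np.diff(x)
    dy = np.diff(y)
    valid = (dx != 0.0) | (dy != 0.0)
    angles = np.degrees(np.arctan2(dy, dx)) % 360.0
    angles[~valid] = np.nan
    mid = lambda v: None if v is None else 0.5 * (np.asarray(v)[1:] + np.asarray(v)[:-1])  # noqa: E731
    return CouplingSeries(angles, valid, mid(t), mid(f), pair)


def classify_phase(gamma: float | np.ndarray) -> Phase | np.ndarray:
    """Binary nearest-diagonal classification of coupling angles.

    In-phase when the angle is closer to the 45/225 diagonal than to the
    135/315 one; exact ties (0, 90, 180, 270 degrees) count as in-phase.
    Equivalent to sin(2 gamma) >= 0.  Vectorised: ndarray in, bool array
    out (True = in-phase).
    """
    g = np.radians(np.asarray(gamma, dtype=float))
    in_phase = np.sin(2.0 * g) >= -1e-12
    if np.isscalar(gamma) or np.ndim(gamma) == 0:
        return Phase.IN_PHASE if bool(in_phase) else Phase.ANTI_PHASE
    return in_phase


def rpr(coupling: CouplingSeries, window_samples: int = 100) -> RPRSeries:
    """Relative phase rate: in-/anti-phase proportions per non-overlapping window.

    Windows are aligned to the start of the record; proportions are over
    the valid (classified) samples of each window and sum to 1.  A window
    with no valid samples is flagged undefined (NaN proportions).
    """
    n = len(coupling)
    if n < window_samples:
        raise ValueError("coupling series shorter than one window")
    n_win = n // window_samples
    in_p = np.full(n_win, np.nan)
    t0 = np.full(n_win, np.nan)
    t1 = np.full(n_win, np.nan)
    fc = np.full(n_win, np.nan)
    is_in = classify_phase(coupling.angles)
    for w in range(n_win):
        sl = slice(w * window_samples, (w + 1) * window_samples)
        v = coupling.valid[sl]
        if v.any():
            in_p[w] = np.count_nonzero(is_in[sl] & v) / np.count_nonzero(v)
        if coupling.t is not None:
            t0[w] = coupling.t[sl][0]
            t1[w] = coupling.t[sl][-1]
        if coupling.f is not None:
            fc[w] = np.mean(coupling.f[sl])
    return RPRSeries(in_p, 1.0 - in_p, t0, t1, fc, window_samples, np.isfinite(in_p))


def windowed_rpr(
    x: np.ndarray,
    y: np.ndarray,
    t: np.ndarray | None = None,
    f: np.ndarray | None = None,
    window_samples: int = 100,
    pair: str = "",
) -> RPRSeries:
    """Relative phase rate computed window by window from the raw signals.

    Convenience composition identical to
    ``rpr(coupling_angle(x, y, t, f), window_samples)``; the binary
    nearest-diagonal classification depends only on the sign of
    dx*dy and is therefore invariant to (positive) rescaling of either
    signal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d series")
    n_win = (len(x) - 1) // window_samples
    if n_win < 1:
        raise ValueError("series shorter than one window")
    in_p = np.full(n_win, np.nan)
    t0 = np.full(n_win, np.nan)
    t1 = np.full(n_win, np.nan)
    fc = np.full(n_win, np.nan)
    for w in range(n_win):
        sl = slice(w * window_samples, (w + 1) * window_samples + 1)
        xs, ys = x[sl], y[sl]
        coup = coupling_angle(xs, ys, pair=pair)
        if coup.valid.any():
            is_in = classify_phase(coup.angles)
            in_p[w] = np.count_nonzero(is_in & coup.valid) / np.count_nonzero(coup.valid)
        if t is not None:
            t0[w] = t[sl][0]
            t1[w] = t[sl][-1]
        if f is not None:
            fc[w] = np.mean(f[sl])
    return RPRSeries(in_p, 1.0 - in_p, t0, t1, fc, window_samples, np.isfinite(in_p))


def _logistic(f, f_t, s, p0=0.0, p1=1.0):
    return p0 + (p1 - p0) / (1.0 + np.exp(-(f - f_t) / s))


def fit_sigmoid(series: RPRSeries, min_range: float = 0.5) -> TransitionEstimate:
    """Least-squares logistic fit of anti-phase proportion vs frequency.

    Fits the four-parameter logistic p(f) = p0 + (p1 - p0)/(1 + exp(-(f -
    f_t)/s)) with free plateaus (the coordination need not reach a pure
    0/1 anti-phase proportion) and reports the midpoint f_t as the
    transition frequency.  Declares no transition when the fitted curve
    spans less than ``min_range`` over the observed frequencies or the
    optimiser fails.
    """
    mask = series.defined & np.isfinite(series.f_centre)
    f = series.f_centre[mask]
    p = series.anti_phase[mask]
    if len(f) < 4:
        raise ValueError("need at least 4 defined windows to fit a transition")
    lo = float(np.mean(p[: max(3, len(p) // 10)]))
    hi = float(np.mean(p[-max(3, len(p) // 10):]))
    half = 0.5 * (lo + hi)
    above = p >= half
    if above.any() and not above.all():
        f0 = f[np.argmax(above)]
    else:
        f0 = 0.5 * (f.min() + f.max())
    try:
        popt, _ = optimize.curve_fit(
            _logistic, f, p, p0=[f0, 0.1, np.clip(lo, 0, 1), np.clip(hi, 0, 1)],
            bounds=([f.min() - 2.0, 1e-3, 0.0, 0.0], [f.max() + 2.0, 10.0, 1.0, 1.0]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        return TransitionEstimate(np.nan, np.nan, np.nan, False, f"fit failed: {exc}")
    f_t, s = popt[0], popt[1]
    fitted = _logistic(f, *popt)
    resid = float(np.sqrt(np.mean((fitted - p) ** 2)))
    span = float(abs(_logistic(f.max(), *popt) - _logistic(f.min(), *popt)))
    if span < min_range:
        return TransitionEstimate(
            float(f_t), float(s), resid, False,
            f"fitted range {span:.2f} < {min_range}: no transition",
        )
    return TransitionEstimate(float(f_t), float(s), resid, True)


def label_strategy(phase_ankle_knee: Phase, phase_knee_hip: Phase) -> StrategyLabel:
    """Postural strategy from the phase of the two adjacent torque pairs."""
    table = {
        (Phase.IN_PHASE, Phase.IN_PHASE): StrategyLabel.ANKLE,
        (Phase.ANTI_PHASE, Phase.IN_PHASE): StrategyLabel.KNEE,
        (Phase.IN_PHASE, Phase.ANTI_PHASE): StrategyLabel.HIP,
        (Phase.ANTI_PHASE, Phase.ANTI_PHASE): StrategyLabel.COMBINED,
    }
    return table[(phase_ankle_knee, phase_knee_hip)]


def compare_series(sim: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and RMSE between two equal-length series."""
    sim = np.asarray(sim, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if sim.shape != ref.shape or sim.ndim != 1 or len(sim) < 3:
        raise ValueError("series must be equal-length 1-d with length >= 3")
    if np.std(sim) == 0.0 or np.std(ref) == 0.0:
        raise ValueError("correlation undefined for zero-variance series")
    r, _ = stats.pearsonr(sim, ref)
    rmse = float(np.sqrt(np.mean((sim - ref) ** 2)))
    return float(r), rmse
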