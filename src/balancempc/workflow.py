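"""End-to-end analysis of a closed-loop simulation table.

Thin orchestration over :mod:`balancempc.coordination` and
:mod:`balancempc.stiffness`: extracts the standard signal pairs from a
simulation frame (adjacent joint torques, COP-COM displacement), runs
vector coding -> RPR -> logistic transition fitting, labels the postural
strategy before and after the ankle-knee transition, and computes per-joint
quasi-stiffness slopes with their sign transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coordination import (
    Phase,
    RPRSeries,
    StrategyLabel,
    TransitionEstimate,
    fit_sigmoid,
    label_strategy,
    windowed_rpr,
)
from .stiffness import QuasiStiffnessResult, quasi_stiffness_cycles, sign_transition

__all__ = ["PAIR_COLUMNS", "PairAnalysis", "AnalysisReport", "analyze_frame"]

PAIR_COLUMNS: dict[str, tuple[str, str]] = {
    "ankle-knee": ("tau_ankle", "tau_knee"),
    "knee-hip": ("tau_knee", "tau_hip"),
    "cop-com": ("cop_x", "com_x"),
}

JOINTS = ("ankle", "knee", "hip")


@dataclass
class PairAnalysis:
    rpr: RPRSeries
    transition: TransitionEstimate


@dataclass
class AnalysisReport:
    pairs: dict[str, PairAnalysis]
    stiffness: dict[str, QuasiStiffnessResult]
    stiffness_transitions: dict[str, float | None]
    strategy_before: StrategyLabel | None = None
    strategy_after: StrategyLabel | None = None


def _window_phase(series: RPRSeries, mask: np.ndarray) -> Phase:
    """Dominant phase over a set of windows."""
    mean_in = np.nanmean(series.in_phase[mask])
    return Phase.IN_PHASE if mean_in >= 0.5 else Phase.ANTI_PHASE


def analyze_frame(
    frame: pd.DataFrame,
    pairs: tuple[str, ...] = ("ankle-knee", "knee-hip", "cop-com"),
    window_samples: int = 100,
    persistence: int = 3,
    stiffness_joints: tuple[str, ...] = JOINTS,
) -> AnalysisReport:
    """Full coordination + quasi-stiffness analysis of a simulation frame.

    The frame must carry the standard simulation columns (see
    :data:`balancempc.mpc.RESULT_COLUMNS`); externally produced CSVs with
    those column names are analysed identically.  The COP-COM pair is
    coded on support-frame displacements (COP and COM relative to the
    moving platform, the quantities a platform-embedded force plate and a
    platform-referenced COM trace provide).
    """
    t = frame["t"].to_numpy()
    f = frame["f_inst"].to_numpy()
    out: dict[str, PairAnalysis] = {}
    for name in pairs:
        try:
            cx, cy = PAIR_COLUMNS[name]
        except KeyError:
            known = ", ".join(PAIR_COLUMNS)
            raise ValueError(f"unknown pair {name!r}; known pairs: {known}")
        x = frame[cx].to_numpy()
        y = frame[cy].to_numpy()
        if name == "cop-com":
            x = x - frame["platform_x"].to_numpy()
            y = y - frame["platform_x"].to_numpy()
        series = windowed_rpr(x, y, t, f, window_samples, name)
        est = fit_sigmoid(series)
        out[name] = PairAnalysis(series, est)

    stiff: dict[str, QuasiStiffnessResult] = {}
    stiff_trans: dict[str, float | None] = {}
    for joint in stiffness_joints:
        qs = quasi_stiffness_cycles(
            frame[f"tau_{joint}"].to_numpy(),
            frame[f"phi_{joint}"].to_numpy(),
            frame["platform_x"].to_numpy(),
            f,
            t,
            joint=joint,
        )
        stiff[joint] = qs
        try:
            stiff_trans[joint] = sign_transition(qs, persistence)
        except ValueError:
            stiff_trans[joint] = None

    before = after = None
    if "ankle-knee" in out and "knee-hip" in out:
        ak, kh = out["ankle-knee"], out["knee-hip"]
        est = ak.transition
        if est.detected:
            lo = ak.rpr.f_centre < est.frequency
            hi = ak.rpr.f_centre > est.frequency
        else:  # no transition: label the whole sweep
            lo = np.ones(len(ak.rpr), dtype=bool)
            hi = lo
        if lo.any() and hi.any():
            before = label_strategy(_window_phase(ak.rpr, lo), _window_phase(kh.rpr, lo))
            after = label_strategy(_window_phase(ak.rpr, hi), _window_phase(kh.rpr, hi))
    return AnalysisReport(out, stiff, stiff_trans, before, after)
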