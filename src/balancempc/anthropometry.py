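"""Segment anthropometry for the four-segment sagittal body model.

The body is reduced to foot, shank, thigh and HAT (head-arms-trunk) segments.
Left and right limbs are lumped, so "shank" is both shanks acting together,
etc.  Segment masses, lengths, centre-of-mass locations and moments of
inertia are obtained by scaling a published proportion table (Winter-style
fractions of total body mass and height) to a subject's total mass and
height.  The default subject (68.4 kg, 1.68 m) is a healthy young adult.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "SegmentParams",
    "AnthropometricModel",
    "build_anthropometry",
    "PROPORTION_TABLES",
    "DEFAULT_MASS",
    "DEFAULT_HEIGHT",
]

DEFAULT_MASS = 68.4  # kg
DEFAULT_HEIGHT = 1.68  # m

# Per segment: fractions of total mass / total height, COM location as a
# fraction of segment length from the proximal (lower) joint, and radius of
# gyration about the segment COM as a fraction of segment length.
# Segment lengths come from standard joint-height fractions of stature:
# ankle 0.039H, knee 0.285H, hip (greater trochanter) 0.530H, vertex 1.0H.
# The HAT centre of mass sits 0.626 of the trochanter-to-glenohumeral
# distance (0.288H) above the hip, with radius of gyration 0.496 of that
# same distance.  Mass fractions sum to exactly 1.
PROPORTION_TABLES: dict[str, dict[str, dict[str, float]]] = {
    "winter": {
        "foot": {"mass": 0.029, "length": 0.152, "com": 0.500, "gyration": 0.475},
        "shank": {"mass": 0.093, "length": 0.246, "com": 0.567, "gyration": 0.302},
        "thigh": {"mass": 0.200, "length": 0.245, "com": 0.567, "gyration": 0.323},
        "hat": {"mass": 0.678, "length": 0.470, "com": 0.383, "gyration": 0.304},
    },
}

_ANKLE_HEIGHT_FRACTION = 0.039
# The ankle joint projects onto the foot about a quarter of the foot length
# ahead of the heel.
_ANKLE_FROM_HEEL_FRACTION = 0.25


@dataclass(frozen=True)
class SegmentParams:
    """Rigid-segment parameters (SI units).

    ``com_distance`` is measured along the segment from its proximal (lower)
    joint; ``inertia`` is about the segment's own centre of mass.
    """

    mass: float
    length: float
    com_distance: float
    inertia: float

    def __post_init__(self) -> None:
        if not (self.mass > 0 and self.length > 0 and self.inertia > 0):
            raise ValueError("segment mass, length and inertia must be positive")
        if not (0.0 <= self.com_distance <= self.length):
            raise ValueError("segment COM must lie within the segment")


@dataclass(frozen=True)
class AnthropometricModel:
    """Scaled four-segment body model.

    The three articulated links (shank, thigh, HAT) stand on a foot that is
    rigidly attached to the platform.  Foot geometry (ankle height, heel and
    toe extents, foot COM offset) is carried for the centre-of-pressure
    free-body computation.
    """

    foot: SegmentParams
    shank: SegmentParams
    thigh: SegmentParams
    hat: SegmentParams
    total_mass: float
    total_height: float
    gravity: float = 9.81
    ankle_height: float = _ANKLE_HEIGHT_FRACTION * DEFAULT_HEIGHT
    foot_com_forward: float = 0.0  # ankle -> foot COM, anterior positive (m)
    heel_x: float = -0.04  # heel position relative to ankle (m)
    toe_x: float = 0.12  # toe position relative to ankle (m)

    def __post_init__(self) -> None:
        seg_sum = self.foot.mass + self.shank.mass + self.thigh.mass + self.hat.mass
        if abs(seg_sum - self.total_mass) > 1e-9 * self.total_mass:
            raise ValueError(
                f"segment masses sum to {seg_sum!r}, not total_mass={self.total_mass!r}"
            )
        if self.total_height <= 0:
            raise ValueError("total_height must be positive")
        if self.gravity <= 0:
            raise ValueError("gravity must be positive")
        if not (self.heel_x < 0.0 < self.toe_x):
            raise ValueError("ankle must lie between heel and toe")

    @property
    def links(self) -> tuple[SegmentParams, SegmentParams, SegmentParams]:
        """The articulated chain above the ankle: shank, thigh, HAT."""
        return (self.shank, self.thigh, self.hat)

    @cached_property
    def link_arrays(self) -> dict[str, np.ndarray]:
        """Stacked link parameter vectors used by the dynamics kernels.

        ``P`` is the first-moment vector P_i = m_i d_i + L_i * sum(m_k, k>i)
        and ``b`` the configuration-independent inertia-coupling matrix with
        b_ii = m_i d_i^2 + L_i^2 sum(m_k, k>i), b_ij = L_i P_j (i < j).
        """
        m = np.array([s.mass for s in self.links])
        L = np.array([s.length for s in self.links])
        d = np.array([s.com_distance for s in self.links])
        Ic = np.array([s.inertia for s in self.links])
        mass_above = np.array([m[1] + m[2], m[2], 0.0])
        P = m * d + L * mass_above
        b = np.zeros((3, 3))
        for i in range(3):
            b[i, i] = m[i] * d[i] ** 2 + L[i] ** 2 * mass_above[i]
            for j in range(i + 1, 3):
                b[i, j] = b[j, i] = L[i] * P[j]
        return {"m": m, "L": L, "d": d, "Ic": Ic, "P": P, "b": b}


def build_anthropometry(
    total_mass: float = DEFAULT_MASS,
    total_height: float = DEFAULT_HEIGHT,
    table: str = "winter",
    gravity: float = 9.81,
) -> AnthropometricModel:
    """Scale a proportion table to a subject's total mass and height.

    Parameters
    ----------
    total_mass, total_height:
        Subject mass (kg) and stature (m); defaults are the mean of the
        young-adult cohort the model emulates.
    table:
        Name of a registered proportion table (currently ``"winter"``).
    """
    if total_mass <= 0 or total_height <= 0:
        raise ValueError("total_mass and total_height must be positive")
    try:
        fractions = PROPORTION_TABLES[table]
    except KeyError:
        known = ", ".join(sorted(PROPORTION_TABLES))
        raise ValueError(f"unknown proportion table {table!r}; known tables: {known}")

    def seg(name: str) -> SegmentParams:
        f = fractions[name]
        mass = f["mass"] * total_mass
        length = f["length"] * total_height
        return SegmentParams(
            mass=mass,
            length=length,
            com_distance=f["com"] * length,
            inertia=mass * (f["gyration"] * length) ** 2,
        )

    foot = seg("foot")
    ankle_from_heel = _ANKLE_FROM_HEEL_FRACTION * foot.length
    return AnthropometricModel(
        foot=foot,
        shank=seg("shank"),
        thigh=seg("thigh"),
        hat=seg("hat"),
        total_mass=total_mass,
        total_height=total_height,
        gravity=gravity,
        ankle_height=_ANKLE_HEIGHT_FRACTION * total_height,
        foot_com_forward=foot.com_distance - ankle_from_heel,
        heel_x=-ankle_from_heel,
        toe_x=foot.length - ankle_from_heel,
    )
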