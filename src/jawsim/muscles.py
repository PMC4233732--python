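"""Muscle strand mechanics.

Each muscle is discretised into strands: piecewise-straight lines of action
from a cranial origin, through optional via points, to a mandibular
insertion.  A strand is a Hill-type actuator reduced to the three parameters
the recruitment problem needs — maximum force, activation factor, and a
small passive elastic tension — with no force–length or force–velocity
scaling and no activation dynamics.

Frames: every path point is tagged ``cranium`` (fixed) or ``mandible``
(moves with the jaw pose).  Tension is uniform along the path (via points
are frictionless).  Forces are applied to the mandible only at
mandible-tagged points: the insertion receives the tension directed toward
its neighbouring path point, and any mandible-tagged interior point
receives the resultant of the tensions in its two adjacent segments.  This
makes the wrench consistent with the virtual-work identity
d(length)/dq = -(moment arm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InvalidParameterError
from .mandible import transform_points

CRANIUM = "cranium"
MANDIBLE = "mandible"

__all__ = [
    "MuscleStrand",
    "PassiveLaw",
    "strand_path_length",
    "passive_tension",
    "strand_tension",
    "strand_wrench",
]


@dataclass
class MuscleStrand:
    """One discretised line of action of a muscle.

    Parameters
    ----------
    muscle : str
        Name of the muscle part this strand belongs to.
    side : str
        'left' or 'right'.
    points : ndarray, shape (k, 3)
        Path polyline, origin first, insertion last, mm.  Mandible-frame
        points are stored in body-frame (closed-pose) coordinates.
    frames : tuple of str
        Frame tag per point; first must be cranium, last mandible.
    max_force_share : float
        This strand's share of the muscle's maximum force, N.
    rest_length : float
        Path length at the closed midline pose, mm (set automatically).
    """

    muscle: str
    side: str
    points: np.ndarray
    frames: tuple
    max_force_share: float
    rest_length: float = field(default=0.0)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.frames = tuple(self.frames)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise GeometryError("strand path needs at least two 3-D points")
        if len(self.frames) != self.points.shape[0]:
            raise GeometryError("one frame tag per path point required")
        if self.frames[0] != CRANIUM or self.frames[-1] != MANDIBLE:
            raise GeometryError("strand must run cranium origin -> mandible insertion")
        if self.max_force_share <= 0:
            raise InvalidParameterError("max_force_share must be positive")
        if self.rest_length == 0.0:
            self.rest_length = _polyline_length(self.points)
        if self.rest_length <= 0:
            raise GeometryError("strand rest length must be positive")

    def posed_points(self, T: np.ndarray) -> np.ndarray:
        pts = self.points.copy()
        mand = [i for i, f in enumerate(self.frames) if f == MANDIBLE]
        if mand:
            pts[mand] = transform_points(T, pts[mand])
        return pts


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def strand_path_length(strand: MuscleStrand, T: np.ndarray) -> float:
    """Length (mm) of the strand polyline with mandible points posed by T."""
    return _polyline_length(strand.posed_points(T))


@dataclass(frozen=True)
class PassiveLaw:
    """Exponential passive-tension law.

    Passive tension is zero for a slack or rest-length strand, rises
    exponentially with strain, and saturates at ``cap_fraction`` of the
    strand's maximum force (default 0.1%) at ``strain_at_cap``.
    """

    cap_fraction: float = 0.001
    shape: float = 5.0
    strain_at_cap: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.cap_fraction <= 0.01):
            raise InvalidParameterError("cap_fraction must lie in (0, 0.01]")
        if self.shape <= 0 or self.strain_at_cap <= 0:
            raise InvalidParameterError("shape and strain_at_cap must be positive")


def passive_tension(strain: float, max_force: float, law: PassiveLaw | None = None) -> float:
    """Passive elastic tension (N) at a given strand strain.

    strain = (length - rest_length) / rest_length.  Zero at or below rest
    length, exponential in between, capped at cap_fraction * max_force.
    """
    if law is None:
        law = PassiveLaw()
    if strain <= 0.0:
        return 0.0
    cap = law.cap_fraction * max_force
    if strain >= law.strain_at_cap:
        return cap
    # normalised so the exponential hits the cap exactly at strain_at_cap
    denom = np.expm1(law.shape * law.strain_at_cap)
    return float(cap * np.expm1(law.shape * strain) / denom)


def strand_tension(activation: float, max_force_share: float, passive: float = 0.0) -> float:
    """Total strand tension: activation * max force share + passive (N)."""
    if not (0.0 <= activation <= 1.0):
        raise InvalidParameterError(f"activation must lie in [0, 1], got {activation}")
    if max_force_share < 0 or passive < 0:
        raise InvalidParameterError("forces must be non-negative")
    return activation * max_force_share + passive


def strand_wrench(strand: MuscleStrand, T: np.ndarray, tension: float,
                  reference=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Wrench (force N, moment N mm) the strand exerts on the mandible.

    The tension acts along the path toward the cranial origin.  Forces are
    applied at every mandible-tagged point (see module docstring); the
    moment is taken about ``reference``.
    """
    if tension < 0:
        raise InvalidParameterError("tension must be non-negative")
    if tension == 0.0:
        return np.zeros(6)
    pts = strand.posed_points(T)
    ref = np.asarray(reference, float)
    segs = np.diff(pts, axis=0)
    lens = np.linalg.norm(segs, axis=1)
    if np.any(lens < 1e-9):
        raise GeometryError("degenerate zero-length path segment")
    units = segs / lens[:, None]
    wrench = np.zeros(6)
    k = len(pts)
    for i, frame in enumerate(strand.frames):
        if frame != MANDIBLE:
            continue
        # pull toward each cranium/mandible neighbour along the path
        f = np.zeros(3)
        if i > 0:
            f += -units[i - 1]  # toward previous point
        if i < k - 1:
            f += units[i]  # toward next point
        F = tension * f
        r = pts[i] - ref
        wrench[:3] += F
        wrench[3:] += np.cross(r, F)
    return wrench
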