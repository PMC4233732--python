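"""Prescribed jaw kinematics: the three-phase reduction bite cycle.

A reduction cycle (the midpoint of a chewing sequence) has three phases:

opening       the jaw opens to the maximal sagittal gape (default 12 deg)
              under digastric action;
fast closing  the jaw closes until the lower tooth row meets the food
              bolus, while swinging toward the working side in the frontal
              plane (default 4 deg; zero for incisor biting);
slow closing  the power stroke: the bolus is crushed/sheared until it has
              been compressed to half its original height.  Shearing
              returns the frontal angle to the midline, crushing holds the
              lateral rotation, incisor biting stays symmetric.

Angles follow cosine ramps through the phase waypoints (C1-continuous,
matching the smooth in vivo gape traces).  The sagittal angle at bolus
contact and at half-compression are solved from the model geometry, so the
fast/slow phase boundary coincides with first plate contact and the cycle
ends exactly at half-compression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .bolus import FoodBolus
from .errors import ConfigError, SimulationSetupError
from .mandible import JawPose, transform_points

RUN_MODES = ("shearing", "crushing", "incisor", "premolar_crushing")

#: default phase durations (opening, fast closing, slow closing), ms.
#: Only the 140 ms slow close is an empirical datum; the others are
#: literature-consistent free parameters.
DEFAULT_DURATIONS = (90.0, 50.0, 140.0)

__all__ = [
    "MotionProfile",
    "build_profile",
    "gape_angles",
    "incisal_gape_mm",
    "pose_for_incisal_gape",
    "contact_time",
    "bite_separation_mm",
    "RUN_MODES",
    "DEFAULT_DURATIONS",
]


def _ramp(u: float) -> float:
    """Cosine ramp, 0 -> 1 with zero slope at both ends."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


@dataclass(frozen=True)
class MotionProfile:
    """Piecewise-smooth sagittal/frontal gape trajectories for one cycle."""

    mode: str
    durations: tuple = DEFAULT_DURATIONS  # ms
    max_sagittal: float = 12.0  # deg, at the opening/fast-closing boundary
    max_frontal: float = 4.0  # deg toward the working side
    contact_sagittal: float = 0.0  # deg, solved at bolus contact
    end_sagittal: float = 0.0  # deg, solved at half-compression
    bite_site: str = "molar_right"
    working_side: str = "right"
    timestep_ms: float = 1.0

    def __post_init__(self):
        if self.mode not in RUN_MODES:
            raise ConfigError(f"unknown motion mode {self.mode!r}")
        if len(self.durations) != 3 or any(d <= 0 for d in self.durations):
            raise ConfigError("three positive phase durations required")

    # -- phase bookkeeping -------------------------------------------------
    @property
    def t_open_end(self) -> float:
        return self.durations[0]

    @property
    def t_fast_end(self) -> float:
        return self.durations[0] + self.durations[1]

    @property
    def t_total(self) -> float:
        return sum(self.durations)

    def phase_of(self, t: float) -> str:
        if t < self.t_open_end:
            return "opening"
        if t < self.t_fast_end:
            return "fast_closing"
        return "slow_closing"

    @property
    def frontal_peak(self) -> float:
        """Frontal angle at bolus contact (end of fast closing)."""
        return 0.0 if self.mode == "incisor" else self.max_frontal

    @property
    def frontal_end(self) -> float:
        """Frontal angle at the end of the slow closing phase."""
        if self.mode == "shearing" or self.mode == "incisor":
            return 0.0
        return self.max_frontal  # crushing holds the lateral rotation

    def times(self) -> np.ndarray:
        n = int(round(self.t_total / self.timestep_ms))
        return np.linspace(0.0, self.t_total, n + 1)

    def angles_at(self, t: float) -> tuple:
        return gape_angles(self, t)

    def pose_at(self, t: float) -> JawPose:
        sag, fro = gape_angles(self, t)
        return JawPose(sagittal_deg=sag, frontal_deg=fro)


def gape_angles(profile: MotionProfile, t: float) -> tuple:
    """(sagittal, frontal) angles in degrees at time t (ms)."""
    if t < 0 or t > profile.t_total + 1e-9:
        raise ValueError(f"time {t} ms outside the cycle [0, {profile.t_total}]")
    d_open, d_fast, d_slow = profile.durations
    if t <= d_open:
        u = _ramp(t / d_open)
        return profile.max_sagittal * u, 0.0
    if t <= profile.t_fast_end:
        u = _ramp((t - d_open) / d_fast)
        sag = profile.max_sagittal + (profile.contact_sagittal - profile.max_sagittal) * u
        return sag, profile.frontal_peak * u
    u = _ramp((t - profile.t_fast_end) / d_slow)
    sag = profile.contact_sagittal + (profile.end_sagittal - profile.contact_sagittal) * u
    fro = profile.frontal_peak + (profile.frontal_end - profile.frontal_peak) * u
    return sag, fro


# ---------------------------------------------------------------------------
# gape / separation geometry
# ---------------------------------------------------------------------------

def bite_separation_mm(model, pose: JawPose, site: str) -> float:
    """Vertical separation (mm) of the upper and lower tooth points at a site."""
    T = model.pose_transform(pose)
    lower = transform_points(T, model.bite_points[site])
    upper = model.upper_tooth_points[site]
    return float(upper[2] - lower[2])


def incisal_gape_mm(model, pose: JawPose) -> float:
    """Vertical separation of the incisal points under the pose, mm."""
    return bite_separation_mm(model, pose, "incisor")


def pose_for_incisal_gape(model, gape_mm: float, frontal_deg: float = 0.0) -> JawPose:
    """Invert the gape function: the sagittal-rotation pose giving a gape."""
    def f(sag):
        return incisal_gape_mm(model, JawPose(sag, frontal_deg)) - gape_mm

    sag = brentq(f, -5.0, 45.0, xtol=1e-10)
    return JawPose(sagittal_deg=sag, frontal_deg=frontal_deg)


def _contact_angle(model, site: str, separation: float, frontal_deg: float) -> float:
    """Sagittal angle at which the tooth separation equals ``separation``."""
    def f(sag):
        return bite_separation_mm(model, JawPose(sag, frontal_deg), site) - separation

    try:
        return brentq(f, -10.0, 45.0, xtol=1e-10)
    except ValueError as exc:
        raise SimulationSetupError(
            f"no sagittal angle in [-10, 45] deg gives separation {separation} mm "
            f"at {site}") from exc


def build_profile(mode: str, model, bolus: FoodBolus,
                  durations: tuple = DEFAULT_DURATIONS,
                  max_sagittal: float = 12.0, max_frontal: float = 4.0,
                  timestep_ms: float = 1.0) -> MotionProfile:
    """Solve the phase waypoint angles for a mode and assemble the profile.

    The contact angle is where the plate separation equals the bolus height
    (with the frontal angle at its contact value); the end angle is where
    the vertical compression reaches half the bolus height (frontal at its
    end value).
    """
    if mode not in RUN_MODES:
        raise ConfigError(f"unknown motion mode {mode!r}")
    proto = MotionProfile(mode=mode, durations=tuple(durations),
                          max_sagittal=max_sagittal, max_frontal=max_frontal,
                          bite_site=bolus.site, working_side=model.working_side,
                          timestep_ms=timestep_ms)
    contact = _contact_angle(model, bolus.site, bolus.height, proto.frontal_peak)
    if contact > max_sagittal:
        raise SimulationSetupError(
            f"bolus of height {bolus.height} mm at {bolus.site} is not cleared "
            f"by the {max_sagittal} deg maximal gape")
    end = _contact_angle(model, bolus.site, bolus.height / 2.0, proto.frontal_end)
    return MotionProfile(mode=mode, durations=tuple(durations),
                         max_sagittal=max_sagittal, max_frontal=max_frontal,
                         contact_sagittal=contact, end_sagittal=end,
                         bite_site=bolus.site, working_side=model.working_side,
                         timestep_ms=timestep_ms)


def contact_time(profile: MotionProfile, bolus: FoodBolus, model) -> float:
    """First time (ms) after maximal opening at which the inter-plate gap closes.

    The gap is the tooth-point separation minus the bolus height; by
    construction of :func:`build_profile` this coincides with the
    fast/slow-closing phase boundary to within the time resolution.
    """
    ts = profile.times()
    ts = ts[ts >= profile.t_open_end]
    prev_gap = None
    for t in ts:
        gap = bite_separation_mm(model, profile.pose_at(t), bolus.site) - bolus.height
        if gap <= 1e-9:
            if prev_gap is None or prev_gap <= 0:
                return float(t)
            # linear interpolation inside the step for sub-timestep accuracy
            t_prev = t - profile.timestep_ms
            return float(t_prev + profile.timestep_ms * prev_gap / (prev_gap - gap))
        prev_gap = gap
    raise SimulationSetupError(
        f"jaw never contacts the {bolus.height} mm bolus at {bolus.site} "
        "within the cycle")
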