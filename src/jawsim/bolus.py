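"""Two-plate spring food bolus.

The bolus is modelled as two rigid plates joined by a tri-axial linear
spring: the lower plate rides on the mandibular tooth at the bite point,
the upper plate sits against the maxillary tooth.  Each world axis carries
a force proportional to the relative plate displacement along that axis,
saturating at a per-axis cap.  The vertical axis is unilateral (resists
compression only); the shear axes act in both directions.  Past the cap the
force plateaus (plastic plateau) rather than unloading.

Mode defaults
-------------
crushing   height 1.3 mm, vertical cap 100 N (food fully compressed only at
           100 N; a half-height power stroke therefore peaks at 50 N)
shearing   height 1.3 mm, caps (20, 20, 60) N (anteroposterior,
           mediolateral, vertical)
incisor    height 2.4 mm, vertical spring law as molar crushing
rigid      effectively incompressible (< 1 um under 500 N), used for the
           maximum-bite-force simulation

Vertical stiffness is cap / height so the cap is reached exactly at full
compression.  Shear stiffness is cap / travel, where the travel is the
excursion of the lower bite point over the power stroke; callers that know
the motion geometry pass it in, otherwise a conservative default is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InvalidParameterError

MODES = ("shearing", "crushing", "incisor", "rigid")

#: default shear travel (mm) when no motion geometry is supplied
DEFAULT_SHEAR_TRAVEL = 1.0
#: minimum travel used to convert a cap into a finite stiffness
MIN_TRAVEL = 0.05

__all__ = ["FoodBolus", "make_bolus", "bolus_force", "MODES"]


@dataclass(frozen=True)
class FoodBolus:
    """Bolus parameters at one bite point.

    stiffness and caps are ordered (anteroposterior, mediolateral,
    vertical) = world (x, y, z).
    """

    site: str
    height: float  # mm
    stiffness: np.ndarray  # N / mm per axis
    caps: np.ndarray  # N per axis
    mode: str

    def __post_init__(self):
        object.__setattr__(self, "stiffness", np.asarray(self.stiffness, float))
        object.__setattr__(self, "caps", np.asarray(self.caps, float))
        if self.height <= 0:
            raise InvalidParameterError(f"bolus height must be positive, got {self.height}")
        if np.any(self.stiffness < 0) or np.any(self.caps < 0):
            raise InvalidParameterError("stiffness and caps must be non-negative")
        if self.mode not in MODES:
            raise ConfigError(f"unknown bolus mode {self.mode!r}")


def make_bolus(mode: str, site: str | None = None,
               shear_travel: tuple | float | None = None,
               **overrides) -> FoodBolus:
    """Construct a bolus with the defaults for a biting mode.

    Parameters
    ----------
    mode : str
        'shearing', 'crushing', 'incisor' or 'rigid'.
    site : str, optional
        Bite-point key; defaults to the conventional site of the mode
        (molar_right for the molar modes, incisor otherwise).
    shear_travel : float, optional
        Mediolateral excursion (mm) of the lower bite point over the
        frontal return of the power stroke.  Only the shearing mode uses
        it: its mediolateral stiffness is cap / travel, so the 20 N
        resistance is fully developed exactly when the jaw has returned to
        the midline.  All other shear axes (incidental occlusal slip) use
        the same proportional law as the vertical axis, cap / height.
    overrides
        Any FoodBolus field (height, stiffness, caps).
    """
    if mode not in MODES:
        raise ConfigError(f"unknown bolus mode {mode!r}")
    travel = DEFAULT_SHEAR_TRAVEL if shear_travel is None else float(shear_travel)
    travel = max(travel, MIN_TRAVEL)

    if mode == "crushing":
        height, caps = 1.3, np.array([20.0, 20.0, 100.0])
        default_site = "molar_right"
    elif mode == "shearing":
        height, caps = 1.3, np.array([20.0, 20.0, 60.0])
        default_site = "molar_right"
    elif mode == "incisor":
        height, caps = 2.4, np.array([20.0, 20.0, 100.0])
        default_site = "incisor"
    else:  # rigid: stiff enough that 500 N compresses < 1 um
        height, caps = 2.4, np.array([1e9, 1e9, 1e9])
        default_site = "incisor"

    height = overrides.pop("height", height)
    caps = np.asarray(overrides.pop("caps", caps), float)
    if mode == "rigid":
        stiffness = np.full(3, 5.0e8)  # N/mm; 500 N -> 1e-6 mm
    else:
        stiffness = caps / height
        if mode == "shearing":
            stiffness = stiffness.copy()
            stiffness[1] = caps[1] / travel
    stiffness = np.asarray(overrides.pop("stiffness", stiffness), float)
    if overrides:
        raise ConfigError(f"unknown bolus overrides: {sorted(overrides)}")
    return FoodBolus(site=site or default_site, height=height,
                     stiffness=stiffness, caps=caps, mode=mode)


def bolus_force(bolus: FoodBolus, displacement) -> np.ndarray:
    """Force (N) on the *lower* plate for a relative plate displacement.

    ``displacement`` is (lower plate - its reference position) in world
    axes, mm; the vertical component is positive when the plates approach
    (compression).  Per axis the force is min(k*|d|, cap) directed against
    the displacement; the vertical axis resists compression only.  The
    upper plate sees the equal and opposite force.
    """
    d = np.asarray(displacement, float)
    f = np.zeros(3)
    for ax in range(2):  # shear axes, bidirectional
        mag = min(bolus.stiffness[ax] * abs(d[ax]), bolus.caps[ax])
        f[ax] = -np.sign(d[ax]) * mag
    comp = d[2]  # compression depth, mm
    if comp > 0:
        f[2] = -min(bolus.stiffness[2] * comp, bolus.caps[2])
    return f
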