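"""Musculoskeletal model construction for the rabbit masticatory system.

Builds the complete model — muscle architecture plus strand geometry — from
a published-architecture table (per-muscle mass, fibre length, PCSA and
maximum force) and either a synthetic, bilaterally mirrored rabbit-scale
landmark set or an attachment-coordinate CSV.

The synthetic geometry emulates the structural features the analysis relies
on: condyles spanning a transverse hinge axis, tooth bite points along the
jaw, and per-muscle origin/insertion attachment bars whose fanned strands
reproduce the qualitative lines of action of the jaw adductors (vertical
temporalis strands on the coronoid and descending ramus, a masseter sling
from the zygomatic arch to the angular process, medially directed pterygoid
pull, and a digastric jaw opener).  Its dimensional defaults are calibration
parameters of the package, not measured anatomy.

Coordinate convention: right-handed, origin at the midpoint between the
condyles, +x anterior, +y toward the animal's left, +z dorsal; mm.  The
working side is the right side.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError, SchemaError
from .mandible import MandibleBody, pose_transform
from .muscles import CRANIUM, MANDIBLE, MuscleStrand

REFERENCE_MUSCLE_STRESS = 25.0  # N cm^-2, the stress at which the shipped forces hold
TISSUE_DENSITY = 1.05  # g cm^-3

#: jaw-closer muscle parts, working nomenclature
CLOSER_PARTS = (
    "superficial_masseter",          # superficial + anterior deep masseter, grouped
    "posterior_deep_masseter",
    "anterior_zygomaticomandibularis",
    "posterior_zygomaticomandibularis",
    "superficial_temporalis",
    "deep_temporalis",
    "medial_pterygoid",
    "lateral_pterygoid",
)
OPENER_PARTS = ("digastric",)
ALL_PARTS = CLOSER_PARTS + OPENER_PARTS

#: maximum forces (N) per muscle part at the reference muscle stress.
#: The whole-temporalis 37.1 N is split into a superficial part of 6.2 N and
#: a deep part carrying the remaining 30.9 N.
PART_MAX_FORCE = {
    "superficial_masseter": 60.9,
    "posterior_deep_masseter": 10.3,
    "anterior_zygomaticomandibularis": 15.0,
    "posterior_zygomaticomandibularis": 10.5,
    "superficial_temporalis": 6.2,
    "deep_temporalis": 30.9,
    "medial_pterygoid": 62.3,
    "lateral_pterygoid": 9.8,
}

BITE_SITES = ("incisor", "premolar_right", "molar_right", "molar_left", "premolar_left")

__all__ = [
    "MuscleArchitecture",
    "MusculoskeletalModel",
    "ModelConfig",
    "compute_pcsa",
    "max_muscle_force",
    "allocate_strands",
    "build_model",
    "load_architecture_table",
    "load_attachments",
    "write_attachments",
    "synthetic_attachment_bars",
]


def compute_pcsa(mass: float, fibre_length: float, pennation_deg: float = 0.0,
                 density: float = TISSUE_DENSITY) -> float:
    """Physiological cross-sectional area, cm^2.

    PCSA = mass * cos(pennation) / (density * fibre_length), with mass in g,
    fibre length in cm and density in g cm^-3.
    """
    if fibre_length <= 0 or density <= 0:
        raise InvalidParameterError("fibre length and density must be positive")
    if mass < 0 or pennation_deg < 0:
        raise InvalidParameterError("mass and pennation must be non-negative")
    return mass * np.cos(np.deg2rad(pennation_deg)) / (density * fibre_length)


def max_muscle_force(pcsa: float, muscle_stress: float = REFERENCE_MUSCLE_STRESS) -> float:
    """Maximum isometric force, N: PCSA (cm^2) times muscle stress (N cm^-2)."""
    if pcsa < 0:
        raise InvalidParameterError(f"pcsa must be non-negative, got {pcsa}")
    if muscle_stress <= 0:
        raise InvalidParameterError("muscle stress must be positive")
    return pcsa * muscle_stress


@dataclass(frozen=True)
class MuscleArchitecture:
    """Architecture record of one muscle part on one side."""

    name: str
    side: str
    mass: float  # g (nan where not measured)
    fibre_length: float  # cm (nan where not measured)
    pcsa: float  # cm^2 (nan where not measured)
    max_force: float  # N
    n_strands: int

    def __post_init__(self):
        if self.name not in ALL_PARTS:
            raise SchemaError(f"unknown muscle part {self.name!r}")
        if self.side not in ("left", "right"):
            raise SchemaError(f"side must be left or right, got {self.side!r}")
        if self.max_force < 0 or (not np.isnan(self.pcsa) and self.pcsa < 0):
            raise InvalidParameterError("max_force and pcsa must be non-negative")
        if self.n_strands < 1:
            raise InvalidParameterError("n_strands must be at least 1")


def load_architecture_table(path=None) -> pd.DataFrame:
    """Load the jaw-closer architecture table (packaged fixture by default).

    Columns: muscle, mass_g, fibre_length_cm, pcsa_cm2, max_force_n; one row
    per muscle (temporalis as a whole, split downstream into superficial and
    deep parts).
    """
    if path is None:
        ref = importlib.resources.files("jawsim.data") / "jaw_closer_architecture.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"muscle", "mass_g", "fibre_length_cm", "pcsa_cm2", "max_force_n"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"architecture table missing columns: {sorted(missing)}")
    return df


def allocate_strands(forces: dict, total: int = 75, min_per_muscle: int = 3,
                     remainder_to: str = "superficial_masseter") -> dict:
    """Allocate a per-side strand budget across muscle parts.

    Proportional to maximum force with a floor of ``min_per_muscle`` strands
    per part; any remainder (positive or negative) is absorbed by
    ``remainder_to``.
    """
    if total < min_per_muscle * len(forces):
        raise ConfigError(
            f"strand budget {total} cannot give {min_per_muscle} strands to "
            f"{len(forces)} muscle parts"
        )
    fsum = sum(forces.values())
    alloc = {
        name: max(min_per_muscle, int(np.floor(total * f / fsum)))
        for name, f in forces.items()
    }
    alloc[remainder_to] += total - sum(alloc.values())
    if alloc[remainder_to] < min_per_muscle:
        raise ConfigError("remainder muscle fell below the minimum strand count")
    return alloc


# ---------------------------------------------------------------------------
# synthetic geometry
# ---------------------------------------------------------------------------

# Right-side attachment bars at the reference jaw length (55 mm condyle to
# incisor).  Each entry: role -> ((x, y, z), (x, y, z)) endpoints of a bar
# along which strands are fanned; 'via_frame' tags the via bar's frame.
# These coordinates are rabbit-scale calibration defaults (see docs).
_RIGHT_BARS = {
    "superficial_masseter": {
        "origin": ((16.0, -11.0, 2.0), (27.0, -11.0, 2.0)),
        "insertion": ((5.0, -9.5, -8.0), (17.0, -9.5, -8.0)),
    },
    "posterior_deep_masseter": {
        "origin": ((8.0, -10.5, 2.0), (13.0, -10.5, 2.0)),
        "insertion": ((5.0, -9.0, -9.0), (11.0, -9.0, -9.0)),
    },
    "anterior_zygomaticomandibularis": {
        "origin": ((18.0, -9.5, 2.0), (23.0, -9.5, 2.0)),
        "insertion": ((13.0, -8.5, -6.0), (18.0, -8.5, -6.0)),
    },
    "posterior_zygomaticomandibularis": {
        "origin": ((9.0, -9.5, 2.0), (14.0, -9.5, 2.0)),
        "insertion": ((9.0, -8.5, -7.0), (14.0, -8.5, -7.0)),
    },
    "superficial_temporalis": {
        "origin": ((1.0, -6.0, 11.0), (7.0, -6.0, 11.0)),
        "via": ((4.0, -7.5, 4.0), (8.0, -7.5, 4.0)),
        "via_frame": CRANIUM,
        "insertion": ((4.0, -7.0, -6.0), (8.0, -7.0, -6.0)),
    },
    "deep_temporalis": {
        "origin": ((-1.0, -5.0, 9.0), (6.0, -5.0, 9.0)),
        "insertion": ((10.0, -6.0, 1.0), (13.0, -6.0, 3.0)),
    },
    "medial_pterygoid": {
        "origin": ((14.0, -3.0, 0.0), (19.0, -3.0, 0.0)),
        "via": ((11.0, -4.5, -6.0), (15.0, -4.5, -6.0)),
        "via_frame": CRANIUM,
        "insertion": ((8.0, -8.0, -9.5), (15.0, -8.0, -9.5)),
    },
    "lateral_pterygoid": {
        "origin": ((12.0, -3.5, -1.0), (15.0, -3.5, -1.0)),
        "insertion": ((1.0, -8.0, -3.0), (4.0, -8.0, -3.0)),
    },
    "digastric": {
        "origin": ((-5.0, -5.0, -7.0), (-2.0, -5.0, -7.0)),
        "insertion": ((42.0, -4.0, -12.0), (47.0, -4.0, -12.0)),
    },
}

_REFERENCE_JAW_LENGTH = 55.0

_BITE_POINTS = {
    "incisor": (55.0, 0.0, -14.0),
    "molar_right": (20.0, -5.0, -8.0),
    "premolar_right": (28.0, -5.5, -9.0),
}

_CONDYLE_HALF_SPAN = 9.0


def _mirror(p):
    return (p[0], -p[1], p[2])


def synthetic_attachment_bars(jaw_length: float = _REFERENCE_JAW_LENGTH) -> dict:
    """Attachment bars for both sides, scaled isotropically to jaw_length."""
    s = jaw_length / _REFERENCE_JAW_LENGTH
    bars = {}
    for name, spec in _RIGHT_BARS.items():
        for side in ("right", "left"):
            entry = {}
            for role in ("origin", "via", "insertion"):
                if role not in spec:
                    continue
                a, b = spec[role]
                if side == "left":
                    a, b = _mirror(a), _mirror(b)
                entry[role] = (tuple(s * v for v in a), tuple(s * v for v in b))
            if "via" in spec:
                entry["via_frame"] = spec["via_frame"]
            bars[(name, side)] = entry
    return bars


@dataclass(frozen=True)
class ModelConfig:
    """Configuration for :func:`build_model`.

    muscle_stress rescales all maximum forces relative to the reference
    stress at which the shipped architecture forces hold.  jitter_mm adds
    seeded Gaussian noise to synthetic attachment coordinates (breaking
    exact bilateral symmetry on purpose); with jitter_mm = 0 the model is
    exactly mirrored.
    """

    muscle_stress: float = REFERENCE_MUSCLE_STRESS
    jaw_length: float = _REFERENCE_JAW_LENGTH
    strands_per_side: int = 75
    strand_allocation: dict | None = None  # muscle part -> count, per side
    geometry_source: str | None = None  # None/'synthetic' or a CSV path
    symmetric: bool = True
    digastric_max_force: float = 10.0
    fossa_tilt_deg: float = 25.0
    jitter_mm: float = 0.0
    seed: int | None = None
    mandible: MandibleBody | None = None
    working_side: str = "right"


@dataclass
class MusculoskeletalModel:
    """The assembled rigid-jaw plus muscle-strand model."""

    architecture: list
    strands: list
    condyle_left: np.ndarray
    condyle_right: np.ndarray
    fossa_normal_left: np.ndarray
    fossa_normal_right: np.ndarray
    bite_points: dict
    upper_tooth_points: dict
    mandible: MandibleBody
    working_side: str = "right"
    config: ModelConfig = field(default_factory=ModelConfig)

    def pose_transform(self, pose) -> np.ndarray:
        return pose_transform(pose, self.condyle_left, self.condyle_right,
                              self.working_side)

    @property
    def closer_strands(self):
        return [s for s in self.strands if s.muscle in CLOSER_PARTS]

    def strands_of(self, muscle: str, side: str | None = None):
        return [s for s in self.strands
                if s.muscle == muscle and (side is None or s.side == side)]

    def muscle_max_force(self, muscle: str, side: str) -> float:
        return sum(s.max_force_share for s in self.strands_of(muscle, side))

    @property
    def total_closer_force(self) -> float:
        """Sum of closer maximum forces over both sides, N."""
        return sum(s.max_force_share for s in self.closer_strands)


def _fan_bar(bar, t):
    a = np.asarray(bar[0], float)
    b = np.asarray(bar[1], float)
    return a + t * (b - a)


def _build_strands_from_bars(bars, allocation, part_forces, jitter_mm, rng):
    strands = []
    for name in ALL_PARTS:
        n = allocation[name]
        for side in ("right", "left"):
            entry = bars[(name, side)]
            share = part_forces[name] / n
            for i in range(n):
                t = (i + 0.5) / n
                pts = [_fan_bar(entry["origin"], t)]
                frames = [CRANIUM]
                if "via" in entry:
                    pts.append(_fan_bar(entry["via"], t))
                    frames.append(entry["via_frame"])
                pts.append(_fan_bar(entry["insertion"], t))
                frames.append(MANDIBLE)
                pts = np.array(pts)
                if jitter_mm > 0:
                    pts = pts + rng.normal(0.0, jitter_mm, size=pts.shape)
                strands.append(MuscleStrand(muscle=name, side=side, points=pts,
                                            frames=tuple(frames),
                                            max_force_share=share))
    return strands


def _architecture_records(allocation, part_forces, stress_scale):
    table = load_architecture_table().set_index("muscle")
    # provenance metadata per part; the temporalis split shares the printed row
    meta = {
        "superficial_masseter": "superficial masseter",
        "posterior_deep_masseter": "posterior deep masseter",
        "anterior_zygomaticomandibularis": "ant. zygomaticomandibularis",
        "posterior_zygomaticomandibularis": "post. zygomaticomandibularis",
        "superficial_temporalis": "temporalis",
        "deep_temporalis": "temporalis",
        "medial_pterygoid": "medial pterygoid",
        "lateral_pterygoid": "lateral pterygoid",
    }
    records = []
    for name in ALL_PARTS:
        if name in meta:
            row = table.loc[meta[name]]
            mass, flen, pcsa = row["mass_g"], row["fibre_length_cm"], row["pcsa_cm2"]
        else:  # digastric: architecture not tabulated
            mass = flen = pcsa = float("nan")
        for side in ("left", "right"):
            records.append(MuscleArchitecture(
                name=name, side=side, mass=float(mass), fibre_length=float(flen),
                pcsa=float(pcsa), max_force=part_forces[name],
                n_strands=allocation[name]))
    return records


def build_model(config: ModelConfig | None = None) -> MusculoskeletalModel:
    """Build the full musculoskeletal model from a configuration.

    With the default configuration this yields 150 strands (75 per side)
    whose per-muscle summed force shares equal the shipped architecture
    forces, on an exactly mirrored synthetic landmark set.
    """
    if config is None:
        config = ModelConfig()
    stress_scale = config.muscle_stress / REFERENCE_MUSCLE_STRESS
    if config.muscle_stress <= 0:
        raise ConfigError("muscle_stress must be positive")

    part_forces = {n: f * stress_scale for n, f in PART_MAX_FORCE.items()}
    part_forces["digastric"] = config.digastric_max_force * stress_scale

    if config.strand_allocation is not None:
        allocation = dict(config.strand_allocation)
        missing = set(ALL_PARTS) - set(allocation)
        if missing:
            raise ConfigError(f"strand allocation missing muscle parts: {sorted(missing)}")
        if sum(allocation.values()) != config.strands_per_side:
            raise ConfigError(
                f"strand allocation sums to {sum(allocation.values())}, "
                f"expected {config.strands_per_side} per side")
    else:
        allocation = allocate_strands(part_forces, total=config.strands_per_side)

    rng = np.random.default_rng(config.seed)
    jitter = 0.0 if config.symmetric else config.jitter_mm

    source = config.geometry_source
    if source in (None, "synthetic"):
        bars = synthetic_attachment_bars(config.jaw_length)
        strands = _build_strands_from_bars(bars, allocation, part_forces, jitter, rng)
    else:
        paths = load_attachments(source)
        strands = _strands_from_attachments(paths, allocation, part_forces)

    scale = config.jaw_length / _REFERENCE_JAW_LENGTH
    d = _CONDYLE_HALF_SPAN * scale
    tilt = np.deg2rad(config.fossa_tilt_deg)
    normal = np.array([-np.sin(tilt), 0.0, -np.cos(tilt)])

    bite_points = {}
    for site, p in _BITE_POINTS.items():
        bite_points[site] = scale * np.asarray(p, float)
    bite_points["molar_left"] = bite_points["molar_right"] * np.array([1, -1, 1])
    bite_points["premolar_left"] = bite_points["premolar_right"] * np.array([1, -1, 1])
    upper = {k: v.copy() for k, v in bite_points.items()}  # occlusal contact at closure

    mandible = config.mandible
    if mandible is None:
        mandible = MandibleBody.ellipsoid(
            half_axes=(26.0 * scale, 9.0 * scale, 7.0 * scale),
            com=(22.0 * scale, 0.0, -6.0 * scale))

    return MusculoskeletalModel(
        architecture=_architecture_records(allocation, part_forces, stress_scale),
        strands=strands,
        condyle_left=np.array([0.0, d, 0.0]),
        condyle_right=np.array([0.0, -d, 0.0]),
        fossa_normal_left=normal.copy(),
        fossa_normal_right=normal.copy(),
        bite_points=bite_points,
        upper_tooth_points=upper,
        mandible=mandible,
        working_side=config.working_side,
        config=config,
    )


# ---------------------------------------------------------------------------
# attachment-coordinate CSV dialect
# ---------------------------------------------------------------------------

_ATTACH_COLS = ["muscle", "side", "strand", "role", "frame", "x", "y", "z", "ordinal"]
_ROLES = {"origin", "via", "insertion"}
_FRAMES = {CRANIUM, MANDIBLE}


def write_attachments(model: MusculoskeletalModel, path) -> None:
    """Write every strand's polyline to the attachment CSV dialect."""
    rows = []
    counters = {}
    for s in model.strands:
        key = (s.muscle, s.side)
        idx = counters.get(key, 0)
        counters[key] = idx + 1
        k = len(s.frames)
        for j, (p, f) in enumerate(zip(s.points, s.frames)):
            role = "origin" if j == 0 else ("insertion" if j == k - 1 else "via")
            rows.append((s.muscle, s.side, idx, role, f, p[0], p[1], p[2], j))
    pd.DataFrame(rows, columns=_ATTACH_COLS).to_csv(path, index=False)


def load_attachments(path) -> dict:
    """Load an attachment CSV into ordered polylines per strand.

    Returns a dict (muscle, side, strand index) -> (points array, frame
    tuple), points in ordinal order.  Round-trips losslessly through
    :func:`write_attachments`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_ATTACH_COLS) - set(df.columns)
    if missing:
        raise SchemaError(f"attachment file missing columns: {sorted(missing)}")
    for i, row in df.iterrows():
        if row["muscle"] not in ALL_PARTS:
            raise SchemaError(f"row {i}: unknown muscle name {row['muscle']!r}")
        if row["role"] not in _ROLES:
            raise SchemaError(f"row {i}: unknown role {row['role']!r}")
        if row["frame"] not in _FRAMES:
            raise SchemaError(f"row {i}: unknown frame {row['frame']!r}")
        for c in ("x", "y", "z"):
            if not np.isfinite(row[c]):
                raise SchemaError(f"row {i}: non-numeric coordinate in column {c!r}")
    paths = {}
    for (muscle, side, idx), grp in df.groupby(["muscle", "side", "strand"], sort=True):
        grp = grp.sort_values("ordinal")
        pts = grp[["x", "y", "z"]].to_numpy(float)
        frames = tuple(grp["frame"])
        paths[(muscle, side, int(idx))] = (pts, frames)
    return paths


def _strands_from_attachments(paths, allocation, part_forces):
    seen = {}
    for (muscle, side, _idx) in paths:
        seen.setdefault(muscle, set()).add(side)
    missing = [m for m in ALL_PARTS
               if m not in seen or seen[m] != {"left", "right"}]
    if missing:
        raise SchemaError(f"attachment file missing muscles (both sides required): {missing}")
    counts = {}
    for (muscle, side, _idx) in paths:
        counts[(muscle, side)] = counts.get((muscle, side), 0) + 1
    strands = []
    for (muscle, side, idx) in sorted(paths):
        pts, frames = paths[(muscle, side, idx)]
        share = part_forces[muscle] / counts[(muscle, side)]
        strands.append(MuscleStrand(muscle=muscle, side=side, points=pts,
                                    frames=frames, max_force_share=share))
    return strands
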