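"""Rigid mandible: inertial properties, pose kinematics, TMJ admissibility,
and the six-degree-of-freedom force/moment balance.

Conventions
-----------
Right-handed world frame with origin at the midpoint between the two
mandibular condyles, +x anterior, +y toward the animal's left, +z dorsal.
Lengths in mm, forces in N, moments in N mm, masses in g.  The closed,
midline jaw pose is the identity transform, so body-frame coordinates of
mandibular landmarks coincide with their world positions at closure.

The jaw pose is parameterised the way cineradiographic chewing data are
reported: a sagittal (lateral-view) gape angle about the transverse axis
through both condyles, a frontal-view rotation toward the working side
about the anteroposterior axis through the *balancing* condyle (so the
balancing condyle stays essentially stationary while the working condyle
translates), and an optional anteroposterior condylar translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InvalidParameterError

GRAVITY_MS2 = 9.81  # standard gravity, m s^-2

__all__ = [
    "MandibleBody",
    "JawPose",
    "inertia_from_mesh",
    "pose_transform",
    "transform_points",
    "admissible_joint_reaction",
    "gravity_wrench",
    "equilibrium_residual",
]


@dataclass(frozen=True)
class MandibleBody:
    """Mass properties of the mandible as a single rigid body.

    Parameters
    ----------
    mass : float
        Mass in g.
    com : ndarray, shape (3,)
        Centre of mass, mm, body frame.
    inertia : ndarray, shape (3, 3)
        Inertia tensor about the centre of mass, g mm^2, body frame.
    """

    mass: float
    com: np.ndarray
    inertia: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "com", np.asarray(self.com, dtype=float))
        object.__setattr__(self, "inertia", np.asarray(self.inertia, dtype=float))
        if self.mass <= 0:
            raise InvalidParameterError(f"mandible mass must be positive, got {self.mass}")
        I = self.inertia
        if I.shape != (3, 3) or not np.allclose(I, I.T, atol=1e-9 * max(1.0, abs(I).max())):
            raise InvalidParameterError("inertia tensor must be symmetric 3x3")
        w = np.linalg.eigvalsh(I)
        if w[0] <= 0:
            raise InvalidParameterError("inertia tensor must be positive definite")
        # principal moments of any real mass distribution satisfy the
        # triangle inequalities Ia + Ib >= Ic
        if w[0] + w[1] < w[2] * (1 - 1e-9):
            raise InvalidParameterError("principal moments violate the triangle inequality")

    @classmethod
    def ellipsoid(cls, half_axes=(26.0, 9.0, 7.0), com=(22.0, 0.0, -6.0),
                  density: float = 1.05) -> "MandibleBody":
        """Solid-ellipsoid approximation of the mandible.

        ``density`` is in g cm^-3; half axes and centre in mm.  Used when no
        surface mesh is available.
        """
        a, b, c = (float(v) for v in half_axes)
        volume_mm3 = 4.0 / 3.0 * np.pi * a * b * c
        mass = volume_mm3 * density / 1000.0
        inertia = mass / 5.0 * np.diag([b * b + c * c, a * a + c * c, a * a + b * b])
        return cls(mass=mass, com=np.asarray(com, float), inertia=inertia)


def inertia_from_mesh(mesh, density: float = 1.05):
    """Mass, centre of mass and inertia tensor of a watertight surface mesh.

    Parameters
    ----------
    mesh : trimesh.Trimesh
        Watertight mesh with consistent outward normals, units mm.
    density : float
        Tissue density in g cm^-3 (default 1.05).

    Returns
    -------
    (mass, com, inertia) : (float g, ndarray mm, ndarray g mm^2)
        Inertia is about the centre of mass in the mesh frame.
    """
    if density <= 0:
        raise InvalidParameterError(f"density must be positive, got {density}")
    if not mesh.is_watertight:
        raise GeometryError("mesh is not watertight; volume integrals are undefined")
    mesh = mesh.copy()
    mesh.density = density / 1000.0  # g cm^-3 -> g mm^-3
    com = np.asarray(mesh.center_mass, dtype=float)
    # trimesh reports moment_inertia about the centre of mass
    return float(mesh.mass), com, np.asarray(mesh.moment_inertia, dtype=float)


@dataclass(frozen=True)
class JawPose:
    """Mandible pose along the chewing stroke.

    sagittal_deg
        Lateral-view gape angle; positive opens the jaw (incisor drops).
    frontal_deg
        Frontal-view rotation, positive toward the working side.
    condylar_translation
        Anteroposterior translation (mm) of the (left, right) condyle.
        Unequal values yield a yaw about the vertical axis.
    velocity, acceleration
        Optional generalized 6-vectors (vx, vy, vz, wx, wy, wz) in mm/s and
        rad/s about the world origin; used only by the dynamic residual.
    """

    sagittal_deg: float = 0.0
    frontal_deg: float = 0.0
    condylar_translation: tuple = (0.0, 0.0)
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(6))
    acceleration: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def is_identity(self) -> bool:
        return (
            self.sagittal_deg == 0.0
            and self.frontal_deg == 0.0
            and self.condylar_translation[0] == 0.0
            and self.condylar_translation[1] == 0.0
        )


def _rot_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    ux, uy, uz = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    K = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(axis, axis)


def _homog(R: np.ndarray, t: np.ndarray) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = t
    return T


def _rot_about_point(axis: np.ndarray, angle_rad: float, point: np.ndarray) -> np.ndarray:
    R = _rot_axis(np.asarray(axis, float), angle_rad)
    p = np.asarray(point, float)
    return _homog(R, p - R @ p)


def pose_transform(pose: JawPose, condyle_left, condyle_right,
                   working_side: str = "right") -> np.ndarray:
    """4x4 rigid transform mapping body-frame (closed-pose) points to world.

    Composition: sagittal rotation about the transverse axis through the two
    condyles, then frontal rotation about the anteroposterior axis through
    the balancing-side condyle, then the condylar translation.  The frontal
    axis placement keeps the balancing condyle essentially stationary while
    the working condyle displaces, matching the cineradiographic description
    of the rabbit power stroke.
    """
    cl = np.asarray(condyle_left, float)
    cr = np.asarray(condyle_right, float)
    mid = 0.5 * (cl + cr)
    trans_axis = cr - cl
    n = np.linalg.norm(trans_axis)
    if n < 1e-12:
        raise GeometryError("condyles are coincident; transverse axis undefined")
    trans_axis = trans_axis / n
    # body y-axis points left; +sagittal about -(cr-cl)/|..| == +y drops the incisor
    sag = _rot_about_point(-trans_axis, np.deg2rad(pose.sagittal_deg), mid)

    balancing = cl if working_side == "right" else cr
    # positive frontal angle swings the chin toward the working side
    sign = -1.0 if working_side == "right" else 1.0
    frontal = _rot_about_point(np.array([1.0, 0.0, 0.0]),
                               sign * np.deg2rad(pose.frontal_deg), balancing)

    tl, tr = pose.condylar_translation
    mean_t = 0.5 * (tl + tr)
    half_span = 0.5 * n
    yaw = (tr - tl) / (2.0 * half_span)  # small-angle yaw about +z through mid
    yawT = _rot_about_point(np.array([0.0, 0.0, 1.0]), yaw, mid)
    shift = _homog(np.eye(3), np.array([mean_t, 0.0, 0.0]))

    return shift @ yawT @ frontal @ sag


def transform_points(T: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Apply a 4x4 transform to an (n, 3) or (3,) array of points."""
    pts = np.asarray(pts, float)
    single = pts.ndim == 1
    P = np.atleast_2d(pts)
    out = P @ T[:3, :3].T + T[:3, 3]
    return out[0] if single else out


def admissible_joint_reaction(candidate, fossa_normal, mu: float = 0.0):
    """Test/project a candidate TMJ reaction against the unilateral contact law.

    The reaction on the mandible must have a non-negative component along the
    fossa normal (compression only) and a tangential part bounded by
    ``mu`` times the normal component.  Projection clamps the normal at zero
    and rescales the tangential part onto the friction bound, keeping the
    normal magnitude fixed.

    Returns
    -------
    (admissible, projected) : (bool, ndarray shape (3,))
    """
    c = np.asarray(candidate, float)
    n = np.asarray(fossa_normal, float)
    n = n / np.linalg.norm(n)
    lam = float(c @ n)
    tang = c - lam * n
    tnorm = np.linalg.norm(tang)
    ok = lam >= -1e-12 and tnorm <= mu * max(lam, 0.0) + 1e-12
    lam_p = max(lam, 0.0)
    bound = mu * lam_p
    if tnorm > bound:
        tang = tang * (bound / tnorm) if tnorm > 0 else tang
    return ok, lam_p * n + tang


def wrench_at(point, force, reference=(0.0, 0.0, 0.0)) -> np.ndarray:
    """6-vector (F, M) of a point force about a reference point (N, N mm)."""
    r = np.asarray(point, float) - np.asarray(reference, float)
    F = np.asarray(force, float)
    return np.concatenate([F, np.cross(r, F)])


def gravity_wrench(body: MandibleBody, T: np.ndarray,
                   reference=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Weight of the mandible acting at its (posed) centre of mass."""
    com_w = transform_points(T, body.com)
    weight = np.array([0.0, 0.0, -body.mass * 1e-3 * GRAVITY_MS2])  # N
    return wrench_at(com_w, weight, reference)


def inertial_wrench(body: MandibleBody, pose: JawPose, T: np.ndarray,
                    reference=(0.0, 0.0, 0.0)) -> np.ndarray:
    """M qdd plus gyroscopic terms, expressed about the reference point.

    Velocities/accelerations are taken from the pose's generalized 6-vectors
    (linear about the reference point, angular of the body).  Zero vectors
    give a zero wrench, so the quasi-static and dynamic residuals agree at
    rest.
    """
    v, a = np.asarray(pose.velocity, float), np.asarray(pose.acceleration, float)
    if not (v.any() or a.any()):
        return np.zeros(6)
    R = T[:3, :3]
    Iw = R @ body.inertia @ R.T  # g mm^2, world axes
    com_w = transform_points(T, body.com)
    r = com_w - np.asarray(reference, float)
    omega, alpha = v[3:], a[3:]
    a_com = a[:3] + np.cross(alpha, r) + np.cross(omega, np.cross(omega, r))
    F = body.mass * 1e-3 * a_com * 1e-3  # g*mm/s^2 -> N (kg m / s^2)
    M_com = (Iw @ alpha + np.cross(omega, Iw @ omega)) * 1e-6  # g mm^2/s^2 -> N mm
    M = M_com + np.cross(r, F)
    return np.concatenate([F, M])


def equilibrium_residual(strand_wrenches, joint_wrenches, bolus_wrench,
                         body: MandibleBody | None, T: np.ndarray,
                         pose: JawPose | None = None,
                         gravity_on: bool = True,
                         dynamic: bool = False,
                         reference=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Assemble the 6-DOF force/moment residual about the reference point.

    residual = sum(strand wrenches) + sum(joint wrenches) + bolus wrench
               + gravity wrench - inertial wrench

    A consistent static (or dynamic) state has residual zero.  All wrenches
    must already be expressed about the same reference point.
    """
    res = np.zeros(6)
    for w in strand_wrenches:
        res = res + np.asarray(w, float)
    for w in joint_wrenches:
        res = res + np.asarray(w, float)
    if bolus_wrench is not None:
        res = res + np.asarray(bolus_wrench, float)
    if gravity_on and body is not None:
        res = res + gravity_wrench(body, T, reference)
    if dynamic and body is not None and pose is not None:
        res = res - inertial_wrench(body, pose, T, reference)
    return res
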