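"""Minimum-effort muscle recruitment along a prescribed jaw motion.

At each timestep the mandible pose (hence every strand's line of action and
the bolus force) is known; the unknowns are the strand activations and the
temporomandibular joint reactions.  The solver finds the bounded
minimum-effort recruitment

    minimize    sum_i a_i^2
    subject to  sum_i a_i * W_i + sum_c lambda_c * N_c + w_const = 0
                0 <= a_i <= 1,   a_i = 0 outside the phase's allowed set
                lambda_c >= 0    (compressive, frictionless TMJ normals)
                tied mirrored pairs equal (symmetric incisor biting)

where W_i is strand i's wrench per unit activation, N_c the unit-reaction
wrench of condyle c, and w_const collects passive tension, gravity and the
bolus load.  This is a convex bounded QP; it is solved as a weighted
stacked least-squares problem (penalty weight 1e6 on the six equilibrium
rows) followed by an active-set polish that re-solves the free variables
against the exact equilibrium constraint, driving the residual to machine
precision.  If the equilibrium is unreachable within the bounds the solver
returns the least-residual recruitment and flags the step infeasible.

Muscle groups
-------------
Chewing recruits the closers in two functional groups.  Group 1 (molar
occlusion) is the working-side posterior deep masseter, both
zygomaticomandibularis parts and both temporalis parts, plus the
balancing-side superficial masseter and both pterygoids; group 2 is the
mirror set, recruited from slow-closing onset to drive/stabilise the power
stroke.  Opening is performed by the digastrics alone; incisor biting
recruits all closers bilaterally with mirrored pairs tied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .anatomy import CLOSER_PARTS, MusculoskeletalModel
from .errors import ConfigError
from .mandible import JawPose, gravity_wrench, transform_points, wrench_at
from .motion import MotionProfile, bite_separation_mm
from .muscles import PassiveLaw, passive_tension, strand_path_length, strand_wrench
from .bolus import FoodBolus, bolus_force

#: group-1 muscle parts on the working side; the balancing side carries the
#: complementary protractor set.  Group 2 is the exact mirror.
_GROUP1_WORKING = (
    "posterior_deep_masseter",
    "anterior_zygomaticomandibularis",
    "posterior_zygomaticomandibularis",
    "superficial_temporalis",
    "deep_temporalis",
)
_GROUP1_BALANCING = ("superficial_masseter", "medial_pterygoid", "lateral_pterygoid")

FORCE_TOL = 1e-6  # N
MOMENT_TOL = 1e-4  # N mm
_PENALTY = 1e6
_REG_LAMBDA = 1e-9

__all__ = [
    "RecruitmentScheme",
    "SolverResult",
    "SimulationResult",
    "solve_step",
    "solve_trajectory",
    "muscle_group",
    "FORCE_TOL",
    "MOMENT_TOL",
]


def muscle_group(model: MusculoskeletalModel, group: int) -> set:
    """The (muscle part, side) pairs of recruitment group 1 or 2."""
    working = model.working_side
    balancing = "left" if working == "right" else "right"
    if group == 1:
        return {(m, working) for m in _GROUP1_WORKING} | \
               {(m, balancing) for m in _GROUP1_BALANCING}
    if group == 2:
        return {(m, balancing) for m in _GROUP1_WORKING} | \
               {(m, working) for m in _GROUP1_BALANCING}
    raise ConfigError(f"muscle group must be 1 or 2, got {group}")


@dataclass(frozen=True)
class RecruitmentScheme:
    """Phase-resolved allowed strand sets (and symmetry ties) for one mode."""

    mode: str  # shearing | crushing | premolar_crushing | incisor | maxbite
    tie_mirrored: bool = False

    @classmethod
    def for_mode(cls, mode: str) -> "RecruitmentScheme":
        if mode not in ("shearing", "crushing", "premolar_crushing", "incisor",
                        "maxbite"):
            raise ConfigError(f"unknown recruitment mode {mode!r}")
        return cls(mode=mode, tie_mirrored=(mode == "incisor"))

    def allowed_mask(self, model: MusculoskeletalModel, phase: str) -> np.ndarray:
        """Boolean mask over model.strands of strands allowed to activate."""
        if phase == "opening":
            keys = {("digastric", "left"), ("digastric", "right")}
        elif self.mode in ("incisor", "maxbite"):
            keys = {(m, s) for m in CLOSER_PARTS for s in ("left", "right")}
        elif phase == "fast_closing":
            keys = muscle_group(model, 1)
        elif phase == "slow_closing":
            keys = muscle_group(model, 1) | muscle_group(model, 2)
        else:
            raise ConfigError(f"unknown phase {phase!r}")
        return np.array([(s.muscle, s.side) in keys for s in model.strands])

    def tie_pairs(self, model: MusculoskeletalModel) -> list:
        """Mirrored strand index pairs forced to equal activation."""
        if not self.tie_mirrored:
            return []
        index = {}
        order = {}
        for i, s in enumerate(model.strands):
            k = (s.muscle, s.side)
            order[k] = order.get(k, -1) + 1
            index[(s.muscle, s.side, order[k])] = i
        pairs = []
        for (muscle, side, j), i in index.items():
            if side == "right":
                partner = index.get((muscle, "left", j))
                if partner is not None:
                    pairs.append((i, partner))
        return pairs


@dataclass
class SolverResult:
    """One timestep's recruitment solution."""

    activations: np.ndarray  # per strand, in [0, 1]
    reaction_left: np.ndarray  # N, 3-vector on the mandible
    reaction_right: np.ndarray
    residual: np.ndarray  # 6-vector (N, N mm)
    feasible: bool
    objective: float  # sum of squared activations

    @property
    def force_residual(self) -> float:
        return float(np.abs(self.residual[:3]).max())

    @property
    def moment_residual(self) -> float:
        return float(np.abs(self.residual[3:]).max())


def _strand_passive(model, strand, T, law: PassiveLaw) -> float:
    length = strand_path_length(strand, T)
    strain = (length - strand.rest_length) / strand.rest_length
    return passive_tension(strain, strand.max_force_share, law)


def min_effort_qp(A: np.ndarray, b: np.ndarray, n_bounded: int,
                  weights: np.ndarray | None = None):
    """Solve  min sum(w_j x_j^2)  s.t.  A x = b,  bounds on x.

    The first ``n_bounded`` variables (activations) are bounded to [0, 1]
    and carry unit (or ``weights``) quadratic cost; the remaining variables
    (joint-reaction magnitudes) are bounded to [0, inf) and carry only a
    tiny regularising cost for uniqueness.

    Solved as a weighted stacked least-squares problem (penalty 1e6 on the
    equality rows) and polished on the resulting active set so that, when
    the constraints are attainable, the residual ``A x - b`` is at machine
    precision.  Returns (x, residual).
    """
    m_total = A.shape[1]
    n_react = m_total - n_bounded
    if weights is None:
        weights = np.ones(n_bounded)
    top = A * _PENALTY
    reg = np.zeros((m_total, m_total))
    reg[:n_bounded, :n_bounded] = np.diag(np.sqrt(weights))
    if n_react:
        reg[n_bounded:, n_bounded:] = np.sqrt(_REG_LAMBDA) * np.eye(n_react)
    stacked = np.vstack([top, reg])
    b_vec = np.concatenate([b * _PENALTY, np.zeros(m_total)])
    lb = np.zeros(m_total)
    ub = np.concatenate([np.ones(n_bounded), np.full(n_react, np.inf)])
    sol = lsq_linear(stacked, b_vec, bounds=(lb, ub), method="bvls", tol=1e-14)
    x = sol.x

    # active-set polish: freeze variables at bounds, re-solve the free block
    # exactly via a scaled minimum-norm least-squares solve
    tol_b = 1e-9
    at_lo = x < tol_b
    at_hi = np.concatenate([x[:n_bounded] > 1 - tol_b, np.zeros(n_react, bool)])
    free = ~(at_lo | at_hi)
    if free.any():
        x_try = x.copy()
        x_try[at_lo] = 0.0
        x_try[np.flatnonzero(at_hi)] = 1.0
        col_scale = np.concatenate([np.sqrt(weights),
                                    np.full(n_react, np.sqrt(_REG_LAMBDA))])
        Bf = A[:, free] / col_scale[free]
        rhs_f = b - A[:, ~free] @ x_try[~free]
        y = np.linalg.pinv(Bf, rcond=1e-12) @ rhs_f
        cand = y / col_scale[free]
        n_free_act = int(np.count_nonzero(free[:n_bounded]))
        ok = np.all(cand >= -1e-9) and np.all(cand[:n_free_act] <= 1 + 1e-9)
        if ok:
            x_try[free] = np.clip(cand, 0.0, None)
            x_try[:n_bounded] = np.clip(x_try[:n_bounded], 0.0, 1.0)
            if (np.linalg.norm(A @ x_try - b)
                    <= np.linalg.norm(A @ x - b) + 1e-9):
                x = x_try
    return x, A @ x - b


def solve_step(model: MusculoskeletalModel, pose: JawPose,
               scheme: RecruitmentScheme, phase: str,
               bolus_wrench: np.ndarray | None = None,
               gravity_on: bool = True,
               include_passive: bool = True,
               passive_law: PassiveLaw | None = None) -> SolverResult:
    """Solve the 6-DOF static recruitment problem at one pose.

    ``bolus_wrench`` is the wrench (about the world origin) of the food
    reaction on the mandible, already evaluated at this pose.
    """
    T = model.pose_transform(pose)
    law = passive_law or PassiveLaw()
    n = len(model.strands)
    mask = scheme.allowed_mask(model, phase)

    const = np.zeros(6)
    if bolus_wrench is not None:
        const = const + np.asarray(bolus_wrench, float)
    if gravity_on:
        const = const + gravity_wrench(model.mandible, T)
    # activation-independent passive tension of every strand
    if include_passive:
        for s in model.strands:
            p = _strand_passive(model, s, T, law)
            if p > 0.0:
                const = const + strand_wrench(s, T, p)

    # wrench per unit activation for allowed strands
    idx = np.flatnonzero(mask)
    A = np.zeros((6, idx.size))
    for j, i in enumerate(idx):
        s = model.strands[i]
        A[:, j] = strand_wrench(s, T, s.max_force_share)

    # unit joint-reaction wrenches at the posed condyles
    cl = transform_points(T, model.condyle_left)
    cr = transform_points(T, model.condyle_right)
    J = np.column_stack([
        wrench_at(cl, model.fossa_normal_left),
        wrench_at(cr, model.fossa_normal_right),
    ])

    # merge tied mirrored pairs into single variables
    pairs = [(int(np.searchsorted(idx, i)), int(np.searchsorted(idx, j)))
             for i, j in scheme.tie_pairs(model)
             if mask[i] and mask[j]]
    group_of = np.arange(idx.size)
    for a_loc, b_loc in pairs:
        group_of[group_of == group_of[b_loc]] = group_of[a_loc]
    groups = np.unique(group_of)
    M = np.zeros((idx.size, groups.size))
    for g_col, g in enumerate(groups):
        M[group_of == g, g_col] = 1.0
    weights = M.sum(axis=0)  # strands per variable

    Av = A @ M
    m = groups.size
    x, _ = min_effort_qp(np.hstack([Av, J]), -const, n_bounded=m, weights=weights)
    v = x[:m]
    lam = x[m:]
    a_allowed = np.clip(M @ v, 0.0, 1.0)
    activations = np.zeros(n)
    activations[idx] = a_allowed

    residual = Av @ v + J @ lam + const
    feasible = (np.abs(residual[:3]).max() <= FORCE_TOL
                and np.abs(residual[3:]).max() <= MOMENT_TOL)
    return SolverResult(
        activations=activations,
        reaction_left=lam[0] * model.fossa_normal_left,
        reaction_right=lam[1] * model.fossa_normal_right,
        residual=residual,
        feasible=bool(feasible),
        objective=float(np.sum(a_allowed**2)),
    )


def residual_for_state(model: MusculoskeletalModel, pose: JawPose,
                       activations, reaction_left=None, reaction_right=None,
                       bolus_force_vec=None, bolus_point=None,
                       gravity_on: bool = True,
                       include_passive: bool = False,
                       dynamic: bool = False) -> np.ndarray:
    """6-DOF equilibrium residual for an explicit mechanical state.

    Assembles strand wrenches from the given activations, the joint
    reactions (3-vectors on the mandible at the posed condyles), an
    optional bolus force applied at a body-frame point, gravity and (in
    dynamic mode) the inertial wrench.  Linear in the activations at fixed
    pose, which is what makes the recruitment problem a convex QP.
    """
    from .mandible import equilibrium_residual as _assemble

    T = model.pose_transform(pose)
    a = np.asarray(activations, float)
    law = PassiveLaw()
    sw = []
    for i, s in enumerate(model.strands):
        tension = a[i] * s.max_force_share
        if include_passive:
            tension += _strand_passive(model, s, T, law)
        if tension > 0.0:
            sw.append(strand_wrench(s, T, tension))
    jw = []
    for reaction, condyle in ((reaction_left, model.condyle_left),
                              (reaction_right, model.condyle_right)):
        if reaction is not None:
            jw.append(wrench_at(transform_points(T, condyle), reaction))
    bw = None
    if bolus_force_vec is not None:
        point = transform_points(T, np.asarray(bolus_point, float))
        bw = wrench_at(point, bolus_force_vec)
    return _assemble(sw, jw, bw, model.mandible, T, pose=pose,
                     gravity_on=gravity_on, dynamic=dynamic)


@dataclass
class SimulationResult:
    """Time series produced by a full-cycle simulation."""

    time_ms: np.ndarray
    phase: list
    activations: np.ndarray  # (n_t, n_strands)
    bolus_forces: np.ndarray  # (n_t, 3) force on the lower plate, N
    reactions_left: np.ndarray  # (n_t, 3)
    reactions_right: np.ndarray
    feasible: np.ndarray  # (n_t,) bool
    residual_force: np.ndarray  # (n_t,) max abs force residual, N
    residual_moment: np.ndarray  # (n_t,) max abs moment residual, N mm
    model: MusculoskeletalModel
    profile: MotionProfile
    bolus: FoodBolus | None
    mode: str = ""
    contact_reference: np.ndarray | None = None

    @property
    def bite_forces(self) -> np.ndarray:
        """Force the lower teeth exert on the bolus, N (n_t, 3)."""
        return -self.bolus_forces

    def phase_indices(self, name: str) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.phase) if p == name])


def _bolus_state(model, profile, bolus, pose, contact_ref):
    """Displacement of the lower plate relative to its contact reference."""
    T = model.pose_transform(pose)
    lower = transform_points(T, model.bite_points[bolus.site])
    upper = model.upper_tooth_points[bolus.site]
    compression = bolus.height - (upper[2] - lower[2])
    d = np.array([lower[0] - contact_ref[0], lower[1] - contact_ref[1], compression])
    return lower, d


def solve_trajectory(model: MusculoskeletalModel, profile: MotionProfile,
                     bolus: FoodBolus, scheme: RecruitmentScheme | None = None,
                     gravity_on: bool = True,
                     include_passive: bool = True) -> SimulationResult:
    """Run the quasi-static recruitment solve over a full cycle.

    The bolus engages at the fast/slow-closing boundary (where the profile
    construction places first plate contact); its shear reference is the
    lower bite point's position at that instant.
    """
    if scheme is None:
        mode = "crushing" if profile.mode == "premolar_crushing" else profile.mode
        scheme = RecruitmentScheme.for_mode(mode)
    ts = profile.times()
    n_t = ts.size
    n = len(model.strands)

    contact_pose = profile.pose_at(profile.t_fast_end)
    T_c = model.pose_transform(contact_pose)
    contact_ref = transform_points(T_c, model.bite_points[bolus.site])

    acts = np.zeros((n_t, n))
    bf = np.zeros((n_t, 3))
    rl = np.zeros((n_t, 3))
    rr = np.zeros((n_t, 3))
    feas = np.zeros(n_t, bool)
    res_f = np.zeros(n_t)
    res_m = np.zeros(n_t)
    phases = []

    for k, t in enumerate(ts):
        pose = profile.pose_at(t)
        phase = profile.phase_of(t)
        phases.append(phase)
        wrench = None
        if phase == "slow_closing":
            lower, d = _bolus_state(model, profile, bolus, pose, contact_ref)
            if d[2] > -1e-9:  # plates engaged
                f = bolus_force(bolus, d)
                bf[k] = f
                wrench = wrench_at(lower, f)
        r = solve_step(model, pose, scheme, phase, bolus_wrench=wrench,
                       gravity_on=gravity_on, include_passive=include_passive)
        acts[k] = r.activations
        rl[k] = r.reaction_left
        rr[k] = r.reaction_right
        feas[k] = r.feasible
        res_f[k] = r.force_residual
        res_m[k] = r.moment_residual

    return SimulationResult(
        time_ms=ts, phase=phases, activations=acts, bolus_forces=bf,
        reactions_left=rl, reactions_right=rr, feasible=feas,
        residual_force=res_f, residual_moment=res_m,
        model=model, profile=profile, bolus=bolus, mode=profile.mode,
        contact_reference=contact_ref)
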