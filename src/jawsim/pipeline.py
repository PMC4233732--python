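"""Mastication experiments and reporting statistics.

Orchestrates the study's simulation set — molar shearing, molar crushing,
incisor biting, premolar crushing, and the maximum incisor bite force
against a rigid bolus — and computes the derived quantities used for
reporting: bite-force components as percentages of the resultant, the
per-muscle peak-activation table, the recruited fraction of the total
available closer force, and the comparison of the predicted maximum bite
force with measured statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .anatomy import CLOSER_PARTS, ModelConfig, MusculoskeletalModel, build_model
from .bolus import FoodBolus, make_bolus
from .errors import InvalidParameterError, SimulationSetupError
from .mandible import gravity_wrench, transform_points, wrench_at
from .motion import (DEFAULT_DURATIONS, RUN_MODES, build_profile,
                     pose_for_incisal_gape)
from .muscles import PassiveLaw, strand_wrench
from .solver import (RecruitmentScheme, SimulationResult, _strand_passive,
                     solve_trajectory)

#: measured incisor bite-force statistics used for model validation:
#: (mean N, standard deviation N, absolute maximum N)
MEASURED_INCISOR_STATS = (69.1, 13.3, 95.2)

__all__ = [
    "BiteRecord",
    "run_mode",
    "max_incisor_bite_force",
    "bite_force_components",
    "recruited_fraction",
    "peak_activation_table",
    "compare_with_measured",
    "muscle_activation_series",
    "group_activation_series",
    "peak_recruited_fraction",
    "bite_record",
    "MEASURED_INCISOR_STATS",
    "RUN_MODES",
]


@dataclass(frozen=True)
class BiteRecord:
    """A bite force resolved into world-axis components.

    components are (anteroposterior, mediolateral, vertical) in N; the
    percentages are unsigned fractions of the resultant, so their squared
    sum (as fractions) is one.
    """

    resultant: float
    components: tuple
    percentages: tuple
    site: str = ""
    mode: str = ""


def bite_force_components(force, site: str = "", mode: str = "") -> BiteRecord:
    """Resolve a bite-force 3-vector into component percentages of resultant."""
    f = np.asarray(force, float)
    resultant = float(np.linalg.norm(f))
    if resultant == 0.0:
        raise InvalidParameterError("component percentages undefined for a zero force")
    pct = tuple(100.0 * abs(c) / resultant for c in f)
    return BiteRecord(resultant=resultant, components=tuple(f), percentages=pct,
                      site=site, mode=mode)


def _mode_bolus(mode: str, model: MusculoskeletalModel, profile_kw: dict,
                bolus_overrides: dict | None) -> FoodBolus:
    """Bolus for a run mode, with shear stiffness set from the power-stroke
    excursion of the lower bite point."""
    base_mode = "crushing" if mode == "premolar_crushing" else mode
    site = {"shearing": "molar_right", "crushing": "molar_right",
            "premolar_crushing": "premolar_right", "incisor": "incisor"}[mode]
    overrides = dict(bolus_overrides or {})
    if mode != "shearing":
        return make_bolus(base_mode, site=site, **overrides)
    # mediolateral excursion of the bite point over the frontal return sets
    # the shearing-mode mediolateral stiffness (cap reached at the midline)
    prov = make_bolus(base_mode, site=site, **overrides)
    profile = build_profile(mode, model, prov, **profile_kw)
    p_c = transform_points(model.pose_transform(profile.pose_at(profile.t_fast_end)),
                           model.bite_points[site])
    p_e = transform_points(model.pose_transform(profile.pose_at(profile.t_total)),
                           model.bite_points[site])
    return make_bolus(base_mode, site=site, shear_travel=abs(p_e[1] - p_c[1]),
                      **overrides)


def run_mode(mode: str, config: ModelConfig | None = None,
             model: MusculoskeletalModel | None = None,
             durations=DEFAULT_DURATIONS, timestep_ms: float = 1.0,
             bolus_overrides: dict | None = None,
             gravity_on: bool = True) -> SimulationResult:
    """Run one full reduction-cycle simulation.

    mode is one of shearing, crushing, incisor, premolar_crushing.  The
    molar modes place the bolus between the most posterior right molars;
    premolar crushing re-uses the crushing set-up at the premolar bite
    point.  The slow-closing phase ends at half-compression of the bolus.
    """
    if mode not in RUN_MODES:
        raise SimulationSetupError(f"unknown run mode {mode!r}")
    if model is None:
        model = build_model(config)
    profile_kw = {"durations": tuple(durations), "timestep_ms": timestep_ms}
    bolus = _mode_bolus(mode, model, profile_kw, bolus_overrides)
    profile = build_profile(mode, model, bolus, **profile_kw)
    return solve_trajectory(model, profile, bolus, gravity_on=gravity_on)


def max_incisor_bite_force(model: MusculoskeletalModel | None = None,
                           gape_mm: float = 5.5,
                           gravity_on: bool = True,
                           include_passive: bool = True):
    """Maximum achievable incisor bite force against a rigid bolus.

    All jaw closers are held at full activation at the pose giving the
    requested incisal gape; the static 6-DOF balance is then solved for the
    bite reaction at the incisor point (transmitted by the rigid,
    high-friction bolus) and the compressive condylar reactions.

    Returns
    -------
    (record, info) : (BiteRecord, dict)
        Bite force exerted on the bolus; info carries the joint reaction
        magnitudes and the equilibrium residual.
    """
    if model is None:
        model = build_model()
    pose = pose_for_incisal_gape(model, gape_mm)
    T = model.pose_transform(pose)
    law = PassiveLaw()

    total = np.zeros(6)
    for s in model.strands:
        tension = 0.0
        if s.muscle in CLOSER_PARTS:
            tension = s.max_force_share
        if include_passive:
            tension += _strand_passive(model, s, T, law)
        if tension > 0.0:
            total += strand_wrench(s, T, tension)
    if gravity_on:
        total += gravity_wrench(model.mandible, T)

    incisor = transform_points(T, model.bite_points["incisor"])
    cl = transform_points(T, model.condyle_left)
    cr = transform_points(T, model.condyle_right)
    # unknowns: bite reaction on the mandible (3, unbounded: rigid bolus with
    # high friction) and the two compressive condylar magnitudes
    cols = [wrench_at(incisor, e) for e in np.eye(3)]
    cols.append(wrench_at(cl, model.fossa_normal_left))
    cols.append(wrench_at(cr, model.fossa_normal_right))
    B = np.column_stack(cols)
    lb = np.array([-np.inf, -np.inf, -np.inf, 0.0, 0.0])
    ub = np.full(5, np.inf)
    sol = lsq_linear(B, -total, bounds=(lb, ub), method="bvls", tol=1e-14)
    residual = B @ sol.x + total
    if np.abs(residual).max() > 1e-3:
        raise SimulationSetupError(
            "static balance not solvable with the joint-reaction model "
            f"(residual {np.abs(residual).max():.3g})")
    bite_on_mandible = sol.x[:3]
    record = bite_force_components(-bite_on_mandible, site="incisor", mode="maxbite")
    info = {
        "gape_mm": gape_mm,
        "pose_sagittal_deg": pose.sagittal_deg,
        "joint_left_N": float(sol.x[3]),
        "joint_right_N": float(sol.x[4]),
        "residual": residual,
    }
    return record, info


def muscle_activation_series(result: SimulationResult) -> pd.DataFrame:
    """Force-weighted mean activation per muscle part and side over time.

    Columns are (muscle, side); values in [0, 1].
    """
    model = result.model
    data = {}
    for part in CLOSER_PARTS + ("digastric",):
        for side in ("left", "right"):
            sel = [i for i, s in enumerate(model.strands)
                   if s.muscle == part and s.side == side]
            if not sel:
                continue
            shares = np.array([model.strands[i].max_force_share for i in sel])
            data[(part, side)] = result.activations[:, sel] @ shares / shares.sum()
    df = pd.DataFrame(data, index=result.time_ms)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["muscle", "side"])
    return df


def group_activation_series(result: SimulationResult) -> pd.DataFrame:
    """Force-weighted mean activation of recruitment groups 1 and 2 over time."""
    from .solver import muscle_group

    series = muscle_activation_series(result)
    model = result.model
    out = {}
    for g in (1, 2):
        total = np.zeros(len(result.time_ms))
        wsum = 0.0
        for muscle, side in muscle_group(model, g):
            F = model.muscle_max_force(muscle, side)
            total += series[(muscle, side)].to_numpy() * F
            wsum += F
        out[g] = total / wsum
    return pd.DataFrame(out, index=result.time_ms)


def peak_activation_table(result: SimulationResult,
                          side_average: bool | None = None) -> pd.DataFrame:
    """Per-muscle peak activation percentages over the cycle.

    Rows are closer muscle parts; columns the balancing and working sides
    (peak of the force-weighted mean strand activation, x100).  For incisor
    biting, where recruitment is symmetric, a side-averaged column is
    reported as well.
    """
    if side_average is None:
        side_average = result.mode == "incisor"
    series = muscle_activation_series(result)
    model = result.model
    working = model.working_side
    balancing = "left" if working == "right" else "right"
    rows = {}
    for part in CLOSER_PARTS:
        peak_b = 100.0 * series[(part, balancing)].max()
        peak_w = 100.0 * series[(part, working)].max()
        row = {"balancing": peak_b, "working": peak_w}
        if side_average:
            row["mean"] = 0.5 * (peak_b + peak_w)
        rows[part] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def recruited_fraction(activations, model: MusculoskeletalModel) -> float:
    """Percentage of the total available closer force that is recruited.

    100 * sum_i a_i F_i / sum_i F_i over all closer strands on both sides
    (the digastric is excluded from numerator and denominator).
    """
    a = np.asarray(activations, float)
    num = 0.0
    den = 0.0
    for i, s in enumerate(model.strands):
        if s.muscle in CLOSER_PARTS:
            num += a[i] * s.max_force_share
            den += s.max_force_share
    return 100.0 * num / den


def peak_recruited_fraction(result: SimulationResult) -> float:
    """Recruited fraction at the instant of peak total recruited force."""
    model = result.model
    shares = np.array([s.max_force_share if s.muscle in CLOSER_PARTS else 0.0
                       for s in model.strands])
    totals = result.activations @ shares
    k = int(np.argmax(totals))
    return recruited_fraction(result.activations[k], model)


def bite_record(result: SimulationResult) -> BiteRecord:
    """Bite force at the instant of peak resultant bolus force."""
    norms = np.linalg.norm(result.bite_forces, axis=1)
    k = int(np.argmax(norms))
    if norms[k] == 0.0:
        raise SimulationSetupError("no bolus force was developed during the run")
    return bite_force_components(result.bite_forces[k],
                                 site=result.bolus.site, mode=result.mode)


def compare_with_measured(bite: BiteRecord,
                          mean: float = MEASURED_INCISOR_STATS[0],
                          sd: float = MEASURED_INCISOR_STATS[1],
                          abs_max: float = MEASURED_INCISOR_STATS[2]) -> dict:
    """Compare a predicted bite force with measured summary statistics.

    Returns the z-score of the prediction against the measured mean/s.d.,
    whether it falls within +/- 1 s.d., and whether it stays strictly below
    the absolute maximum measured force.
    """
    if sd <= 0:
        raise InvalidParameterError(f"standard deviation must be positive, got {sd}")
    z = (bite.resultant - mean) / sd
    return {
        "predicted_N": bite.resultant,
        "z_score": z,
        "within_1sd": bool(abs(z) <= 1.0),
        "below_abs_max": bool(bite.resultant < abs_max),
        "mean_N": mean,
        "sd_N": sd,
        "abs_max_N": abs_max,
    }
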