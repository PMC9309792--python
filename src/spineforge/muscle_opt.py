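"""Static optimization of muscle forces and joint reaction decomposition.

Muscle redundancy is resolved by minimizing the sum of cubed muscle
stresses ``sum((F_i / PCSA_i)^3)`` subject to moment equilibrium about the
frontal (X) and sagittal (Z) axes at each actuated joint and to the bounds
``0 <= F_i <= sigma_max * PCSA_i``.  Axial moments are left unconstrained.
The cost is convex on the feasible box, so a deterministic multi-start of
a gradient-based solver stands in for a global search; only active forces
are modeled (no passive muscle elasticity).

Joint reactions follow from superstructure equilibrium: the reaction force
equals minus the resultant of gravity, external, muscle and ligament
forces acting on everything superior to the joint, decomposed in the joint
frame into compression (along the superior axis), anterior-posterior shear
and lateral shear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear, minimize

from .anatomy import SpineModel, ligament_force, superstructure
from .statics import LoadCase, Posture, _posed_elements, net_joint_moments

__all__ = [
    "OptimizationProblem",
    "StaticSolution",
    "InfeasibleProblemError",
    "moment_arm",
    "build_problem",
    "solve",
    "joint_reactions",
    "normalize_to_standing",
    "ligament_utilization",
]

#: N per cm^2 at 1 MPa
_MPA_TO_N_PER_CM2 = 100.0


class InfeasibleProblemError(RuntimeError):
    """Equality constraints unreachable within the force bounds."""

    def __init__(self, worst: str, residual: float):
        self.worst_constraint = worst
        self.residual = residual
        super().__init__(
            f"moment equilibrium unreachable: worst constraint {worst} "
            f"(residual {residual:.2f} N*m); consider raising the maximal muscle stress"
        )


@dataclass
class OptimizationProblem:
    """Linearly constrained cubic-stress muscle force problem.

    ``moment_arms`` has shape (n_constraints, n_fascicles) in metres
    (moment per newton of fascicle force about each constrained axis);
    ``target_moments`` is the required actuator moment per constraint row
    in N*m.
    """

    moment_arms: np.ndarray
    pcsa: np.ndarray
    target_moments: np.ndarray
    sigma_max_mpa: float = 1.0
    labels: list[str] = field(default_factory=list)
    constraint_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.moment_arms = np.atleast_2d(np.asarray(self.moment_arms, float))
        self.pcsa = np.asarray(self.pcsa, float)
        self.target_moments = np.atleast_1d(np.asarray(self.target_moments, float))
        if not np.all(np.isfinite(self.moment_arms)):
            raise ValueError("moment arms must be finite")
        if self.moment_arms.shape[0] > self.moment_arms.shape[1]:
            raise ValueError("need at least as many fascicles as constraints")

    @property
    def force_bounds(self) -> np.ndarray:
        return self.sigma_max_mpa * _MPA_TO_N_PER_CM2 * self.pcsa


@dataclass
class StaticSolution:
    forces_n: np.ndarray
    cost: float
    residuals_nm: np.ndarray
    labels: list[str] = field(default_factory=list)
    constraint_names: list[str] = field(default_factory=list)
    reactions: dict[str, dict[str, float]] = field(default_factory=dict)
    ligament_utilization: dict[str, float] = field(default_factory=dict)


def moment_arm(origin: np.ndarray, insertion: np.ndarray, joint_origin: np.ndarray) -> np.ndarray:
    """3-D moment arm (m) of a point-to-point line of action about a joint.

    ``r x u`` with ``r`` from the joint to the insertion-side attachment and
    ``u`` the unit line of action from origin to insertion; positions in mm.
    """
    d = np.asarray(insertion, float) - np.asarray(origin, float)
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise ValueError("zero-length fascicle")
    u = d / n
    r = (np.asarray(insertion, float) - np.asarray(joint_origin, float)) * 1e-3
    return np.cross(r, u)


def build_problem(
    model: SpineModel,
    posture: Posture,
    case: LoadCase | None = None,
    sigma_max_mpa: float = 1.0,
) -> OptimizationProblem:
    """Assemble the equilibrium-constrained force problem for a posed model.

    Constraint rows are the frontal (X) and sagittal (Z) moments at each
    actuated joint; a fascicle contributes when its endpoints span the
    joint, through the moment of its pull on the superstructure-side
    attachment.
    """
    poses, _coms, jframes, _lig, _loads = _posed_elements(model, posture, case)
    targets = net_joint_moments(model, posture, case)
    n = len(model.muscles)
    rows = []
    b = []
    names = []
    for jf in model.joints:
        oj, Rj = jframes[jf.name]
        sup = set(superstructure(jf.name))
        arms = np.zeros((3, n))
        for i, mus in enumerate(model.muscles):
            o_in = mus.origin.body in sup
            i_in = mus.insertion.body in sup
            if o_in == i_in:
                continue  # does not cross this joint
            p_o = poses[mus.origin.body].apply(mus.origin.position)
            p_i = poses[mus.insertion.body].apply(mus.insertion.position)
            p_sup, p_other = (p_o, p_i) if o_in else (p_i, p_o)
            d = p_other - p_sup
            u = d / np.linalg.norm(d)
            a_world = np.cross((p_sup - oj) * 1e-3, u)
            arms[:, i] = Rj.T @ a_world
        for ax, axname in ((0, "Mx"), (2, "Mz")):
            rows.append(arms[ax])
            b.append(targets[jf.name][ax])
            names.append(f"{jf.name}:{axname}")
    return OptimizationProblem(
        moment_arms=np.array(rows),
        pcsa=np.array([m.pcsa_cm2 for m in model.muscles]),
        target_moments=np.array(b),
        sigma_max_mpa=sigma_max_mpa,
        labels=[f"{m.group}_{m.side}_{i}" for i, m in enumerate(model.muscles)],
        constraint_names=names,
    )


def solve(
    problem: OptimizationProblem,
    tol_nm: float = 0.1,
    n_starts: int = 10,
    seed: int = 0,
) -> StaticSolution:
    """Cubic-stress optimal fascicle forces under moment equilibrium.

    SLSQP from a least-squares feasible start plus deterministic random
    restarts (the cost is convex on the box, so the restarts are a
    verification, not a necessity).  Equality residuals above ``tol_nm``
    raise :class:`InfeasibleProblemError` naming the worst constraint.
    """
    A = problem.moment_arms
    b = problem.target_moments
    ub = problem.force_bounds
    p = problem.pcsa
    nf = A.shape[1]

    def cost(f: np.ndarray) -> float:
        return float(np.sum((f / p) ** 3))

    def grad(f: np.ndarray) -> np.ndarray:
        return 3.0 * f**2 / p**3

    cons = {"type": "eq", "fun": lambda f: A @ f - b, "jac": lambda f: A}
    bounds = [(0.0, float(u)) for u in ub]

    ls = lsq_linear(A, b, bounds=(np.zeros(nf), ub), tol=1e-12)
    starts = [ls.x]
    rng = np.random.default_rng(seed)
    for _ in range(max(n_starts - 1, 0)):
        starts.append(rng.uniform(0.0, 1.0, nf) * ub * 0.1)

    best = None
    for x0 in starts:
        res = minimize(
            cost,
            np.clip(x0, 0.0, ub),
            jac=grad,
            method="SLSQP",
            bounds=bounds,
            constraints=[cons],
            options={"maxiter": 400, "ftol": 1e-12},
        )
        resid = np.abs(A @ res.x - b)
        if resid.max() > tol_nm:
            continue
        if best is None or cost(res.x) < cost(best):
            best = res.x
    if best is None:
        # report the best-achievable residual from the least-squares relaxation
        resid = np.abs(A @ ls.x - b)
        worst = int(np.argmax(resid))
        name = (
            problem.constraint_names[worst]
            if problem.constraint_names
            else f"row {worst}"
        )
        raise InfeasibleProblemError(name, float(resid[worst]))
    forces = np.clip(best, 0.0, ub)
    return StaticSolution(
        forces_n=forces,
        cost=cost(forces),
        residuals_nm=A @ forces - b,
        labels=list(problem.labels),
        constraint_names=list(problem.constraint_names),
    )


def joint_reactions(
    model: SpineModel,
    posture: Posture,
    forces_n: np.ndarray,
    case: LoadCase | None = None,
) -> dict[str, dict[str, float]]:
    """Compression and shear components of each joint's reaction force (N).

    The reaction equals minus the resultant of all forces on the
    superstructure; in the joint frame, compression is the force pressing
    along the inferior direction of the superior axis, anterior-posterior
    shear the anterior component and lateral shear the subject-left
    component.
    """
    poses, coms, jframes, lig_pts, loads = _posed_elements(model, posture, case)
    g = np.array([0.0, -model.gravity_m_s2, 0.0])
    out: dict[str, dict[str, float]] = {}
    for jf in model.joints:
        oj, Rj = jframes[jf.name]
        sup = set(superstructure(jf.name))
        F = np.zeros(3)
        for bname in sup:
            F += model.bodies[bname].mass_kg * g
        for ld in loads:
            if ld.body in sup:
                F += ld.force_n
        for lig, (p_inf, p_sup) in zip(model.ligaments, lig_pts):
            if lig.attach_superior.body not in sup or lig.attach_inferior.body in sup:
                continue
            d = p_inf - p_sup
            l = np.linalg.norm(d)
            fl = ligament_force(lig, l)
            if fl > 0:
                F += fl * d / l
        for i, mus in enumerate(model.muscles):
            o_in = mus.origin.body in sup
            i_in = mus.insertion.body in sup
            if o_in == i_in:
                continue
            p_o = poses[mus.origin.body].apply(mus.origin.position)
            p_i = poses[mus.insertion.body].apply(mus.insertion.position)
            p_sup, p_other = (p_o, p_i) if o_in else (p_i, p_o)
            d = p_other - p_sup
            F += forces_n[i] * d / np.linalg.norm(d)
        # reaction on the superstructure from below; under load it points
        # superiorly, so compression is its +Y (superior-axis) component
        local = Rj.T @ (-F)
        out[jf.name] = {
            "compression_n": float(local[1]),
            "ap_shear_n": float(local[0]),
            "lateral_shear_n": float(local[2]),
        }
    return out


def normalize_to_standing(
    results: dict[str, dict[str, dict[str, float]]],
    standing_case: str = "standing",
) -> dict[str, dict[str, float]]:
    """Per-joint compression of every case divided by the standing compression."""
    if standing_case not in results:
        raise KeyError(f"standing case {standing_case!r} missing from results")
    ref = results[standing_case]
    out: dict[str, dict[str, float]] = {}
    for case, joints in results.items():
        row = {}
        for j, comp in joints.items():
            denom = ref[j]["compression_n"]
            if abs(denom) < 1e-9:
                raise ZeroDivisionError(f"zero standing compression at {j}")
            row[j] = comp["compression_n"] / denom
        out[case] = row
    return out


def ligament_utilization(model: SpineModel, posture: Posture) -> dict[str, float]:
    """Per-ligament force divided by its force at the end of the linear region.

    Utilization 1.0 marks the failure-onset force ``F_B``; larger values are
    supra-physiological states worth flagging.
    """
    _poses, _coms, _jf, lig_pts, _loads = _posed_elements(model, posture, None)
    out: dict[str, float] = {}
    for lig, (p_inf, p_sup) in zip(model.ligaments, lig_pts):
        l = float(np.linalg.norm(p_sup - p_inf))
        out[f"{lig.name}@{lig.joint}"] = ligament_force(lig, l) / lig.F_B
    return out
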