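"""Pose-mode physics: spring-damper placement with one-sided collision response.

Manipulated objects are pulled toward a target pose by a force proportional
to the position error and a torque proportional to the orientation error
(axis-angle).  The defining contract of pose mode is asymmetry: *only the
manipulated objects move*.  Collision response forces — penalty forces along
the contact normals of the other body — act solely on manipulated objects,
so a commanded object can be slid along an obstacle but cannot pass through
it, and the obstacle never budges.  This also caps collision work at m·n
pair tests per step for m manipulated among n objects.

A rejected earlier design is retained for comparison
(:func:`settle_reject_mode`): move only if the candidate pose is collision
free.  Resting contact then blocks *every* candidate, so objects stick and
cannot slide — the failure that motivated the penalty-force design.

Unit mass and unit inertia are used for every object: the integrator is a
pose controller, not a dynamics simulation, and the user-level behaviours
(convergence, non-penetration, sliding) do not depend on mass distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .collision import CollisionReport, scene_collisions
from .scene import Scene
from .transforms import RigidTransform

__all__ = [
    "PhysicsParams",
    "ManipulationState",
    "StepDiagnostics",
    "tracker_wrench",
    "collision_response",
    "penetration_depth",
    "substep",
    "settle",
    "step",
    "settle_reject_mode",
    "step_reject_mode",
]


@dataclass(frozen=True)
class PhysicsParams:
    """Controller gains and integrator settings.

    k_translate : pull force per Angstrom of position error
    k_rotate    : pull torque per radian of orientation error
    damping     : per-step velocity retention factor in (0, 1]
    response_gain : penalty force per contact (along the contact normal)
    dt          : integrator time step (arbitrary time unit)
    penetration_tolerance : acceptable residual overlap, Angstroms
    max_iterations : settle-loop cap
    convergence_threshold : combined wrench norm below which the loop stops
    """

    k_translate: float = 1.0
    k_rotate: float = 1.0
    damping: float = 0.5
    response_gain: float = 10.0
    dt: float = 0.05
    penetration_tolerance: float = 0.1
    max_iterations: int = 2000
    convergence_threshold: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("k_translate", "k_rotate", "damping", "response_gain", "dt",
                     "penetration_tolerance", "convergence_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.damping > 1.0:
            raise ValueError("damping must be <= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ManipulationState:
    """Which objects are being manipulated, where they are being pulled to,
    and their current (linear, angular) velocities."""

    manipulated: set[str] = field(default_factory=set)
    targets: dict[str, RigidTransform] = field(default_factory=dict)
    velocity: dict[str, np.ndarray] = field(default_factory=dict)
    angular_velocity: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for oid in self.manipulated:
            self.velocity.setdefault(oid, np.zeros(3))
            self.angular_velocity.setdefault(oid, np.zeros(3))

    def check_finite(self) -> None:
        for oid in self.manipulated:
            if not (np.all(np.isfinite(self.velocity[oid]))
                    and np.all(np.isfinite(self.angular_velocity[oid]))):
                raise FloatingPointError(f"non-finite velocity state for object {oid!r}")


@dataclass
class StepDiagnostics:
    iterations: int = 0
    converged: bool = False
    final_wrench_norm: float = float("inf")
    max_penetration: float = 0.0
    collision_tests: int = 0


def tracker_wrench(
    current: RigidTransform, target: RigidTransform, params: PhysicsParams
) -> tuple[np.ndarray, np.ndarray]:
    """Force toward the target position and torque toward the target
    orientation (axis-angle of the world-frame rotation error); both vanish
    exactly when the poses coincide."""
    force = params.k_translate * (target.translation - current.translation)
    err = Rotation.from_matrix(target.rotation @ current.rotation.T).as_rotvec()
    torque = params.k_rotate * err
    return force, torque


def _object_center(obj) -> np.ndarray:
    return obj.pose.apply(obj.mesh.vertices.mean(axis=0))


def collision_response(
    report: CollisionReport,
    scene: Scene,
    manipulated: set[str],
    params: PhysicsParams,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Penalty wrenches on manipulated objects only.

    For each contact, the manipulated object receives ``response_gain``
    times the unit face normal of the *other* body's contact triangle
    (outward winding makes it point away from that body), applied at the
    contact triangle pair's midpoint; the induced torque is offset x force.
    Non-manipulated objects receive nothing.
    """
    wrenches = {oid: (np.zeros(3), np.zeros(3)) for oid in manipulated}
    for pair in report.colliding_pairs:
        ida, idb = pair
        obj_a, obj_b = scene.objects[ida], scene.objects[idb]
        contacts = report.contacts[pair]
        fa_idx = np.array([c[0] for c in contacts])
        fb_idx = np.array([c[1] for c in contacts])
        normals_a = (scene.objects[ida].mesh.face_normals()[fa_idx]) @ obj_a.pose.rotation.T
        normals_b = (scene.objects[idb].mesh.face_normals()[fb_idx]) @ obj_b.pose.rotation.T
        tri_a = obj_a.pose.apply(obj_a.mesh.vertices)[obj_a.mesh.faces[fa_idx]]
        tri_b = obj_b.pose.apply(obj_b.mesh.vertices)[obj_b.mesh.faces[fb_idx]]
        points = (tri_a.mean(axis=1) + tri_b.mean(axis=1)) / 2.0
        if ida in manipulated:
            f = params.response_gain * normals_b
            force, torque = wrenches[ida]
            force = force + f.sum(axis=0)
            torque = torque + np.cross(points - _object_center(obj_a), f).sum(axis=0)
            wrenches[ida] = (force, torque)
        if idb in manipulated:
            f = params.response_gain * normals_a
            force, torque = wrenches[idb]
            force = force + f.sum(axis=0)
            torque = torque + np.cross(points - _object_center(obj_b), f).sum(axis=0)
            wrenches[idb] = (force, torque)
    return wrenches


def penetration_depth(report: CollisionReport, scene: Scene) -> float:
    """Approximate maximum overlap: for each contact, how far the deepest
    vertex of one contact triangle sits behind the other triangle's plane
    (a diagnostic, not an exact minimum translation distance)."""
    worst = 0.0
    for pair in report.colliding_pairs:
        ida, idb = pair
        obj_a, obj_b = scene.objects[ida], scene.objects[idb]
        verts_a = obj_a.pose.apply(obj_a.mesh.vertices)
        verts_b = obj_b.pose.apply(obj_b.mesh.vertices)
        normals_a = obj_a.mesh.face_normals() @ obj_a.pose.rotation.T
        normals_b = obj_b.mesh.face_normals() @ obj_b.pose.rotation.T
        for fa, fb in report.contacts[pair]:
            ta = verts_a[obj_a.mesh.faces[fa]]
            tb = verts_b[obj_b.mesh.faces[fb]]
            # depth of A's triangle behind B's plane, and vice versa
            da = -np.min((ta - tb[0]) @ normals_b[fb])
            db = -np.min((tb - ta[0]) @ normals_a[fa])
            worst = max(worst, max(0.0, min(da, db)))
    return worst


def _integrate(obj, state: ManipulationState, force, torque, params: PhysicsParams) -> None:
    oid = obj.id
    v = params.damping * state.velocity[oid] + params.dt * force
    w = params.damping * state.angular_velocity[oid] + params.dt * torque
    state.velocity[oid] = v
    state.angular_velocity[oid] = w
    t = obj.pose.translation + params.dt * v
    wn = np.linalg.norm(w)
    if wn * params.dt > 1e-15:
        R = Rotation.from_rotvec(params.dt * w).as_matrix() @ obj.pose.rotation
        U, _, Vt = np.linalg.svd(R)
        R = U @ Vt
    else:
        R = obj.pose.rotation
    obj.pose = RigidTransform(R, t)


def _wrenches(scene, state, params, extra_wrench):
    """Tracker + collision + extra wrenches; returns (per-object wrench,
    collision report)."""
    report = scene_collisions(scene, state.manipulated)
    response = collision_response(report, scene, state.manipulated, params)
    extra = extra_wrench(scene) if extra_wrench is not None else {}
    out = {}
    for oid in sorted(state.manipulated):
        obj = scene.objects[oid]
        f = np.zeros(3)
        tq = np.zeros(3)
        if oid in state.targets:
            tf, tt = tracker_wrench(obj.pose, state.targets[oid], params)
            f, tq = f + tf, tq + tt
        rf, rt = response[oid]
        f, tq = f + rf, tq + rt
        if oid in extra:
            ef, et = extra[oid]
            f, tq = f + ef, tq + et
        out[oid] = (f, tq)
    return out, report


def substep(
    scene: Scene,
    state: ManipulationState,
    params: PhysicsParams,
    extra_wrench=None,
) -> tuple[float, CollisionReport]:
    """One damped semi-implicit Euler step of every manipulated object.

    Returns the combined wrench norm before integration and the collision
    report used.  Non-manipulated poses are not touched at all.
    """
    state.check_finite()
    wrenches, report = _wrenches(scene, state, params, extra_wrench)
    norm2 = 0.0
    for oid, (f, tq) in wrenches.items():
        norm2 += float(f @ f + tq @ tq)
        _integrate(scene.objects[oid], state, f, tq, params)
    state.check_finite()
    return float(np.sqrt(norm2)), report


def settle(
    scene: Scene,
    state: ManipulationState,
    params: PhysicsParams | None = None,
    extra_wrench=None,
) -> StepDiagnostics:
    """Drive manipulated objects until the combined wrench norm drops below
    the convergence threshold or ``max_iterations`` is reached."""
    params = params or PhysicsParams()
    diag = StepDiagnostics()
    for it in range(params.max_iterations):
        norm, report = substep(scene, state, params, extra_wrench)
        diag.iterations = it + 1
        diag.final_wrench_norm = norm
        diag.collision_tests += report.tests_performed
        if norm < params.convergence_threshold:
            diag.converged = True
            break
    final_report = scene_collisions(scene, state.manipulated)
    diag.max_penetration = penetration_depth(final_report, scene)
    return diag


# canonical name: one "step" of pose-mode physics runs to convergence
step = settle


def substep_reject_mode(
    scene: Scene, state: ManipulationState, params: PhysicsParams
) -> tuple[float, int]:
    """One step of the rejected first design: integrate the tracker wrench
    alone, then apply the candidate pose only if it is collision free.  A
    rejected candidate resets the object's velocity (otherwise accumulated
    velocity would eventually tunnel through the blocking contact)."""
    state.check_finite()
    norm2 = 0.0
    tests = 0
    for oid in sorted(state.manipulated):
        obj = scene.objects[oid]
        f = np.zeros(3)
        tq = np.zeros(3)
        if oid in state.targets:
            f, tq = tracker_wrench(obj.pose, state.targets[oid], params)
        norm2 += float(f @ f + tq @ tq)
        old_pose = obj.pose
        _integrate(obj, state, f, tq, params)
        report = scene_collisions(scene, {oid})
        tests += report.tests_performed
        if report.colliding_pairs:
            obj.pose = old_pose
            state.velocity[oid] = np.zeros(3)
            state.angular_velocity[oid] = np.zeros(3)
    state.check_finite()
    return float(np.sqrt(norm2)), tests


def settle_reject_mode(
    scene: Scene, state: ManipulationState, params: PhysicsParams | None = None
) -> StepDiagnostics:
    """Reject-on-collision comparison mode, run to convergence or the
    iteration cap."""
    params = params or PhysicsParams()
    diag = StepDiagnostics()
    for it in range(params.max_iterations):
        norm, tests = substep_reject_mode(scene, state, params)
        diag.iterations = it + 1
        diag.final_wrench_norm = norm
        diag.collision_tests += tests
        if norm < params.convergence_threshold:
            diag.converged = True
            break
    final_report = scene_collisions(scene, state.manipulated)
    diag.max_penetration = penetration_depth(final_report, scene)
    return diag


step_reject_mode = settle_reject_mode
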