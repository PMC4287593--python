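"""Spring connectors: rest-length springs, terminus snapping, layout relaxation.

A :class:`SpringConnector` links an attachment point on one object to one on
another.  In ``force`` mode it is a Hookean spring with rest length ``L0``
(Angstroms): when the attachment separation is a known experimental distance
(two-color fluorescence, FRET), the spring encodes it as a soft layout
constraint, and relaxing the scene pulls the arrangement toward feasibility
while collision response keeps objects from overlapping.  In ``visual`` mode
the connector exerts nothing — it marks a structurally unresolved linker,
such as the disordered region between protein domains.

Connector ends can be snapped to the N- or C-terminus of a protein chain
(the first/last alpha-carbon), the natural anchor points for inter-domain
linkers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .meshes import AtomicStructure
from .physics import ManipulationState, PhysicsParams, StepDiagnostics, settle
from .scene import Scene

__all__ = [
    "SpringConnector",
    "spring_wrench",
    "total_spring_wrenches",
    "spring_energy",
    "snap_to_terminus",
    "relax_layout",
    "LayoutResult",
]

# direction used for exactly coincident endpoints with L0 > 0 (force
# direction is undefined there; one deterministic nudge breaks the tie)
_TIE_BREAK_DIRECTION = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class SpringConnector:
    """A connector between ``(object id, local attachment point)`` ends."""

    end_a: tuple[str, np.ndarray]
    end_b: tuple[str, np.ndarray]
    stiffness: float = 1.0
    rest_length: float = 0.0
    mode: str = "force"
    id: str = "connector"

    def __post_init__(self) -> None:
        if self.mode not in ("force", "visual"):
            raise ValueError(f"mode must be 'force' or 'visual', got {self.mode!r}")
        if self.rest_length < 0:
            raise ValueError("rest length must be >= 0")
        if self.mode == "force" and self.stiffness <= 0:
            raise ValueError("force-mode springs need positive stiffness")
        for name, end in (("end_a", self.end_a), ("end_b", self.end_b)):
            oid, point = end
            point = np.asarray(point, dtype=float).reshape(3)
            if not np.all(np.isfinite(point)):
                raise ValueError(f"{name} attachment point is non-finite")
            point.setflags(write=False)
            object.__setattr__(self, name, (str(oid), point))

    def world_endpoints(self, scene: Scene) -> tuple[np.ndarray, np.ndarray]:
        pa = scene.require(self.end_a[0]).pose.apply(self.end_a[1])
        pb = scene.require(self.end_b[0]).pose.apply(self.end_b[1])
        return pa, pb

    def length(self, scene: Scene) -> float:
        pa, pb = self.world_endpoints(scene)
        return float(np.linalg.norm(pb - pa))

    def residual(self, scene: Scene) -> float:
        """|current length - rest length| in Angstroms."""
        return abs(self.length(scene) - self.rest_length)


def spring_wrench(
    conn: SpringConnector, scene: Scene
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Hookean wrench on each endpoint object.

    With ``d = world(end_b) - world(end_a)``, the force on A is
    ``k (|d| - L0) d_hat`` (toward B when stretched) and on B its negation;
    torques are attachment-offset cross force.  Visual connectors are
    no-ops.  Forces sum to zero exactly.
    """
    obj_a = scene.require(conn.end_a[0])
    obj_b = scene.require(conn.end_b[0])
    zero = {obj_a.id: (np.zeros(3), np.zeros(3)), obj_b.id: (np.zeros(3), np.zeros(3))}
    if conn.mode == "visual":
        return zero
    pa, pb = conn.world_endpoints(scene)
    d = pb - pa
    length = float(np.linalg.norm(d))
    if length < 1e-12:
        if conn.rest_length <= 0:
            return zero
        direction = _TIE_BREAK_DIRECTION
    else:
        direction = d / length
    f_a = conn.stiffness * (length - conn.rest_length) * direction
    f_b = -f_a
    center_a = obj_a.pose.apply(obj_a.mesh.vertices.mean(axis=0))
    center_b = obj_b.pose.apply(obj_b.mesh.vertices.mean(axis=0))
    tau_a = np.cross(pa - center_a, f_a)
    tau_b = np.cross(pb - center_b, f_b)
    if obj_a.id == obj_b.id:  # self-connector: wrenches cancel on one body
        return {obj_a.id: (f_a + f_b, tau_a + tau_b)}
    return {obj_a.id: (f_a, tau_a), obj_b.id: (f_b, tau_b)}


def total_spring_wrenches(
    connectors: list[SpringConnector], scene: Scene
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    total: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for conn in connectors:
        for oid, (f, tq) in spring_wrench(conn, scene).items():
            f0, t0 = total.get(oid, (np.zeros(3), np.zeros(3)))
            total[oid] = (f0 + f, t0 + tq)
    return total


def spring_energy(connectors: list[SpringConnector], scene: Scene) -> float:
    """Sum of (1/2) k (|d| - L0)^2 over force-mode connectors."""
    e = 0.0
    for conn in connectors:
        if conn.mode == "force":
            e += 0.5 * conn.stiffness * (conn.length(scene) - conn.rest_length) ** 2
    return e


def snap_to_terminus(
    conn: SpringConnector,
    end: str,
    structure: AtomicStructure,
    chain_id: str,
    terminus: str,
) -> SpringConnector:
    """Return a connector with the given end's local attachment point moved
    to the chain's N- or C-terminal alpha-carbon (structure coordinates are
    the object's local frame)."""
    if end not in ("a", "b"):
        raise ValueError(f"end must be 'a' or 'b', got {end!r}")
    point = structure.terminus_position(chain_id, terminus)
    if end == "a":
        return replace(conn, end_a=(conn.end_a[0], point))
    return replace(conn, end_b=(conn.end_b[0], point))


@dataclass
class LayoutResult:
    diagnostics: StepDiagnostics
    residuals: dict[str, float]

    @property
    def max_residual(self) -> float:
        return max(self.residuals.values()) if self.residuals else 0.0


def relax_layout(
    scene: Scene,
    connectors: list[SpringConnector],
    params: PhysicsParams | None = None,
    free_ids: set[str] | None = None,
) -> LayoutResult:
    """Relax spring-connected objects toward the constraint network.

    Every object touched by a force-mode connector (plus any ``free_ids``)
    is treated as manipulated — no tracker targets, only spring wrenches
    and collision response — and stepped until the net wrench converges.
    Infeasible networks do not error: they settle at a force-balance local
    optimum and the per-connector residuals report how far each constraint
    remains from satisfied.
    """
    params = params or PhysicsParams()
    force_conns = [c for c in connectors if c.mode == "force"]
    if not force_conns:
        raise ValueError("relax_layout needs at least one force-mode connector")
    manipulated = set(free_ids or set())
    for conn in force_conns:
        manipulated.add(conn.end_a[0])
        manipulated.add(conn.end_b[0])
    for oid in manipulated:
        scene.require(oid)
    state = ManipulationState(manipulated=manipulated)
    diag = settle(
        scene,
        state,
        params,
        extra_wrench=lambda sc: total_spring_wrenches(force_conns, sc),
    )
    residuals = {c.id: c.residual(scene) for c in connectors if c.mode == "force"}
    return LayoutResult(diag, residuals)
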