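"""BVH-accelerated mesh collision detection with scene-level filtering.

Three layers:

* a vectorized triangle–triangle intersection predicate (separating-axis
  test over the 17 candidate axes of a triangle pair; touching counts as
  colliding);
* per-mesh axis-aligned bounding-box trees built in the mesh's local frame
  and re-bounded under each query pose (:func:`build_bvh`,
  :func:`collide_pair`);
* scene-level queries that exploit structure to skip tests.  In pose mode
  only objects the user moves can change, so only pairs touching a moving
  object are tested — m·n pair queries instead of n² (:func:`scene_collisions`).
  Inside a crystal-by-example chain every consecutive pair shares the same
  relative pose and geometry, so testing copy 1 against copy k+1 answers
  the question for every pair at offset k: n−1 queries cover all internal
  pairs (:func:`chain_internal_collisions`).

Reports carry ``tests_performed`` — the number of object-pair BVH queries,
not triangle tests — so the filtering guarantees are observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meshes import TriangleMesh
from .scene import Scene
from .transforms import RigidTransform

__all__ = [
    "CollisionReport",
    "BoundingVolumeHierarchy",
    "build_bvh",
    "get_bvh",
    "collide_pair",
    "brute_force_pair",
    "scene_collisions",
    "chain_internal_collisions",
    "chain_external_collisions",
    "tri_tri_intersect",
]

_EPS = 1e-9


# ---------------------------------------------------------------------------
# Triangle-triangle predicate (separating axis test)
# ---------------------------------------------------------------------------

def tri_tri_intersect(tri_a: np.ndarray, tri_b: np.ndarray) -> np.ndarray:
    """Closed intersection test for corresponding triangle pairs.

    ``tri_a`` and ``tri_b`` are (N, 3, 3) corner arrays.  Two triangles are
    disjoint iff some axis among {both normals, the 9 edge-edge cross
    products, the 6 in-plane edge normals} strictly separates their
    projections; shared points (touching) therefore count as colliding.
    Returns a boolean (N,) array.
    """
    A = np.asarray(tri_a, dtype=float).reshape(-1, 3, 3)
    B = np.asarray(tri_b, dtype=float).reshape(-1, 3, 3)
    n = len(A)
    if n == 0:
        return np.zeros(0, dtype=bool)

    eA = np.stack([A[:, 1] - A[:, 0], A[:, 2] - A[:, 1], A[:, 0] - A[:, 2]], axis=1)
    eB = np.stack([B[:, 1] - B[:, 0], B[:, 2] - B[:, 1], B[:, 0] - B[:, 2]], axis=1)
    nA = np.cross(eA[:, 0], eA[:, 1])[:, None, :]
    nB = np.cross(eB[:, 0], eB[:, 1])[:, None, :]
    cross_ee = np.cross(eA[:, :, None, :], eB[:, None, :, :]).reshape(n, 9, 3)
    inplane_a = np.cross(np.broadcast_to(nA, eA.shape), eA)
    inplane_b = np.cross(np.broadcast_to(nB, eB.shape), eB)
    axes = np.concatenate([nA, nB, cross_ee, inplane_a, inplane_b], axis=1)  # (n,17,3)

    norms = np.linalg.norm(axes, axis=2)
    valid = norms > 1e-12
    safe = np.where(valid, norms, 1.0)
    axes = axes / safe[:, :, None]

    projA = np.einsum("nkd,nvd->nkv", axes, A)  # (n,17,3)
    projB = np.einsum("nkd,nvd->nkv", axes, B)
    minA, maxA = projA.min(axis=2), projA.max(axis=2)
    minB, maxB = projB.min(axis=2), projB.max(axis=2)
    separated = ((minA > maxB + _EPS) | (minB > maxA + _EPS)) & valid
    return ~separated.any(axis=1)


# ---------------------------------------------------------------------------
# Bounding volume hierarchy
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    lo: np.ndarray
    hi: np.ndarray
    left: int = -1
    right: int = -1
    tris: np.ndarray | None = None  # leaf triangle indices


class BoundingVolumeHierarchy:
    """Axis-aligned box tree over a mesh's triangles, built in the mesh's
    local frame (median split on the longest axis, leaves of <= 4
    triangles).  Parent boxes contain children; leaves partition the face
    set."""

    LEAF_SIZE = 4

    def __init__(self, mesh: TriangleMesh) -> None:
        if mesh.num_faces == 0:
            raise ValueError("cannot build a BVH over an empty mesh")
        self.mesh = mesh
        tris = mesh.triangles()
        self._tri_lo = tris.min(axis=1)
        self._tri_hi = tris.max(axis=1)
        centroids = tris.mean(axis=1)
        self.nodes: list[_Node] = []
        self.root = self._build(np.arange(mesh.num_faces), centroids)

    def _build(self, idx: np.ndarray, centroids: np.ndarray) -> int:
        lo = self._tri_lo[idx].min(axis=0)
        hi = self._tri_hi[idx].max(axis=0)
        node_id = len(self.nodes)
        node = _Node(lo, hi)
        self.nodes.append(node)
        if len(idx) <= self.LEAF_SIZE:
            node.tris = idx
            return node_id
        axis = int(np.argmax(hi - lo))
        order = idx[np.argsort(centroids[idx, axis], kind="stable")]
        half = len(order) // 2
        node.left = self._build(order[:half], centroids)
        node.right = self._build(order[half:], centroids)
        return node_id

    def depth(self) -> int:
        def _d(i: int) -> int:
            node = self.nodes[i]
            if node.tris is not None:
                return 1
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def leaf_triangle_sets(self) -> list[np.ndarray]:
        return [n.tris for n in self.nodes if n.tris is not None]

    def world_bounds(self, pose: RigidTransform) -> tuple[np.ndarray, np.ndarray]:
        """(num_nodes, 3) lo/hi world AABBs: local boxes re-bounded under
        the pose (conservative)."""
        lo = np.array([n.lo for n in self.nodes])
        hi = np.array([n.hi for n in self.nodes])
        # 8 corners of each local box, transformed, then re-bounded.
        corners = np.empty((len(lo), 8, 3))
        for c in range(8):
            sel = [(lo, hi)[(c >> d) & 1][:, d] for d in range(3)]
            corners[:, c, :] = np.stack(sel, axis=1)
        world = corners @ pose.rotation.T + pose.translation
        return world.min(axis=1), world.max(axis=1)


def build_bvh(mesh: TriangleMesh) -> BoundingVolumeHierarchy:
    return BoundingVolumeHierarchy(mesh)


def get_bvh(mesh: TriangleMesh) -> BoundingVolumeHierarchy:
    """Per-mesh cached BVH (meshes are immutable, so caching is safe)."""
    cached = getattr(mesh, "_bvh_cache", None)
    if cached is None:
        cached = build_bvh(mesh)
        object.__setattr__(mesh, "_bvh_cache", cached)
    return cached


def collide_pair(
    bvh_a: BoundingVolumeHierarchy,
    pose_a: RigidTransform,
    bvh_b: BoundingVolumeHierarchy,
    pose_b: RigidTransform,
    mode: str = "all",
) -> list[tuple[int, int]]:
    """World-space triangle-pair contacts between two posed meshes.

    ``mode="all"`` returns every intersecting (face index A, face index B)
    pair; ``mode="first"`` returns at most one contact (empty iff the
    meshes are disjoint).
    """
    if mode not in ("all", "first"):
        raise ValueError(f"mode must be 'all' or 'first', got {mode!r}")
    lo_a, hi_a = bvh_a.world_bounds(pose_a)
    lo_b, hi_b = bvh_b.world_bounds(pose_b)

    pairs: list[tuple[int, int]] = []
    stack = [(bvh_a.root, bvh_b.root)]
    cand_a: list[np.ndarray] = []
    cand_b: list[np.ndarray] = []
    while stack:
        ia, ib = stack.pop()
        if np.any(lo_a[ia] > hi_b[ib] + _EPS) or np.any(lo_b[ib] > hi_a[ia] + _EPS):
            continue
        na, nb = bvh_a.nodes[ia], bvh_b.nodes[ib]
        leaf_a, leaf_b = na.tris is not None, nb.tris is not None
        if leaf_a and leaf_b:
            ga, gb = np.meshgrid(na.tris, nb.tris, indexing="ij")
            cand_a.append(ga.ravel())
            cand_b.append(gb.ravel())
        elif leaf_a or (not leaf_b and (hi_b[ib] - lo_b[ib]).max() > (hi_a[ia] - lo_a[ia]).max()):
            stack.append((ia, nb.left))
            stack.append((ia, nb.right))
        else:
            stack.append((na.left, ib))
            stack.append((na.right, ib))
    if not cand_a:
        return []
    ca = np.concatenate(cand_a)
    cb = np.concatenate(cand_b)
    verts_a = pose_a.apply(bvh_a.mesh.vertices)
    verts_b = pose_b.apply(bvh_b.mesh.vertices)
    tris_a = verts_a[bvh_a.mesh.faces[ca]]
    tris_b = verts_b[bvh_b.mesh.faces[cb]]
    hits = tri_tri_intersect(tris_a, tris_b)
    idx = np.flatnonzero(hits)
    if mode == "first":
        if idx.size == 0:
            return []
        k = idx[0]
        return [(int(ca[k]), int(cb[k]))]
    pairs = [(int(ca[k]), int(cb[k])) for k in idx]
    pairs.sort()
    return pairs


def brute_force_pair(
    mesh_a: TriangleMesh,
    pose_a: RigidTransform,
    mesh_b: TriangleMesh,
    pose_b: RigidTransform,
    chunk: int = 262_144,
) -> list[tuple[int, int]]:
    """Exhaustive all-triangle-pairs contacts (the O(Fa*Fb) reference the
    BVH path is checked against)."""
    verts_a = pose_a.apply(mesh_a.vertices)
    verts_b = pose_b.apply(mesh_b.vertices)
    tris_a = verts_a[mesh_a.faces]
    tris_b = verts_b[mesh_b.faces]
    fa, fb = len(tris_a), len(tris_b)
    ia, ib = np.meshgrid(np.arange(fa), np.arange(fb), indexing="ij")
    ia, ib = ia.ravel(), ib.ravel()
    out: list[tuple[int, int]] = []
    for start in range(0, len(ia), chunk):
        sa = ia[start : start + chunk]
        sb = ib[start : start + chunk]
        hits = tri_tri_intersect(tris_a[sa], tris_b[sb])
        out.extend((int(x), int(y)) for x, y in zip(sa[hits], sb[hits]))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Reports and scene-level queries
# ---------------------------------------------------------------------------

def _norm_pair(a, b) -> tuple:
    return (a, b) if str(a) < str(b) else (b, a)


@dataclass(frozen=True)
class CollisionReport:
    """Colliding object pairs with their triangle-pair contacts and the
    number of object-pair BVH queries performed.

    For pairwise scene queries ``tests_performed >= len(colliding_pairs)``;
    chain-internal reports may list more pairs than tests — that surplus is
    exactly the work the repeated-structure argument saves.
    """

    colliding_pairs: frozenset = field(default_factory=frozenset)
    contacts: dict = field(default_factory=dict)
    tests_performed: int = 0

    def __post_init__(self) -> None:
        if self.tests_performed < 0:
            raise ValueError("tests_performed must be non-negative")
        for pair in self.colliding_pairs:
            if pair not in self.contacts or len(self.contacts[pair]) == 0:
                raise ValueError(f"colliding pair {pair} has no contacts")

    @property
    def num_colliding_pairs(self) -> int:
        return len(self.colliding_pairs)


def scene_collisions(scene: Scene, moving_ids: set | frozenset | list) -> CollisionReport:
    """Pose-mode filtered query: only pairs with at least one moving member
    are tested, so at most m*n pair queries for m moving among n objects.
    Objects not being moved cannot generate new collisions with each other."""
    moving = set(moving_ids)
    for oid in moving:
        scene.require(oid)
    all_ids = sorted(scene.objects)
    tested = set()
    contacts: dict[tuple, list] = {}
    tests = 0
    for mid in sorted(moving):
        for oid in all_ids:
            if oid == mid:
                continue
            pair = _norm_pair(mid, oid)
            if pair in tested:
                continue
            tested.add(pair)
            a, b = scene.objects[pair[0]], scene.objects[pair[1]]
            hits = collide_pair(get_bvh(a.mesh), a.pose, get_bvh(b.mesh), b.pose)
            tests += 1
            if hits:
                contacts[pair] = hits
    return CollisionReport(frozenset(contacts), contacts, tests)


def chain_internal_collisions(chain) -> CollisionReport:
    """Internal contacts of a crystal-by-example chain with n-1 pair tests.

    Copy 1 is tested against copies 2..n.  Because every pair at offset k
    has the identical relative pose and the same geometry, a hit between
    copies (1, k+1) implies hits between (i, i+k) for every i; those
    implied pairs are reported with the representative pair's contact list
    (the relative pose being identical, the contact topology is too).
    Pairs are keyed by 1-based copy index.
    """
    n = chain.n
    if n < 2:
        raise ValueError("chain must have at least 2 copies")
    bvh = get_bvh(chain.base_mesh)
    contacts: dict[tuple, list] = {}
    tests = 0
    for k in range(1, n):
        hits = collide_pair(bvh, chain.pose_of(1), bvh, chain.pose_of(1 + k))
        tests += 1
        if hits:
            for i in range(1, n - k + 1):
                contacts[(i, i + k)] = list(hits)
    return CollisionReport(frozenset(contacts), contacts, tests)


def chain_external_collisions(chain, scene: Scene, exclude: set | None = None) -> CollisionReport:
    """Contacts between chain members and (non-excluded) scene objects.

    Every member must be tested against every external object; no
    repeated-structure shortcut applies because external objects have no
    fixed relation to the chain.  Pairs are (member id string, object id).
    """
    exclude = exclude or set()
    bvh = get_bvh(chain.base_mesh)
    contacts: dict[tuple, list] = {}
    tests = 0
    for i in range(1, chain.n + 1):
        pose_i = chain.pose_of(i)
        for oid in sorted(scene.objects):
            if oid in exclude:
                continue
            obj = scene.objects[oid]
            hits = collide_pair(bvh, pose_i, get_bvh(obj.mesh), obj.pose)
            tests += 1
            if hits:
                contacts[(chain.member_id(i), oid)] = hits
    return CollisionReport(frozenset(contacts), contacts, tests)
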