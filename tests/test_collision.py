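"""Collision detection: predicate correctness, BVH-vs-exhaustive equivalence,
pose-mode filtering, and the chain-internal test reduction."""

import numpy as np
import pytest

from molscene import (
    RigidTransform,
    Scene,
    SceneObject,
    brute_force_pair,
    build_bvh,
    chain_external_collisions,
    chain_from_transform,
    chain_internal_collisions,
    collide_pair,
    make_fixture,
    scene_collisions,
    tri_tri_intersect,
)
from molscene.collision import get_bvh
from molscene.scene import UnknownIdError

I = RigidTransform.identity()


class TestTriTriPredicate:
    """Hand-constructed pairs with known status pin the predicate itself,
    independently of any enumeration or culling strategy."""

    CASES = [
        # (triangle A, triangle B, intersect?)
        # identical triangles
        ([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 0, 0], [1, 0, 0], [0, 1, 0]], True),
        # clearly separated along z
        ([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 0, 5], [1, 0, 5], [0, 1, 5]], False),
        # piercing: B passes through A's interior
        ([[0, 0, 0], [2, 0, 0], [0, 2, 0]], [[0.5, 0.5, -1], [0.5, 0.5, 1], [1.5, 0.5, 0]], True),
        # touching at a single shared vertex (closed test counts it)
        ([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 0, 0], [-1, 0, 0], [0, -1, 0]], True),
        # touching along a shared edge
        ([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 0, 0], [1, 0, 0], [0, 0, -1]], True),
        # coplanar overlapping
        ([[0, 0, 0], [2, 0, 0], [0, 2, 0]], [[0.5, 0.5, 0], [2.5, 0.5, 0], [0.5, 2.5, 0]], True),
        # coplanar disjoint
        ([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[3, 3, 0], [4, 3, 0], [3, 4, 0]], False),
        # parallel planes, small gap
        ([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 0, 1e-6], [1, 0, 1e-6], [0, 1, 1e-6]], False),
        # vertex of B touching A's interior point
        ([[0, 0, 0], [2, 0, 0], [0, 2, 0]], [[0.5, 0.5, 0], [0.5, 0.5, 1], [1.5, 0.5, 1]], True),
        # near miss beside an edge
        ([[0, 0, 0], [2, 0, 0], [0, 2, 0]], [[3, -1, -1], [3, -1, 1], [3, 1, 0]], False),
    ]

    @pytest.mark.parametrize("tri_a,tri_b,expected", CASES)
    def test_known_pairs(self, tri_a, tri_b, expected):
        got = tri_tri_intersect(np.array([tri_a]), np.array([tri_b]))[0]
        assert bool(got) is expected

    @pytest.mark.parametrize("tri_a,tri_b,expected", CASES)
    def test_symmetric(self, tri_a, tri_b, expected):
        ab = tri_tri_intersect(np.array([tri_a]), np.array([tri_b]))[0]
        ba = tri_tri_intersect(np.array([tri_b]), np.array([tri_a]))[0]
        assert bool(ab) == bool(ba) == expected


class TestBvhConstruction:
    def test_single_triangle_single_leaf(self):
        from molscene import TriangleMesh

        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        bvh = build_bvh(mesh)
        leaves = bvh.leaf_triangle_sets()
        assert len(leaves) == 1 and leaves[0].tolist() == [0]

    def test_depth_bound(self, coarse_sphere):
        bvh = build_bvh(coarse_sphere)
        n = coarse_sphere.num_faces
        assert bvh.depth() <= 2 * int(np.ceil(np.log2(n))) + 1

    def test_leaves_partition_faces(self, coarse_sphere):
        bvh = build_bvh(coarse_sphere)
        seen = np.concatenate(bvh.leaf_triangle_sets())
        assert sorted(seen.tolist()) == list(range(coarse_sphere.num_faces))

    def test_parent_contains_children(self, coarse_sphere):
        bvh = build_bvh(coarse_sphere)
        for node in bvh.nodes:
            if node.tris is None:
                for child in (bvh.nodes[node.left], bvh.nodes[node.right]):
                    assert np.all(node.lo <= child.lo + 1e-12)
                    assert np.all(node.hi >= child.hi - 1e-12)

    def test_empty_mesh_rejected(self):
        from molscene import TriangleMesh

        with pytest.raises(ValueError):
            build_bvh(TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int)))


class TestCollidePair:
    def test_separated_spheres(self, coarse_sphere):
        bvh = build_bvh(coarse_sphere)
        assert collide_pair(bvh, I, bvh, RigidTransform.from_translation([3, 0, 0])) == []

    def test_overlapping_spheres(self, coarse_sphere):
        bvh = build_bvh(coarse_sphere)
        hits = collide_pair(bvh, I, bvh, RigidTransform.from_translation([1.5, 0, 0]))
        assert len(hits) > 0

    def test_first_mode(self, coarse_sphere):
        bvh = build_bvh(coarse_sphere)
        near = RigidTransform.from_translation([1.5, 0, 0])
        far = RigidTransform.from_translation([3, 0, 0])
        assert len(collide_pair(bvh, I, bvh, near, mode="first")) == 1
        assert collide_pair(bvh, I, bvh, far, mode="first") == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_oracle(self, seed, coarse_sphere):
        from conftest import random_transform

        rng = np.random.default_rng(seed)
        blob = make_fixture("blob", {"subdivisions": 1}, seed=seed)
        pose_a = random_transform(rng, span=1.0)
        pose_b = random_transform(rng, span=2.0)
        bvh_a, bvh_b = build_bvh(coarse_sphere), build_bvh(blob)
        fast = collide_pair(bvh_a, pose_a, bvh_b, pose_b)
        slow = brute_force_pair(coarse_sphere, pose_a, blob, pose_b)
        assert fast == slow

    def test_symmetry(self, coarse_sphere):
        blob = make_fixture("blob", {}, seed=5)
        pose = RigidTransform.from_translation([0.8, 0.2, 0.1])
        ab = collide_pair(build_bvh(coarse_sphere), I, build_bvh(blob), pose)
        ba = collide_pair(build_bvh(blob), pose, build_bvh(coarse_sphere), I)
        assert sorted((b, a) for a, b in ab) == sorted(ba)


def _random_scene(seed: int, n: int = 6):
    from conftest import random_transform

    rng = np.random.default_rng(seed)
    sc = Scene()
    kinds = ["sphere", "blob", "ellipsoid"]
    for i in range(n):
        kind = kinds[int(rng.integers(len(kinds)))]
        mesh = make_fixture(kind, {"subdivisions": 1}, seed=int(rng.integers(1000)))
        sc.add_object(SceneObject(f"obj{i}", mesh, random_transform(rng, span=2.0)))
    return sc


def _brute_scene_pairs(sc: Scene, restrict_to=None):
    ids = sorted(sc.objects)
    pairs = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if restrict_to is not None and a not in restrict_to and b not in restrict_to:
                continue
            oa, ob = sc.objects[a], sc.objects[b]
            if brute_force_pair(oa.mesh, oa.pose, ob.mesh, ob.pose):
                pairs.add((a, b))
    return pairs


class TestSceneCollisions:
    def test_empty_moving_set(self):
        sc = _random_scene(0)
        rep = scene_collisions(sc, set())
        assert rep.tests_performed == 0 and not rep.colliding_pairs

    def test_single_mover_test_count(self):
        sc = _random_scene(1, n=10)
        rep = scene_collisions(sc, {"obj0"})
        assert rep.tests_performed == 9

    def test_unknown_id_rejected(self):
        sc = _random_scene(2)
        with pytest.raises(UnknownIdError):
            scene_collisions(sc, {"ghost"})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_moving_pairs(self, seed):
        sc = _random_scene(100 + seed, n=8)
        moving = {"obj0", "obj3"}
        rep = scene_collisions(sc, moving)
        assert rep.tests_performed <= len(moving) * len(sc)
        assert set(rep.colliding_pairs) == _brute_scene_pairs(sc, restrict_to=moving)

    def test_mn_bound_grid(self):
        for n in (3, 6, 9):
            sc = _random_scene(500 + n, n=n)
            for m in (1, 2, n):
                moving = {f"obj{i}" for i in range(m)}
                rep = scene_collisions(sc, moving)
                assert rep.tests_performed <= m * n


class TestChainInternal:
    def test_spaced_chain_empty(self, coarse_sphere):
        chain = chain_from_transform(
            coarse_sphere, I, RigidTransform.from_translation([2.5, 0, 0]), 6
        )
        rep = chain_internal_collisions(chain)
        assert rep.tests_performed == 5 and not rep.colliding_pairs

    def test_adjacent_contacts(self, coarse_sphere):
        chain = chain_from_transform(
            coarse_sphere, I, RigidTransform.from_translation([1.5, 0, 0]), 6
        )
        rep = chain_internal_collisions(chain)
        assert rep.tests_performed == 5
        assert set(rep.colliding_pairs) == {(1, 2), (2, 3), (3, 4), (4, 5), (5, 6)}

    def test_tight_helix_implied_pairs_match_brute_force(self, coarse_sphere):
        from molscene.transforms import screw_transform

        # tight screw: copy 1 overlaps copies 2 AND 3
        t_ab = screw_transform([0, 0, 1], np.pi / 6, 0.9)
        chain = chain_from_transform(coarse_sphere, I, t_ab, 6)
        rep = chain_internal_collisions(chain)
        assert rep.tests_performed == 5
        brute = set()
        for i in range(1, 7):
            for j in range(i + 1, 7):
                if brute_force_pair(
                    coarse_sphere, chain.pose_of(i), coarse_sphere, chain.pose_of(j)
                ):
                    brute.add((i, j))
        assert set(rep.colliding_pairs) == brute
        # both offsets present
        offsets = {j - i for i, j in rep.colliding_pairs}
        assert offsets == {1, 2}

    def test_exactly_n_minus_one_tests(self, coarse_sphere):
        for n in (2, 5, 17, 50):
            chain = chain_from_transform(
                coarse_sphere, I, RigidTransform.from_translation([2.5, 0, 0]), n
            )
            assert chain_internal_collisions(chain).tests_performed == n - 1

    def test_short_chain_rejected(self, coarse_sphere):
        with pytest.raises(ValueError):
            chain_from_transform(coarse_sphere, I, RigidTransform.from_translation([2, 0, 0]), 1)


class TestChainExternal:
    def _chain(self, coarse_sphere, n=5):
        return chain_from_transform(
            coarse_sphere, I, RigidTransform.from_translation([2.5, 0, 0]), n
        )

    def test_empty_scene(self, coarse_sphere):
        rep = chain_external_collisions(self._chain(coarse_sphere), Scene())
        assert not rep.colliding_pairs

    def test_single_overlapping_external(self, coarse_sphere):
        sc = Scene()
        # copy 3 sits at x = 5; place an external sphere just touching it
        sc.add_object(
            SceneObject("ext", coarse_sphere, RigidTransform.from_translation([5.0, 1.5, 0]))
        )
        rep = chain_external_collisions(self._chain(coarse_sphere), sc)
        assert set(rep.colliding_pairs) == {("chain[3]", "ext")}

    def test_moved_away_as_unit(self, coarse_sphere):
        from molscene import move_chain

        sc = Scene()
        sc.add_object(SceneObject("ext", coarse_sphere, I))
        chain = move_chain(
            self._chain(coarse_sphere), RigidTransform.from_translation([100, 0, 0])
        )
        rep = chain_external_collisions(chain, sc)
        assert not rep.colliding_pairs


class TestReportInvariants:
    def test_pairs_have_contacts_and_test_accounting(self):
        sc = _random_scene(7, n=6)
        rep = scene_collisions(sc, set(sc.objects))
        assert rep.tests_performed >= len(rep.colliding_pairs)
        for pair in rep.colliding_pairs:
            assert len(rep.contacts[pair]) >= 1

    def test_bvh_cached_per_mesh(self, coarse_sphere):
        assert get_bvh(coarse_sphere) is get_bvh(coarse_sphere)
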