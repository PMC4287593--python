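"""Scene-document JSON round-trips, validation, duplication, group
export/import, and the CLI wrappers."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from molscene import (
    Keyframe,
    RigidTransform,
    SceneDocument,
    SceneObject,
    SceneValidationError,
    SpringConnector,
    duplicate,
    export_group,
    import_group,
    load_scene,
    make_fixture,
    save_scene,
    set_keyframe,
)
from molscene.cli import main as cli_main
from molscene.scene import Group
from molscene.sceneio import ChainSpec, scene_from_dict, scene_to_dict

SPHERE_SRC = {"kind": "fixture", "fixture": "sphere",
              "params": {"radius": 1.0, "subdivisions": 1}, "seed": 0}


def sphere_obj(oid, pos=(0, 0, 0)):
    return SceneObject(
        oid,
        make_fixture("sphere", {"radius": 1.0, "subdivisions": 1}),
        RigidTransform.from_translation(pos),
        mesh_source=dict(SPHERE_SRC),
    )


def example_doc():
    doc = SceneDocument()
    doc.scene.add_object(sphere_obj("a", (1, 2, 3)))
    doc.scene.add_object(sphere_obj("b"))
    doc.scene.add_group(Group("g", ["a", "b"]))
    doc.chains["ch"] = ChainSpec(
        "ch", dict(SPHERE_SRC), RigidTransform.identity(),
        RigidTransform.from_translation([0, 0, 2.75]), 4,
    )
    doc.connectors.append(
        SpringConnector(("a", [0, 0, 0]), ("b", [0.5, 0, 0]), 2.0, 5.0, id="s1")
    )
    set_keyframe(doc.timeline, "a", Keyframe(0.0))
    set_keyframe(
        doc.timeline, "a",
        Keyframe(1.0, RigidTransform.from_translation([2, 0, 0]), color=(1, 0, 0)),
    )
    return doc


class TestRoundTrip:
    def test_empty_scene(self, tmp_path):
        p = tmp_path / "empty.json"
        save_scene(SceneDocument(), p)
        assert scene_to_dict(load_scene(p)) == scene_to_dict(SceneDocument())

    def test_full_document(self, tmp_path):
        doc = example_doc()
        p = tmp_path / "scene.json"
        save_scene(doc, p)
        assert scene_to_dict(load_scene(p)) == scene_to_dict(doc)

    def test_obj_mesh_source_resolved_relative_to_document(self, tmp_path):
        from molscene import save_obj

        mesh = make_fixture("sphere", {"subdivisions": 1})
        save_obj(mesh, tmp_path / "mono.obj")
        doc = SceneDocument()
        obj = sphere_obj("a")
        obj.mesh_source = {"kind": "obj", "path": "mono.obj"}
        doc.scene.add_object(obj)
        save_scene(doc, tmp_path / "scene.json")
        back = load_scene(tmp_path / "scene.json")
        assert back.scene.objects["a"].mesh.num_faces == mesh.num_faces


class TestValidation:
    def test_dangling_connector_reference_named(self):
        d = scene_to_dict(example_doc())
        d["connectors"][0]["end_b"]["object"] = "missing"
        with pytest.raises(SceneValidationError, match="missing"):
            scene_from_dict(d)

    def test_unknown_top_level_key_named(self):
        d = scene_to_dict(example_doc())
        d["surprise"] = 1
        with pytest.raises(SceneValidationError, match="surprise"):
            scene_from_dict(d)

    def test_unknown_object_key_named(self):
        d = scene_to_dict(example_doc())
        d["objects"][0]["shininess"] = 0.5
        with pytest.raises(SceneValidationError, match="shininess"):
            scene_from_dict(d)

    def test_unrecognized_version_rejected(self):
        d = scene_to_dict(example_doc())
        d["version"] = 99
        with pytest.raises(SceneValidationError, match="version"):
            scene_from_dict(d)


class TestDuplicate:
    def test_single_object(self):
        doc = example_doc()
        new_id = duplicate(doc, "a")
        assert len(doc.scene.objects) == 3
        assert doc.scene.objects[new_id].mesh is doc.scene.objects["a"].mesh
        assert doc.timeline.times(new_id) == doc.timeline.times("a")

    def test_group_copy(self):
        doc = example_doc()
        new_gid = duplicate(doc, "g")
        assert len(doc.scene.objects) == 4
        assert len(doc.scene.groups[new_gid].members) == 2

    def test_copy_is_independent(self):
        doc = example_doc()
        new_id = duplicate(doc, "a")
        original_pose = doc.scene.objects["a"].pose
        doc.scene.objects[new_id].pose = RigidTransform.from_translation([50, 0, 0])
        assert doc.scene.objects["a"].pose is original_pose

    def test_unknown_id_rejected(self):
        with pytest.raises(SceneValidationError):
            duplicate(example_doc(), "nope")


class TestGroupExportImport:
    def test_fragment_is_valid_document(self, tmp_path):
        doc = example_doc()
        frag = tmp_path / "frag.json"
        export_group(doc, "g", frag)
        loaded = load_scene(frag)  # must parse under the same schema
        assert len(loaded.scene.objects) == 2

    def test_import_preserves_member_count(self, tmp_path):
        doc = example_doc()
        frag = tmp_path / "frag.json"
        export_group(doc, "g", frag)
        fresh = SceneDocument()
        mapping = import_group(fresh, frag)
        assert len(fresh.scene.objects) == 2
        assert set(mapping) == {"a", "b", "g"}

    def test_import_twice_disjoint_copies(self, tmp_path):
        doc = example_doc()
        frag = tmp_path / "frag.json"
        export_group(doc, "g", frag)
        m1 = import_group(doc, frag)
        m2 = import_group(doc, frag)
        assert set(m1.values()).isdisjoint(m2.values())
        assert len(doc.scene.objects) == 6

    def test_relative_poses_preserved(self, tmp_path):
        from molscene import relative_transform

        doc = example_doc()
        rel_before = relative_transform(
            doc.scene.objects["a"].pose, doc.scene.objects["b"].pose
        )
        frag = tmp_path / "frag.json"
        export_group(doc, "g", frag)
        fresh = SceneDocument()
        mapping = import_group(fresh, frag)
        rel_after = relative_transform(
            fresh.scene.objects[mapping["a"]].pose,
            fresh.scene.objects[mapping["b"]].pose,
        )
        assert rel_before.almost_equal(rel_after, tol=1e-9)


class TestCli:
    def _save(self, tmp_path):
        p = tmp_path / "scene.json"
        save_scene(example_doc(), p)
        return p

    def test_info(self, tmp_path):
        p = self._save(tmp_path)
        res = CliRunner().invoke(cli_main, ["info", "--scene", str(p)])
        assert res.exit_code == 0
        payload = json.loads(res.output)
        assert payload["objects"] == 2 and payload["chains"] == {"ch": 4}

    def test_build_chain_writes_obj_and_manifest(self, tmp_path):
        p = self._save(tmp_path)
        out = tmp_path / "chain.obj"
        man = tmp_path / "man.json"
        res = CliRunner().invoke(cli_main, [
            "build-chain", "--scene", str(p), "--chain", "ch",
            "--out", str(out), "--manifest", str(man),
        ])
        assert res.exit_code == 0
        from molscene import load_obj

        mesh = load_obj(out)
        assert mesh.num_faces == 4 * 80
        poses = json.loads(man.read_text())
        assert len(poses) == 4
        np.testing.assert_allclose(np.array(poses["copy_4"]).reshape(4, 4)[2, 3], 8.25)

    def test_collide_check(self, tmp_path):
        p = self._save(tmp_path)
        res = CliRunner().invoke(cli_main, ["collide-check", "--scene", str(p), "--moving", "a"])
        assert res.exit_code == 0
        payload = json.loads(res.output)
        assert payload["tests_performed"] == 1

    def test_animate_export(self, tmp_path):
        p = self._save(tmp_path)
        out = tmp_path / "frames.jsonl"
        res = CliRunner().invoke(cli_main, [
            "animate-export", "--scene", str(p), "--fps", "24", "--t1", "1.0",
            "--out", str(out),
        ])
        assert res.exit_code == 0
        lines = out.read_text().splitlines()
        assert len(lines) == 25
        first = json.loads(lines[0])
        assert set(first["objects"]) == {"a", "b"}

    def test_validation_error_exit_code(self, tmp_path):
        p = tmp_path / "bad.json"
        d = scene_to_dict(example_doc())
        d["objects"][0]["mystery"] = True
        p.write_text(json.dumps(d))
        res = CliRunner().invoke(cli_main, ["info", "--scene", str(p)])
        assert res.exit_code == 2

    def test_fixture_command(self, tmp_path):
        out = tmp_path / "s.obj"
        res = CliRunner().invoke(cli_main, [
            "fixture", "--kind", "sphere",
            "--params", '{"radius": 2.0, "subdivisions": 1}', "--out", str(out),
        ])
        assert res.exit_code == 0
        from molscene import load_obj

        mesh = load_obj(out)
        assert np.abs(np.linalg.norm(mesh.vertices, axis=1) - 2.0).max() < 1e-6

    def test_place_converges(self, tmp_path):
        p = self._save(tmp_path)
        out = tmp_path / "placed.json"
        res = CliRunner().invoke(cli_main, [
            "place", "--scene", str(p), "--object", "b",
            "--target-translation", "0,8,0", "--out", str(out),
        ])
        assert res.exit_code == 0
        placed = load_scene(out)
        np.testing.assert_allclose(
            placed.scene.objects["b"].pose.translation, [0, 8, 0], atol=1e-2
        )

    def test_relax_reports_residuals(self, tmp_path):
        p = self._save(tmp_path)
        out = tmp_path / "relaxed.json"
        resid = tmp_path / "resid.json"
        res = CliRunner().invoke(cli_main, [
            "relax", "--scene", str(p), "--out", str(out), "--residuals", str(resid),
        ])
        assert res.exit_code == 0
        residuals = json.loads(resid.read_text())
        assert residuals["s1"] < 0.05 * 5.0
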