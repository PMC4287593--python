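"""JSON scene documents: persistence, duplication, and group export/import.

A scene document is a human-diffable JSON file with a mandatory format
version, an object table (each object's mesh given either as an OBJ path,
relative to the document, or as a reproducible fixture spec), groups,
crystal-by-example chain specs, spring connectors, an animation timeline,
and physics parameters.  Poses are 4x4 row-major homogeneous matrices.
Unknown keys are rejected by name and dangling id references are collected
into a single validation error, so a hand-edited file fails loudly rather
than silently dropping state.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .animation import Keyframe, Timeline, set_keyframe
from .crystal import CrystalChain, chain_from_transform
from .meshes import TriangleMesh, load_obj, make_fixture
from .physics import PhysicsParams
from .scene import Group, Scene, SceneObject
from .springs import SpringConnector
from .transforms import RigidTransform

__all__ = [
    "SceneDocument",
    "ChainSpec",
    "SceneValidationError",
    "load_scene",
    "save_scene",
    "scene_to_dict",
    "scene_from_dict",
    "duplicate",
    "export_group",
    "import_group",
]

FORMAT_VERSION = 1


class SceneValidationError(ValueError):
    """A scene document that references missing ids or carries unknown keys."""


def _check_keys(record: dict, allowed: set[str], context: str) -> None:
    unknown = set(record) - allowed
    if unknown:
        names = ", ".join(sorted(unknown))
        raise SceneValidationError(f"unknown key(s) in {context}: {names}")


def _pose_to_list(T: RigidTransform) -> list[float]:
    return [float(x) for x in T.matrix().ravel()]


def _pose_from_list(values, context: str) -> RigidTransform:
    arr = np.asarray(values, dtype=float)
    if arr.size != 16:
        raise SceneValidationError(f"{context}: pose must be 16 numbers (4x4 row-major)")
    return RigidTransform.from_matrix(arr.reshape(4, 4))


@dataclass
class ChainSpec:
    """Serializable crystal chain: monomer mesh source + T_A, T_AB, n."""

    id: str
    base_source: dict
    T_A: RigidTransform
    T_AB: RigidTransform
    n: int

    def materialize(self, base_dir: str = ".") -> CrystalChain:
        mesh = _resolve_mesh(self.base_source, base_dir, context=f"chain {self.id!r}")
        return chain_from_transform(mesh, self.T_A, self.T_AB, self.n, id=self.id)


@dataclass
class SceneDocument:
    scene: Scene = field(default_factory=Scene)
    chains: dict[str, ChainSpec] = field(default_factory=dict)
    connectors: list[SpringConnector] = field(default_factory=list)
    timeline: Timeline = field(default_factory=Timeline)
    physics: PhysicsParams = field(default_factory=PhysicsParams)
    base_dir: str = "."


def _resolve_mesh(source: dict, base_dir: str, context: str) -> TriangleMesh:
    _check_keys(source, {"kind", "fixture", "params", "seed", "path"}, f"{context} mesh source")
    kind = source.get("kind")
    if kind == "fixture":
        return make_fixture(
            source.get("fixture", "sphere"),
            source.get("params", {}),
            seed=int(source.get("seed", 0)),
        )
    if kind == "obj":
        path = source.get("path")
        if path is None:
            raise SceneValidationError(f"{context}: obj mesh source needs a 'path'")
        full = path if os.path.isabs(path) else os.path.join(base_dir, path)
        return load_obj(full)
    raise SceneValidationError(f"{context}: unknown mesh source kind {kind!r}")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_OBJECT_KEYS = {"id", "mesh", "pose", "color", "group", "visible"}
_GROUP_KEYS = {"id", "members"}
_CHAIN_KEYS = {"id", "base", "t_a", "t_ab", "n"}
_CONNECTOR_KEYS = {"id", "end_a", "end_b", "stiffness", "rest_length", "mode"}
_END_KEYS = {"object", "point"}
_KEYFRAME_KEYS = {"time", "pose", "color", "group", "visible"}
_TOP_KEYS = {"version", "objects", "groups", "chains", "connectors", "timeline", "physics"}
_TIMELINE_KEYS = {"duration", "keyframes"}
_PHYSICS_KEYS = {
    "k_translate", "k_rotate", "damping", "response_gain", "dt",
    "penetration_tolerance", "max_iterations", "convergence_threshold",
}


def scene_to_dict(doc: SceneDocument) -> dict:
    objects = []
    for obj in doc.scene.objects.values():
        if obj.mesh_source is None:
            raise SceneValidationError(
                f"object {obj.id!r} has no serializable mesh source"
            )
        objects.append(
            {
                "id": obj.id,
                "mesh": obj.mesh_source,
                "pose": _pose_to_list(obj.pose),
                "color": list(obj.color) if not isinstance(obj.color, str) else obj.color,
                "group": obj.group,
                "visible": obj.visible,
            }
        )
    groups = [{"id": g.id, "members": list(g.members)} for g in doc.scene.groups.values()]
    chains = [
        {
            "id": c.id,
            "base": c.base_source,
            "t_a": _pose_to_list(c.T_A),
            "t_ab": _pose_to_list(c.T_AB),
            "n": c.n,
        }
        for c in doc.chains.values()
    ]
    connectors = [
        {
            "id": c.id,
            "end_a": {"object": c.end_a[0], "point": [float(x) for x in c.end_a[1]]},
            "end_b": {"object": c.end_b[0], "point": [float(x) for x in c.end_b[1]]},
            "stiffness": c.stiffness,
            "rest_length": c.rest_length,
            "mode": c.mode,
        }
        for c in doc.connectors
    ]
    keyframes = {
        oid: [
            {
                "time": k.time,
                "pose": _pose_to_list(k.pose),
                "color": list(k.color) if not isinstance(k.color, str) else k.color,
                "group": k.group,
                "visible": k.visible,
            }
            for k in frames
        ]
        for oid, frames in doc.timeline.keyframes.items()
        if frames
    }
    return {
        "version": FORMAT_VERSION,
        "objects": objects,
        "groups": groups,
        "chains": chains,
        "connectors": connectors,
        "timeline": {"duration": doc.timeline.duration, "keyframes": keyframes},
        "physics": {k: getattr(doc.physics, k) for k in sorted(_PHYSICS_KEYS)},
    }


def scene_from_dict(data: dict, base_dir: str = ".") -> SceneDocument:
    _check_keys(data, _TOP_KEYS, "scene document")
    version = data.get("version")
    if version != FORMAT_VERSION:
        raise SceneValidationError(
            f"unrecognized scene format version {version!r} (expected {FORMAT_VERSION})"
        )
    doc = SceneDocument(base_dir=base_dir)
    dangling: list[str] = []

    for rec in data.get("objects", []):
        _check_keys(rec, _OBJECT_KEYS, f"object {rec.get('id')!r}")
        oid = rec["id"]
        mesh = _resolve_mesh(rec["mesh"], base_dir, context=f"object {oid!r}")
        color = rec.get("color", [0.5, 0.5, 0.5])
        doc.scene.add_object(
            SceneObject(
                id=oid,
                mesh=mesh,
                pose=_pose_from_list(rec.get("pose", np.eye(4).ravel()), f"object {oid!r}"),
                color=color if isinstance(color, str) else tuple(color),
                group=rec.get("group"),
                visible=bool(rec.get("visible", True)),
                mesh_source=copy.deepcopy(rec["mesh"]),
            )
        )

    for rec in data.get("groups", []):
        _check_keys(rec, _GROUP_KEYS, f"group {rec.get('id')!r}")
        missing = [m for m in rec.get("members", []) if m not in doc.scene.objects]
        if missing:
            dangling.extend(f"group {rec['id']!r} -> {m!r}" for m in missing)
            continue
        doc.scene.add_group(Group(rec["id"], list(rec.get("members", []))))

    for rec in data.get("chains", []):
        _check_keys(rec, _CHAIN_KEYS, f"chain {rec.get('id')!r}")
        doc.chains[rec["id"]] = ChainSpec(
            id=rec["id"],
            base_source=copy.deepcopy(rec["base"]),
            T_A=_pose_from_list(rec["t_a"], f"chain {rec['id']!r} t_a"),
            T_AB=_pose_from_list(rec["t_ab"], f"chain {rec['id']!r} t_ab"),
            n=int(rec["n"]),
        )

    for rec in data.get("connectors", []):
        _check_keys(rec, _CONNECTOR_KEYS, f"connector {rec.get('id')!r}")
        ends = []
        missing = []
        for end_name in ("end_a", "end_b"):
            end = rec[end_name]
            _check_keys(end, _END_KEYS, f"connector {rec.get('id')!r} {end_name}")
            if end["object"] not in doc.scene.objects:
                missing.append(f"connector {rec.get('id')!r} -> {end['object']!r}")
            ends.append((end["object"], np.asarray(end["point"], dtype=float)))
        if missing:
            dangling.extend(missing)
            continue
        doc.connectors.append(
            SpringConnector(
                end_a=ends[0],
                end_b=ends[1],
                stiffness=float(rec.get("stiffness", 1.0)),
                rest_length=float(rec.get("rest_length", 0.0)),
                mode=rec.get("mode", "force"),
                id=rec.get("id", "connector"),
            )
        )

    tl = data.get("timeline", {})
    _check_keys(tl, _TIMELINE_KEYS, "timeline")
    doc.timeline.duration = float(tl.get("duration", 0.0))
    for oid, frames in tl.get("keyframes", {}).items():
        if oid not in doc.scene.objects:
            dangling.append(f"timeline -> {oid!r}")
            continue
        for rec in frames:
            _check_keys(rec, _KEYFRAME_KEYS, f"keyframe of {oid!r}")
            color = rec.get("color", [0.5, 0.5, 0.5])
            set_keyframe(
                doc.timeline,
                oid,
                Keyframe(
                    time=float(rec["time"]),
                    pose=_pose_from_list(rec["pose"], f"keyframe of {oid!r}"),
                    color=color if isinstance(color, str) else tuple(color),
                    group=rec.get("group"),
                    visible=bool(rec.get("visible", True)),
                ),
            )

    phys = data.get("physics", {})
    _check_keys(phys, _PHYSICS_KEYS, "physics")
    doc.physics = PhysicsParams(**phys)

    if dangling:
        raise SceneValidationError(
            "dangling id reference(s): " + "; ".join(sorted(dangling))
        )
    return doc


def load_scene(path) -> SceneDocument:
    with open(path) as fh:
        data = json.load(fh)
    return scene_from_dict(data, base_dir=os.path.dirname(os.path.abspath(path)))


def save_scene(doc: SceneDocument, path) -> None:
    with open(path, "w") as fh:
        json.dump(scene_to_dict(doc), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Duplication and group save/import
# ---------------------------------------------------------------------------

def _copy_object(doc: SceneDocument, oid: str, new_id: str, group: str | None) -> None:
    src = doc.scene.require(oid)
    dup = src.copy(new_id)
    dup.group = group
    doc.scene.add_object(dup)
    for kf in doc.timeline.keyframes.get(oid, []):
        set_keyframe(doc.timeline, new_id, kf)


def duplicate(doc: SceneDocument, target_id: str) -> str:
    """Deep-copy an object or group (recursively, members included) under
    fresh ids; poses and keyframes are copied and the copy is fully
    independent of the original.  Returns the new top-level id."""
    if target_id in doc.scene.objects:
        new_id = doc.scene.fresh_id(target_id)
        _copy_object(doc, target_id, new_id, group=None)
        return new_id
    if target_id in doc.scene.groups:
        group = doc.scene.groups[target_id]
        new_gid = doc.scene.fresh_id(target_id)
        new_members = []
        for member in group.members:
            new_mid = doc.scene.fresh_id(member)
            _copy_object(doc, member, new_mid, group=new_gid)
            new_members.append(new_mid)
        doc.scene.add_group(Group(new_gid, new_members))
        return new_gid
    raise SceneValidationError(f"unknown object or group id {target_id!r}")


def export_group(doc: SceneDocument, group_id: str, path) -> None:
    """Write a group and its members as a standalone, re-importable scene
    document fragment."""
    group = doc.scene.require_group(group_id)
    frag = SceneDocument(base_dir=doc.base_dir, physics=doc.physics)
    for member in group.members:
        obj = doc.scene.require(member)
        frag.scene.add_object(obj.copy(member))
        for kf in doc.timeline.keyframes.get(member, []):
            set_keyframe(frag.timeline, member, kf)
    frag.scene.add_group(Group(group.id, list(group.members)))
    save_scene(frag, path)


def import_group(doc: SceneDocument, path) -> dict[str, str]:
    """Merge a fragment file into the document.  Colliding ids are remapped
    to fresh ones (never overwritten); returns the old-id -> new-id map."""
    frag = load_scene(path)
    mapping: dict[str, str] = {}
    for oid in frag.scene.objects:
        mapping[oid] = doc.scene.fresh_id(oid)
    for gid in frag.scene.groups:
        mapping[gid] = doc.scene.fresh_id(gid)
    for oid, obj in frag.scene.objects.items():
        dup = obj.copy(mapping[oid])
        dup.group = mapping.get(obj.group) if obj.group else None
        doc.scene.add_object(dup)
        for kf in frag.timeline.keyframes.get(oid, []):
            set_keyframe(doc.timeline, mapping[oid], kf)
    for gid, group in frag.scene.groups.items():
        doc.scene.add_group(Group(mapping[gid], [mapping[m] for m in group.members]))
    return mapping
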