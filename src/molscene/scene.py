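"""Scene graph: rigid mesh instances, groups, and lookups.

A :class:`Scene` is a flat table of :class:`SceneObject` instances (a shared
mesh plus a world pose, a display color, and optional group membership) and
a table of :class:`Group` records.  Everything downstream — collision
queries, pose-mode physics, spring layout, animation sampling — operates on
this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .meshes import TriangleMesh
from .transforms import RigidTransform

__all__ = ["SceneObject", "Group", "Scene", "UnknownIdError"]


class UnknownIdError(KeyError):
    """An object or group id that does not resolve in the scene."""


@dataclass
class SceneObject:
    """A rigid instance of a mesh with a world pose."""

    id: str
    mesh: TriangleMesh
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    color: tuple[float, float, float] = (0.5, 0.5, 0.5)
    group: str | None = None
    visible: bool = True
    # provenance for serialization: {"kind": "fixture"|"obj", ...}
    mesh_source: dict | None = None

    def copy(self, new_id: str) -> "SceneObject":
        return replace(self, id=new_id)


@dataclass
class Group:
    id: str
    members: list[str] = field(default_factory=list)


class Scene:
    """Mutable container of objects and groups with id lookup."""

    def __init__(self) -> None:
        self.objects: dict[str, SceneObject] = {}
        self.groups: dict[str, Group] = {}

    def add_object(self, obj: SceneObject) -> SceneObject:
        if obj.id in self.objects:
            raise ValueError(f"duplicate object id {obj.id!r}")
        self.objects[obj.id] = obj
        return obj

    def add_group(self, group: Group) -> Group:
        if group.id in self.groups:
            raise ValueError(f"duplicate group id {group.id!r}")
        for m in group.members:
            self.require(m)
        self.groups[group.id] = group
        for m in group.members:
            self.objects[m].group = group.id
        return group

    def require(self, object_id: str) -> SceneObject:
        try:
            return self.objects[object_id]
        except KeyError:
            raise UnknownIdError(f"unknown object id {object_id!r}") from None

    def require_group(self, group_id: str) -> Group:
        try:
            return self.groups[group_id]
        except KeyError:
            raise UnknownIdError(f"unknown group id {group_id!r}") from None

    def fresh_id(self, base: str) -> str:
        if base not in self.objects and base not in self.groups:
            return base
        k = 1
        while f"{base}_{k}" in self.objects or f"{base}_{k}" in self.groups:
            k += 1
        return f"{base}_{k}"

    def ids(self) -> list[str]:
        return list(self.objects)

    def __len__(self) -> int:
        return len(self.objects)
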