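"""Crystal-by-example: replicate one monomer into a repeated structure.

Place two copies of a monomer, A and B, with world poses ``T_A`` and
``T_B``.  The relative transform ``T_AB = T_A^-1 T_B`` — B expressed in A's
local frame — defines the packing geometry; applying it repeatedly
generates the whole chain:

    T_i = T_A * T_AB^(i-1),   i = 1 .. n   (copies numbered from 1)

Every consecutive pair then has the same relative transform, which is what
makes the chain a discrete helix when ``T_AB`` is a screw motion (actin,
fibrin protofibrils, microtubule protofilaments all pack this way), and is
also what the collision module exploits to test internal contacts with only
n-1 pairwise queries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .meshes import TriangleMesh
from .transforms import (
    RigidTransform,
    ScrewParameters,
    compose,
    relative_transform,
    screw_decompose,
    transform_power,
)

__all__ = [
    "CrystalChain",
    "chain_from_pair",
    "chain_from_transform",
    "set_internal_transform",
    "move_chain",
    "describe_helix",
]


@dataclass(frozen=True)
class CrystalChain:
    """A replicated structure: one mesh, ``n`` derived poses.

    Copies are numbered 1..n in the public API (:meth:`pose_of`); the
    ``copy_poses`` list is 0-based.
    """

    base_mesh: TriangleMesh
    T_A: RigidTransform
    T_AB: RigidTransform
    n: int
    id: str = "chain"
    copy_poses: list[RigidTransform] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"a chain needs at least 2 copies, got n={self.n}")
        if self.T_AB.almost_equal(RigidTransform.identity(), tol=1e-12):
            warnings.warn(
                "inter-copy transform is the identity: all copies coincide",
                stacklevel=3,
            )
        poses = _generate_poses(self.T_A, self.T_AB, self.n)
        object.__setattr__(self, "copy_poses", poses)

    def pose_of(self, i: int) -> RigidTransform:
        """World pose of copy ``i`` (1-based)."""
        if not 1 <= i <= self.n:
            raise IndexError(f"copy index {i} outside 1..{self.n}")
        return self.copy_poses[i - 1]

    def member_id(self, i: int) -> str:
        return f"{self.id}[{i}]"


def _generate_poses(T_A: RigidTransform, T_AB: RigidTransform, n: int) -> list[RigidTransform]:
    poses = [T_A]
    for _ in range(n - 1):
        poses.append(compose(poses[-1], T_AB))
    return poses


def chain_from_pair(
    base_mesh: TriangleMesh,
    TA: RigidTransform,
    TB: RigidTransform,
    n: int,
    id: str = "chain",
) -> CrystalChain:
    """Build a chain from the poses of the first two copies (the
    by-example gesture: copy i+1 sits relative to copy i exactly as B sits
    relative to A)."""
    if n < 2:
        raise ValueError(f"a chain needs at least 2 copies, got n={n}")
    return CrystalChain(base_mesh, TA, relative_transform(TA, TB), n, id=id)


def chain_from_transform(
    base_mesh: TriangleMesh,
    TA: RigidTransform,
    T_AB: RigidTransform,
    n: int,
    id: str = "chain",
) -> CrystalChain:
    """Build a chain from a directly entered inter-copy transform (for
    structures whose monomer-to-monomer transform is known, e.g. from
    crystallographic symmetry)."""
    return CrystalChain(base_mesh, TA, T_AB, n, id=id)


def set_internal_transform(chain: CrystalChain, T_AB: RigidTransform) -> CrystalChain:
    """Replace the inter-copy transform; all downstream copies regenerate
    (the live-update path while the packing is being adjusted)."""
    return CrystalChain(chain.base_mesh, chain.T_A, T_AB, chain.n, id=chain.id)


def move_chain(chain: CrystalChain, T: RigidTransform) -> CrystalChain:
    """Rigidly move the whole structure as a unit: every copy pose is
    left-multiplied by ``T``; the internal geometry is untouched."""
    return CrystalChain(chain.base_mesh, compose(T, chain.T_A), chain.T_AB, chain.n, id=chain.id)


def describe_helix(chain: CrystalChain) -> ScrewParameters:
    """Screw parameters (twist, rise, axis) of the repeat transform."""
    return screw_decompose(chain.T_AB)


def relative_copy_transform(chain: CrystalChain, i: int, j: int) -> RigidTransform:
    """T_{i,j}: the transform from copy i's frame to copy j's (1-based,
    j >= i).  Equals T_AB^(j-i) by the chain law."""
    if j < i:
        raise ValueError("requires j >= i")
    return transform_power(chain.T_AB, j - i)
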