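"""Atomic structures: a Gaussian-density molecular surface and terminus
snapping for connectors.

Builds a tiny synthetic peptide-like structure in memory, triangulates its
probe-inflated Gaussian envelope (the stand-in for a solvent-excluded
surface), and snaps a spring connector end to the chain's C-terminal
alpha-carbon — the anchor a disordered-linker connector would use.
"""

import numpy as np

from molscene import SpringConnector, compute_obb, surface_from_atoms
from molscene.meshes import structure_from_arrays
from molscene.springs import snap_to_terminus

# synthetic 3-residue backbone trace (N, CA, C per residue)
structure = structure_from_arrays(
    element=["N", "C", "C", "N", "C", "C", "N", "C", "C"],
    chain_id=["A"] * 9,
    res_id=[1, 1, 1, 2, 2, 2, 3, 3, 3],
    atom_name=["N", "CA", "C"] * 3,
    coord=[
        [0.0, 0.0, 0.0], [1.46, 0.0, 0.0], [2.01, 1.42, 0.0],
        [3.33, 1.54, 0.0], [3.99, 2.83, 0.0], [5.50, 2.71, 0.0],
        [6.19, 3.84, 0.0], [7.65, 3.84, 0.0], [8.19, 5.26, 0.0],
    ],
)

mesh = surface_from_atoms(structure, probe_radius=1.4, grid_spacing=0.4)
obb = compute_obb(mesh)
print(f"surface: {mesh.num_vertices} vertices, {mesh.num_faces} faces, "
      f"watertight={mesh.is_watertight()}")
print(f"bounding box half-extents: {np.round(obb.half_extents, 2)} A")

conn = SpringConnector(("pep", [0, 0, 0]), ("other", [0, 0, 0]), rest_length=12.0)
conn = snap_to_terminus(conn, "a", structure, "A", "C")
print(f"connector end snapped to C-terminal CA at {conn.end_a[1]} A")
# the attachment is in the object's local (structure) frame; the world
# position follows the object's pose automatically
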