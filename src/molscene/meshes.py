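"""Triangle-mesh surfaces, oriented bounding boxes, fixtures, and OBJ/PDB I/O.

Molecules are represented as rigid triangle meshes approximating their
solvent-excluded surface.  Real structures enter either as Wavefront OBJ
meshes exported by an external surfacing tool, or as PDB atomic structures
from which :func:`surface_from_atoms` builds a Gaussian-density isosurface —
a documented stand-in for the true Connolly surface.  A fixture generator
(:func:`make_fixture`) produces spheres, ellipsoids, and seeded random blob
"monomers" so tests and examples never need a download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh.creation
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.measure import marching_cubes

__all__ = [
    "TriangleMesh",
    "OrientedBoundingBox",
    "AtomicStructure",
    "OBJParseError",
    "DegenerateGeometryError",
    "EmptyStructureError",
    "load_obj",
    "save_obj",
    "load_pdb",
    "structure_from_arrays",
    "surface_from_atoms",
    "compute_obb",
    "make_fixture",
    "VDW_RADII",
]


class OBJParseError(ValueError):
    """Malformed OBJ content; the message names the offending line."""


class DegenerateGeometryError(ValueError):
    """Geometry too degenerate for the requested operation."""


class EmptyStructureError(ValueError):
    """A PDB file with no ATOM/HETATM records."""


# Bondi van der Waals radii (Angstroms) for the elements that dominate
# protein structures; unknown elements fall back to carbon.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "FE": 2.00, "ZN": 1.39,
    "MG": 1.73, "CA": 2.31, "NA": 2.27, "K": 2.75,
}
_DEFAULT_RADIUS = 1.70


@dataclass(frozen=True)
class TriangleMesh:
    """An indexed triangle mesh: ``vertices`` (N, 3) in Angstroms and
    ``faces`` (M, 3) vertex-index triples (0-based, counter-clockwise
    winding gives outward normals for all fixtures)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(v)):
            raise ValueError("mesh vertices contain non-finite coordinates")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face index out of range")
        if f.size and np.any(
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ):
            raise ValueError("degenerate face (repeated vertex index)")
        v.setflags(write=False)
        f.setflags(write=False)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def num_vertices(self) -> int:
        return len(self.vertices)

    @property
    def num_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(M, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        """Unit normals following the winding order."""
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        norms = np.linalg.norm(n, axis=1)
        norms[norms == 0] = 1.0
        return n / norms[:, None]

    def volume(self) -> float:
        """Signed enclosed volume by the divergence theorem (positive for
        outward winding)."""
        t = self.triangles()
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def is_watertight(self) -> bool:
        """True iff every undirected edge is shared by exactly two faces."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def connected_component_count(self) -> int:
        i = np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]])
        j = np.concatenate([self.faces[:, 1], self.faces[:, 2], self.faces[:, 0]])
        adj = coo_matrix(
            (np.ones(len(i)), (i, j)), shape=(self.num_vertices, self.num_vertices)
        )
        n, _ = connected_components(adj, directed=False)
        return int(n)


@dataclass(frozen=True)
class OrientedBoundingBox:
    """A box aligned to a mesh's principal axes: ``axes`` columns are the
    box's local x/y/z directions (orthonormal, det +1)."""

    center: np.ndarray
    axes: np.ndarray
    half_extents: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        A = np.asarray(self.axes, dtype=float).reshape(3, 3)
        h = np.asarray(self.half_extents, dtype=float).reshape(3)
        if np.abs(A.T @ A - np.eye(3)).max() > 1e-9 or abs(np.linalg.det(A) - 1) > 1e-9:
            raise ValueError("OBB axes must be orthonormal with determinant +1")
        if np.any(h <= 0):
            raise ValueError("half extents must be positive")
        for arr in (c, A, h):
            arr.setflags(write=False)
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "axes", A)
        object.__setattr__(self, "half_extents", h)

    def volume(self) -> float:
        return float(8.0 * np.prod(self.half_extents))

    def contains(self, points, tol: float = 1e-6) -> np.ndarray:
        local = (np.atleast_2d(points) - self.center) @ self.axes
        return np.all(np.abs(local) <= self.half_extents + tol, axis=1)


@dataclass(frozen=True)
class AtomicStructure:
    """Per-atom records from a PDB file (first model, altloc ' '/'A' only)."""

    element: np.ndarray  # (N,) str
    chain_id: np.ndarray  # (N,) str
    res_id: np.ndarray  # (N,) int
    atom_name: np.ndarray  # (N,) str
    coord: np.ndarray  # (N, 3) float, Angstroms

    @property
    def num_atoms(self) -> int:
        return len(self.coord)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def terminal_ca_indices(self, chain: str) -> tuple[int, int]:
        """Indices of the first and last alpha-carbon of ``chain`` in record
        order — the N- and C-terminus attachment points."""
        mask = (self.chain_id == chain) & (self.atom_name == "CA")
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"chain {chain!r} has no alpha-carbon atoms")
        return int(idx[0]), int(idx[-1])

    def terminus_position(self, chain: str, terminus: str) -> np.ndarray:
        first, last = self.terminal_ca_indices(chain)
        if terminus.upper() == "N":
            return self.coord[first]
        if terminus.upper() == "C":
            return self.coord[last]
        raise ValueError(f"terminus must be 'N' or 'C', got {terminus!r}")

    def radii(self, probe: float = 0.0) -> np.ndarray:
        return np.array(
            [VDW_RADII.get(str(e).upper(), _DEFAULT_RADIUS) + probe for e in self.element]
        )


def structure_from_arrays(element, chain_id, res_id, atom_name, coord) -> AtomicStructure:
    element = np.asarray(element, dtype="U4")
    chain_id = np.asarray(chain_id, dtype="U4")
    res_id = np.asarray(res_id, dtype=np.int64)
    atom_name = np.asarray(atom_name, dtype="U6")
    coord = np.asarray(coord, dtype=float).reshape(-1, 3)
    if len(coord) == 0:
        raise EmptyStructureError("structure has no atoms")
    for arr in (element, chain_id, res_id, atom_name, coord):
        arr.setflags(write=False)
    return AtomicStructure(element, chain_id, res_id, atom_name, coord)


# ---------------------------------------------------------------------------
# OBJ I/O (minimal dialect: "v x y z" and "f i j k" lines only)
# ---------------------------------------------------------------------------

def save_obj(mesh: TriangleMesh, path) -> None:
    """Write vertices to 9 significant digits and faces with 1-based indices."""
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def load_obj(path) -> TriangleMesh:
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise OBJParseError(f"line {lineno}: vertex needs 3 coordinates: {line!r}")
                try:
                    vertices.append([float(x) for x in parts[1:4]])
                except ValueError as exc:
                    raise OBJParseError(f"line {lineno}: bad vertex coordinate: {line!r}") from exc
            elif tag == "f":
                if len(parts) != 4:
                    raise OBJParseError(
                        f"line {lineno}: only triangular faces supported: {line!r}"
                    )
                idx = []
                for token in parts[1:]:
                    head = token.split("/")[0]  # normals/texcoords ignored
                    try:
                        i = int(head)
                    except ValueError as exc:
                        raise OBJParseError(f"line {lineno}: bad face index: {line!r}") from exc
                    if i == 0:
                        raise OBJParseError(f"line {lineno}: OBJ face indices are 1-based")
                    idx.append(i - 1 if i > 0 else len(vertices) + i)
                faces.append(idx)
            # all other tags (vn, vt, o, g, s, usemtl, ...) are ignored
    f = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    if f.size and (f.min() < 0 or f.max() >= len(vertices)):
        bad = int(f.max()) + 1
        raise OBJParseError(f"face index {bad} out of range for {len(vertices)} vertices")
    return TriangleMesh(np.asarray(vertices, dtype=float).reshape(-1, 3), f)


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def load_pdb(path) -> AtomicStructure:
    """Parse fixed-column ATOM/HETATM records via biotite.

    Dialect: first MODEL only; alternate locations other than ' '/'A'
    dropped; atom count equals retained records.
    """
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(path))
    try:
        atoms = pdb_file.get_structure(model=1, altloc="all")
    except Exception as exc:
        raise EmptyStructureError(f"no parsable ATOM records in {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"no ATOM/HETATM records in {path}")
    altloc = atoms.get_annotation("altloc_id")
    keep = np.isin(altloc, ["", " ", ".", "A"])
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"no atoms with altloc ' '/'A' in {path}")
    return structure_from_arrays(
        atoms.element, atoms.chain_id, atoms.res_id, atoms.atom_name, atoms.coord
    )


# ---------------------------------------------------------------------------
# Gaussian-density isosurface (simplified solvent-excluded surface stand-in)
# ---------------------------------------------------------------------------

def surface_from_atoms(
    structure: AtomicStructure,
    probe_radius: float = 1.4,
    grid_spacing: float = 0.5,
    sigma: float = 1.2,
) -> TriangleMesh:
    """Triangulate the isosurface of ``sum_i exp(-(|p - c_i|^2 - R_i^2) / sigma^2)``
    at level 1, with ``R_i = vdW_i + probe_radius``.

    For a single atom the level-1 surface sits exactly at radius ``R_i``;
    for clusters the Gaussians blend, giving a smooth envelope that stands in
    for the probe-rolled Connolly surface.  ``sigma`` (Angstroms) controls
    the blend sharpness.
    """
    if structure.num_atoms < 1:
        raise EmptyStructureError("structure has no atoms")
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    centers = structure.coord
    radii = structure.radii(probe=probe_radius)
    pad = radii.max() + 3.0 * sigma
    lo = centers.min(axis=0) - pad
    hi = centers.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / grid_spacing).astype(int) + 1, 2)
    axes = [lo[d] + grid_spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    density = np.zeros(len(grid))
    s2 = sigma * sigma
    chunk = 200_000
    for start in range(0, len(grid), chunk):
        block = grid[start : start + chunk]
        d2 = ((block[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        expo = np.clip(-(d2 - radii[None, :] ** 2) / s2, -60.0, 60.0)
        density[start : start + chunk] = np.exp(expo).sum(axis=1)
    density = density.reshape(shape)

    if density.max() < 1.0:
        raise DegenerateGeometryError(
            f"grid spacing {grid_spacing} too coarse to resolve any atom"
        )
    verts, faces, _, _ = marching_cubes(density, level=1.0, spacing=(grid_spacing,) * 3)
    verts = verts + lo
    return TriangleMesh(verts, faces)


# ---------------------------------------------------------------------------
# Oriented bounding box (principal-axes PCA)
# ---------------------------------------------------------------------------

def compute_obb(mesh: TriangleMesh) -> OrientedBoundingBox:
    """PCA box: axes are vertex-covariance eigenvectors (descending
    eigenvalue; ties broken by axis index), extents from the projection
    range.  Not the minimum-volume box."""
    v = mesh.vertices
    if len(v) < 3:
        raise DegenerateGeometryError("OBB requires at least 3 vertices")
    centered = v - v.mean(axis=0)
    cov = centered.T @ centered / len(v)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(-evals, kind="stable")
    evals, axes = evals[order], evecs[:, order]
    if evals[1] < 1e-18 * max(evals[0], 1.0):
        raise DegenerateGeometryError("mesh vertices are collinear")
    # Deterministic sign: make the largest-magnitude component of each axis
    # positive, then fix handedness on the last axis.
    for k in range(3):
        lead = np.argmax(np.abs(axes[:, k]))
        if axes[lead, k] < 0:
            axes[:, k] = -axes[:, k]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    local = v @ axes
    lo, hi = local.min(axis=0), local.max(axis=0)
    half = np.maximum((hi - lo) / 2.0, 1e-9)
    center = axes @ ((lo + hi) / 2.0)
    return OrientedBoundingBox(center, axes, half)


# ---------------------------------------------------------------------------
# Fixture meshes
# ---------------------------------------------------------------------------

def make_fixture(kind: str, params: dict | None = None, seed: int = 0) -> TriangleMesh:
    """Generate a synthetic molecular-surface stand-in.

    kinds:
      ``sphere``    — icosphere; params: radius (default 1), subdivisions (2)
      ``ellipsoid`` — scaled icosphere; params: radii (3-tuple), subdivisions
      ``blob``      — ellipsoid with smooth seeded radial noise; params:
                      radii, subdivisions, amplitude (default 0.15)
      ``box``       — axis-aligned box (walls/obstacles); params: extents
                      (3-tuple, default (1,1,1)), center (default origin)

    Deterministic for a fixed seed.
    """
    params = dict(params or {})
    if kind == "box":
        extents = np.asarray(params.pop("extents", (1.0, 1.0, 1.0)), dtype=float)
        center = np.asarray(params.pop("center", (0.0, 0.0, 0.0)), dtype=float)
        if np.any(extents <= 0):
            raise ValueError("box extents must be positive")
        m = trimesh.creation.box(extents=extents)
        return TriangleMesh(np.asarray(m.vertices) + center, np.asarray(m.faces))
    if kind == "sphere":
        radius = float(params.pop("radius", 1.0))
        sub = int(params.pop("subdivisions", 2))
        if radius <= 0:
            raise ValueError("sphere radius must be positive")
        m = trimesh.creation.icosphere(subdivisions=sub, radius=radius)
        return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces))
    if kind == "ellipsoid":
        radii = np.asarray(params.pop("radii", (1.0, 1.5, 2.0)), dtype=float)
        sub = int(params.pop("subdivisions", 2))
        if np.any(radii <= 0):
            raise ValueError("ellipsoid radii must be positive")
        m = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
        return TriangleMesh(np.asarray(m.vertices) * radii, np.asarray(m.faces))
    if kind == "blob":
        rng = np.random.default_rng(seed)
        radii = np.asarray(params.pop("radii", (1.0, 1.3, 1.7)), dtype=float)
        sub = int(params.pop("subdivisions", 2))
        amplitude = float(params.pop("amplitude", 0.15))
        m = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
        v = np.asarray(m.vertices)
        # Smooth low-frequency radial noise: a few random plane waves on the
        # unit sphere keep the surface wobbly but star-shaped.
        bump = np.zeros(len(v))
        for _ in range(4):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            freq = rng.uniform(1.0, 3.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            bump += rng.uniform(0.3, 1.0) * np.sin(freq * (v @ direction) * np.pi + phase)
        bump /= max(np.abs(bump).max(), 1e-12)
        v = v * (1.0 + amplitude * bump)[:, None] * radii
        return TriangleMesh(v, np.asarray(m.faces))
    raise ValueError(f"unknown fixture kind {kind!r}")
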