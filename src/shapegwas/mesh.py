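"""Triangle-mesh container, validation, IO and elementary geometry.

A closed, consistently oriented 2-manifold triangle mesh is the input of the
spectral shape descriptor.  Validation is strict: the Laplace-Beltrami
eigenproblem assumes a closed surface (every edge shared by exactly two
faces) with outward orientation, and a disconnected or open mesh silently
corrupts the spectrum (extra or shifted zero modes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TriangleMesh",
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "mesh_volume",
    "mesh_area",
]


class MeshValidationError(ValueError):
    """Raised when a mesh violates the closed-manifold contract."""


@dataclass(frozen=True)
class TriangleMesh:
    """Closed oriented triangle mesh.

    Parameters
    ----------
    vertices : (n_vertices, 3) float array
        Coordinates in millimetres.
    faces : (n_faces, 3) int array
        0-based vertex indices with consistent (outward) winding.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshValidationError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshValidationError(f"faces must be (m, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshValidationError("face indices out of vertex range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_areas(self) -> np.ndarray:
        p0, p1, p2 = (self.vertices[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)

    def validate(self, require_closed: bool = True) -> None:
        """Check the closed-manifold invariants, raising with counts."""
        validate_mesh(self, require_closed=require_closed)


def _edge_counts(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    undirected = np.sort(edges, axis=1)
    uniq, counts = np.unique(undirected, axis=0, return_counts=True)
    return uniq, counts


def validate_mesh(mesh: TriangleMesh, require_closed: bool = True) -> None:
    """Validate closedness, orientation consistency and non-degeneracy.

    Raises
    ------
    MeshValidationError
        Naming the violated invariant and the number of offending elements.
    """
    if mesh.n_faces == 0:
        raise MeshValidationError("mesh has no faces")
    areas = mesh.triangle_areas()
    scale = float(np.linalg.norm(np.ptp(mesh.vertices, axis=0)))
    n_degenerate = int(np.sum(areas < 1e-14 * max(scale, 1.0) ** 2))
    if n_degenerate:
        raise MeshValidationError(f"{n_degenerate} zero-area (degenerate) faces")

    uniq, counts = _edge_counts(mesh.faces)
    if require_closed:
        n_boundary = int(np.sum(counts == 1))
        n_nonmanifold = int(np.sum(counts > 2))
        if n_boundary:
            raise MeshValidationError(
                f"open manifold: {n_boundary} boundary edges (each edge must "
                "be shared by exactly 2 faces)"
            )
        if n_nonmanifold:
            raise MeshValidationError(
                f"non-manifold: {n_nonmanifold} edges shared by >2 faces"
            )
        # consistent winding: each undirected edge must appear once in each
        # direction among the directed half-edges
        directed = np.vstack(
            [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
        )
        d_uniq, d_counts = np.unique(directed, axis=0, return_counts=True)
        n_repeated = int(np.sum(d_counts > 1))
        if n_repeated:
            raise MeshValidationError(
                f"inconsistent winding: {n_repeated} directed edges repeated"
            )
        # connectedness: a disconnected surface has a multiplicity-2 zero mode
        import scipy.sparse as sp
        import scipy.sparse.csgraph as csgraph

        rows = uniq[:, 0]
        cols = uniq[:, 1]
        adj = sp.coo_matrix(
            (np.ones(len(uniq)), (rows, cols)),
            shape=(mesh.n_vertices, mesh.n_vertices),
        )
        n_comp, _ = csgraph.connected_components(adj, directed=False)
        if n_comp != 1:
            raise MeshValidationError(
                f"disconnected surface: {n_comp} connected components"
            )


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (mm^3) by the divergence theorem.

    Sum of signed tetrahedra spanned by the origin and each face; positive
    for outward-oriented closed surfaces.
    """
    p0, p1, p2 = (mesh.vertices[mesh.faces[:, i]] for i in range(3))
    vol = float(np.einsum("ij,ij->", p0, np.cross(p1, p2)) / 6.0)
    if vol <= 0:
        raise MeshValidationError(
            f"signed volume {vol:.4g} <= 0: faces appear inward-oriented; "
            "flip the winding before computing the spectrum"
        )
    return vol


def mesh_area(mesh: TriangleMesh) -> float:
    """Total surface area (mm^2)."""
    return float(mesh.triangle_areas().sum())


_FORMATS = ("off", "ply", "fs")


def read_mesh(path: str | Path, fmt: str | None = None) -> TriangleMesh:
    """Read and validate a closed surface from OFF, PLY or FreeSurfer file.

    ``fmt`` is inferred from the suffix when omitted (``.off``, ``.ply``;
    anything else is tried as a FreeSurfer binary surface).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = suffix if suffix in ("off", "ply") else "fs"
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "fs":
        from nibabel.freesurfer.io import read_geometry

        vertices, faces = read_geometry(str(path))
        mesh = TriangleMesh(np.asarray(vertices), np.asarray(faces))
    else:
        tm = _trimesh.load(str(path), file_type=fmt, process=False)
        mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    mesh.validate()
    return mesh


def write_mesh(mesh: TriangleMesh, path: str | Path, fmt: str | None = None) -> None:
    """Write a mesh as OFF or PLY (format inferred from suffix by default)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    if fmt not in ("off", "ply"):
        raise ValueError(f"unsupported output format {fmt!r}")
    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path), file_type=fmt)
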