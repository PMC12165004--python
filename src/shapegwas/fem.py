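"""Linear (P1) finite-element discretization of the Laplace-Beltrami operator.

On a closed triangle mesh the Helmholtz eigenproblem Δf = -λf discretizes to
the sparse generalized symmetric problem ``A f = λ B f`` with

* ``A`` the cotangent stiffness matrix: for each triangle, the edge opposite
  the angle α contributes cot(α)/2 off-diagonally (and its negative to the
  two diagonals), so every row sums to zero and the constant vector spans
  the nullspace;
* ``B`` the consistent linear-FEM mass matrix: each triangle of area ``s``
  contributes ``s/6`` to the three diagonal entries and ``s/12`` to each
  off-diagonal vertex pair.

A lumped (diagonal) mass matrix is available behind a flag for comparison;
the consistent matrix is the default.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TriangleMesh, MeshValidationError

__all__ = ["assemble_fem", "solve_spectrum", "EigensolverError"]


class EigensolverError(RuntimeError):
    """Raised when the sparse eigensolver fails to converge."""


def assemble_fem(
    mesh: TriangleMesh, lumped_mass: bool = False
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Assemble stiffness and mass matrices for the P1 Laplace-Beltrami FEM.

    Parameters
    ----------
    mesh : TriangleMesh
        Closed oriented mesh (validated by the caller or `read_mesh`).
    lumped_mass : bool
        If True return the row-lumped diagonal mass matrix instead of the
        consistent one.

    Returns
    -------
    (A, B) : sparse CSR matrices, both symmetric; A positive semidefinite
    with the constant vector in its nullspace, B positive definite.
    """
    v = mesh.vertices
    f = mesh.faces
    n = mesh.n_vertices

    # per-triangle geometry
    p = [v[f[:, i]] for i in range(3)]
    areas = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]), axis=1)
    scale = float(areas.max()) if len(areas) else 0.0
    bad = np.nonzero(areas < 1e-14 * max(scale, 1.0))[0]
    if bad.size:
        raise MeshValidationError(
            f"degenerate triangle(s) at face indices {bad[:10].tolist()}"
        )

    rows, cols, a_vals = [], [], []
    m_rows, m_cols, m_vals = [], [], []
    # loop over the 3 corners: the edge (j,k) opposite corner i gets cot/2
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        e1 = p[j] - p[i]
        e2 = p[k] - p[i]
        # cot of the angle at corner i
        cos_num = np.einsum("ij,ij->i", e1, e2)
        sin_num = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = cos_num / sin_num
        w = 0.5 * cot
        # off-diagonal -w on (j,k) and (k,j); +w on the two diagonals
        rows.extend([f[:, j], f[:, k], f[:, j], f[:, k]])
        cols.extend([f[:, k], f[:, j], f[:, j], f[:, k]])
        a_vals.extend([-w, -w, w, w])

        m_rows.extend([f[:, j], f[:, k]])
        m_cols.extend([f[:, k], f[:, j]])
        m_vals.extend([areas / 12.0, areas / 12.0])

    for i in range(3):
        m_rows.append(f[:, i])
        m_cols.append(f[:, i])
        m_vals.append(areas / 6.0)

    A = sp.coo_matrix(
        (np.concatenate(a_vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    B = sp.coo_matrix(
        (np.concatenate(m_vals), (np.concatenate(m_rows), np.concatenate(m_cols))),
        shape=(n, n),
    ).tocsr()
    if lumped_mass:
        B = sp.diags(np.asarray(B.sum(axis=1)).ravel()).tocsr()
    return A, B


def solve_spectrum(
    A: sp.spmatrix,
    B: sp.spmatrix,
    k: int = 50,
    tol: float = 0.0,
    sigma: float | None = None,
) -> np.ndarray:
    """Smallest ``k`` eigenvalues of ``A f = λ B f``, ascending.

    Shift-invert around a small negative shift (scaled to the spectrum's
    magnitude) handles the singular zero mode of the closed surface.  The
    default tolerance is machine precision: the sphere-like spectra here
    carry high-multiplicity clusters, and a looser ARPACK tolerance can
    terminate before resolving every copy of a degenerate eigenvalue.  The
    start vector is a fixed-seed generic vector: it is deterministic, so
    repeated runs give identical spectra, yet overlaps every eigenspace —
    a structured start vector on a symmetric mesh can miss whole
    multiplets.
    """
    n = A.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the vertex count {n}")
    if sigma is None:
        sigma = -1e-3 * float(A.diagonal().sum() / B.diagonal().sum())
    v0 = np.random.default_rng(1905).standard_normal(n)
    try:
        vals = spla.eigsh(
            A,
            k=k,
            M=B,
            sigma=sigma,
            which="LM",
            tol=tol,
            v0=v0,
            return_eigenvectors=False,
        )
    except spla.ArpackNoConvergence as exc:  # pragma: no cover - rare
        raise EigensolverError(
            f"ARPACK failed to converge: {len(exc.eigenvalues)} of {k} "
            f"eigenvalues converged"
        ) from exc
    vals = np.sort(np.real(vals))
    return vals
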