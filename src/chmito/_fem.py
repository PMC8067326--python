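"""P1 simplex finite-element kernels shared by the solver and the diagnostics.

Everything here operates on a flat description of a simplicial mesh:
``element_coords`` of shape (E, n, d) with n = d + 1 vertices per element,
and an integer connectivity array ``elements`` of shape (E, n) addressing
``n_nodes`` global nodes.  Periodic meshes are supported transparently
because geometry is taken from ``element_coords`` (which may contain the
periodic image of a wrapped vertex) while fields live on global nodes.

Polynomial integrals over simplices use the closed form

    ∫_T λ_0^{a_0} ... λ_d^{a_d} dx = |T| · d! · a_0! ... a_d! / (d + |a|)!

so mass matrices and the quartic double-well terms are integrated exactly
for piecewise-linear fields.
"""

from __future__ import annotations

from functools import cached_property
from math import factorial

import numpy as np
import scipy.sparse as sp


def moment_tensor(dim: int, order: int) -> np.ndarray:
    """Exact integrals of products of ``order`` barycentric coordinates.

    Returns a tensor C with ``order`` axes of length dim+1 such that
    ``|T| * C[i, j, ...]`` equals the integral of λ_i λ_j ... over a
    simplex of measure |T|.
    """
    n = dim + 1
    shape = (n,) * order
    C = np.zeros(shape)
    for idx in np.ndindex(shape):
        counts = np.bincount(np.asarray(idx), minlength=n)
        num = factorial(dim)
        for c in counts:
            num *= factorial(int(c))
        C[idx] = num / factorial(dim + order)
    return C


def boundary_facet_array(elements: np.ndarray) -> np.ndarray:
    """Facets (sorted node tuples) that belong to exactly one element."""
    E, n = elements.shape
    parts = [np.sort(np.delete(elements, i, axis=1), axis=1) for i in range(n)]
    allf = np.vstack(parts)
    uniq, counts = np.unique(allf, axis=0, return_counts=True)
    return uniq[counts == 1]


class FemOps:
    """Assembled P1 operators for one mesh.

    Caches the mass matrix M, stiffness matrix K (both CSR), exact
    quadrature tensors for the quartic bulk free energy, and the scatter
    indices needed to reassemble the state-dependent Jacobian block fast.
    """

    def __init__(self, element_coords: np.ndarray, elements: np.ndarray, n_nodes: int):
        ec = np.asarray(element_coords, dtype=float)
        self.elements = np.asarray(elements, dtype=np.int64)
        self.n_nodes = int(n_nodes)
        E, n, d = ec.shape
        if n != d + 1:
            raise ValueError(f"expected {d + 1} vertices per {d}-simplex, got {n}")
        self.dim = d
        self.n_vert = n

        # Edge-vector Jacobian rows e_i = x_i - x_0; measure = |det| / d!
        J = ec[:, 1:, :] - ec[:, :1, :]          # (E, d, d)
        det = np.linalg.det(J)
        self.measures = np.abs(det) / factorial(d)
        if np.any(self.measures <= 0):
            raise ValueError("degenerate (zero-measure) element in mesh")
        Jinv = np.linalg.inv(J)                   # (E, d, d)
        g = np.transpose(Jinv, (0, 2, 1))         # g[e, i-1, :] = grad λ_i
        self.grads = np.concatenate([-g.sum(axis=1, keepdims=True), g], axis=1)  # (E, n, d)

        self.C2 = moment_tensor(d, 2)
        self.C4 = moment_tensor(d, 4)

        # COO scatter pattern reused for every element-matrix assembly.
        self._rows = np.repeat(self.elements, n, axis=1).ravel()
        self._cols = np.tile(self.elements, (1, n)).ravel()

    # ---- assembled operators -------------------------------------------------

    def _assemble(self, elem_mats: np.ndarray) -> sp.csr_matrix:
        A = sp.coo_matrix(
            (elem_mats.ravel(), (self._rows, self._cols)),
            shape=(self.n_nodes, self.n_nodes),
        )
        return A.tocsr()

    @cached_property
    def mass(self) -> sp.csr_matrix:
        Me = self.measures[:, None, None] * self.C2[None, :, :]
        return self._assemble(Me)

    @cached_property
    def stiffness(self) -> sp.csr_matrix:
        Ke = self.measures[:, None, None] * np.einsum("eid,ejd->eij", self.grads, self.grads)
        return self._assemble(Ke)

    @cached_property
    def node_weights(self) -> np.ndarray:
        """Row sums of the mass matrix: exact quadrature weights for ∫ψ."""
        w = np.zeros(self.n_nodes)
        np.add.at(w, self.elements, np.broadcast_to(
            self.measures[:, None] / self.n_vert, self.elements.shape))
        return w

    @cached_property
    def total_measure(self) -> float:
        return float(self.measures.sum())

    # ---- integrals of nodal fields ------------------------------------------

    def integrate(self, values: np.ndarray) -> float:
        """∫ψ, exact for P1 fields."""
        return float(self.node_weights @ values)

    def integrate_double_well(self, values: np.ndarray) -> float:
        """∫ (1/4)(ψ² − 1)², exact for the quartic in the nodal interpolant."""
        p = values[self.elements]                               # (E, n)
        q4 = np.einsum("ijkl,ei,ej,ek,el->e", self.C4, p, p, p, p, optimize=True)
        q2 = np.einsum("ij,ei,ej->e", self.C2, p, p, optimize=True)
        return float(np.sum(self.measures * (q4 - 2.0 * q2 + 1.0)) / 4.0)

    def gradient_energy(self, values: np.ndarray, coeff: float) -> float:
        """(coeff/2) ∫ |∇ψ|² via the stiffness matrix."""
        return float(0.5 * coeff * (values @ (self.stiffness @ values)))

    def l2_norm(self, values: np.ndarray) -> float:
        return float(np.sqrt(max(values @ (self.mass @ values), 0.0)))

    # ---- cubic nonlinearity f'(ψ) = ψ³ − ψ ----------------------------------

    def cubic_term(self, values: np.ndarray) -> np.ndarray:
        """Load vector N_i = ∫ (ψ³ − ψ) λ_i, exact Galerkin quadrature."""
        p = values[self.elements]
        cub = np.einsum("ijkl,ej,ek,el->ei", self.C4, p, p, p, optimize=True)
        lin = p @ self.C2.T
        elem = self.measures[:, None] * (cub - lin)
        out = np.zeros(self.n_nodes)
        np.add.at(out, self.elements, elem)
        return out

    def cubic_jacobian(self, values: np.ndarray) -> sp.csr_matrix:
        """dN/dψ as a sparse matrix (3∫ψ²λλ − M element blocks)."""
        p = values[self.elements]
        quad = 3.0 * np.einsum("ijkl,ek,el->eij", self.C4, p, p, optimize=True)
        elem = self.measures[:, None, None] * (quad - self.C2[None, :, :])
        return self._assemble(elem)
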