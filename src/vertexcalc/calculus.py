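"""Discrete differential operators on a polygonal monolayer.

Sixteen operators act between four kinds of field: scalars on vertices
(space V, isomorphic to scalars on dual triangles T), scalars on cells
(space F, isomorphic to scalars on cell centres C), and 2D vectors on
edges (space E, isomorphic to vectors on links L).  Per-edge vector fields
are stored as flat arrays of length ``2 N_e`` with interleaved x/y
components, so every operator is a plain sparse matrix.

Eight operators are primary (grad/div/curl built directly from the
incidence matrices and the metric); the other eight ("tilde" variants,
prefixed ``t``) are their adjoints under the inner products

    [phi, psi]_V = sum_k E_k phi_k psi_k,
    [f, g]_F     = sum_i A_i f_i g_i,
    [a, b]_E     = sum_j F_j a_j . b_j .

Composing them yields four scalar Laplacians:

    L_V = E^-1 A^T T_e^-1 A          (vertices)
    L_T = E^-1 A^T T_l A             (triangles)
    L_F = H^-1 B I_b T_e B^T         (cell faces)
    L_C = H^-1 B I_b T_l^-1 B^T      (cell centres)

where the diagonal projector ``I_b`` removes "orphan" links at the
periphery (links reaching only one cell centre), so that each Laplacian
annihilates the uniform field.  The face/centre Laplacians equal the
operator compositions threaded through the orphan-link projector ``P_b``
acting on edge fields, e.g. ``L_F = -div_c @ P_b @ tgrad_c``; the
projector-free compositions ``L_F_full = -div_c @ tgrad_c`` are strictly
positive definite and are the natural solvers for Helmholtz decomposition
(see :mod:`vertexcalc.hodge`).

At the monolayer boundary the dual faces are kites rather than triangles;
``div_v_kite`` / ``CURL_v_kite`` (and their adjoints) replace the rows of
``div_v`` / ``CURL_v`` at peripheral vertices by flux and circulation
integrals around the actual kite boundary, which is what makes the
geometric closures ``div_v m / 2 = 1`` and the boundary-pressure integral
exact (their interior rows coincide with the plain operators).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .complex import Topology
from .geometry import Geometry, rot_cw

__all__ = ["OperatorSet", "build_operators", "inner_products", "verify_adjointness"]


def _vec_from_scalar(rows_j, cols, vecs, n_e, n_cols):
    """(2 N_e x n_cols) operator: scalar field -> per-edge vectors."""
    r = np.empty(2 * len(rows_j), dtype=np.int64)
    r[0::2] = 2 * rows_j
    r[1::2] = 2 * rows_j + 1
    c = np.repeat(cols, 2)
    d = vecs.ravel()
    return sp.csr_matrix((d, (r, c)), shape=(2 * n_e, n_cols))


def _scalar_from_vec(rows, cols_j, vecs, n_rows, n_e):
    """(n_rows x 2 N_e) operator: per-edge vectors -> scalar field."""
    r = np.repeat(rows, 2)
    c = np.empty(2 * len(cols_j), dtype=np.int64)
    c[0::2] = 2 * cols_j
    c[1::2] = 2 * cols_j + 1
    d = vecs.ravel()
    return sp.csr_matrix((d, (r, c)), shape=(n_rows, 2 * n_e))


@dataclass
class OperatorSet:
    T: Topology
    G: Geometry
    # primary
    grad_v: sp.csr_matrix      # V -> E (parallel)
    curl_v: sp.csr_matrix      # V -> E (perpendicular)
    curl_c: sp.csr_matrix      # E -> F (circulation around cells)
    div_c: sp.csr_matrix       # E -> F (flux out of cells)
    grad_c: sp.csr_matrix      # C -> L (parallel)
    CURL_c: sp.csr_matrix      # C -> L (perpendicular)
    CURL_v: sp.csr_matrix      # L -> T (circulation around triangles)
    div_v: sp.csr_matrix       # L -> T (flux out of triangles)
    # derived (adjoints)
    tCURL_v: sp.csr_matrix
    tgrad_v: sp.csr_matrix
    tdiv_c: sp.csr_matrix
    tCURL_c: sp.csr_matrix
    tcurl_c: sp.csr_matrix
    tgrad_c: sp.csr_matrix
    tdiv_v: sp.csr_matrix
    tcurl_v: sp.csr_matrix
    # peripheral-kite boundary variants (rows at peripheral vertices use
    # fluxes around the dual kite faces; interior rows match div_v/CURL_v)
    div_v_kite: sp.csr_matrix
    CURL_v_kite: sp.csr_matrix
    tgrad_v_kite: sp.csr_matrix
    tCURL_v_kite: sp.csr_matrix
    # Laplacians
    L_V: sp.csr_matrix
    L_T: sp.csr_matrix
    L_F: sp.csr_matrix
    L_C: sp.csr_matrix
    L_F_full: sp.csr_matrix
    L_C_full: sp.csr_matrix
    # inner products (diagonals)
    M_V: np.ndarray
    M_F: np.ndarray
    M_E: np.ndarray
    # orphan-link projector on edge vector fields (diagonal, length 2 N_e)
    P_b: np.ndarray

    def inner_V(self, x, y):
        return float(np.dot(x, self.M_V * y))

    def inner_F(self, x, y):
        return float(np.dot(x, self.M_F * y))

    def inner_E(self, x, y):
        return float(np.dot(x, self.M_E * y))

    def export_sparse(self, path_prefix: str):
        """Write every operator in coordinate text format (i j value)."""
        import os

        for name in ("grad_v", "curl_v", "curl_c", "div_c", "grad_c",
                     "CURL_c", "CURL_v", "div_v", "tCURL_v", "tgrad_v",
                     "tdiv_c", "tCURL_c", "tcurl_c", "tgrad_c", "tdiv_v",
                     "tcurl_v", "L_V", "L_T", "L_F", "L_C"):
            M = getattr(self, name).tocoo()
            out = os.path.join(path_prefix + name + ".coo.txt")
            with open(out, "w") as fh:
                fh.write(f"# {M.shape[0]} {M.shape[1]} {M.nnz}\n")
                for r, c, v in zip(M.row, M.col, M.data):
                    fh.write(f"{r} {c} {v:.17g}\n")


def build_operators(T: Topology, G: Geometry) -> OperatorSet:
    """Assemble the full operator set for a positioned complex.

    Refuses to build if the edge/link orientation constraint
    ``F_j = t_j x T_j > 0`` does not hold.
    """
    if np.any(G.F <= 0):
        raise ValueError("orientation constraint F_j > 0 violated; "
                         "geometry must be assembled first")

    n_e, n_v, n_c = T.N_e, T.N_v, T.N_c
    A_coo = T.A.tocoo()
    B_coo = T.B.tocoo()
    aj, ak, av = A_coo.row, A_coo.col, A_coo.data.astype(float)
    bi, bj, bv = B_coo.row, B_coo.col, B_coo.data.astype(float)

    t, Tl, F = G.t, G.Tl, G.F
    t2 = G.t_len**2
    T2 = G.T_len**2
    eps_t = rot_cw(t)          # eps_k t_j
    eps_T = rot_cw(Tl)         # eps_k T_j ; eps_i (.) = -eps_k (.)

    # --- primary, vertex-based (V -> E) ---
    grad_v = _vec_from_scalar(aj, ak, av[:, None] * t[aj] / t2[aj, None], n_e, n_v)
    curl_v = _vec_from_scalar(aj, ak, av[:, None] * eps_t[aj] / t2[aj, None], n_e, n_v)
    # --- primary, cell-based (C -> L) ---
    grad_c = _vec_from_scalar(bj, bi, bv[:, None] * Tl[bj] / T2[bj, None], n_e, n_c)
    CURL_c = _vec_from_scalar(bj, bi, -bv[:, None] * eps_T[bj] / T2[bj, None], n_e, n_c)
    # --- primary, E -> F ---
    curl_c = _scalar_from_vec(bi, bj, bv[:, None] * t[bj] / G.A[bi, None], n_c, n_e)
    div_c = _scalar_from_vec(bi, bj, bv[:, None] * eps_t[bj] / G.A[bi, None], n_c, n_e)
    # --- primary, L -> T ---
    CURL_v = _scalar_from_vec(ak, aj, av[:, None] * Tl[aj] / G.E[ak, None], n_v, n_e)
    div_v = _scalar_from_vec(ak, aj, -av[:, None] * eps_T[aj] / G.E[ak, None], n_v, n_e)

    # --- derived (tilde) ---
    tCURL_v = _vec_from_scalar(aj, ak, av[:, None] * Tl[aj] / F[aj, None], n_e, n_v)
    tgrad_v = _vec_from_scalar(aj, ak, av[:, None] * eps_T[aj] / F[aj, None], n_e, n_v)
    tcurl_c = _vec_from_scalar(bj, bi, bv[:, None] * t[bj] / F[bj, None], n_e, n_c)
    tgrad_c = _vec_from_scalar(bj, bi, -bv[:, None] * eps_t[bj] / F[bj, None], n_e, n_c)
    w = (F / T2)[bj, None]
    tdiv_c = _scalar_from_vec(bi, bj, -bv[:, None] * w * Tl[bj] / G.A[bi, None], n_c, n_e)
    tCURL_c = _scalar_from_vec(bi, bj, -bv[:, None] * w * eps_T[bj] / G.A[bi, None], n_c, n_e)
    w = (F / t2)[aj, None]
    tdiv_v = _scalar_from_vec(ak, aj, -av[:, None] * w * t[aj] / G.E[ak, None], n_v, n_e)
    tcurl_v = _scalar_from_vec(ak, aj, av[:, None] * w * eps_t[aj] / G.E[ak, None], n_v, n_e)

    # --- peripheral-kite variants from the dual-face side vectors ---
    sj, sk, su = G.face_sides
    div_v_kite = _scalar_from_vec(sk, sj, rot_cw(su) / G.E[sk, None], n_v, n_e)
    CURL_v_kite = _scalar_from_vec(sk, sj, -su / G.E[sk, None], n_v, n_e)
    tCURL_v_kite = _vec_from_scalar(sj, sk, -su / F[sj, None], n_e, n_v)
    tgrad_v_kite = _vec_from_scalar(sj, sk, -rot_cw(su) / F[sj, None], n_e, n_v)

    # --- Laplacians ---
    Einv = sp.diags(1.0 / G.E)
    Hinv = sp.diags(1.0 / G.A)
    Te = sp.diags(t2 / F)
    Te_inv = sp.diags(F / t2)
    Tl_m = sp.diags(T2 / F)
    Tl_inv = sp.diags(F / T2)
    Ib = sp.diags(T.I_b)
    At, Bt = T.A.T.astype(float), T.B.T.astype(float)
    Af, Bf = T.A.astype(float), T.B.astype(float)
    L_V = (Einv @ At @ Te_inv @ Af).tocsr()
    L_T = (Einv @ At @ Tl_m @ Af).tocsr()
    L_F = (Hinv @ Bf @ Ib @ Te @ Bt).tocsr()
    L_C = (Hinv @ Bf @ Ib @ Tl_inv @ Bt).tocsr()
    L_F_full = (Hinv @ Bf @ Te @ Bt).tocsr()
    L_C_full = (Hinv @ Bf @ Tl_inv @ Bt).tocsr()

    M_V = G.E.copy()
    M_F = G.A.copy()
    M_E = np.repeat(F, 2)
    P_b = np.repeat(T.I_b, 2)

    return OperatorSet(
        T=T, G=G,
        grad_v=grad_v, curl_v=curl_v, curl_c=curl_c, div_c=div_c,
        grad_c=grad_c, CURL_c=CURL_c, CURL_v=CURL_v, div_v=div_v,
        tCURL_v=tCURL_v, tgrad_v=tgrad_v, tdiv_c=tdiv_c, tCURL_c=tCURL_c,
        tcurl_c=tcurl_c, tgrad_c=tgrad_c, tdiv_v=tdiv_v, tcurl_v=tcurl_v,
        div_v_kite=div_v_kite, CURL_v_kite=CURL_v_kite,
        tgrad_v_kite=tgrad_v_kite, tCURL_v_kite=tCURL_v_kite,
        L_V=L_V, L_T=L_T, L_F=L_F, L_C=L_C,
        L_F_full=L_F_full, L_C_full=L_C_full,
        M_V=M_V, M_F=M_F, M_E=M_E, P_b=P_b,
    )


def inner_products(T: Topology, G: Geometry):
    """Inner-product weight matrices M_V, M_E, M_F (positive diagonals)."""
    M = {
        "M_V": sp.diags(G.E),
        "M_E": sp.diags(np.repeat(G.F, 2)),
        "M_F": sp.diags(G.A),
    }
    for name, mat in M.items():
        if np.any(mat.diagonal() <= 0):
            raise ValueError(f"nonpositive weight in {name}")
    return M


#: (primary, derived, scalar side, sign) with the convention
#: <primary(x), b>_E = sign * <x, derived(b)>_scalar ;
#: divergence-type derived operators are negative adjoints of gradients.
ADJOINT_PAIRS = [
    ("grad_v", "tdiv_v", "V", -1.0),
    ("curl_v", "tcurl_v", "V", +1.0),
    ("tCURL_v", "CURL_v", "V", +1.0),
    ("tgrad_v", "div_v", "V", -1.0),
    ("grad_c", "tdiv_c", "F", -1.0),
    ("CURL_c", "tCURL_c", "F", +1.0),
    ("tcurl_c", "curl_c", "F", +1.0),
    ("tgrad_c", "div_c", "F", -1.0),
]


def verify_adjointness(O: OperatorSet, n_trials: int = 50, seed: int = 0,
                       tol: float = 1e-10):
    """Check the eight adjoint pairs on random field pairs.

    Returns a list of failures ``(primary, derived, residual)``; empty when
    every pair satisfies its adjoint identity to within ``tol`` (relative
    to the magnitude of the inner products involved).
    """
    rng = np.random.default_rng(seed)
    failures = []
    for prim_name, der_name, side, sign in ADJOINT_PAIRS:
        P = getattr(O, prim_name)
        D = getattr(O, der_name)
        M_s = O.M_V if side == "V" else O.M_F
        n_scalar = P.shape[1]
        worst = 0.0
        for _ in range(n_trials):
            x = rng.standard_normal(n_scalar)
            b = rng.standard_normal(2 * O.T.N_e)
            lhs = float(np.dot(P @ x, O.M_E * b))
            rhs = sign * float(np.dot(x, M_s * (D @ b)))
            scale = max(abs(lhs), abs(rhs), 1.0)
            worst = max(worst, abs(lhs - rhs) / scale)
        if worst > tol:
            failures.append((prim_name, der_name, worst))
    return failures
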