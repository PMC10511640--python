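"""Spectral machinery and Helmholtz-Hodge decomposition.

Each scalar Laplacian ``L`` is self-adjoint under a diagonal inner product
``M`` (areas of dual faces for vertex/triangle fields, cell areas for
face/centre fields), so it has a real spectrum and an M-orthonormal
eigenbasis; Poisson problems are solved by eigenmode expansion with an
explicit solvability check against any kernel mode.

A per-edge vector field ``h`` splits into components parallel and
perpendicular to edges (primal representation) or to links (dual
representation), each generated by a pair of scalar potentials.  On the
primal network::

    h_par  = grad_v psi_v + tcurl_c Psi_c
    h_perp = tgrad_c psi_c + curl_v Psi_v

with the potentials determined by four Poisson problems (two on cells,
two on vertices).  The face-side problems use the projector-free face
Laplacian ``L_F_full = -div_c o tgrad_c``, which is positive definite on a
bounded monolayer, so the decomposition of an arbitrary edge field is
unique and reconstructs it exactly; the cell-side potentials carry no
additive gauge freedom, while the vertex-side potentials are reported
with zero M-weighted mean.  The dual representation is analogous with
the roles of the networks exchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .calculus import OperatorSet

__all__ = [
    "SpectralBasis", "PotentialSet", "eigenbasis", "solve_poisson",
    "helmholtz_primal", "helmholtz_dual", "spectrum",
]

#: relative rank cutoff separating kernel modes from the rest
KERNEL_CUTOFF = 1e-10


@dataclass
class SpectralBasis:
    """Eigenvalues (ascending) and M-orthonormal eigenmodes of a Laplacian."""

    eigenvalues: np.ndarray
    modes: np.ndarray          # columns, M-orthonormal
    M: np.ndarray              # diagonal weights

    @property
    def n_kernel(self) -> int:
        lam_max = self.eigenvalues[-1] if len(self.eigenvalues) else 1.0
        return int(np.sum(np.abs(self.eigenvalues) <= KERNEL_CUTOFF * max(lam_max, 1.0)))

    def coefficients(self, field: np.ndarray) -> np.ndarray:
        """M-inner products of a scalar field with every eigenmode."""
        return self.modes.T @ (self.M * field)


def eigenbasis(L, M: np.ndarray, tol: float = 1e-10) -> SpectralBasis:
    """Full eigendecomposition of ``L`` under the diagonal inner product ``M``.

    ``M^(1/2) L M^(-1/2)`` must be symmetric to within ``tol`` (relative);
    eigenvalues are returned ascending, and each mode's sign is fixed so
    that its largest-magnitude entry is positive.
    """
    Ld = L.toarray() if sp.issparse(L) else np.asarray(L, dtype=float)
    s = np.sqrt(M)
    S = (Ld * s[:, None]) / s[None, :]
    asym = np.abs(S - S.T).max()
    scale = max(np.abs(S).max(), 1.0)
    if asym > tol * scale:
        raise ValueError(f"operator not self-adjoint under M (residual {asym:.2e})")
    lam, U = scipy.linalg.eigh(0.5 * (S + S.T))
    modes = U / s[:, None]
    idx = np.abs(modes).argmax(axis=0)
    signs = np.sign(modes[idx, np.arange(modes.shape[1])])
    signs[signs == 0] = 1.0
    return SpectralBasis(eigenvalues=lam, modes=modes * signs, M=M)


def solve_poisson(L, M: np.ndarray, rhs: np.ndarray, basis: SpectralBasis = None,
                  tol: float = 1e-8):
    """Solve ``L x = rhs`` by eigenmode expansion.

    If ``L`` has kernel modes, ``rhs`` must be M-orthogonal to them to
    within ``tol`` (relative to ||rhs||_M); otherwise a ``ValueError``
    reporting the offending integral is raised.  The solution is the
    minimum-M-norm one, shifted to zero M-weighted mean whenever the
    uniform field lies in the kernel (in which case the constant is pure
    gauge).
    """
    if basis is None:
        basis = eigenbasis(L, M)
    coeff = basis.coefficients(rhs)
    nk = basis.n_kernel
    rhs_norm = np.sqrt(max(np.dot(rhs, M * rhs), 0.0))
    if nk:
        bad = np.abs(coeff[:nk]).max()
        if bad > tol * rhs_norm and bad > 1e-13:
            raise ValueError(
                f"solvability violated: kernel-mode integral {bad:.3e} "
                f"(||rhs||_M = {rhs_norm:.3e})"
            )
    lam = basis.eigenvalues.copy()
    inv = np.zeros_like(lam)
    inv[nk:] = 1.0 / lam[nk:]
    x = basis.modes @ (inv * coeff)
    if nk:
        x = x - np.dot(M, x) / M.sum()
    return x


@dataclass
class PotentialSet:
    """Scalar potentials of one Helmholtz representation of an edge field.

    ``psi``-type potentials generate the flux (gradient-like) part and are
    the discrete Airy-function analogues; ``Psi``-type potentials generate
    the circulation part (Mindlin analogues).  ``network`` records whether
    the representation is over the primal cells ("primal") or the dual
    triangulation ("dual").
    """

    network: str
    psi_c: np.ndarray
    Psi_c: np.ndarray
    psi_v: np.ndarray
    Psi_v: np.ndarray
    h_par: np.ndarray
    h_perp: np.ndarray
    residual: float


def _dense_solve_spd(L, M, rhs):
    """Unique solve of a positive-definite (under M) Laplacian."""
    K = (L.toarray() if sp.issparse(L) else np.asarray(L)) * M[:, None]
    return scipy.linalg.solve(0.5 * (K + K.T), M * rhs, assume_a="pos")


def helmholtz_primal(O: OperatorSet, h: np.ndarray, tol: float = 1e-8) -> PotentialSet:
    """Decompose an edge field over the primal network (cells/vertices)."""
    h = np.asarray(h, dtype=float).ravel()
    psi_c = _dense_solve_spd(O.L_F_full, O.M_F, -(O.div_c @ h))
    Psi_c = _dense_solve_spd(O.L_F_full, O.M_F, O.curl_c @ h)
    bV = eigenbasis(O.L_V, O.M_V)
    psi_v = solve_poisson(O.L_V, O.M_V, -(O.tdiv_v @ h), basis=bV)
    Psi_v = solve_poisson(O.L_V, O.M_V, O.tcurl_v @ h, basis=bV)
    h_par = O.grad_v @ psi_v + O.tcurl_c @ Psi_c
    h_perp = O.tgrad_c @ psi_c + O.curl_v @ Psi_v
    res = _rel_residual(h, h_par + h_perp)
    if res > tol:
        raise ValueError(f"primal Helmholtz reconstruction failed: {res:.3e}")
    return PotentialSet("primal", psi_c, Psi_c, psi_v, Psi_v, h_par, h_perp, res)


def helmholtz_dual(O: OperatorSet, h: np.ndarray, tol: float = 1e-8) -> PotentialSet:
    """Decompose the same edge field over the dual network (links)."""
    h = np.asarray(h, dtype=float).ravel()
    psi_c = _dense_solve_spd(O.L_C_full, O.M_F, -(O.tdiv_c @ h))
    Psi_c = _dense_solve_spd(O.L_C_full, O.M_F, O.tCURL_c @ h)
    bT = eigenbasis(O.L_T, O.M_V)
    psi_v = solve_poisson(O.L_T, O.M_V, -(O.div_v @ h), basis=bT)
    Psi_v = solve_poisson(O.L_T, O.M_V, O.CURL_v @ h, basis=bT)
    h_par = O.grad_c @ psi_c + O.tCURL_v @ Psi_v
    h_perp = O.tgrad_v @ psi_v + O.CURL_c @ Psi_c
    res = _rel_residual(h, h_par + h_perp)
    if res > tol:
        raise ValueError(f"dual Helmholtz reconstruction failed: {res:.3e}")
    return PotentialSet("dual", psi_c, Psi_c, psi_v, Psi_v, h_par, h_perp, res)


def _rel_residual(h, h_rec):
    nh = np.linalg.norm(h)
    return float(np.linalg.norm(h - h_rec) / (nh if nh > 0 else 1.0))


def spectrum(potential: np.ndarray, basis: SpectralBasis) -> np.ndarray:
    """Spectral coefficient amplitudes of a scalar field.

    Coefficients are the M-inner products with the eigenmodes, so Parseval
    holds: ``sum(coeff**2) = ||potential||_M^2``.
    """
    potential = np.asarray(potential, dtype=float)
    if potential.shape[0] != basis.modes.shape[0]:
        raise ValueError("field and basis dimensions do not match")
    return basis.coefficients(potential)
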