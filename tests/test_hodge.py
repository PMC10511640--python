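"""Spectral solves and Helmholtz-Hodge decomposition."""

import numpy as np
import pytest
import scipy.linalg

from vertexcalc import build_operators, regular_hexagon
from vertexcalc.hodge import (
    eigenbasis, helmholtz_dual, helmholtz_primal, solve_poisson, spectrum,
)


RNG = np.random.default_rng(7)


def _zero_mean(x, M):
    return x - np.dot(M, x) / M.sum()


def test_zero_modes_of_all_laplacians(disordered_ops):
    O = disordered_ops
    for L, M in ((O.L_V, O.M_V), (O.L_T, O.M_V), (O.L_F, O.M_F), (O.L_C, O.M_F)):
        b = eigenbasis(L, M)
        assert abs(b.eigenvalues[0]) < 1e-10
        u = b.modes[:, 0]
        assert np.abs(u / u[0] - 1).max() < 1e-8     # uniform mode
        # M-orthonormality
        Gram = b.modes.T @ (np.diag(M) @ b.modes)
        assert np.abs(Gram - np.eye(len(M))).max() < 1e-10


def test_hexagon_face_laplacian_is_zero():
    T, G = regular_hexagon(1.0)
    O = build_operators(T, G)
    b = eigenbasis(O.L_F, O.M_F)
    assert b.eigenvalues.shape == (1,)
    assert abs(b.eigenvalues[0]) < 1e-14


def test_eigenvalues_match_dense_generalized_oracle(disordered_ops):
    """Cross-check against scipy's generalized eigensolver on K x = l M x
    with K = M L_V (an independent computational route)."""
    O = disordered_ops
    K = O.L_V.toarray() * O.M_V[:, None]
    lam_oracle = scipy.linalg.eigh(0.5 * (K + K.T), np.diag(O.M_V),
                                   eigvals_only=True)
    b = eigenbasis(O.L_V, O.M_V)
    assert np.abs(b.eigenvalues - lam_oracle).max() < 1e-8


def test_poisson_zero_rhs(disordered_ops):
    O = disordered_ops
    x = solve_poisson(O.L_V, O.M_V, np.zeros(O.T.N_v))
    assert np.abs(x).max() < 1e-12


def test_poisson_forward_apply_roundtrip(disordered_ops):
    O = disordered_ops
    y = _zero_mean(RNG.standard_normal(O.T.N_v), O.M_V)
    x = solve_poisson(O.L_V, O.M_V, O.L_V @ y)
    assert np.abs(x - y).max() < 1e-9


def test_poisson_kernel_forcing_raises(disordered_ops):
    O = disordered_ops
    with pytest.raises(ValueError, match="solvability"):
        solve_poisson(O.L_V, O.M_V, np.ones(O.T.N_v))


@pytest.mark.parametrize("which", ["primal", "dual"])
def test_helmholtz_roundtrip_random_fields(disordered_ops, which):
    O = disordered_ops
    fn = helmholtz_primal if which == "primal" else helmholtz_dual
    for trial in range(5):
        h = RNG.standard_normal(2 * O.T.N_e)
        P = fn(O, h)
        assert P.residual < 1e-8
        # parallel and perpendicular parts are orthogonal per edge
        hp = P.h_par.reshape(-1, 2)
        t = O.G.t if which == "primal" else O.G.Tl
        perp = P.h_perp.reshape(-1, 2)
        assert np.abs(np.einsum("jd,jd->j", perp, t)).max() < 1e-10 * np.abs(h).max()
        del hp


def test_helmholtz_pure_gradient_field(disordered_ops):
    O = disordered_ops
    phi = RNG.standard_normal(O.T.N_v)
    P = helmholtz_primal(O, O.grad_v @ phi)
    assert np.abs(P.Psi_c).max() < 1e-10
    assert np.abs(P.psi_c).max() < 1e-10
    assert np.abs(P.Psi_v).max() < 1e-10
    got = _zero_mean(P.psi_v, O.M_V)
    want = _zero_mean(phi, O.M_V)
    assert np.abs(got - want).max() < 1e-9


def test_helmholtz_perpendicular_field_has_no_parallel_part(disordered_ops):
    O = disordered_ops
    t_hat = O.G.t / O.G.t_len[:, None]
    amp = RNG.standard_normal(O.T.N_e)
    h = (amp[:, None] * np.stack([t_hat[:, 1], -t_hat[:, 0]], axis=1)).ravel()
    P = helmholtz_primal(O, h)
    assert np.abs(P.h_par).max() < 1e-9
    assert np.abs(P.h_perp - h).max() < 1e-9


def test_zero_field_gives_zero_potentials(disordered_ops):
    O = disordered_ops
    P = helmholtz_dual(O, np.zeros(2 * O.T.N_e))
    for pot in (P.psi_c, P.Psi_c, P.psi_v, P.Psi_v):
        assert np.abs(pot).max() < 1e-12


def test_orthogonal_mesh_dual_matches_primal(flower):
    """With edges perpendicular to links the dual representation collapses
    onto the primal one: psi-potentials coincide, Psi_v flips sign."""
    T, G = flower
    O = build_operators(T, G)
    h = RNG.standard_normal(2 * T.N_e)
    P = helmholtz_primal(O, h)
    D = helmholtz_dual(O, h)
    assert np.abs(P.psi_c - D.psi_c).max() < 1e-9
    assert np.abs(_zero_mean(P.psi_v, O.M_V) - _zero_mean(D.psi_v, O.M_V)).max() < 1e-9
    assert np.abs(_zero_mean(P.Psi_v, O.M_V) + _zero_mean(D.Psi_v, O.M_V)).max() < 1e-9


def test_spectrum_parseval_and_one_hot(disordered_ops):
    O = disordered_ops
    b = eigenbasis(O.L_F, O.M_F)
    f = RNG.standard_normal(O.T.N_c)
    c = spectrum(f, b)
    assert np.dot(c, c) == pytest.approx(np.dot(f, O.M_F * f), rel=1e-10)
    c1 = spectrum(b.modes[:, 3], b)
    expected = np.zeros(O.T.N_c)
    expected[3] = 1.0
    assert np.abs(c1 - expected).max() < 1e-10
    with pytest.raises(ValueError):
        spectrum(np.zeros(O.T.N_v + 1), b)
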