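"""Mechanics: energy, forces, force potential, stresses, couples."""

import numpy as np
import pytest
import scipy.optimize

from vertexcalc import hex_patch, perturb, regular_hexagon
from vertexcalc.mechanics import (
    EnergyParams, VertexModelEnergy, _force_reconstruction_residual, affine_couple,
    affine_stress, cell_energy, force_potential, stresses, vertex_forces,
)

RNG = np.random.default_rng(11)


def test_cell_energy_direct_values():
    params = EnergyParams(Gamma=0.2, L0=0.75, P_ext=0.0)
    T, G = regular_hexagon((2 / (3 * np.sqrt(3))) ** 0.5)   # unit area
    en = cell_energy(G, params)
    assert G.A[0] == pytest.approx(1.0, rel=1e-12)
    assert en["pressure"][0] == pytest.approx(0.0, abs=1e-12)
    # closed form: U = Gamma (L - L0)^2 / 2 at A = 1
    L = G.L[0]
    assert en["U"][0] == pytest.approx(0.1 * (L - 0.75) ** 2, rel=1e-12)


def test_cell_energy_area_term():
    # A = 1.5, L = L0 gives U = 0.125 and pressure 0.5 for any Gamma
    side = (1.5 * 2 / (3 * np.sqrt(3))) ** 0.5
    T, G = regular_hexagon(side)
    params = EnergyParams(Gamma=0.2, L0=G.L[0], P_ext=0.0)
    en = cell_energy(G, params)
    assert en["U"][0] == pytest.approx(0.125, rel=1e-12)
    assert en["pressure"][0] == pytest.approx(0.5, rel=1e-12)
    assert en["tension"][0] == pytest.approx(0.0, abs=1e-12)


def test_forces_match_central_difference_gradient(flower):
    """Analytic energy gradient vs central differences on random
    perturbations of the honeycomb patch."""
    T, G0 = flower
    params = EnergyParams()
    model = VertexModelEnergy(T, params)
    for trial in range(20):
        _, G = perturb(T, G0, 0.15, seed=trial)
        x = G.r.ravel()
        g = model.gradient(x)
        idx = RNG.integers(0, x.size, size=8)
        for a in idx:
            xp, xm = x.copy(), x.copy()
            xp[a] += 1e-6
            xm[a] -= 1e-6
            fd = (model.energy(xp) - model.energy(xm)) / 2e-6
            assert g[a] == pytest.approx(fd, abs=2e-6)


def test_per_cell_force_closure_off_equilibrium(flower):
    """sum_k C_ik f_ik = 0 for every cell even away from equilibrium
    (translation invariance of the cell energy)."""
    T, G0 = flower
    _, G = perturb(T, G0, 0.2, seed=9)
    i_idx, _, f, _ = vertex_forces(T, G, EnergyParams(Gamma=0.2, L0=0.7, P_ext=0.1))
    percell = np.zeros((T.N_c, 2))
    np.add.at(percell, i_idx, f)
    assert np.linalg.norm(percell, axis=1).max() < 1e-12


def test_equilibrium_residual_vanishes(grown_state):
    T, G, O, params, st = grown_state
    net = st.forces[3]
    assert np.linalg.norm(net, axis=1).max() < 1e-10


def test_force_potential_consistency(grown_state):
    """h reproduces every f_ik through the incidence contraction and all
    independent cycles close."""
    T, G, O, params, st = grown_state
    assert st.h_info["worst_cycle"] < 1e-10
    assert _force_reconstruction_residual(T, st.h, st.forces) < 1e-10


def test_force_potential_gauge_invariance(grown_state):
    T, G, O, params, st = grown_state
    h2 = st.h + np.array([0.37, -1.2])
    assert _force_reconstruction_residual(T, h2, st.forces) < 1e-10


def test_force_potential_requires_equilibrium(flower):
    T, G0 = flower
    _, G = perturb(T, G0, 0.2, seed=2)
    params = EnergyParams()
    forces = vertex_forces(T, G, params)
    with pytest.raises(ValueError, match="equilibrium"):
        force_potential(T, G, forces, params)


def test_peripheral_loop_congruent_to_periphery(grown_state):
    """The peripheral values of h trace the monolayer periphery (as
    sampled by the edge-link intersections m) scaled by -P_ext."""
    T, G, O, params, st = grown_state
    per = T.peripheral_edges
    assert np.abs(st.h[per] + params.P_ext * G.m[per]).max() < 1e-10


def test_stress_two_routes_agree(grown_state):
    T, G, O, params, st = grown_state
    s = st.stress
    assert np.abs(s["sigma_c"] - s["sigma_c_h"]).max() < 1e-10
    assert np.abs(s["sigma_v"] - s["sigma_v_h"]).max() < 1e-10


def test_cells_carry_no_torque(grown_state):
    T, G, O, params, st = grown_state
    assert np.abs(O.curl_c @ st.h.ravel()).max() < 1e-8
    assert np.abs(st.stress["antisym_c"]).max() < 1e-8


def test_trijunction_stress_generically_asymmetric(grown_state):
    """Cell stresses are symmetric but trijunction stresses are not: the
    antisymmetry is a genuine couple, well above round-off on a
    disordered monolayer."""
    T, G, O, params, st = grown_state
    assert np.abs(st.stress["antisym_v"]).max() > 1e-4


def test_force_moment_conservation(grown_state):
    """sum_i A_i sigma_c_i = P_ext A I (compression-positive convention)."""
    T, G, O, params, st = grown_state
    total = (G.A[:, None, None] * st.stress["sigma_c"]).sum(axis=0)
    assert np.abs(total - params.P_ext * G.A.sum() * np.eye(2)).max() < 1e-8


def test_pressure_conservation(grown_state):
    """Area-weighted mean effective pressure equals P_ext on both
    networks (the boundary-integral identities)."""
    T, G, O, params, st = grown_state
    area = G.A.sum()
    mean_c = (G.A * st.stress["P_eff_c"]).sum() / area
    mean_v = (G.E * st.stress["P_eff_v"]).sum() / area
    assert mean_c == pytest.approx(params.P_ext, abs=1e-8)
    assert mean_v == pytest.approx(params.P_ext, abs=1e-8)


def test_pressure_from_divergence(grown_state):
    T, G, O, params, st = grown_state
    hf = st.h.ravel()
    assert np.abs(st.stress["P_eff_c"] + 0.5 * (O.div_c @ hf)).max() < 1e-10
    interior = ~T.peripheral_vertices
    diff = st.stress["P_eff_v"] - st.stress["trace_v_half"]
    assert np.abs(diff[interior]).max() < 1e-9


def test_single_hexagon_isotropic_stress():
    """A lone cell at equilibrium under external pressure carries the
    isotropic stress P_ext I (compression-positive)."""
    params = EnergyParams()
    from vertexcalc.dynamics import SimConfig, relax
    T, G = regular_hexagon(0.62)
    T, G, _ = relax(T, G.r, SimConfig(params=params, force_tol=1e-12))
    forces = vertex_forces(T, G, params)
    h, _ = force_potential(T, G, forces, params)
    s = stresses(T, G, forces, h, params)
    assert np.abs(s["sigma_c"][0] - params.P_ext * np.eye(2)).max() < 1e-8


def test_affine_stress(grown_state):
    T, G, O, params, st = grown_state
    aff = st.affine
    traceQ = aff["Q"][:, 0, 0] + aff["Q"][:, 1, 1]
    assert np.abs(traceQ - 1).max() < 1e-12
    assert np.abs(aff["varsigma_c"] - st.stress["sigma_c"]).max() < 1e-8
    assert np.abs(aff["P_eff"] - st.stress["P_eff_c"]).max() < 1e-8


def test_shape_tensor_trace_random_geometry(flower):
    T, G0 = flower
    _, G = perturb(T, G0, 0.25, seed=4)
    aff = affine_stress(T, G, EnergyParams())
    traceQ = aff["Q"][:, 0, 0] + aff["Q"][:, 1, 1]
    assert np.abs(traceQ - 1).max() < 1e-12


def test_regular_hexagon_shape_tensor():
    T, G = regular_hexagon(1.0)
    aff = affine_stress(T, G, EnergyParams())
    assert np.abs(aff["Q"][0] - 0.5 * np.eye(2)).max() < 1e-12


def test_stress_potentials_solvability_and_forward(grown_state):
    T, G, O, params, st = grown_state
    pots = st.potentials
    hscale = np.linalg.norm(st.h)
    for name, val in pots.solvability.items():
        assert abs(val) < 1e-8 * max(hscale, 1.0), name
    # the face Poisson problem reproduces its corrected forcing
    rhs = -(O.div_c @ pots.h_breve)
    assert np.abs(O.L_F @ pots.psi_c - rhs).max() < 1e-9
    assert np.abs(pots.Psi_c).max() == 0.0


def test_couple_stress_structure(grown_state):
    T, G, O, params, st = grown_state
    cp = st.couples
    assert cp["mu_perp_residual"] < 1e-10          # mu normal to edges
    assert np.abs(cp["div_c_mu"]).max() < 1e-10    # exact sequence
    # dual couple reproduces the trijunction torque of h
    assert np.abs(cp["CURL_v_mu_dual"] + cp["CURL_v_h"]).max() < 1e-8
    # total torque integral vanishes at equilibrium
    total = np.dot(O.M_V, cp["CURL_v_h_kite"])
    assert abs(total) < 1e-8 * max(np.linalg.norm(st.h), 1.0)


def test_uniform_Psi_gives_zero_couple(disordered_ops):
    O = disordered_ops
    mu = -(O.curl_v @ np.ones(O.T.N_v))
    assert np.abs(mu).max() < 1e-13


def test_trijunction_torque_two_routes(grown_state):
    """Antisymmetric trijunction stress from the force moments equals the
    one from the force potential's circulation at internal vertices."""
    T, G, O, params, st = grown_state
    interior = ~T.peripheral_vertices
    lhs = st.stress["antisym_v"]
    rhs = -0.5 * (O.CURL_v @ st.h.ravel())
    assert np.abs(lhs - rhs)[interior].max() < 1e-9


def test_affine_couple_uniform_pressure(grown_state):
    """With uniform cell pressures the affine trijunction couple vanishes
    at internal vertices (pressure differences drive it)."""
    T, G, O, params, st = grown_state
    ac = affine_couple(T, G, np.full(T.N_c, 0.3), P_ext=params.P_ext)
    interior = ~T.peripheral_vertices
    assert np.abs(ac["C_k"][interior]).max() < 1e-12


def test_affine_couple_uniform_edges():
    """With uniform edge lengths the couple vanishes via B A = 0."""
    T, G = hex_patch(2)
    ac = affine_couple(T, G, RNG.standard_normal(T.N_c), P_ext=0.2)
    interior = ~T.peripheral_vertices
    assert np.abs(ac["C_k"][interior]).max() < 1e-12


def test_affine_couple_hand_summed_oracle(grown_state):
    """C_k at an internal vertex equals the explicit pressure-jump sum
    -(1/6E_k) sum_ij P_i B_ij t_j^2 A_jk evaluated with plain loops."""
    T, G, O, params, st = grown_state
    press = st.energy["pressure"]
    ac = st.affine_couples
    interior = np.where(~T.peripheral_vertices)[0]
    B, A = T.B.toarray(), T.A.toarray()
    for k in interior[:5]:
        acc = 0.0
        for j in range(T.N_e):
            if A[j, k] == 0:
                continue
            jump = sum(press[i] * B[i, j] for i in range(T.N_c))
            acc += jump * G.t_len[j] ** 2 * A[j, k]
        want = -acc / (6 * G.E[k])
        assert ac["C_k"][k] == pytest.approx(want, abs=1e-12)
        assert ac["C_k_explicit"][k] == pytest.approx(want, abs=1e-12)


def test_affine_couple_repartition_identity(grown_state):
    T, G, O, params, st = grown_state
    ac = st.affine_couples
    for kap in ([1.0, 0.0], [0.3, -0.7]):
        kap = np.array(kap)
        lhs = (G.A * (2 * ac["m_c"] @ kap)).sum()
        rhs = (0.5 * G.F * (2 * ac["m_edge"] @ kap)).sum()
        assert lhs == pytest.approx(rhs, abs=1e-12)


def test_affine_and_measured_couples_both_present(grown_state):
    """The affine prediction and the measured trijunction torque are both
    nonzero on a disordered monolayer but differ (non-affine relaxation);
    the suite records their magnitude ratio rather than forcing equality."""
    T, G, O, params, st = grown_state
    interior = ~T.peripheral_vertices
    measured = st.couples["CURL_v_h"][interior]
    predicted = st.affine_couples["C_k"][interior]
    assert np.abs(measured).max() > 1e-6
    assert np.abs(predicted).max() > 1e-6
    ratio = np.abs(predicted).max() / np.abs(measured).max()
    assert not np.isclose(ratio, 1.0, rtol=1e-3)


def test_regular_patch_interior_cells_have_no_affine_couple():
    """Symmetric cells (uniform edge lengths) have vanishing cell couple
    vector."""
    T, G = hex_patch(2)
    ac = affine_couple(T, G, G.A - 1.0, P_ext=0.2)
    inner = ~T.border_cells
    assert np.abs(ac["m_c"][inner]).max() < 1e-12
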