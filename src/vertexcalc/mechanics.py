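"""Vertex-model mechanics: forces, force potential, stresses, couples.

Constitutive model
------------------
Each cell carries the standard area/perimeter energy

    U(A_i, L_i) = (A_i - 1)^2 / 2 + Gamma (L_i - L_0)^2 / 2,

so cell pressure and tension are ``P_i = A_i - 1`` and
``T_i = Gamma (L_i - L_0)``; the monolayer energy is
``sum_i U_i + P_ext * total_area`` with a uniform external pressure
acting on the periphery only.

Forces and the Maxwell-Cremona potential
----------------------------------------
``f_ik`` is the force cell ``i`` exerts on vertex ``k`` (minus the
gradient of ``U_i + P_ext A_i``); at equilibrium the forces balance
around every vertex and around every cell.  Rotating the forces by pi/2
tiles them into closed polygons whose vertices define a per-edge vector
potential ``h`` satisfying

    f_ik = - sum_j eps_i B_ij h_j A_jk .

``h`` is recovered by spanning-tree integration of the rotated forces;
closure of every independent cycle is the practical equilibrium test.
Cell and trijunction stresses follow either as first moments of the
forces or algebraically from ``h``; their traces give effective pressures
and their antisymmetric parts measure torques.  The Airy-type potentials
are obtained from the corrected field ``h + P_ext m`` (``m`` the
edge-link intersection points), which satisfies the solvability
conditions of the singular face/triangle Poisson problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .complex import Topology
from .geometry import Geometry, rot_cw, cross2
from .calculus import OperatorSet
from .hodge import eigenbasis, solve_poisson

__all__ = [
    "EnergyParams", "VertexModelEnergy", "cell_energy", "vertex_forces",
    "force_potential", "stresses", "affine_stress", "stress_potentials",
    "couple_stress", "affine_couple", "MechState", "analyse",
]


@dataclass
class EnergyParams:
    """Parameters of the cell energy (dimensionless units: target area 1)."""

    Gamma: float = 0.2      # perimeter stiffness
    L0: float = 0.75        # target perimeter
    P_ext: float = 0.2      # external pressure on the periphery
    eta: float = 1.0        # vertex drag

    def __post_init__(self):
        if self.Gamma <= 0 or self.eta <= 0:
            raise ValueError("Gamma and eta must be positive")


class VertexModelEnergy:
    """Fast energy/gradient evaluator for fixed topology.

    Works directly from vertex positions (no full geometry assembly), so
    it is the workhorse of relaxation.  The net force on vertex ``k`` is
    minus the gradient of the total energy with respect to ``r_k``.
    """

    def __init__(self, T: Topology, params: EnergyParams):
        self.T = T
        self.p = params
        self.A_inc = T.A.astype(float).tocsr()
        self.A_abs = abs(T.A).astype(float).tocsr()
        self.B_inc = T.B.astype(float).tocsr()
        self.B_abs = abs(T.B).astype(float).tocsr()
        self.A_inc_T = self.A_inc.T.tocsr()
        self.A_abs_T = self.A_abs.T.tocsr()
        self.B_inc_T = self.B_inc.T.tocsr()
        self.B_abs_T = self.B_abs.T.tocsr()

    def _measures(self, r):
        t = self.A_inc @ r
        c = 0.5 * (self.A_abs @ r)
        t_len = np.linalg.norm(t, axis=1)
        area = -0.5 * (self.B_inc @ cross2(t, c))
        perim = self.B_abs @ t_len
        return t, t_len, area, perim

    def energy(self, r):
        r = r.reshape(-1, 2)
        _, _, area, perim = self._measures(r)
        U = 0.5 * (area - 1.0) ** 2 + 0.5 * self.p.Gamma * (perim - self.p.L0) ** 2
        return float(U.sum() + self.p.P_ext * area.sum())

    def gradient(self, r):
        """d(total energy)/dr, flattened; the net vertex force is -gradient."""
        r = r.reshape(-1, 2)
        t, t_len, area, perim = self._measures(r)
        press = area - 1.0 + self.p.P_ext
        tens = self.p.Gamma * (perim - self.p.L0)
        g_edge = (self.B_inc_T @ press)[:, None] * rot_cw(t)
        grad_area = 0.5 * (self.A_abs_T @ g_edge)
        # a transiently collapsed edge has no defined direction; zero its
        # tension pull rather than poisoning the line search with NaNs
        that = t / np.maximum(t_len, 1e-30)[:, None]
        grad_perim = self.A_inc_T @ ((self.B_abs_T @ tens)[:, None] * that)
        return (grad_area + grad_perim).ravel()

    def net_forces(self, r):
        return -self.gradient(r).reshape(-1, 2)

    def max_force(self, r):
        return float(np.linalg.norm(self.net_forces(r), axis=1).max())


def cell_energy(G: Geometry, params: EnergyParams):
    """Per-cell energies, total energy, cell pressures and tensions."""
    U = 0.5 * (G.A - 1.0) ** 2 + 0.5 * params.Gamma * (G.L - params.L0) ** 2
    pressure = G.A - 1.0
    tension = params.Gamma * (G.L - params.L0)
    total = float(U.sum() + params.P_ext * G.A.sum())
    return {"U": U, "total": total, "pressure": pressure, "tension": tension}


def vertex_forces(T: Topology, G: Geometry, params: EnergyParams):
    """Per-(cell, vertex) forces ``f_ik`` and the equilibrium residual.

    ``f_ik = dU_i/dr_k`` is the elastic force revealed at vertex ``k`` by
    cell ``i``; the external pressure is not folded into it but acts as an
    explicit boundary load ``ext_k = P_ext * sum_i C_ik dA_i/dr_k``
    (nonzero only at peripheral vertices).  Equilibrium is
    ``sum_i C_ik f_ik + ext_k = 0``; minus that sum is the dynamic net
    force driving relaxation.

    Returns ``(i_idx, k_idx, f, net)`` with ``f[n]`` the force of cell
    ``i_idx[n]`` at vertex ``k_idx[n]`` and ``net`` the equilibrium
    residual per vertex (zero at equilibrium).
    """
    en = cell_energy(G, params)
    press = en["pressure"]
    tens = en["tension"]
    that = G.t / G.t_len[:, None]
    eps_t = rot_cw(G.t)

    i_list, k_list, f_list, ext_list = [], [], [], []
    for i, cell in enumerate(T.cells):
        loop = T.cell_edge_loop(i)
        for mth, k in enumerate(cell):
            j_prev, j_next = loop[mth - 1], loop[mth]
            # dA_i/dr_k = (n_prev + n_next)/2 with n_ij = B_ij eps t_j
            b_prev = T.B[i, j_prev]
            b_next = T.B[i, j_next]
            dA = 0.5 * (b_prev * eps_t[j_prev] + b_next * eps_t[j_next])
            # dL_i/dr_k = sum over the two edges of A_jk t_hat_j
            dL = T.A[j_prev, k] * that[j_prev] + T.A[j_next, k] * that[j_next]
            i_list.append(i)
            k_list.append(k)
            f_list.append(press[i] * dA + tens[i] * dL)
            ext_list.append(params.P_ext * dA)
    i_idx = np.array(i_list)
    k_idx = np.array(k_list)
    f = np.array(f_list)
    net = np.zeros((T.N_v, 2))
    np.add.at(net, k_idx, f + np.array(ext_list))
    return i_idx, k_idx, f, net


def force_potential(T: Topology, G: Geometry, forces, params: EnergyParams,
                    tol: float = 1e-8):
    """Reconstruct the per-edge force potential ``h`` from equilibrium forces.

    Adjacent edges of a cell (sharing a vertex) differ by the rotated
    force of that cell at that vertex; integrating these differences over
    a spanning tree of the edge-adjacency network determines ``h`` up to a
    constant, which is fixed so that the peripheral loop of ``h`` sits at
    ``-P_ext`` times the centroid of the periphery as traced by the
    edge-link intersections ``m``.  Every independent cycle must close to
    within ``tol`` (relative to the force scale); failure means the forces
    are not in equilibrium and is reported with the worst residual.
    """
    i_idx, k_idx, f, net = forces

    scale = 1.0 + float(np.linalg.norm(f, axis=1).mean())
    worst_net = float(np.linalg.norm(net, axis=1).max())
    if worst_net > tol * scale:
        raise ValueError(
            f"forces not in equilibrium (max vertex resultant {worst_net:.3e}); "
            "the force potential would be path dependent"
        )

    # arcs: h_{j_next} - h_{j_prev} = -eps f_ik  for cell i at vertex k
    fmap = {(int(i), int(k)): f[n] for n, (i, k) in enumerate(zip(i_idx, k_idx))}
    arcs = []
    for i, cell in enumerate(T.cells):
        loop = T.cell_edge_loop(i)
        for mth, k in enumerate(cell):
            arcs.append((loop[mth - 1], loop[mth], -rot_cw(fmap[(i, int(k))])))

    n_e = T.N_e
    h = np.zeros((n_e, 2))
    seen = np.zeros(n_e, dtype=bool)
    adj = [[] for _ in range(n_e)]
    for a, b, d in arcs:
        adj[a].append((b, d))
        adj[b].append((a, -d))
    stack = [0]
    seen[0] = True
    while stack:
        a = stack.pop()
        for b, d in adj[a]:
            if not seen[b]:
                seen[b] = True
                h[b] = h[a] + d
                stack.append(b)
    if not seen.all():
        raise ValueError("edge-adjacency network is disconnected")

    worst_cycle = max(
        float(np.linalg.norm(h[b] - h[a] - d)) for a, b, d in arcs
    )
    if worst_cycle > tol * scale:
        raise ValueError(
            f"forces not in equilibrium: worst cycle closure {worst_cycle:.3e}"
        )

    per = T.peripheral_edges
    shift = -params.P_ext * G.m[per].mean(axis=0) - h[per].mean(axis=0)
    h += shift
    return h, {"worst_cycle": worst_cycle, "max_net_force": worst_net}


def _force_reconstruction_residual(T: Topology, h, forces):
    """Max residual of the defining relation f_ik = sum_j eps_i B_ij h_j A_jk."""
    i_idx, k_idx, f, _ = forces
    worst = 0.0
    B, A = T.B, T.A
    for n, (i, k) in enumerate(zip(i_idx, k_idx)):
        loop = T.cell_edge_loop(int(i))
        acc = np.zeros(2)
        for j in loop:
            coef = B[i, j] * A[j, k]
            if coef:
                acc += coef * h[j]
        # eps_i = -eps
        worst = max(worst, float(np.linalg.norm(f[n] + rot_cw(acc))))
    return worst


def stresses(T: Topology, G: Geometry, forces, h, params: EnergyParams):
    """Cell and trijunction force stresses, pressures and torque measures.

    Each stress is computed twice: as the first moment of the elastic
    forces and from the force potential ``h``; the two routes agree
    identically at equilibrium (for trijunction stresses the potential
    route carries an explicit boundary term from the peripheral edge
    centroids).  Stresses here are compression-positive (an externally
    squeezed monolayer has positive mean stress), so the effective
    pressures ``P_eff = tr(sigma)/2 = -div h / 2`` average to ``+P_ext``.
    Returns a dict with per-cell tensors ``sigma_c`` (2x2), per-vertex
    tensors ``sigma_v``, effective pressures, and the antisymmetry
    scalars: the cell one vanishes at equilibrium (cells carry no torque)
    while the trijunction one is generically nonzero.
    """
    i_idx, k_idx, f, _ = forces
    hv = h.reshape(-1, 2)

    sigma_c = np.zeros((T.N_c, 2, 2))
    np.add.at(sigma_c, i_idx, -G.r[k_idx][:, :, None] * f[:, None, :])
    sigma_c /= G.A[:, None, None]

    sigma_v = np.zeros((T.N_v, 2, 2))
    np.add.at(sigma_v, k_idx, G.R[i_idx][:, :, None] * f[:, None, :])
    sigma_v /= G.E[:, None, None]

    # potential route: A_i sigma_c = sum_j B_ij (t_j x h_j) eps_i
    eps_i = np.array([[0.0, -1.0], [1.0, 0.0]])
    eps_k = -eps_i
    Bc = T.B.tocoo()
    sigma_c_h = np.zeros_like(sigma_c)
    contrib = (G.t[Bc.col][:, :, None] * hv[Bc.col][:, None, :]) @ eps_i
    np.add.at(sigma_c_h, Bc.row, Bc.data[:, None, None] * contrib)
    sigma_c_h /= G.A[:, None, None]

    Ac = T.A.tocoo()
    sigma_v_h = np.zeros_like(sigma_v)
    contrib = (G.Tl[Ac.row][:, :, None] * hv[Ac.row][:, None, :]) @ eps_k
    np.add.at(sigma_v_h, Ac.col, Ac.data[:, None, None] * contrib)
    # boundary term: peripheral links terminate on edge centroids, which
    # re-enter when the differencing is moved from h onto the links
    s_j = np.asarray(T.B.sum(axis=0)).ravel().astype(float)
    per = np.where(T.peripheral_edges)[0]
    eih = -rot_cw(hv)      # eps_i h_j
    for j in per:
        for k in T.edges[j]:
            a = T.A[j, k]
            sigma_v_h[k] += a * s_j[j] * np.outer(G.c[j], eih[j])
    sigma_v_h /= G.E[:, None, None]

    trace_c = sigma_c[:, 0, 0] + sigma_c[:, 1, 1]
    trace_v = sigma_v[:, 0, 0] + sigma_v[:, 1, 1]

    # trijunction effective pressure as the kite-face flux -div_v h / 2;
    # identical to tr(sigma_v)/2 at internal vertices, and at peripheral
    # kites it includes the boundary-load flux so that its area-weighted
    # mean equals the external pressure
    sj, sk, su = G.face_sides
    P_eff_v = np.zeros(T.N_v)
    np.add.at(P_eff_v, sk, np.einsum("nd,nd->n", rot_cw(su), hv[sj]))
    P_eff_v *= -0.5 / G.E

    return {
        "sigma_c": sigma_c, "sigma_c_h": sigma_c_h,
        "sigma_v": sigma_v, "sigma_v_h": sigma_v_h,
        "P_eff_c": 0.5 * trace_c,
        "P_eff_v": P_eff_v,
        "trace_v_half": 0.5 * trace_v,
        "antisym_c": 0.5 * (sigma_c[:, 1, 0] - sigma_c[:, 0, 1]),
        "antisym_v": 0.5 * (sigma_v[:, 1, 0] - sigma_v[:, 0, 1]),
    }


def affine_stress(T: Topology, G: Geometry, params: EnergyParams):
    """Shape tensor Q_i and the affine (virtual-work) cell stress.

    ``Q_i = (1/L_i) sum_j |B_ij| t_j (x) t_hat_j`` has unit trace.  In the
    compression-positive convention used throughout, the affine stress is
    ``-(P_i I + (T_i L_i / A_i) Q_i)``; it is symmetric and equals the
    moment-of-forces stress at equilibrium, and its half-trace gives the
    effective pressure ``-(P_i + T_i L_i / (2 A_i))``.
    """
    en = cell_energy(G, params)
    that = G.t / G.t_len[:, None]
    Bc = abs(T.B).tocoo()
    Q = np.zeros((T.N_c, 2, 2))
    outer = G.t[Bc.col][:, :, None] * that[Bc.col][:, None, :]
    np.add.at(Q, Bc.row, Bc.data[:, None, None] * outer)
    Q /= G.L[:, None, None]
    I2 = np.eye(2)
    varsigma = -(en["pressure"][:, None, None] * I2
                 + (en["tension"] * G.L / G.A)[:, None, None] * Q)
    P_eff = -(en["pressure"] + en["tension"] * G.L / (2.0 * G.A))
    return {"Q": Q, "varsigma_c": varsigma, "P_eff": P_eff}


@dataclass
class StressPotentials:
    """Scalar potentials of the equilibrium force potential.

    Airy-type (``psi``) potentials are solved from the corrected field
    ``h_breve = h + P_ext m`` via the singular Laplacians (their kernel
    integrals vanish by the boundary-pressure identities); Mindlin-type
    (``Psi``) potentials are solved from ``h`` itself.  ``Psi_c`` is
    identically zero because cells carry no torque.
    """

    psi_c: np.ndarray
    Psi_c: np.ndarray
    psi_v: np.ndarray
    Psi_v: np.ndarray
    psi_v_dual: np.ndarray      # over triangles
    Psi_v_dual: np.ndarray
    psi_c_dual: np.ndarray      # over cell centres
    Psi_c_dual: np.ndarray
    h_breve: np.ndarray
    solvability: dict


def stress_potentials(O: OperatorSet, h, params: EnergyParams,
                      tol: float = 1e-6) -> StressPotentials:
    T, G = O.T, O.G
    hv = np.asarray(h, dtype=float).reshape(-1, 2)
    hb = (hv + params.P_ext * G.m).ravel()
    hflat = hv.ravel()

    area = G.A.sum()
    sol = {
        "div_c": float(O.inner_F(np.ones(T.N_c), O.div_c @ hb)),
        "div_v": float(O.inner_V(np.ones(T.N_v), O.div_v_kite @ hb)),
        "curl_c": float(O.inner_F(np.ones(T.N_c), O.curl_c @ hflat)),
        "CURL_v": float(O.inner_V(np.ones(T.N_v), O.CURL_v_kite @ hflat)),
    }
    hscale = max(float(np.linalg.norm(hflat)), 1e-300)
    for name, val in sol.items():
        if abs(val) > tol * hscale * max(area, 1.0):
            raise ValueError(f"solvability residual {name} = {val:.3e}")

    bF = eigenbasis(O.L_F, O.M_F)
    bV = eigenbasis(O.L_V, O.M_V)
    bT = eigenbasis(O.L_T, O.M_V)
    bC = eigenbasis(O.L_C, O.M_F)
    Pb = O.P_b

    psi_c = solve_poisson(O.L_F, O.M_F, -(O.div_c @ hb), basis=bF)
    psi_v = solve_poisson(O.L_V, O.M_V, -(O.tdiv_v @ hb), basis=bV)
    Psi_v = solve_poisson(O.L_V, O.M_V, O.tcurl_v @ hflat, basis=bV)
    Psi_c = np.zeros(T.N_c)

    psi_v_dual = solve_poisson(O.L_T, O.M_V, -(O.div_v @ hb), basis=bT)
    Psi_v_dual = solve_poisson(O.L_T, O.M_V, O.CURL_v @ hflat, basis=bT)
    psi_c_dual = solve_poisson(O.L_C, O.M_F, -(O.tdiv_c @ (Pb * hb)), basis=bC)
    Psi_c_dual = solve_poisson(O.L_C, O.M_F, O.tCURL_c @ (Pb * hflat), basis=bC)

    return StressPotentials(
        psi_c=psi_c, Psi_c=Psi_c, psi_v=psi_v, Psi_v=Psi_v,
        psi_v_dual=psi_v_dual, Psi_v_dual=Psi_v_dual,
        psi_c_dual=psi_c_dual, Psi_c_dual=Psi_c_dual,
        h_breve=hb, solvability=sol,
    )


def couple_stress(O: OperatorSet, pots: StressPotentials, h):
    """Couple-stress vectors and trijunction torque measures.

    ``mu = -curl_v Psi_v`` lies normal to every edge and has identically
    zero divergence around cells (it exerts no couple traction on any
    cell); its dual counterpart reproduces the antisymmetric trijunction
    stress through ``CURL_v``.
    """
    T = O.T
    hflat = np.asarray(h, dtype=float).ravel()
    mu = -(O.curl_v @ pots.Psi_v)
    mu_dual = -(O.tCURL_v @ pots.Psi_v_dual) - (O.CURL_c @ pots.Psi_c_dual)
    muv = mu.reshape(-1, 2)
    perp = float(np.abs(np.einsum("jd,jd->j", muv, O.G.t)).max())
    return {
        "mu": mu,
        "mu_dual": mu_dual,
        "mu_perp_residual": perp,
        "div_c_mu": O.div_c @ mu,
        "CURL_v_mu_dual": O.CURL_v @ mu_dual,
        "CURL_v_h": O.CURL_v @ hflat,
        "CURL_v_h_kite": O.CURL_v_kite @ hflat,
        "curl_c_h": O.curl_c @ hflat,
    }


def affine_couple(T: Topology, G: Geometry, pressures, P_ext: float):
    """Affine-approximation couple vectors from intercellular pressure jumps.

    ``m_c[i]`` is the cell couple vector (vanishes for symmetric cells),
    ``m_edge[j]`` its repartition onto edges/links, and ``C_k`` the
    resulting trijunction couple: the pressure difference across each edge
    times the squared edge length, summed around the vertex.  ``C_k``
    vanishes when pressures are uniform or when all edges have equal
    length (internal vertices).
    """
    eps_t = rot_cw(G.t)               # n_ij = B_ij eps t_j
    Bc = T.B.tocoo()
    pP = np.asarray(pressures, dtype=float) + P_ext

    m_c = np.zeros((T.N_c, 2))
    w = (G.t_len**2)[Bc.col, None] * Bc.data[:, None] * eps_t[Bc.col]
    np.add.at(m_c, Bc.row, pP[Bc.row, None] * w / 1.0)
    m_c *= 1.0 / (12.0 * G.A[:, None])

    m_edge = np.zeros((T.N_e, 2))
    np.add.at(m_edge, Bc.col, (pP[Bc.row, None] * Bc.data[:, None]) * eps_t[Bc.col])
    m_edge *= (G.t_len**2 / (6.0 * G.F))[:, None]

    # trijunction couple: CURL_v of m_edge; explicit pressure-jump form at
    # internal vertices
    Ac = T.A.tocoo()
    C_k = np.zeros(T.N_v)
    np.add.at(C_k, Ac.col, Ac.data * np.einsum("jd,jd->j", G.Tl, m_edge)[Ac.row])
    C_k /= G.E

    jump = np.zeros(T.N_e)
    np.add.at(jump, Bc.col, Bc.data * np.asarray(pressures, dtype=float)[Bc.row])
    C_k_explicit = np.zeros(T.N_v)
    np.add.at(C_k_explicit, Ac.col, Ac.data * (jump * G.t_len**2)[Ac.row])
    C_k_explicit *= -1.0 / (6.0 * G.E)

    return {"m_c": m_c, "m_edge": m_edge, "C_k": C_k, "C_k_explicit": C_k_explicit}


@dataclass
class MechState:
    """Complete mechanical analysis of an equilibrium monolayer."""

    energy: dict
    forces: tuple
    h: np.ndarray
    h_info: dict
    stress: dict
    affine: dict
    potentials: StressPotentials
    couples: dict
    affine_couples: dict


def analyse(T: Topology, G: Geometry, params: EnergyParams,
            O: OperatorSet = None, equilibrium_tol: float = 1e-8) -> MechState:
    """Run the full mechanical pipeline on an equilibrium configuration."""
    from .calculus import build_operators

    if O is None:
        O = build_operators(T, G)
    en = cell_energy(G, params)
    forces = vertex_forces(T, G, params)
    h, info = force_potential(T, G, forces, params, tol=equilibrium_tol)
    st = stresses(T, G, forces, h, params)
    aff = affine_stress(T, G, params)
    pots = stress_potentials(O, h, params)
    cp = couple_stress(O, pots, h)
    ac = affine_couple(T, G, en["pressure"], params.P_ext)
    return MechState(
        energy=en, forces=forces, h=h, h_info=info, stress=st, affine=aff,
        potentials=pots, couples=cp, affine_couples=ac,
    )
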