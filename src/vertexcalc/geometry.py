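"""Metric quantities of a positioned cell complex.

Conventions
-----------
The 2D Levi-Civita matrix ``eps = [[0, 1], [-1, 0]]`` rotates a vector
clockwise by pi/2.  Cell orientations are ``eps_i = -eps`` (all cells) and
triangle orientations ``eps_k = +eps`` (opposite sense).  With every cell
traversed counterclockwise these signs make the area identities

    sum_j B_ij t_j (x) c_j = A_i eps_i,     A_i > 0,

come out positive, and the edge/link orientation constraint

    T_j . (eps_i t_j) = t_j . (eps_k T_j) = F_j > 0

holds automatically, where F_j/2 is the area of the trapezium (interior
edges) or triangle (peripheral edges) spanned by edge ``t_j`` and its dual
link ``T_j``.

Links triangulate cell centres (plain vertex centroids ``R_i``); at the
periphery they connect border-cell centres to peripheral edge centroids.
The dual tessellation therefore has triangular faces around internal
vertices and kite-shaped faces (one kite, or a pair sharing a chord)
around peripheral vertices; ``E_k`` is the face area, and cells, trapezia
and dual faces all partition the total area:

    sum_i A_i = sum_j F_j / 2 = sum_k E_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .complex import Topology, build_complex

__all__ = [
    "EPS",
    "Geometry",
    "assemble_geometry",
    "metric_matrices",
    "edge_link_intersections",
]

#: clockwise pi/2 rotation
EPS = np.array([[0.0, 1.0], [-1.0, 0.0]])


def rot_cw(v: np.ndarray) -> np.ndarray:
    """Apply ``EPS`` (clockwise pi/2 rotation) along the last axis."""
    return np.stack([v[..., 1], -v[..., 0]], axis=-1)


def cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def polygon_area(pts: np.ndarray) -> float:
    """Signed shoelace area (positive for counterclockwise order)."""
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class Geometry:
    T: Topology
    r: np.ndarray              # vertex positions (N_v, 2)
    t: np.ndarray              # edge vectors (N_e, 2)
    t_len: np.ndarray
    c: np.ndarray              # edge centroids
    c_p: np.ndarray            # peripheral edge centroids (0 elsewhere)
    R: np.ndarray              # cell centres (vertex centroids)
    Tl: np.ndarray             # link vectors (N_e, 2)
    T_len: np.ndarray
    C_link: np.ndarray         # link centroids
    m: np.ndarray              # edge-link intersection points
    A: np.ndarray              # cell areas
    L: np.ndarray              # cell perimeters
    E: np.ndarray              # dual-face (triangle / kite) areas
    F: np.ndarray              # 2 x trapezium area per edge
    K: dict                    # kite areas keyed by (cell, vertex)
    # per-(edge, vertex) side vectors of the dual faces, used by the
    # peripheral-kite operator variants: u[jk] sums the (counterclockwise)
    # boundary sides of face k attributed to edge j; for internal vertices
    # u_jk = -A_jk T_j.
    face_sides: tuple = field(repr=False, default=None)

    @property
    def total_area(self) -> float:
        return float(self.A.sum())

    def outward_normal(self, i: int, j: int) -> np.ndarray:
        """Outward normal of cell ``i`` at edge ``j``: n_ij = -eps_i B_ij t_j."""
        b = self.T.B[i, j]
        return rot_cw(self.t[j]) * b  # -eps_i = +eps

    def per_cell_tables(self):
        """Per-cell, per-edge and per-vertex summary tables (pandas)."""
        import pandas as pd

        cells = pd.DataFrame(
            {"area": self.A, "perimeter": self.L, "n_edges": self.T.Z}
        )
        edges = pd.DataFrame(
            {"t": self.t_len, "T": self.T_len, "F": self.F,
             "peripheral": self.T.peripheral_edges}
        )
        verts = pd.DataFrame(
            {"E": self.E, "peripheral": self.T.peripheral_vertices}
        )
        return cells, edges, verts


def _canonicalise_ccw(T: Topology, positions: np.ndarray) -> Topology:
    """Rebuild the complex with every cell ordered counterclockwise."""
    flipped = False
    cells = []
    for c in T.cells:
        a = polygon_area(positions[c])
        if a == 0.0:
            raise ValueError("degenerate cell with zero area")
        if a < 0:
            cells.append(c[::-1])
            flipped = True
        else:
            cells.append(c)
    return build_complex(cells) if flipped else T


def _dual_face_polygon(T: Topology, r, c, R, k: int):
    """Ordered boundary of the dual face around peripheral vertex ``k``.

    Returns (points, tags): the face polygon in counterclockwise order and,
    per side, the edge index the side is attributed to.  Faces are the kite
    (one adjacent cell) or the pair of kites joined along the chord between
    the two cell centres (two adjacent cells).
    """
    A_csc = T.A.tocsc()
    edges_at_k = A_csc.indices[A_csc.indptr[k]:A_csc.indptr[k + 1]]
    per = [j for j in edges_at_k if T.peripheral_edges[j]]
    interior = [j for j in edges_at_k if not T.peripheral_edges[j]]
    if len(per) != 2:
        raise ValueError(f"peripheral vertex {k} has {len(per)} peripheral edges")
    jA, jB = per

    B_csc = T.B.tocsc()

    def _cell_of(j):
        return B_csc.indices[B_csc.indptr[j]:B_csc.indptr[j + 1]]

    cells_A = set(_cell_of(jA))
    cells_B = set(_cell_of(jB))
    if interior:
        (j0,) = interior
        iA = cells_A.pop()
        iB = cells_B.pop()
        pts = [r[k], c[jA], R[iA], R[iB], c[jB]]
        tags = [jA, jA, j0, jB, jB]
    else:
        (i,) = cells_A
        pts = [r[k], c[jA], R[i], c[jB]]
        tags = [jA, jA, jB, jB]
    pts = np.array(pts)
    if polygon_area(pts) < 0:
        pts = pts[::-1]
        # side s runs pts[s] -> pts[s+1]; reversing the vertex ring maps the
        # side between old points (p, p+1) to the side between new points
        # (n-1-p-1, n-1-p), whose tag is the old tags[p]
        tags = tags[::-1]
        tags = tags[1:] + tags[:1]
    return pts, tags


def assemble_geometry(T: Topology, positions: np.ndarray):
    """Compute every metric field of a positioned complex.

    Cells are canonicalised to counterclockwise order first (which may
    rebuild the incidence matrices); the returned pair is
    ``(topology, geometry)`` with the topology actually used.

    Raises
    ------
    ValueError
        For nonpositive cell areas, self-intersecting cells, or a
        degenerate edge/link pair (``F_j`` vanishing relative to its mean).
    """
    positions = np.asarray(positions, dtype=float)
    T = _canonicalise_ccw(T, positions)
    r = positions

    t = T.A @ r                            # edge vectors, lo -> hi
    t_len = np.linalg.norm(t, axis=1)
    if np.any(t_len == 0):
        raise ValueError("degenerate zero-length edge")
    c = 0.5 * (abs(T.A) @ r)

    Zinv = 1.0 / T.Z
    R = (T.C @ r) * Zinv[:, None]

    s = np.asarray(T.B.sum(axis=0)).ravel().astype(float)   # +-1 peripheral, 0 interior
    c_p = (np.abs(s)[:, None]) * c
    Tl = T.B.T @ R - s[:, None] * c

    T_len = np.linalg.norm(Tl, axis=1)
    F = cross2(t, Tl)
    if np.any(F <= 0):
        bad = int(np.argmin(F))
        raise ValueError(
            f"orientation constraint violated at edge {bad}: F={F[bad]:.3e}"
        )
    if np.any(F < 1e-12 * F.mean()):
        raise ValueError("degenerate edge/link pair (F_j ~ 0)")

    # cell areas and perimeters
    Babs = abs(T.B)
    L = Babs @ t_len
    A = np.zeros(T.N_c)
    for i, cell in enumerate(T.cells):
        A[i] = polygon_area(r[cell])
    if np.any(A <= 0):
        raise ValueError("cell with nonpositive area after canonicalisation")
    # guard against self-intersecting polygons: shoelace must match the
    # kite partition computed below (checked at the end)

    # link centroids: midpoints of link endpoints (cell centres, or cell
    # centre and peripheral edge centroid)
    C_link = 0.5 * (Babs.T @ R) + 0.5 * c_p

    m = edge_link_intersections_raw(T, r, c, R, Tl)

    # dual-face areas E_k and the per-(edge,vertex) side vectors
    E = np.zeros(T.N_v)
    A_coo = T.A.tocoo()
    interior = ~T.peripheral_vertices
    # internal vertices: triangle of the three cell centres, via
    # E_k = 1/2 sum_j N_jk . C_j with N_jk = -eps_k A_jk T_j
    NdotC = cross2(Tl, C_link)            # (eps T) . C = -cross(T, C) -> sign below
    # (eps_k T_j) . C_j = -cross2(T_j, C_j); N_jk = -A_jk eps_k T_j
    # E_k = 1/2 sum_j A_jk cross2(T_j, C_j) ... sign fixed by CCW convention
    contrib = np.zeros(T.N_v)
    np.add.at(contrib, A_coo.col, A_coo.data * NdotC[A_coo.row])
    E[interior] = 0.5 * contrib[interior]

    side_rows, side_cols, side_ux, side_uy = [], [], [], []
    # internal vertices: u_jk = -A_jk T_j
    mask_int = interior[A_coo.col]
    side_rows.extend(A_coo.row[mask_int].tolist())
    side_cols.extend(A_coo.col[mask_int].tolist())
    u_int = -A_coo.data[mask_int, None] * Tl[A_coo.row[mask_int]]
    side_ux.extend(u_int[:, 0].tolist())
    side_uy.extend(u_int[:, 1].tolist())

    for k in np.where(T.peripheral_vertices)[0]:
        pts, tags = _dual_face_polygon(T, r, c, R, k)
        E[k] = polygon_area(pts)
        n = len(pts)
        acc = {}
        for sidx in range(n):
            v = pts[(sidx + 1) % n] - pts[sidx]
            j = tags[sidx]
            acc[j] = acc.get(j, np.zeros(2)) + v
        for j, u in acc.items():
            side_rows.append(j)
            side_cols.append(int(k))
            side_ux.append(u[0])
            side_uy.append(u[1])
    if np.any(E <= 0):
        raise ValueError("nonpositive dual-face area")

    face_sides = (
        np.array(side_rows, dtype=np.int64),
        np.array(side_cols, dtype=np.int64),
        np.column_stack([side_ux, side_uy]),
    )

    # kite areas K_ik: quadrilateral (cell centre, edge centroid, vertex,
    # edge centroid); they partition each cell
    K = {}
    for i, cell in enumerate(T.cells):
        z = len(cell)
        loop = T.cell_edge_loop(i)
        for mth, k in enumerate(cell):
            j_prev = loop[mth - 1]
            j_next = loop[mth]
            quad = np.array([R[i], c[j_prev], r[k], c[j_next]])
            a = polygon_area(quad)
            K[(i, int(k))] = abs(a)
        if abs(sum(K[(i, int(k))] for k in cell) - A[i]) > 1e-9 * max(A[i], 1.0):
            raise ValueError(f"cell {i} is self-intersecting")

    return T, Geometry(
        T=T, r=r, t=t, t_len=t_len, c=c, c_p=c_p, R=R, Tl=Tl, T_len=T_len,
        C_link=C_link, m=m, A=A, L=L, E=E, F=F, K=K, face_sides=face_sides,
    )


def edge_link_intersections_raw(T: Topology, r, c, R, Tl) -> np.ndarray:
    """Intersection m_j of the line through edge j with the line through
    link j.  For peripheral edges the link terminates on the edge centroid,
    so m_j = c_j exactly."""
    N_e = T.N_e
    m = np.zeros((N_e, 2))
    t = T.A @ r
    # a point on each link line: the centre of any adjacent cell
    B_csc = T.B.tocsc()
    first_cell = np.zeros(N_e, dtype=np.int64)
    for j in range(N_e):
        first_cell[j] = B_csc.indices[B_csc.indptr[j]]
    P_edge = c                      # point on the edge line
    P_link = R[first_cell]          # point on the link line
    denom = cross2(t, Tl)
    if np.any(denom == 0):
        raise ValueError("parallel edge and link (F_j = 0)")
    # solve P_edge + a t = P_link + b T  =>  a = cross(P_link - P_edge, T)/cross(t, T)
    a = cross2(P_link - P_edge, Tl) / denom
    m = P_edge + a[:, None] * t
    m[T.peripheral_edges] = c[T.peripheral_edges]
    return m


def edge_link_intersections(G: Geometry) -> np.ndarray:
    """Edge-link intersection points ``m_j`` of a geometry (already cached)."""
    return G.m


def metric_matrices(G: Geometry):
    """Diagonal metric matrices H, E, T_e, T_l.

    ``H = diag(A_i)``, ``E = diag(E_k)``, ``T_e = diag(t_j^2 / F_j)``,
    ``T_l = diag(T_j^2 / F_j)``; all entries strictly positive.
    """
    H = sp.diags(G.A)
    E = sp.diags(G.E)
    T_e = sp.diags(G.t_len**2 / G.F)
    T_l = sp.diags(G.T_len**2 / G.F)
    for M, name in ((H, "H"), (E, "E"), (T_e, "T_e"), (T_l, "T_l")):
        if np.any(M.diagonal() <= 0):
            raise ValueError(f"nonpositive diagonal entry in {name}")
    return {"H": H, "E": E, "T_e": T_e, "T_l": T_l}
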