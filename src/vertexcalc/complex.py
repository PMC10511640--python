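"""Combinatorial cell complex of a confluent planar monolayer.

A monolayer is a simply connected tiling of the plane by polygonal cells.
Its topology is carried by two signed incidence matrices:

* ``A`` (edges x vertices): ``A[j, k] = +1`` if edge ``j`` points into
  vertex ``k``, ``-1`` if it points out of it, ``0`` otherwise.
* ``B`` (cells x edges): ``B[i, j] = +1`` if edge ``j`` bounds cell ``i``
  with congruent orientation (the edge direction agrees with the cell's
  traversal order), ``-1`` if opposite, ``0`` otherwise.

The product ``B @ A`` vanishes identically ("the boundary of a boundary is
empty"); this identity underpins every discrete differential operator built
downstream.  Internal vertices are tricellular: they touch exactly three
cells and three edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["Topology", "build_complex", "validate_topology", "divide_cell"]


@dataclass
class Topology:
    """Incidence description of a polygonal cell complex.

    Attributes
    ----------
    cells : list of list of int
        Per-cell cyclically ordered vertex indices (the generating data;
        edge enumeration and incidence matrices are derived from it
        deterministically).
    edges : ndarray, shape (N_e, 2)
        Vertex pairs ``(lo, hi)`` with ``lo < hi``; edge ``j`` is oriented
        from ``lo`` to ``hi``.  Rows are sorted lexicographically, which
        makes the enumeration reproducible.
    A, B : scipy.sparse.csr_matrix of int8
        Signed incidence matrices described in the module docstring.
    C : scipy.sparse.csr_matrix of int8
        Unsigned cell-vertex adjacency, ``C = |B| |A| / 2``.
    Z : ndarray of int
        Number of edges (= vertices) of each cell.
    peripheral_edges, peripheral_vertices, border_cells : ndarray of bool
        An edge is peripheral iff it bounds exactly one cell; a vertex is
        peripheral iff it lies on a peripheral edge; a cell is a border
        cell iff it owns a peripheral edge.
    I_b : ndarray of float
        Diagonal of the projector that removes "orphan" links at the
        periphery (links that reach only one cell centre): 1 on interior
        edges, 0 on peripheral edges.
    """

    cells: list
    edges: np.ndarray
    A: sp.csr_matrix
    B: sp.csr_matrix
    C: sp.csr_matrix
    Z: np.ndarray
    peripheral_edges: np.ndarray
    peripheral_vertices: np.ndarray
    border_cells: np.ndarray
    I_b: np.ndarray
    edge_index: dict = field(repr=False, default_factory=dict)

    @property
    def N_c(self) -> int:
        return len(self.cells)

    @property
    def N_e(self) -> int:
        return self.edges.shape[0]

    @property
    def N_v(self) -> int:
        return int(max(max(c) for c in self.cells)) + 1

    @property
    def euler_characteristic(self) -> int:
        return self.N_c - self.N_e + self.N_v

    def cell_edge_loop(self, i: int) -> list:
        """Edge indices of cell ``i`` in traversal order."""
        verts = self.cells[i]
        z = len(verts)
        return [self.edge_index[_key(verts[m], verts[(m + 1) % z])] for m in range(z)]


def _key(a: int, b: int) -> tuple:
    return (a, b) if a < b else (b, a)


def build_complex(cells) -> Topology:
    """Build a :class:`Topology` from per-cell ordered vertex lists.

    Parameters
    ----------
    cells : sequence of sequence of int
        Cyclically ordered vertex indices of each cell.  Shared edges must
        appear in exactly two cells with opposite traversal order.

    Raises
    ------
    ValueError
        For non-manifold edges (in more than two cells), internal vertices
        that are not tricellular, or a disconnected input.
    """
    cells = [list(map(int, c)) for c in cells]
    if not cells:
        raise ValueError("empty cell list")
    for c in cells:
        if len(c) < 3 or len(set(c)) != len(c):
            raise ValueError(f"invalid cell vertex list: {c}")

    n_v = max(max(c) for c in cells) + 1

    # deterministic edge enumeration: sorted unordered vertex pairs
    edge_cells: dict = {}
    for i, c in enumerate(cells):
        z = len(c)
        for m in range(z):
            a, b = c[m], c[(m + 1) % z]
            k = _key(a, b)
            edge_cells.setdefault(k, []).append((i, 1 if a < b else -1))

    for k, owners in edge_cells.items():
        if len(owners) > 2:
            raise ValueError(f"non-manifold edge {k}: bounds {len(owners)} cells")
        if len(owners) == 2 and owners[0][1] == owners[1][1]:
            raise ValueError(f"edge {k} traversed in the same direction by both cells")

    edges = np.array(sorted(edge_cells), dtype=np.int64).reshape(-1, 2)
    edge_index = {tuple(e): j for j, e in enumerate(map(tuple, edges))}
    n_e = len(edges)
    n_c = len(cells)

    # A: edge j points lo -> hi
    rows = np.repeat(np.arange(n_e), 2)
    cols = edges.ravel()
    vals = np.tile(np.array([-1, 1], dtype=np.int8), n_e)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n_e, n_v))

    b_rows, b_cols, b_vals = [], [], []
    for k, owners in edge_cells.items():
        j = edge_index[k]
        for i, s in owners:
            b_rows.append(i)
            b_cols.append(j)
            b_vals.append(s)
    B = sp.csr_matrix(
        (np.array(b_vals, dtype=np.int8), (b_rows, b_cols)), shape=(n_c, n_e)
    )

    C = (abs(B) @ abs(A)) * 0.5
    C = C.astype(np.int8).tocsr()
    Z = np.asarray(abs(B).sum(axis=1)).ravel().astype(np.int64)

    n_cells_per_edge = np.asarray(abs(B).sum(axis=0)).ravel()
    peripheral_edges = n_cells_per_edge == 1
    peripheral_vertices = np.zeros(n_v, dtype=bool)
    peripheral_vertices[np.unique(edges[peripheral_edges].ravel())] = True
    border_cells = np.asarray(
        (abs(B)[:, peripheral_edges]).sum(axis=1)
    ).ravel() > 0
    I_b = (~peripheral_edges).astype(float)

    T = Topology(
        cells=cells,
        edges=edges,
        A=A,
        B=B,
        C=C,
        Z=Z,
        peripheral_edges=peripheral_edges,
        peripheral_vertices=peripheral_vertices,
        border_cells=border_cells,
        I_b=I_b,
        edge_index=edge_index,
    )

    report = validate_topology(T)
    fatal = [r for r in report if r[0] in ("degree", "disconnected")]
    if fatal:
        raise ValueError("; ".join(str(r) for r in fatal))
    return T


def validate_topology(T: Topology) -> list:
    """Report every violated topological invariant.

    Returns a list of tuples ``(kind, detail)``; an empty list means the
    complex is valid.  Checked: ``B A = 0`` in integer arithmetic,
    ``C = |B||A|/2``, tricellularity of internal vertices, connectivity and
    the Euler characteristic of a simply connected complex.
    """
    report = []

    BA = (T.B @ T.A).tocoo()
    for i, k, v in zip(BA.row, BA.col, BA.data):
        if v != 0:
            report.append(("BA", (int(i), int(k), int(v))))

    C2 = (abs(T.B) @ abs(T.A)).toarray()
    if not np.array_equal(C2, 2 * T.C.toarray()):
        report.append(("C", "C != |B||A|/2"))

    deg_cells = np.asarray(T.C.sum(axis=0)).ravel()
    deg_edges = np.asarray(abs(T.A).sum(axis=0)).ravel()
    for k in np.where(~T.peripheral_vertices)[0]:
        if deg_cells[k] != 3 or deg_edges[k] != 3:
            report.append(
                ("degree", f"internal vertex {k}: {deg_cells[k]} cells, "
                           f"{deg_edges[k]} edges (expected 3, 3)")
            )

    adj = sp.csr_matrix(
        (np.ones(T.N_e), (T.edges[:, 0], T.edges[:, 1])), shape=(T.N_v, T.N_v)
    )
    n_comp = sp.csgraph.connected_components(
        adj, directed=False, return_labels=False
    )
    if n_comp != 1:
        report.append(("disconnected", f"{n_comp} components"))

    chi = T.euler_characteristic
    if chi != 1:
        report.append(("euler", f"N_c - N_e + N_v = {chi} (expected 1)"))

    return report


def divide_cell(T: Topology, i: int, arc1, arc2, new_ids=None) -> Topology:
    """Split cell ``i`` along a new edge joining two new vertices.

    ``arc1`` and ``arc2`` are the two complementary vertex-ordered arcs of
    cell ``i``'s boundary.  Two new vertices are inserted on the edges
    separating the arcs (divisions always bisect two edges, never pass
    through a vertex, so internal vertices stay tricellular) and joined by
    a new edge.  Returns a rebuilt :class:`Topology` with one extra cell,
    three extra edges and two extra vertices; the Euler characteristic is
    preserved.
    """
    arc1, arc2 = list(arc1), list(arc2)
    cell = T.cells[i]
    if sorted(arc1 + arc2) != sorted(cell) or not arc1 or not arc2:
        raise ValueError("arcs do not partition the cell boundary")
    # the arcs must be contiguous runs of the cell's cyclic vertex order
    z = len(cell)
    doubled = cell + cell
    def _is_run(arc):
        for s in range(z):
            if doubled[s:s + len(arc)] == arc:
                return s
        return None
    s1 = _is_run(arc1)
    s2 = _is_run(arc2)
    if s1 is None or s2 is None:
        raise ValueError("arcs are not contiguous in the cell's vertex order")
    if (s1 + len(arc1)) % z != s2 % z or (s2 + len(arc2)) % z != s1 % z:
        raise ValueError("arcs are not complementary")

    n_v = T.N_v
    if new_ids is None:
        new_ids = (n_v, n_v + 1)
    va, vb = new_ids  # va on edge (arc1[-1], arc2[0]); vb on edge (arc2[-1], arc1[0])

    split_a = _key(arc1[-1], arc2[0])
    split_b = _key(arc2[-1], arc1[0])
    if split_a == split_b:
        raise ValueError("division must split two distinct edges")

    def _insert(lst, a, b, v):
        out = []
        zz = len(lst)
        for m in range(zz):
            out.append(lst[m])
            if _key(lst[m], lst[(m + 1) % zz]) == _key(a, b):
                out.append(v)
        return out

    new_cells = []
    for ic, c in enumerate(T.cells):
        if ic == i:
            continue
        cc = c
        if _key(*split_a) in (_key(c[m], c[(m + 1) % len(c)]) for m in range(len(c))):
            cc = _insert(cc, *split_a, va)
        if _key(*split_b) in (_key(cc[m], cc[(m + 1) % len(cc)]) for m in range(len(cc))):
            cc = _insert(cc, *split_b, vb)
        new_cells.append(cc)

    # traversal: ...arc1, va (on split_a), then along the new edge to vb
    # (on split_b), closing to arc1[0]; likewise for the sibling
    daughter1 = list(arc1) + [va, vb]
    daughter2 = list(arc2) + [vb, va]
    new_cells.extend([daughter1, daughter2])

    return build_complex(new_cells)
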