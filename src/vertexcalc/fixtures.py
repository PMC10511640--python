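"""Deterministic analytic meshes for tests and worked examples.

All fixtures are generated from closed-form coordinates (no data files),
so rebuilding one always yields bit-identical topology and geometry.
The honeycomb patch doubles as the edge-link orthogonality fixture: in a
regular hexagonal tiling every link is perpendicular to its edge, which
collapses the four Laplacians to two.
"""

from __future__ import annotations

import numpy as np

from .complex import Topology, build_complex
from .geometry import Geometry, assemble_geometry

__all__ = ["regular_hexagon", "hex_patch", "perturb", "from_mesh"]


def from_mesh(cells, positions):
    """Build (Topology, Geometry) from per-cell vertex lists + coordinates."""
    T = build_complex(cells)
    return assemble_geometry(T, np.asarray(positions, dtype=float))


def regular_hexagon(side: float = 1.0):
    """Single regular hexagonal cell of the given side length.

    Area is ``(3 sqrt(3) / 2) side^2``; ``side = (2 / (3 sqrt(3)))**0.5``
    (about 0.6204) gives unit area, the rest state of the standard cell
    energy.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    ang = np.pi / 3 * np.arange(6)
    pos = side * np.column_stack([np.cos(ang), np.sin(ang)])
    return from_mesh([[0, 1, 2, 3, 4, 5]], pos)


def hex_patch(rings: int = 1, side: float = 1.0):
    """Honeycomb patch: all cells within ``rings`` of a central hexagon.

    Contains ``3 rings (rings+1) + 1`` cells and ``6 (rings+1)^2``
    vertices, every internal vertex tricellular.  Edges are exactly
    orthogonal to links, making this the reference mesh for the
    orthogonal-limit identities ``L_T = L_V`` and ``L_F = L_C``.
    """
    if rings < 0:
        raise ValueError("rings must be >= 0")
    s3 = np.sqrt(3.0)
    centres = []
    for q in range(-rings, rings + 1):
        for r in range(-rings, rings + 1):
            if abs(q + r) <= rings:
                centres.append((side * s3 * (q + r / 2.0), side * 1.5 * r))
    ang = np.pi / 6 + np.pi / 3 * np.arange(6)
    offsets = side * np.column_stack([np.cos(ang), np.sin(ang)])

    vid: dict = {}
    pos = []
    cells = []
    for cx, cy in sorted(centres):
        cell = []
        for ox, oy in offsets:
            key = (round(cx + ox, 9), round(cy + oy, 9))
            if key not in vid:
                vid[key] = len(pos)
                pos.append([cx + ox, cy + oy])
            cell.append(vid[key])
        cells.append(cell)
    return from_mesh(cells, np.array(pos))


def perturb(T: Topology, G: Geometry, amplitude: float, seed: int = 0):
    """Jitter interior vertices by uniform displacements in
    ``[-amplitude, amplitude]^2`` (deterministic in ``seed``) and rebuild
    the geometry.  Raises if the jitter inverts a cell."""
    rng = np.random.default_rng(seed)
    r = G.r.copy()
    interior = ~T.peripheral_vertices
    r[interior] += amplitude * rng.uniform(-1, 1, size=(interior.sum(), 2))
    return assemble_geometry(T, r)
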