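"""Mesh JSON serialisation.

Schema: ``{"vertices": [[x, y], ...], "cells": [[k0, k1, ...], ...]}``
with cells as cyclically ordered vertex index lists.  Coordinates round
trip bit-exactly (JSON floats are written with ``repr`` precision).
"""

from __future__ import annotations

import json

import numpy as np

from .complex import build_complex
from .geometry import assemble_geometry

__all__ = ["save_mesh", "load_mesh", "mesh_dict"]


def mesh_dict(T, G) -> dict:
    return {
        "vertices": [[float(x), float(y)] for x, y in G.r],
        "cells": [list(map(int, c)) for c in T.cells],
    }


def save_mesh(path, T, G) -> None:
    with open(path, "w") as fh:
        json.dump(mesh_dict(T, G), fh)


def load_mesh(path):
    """Load a mesh JSON file; returns (Topology, Geometry)."""
    with open(path) as fh:
        d = json.load(fh)
    if "vertices" not in d or "cells" not in d:
        raise ValueError("mesh JSON must contain 'vertices' and 'cells'")
    T = build_complex(d["cells"])
    return assemble_geometry(T, np.asarray(d["vertices"], dtype=float))
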