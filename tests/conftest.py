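import pytest

from vertexcalc import build_operators, hex_patch, perturb
from vertexcalc.dynamics import SimConfig, grow
from vertexcalc.mechanics import analyse


@pytest.fixture(scope="session")
def flower():
    """7-cell honeycomb patch (1 ring)."""
    return hex_patch(1)


@pytest.fixture(scope="session")
def disordered():
    """Perturbed 2-ring patch: disordered geometry, fixed topology."""
    T, G = hex_patch(2)
    return perturb(T, G, 0.2, seed=5)


@pytest.fixture(scope="session")
def disordered_ops(disordered):
    T, G = disordered
    return build_operators(T, G)


@pytest.fixture(scope="session")
def grown():
    """30-cell equilibrium monolayer grown by random division (seeded)."""
    cfg = SimConfig(n_cells=30, seed=1)
    T, G, info = grow(cfg)
    return T, G, cfg, info


@pytest.fixture(scope="session")
def grown_state(grown):
    T, G, cfg, _ = grown
    O = build_operators(T, G)
    state = analyse(T, G, cfg.params, O=O)
    return T, G, O, cfg.params, state
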