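import numpy as np
import pytest

from sorbmech.system import SystemConfiguration


def make_gas(n, box_length, seed=0, species="solvent"):
    """Uniform random single-bead gas configuration."""
    rng = np.random.default_rng(seed)
    return SystemConfiguration(
        positions=rng.uniform(0, box_length, size=(n, 3)),
        species=np.array([species] * n, dtype=object),
        bonds=np.empty((0, 2), dtype=np.intp),
        crosslinks=np.empty((0, 2), dtype=np.intp),
        box=np.full(3, float(box_length)),
    )


def make_lattice(n_side, spacing, jitter=0.0, seed=0, species="solvent"):
    """Simple cubic lattice configuration, optionally jittered."""
    rng = np.random.default_rng(seed)
    g = (np.arange(n_side) + 0.5) * spacing
    pos = np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)
    L = n_side * spacing
    if jitter:
        pos = (pos + rng.uniform(-jitter, jitter, pos.shape)) % L
    return SystemConfiguration(
        positions=pos,
        species=np.array([species] * len(pos), dtype=object),
        bonds=np.empty((0, 2), dtype=np.intp),
        crosslinks=np.empty((0, 2), dtype=np.intp),
        box=np.full(3, L),
    )


@pytest.fixture
def lj_gas():
    return make_gas


@pytest.fixture
def lattice():
    return make_lattice
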