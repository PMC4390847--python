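import numpy as np
import pytest

from osmocell.network import Reaction, ReactionNetwork, parse_network
from osmocell.reactor import (
    MembraneSpec,
    VesicleEnvironment,
    VesicleReactor,
    sphere_surface_from_diameter,
)
from osmocell.search import SCHLOGL_BULK, WILHELM_BULK, schlogl_network, wilhelm_network


@pytest.fixture
def schlogl_net():
    return schlogl_network()


@pytest.fixture
def wilhelm_net():
    return wilhelm_network()


@pytest.fixture
def surface_400nm():
    return sphere_surface_from_diameter(400.0)


@pytest.fixture
def schlogl_vesicle(schlogl_net):
    """Encapsulated Schlögl switch in the low-buffer (mM) regime.

    Externals of the former reservoir species X, Z are pinned at the bulk
    regime values; the intermediate Y diffuses against a small external pool.
    """
    env = VesicleEnvironment(
        b_eps=0.002,
        s_eps={"X": SCHLOGL_BULK["x"], "Y": 0.001, "Z": SCHLOGL_BULK["z"]},
    )
    mem = MembraneSpec(D_mult={"X": 1.0, "Y": 2.0, "Z": 0.5})
    return VesicleReactor(network=schlogl_net, environment=env, membrane=mem, B_T=1000.0)


@pytest.fixture
def inert_single_reactor():
    """One inert diffusing solute: unique steady state at s = s_eps."""
    net = ReactionNetwork(["A"], [])
    env = VesicleEnvironment(b_eps=0.2, s_eps={"A": 0.05})
    mem = MembraneSpec(D_mult={"A": 1.0})
    return VesicleReactor(network=net, environment=env, membrane=mem, B_T=63064.0)


@pytest.fixture
def two_uni_reactor():
    """Two chemically-independent unimolecular reactions sharing a vesicle."""
    net = parse_network("X -> Y (k=0.5); P -> Q (k=2.0)")
    env = VesicleEnvironment(
        b_eps=0.15, s_eps={"X": 0.05, "Y": 0.01, "P": 0.04, "Q": 0.02}
    )
    mem = MembraneSpec(D_mult={"X": 5.0, "Y": 0.8, "P": 3.0, "Q": 0.5})
    return VesicleReactor(network=net, environment=env, membrane=mem, B_T=40000.0)


def random_reactor(rng, n_species=2, reversible=False):
    """A small random mass-action vesicle reactor for property tests."""
    names = [f"S{i}" for i in range(n_species)]
    reactions = []
    n_rx = int(rng.integers(1, 3))
    for _ in range(n_rx):
        order = int(rng.integers(1, 3))
        lhs = {}
        for _ in range(order):
            sp = names[int(rng.integers(n_species))]
            lhs[sp] = lhs.get(sp, 0) + 1
        rhs = {}
        for _ in range(int(rng.integers(1, 3))):
            sp = names[int(rng.integers(n_species))]
            rhs[sp] = rhs.get(sp, 0) + 1
        if lhs == rhs:
            rhs = {names[int(rng.integers(n_species))]: 1}
            if lhs == rhs:
                continue
        k = float(rng.uniform(0.1, 10.0))
        kr = float(rng.uniform(0.0, k / 10)) if reversible else 0.0
        reactions.append(Reaction(lhs, rhs, k, kr))
    if not reactions:
        reactions = [Reaction({names[0]: 1}, {names[-1]: 1}, 1.0)]
    net = ReactionNetwork(names, reactions)
    env = VesicleEnvironment(
        b_eps=float(rng.uniform(0.1, 0.3)),
        s_eps={sp: float(rng.uniform(0.0, 0.2)) for sp in names},
    )
    mem = MembraneSpec(D_mult={sp: float(rng.uniform(0.2, 50.0)) for sp in names})
    B_T = float(rng.uniform(1000, 100000))
    return VesicleReactor(network=net, environment=env, membrane=mem, B_T=B_T)
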