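import numpy as np
import pytest

from aktnfkb.network import compile_network
from aktnfkb.pathway import build_default_model, default_catalog
from aktnfkb.simulate import constant_protocol, simulate


@pytest.fixture(scope="session")
def baseline():
    return build_default_model()


@pytest.fixture(scope="session")
def baseline_model(baseline):
    return compile_network(baseline)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def stimulated_trajectory(baseline_model):
    """Baseline model under 10 nM EGF for 10 h (1-min output grid)."""
    return simulate(baseline_model, constant_protocol(10.0, 10.0))


def random_toy_network(rng: np.random.Generator, max_species: int = 6, max_reactions: int = 10):
    """A random small mass-action/MM network for matrix-vs-loop property tests."""
    from aktnfkb.network import RateLaw, Reaction, ReactionNetwork, Species

    n_sp = rng.integers(2, max_species + 1)
    ids = [f"S{i}" for i in range(n_sp)]
    species = [Species(sid, sid, "cytoplasm", float(rng.uniform(0, 5))) for sid in ids]
    n_rx = rng.integers(1, max_reactions + 1)
    reactions = []
    for j in range(n_rx):
        kind = rng.choice(["ma1", "ma2", "ma2same", "ma0", "mm"])
        prods = tuple(
            (ids[i], int(rng.integers(1, 3)))
            for i in rng.choice(n_sp, size=rng.integers(0, 3), replace=False)
        )
        if kind == "mm":
            sub = ids[rng.integers(n_sp)]
            law = RateLaw("michaelis_menten", vmax=float(rng.uniform(0.5, 5)),
                          km=float(rng.uniform(0.2, 3)))
            reac = ((sub, 1),)
        else:
            law = RateLaw("mass_action", k=float(rng.uniform(0.1, 3)),
                          c=float(rng.choice([0.0, 0.5])))
            if kind == "ma0":
                reac = ()
                if not prods:
                    prods = ((ids[0], 1),)
            elif kind == "ma1":
                reac = ((ids[rng.integers(n_sp)], 1),)
            elif kind == "ma2same":
                reac = ((ids[rng.integers(n_sp)], 2),)
            else:
                a, b = rng.choice(n_sp, size=2, replace=False)
                reac = ((ids[a], 1), (ids[b], 1))
        reactions.append(Reaction(f"r{j}", reac, prods, law, "receptor"))
    return ReactionNetwork(species=species, reactions=reactions, metadata={})
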