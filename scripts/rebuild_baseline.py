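"""Regenerate the bundled baseline model file.

Builds the network from the programmatic tables, relaxes it to its
unstimulated steady state (500 h at zero EGF), and stores the relaxed state
as the bundled initial concentrations so that every simulation starts from a
quiescent cell.  Run from the repository root:

    python scripts/rebuild_baseline.py
"""

from pathlib import Path

import numpy as np

from aktnfkb._baseline import build_network
from aktnfkb.network import ReactionNetwork, Species, compile_network, serialize_network
from aktnfkb.simulate import constant_protocol, simulate

OUT = Path(__file__).resolve().parent.parent / "src" / "aktnfkb" / "models" / "baseline.json"


def equilibrated_network() -> ReactionNetwork:
    net = build_network()
    model = compile_network(net)
    traj = simulate(model, constant_protocol(0.0, 1500.0), t_grid=np.linspace(0.0, 1500.0, 26))
    rest = traj.states[-1]
    # polish to machine-precision steady state with a Newton solve at u = 0
    from scipy.optimize import least_squares

    from aktnfkb.network import evaluate_rhs, rhs_jacobian

    sol = least_squares(
        lambda x: evaluate_rhs(model, np.maximum(x, 0.0), 0.0),
        rest,
        jac=lambda x: rhs_jacobian(model, np.maximum(x, 0.0), 0.0),
        method="trf",
        bounds=(0.0, np.inf),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    rest = np.maximum(sol.x, 0.0)
    resid = np.abs(evaluate_rhs(model, rest, 0.0)).max()
    assert resid < 1e-9, f"steady-state residual too large ({resid} nM/h)"
    species = []
    for s, x in zip(net.species, rest):
        x0 = 0.0 if s.is_input else float(x)
        species.append(
            Species(id=s.id, name=s.name, compartment=s.compartment, initial_nM=x0, is_input=s.is_input)
        )
    meta = dict(net.metadata)
    meta["initial_state"] = "relaxed to the unstimulated steady state (1500 h at 0 nM EGF)"
    return ReactionNetwork(species=species, reactions=list(net.reactions), metadata=meta)


if __name__ == "__main__":
    OUT.parent.mkdir(parents=True, exist_ok=True)
    net = equilibrated_network()
    serialize_network(net, OUT)
    print(f"wrote {OUT} ({len(net.species)} species, {len(net.reactions)} reactions)")
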