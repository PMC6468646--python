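"""Baseline behavior of the EGF -> PI3K-Akt -> IKK -> NF-kB model.

Simulates the bundled 42-species / 96-reaction model (i) without stimulation
for 10 h, confirming the resting state is quiescent, and (ii) under 10 nM
EGF for 10 h, the stimulation used throughout.  Writes the observable time
courses to results/baseline/ and prints the timing summary of each readout.

Run from the repository root:  python analysis/01_simulate_baseline.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from aktnfkb.network import compile_network, conserved_pools
from aktnfkb.pathway import build_default_model, default_catalog
from aktnfkb.simulate import constant_protocol, observable, simulate

OUT = Path("results/baseline")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    net = build_default_model()
    model = compile_network(net)
    catalog = default_catalog()
    print(f"model: {net.summary()}")

    # quiescence without EGF
    rest = simulate(model, constant_protocol(0.0, 10.0))
    nn0 = observable(rest, catalog, "nuclear_NFkB")
    print(f"unstimulated 10 h: nuclear NF-kB drifts by {np.abs(nn0 - nn0[0]).max():.3g} nM "
          f"(pool 100 nM)")

    # 10 nM EGF for 10 h
    traj = simulate(model, constant_protocol(10.0, 10.0))
    obs = {"time_h": traj.times}
    for oid in catalog.observables:
        obs[oid] = observable(traj, catalog, oid)
    df = pd.DataFrame(obs)
    df.to_csv(OUT / "observables_10nM_10h.tsv", sep="\t", index=False)
    traj.write_tsv(OUT / "trajectory_10nM_10h.tsv")

    for oid in ("pAkt_S473", "pIKK", "pIkBa", "nuclear_NFkB"):
        y = df[oid].to_numpy()
        print(f"  {oid:14s} peak {y.max():8.2f} nM at {df['time_h'][np.argmax(y)]:.2f} h, "
              f"final {y[-1]:8.2f} nM")

    pools = conserved_pools(net)
    drift = max(
        np.abs(sum(c * traj.col(s) for s, c in p.items())
               - sum(c * traj.col(s) for s, c in p.items())[0]).max()
        for p in pools
    )
    print(f"conserved pools: {len(pools)}; worst absolute drift over 10 h: {drift:.3g} nM")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
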