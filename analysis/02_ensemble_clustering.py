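"""Random sampling of the Akt -> IKK coupling rate and response categories.

No estimate of how fast phospho-Akt activates IKK is available, so the rate
constant is sampled log-uniformly over five decades (1e-3 to 1e2 per nM per
hour) and the model is integrated once per draw under 10 nM EGF for 10 h.
The nuclear NF-kB time courses are then grouped by k-means into a small set
of characteristic response categories.  The full reproduction uses 7000
draws (pass --full); the default is a 500-draw survey with identical
settings.

Run from the repository root:  python analysis/02_ensemble_clustering.py
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from aktnfkb.ensemble import (
    SamplingSpec,
    classify_clusters,
    cluster_responses,
    run_ensemble,
)
from aktnfkb.pathway import build_default_model
from aktnfkb.simulate import constant_protocol

OUT = Path("results/ensemble")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=500)
    ap.add_argument("--full", action="store_true", help="use the full 7000 draws")
    ap.add_argument("--seed", type=int, default=17)
    args = ap.parse_args()
    n = 7000 if args.full else args.n

    OUT.mkdir(parents=True, exist_ok=True)
    net = build_default_model()
    ens = run_ensemble(
        net,
        SamplingSpec(low=1e-3, high=1e2, n_draws=n, seed=args.seed),
        constant_protocol(10.0, 10.0),
    )
    print(f"ran {ens.n_total} simulations ({len(ens.failed)} failed)")

    classes = cluster_responses(ens, k="auto", seed=args.seed)
    names = classify_clusters(ens, classes)
    print(f"k-means chose {classes.chosen_k} response categories:")
    rows = []
    for label, shape in sorted(names.items()):
        members = np.nonzero(classes.labels == label)[0]
        ks = ens.draws[members]
        amps = ens.trajectories[members].max(axis=1)
        rows.append({
            "cluster": label, "category": shape, "n": len(members),
            "coupling_rate_min": ks.min(), "coupling_rate_max": ks.max(),
            "median_peak_nM": float(np.median(amps)),
        })
        print(f"  cluster {label:2d} [{shape:9s}] n={len(members):4d} "
              f"k in [{ks.min():.3g}, {ks.max():.3g}] /nM/h, "
              f"median peak {np.median(amps):.1f} nM")
    pd.DataFrame(rows).to_csv(OUT / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame({"draw": np.arange(n), "coupling_rate": ens.draws,
                  "label": classes.labels}).to_csv(OUT / "draws_labels.tsv", sep="\t", index=False)
    cent = pd.DataFrame(classes.centroids.T)
    cent.insert(0, "time_h", classes.feature_times)
    cent.to_csv(OUT / "centroids.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
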