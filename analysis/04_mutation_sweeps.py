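"""In silico mutation experiments on the calibrated model.

Sweeps the prostate-cancer-associated perturbations of the PI3K-Akt arm --
EGFR overexpression (80-360 nM, stimulated with 360 nM EGF for 10 h), PI3K
overexpression (10-100 nM), PTEN loss (deleting the PIP3 dephosphorylation
step), and PP2A titration (0-11 nM), each under 10 nM EGF -- and ranks them
by the severity of their effect on nuclear NF-kB.  Persistence after EGF
washout (removal at 5 h, observation to 10 h) separates mutations that
merely amplify the transient response from those that lock the pathway on.

Run from the repository root:  python analysis/04_mutation_sweeps.py
"""

import argparse
from pathlib import Path

from aktnfkb.ensemble import SamplingSpec, run_ensemble, select_calibrated
from aktnfkb.experiments import ScenarioSweep, compare_scenarios, run_sweep
from aktnfkb.pathway import build_default_model, scenario_grid, with_coupling_rate
from aktnfkb.simulate import constant_protocol, washout_protocol

OUT = Path("results/mutations")

SWEEP_PROTOCOLS = {
    "egfr_overexpression": constant_protocol(360.0, 10.0),
    "pi3k_overexpression": constant_protocol(10.0, 5.0),
    "pten_loss": constant_protocol(10.0, 5.0),
    "pp2a_titration": constant_protocol(10.0, 5.0),
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    args = ap.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    net = build_default_model()
    ens = run_ensemble(
        net,
        SamplingSpec(low=1e-3, high=1e2, n_draws=100, seed=args.seed),
        constant_protocol(10.0, 10.0),
    )
    nominal = select_calibrated(ens).nominal_rate
    print(f"calibrated coupling rate: {nominal:.4g} /nM/h")
    calibrated = with_coupling_rate(net, nominal)

    # stimulation sweeps at the protocols of the published figure
    for family, protocol in SWEEP_PROTOCOLS.items():
        res = run_sweep(calibrated, ScenarioSweep(family=family,
                                                  grid=scenario_grid(family),
                                                  protocol=protocol))
        res.table.to_csv(OUT / f"{family}_sweep.tsv", sep="\t", index=False)
        print(f"{family}: fold change in final nuclear NF-kB = "
              f"{res.fold_change('final_nuclear_NFkB'):.2f}")

    # persistence after EGF washout: the headline contrast
    wash = washout_protocol(10.0, 5.0, 10.0)
    washout_sweeps = [
        run_sweep(calibrated, ScenarioSweep(family=f, grid=scenario_grid(f), protocol=wash))
        for f in ("pten_loss", "egfr_overexpression", "pi3k_overexpression", "pp2a_titration")
    ]
    for res in washout_sweeps:
        res.table.to_csv(OUT / f"{res.family}_washout.tsv", sep="\t", index=False)
    report = compare_scenarios(washout_sweeps, "final_nuclear_NFkB")
    report.to_csv(OUT / "severity_ranking.tsv", sep="\t", index=False)
    print("\nseverity ranking after EGF washout (final nuclear NF-kB fold change):")
    print(report.to_string(index=False))
    print(f"\nwrote {OUT}/")


if __name__ == "__main__":
    main()
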