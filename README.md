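# aktnfkb

Kinetic modeling of the crosstalk between EGF-driven PI3K–Akt signaling and
the NF-κB pathway, built around the hypothesis that the IKK complex is the
coordination point between the two.  The package is aimed at systems
biologists studying constitutive NF-κB activation in prostate cancer: it
provides the reaction-network model, a stiff ODE simulation layer, a
random-sampling analysis of the one unmeasured step (how fast phospho-Akt
activates IKK), and in silico versions of the pathway mutations observed in
tumors (EGFR/PI3K overexpression, PTEN loss, PP2A loss).

## Model

The network (42 species, 96 reactions) is integrated as

$$\dot{x} = S_{MM}\,v(x) \;+\; (S_{out}-S_{in})\,\mathrm{diag}(k)\,
\prod_i x_i^{S_{in}}\,(1 + c\,u),$$

with mass-action kinetics for all steps except receptor-level catalysis
(Michaelis–Menten, $v = V_{max}S/(K_m+S)$), concentrations in nM and time in
hours; $u$ is the extracellular EGF level, clamped to the stimulation
protocol.  Four modules: receptor (binding, dimerization,
autophosphorylation, internalization), PI3K–Akt (PIP2→PIP3 by active PI3K,
PIP3→PIP2 by PTEN, membrane recruitment and two-site activation of Akt,
deactivation by PP2A), a single coupling reaction
pAkt + IKK → pAkt + IKKa whose rate constant is the unknown, and an
IκBα-only NF-κB negative-feedback loop.  Total NF-κB, PTEN, PP2A, Akt and
the PDKs are conserved moieties.  See `docs/methods.md` for the full
account.

## Worked example

```python
import numpy as np
from aktnfkb import (build_default_model, default_catalog, compile_network,
                     constant_protocol, simulate, observable,
                     SamplingSpec, run_ensemble, select_calibrated,
                     with_coupling_rate)

net = build_default_model()          # bundled 42-species / 96-reaction model
catalog = default_catalog()

# sample the unknown Akt->IKK coupling rate over five decades and keep the
# draws whose nuclear NF-kB response matches the observed timing
ens = run_ensemble(net, SamplingSpec(low=1e-3, high=1e2, n_draws=100, seed=17),
                   constant_protocol(10.0, 10.0))      # 10 nM EGF, 10 h
cal = select_calibrated(ens)
print(f"kept {cal.kept.size}/100 draws, nominal rate {cal.nominal_rate:.2f} /nM/h")

# simulate the calibrated model and measure the activation timing
traj = simulate(compile_network(with_coupling_rate(net, cal.nominal_rate)),
                constant_protocol(10.0, 10.0))
y = observable(traj, catalog, "nuclear_NFkB")
i0 = int(np.argmax(y >= 0.5 * y.max()))
print(f"half-max nuclear NF-kB at {traj.times[i0]*60:.0f} min, "
      f"peak {y.max():.1f} nM of a 100 nM pool")
```

prints

```
kept 14/100 draws, nominal rate 26.08 /nM/h
half-max nuclear NF-kB at 14 min, peak 97.0 nM of a 100 nM pool
```

i.e. with the constraint-selected coupling rate, EGF drives half-maximal
nuclear NF-κB within 15 minutes and the response saturates near the total
NF-κB pool — matching the qualitative timing seen in EGF-stimulated
prostate epithelial cells.

The analysis drivers reproduce the full study in sequence and write their
tables under `results/`:

```bash
python analysis/01_simulate_baseline.py     # quiescence + stimulated time courses
python analysis/02_ensemble_clustering.py   # coupling-rate ensemble + k-means categories
python analysis/03_calibration.py           # constraint selection, nominal rate
python analysis/04_mutation_sweeps.py       # EGFR/PI3K/PTEN/PP2A scenarios + ranking
```

`analysis/04` shows the headline contrast: after EGF washout at 5 h,
the unperturbed model re-sequesters NF-κB (persistence index < 0.05) while
PTEN loss keeps > 90% of its pre-washout nuclear NF-κB at 10 h; receptor
overexpression alone never produces persistent activation.

A `click` CLI wraps the same stages
(`aktnfkb simulate | ensemble | cluster | scenario sweep | export`);
`export` writes the model as an SBML Level 3 document.

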