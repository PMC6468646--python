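# Methods

## The model

`aktnfkb` implements a deterministic kinetic model of EGF-driven signaling
from the receptor through PI3K-Akt to the IKK–IκB–NF-κB module, written as a
reaction network and compiled to the stoichiometric state equation

```
ẋ = S_MM · v(x) + (S_out − S_in) · diag(k) · Π x^{S_in} · (1 + c·u)
```

with concentrations in nM and time in hours.  `S_in`/`S_out` are the
reactant/product stoichiometry matrices of the mass-action reactions, `S_MM`
the net stoichiometry of the Michaelis–Menten reactions (used only for
receptor-level catalysis: autophosphorylation and the two receptor
dephosphorylation steps), and `u` is the extracellular EGF level.  The
mass-action product is evaluated as a direct power product with the
convention 0⁰ = 1, which agrees with the equivalent `exp(S_inᵀ log x)` form
on the positive orthant but is also defined at zero concentrations.

EGF is a species with a special role: its level is clamped to the
stimulation protocol (piecewise-constant segments) and is not integrated.
Reactions may consume or produce it stoichiometrically; its row of the
state derivative is forced to zero.  The `(1 + c·u)` input-coupling factor
is supported for mass-action reactions but the bundled model expresses all
EGF dependence through the clamped species itself (`c = 0` everywhere).

The bundled network has 42 species and 96 reactions in four modules:

* **receptor** — EGF binding (Kd 1 nM), dimerization, Michaelis–Menten
  autophosphorylation/dephosphorylation, internalization with recycling and
  degradation, and slow receptor synthesis/turnover (steady state 100 nM).
  Receptor loss from the surface is what makes phospho-Akt peak
  (~45 nM at ~40 min under 10 nM EGF) and then partially decline.
* **pi3k_akt** — PI3K recruitment to phosphorylated receptor and release as
  active PI3K; catalytic PIP2→PIP3 conversion through an explicit
  enzyme–substrate complex; PTEN-catalyzed PIP3→PIP2 dephosphorylation as a
  single bimolecular step (so that PTEN loss is the deletion of exactly one
  reaction); PIP3-mediated Akt membrane recruitment; two-site activation
  (Thr308 by PDK1, Ser473 by a lumped PDK2 activity, each through an
  explicit complex); and PP2A-catalyzed deactivation of phospho-Akt in the
  cytosol and at the membrane.
* **coupling** — a single mass-action step `pAkt + IKK → pAkt + IKKa`.
  Its rate constant is the model's only unknown (see Calibration).
* **nfkb** — an IκBα-only negative-feedback loop: active IKK binds and
  phosphorylates IκBα free and in complex with NF-κB; phospho-IκBα is
  degraded (t½ ≈ 1.4 min), freeing NF-κB to enter the nucleus; nuclear
  NF-κB induces IκBα transcription on top of a strong constitutive IκBα
  synthesis; newly made IκBα recaptures cytoplasmic NF-κB, enters the
  nucleus, and exports NF-κB as a complex.  IKK cycles through an active
  and a refractory state with fast dephosphorylation back to the inactive
  pool.

Total NF-κB (100 nM across its six free/complexed/nuclear forms), PTEN,
PP2A, Akt, PDK1 and PDK2 are conserved moieties; `conserved_pools` finds
them as non-negative integer rays of the left null space (exact rational
null space via sympy, positivized per species by a small linear program,
verified against the integer stoichiometry).  Receptor, PI3K, PIP2, IKK and
the transcripts turn over and are not conserved.

The bundled `models/baseline.json` stores the network with initial
concentrations relaxed to the unstimulated steady state (1500 h at zero EGF
followed by a bounded least-squares polish of the residual; steady-state
residual < 1e-7 nM/h).  Every simulation therefore starts from a quiescent
cell: without EGF, nuclear NF-κB stays at its resting value (≈0.4 nM free
plus complexed, under 1% of the pool) indefinitely.

### Where the numbers come from

The published description of this system fixes its size (96 reactions, 42
state variables), its mechanisms, the stimulation protocols, and the
qualitative timing of the NF-κB response; it does not print the reaction
list or rate constants.  The network here is a reconstruction: rate
constants start from the order of magnitude of the canonical EGFR/PI3K and
IκB–NF-κB kinetic models this architecture descends from and were then
adjusted, before any acceptance measurement, so that the model reproduces
the qualitative behaviors the system is documented to have — quiescence
without ligand, half-maximal nuclear NF-κB within 15 min of EGF addition,
a response sustained beyond 6 h, reversal within ~2 h of ligand removal,
and persistent activation when PTEN is absent.  Only ordinal and timing
claims are treated as reproducible; plotted magnitudes are not.

## Simulation

The default integrator is LSODA (variable-order stiff multistep, the same
family as the classical `ode15s` workflow) with the analytic Jacobian of
the power-product rate law; an explicit Runge–Kutta mode exists purely as a
cross-method oracle for tests.  Integration restarts at every EGF-level
discontinuity so the multistep history never spans a jump.  Defaults:
`rel_tol 1e-6`, `abs_tol 1e-9 nM` (the solver is run at `abs_tol/100` so
reported states sit well inside the band), output grid one point per minute
(601 points over 10 h), fine enough to resolve a 15-minute rise criterion.
Negative excursions within `abs_tol + rel_tol·max|x|` are zeroed; anything
larger raises.  Conserved pools drift by < 1e-12 relative over 10 h at the
default tolerances.

Observables are weighted sums of state variables mirroring what each
antibody sees in a blot: `nuclear_NFkB` (free + IκBα-complexed nuclear
NF-κB), `pAkt_S473` (all Ser473-phosphorylated forms including
phosphatase-bound), `pIKK`, `pIkBa`.  `normalize=True` divides a series by
its own maximum — the relative-density convention of densitometry.

## Calibration of the Akt→IKK coupling rate

No estimate of the rate at which phospho-Akt activates IKK is available, so
it is sampled log-uniformly over `[1e-3, 1e2] /nM/h` — five decades around
plausible bimolecular scales — with one 10 h / 10 nM EGF simulation per
draw.  The calibration keeps draws whose nuclear NF-κB series

1. is genuinely induced (peak ≥ 2× its starting value),
2. reaches half of its own maximum within 0.25 h, and
3. stays at or above half-maximum for the following 6 h,

and summarizes them by the geometric median (the ordinary median on the log
scale the draws live on — robust to the tails of the proposal).  Constraint
1 is needed because constraints 2–3 are relative to each trajectory's own
maximum, which a flat resting trajectory satisfies vacuously.  With 100
draws roughly the top decade qualifies, giving a nominal rate around
20–30 /nM/h; the calibrated model crosses half-maximum at 14–15 min and
holds it for the rest of the 10 h window.

## Response categories

For the category analysis the per-draw nuclear NF-κB series are normalized
to their own maximum (shape, not amplitude, defines a category), resampled
to 60 equally spaced points, and clustered with standard k-means (10
restarts, seeded).  Exactly-zero trajectories are assigned to a reserved
null class before clustering.  `k="auto"` chooses the class count in 2–8 by
silhouette.  Because normalization erases amplitude, category naming
restores it as a per-cluster summary: a cluster whose median member moves
nuclear NF-κB by less than 5 nM (5% of the pool — the same band used to
call the unstimulated model quiescent) is a *flat* (no-response) category;
other clusters are named by centroid shape (sustained / transient /
oscillatory).  On the model ensemble the bottom of the sampled range is
flat, the lower-middle decades give graded slow sustained rises, and the
upper decades a fast saturated sustained response.

## Mutation scenarios

Scenarios are declarative edits of the baseline (set or scale initial
concentrations, scale rate constants, delete reactions), applied to copies.
The built-in families and their documented grids:

| family | perturbation | range |
|---|---|---|
| `egfr_overexpression` | EGFR initial | 80–360 nM |
| `pi3k_overexpression` | PI3K initial | 10–100 nM |
| `pten_loss` | delete `pten_pip3_dephos` | — |
| `pp2a_titration` | PP2A initial | 0–11 nM |
| `akt_inhibition` | multiplier on both Akt-activation steps | 0–1 |

Sweep metrics: peak phospho-Akt, final and trapezoid-integrated nuclear
NF-κB, and the persistence index — the observable's final value divided by
its pre-washout maximum (0 = full reversal, 1 = no reversal).  The
persistence protocol extends the published 5 h stimulation with an EGF
washout at 5 h and observation to 10 h, the only reading under which
"persists after removal of stimulation" is computable.  Severity ranking
orders scenarios by the largest fold change of the chosen metric versus
baseline; ties break by persistence, then by name.

The mechanism behind the headline contrast: after washout the receptor
de-phosphorylates and internalizes within minutes, PTEN clears PIP3
(τ ≈ 2–3 min on free PIP3), PP2A removes phospho-Akt, and IKK inactivates,
so baseline nuclear NF-κB is re-sequestered well before 10 h (persistence
< 0.05).  With the PIP3-dephosphorylation step deleted, PIP3 made during
stimulation has no route back to PIP2 (only a slow 0.05 /h turnover), Akt
remains membrane-recruited and phosphorylated, IKK stays active, and
nuclear NF-κB holds above 90% of its pre-washout peak.  Receptor
overexpression, by contrast, changes the input strength but not the
off-kinetics: its post-washout state is indistinguishable from baseline.

## Synthetic data

* **Blot-style observations** — the normalized observable sampled at the
  sparse grid {0.25, 0.5, 1, 2, 4, 6, 8} h with multiplicative lognormal
  noise (`y·exp(ε)`, `ε ~ N(0, σ²)`); band intensities are positive and
  their error scales with signal.  Doses quoted in ng/mL convert to nM with
  EGF's 6.2 kDa molecular weight (100 ng/mL ≈ 16 nM), recorded in
  `config.py` rather than hard-coded.
* **Labeled families** — parametric flat / transient / sustained /
  oscillatory curves with per-replicate lognormal jitter (σ 0.05) on shape
  parameters plus observation noise, ground-truth labels attached.  With
  noise σ ≤ 0.1 the family centroids are separated by more than 5× the mean
  within-family spread, so clustering-recovery tests are fair rather than
  lucky.  These curves emulate the *shapes* real ensembles produce, not the
  model's kinetics: recovering them shows the categorization machinery
  works, not that the model's categories are biologically correct.
* **Toy networks** — decay (A→∅), isomerization (A⇌B) and Michaelis–Menten
  substrate depletion, each with a closed form (the last via root-solving
  `Km·ln(S₀/S) + (S₀−S) = Vmax·t`), used as independent integrator oracles.

All generators are reproducible from their seed; changing the seed changes
the noise but not the noiseless skeletons.

## Problem sizes and numerical choices

The ensemble analyses in the test suite and the acceptance script use
100-draw ensembles for calibration (a few seconds each; the kept set is
non-empty with overwhelming probability at this size) and the full
7000-draw ensemble for the reproduction count; the survey driver
(`analysis/02`) defaults to 500 draws with a `--full` switch.  k-means uses
10 restarts; silhouette-based selection caps k at 8.  Model-file validation
is hand-written with explicit error messages naming the offending entry.
SBML Level 3 export writes kinetic laws as MathML with local parameters and
carries the rate-law kind and module tag in an annotation namespace;
round-trip import is guaranteed only for documents this package wrote.

## Limitations

* The reaction list and parameterization are a reconstruction constrained
  by size, mechanism and qualitative dynamics; absolute magnitudes and the
  exact number of response categories are not meaningful quantities here.
* Phospho-IKKα and phospho-IKKβ are not distinguished (one active-IKK
  species); IκBβ/ε isoforms are omitted (IκBα-only feedback).
* PSA and proliferation are downstream correlates, not model species.
* u is non-depletable by default: stimulation protocols clamp extracellular
  EGF, appropriate for bath application in culture.
* Deterministic mass-action kinetics only — no stochastic (SSA) or spatial
  treatment.
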