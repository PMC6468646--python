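"""The bundled EGF -> PI3K-Akt -> IKK -> NF-kB network and its scenarios.

`build_default_model` loads the shipped 42-species / 96-reaction baseline.
`PathwayCatalog` names the densitometry-style observables (weighted sums of
state variables, mirroring what each antibody would see in a lysate or
nuclear fraction) and the reactions with special roles: the sampled
Akt -> IKK coupling step and the PTEN-catalyzed PIP3 dephosphorylation whose
deletion models PTEN loss.

Scenarios are declarative edits of the baseline: set or scale initial
concentrations, scale rate constants, or delete reactions.  The built-in
families reproduce the in silico mutation experiments: EGFR overexpression
(80-360 nM), PI3K overexpression (10-100 nM), PTEN loss (deletion of the
PIP3 dephosphorylation step), PP2A titration (0-11 nM), and a graded Akt
inhibition that emulates kinase-dead Akt / PI3K inhibitor treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .errors import ScenarioError
from .network import RateLaw, Reaction, ReactionNetwork, Species, parse_network

__all__ = [
    "build_default_model",
    "PathwayCatalog",
    "default_catalog",
    "Scenario",
    "apply_scenario",
    "with_coupling_rate",
    "make_scenario",
    "builtin_scenarios",
    "scenario_grid",
    "SCENARIO_FAMILIES",
]

COUPLING_REACTION = "akt_ikk_coupling"
PTEN_REACTION = "pten_pip3_dephos"


def build_default_model() -> ReactionNetwork:
    """Load the bundled baseline network (42 species, 96 reactions)."""
    path = resources.files("aktnfkb") / "models" / "baseline.json"
    with resources.as_file(path) as p:
        return parse_network(p)


@dataclass(frozen=True)
class PathwayCatalog:
    """Named observables (species weights) and key reaction roles."""

    observables: dict[str, dict[str, float]]
    key_reactions: dict[str, str]

    def validate_against(self, net: ReactionNetwork) -> None:
        sids = set(net.species_ids)
        for oid, weights in self.observables.items():
            missing = set(weights) - sids
            if missing:
                raise ScenarioError(f"observable {oid!r} references unknown species {sorted(missing)}")
        rids = set(net.reaction_ids)
        for role, rid in self.key_reactions.items():
            if rid not in rids:
                raise ScenarioError(f"key reaction {role!r} -> {rid!r} not in network")


def default_catalog() -> PathwayCatalog:
    return PathwayCatalog(
        observables={
            # anti-p65 blot on the nuclear fraction sees free and complexed NF-kB
            "nuclear_NFkB": {"NFkB_n": 1.0, "IkBa_NFkB_n": 1.0},
            "pAkt_S473": {
                "pAkt": 1.0,
                "pAkt_m": 1.0,
                "PP2A_pAkt": 1.0,
                "PP2A_pAkt_m": 1.0,
            },
            "pIKK": {"IKKa": 1.0, "IKKa_IkBa": 1.0, "IKKa_IkBaNFkB": 1.0},
            "pIkBa": {"pIkBa": 1.0, "pIkBa_NFkB": 1.0},
            "total_IkBa": {
                "IkBa": 1.0,
                "IkBa_n": 1.0,
                "IkBa_NFkB": 1.0,
                "IkBa_NFkB_n": 1.0,
                "pIkBa": 1.0,
                "pIkBa_NFkB": 1.0,
                "IKKa_IkBa": 1.0,
                "IKKa_IkBaNFkB": 1.0,
            },
            "PIP3": {"PIP3": 1.0},
        },
        key_reactions={
            "akt_ikk_coupling": COUPLING_REACTION,
            "pten_pip3_dephos": PTEN_REACTION,
            "akt_activation_t308": "akt_phos_t308",
            "akt_activation_s473": "akt_phos_s473",
        },
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """A named perturbation of the baseline network."""

    name: str
    species_scaling: dict[str, float] = field(default_factory=dict)
    species_set: dict[str, float] = field(default_factory=dict)
    deleted_reactions: tuple[str, ...] = ()
    rate_scaling: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for m in (*self.species_scaling.values(), *self.rate_scaling.values()):
            if m < 0:
                raise ScenarioError(f"scenario {self.name!r}: multipliers must be >= 0")
        for v in self.species_set.values():
            if v < 0:
                raise ScenarioError(f"scenario {self.name!r}: set concentrations must be >= 0 nM")

    @property
    def is_identity(self) -> bool:
        return not (
            self.species_scaling or self.species_set or self.deleted_reactions or self.rate_scaling
        )


def apply_scenario(net: ReactionNetwork, s: Scenario) -> ReactionNetwork:
    """Return a modified copy of the network; the input is left untouched."""
    sids = set(net.species_ids)
    rids = set(net.reaction_ids)
    for sid in (*s.species_scaling, *s.species_set):
        if sid not in sids:
            raise ScenarioError(f"scenario {s.name!r}: unknown species {sid!r}")
    for rid in (*s.deleted_reactions, *s.rate_scaling):
        if rid not in rids:
            raise ScenarioError(f"scenario {s.name!r}: unknown reaction {rid!r}")

    species = []
    for sp in net.species:
        x0 = sp.initial_nM
        if sp.id in s.species_scaling:
            x0 = x0 * s.species_scaling[sp.id]
        if sp.id in s.species_set:
            x0 = s.species_set[sp.id]
        if x0 != sp.initial_nM:
            sp = Species(id=sp.id, name=sp.name, compartment=sp.compartment,
                         initial_nM=x0, is_input=sp.is_input)
        species.append(sp)

    reactions = []
    for r in net.reactions:
        if r.id in s.deleted_reactions:
            continue
        if r.id in s.rate_scaling:
            m = s.rate_scaling[r.id]
            law = r.rate_law
            if law.kind == "mass_action":
                law = RateLaw(kind="mass_action", k=law.k * m, c=law.c)
            else:
                law = RateLaw(kind="michaelis_menten", vmax=law.vmax * m, km=law.km)
            r = Reaction(id=r.id, reactants=r.reactants, products=r.products,
                         rate_law=law, module=r.module)
        reactions.append(r)
    return ReactionNetwork(species=species, reactions=reactions, metadata=dict(net.metadata))


def with_coupling_rate(net: ReactionNetwork, k: float) -> ReactionNetwork:
    """Copy of the network with the Akt->IKK coupling rate constant set to k."""
    if k <= 0:
        raise ScenarioError(f"coupling rate must be > 0, got {k}")
    reactions = []
    for r in net.reactions:
        if r.id == COUPLING_REACTION:
            r = Reaction(id=r.id, reactants=r.reactants, products=r.products,
                         rate_law=RateLaw(kind="mass_action", k=float(k), c=r.rate_law.c),
                         module=r.module)
        reactions.append(r)
    return ReactionNetwork(species=list(net.species), reactions=reactions, metadata=dict(net.metadata))


def _load_scenario_families() -> dict[str, dict]:
    """Read the bundled scenario family definitions (scenarios/*.yaml)."""
    import yaml

    fams: dict[str, dict] = {}
    base = resources.files("aktnfkb") / "scenarios"
    for entry in sorted(base.iterdir(), key=lambda e: e.name):
        if not entry.name.endswith(".yaml"):
            continue
        doc = yaml.safe_load(entry.read_text())
        fams[doc["name"]] = doc
    return fams


#: documented level ranges and default sweep grids per scenario family
SCENARIO_FAMILIES: dict[str, dict] = _load_scenario_families()


def make_scenario(name: str, level: float | None = None) -> Scenario:
    """Instantiate a built-in scenario family at a given level.

    Levels are absolute initial concentrations (nM) for the overexpression
    and titration families and an activity multiplier in [0, 1] for
    akt_inhibition; pten_loss takes no level.
    """
    if name not in SCENARIO_FAMILIES:
        raise ScenarioError(f"unknown scenario {name!r}; known: {sorted(SCENARIO_FAMILIES)}")
    fam = SCENARIO_FAMILIES[name]
    if level is None:
        level = fam["default_level"]
    if fam["kind"] == "reaction_deletion":
        return Scenario(name=name, deleted_reactions=(fam["deleted_reaction"],))
    if fam["kind"] == "rate_scaling":
        lo, hi = fam["range_mult"]
        if not lo <= level <= hi:
            raise ScenarioError(f"{name} multiplier must be within [{lo}, {hi}]")
        if level == 1.0:
            return Scenario(name=name)
        return Scenario(name=name, rate_scaling={r: float(level) for r in fam["rate_reactions"]})
    lo, hi = fam["range_nM"]
    if not lo <= level <= hi:
        raise ScenarioError(
            f"{name} level {level} nM outside the documented range [{lo}, {hi}] nM"
        )
    return Scenario(name=name, species_set={fam["species"]: float(level)})


def builtin_scenarios() -> dict[str, Scenario]:
    """The built-in mutation scenarios at their default levels."""
    return {name: make_scenario(name) for name in SCENARIO_FAMILIES}


def scenario_grid(name: str) -> tuple:
    """Default sweep grid of levels for a scenario family."""
    if name not in SCENARIO_FAMILIES:
        raise ScenarioError(f"unknown scenario {name!r}")
    return tuple(SCENARIO_FAMILIES[name]["grid"])
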