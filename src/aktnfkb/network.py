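"""Reaction-network data model and the stoichiometric rate-law compiler.

A network is a list of species and a list of reactions, each reaction carrying
either a mass-action or a Michaelis-Menten rate law.  Compilation turns the
network into the matrix form used by the right-hand side,

    xdot = S_mm @ v(x)  +  (S_out - S_in) @ r(x, u)

with per-reaction rates

    r_j = k_j * prod_i x_i ** S_in[i, j] * (1 + c_j * u)      (mass action)
    v_j = Vmax_j * x_s / (Km_j + x_s)                         (Michaelis-Menten)

Units are fixed repo-wide: concentrations in nM, time in hours, so k carries
1/h for first-order steps, 1/(nM h) for second-order steps and nM/h for
zeroth-order synthesis; Vmax is nM/h and Km is nM.  u is the current level of
the single input species (EGF); reactions with c > 0 are additionally
modulated by the input through the (1 + c u) factor.

The mass-action product is evaluated as a direct power product rather than the
equivalent exp/log matrix form, so that zero concentrations are legal with the
convention 0**0 = 1 (the two forms agree everywhere on the positive orthant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ModelSchemaError, ModelValidationError

COMPARTMENTS = ("extracellular", "membrane", "cytoplasm", "nucleus")
MODULE_TAGS = ("receptor", "pi3k_akt", "coupling", "nfkb")

__all__ = [
    "Species",
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "CompiledModel",
    "parse_network",
    "serialize_network",
    "network_to_dict",
    "network_from_dict",
    "compile_network",
    "mass_action_rates",
    "mm_rates",
    "evaluate_rhs",
    "evaluate_rhs_loop",
    "rhs_jacobian",
    "conserved_pools",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Species:
    id: str
    name: str
    compartment: str
    initial_nM: float
    is_input: bool = False

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("species id may not be empty")
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"species {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if not (self.initial_nM >= 0):
            raise ModelValidationError(
                f"species {self.id!r}: initial concentration must be >= 0 nM, "
                f"got {self.initial_nM}"
            )


@dataclass(frozen=True)
class RateLaw:
    """Either mass_action (k, c) or michaelis_menten (vmax, km)."""

    kind: str
    k: float | None = None
    vmax: float | None = None
    km: float | None = None
    c: float = 0.0

    def __post_init__(self):
        if self.kind == "mass_action":
            if self.k is None or not self.k > 0:
                raise ModelValidationError(
                    f"mass-action law requires k > 0, got {self.k}"
                )
            if self.vmax is not None or self.km is not None:
                raise ModelValidationError(
                    "mass-action law must not carry Michaelis-Menten parameters"
                )
            if self.c < 0:
                raise ModelValidationError(f"input multiplier c must be >= 0, got {self.c}")
        elif self.kind == "michaelis_menten":
            if self.vmax is None or not self.vmax > 0:
                raise ModelValidationError(
                    f"Michaelis-Menten law requires Vmax > 0, got {self.vmax}"
                )
            if self.km is None or not self.km > 0:
                raise ModelValidationError(
                    f"Michaelis-Menten law requires Km > 0, got {self.km}"
                )
            if self.k is not None:
                raise ModelValidationError(
                    "Michaelis-Menten law must not carry a mass-action k"
                )
            if self.c != 0.0:
                raise ModelValidationError(
                    "input coupling (c) is only supported on mass-action reactions"
                )
        else:
            raise ModelValidationError(f"unknown rate-law kind {self.kind!r}")


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_law: RateLaw
    module: str

    def __post_init__(self):
        object.__setattr__(self, "reactants", tuple((s, int(n)) for s, n in self.reactants))
        object.__setattr__(self, "products", tuple((s, int(n)) for s, n in self.products))
        if not self.id:
            raise ModelValidationError("reaction id may not be empty")
        if self.module not in MODULE_TAGS:
            raise ModelValidationError(
                f"reaction {self.id!r}: unknown module tag {self.module!r}"
            )
        if not self.reactants and not self.products:
            raise ModelValidationError(
                f"reaction {self.id!r}: reactants and products may not both be empty"
            )
        for side, pairs in (("reactant", self.reactants), ("product", self.products)):
            for sid, n in pairs:
                if n <= 0:
                    raise ModelValidationError(
                        f"reaction {self.id!r}: {side} stoichiometry for {sid!r} "
                        f"must be a positive integer, got {n}"
                    )
        if self.rate_law.kind == "mass_action":
            if len(self.reactants) > 2:
                raise ModelValidationError(
                    f"reaction {self.id!r}: mass-action reactions are limited to "
                    "2 distinct reactant species"
                )
            order = sum(n for _, n in self.reactants)
            if order > 2:
                raise ModelValidationError(
                    f"reaction {self.id!r}: mass-action order {order} exceeds 2"
                )
        else:
            if len(self.reactants) != 1 or self.reactants[0][1] != 1:
                raise ModelValidationError(
                    f"reaction {self.id!r}: Michaelis-Menten reactions take exactly "
                    "one substrate with stoichiometry 1"
                )

    @property
    def substrate(self) -> str:
        """Substrate species id of a Michaelis-Menten reaction."""
        return self.reactants[0][0]


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- introspection ------------------------------------------------------

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def input_species(self) -> Species | None:
        for s in self.species:
            if s.is_input:
                return s
        return None

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def reaction_by_id(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_nM for s in self.species], dtype=float)

    def summary(self) -> str:
        n_ma = sum(r.rate_law.kind == "mass_action" for r in self.reactions)
        n_mm = len(self.reactions) - n_ma
        return (
            f"{len(self.species)} species, {len(self.reactions)} reactions "
            f"({n_ma} mass action, {n_mm} Michaelis-Menten)"
        )

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        sids = self.species_ids
        if len(set(sids)) != len(sids):
            dupes = sorted({s for s in sids if sids.count(s) > 1})
            raise ModelValidationError(f"duplicate species ids: {dupes}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            dupes = sorted({r for r in rids if rids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        if sum(s.is_input for s in self.species) > 1:
            raise ModelValidationError("at most one species may be flagged is_input")
        known = set(sids)
        for r in self.reactions:
            for sid, _ in (*r.reactants, *r.products):
                if sid not in known:
                    raise ModelSchemaError(
                        f"reaction {r.id!r} references undeclared species {sid!r}"
                    )

    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(
            species=list(self.species),
            reactions=list(self.reactions),
            metadata=dict(self.metadata),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (
            self.species == other.species
            and self.reactions == other.reactions
            and self.metadata == other.metadata
        )


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise ModelSchemaError(f"{context}: missing required key {key!r}")
    return mapping[key]


def network_from_dict(doc: Mapping) -> ReactionNetwork:
    """Build a validated network from a parsed model-file document."""
    if not isinstance(doc, Mapping):
        raise ModelSchemaError("model document must be a JSON object")
    species_docs = _require(doc, "species", "model document")
    reaction_docs = _require(doc, "reactions", "model document")
    species = []
    for sd in species_docs:
        ctx = f"species entry {sd.get('id', '<missing id>')!r}"
        species.append(
            Species(
                id=str(_require(sd, "id", ctx)),
                name=str(sd.get("name", sd["id"])),
                compartment=str(_require(sd, "compartment", ctx)),
                initial_nM=float(_require(sd, "initial_nM", ctx)),
                is_input=bool(sd.get("is_input", False)),
            )
        )
    reactions = []
    for rd in reaction_docs:
        ctx = f"reaction entry {rd.get('id', '<missing id>')!r}"
        law_doc = _require(rd, "rate_law", ctx)
        kind = str(_require(law_doc, "kind", ctx))
        if kind == "mass_action":
            law = RateLaw(
                kind=kind,
                k=float(_require(law_doc, "k", ctx)),
                c=float(law_doc.get("c", 0.0)),
            )
        elif kind == "michaelis_menten":
            law = RateLaw(
                kind=kind,
                vmax=float(_require(law_doc, "vmax", ctx)),
                km=float(_require(law_doc, "km", ctx)),
            )
        else:
            raise ModelSchemaError(f"{ctx}: unknown rate-law kind {kind!r}")
        reactions.append(
            Reaction(
                id=str(_require(rd, "id", ctx)),
                reactants=tuple((str(s), int(n)) for s, n in rd.get("reactants", [])),
                products=tuple((str(s), int(n)) for s, n in rd.get("products", [])),
                rate_law=law,
                module=str(_require(rd, "module", ctx)),
            )
        )
    return ReactionNetwork(
        species=species, reactions=reactions, metadata=dict(doc.get("metadata", {}))
    )


def network_to_dict(net: ReactionNetwork) -> dict:
    return {
        "metadata": dict(net.metadata),
        "species": [
            {
                "id": s.id,
                "name": s.name,
                "compartment": s.compartment,
                "initial_nM": s.initial_nM,
                **({"is_input": True} if s.is_input else {}),
            }
            for s in net.species
        ],
        "reactions": [
            {
                "id": r.id,
                "reactants": [[s, n] for s, n in r.reactants],
                "products": [[s, n] for s, n in r.products],
                "rate_law": (
                    {"kind": "mass_action", "k": r.rate_law.k}
                    | ({"c": r.rate_law.c} if r.rate_law.c else {})
                    if r.rate_law.kind == "mass_action"
                    else {
                        "kind": "michaelis_menten",
                        "vmax": r.rate_law.vmax,
                        "km": r.rate_law.km,
                    }
                ),
                "module": r.module,
            }
            for r in net.reactions
        ],
    }


def parse_network(path) -> ReactionNetwork:
    """Parse and validate a model file in the documented JSON dialect."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelSchemaError(f"{path}: not valid JSON ({exc})") from exc
    return network_from_dict(doc)


def serialize_network(net: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------


@dataclass
class CompiledModel:
    """Matrix form of a network plus the index bookkeeping the RHS needs."""

    species_ids: list[str]
    species_index: dict[str, int]
    input_index: int | None
    # mass-action part
    ma_reaction_ids: list[str]
    S_ma_in: np.ndarray  # (n_species, n_ma) int
    S_ma_out: np.ndarray  # (n_species, n_ma) int
    k_vec: np.ndarray  # (n_ma,) float
    c_vec: np.ndarray  # (n_ma,) float
    # Michaelis-Menten part
    mm_reaction_ids: list[str]
    S_mm: np.ndarray  # (n_species, n_mm) int
    mm_vmax: np.ndarray
    mm_km: np.ndarray
    mm_sub: np.ndarray  # (n_mm,) int substrate row per MM reaction
    x0: np.ndarray = None  # initial state (declaration-order initial_nM)
    # fast-path indexing of the (at most two) mass-action reactant species
    _i1: np.ndarray = field(repr=False, default=None)
    _s1: np.ndarray = field(repr=False, default=None)
    _i2: np.ndarray = field(repr=False, default=None)
    _s2: np.ndarray = field(repr=False, default=None)
    _S_net: np.ndarray = field(repr=False, default=None)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def S_net(self) -> np.ndarray:
        """Net mass-action stoichiometry, S_ma_out - S_ma_in."""
        return self._S_net


def compile_network(net: ReactionNetwork) -> CompiledModel:
    """Populate the stoichiometry matrices and parameter vectors.

    Species order is declaration order; mass-action and Michaelis-Menten
    reactions keep their relative declaration order within their own blocks.
    """
    sidx = {s.id: i for i, s in enumerate(net.species)}
    n = len(net.species)
    ma = [r for r in net.reactions if r.rate_law.kind == "mass_action"]
    mm = [r for r in net.reactions if r.rate_law.kind == "michaelis_menten"]

    S_in = np.zeros((n, len(ma)), dtype=int)
    S_out = np.zeros((n, len(ma)), dtype=int)
    for j, r in enumerate(ma):
        for sid, st in r.reactants:
            S_in[sidx[sid], j] += st
        for sid, st in r.products:
            S_out[sidx[sid], j] += st

    S_mm = np.zeros((n, len(mm)), dtype=int)
    mm_sub = np.zeros(len(mm), dtype=int)
    for j, r in enumerate(mm):
        for sid, st in r.reactants:
            S_mm[sidx[sid], j] -= st
        for sid, st in r.products:
            S_mm[sidx[sid], j] += st
        mm_sub[j] = sidx[r.substrate]

    i1 = np.zeros(len(ma), dtype=int)
    s1 = np.zeros(len(ma), dtype=float)
    i2 = np.zeros(len(ma), dtype=int)
    s2 = np.zeros(len(ma), dtype=float)
    for j, r in enumerate(ma):
        pairs = list(r.reactants)
        if len(pairs) >= 1:
            i1[j], s1[j] = sidx[pairs[0][0]], pairs[0][1]
        if len(pairs) == 2:
            i2[j], s2[j] = sidx[pairs[1][0]], pairs[1][1]

    inp = net.input_species
    return CompiledModel(
        species_ids=list(sidx),
        species_index=sidx,
        input_index=sidx[inp.id] if inp is not None else None,
        ma_reaction_ids=[r.id for r in ma],
        S_ma_in=S_in,
        S_ma_out=S_out,
        k_vec=np.array([r.rate_law.k for r in ma], dtype=float),
        c_vec=np.array([r.rate_law.c for r in ma], dtype=float),
        mm_reaction_ids=[r.id for r in mm],
        S_mm=S_mm,
        mm_vmax=np.array([r.rate_law.vmax for r in mm], dtype=float),
        mm_km=np.array([r.rate_law.km for r in mm], dtype=float),
        mm_sub=mm_sub,
        x0=net.initial_state(),
        _i1=i1,
        _s1=s1,
        _i2=i2,
        _s2=s2,
        _S_net=(S_out - S_in).astype(float),
    )


# ---------------------------------------------------------------------------
# rate and RHS evaluation
# ---------------------------------------------------------------------------


def _check_state(x: np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (n,):
        raise ValueError(f"state vector has shape {x.shape}, expected ({n},)")
    if np.any(x < 0):
        bad = int(np.argmin(x))
        raise ValueError(f"negative concentration x[{bad}] = {x[bad]}")
    return x


def mass_action_rates(model: CompiledModel, x, u: float = 0.0) -> np.ndarray:
    """Per-reaction mass-action rates k * prod(x**S_in) * (1 + c u), nM/h."""
    x = _check_state(x, model.n_species)
    return _ma_rates_fast(model, x, u)


def _ma_rates_fast(model: CompiledModel, x: np.ndarray, u: float) -> np.ndarray:
    # x[i]**0 == 1.0 in IEEE semantics, which realizes the 0**0 = 1 convention
    p = x[model._i1] ** model._s1 * x[model._i2] ** model._s2
    return model.k_vec * p * (1.0 + model.c_vec * u)


def mm_rates(model: CompiledModel, x) -> np.ndarray:
    """Per-reaction Michaelis-Menten rates Vmax * S / (Km + S), nM/h."""
    x = _check_state(x, model.n_species)
    return _mm_rates_fast(model, x)


def _mm_rates_fast(model: CompiledModel, x: np.ndarray) -> np.ndarray:
    s = x[model.mm_sub]
    return model.mm_vmax * s / (model.mm_km + s)


def evaluate_rhs(model: CompiledModel, x, u: float = 0.0) -> np.ndarray:
    """Time derivative S_mm @ v + (S_out - S_in) @ r, in nM/h."""
    x = _check_state(x, model.n_species)
    return _rhs_fast(model, x, u)


def _rhs_fast(model: CompiledModel, x: np.ndarray, u: float) -> np.ndarray:
    dx = model._S_net @ _ma_rates_fast(model, x, u)
    if model.mm_vmax.size:
        dx += model.S_mm @ _mm_rates_fast(model, x)
    return dx


def evaluate_rhs_loop(net: ReactionNetwork, x, u: float = 0.0) -> np.ndarray:
    """Naive per-reaction reference evaluation used as an independent oracle.

    Walks the reaction list species by species instead of going through the
    compiled matrices; kept deliberately simple.
    """
    sidx = {s.id: i for i, s in enumerate(net.species)}
    x = np.asarray(x, dtype=float)
    dx = np.zeros(len(net.species))
    for r in net.reactions:
        if r.rate_law.kind == "mass_action":
            rate = r.rate_law.k * (1.0 + r.rate_law.c * u)
            for sid, st in r.reactants:
                rate *= x[sidx[sid]] ** st
        else:
            s = x[sidx[r.substrate]]
            rate = r.rate_law.vmax * s / (r.rate_law.km + s)
        for sid, st in r.reactants:
            dx[sidx[sid]] -= st * rate
        for sid, st in r.products:
            dx[sidx[sid]] += st * rate
    return dx


def rhs_jacobian(model: CompiledModel, x, u: float = 0.0) -> np.ndarray:
    """Analytic Jacobian of evaluate_rhs with respect to x (stiff solvers)."""
    x = np.asarray(x, dtype=float)
    n = model.n_species
    pref = model.k_vec * (1.0 + model.c_vec * u)
    x1 = x[model._i1]
    x2 = x[model._i2]
    p1 = x1 ** model._s1
    p2 = x2 ** model._s2
    # d/dx1 (x1**s1): s1 * x1**(s1-1); the where() keeps 0**negative out
    d1 = pref * np.where(model._s1 > 0, model._s1 * x1 ** np.maximum(model._s1 - 1, 0), 0.0) * p2
    d2 = pref * p1 * np.where(model._s2 > 0, model._s2 * x2 ** np.maximum(model._s2 - 1, 0), 0.0)
    n_ma = model.k_vec.size
    D = np.zeros((n_ma, n))
    if n_ma:
        np.add.at(D, (np.arange(n_ma), model._i1), d1)
        np.add.at(D, (np.arange(n_ma), model._i2), d2)
    J = model._S_net @ D
    if model.mm_vmax.size:
        s = x[model.mm_sub]
        dv = model.mm_vmax * model.mm_km / (model.mm_km + s) ** 2
        Dm = np.zeros((model.mm_vmax.size, n))
        np.add.at(Dm, (np.arange(model.mm_vmax.size), model.mm_sub), dv)
        J += model.S_mm @ Dm
    return J


# ---------------------------------------------------------------------------
# conserved pools
# ---------------------------------------------------------------------------


def _integerize(vec: Sequence[Fraction]) -> list[int]:
    from math import gcd, lcm

    denoms = [f.denominator for f in vec if f != 0]
    if not denoms:
        return [0] * len(vec)
    m = lcm(*denoms)
    ints = [int(f * m) for f in vec]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g > 1:
        ints = [v // g for v in ints]
    return ints


def conserved_pools(net: ReactionNetwork) -> list[dict[str, int]]:
    """Non-negative integer conservation relations (moiety pools).

    Returns weight vectors w (as species-id -> weight maps) with
    w @ (S_out - S_in) = 0 and w @ S_mm = 0.  The input species is excluded:
    its level is clamped to the stimulation protocol during simulation, so it
    is not a dynamical variable.  Pools are found by solving, for each species,
    a small linear program over the left null space that asks for a
    non-negative combination containing that species; the resulting rays are
    exactified to integers and verified against the integer stoichiometry.
    """
    from scipy.optimize import linprog

    model = compile_network(net)
    S = np.hstack([model.S_ma_out - model.S_ma_in, model.S_mm]).astype(float)
    keep = [i for i, s in enumerate(net.species) if not s.is_input]
    if not keep:
        return []
    S_red = S[keep, :]
    ids = [net.species[i].id for i in keep]

    # rational basis of the left null space
    import sympy

    M = sympy.Matrix(S_red.astype(int)).T
    basis = M.nullspace()
    if not basis:
        return []
    N = np.array([[float(v) for v in b] for b in basis], dtype=float).T  # (n_red, d)
    d = N.shape[1]

    pools: list[tuple[tuple[int, ...], dict[str, int]]] = []
    n_red = len(ids)
    for i in range(n_red):
        # minimize sum(N a) s.t. N a >= 0, (N a)_i >= 1
        A_ub = -N.copy()
        b_ub = np.zeros(n_red)
        b_ub[i] = -1.0
        res = linprog(
            c=N.sum(axis=0),
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=[(None, None)] * d,
            method="highs",
        )
        if not res.success:
            continue
        w = N @ res.x
        w[np.abs(w) < 1e-9] = 0.0
        if np.any(w < 0):
            continue
        fracs = [Fraction(v).limit_denominator(10**6) for v in w]
        ints = _integerize(fracs)
        if any(v < 0 for v in ints):
            continue
        wi = np.zeros(S.shape[0], dtype=int)
        for idx, v in zip(keep, ints):
            wi[idx] = v
        if not np.all(wi @ S.astype(int) == 0):
            continue
        key = tuple(int(v) for v in wi)
        if all(key != k for k, _ in pools) and any(v != 0 for v in key):
            pools.append((key, {sid: v for sid, v in zip(ids, ints) if v != 0}))
    return [p for _, p in pools]
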