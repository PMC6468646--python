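"""Synthetic data generators: blot-style observations, labeled trajectory
families, and toy networks with closed-form solutions.

Three kinds of ground truth back the pipeline's tests:

* noisy relative-density observations of a model observable at sparse time
  points, mimicking loading-control-normalized densitometry (multiplicative
  lognormal noise -- band intensities are positive and their error scales
  with the signal);
* labeled families of time-courses (flat / transient / sustained /
  oscillatory) for clustering-recovery tests, where the true class of every
  series is known by construction;
* tiny reaction networks whose trajectories have closed forms, used as
  independent oracles for the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .config import DEFAULT_BLOT_TIMES
from .network import RateLaw, Reaction, ReactionNetwork, Species
from .pathway import PathwayCatalog
from .simulate import Trajectory, observable

__all__ = [
    "ObservationSet",
    "generate_observations",
    "TrajectoryFamilySpec",
    "LabeledTrajectorySet",
    "generate_family",
    "generate_mixed_families",
    "ToyNetwork",
    "toy_networks",
]

FAMILIES = ("flat", "transient", "sustained", "oscillatory")


# ---------------------------------------------------------------------------
# blot-style observations
# ---------------------------------------------------------------------------


@dataclass
class ObservationSet:
    times: np.ndarray  # h
    values: np.ndarray  # relative densities, unitless, > 0 where signal exists
    observable_id: str
    noise_sd: float
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.times, "value": self.values, "observable": self.observable_id}
        )


def generate_observations(
    traj: Trajectory,
    catalog: PathwayCatalog,
    oid: str,
    times=DEFAULT_BLOT_TIMES,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> ObservationSet:
    """Sample a normalized observable at sparse times with lognormal noise.

    value(t) = y_norm(t) * exp(eps_t),  eps_t ~ Normal(0, noise_sd^2)
    """
    times = np.asarray(times, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if times.min() < traj.times[0] or times.max() > traj.times[-1]:
        raise ValueError(
            f"observation times must lie within the trajectory span "
            f"[{traj.times[0]}, {traj.times[-1]}] h"
        )
    y = observable(traj, catalog, oid, normalize=True)
    clean = np.interp(times, traj.times, y)
    rng = np.random.default_rng(seed)
    noisy = clean * np.exp(rng.normal(0.0, noise_sd, times.size))
    return ObservationSet(times=times, values=noisy, observable_id=oid, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# labeled trajectory families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryFamilySpec:
    family: str
    n: int = 20
    rise_h: float = 0.25
    decay_h: float = 1.5
    period_h: float = 2.0
    amplitude: float = 1.0
    noise_sd: float = 0.05
    jitter_sd: float = 0.05  # lognormal sigma on shape parameters per replicate
    t_end: float = 10.0
    n_points: int = 121
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; known: {FAMILIES}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("rise_h", "decay_h", "period_h", "amplitude", "t_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LabeledTrajectorySet:
    times: np.ndarray  # (T,)
    values: np.ndarray  # (n, T)
    labels: np.ndarray  # (n,) family names

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=[f"t{j}" for j in range(self.times.size)])
        df.insert(0, "label", self.labels)
        return df


def _skeleton(spec: TrajectoryFamilySpec, t: np.ndarray, rise: float, decay: float,
              period: float, amp: float) -> np.ndarray:
    if spec.family == "flat":
        return np.zeros_like(t)
    ramp = 1.0 - np.exp(-t / rise)
    if spec.family == "sustained":
        return amp * ramp
    if spec.family == "transient":
        return amp * ramp * np.exp(-t / decay)
    # oscillatory: damped, non-negative oscillation that starts at zero
    env = np.exp(-t / (4.0 * decay))
    return amp * ramp * env * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / period))


def generate_family(spec: TrajectoryFamilySpec) -> LabeledTrajectorySet:
    """n parametric curves of one family, with per-replicate shape jitter and
    multiplicative observation noise; ground-truth labels attached."""
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, spec.t_end, spec.n_points)
    out = np.empty((spec.n, t.size))
    for i in range(spec.n):
        jit = np.exp(rng.normal(0.0, spec.jitter_sd, 4))
        clean = _skeleton(
            spec, t, spec.rise_h * jit[0], spec.decay_h * jit[1],
            spec.period_h * jit[2], spec.amplitude * jit[3],
        )
        noise = np.exp(rng.normal(0.0, spec.noise_sd, t.size)) if spec.noise_sd > 0 else 1.0
        out[i] = clean * noise
    return LabeledTrajectorySet(
        times=t, values=out, labels=np.array([spec.family] * spec.n)
    )


def generate_mixed_families(specs: list[TrajectoryFamilySpec]) -> LabeledTrajectorySet:
    sets = [generate_family(s) for s in specs]
    t = sets[0].times
    for s in sets[1:]:
        if not np.array_equal(s.times, t):
            raise ValueError("all family specs must share t_end and n_points")
    return LabeledTrajectorySet(
        times=t,
        values=np.vstack([s.values for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
    )


# ---------------------------------------------------------------------------
# toy networks with closed forms
# ---------------------------------------------------------------------------


@dataclass
class ToyNetwork:
    name: str
    network: ReactionNetwork
    analytic: Callable[[np.ndarray], dict[str, np.ndarray]]
    description: str = ""


def _decay_toy(k: float = 1.0, a0: float = 1.0) -> ToyNetwork:
    net = ReactionNetwork(
        species=[Species("A", "A", "cytoplasm", a0)],
        reactions=[
            Reaction("decay", (("A", 1),), (), RateLaw("mass_action", k=k), "receptor")
        ],
        metadata={"name": "decay"},
    )

    def sol(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return {"A": a0 * np.exp(-k * t)}

    return ToyNetwork("decay", net, sol, "A -> 0, exponential decay")


def _iso_toy(kf: float = 2.0, kb: float = 1.0, a0: float = 1.0) -> ToyNetwork:
    net = ReactionNetwork(
        species=[Species("A", "A", "cytoplasm", a0), Species("B", "B", "cytoplasm", 0.0)],
        reactions=[
            Reaction("fwd", (("A", 1),), (("B", 1),), RateLaw("mass_action", k=kf), "receptor"),
            Reaction("bwd", (("B", 1),), (("A", 1),), RateLaw("mass_action", k=kb), "receptor"),
        ],
        metadata={"name": "iso"},
    )
    s = kf + kb

    def sol(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        a = a0 * (kb + kf * np.exp(-s * t)) / s
        return {"A": a, "B": a0 - a}

    return ToyNetwork("iso", net, sol, "A <-> B, relaxation to equilibrium ratio kf/kb")


def _mm_depletion_toy(vmax: float = 1.0, km: float = 1.0, s0: float = 2.0) -> ToyNetwork:
    net = ReactionNetwork(
        species=[Species("S", "S", "cytoplasm", s0), Species("P", "P", "cytoplasm", 0.0)],
        reactions=[
            Reaction(
                "conv", (("S", 1),), (("P", 1),),
                RateLaw("michaelis_menten", vmax=vmax, km=km), "receptor",
            )
        ],
        metadata={"name": "mm_depletion"},
    )

    def sol(t):
        # invert the substrate-depletion relation Km ln(S0/S) + (S0 - S) = Vmax t
        from scipy.optimize import brentq

        t = np.atleast_1d(np.asarray(t, dtype=float))
        s_vals = np.empty_like(t)
        for i, ti in enumerate(t):
            f = lambda s: km * np.log(s0 / s) + (s0 - s) - vmax * ti
            s_vals[i] = s0 if ti == 0 else brentq(f, 1e-12, s0)
        return {"S": s_vals, "P": s0 - s_vals}

    return ToyNetwork(
        "mm_depletion", net, sol, "S -> P by Michaelis-Menten, implicit closed form"
    )


def toy_networks() -> dict[str, ToyNetwork]:
    """Closed-form validation networks keyed by name."""
    toys = [_decay_toy(), _iso_toy(), _mm_depletion_toy()]
    return {t.name: t for t in toys}
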