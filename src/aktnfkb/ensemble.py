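"""Ensemble exploration of the unknown Akt -> IKK coupling rate.

No literature estimate exists for how fast phospho-Akt activates the IKK
complex, so the coupling rate constant is treated as an unknown: it is
sampled log-uniformly over several decades, the model is integrated once per
draw, and the resulting nuclear NF-kB time-courses are grouped into a small
set of characteristic shapes by k-means.  A calibration stage then keeps the
draws whose response matches the experimentally observed timing -- activation
within 15 min of EGF addition, sustained for the following 6 h -- and
summarizes them into a single nominal rate (geometric median, robust on the
log scale the draws live on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EnsembleError
from .network import ReactionNetwork, compile_network
from .pathway import COUPLING_REACTION, PathwayCatalog, default_catalog
from .simulate import InputProtocol, SolverSettings, default_grid, observable, simulate

__all__ = [
    "SamplingSpec",
    "EnsembleResult",
    "ResponseClasses",
    "CalibrationConstraints",
    "CalibrationResult",
    "sample_rates",
    "run_ensemble",
    "cluster_responses",
    "classify_clusters",
    "describe_centroid",
    "select_calibrated",
]

NULL_LABEL = -1  # reserved class for flat-zero trajectories


@dataclass(frozen=True)
class SamplingSpec:
    """Log-uniform sampling of one reaction's rate constant."""

    target_reaction: str = COUPLING_REACTION
    distribution: str = "log_uniform"
    low: float = 1e-3  # per nM per h
    high: float = 1e2
    n_draws: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.distribution != "log_uniform":
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not (0 < self.low < self.high):
            raise ValueError("need 0 < low < high")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def sample_rates(spec: SamplingSpec) -> np.ndarray:
    """Draw n_draws rate constants, log-uniform on [low, high]."""
    rng = np.random.default_rng(spec.seed)
    return np.exp(rng.uniform(np.log(spec.low), np.log(spec.high), spec.n_draws))


@dataclass
class EnsembleResult:
    draws: np.ndarray  # (n,) sampled rate constants
    times: np.ndarray  # (T,) shared output grid, h
    trajectories: np.ndarray  # (n, T) observable series; NaN rows for failures
    failed: list[int]  # indices of failed integrations
    observable_id: str
    labels: np.ndarray | None = None  # filled by cluster_responses
    meta: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        """Completed plus failed simulations."""
        return len(self.draws)

    @property
    def ok_indices(self) -> np.ndarray:
        mask = np.ones(len(self.draws), dtype=bool)
        mask[self.failed] = False
        return np.nonzero(mask)[0]


def run_ensemble(
    net: ReactionNetwork,
    spec: SamplingSpec,
    protocol: InputProtocol,
    settings: SolverSettings | None = None,
    catalog: PathwayCatalog | None = None,
    observable_id: str = "nuclear_NFkB",
    t_grid: np.ndarray | None = None,
    max_failure_fraction: float = 0.10,
) -> EnsembleResult:
    """One simulation per sampled coupling rate, on a shared time grid."""
    catalog = catalog or default_catalog()
    settings = settings or SolverSettings()
    if t_grid is None:
        t_grid = default_grid(protocol)
    target = net.reaction_by_id(spec.target_reaction)
    if target.rate_law.kind != "mass_action":
        raise EnsembleError(f"target reaction {spec.target_reaction!r} must be mass action")

    draws = sample_rates(spec)
    model = compile_network(net)
    col = model.ma_reaction_ids.index(spec.target_reaction)
    base_x0 = model.x0.copy()

    trajs = np.full((len(draws), len(t_grid)), np.nan)
    failed: list[int] = []
    for i, k in enumerate(draws):
        model.k_vec[col] = k
        model.x0 = base_x0.copy()
        try:
            tr = simulate(model, protocol, settings, t_grid)
        except Exception:
            failed.append(i)
            continue
        trajs[i] = observable(tr, catalog, observable_id)
    if len(draws) and len(failed) / len(draws) > max_failure_fraction:
        raise EnsembleError(
            f"{len(failed)}/{len(draws)} ensemble integrations failed; "
            "the sampling bounds are probably infeasible"
        )
    return EnsembleResult(
        draws=draws,
        times=np.asarray(t_grid, dtype=float),
        trajectories=trajs,
        failed=failed,
        observable_id=observable_id,
        meta={"spec": spec, "protocol": protocol},
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ResponseClasses:
    labels: np.ndarray  # per-draw label; NULL_LABEL for flat-zero, NaN-failures excluded
    centroids: np.ndarray  # (k, n_features) normalized centroid shapes
    chosen_k: int  # number of classes including the null class if present
    feature_times: np.ndarray
    silhouette_by_k: dict[int, float] = field(default_factory=dict)


def _features(times: np.ndarray, trajs: np.ndarray, n_points: int) -> np.ndarray:
    """Own-max normalization followed by resampling to a fixed-length grid."""
    grid = np.linspace(times[0], times[-1], n_points)
    out = np.empty((trajs.shape[0], n_points))
    for i, y in enumerate(trajs):
        m = y.max()
        yn = y / m if m > 0 else y
        out[i] = np.interp(grid, times, yn)
    return out


def cluster_responses(
    ens: EnsembleResult,
    k: int | str = "auto",
    seed: int = 0,
    n_features: int = 60,
    n_init: int = 10,
    null_threshold: float = 1e-9,
) -> ResponseClasses:
    """Group response shapes with standard k-means.

    Shapes -- not amplitudes -- define the classes: every trajectory is
    normalized to its own maximum before clustering (amplitude is still
    available from the stored trajectories).  Flat-zero trajectories have no
    shape to normalize and are assigned to a reserved null class first.
    ``k`` counts all classes including the null one; "auto" picks the best
    silhouette over total class counts 2..8.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    ok = ens.ok_indices
    trajs = ens.trajectories[ok]
    grid = np.linspace(ens.times[0], ens.times[-1], n_features)
    is_null = trajs.max(axis=1) <= null_threshold
    feats = _features(ens.times, trajs[~is_null], n_features)
    n_null_classes = int(is_null.any())
    n_active = feats.shape[0]

    def fit(n_clusters: int):
        km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
        return km.fit_predict(feats), km.cluster_centers_

    silhouettes: dict[int, float] = {}
    if k == "auto":
        best = None
        for k_total in range(2, 9):
            k_means = k_total - n_null_classes
            if k_means < 1 or k_means > max(n_active - 1, 1):
                continue
            if k_means == 1:
                silhouettes[k_total] = -1.0  # silhouette undefined for one cluster
                continue
            lab, _ = fit(k_means)
            if len(set(lab)) < 2:
                silhouettes[k_total] = -1.0
                continue
            silhouettes[k_total] = float(silhouette_score(feats, lab, random_state=seed))
        if not silhouettes:
            raise ValueError("too few trajectories for automatic class selection")
        k_total = max(silhouettes, key=lambda kk: (silhouettes[kk], -kk))
    else:
        k_total = int(k)
        if k_total < 1:
            raise ValueError("k must be >= 1")
        if k_total - n_null_classes > n_active:
            raise ValueError(
                f"k = {k_total} exceeds the {n_active + n_null_classes} usable trajectories"
            )

    k_means = k_total - n_null_classes
    if n_active and k_means >= 1:
        lab, centers = fit(k_means)
    else:
        lab = np.empty(0, dtype=int)
        centers = np.empty((0, n_features))

    labels = np.full(len(ens.draws), NULL_LABEL - 1)  # sentinel for failures
    active_ids = ok[~is_null]
    null_ids = ok[is_null]
    labels[null_ids] = NULL_LABEL
    labels[active_ids] = lab
    ens.labels = labels
    return ResponseClasses(
        labels=labels,
        centroids=centers,
        chosen_k=k_total,
        feature_times=grid,
        silhouette_by_k=silhouettes,
    )


def classify_clusters(
    ens: EnsembleResult, classes: ResponseClasses, flat_amplitude: float = 5.0
) -> dict[int, str]:
    """Name each cluster's response category, amplitude included.

    Own-max normalization deliberately removes amplitude before clustering,
    so it is restored here as the per-cluster summary: a cluster whose median
    member never moves the observable by more than ``flat_amplitude`` (nM;
    default 5, i.e. 5% of the 100-nM NF-kB pool, the same band used to call
    the unstimulated model quiescent) is a "flat" (no-response) category
    regardless of the shape of its vanishing trend.  Other clusters are named
    by their centroid shape.  The reserved null class, when present, is flat
    by construction.
    """
    out: dict[int, str] = {}
    labels = classes.labels
    if (labels == NULL_LABEL).any():
        out[NULL_LABEL] = "flat"
    for j, centroid in enumerate(classes.centroids):
        members = np.nonzero(labels == j)[0]
        amp = float(np.median(ens.trajectories[members].max(axis=1))) if members.size else 0.0
        out[j] = "flat" if amp < flat_amplitude else describe_centroid(centroid)
    return out


def describe_centroid(centroid: np.ndarray) -> str:
    """Classify a normalized centroid shape: flat/sustained/transient/oscillatory."""
    from scipy.signal import find_peaks

    c = np.asarray(centroid, dtype=float)
    rng = c.max() - c.min()
    if rng < 0.25:
        return "flat"
    peaks, _ = find_peaks(c, prominence=0.15)
    if len(peaks) >= 2:
        return "oscillatory"
    if c[0] < 0.5 and c[-1] >= 0.5 * c.max():
        return "sustained"
    if c[0] < 0.5 and c[-1] < 0.35 * c.max():
        return "transient"
    return "other"


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationConstraints:
    """Qualitative timing constraints on the nuclear NF-kB response.

    A trajectory qualifies when it is genuinely induced (peak at least
    min_fold_induction times its starting level), reaches sustain_fraction of
    its own maximum no later than rise_deadline, and stays at or above that
    level for the following sustain_horizon hours.
    """

    rise_deadline: float = 0.25  # h
    sustain_horizon: float = 6.0  # h
    sustain_fraction: float = 0.5
    min_fold_induction: float = 2.0

    def __post_init__(self):
        if not (self.rise_deadline > 0 and self.sustain_horizon > 0):
            raise ValueError("deadlines must be positive")
        if not 0 < self.sustain_fraction <= 1:
            raise ValueError("sustain_fraction must be in (0, 1]")
        if self.min_fold_induction < 1:
            raise ValueError("min_fold_induction must be >= 1")


@dataclass
class CalibrationResult:
    kept: np.ndarray  # indices of qualifying draws
    nominal_rate: float | None  # geometric median of kept draws
    constraints: CalibrationConstraints


def _qualifies(times: np.ndarray, y: np.ndarray, c: CalibrationConstraints) -> bool:
    m = y.max()
    if not m > 0:
        return False
    y0 = y[0]
    if y0 > 0 and m / y0 < c.min_fold_induction:
        return False
    thr = c.sustain_fraction * m
    above = y >= thr
    if not above.any():
        return False
    i0 = int(np.argmax(above))
    t0 = times[i0]
    if t0 > c.rise_deadline:
        return False
    window = (times >= t0) & (times <= t0 + c.sustain_horizon)
    return bool(np.all(above[window]))


def select_calibrated(
    ens: EnsembleResult, constraints: CalibrationConstraints | None = None
) -> CalibrationResult:
    """Keep draws matching the timing constraints; summarize a nominal rate.

    The nominal rate is the geometric median of the kept draws, i.e. the
    ordinary median on the log scale -- robust against the tails of the
    log-uniform proposal.  An empty kept set is reported, not raised.
    """
    c = constraints or CalibrationConstraints()
    if ens.n_total == 0:
        raise EnsembleError("empty ensemble")
    kept = [
        i
        for i in ens.ok_indices
        if _qualifies(ens.times, ens.trajectories[i], c)
    ]
    kept = np.asarray(kept, dtype=int)
    nominal = float(np.exp(np.median(np.log(ens.draws[kept])))) if kept.size else None
    return CalibrationResult(kept=kept, nominal_rate=nominal, constraints=c)
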