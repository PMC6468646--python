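"""In silico mutation experiments: scenario sweeps and severity metrics.

Each sweep applies one built-in scenario family over a grid of levels
(receptor or PI3K overexpression, PP2A titration, PTEN loss, Akt
inhibition), simulates the stimulation protocol, and tabulates severity
metrics: peak phospho-Akt, final and integrated nuclear NF-kB, and -- for
protocols that remove EGF partway -- a persistence index quantifying how
much of the activation survives the washout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ScenarioError, SimulationError
from .network import ReactionNetwork, compile_network
from .pathway import PathwayCatalog, apply_scenario, default_catalog, make_scenario
from .simulate import InputProtocol, SolverSettings, Trajectory, observable, simulate

__all__ = [
    "ScenarioSweep",
    "SweepResult",
    "persistence_index",
    "run_sweep",
    "compare_scenarios",
]

METRICS = ("peak_pAkt", "final_nuclear_NFkB", "auc_nuclear_NFkB", "persistence_index")


def persistence_index(
    traj: Trajectory, catalog: PathwayCatalog, oid: str, t_off: float
) -> float:
    """Final observable level relative to its pre-washout maximum.

    0 means full reversal after EGF removal, 1 means the activation held its
    pre-washout peak, and values above 1 indicate continued accumulation.
    """
    if traj.protocol.washout_time() != t_off:
        raise ScenarioError(
            f"protocol has no EGF washout at t = {t_off} h "
            f"(washout at {traj.protocol.washout_time()})"
        )
    y = observable(traj, catalog, oid)
    pre = y[traj.times <= t_off]
    peak = float(pre.max()) if pre.size else 0.0
    if peak <= 0:
        return 0.0
    return float(y[-1] / peak)


@dataclass(frozen=True)
class ScenarioSweep:
    family: str
    grid: tuple  # levels (nM or multiplier); (None,) for pten_loss
    protocol: InputProtocol
    metrics: tuple[str, ...] = METRICS

    def __post_init__(self):
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}")
        if not self.grid:
            raise ValueError("sweep grid may not be empty")


@dataclass
class SweepResult:
    family: str
    table: pd.DataFrame  # rows: baseline + one per level; columns: metrics
    protocol: InputProtocol
    meta: dict = field(default_factory=dict)

    def fold_change(self, metric: str) -> float:
        """Largest |fold change| of the metric over the grid vs baseline."""
        if metric not in self.table.columns:
            raise ValueError(f"metric {metric!r} missing from sweep table")
        base = self.table.loc[self.table["role"] == "baseline", metric].iloc[0]
        levels = self.table.loc[self.table["role"] == "level", metric].dropna()
        if not np.isfinite(base) or base == 0 or levels.empty:
            return float("nan")
        return float((levels / base).abs().max())

    def max_persistence(self) -> float:
        col = self.table.get("persistence_index")
        if col is None or col.dropna().empty:
            return float("nan")
        return float(col.dropna().max())


def _metrics_row(
    traj: Trajectory, catalog: PathwayCatalog, protocol: InputProtocol, wanted
) -> dict:
    row: dict[str, float] = {}
    nn = observable(traj, catalog, "nuclear_NFkB")
    if "peak_pAkt" in wanted:
        row["peak_pAkt"] = float(observable(traj, catalog, "pAkt_S473").max())
    if "final_nuclear_NFkB" in wanted:
        row["final_nuclear_NFkB"] = float(nn[-1])
    if "auc_nuclear_NFkB" in wanted:
        row["auc_nuclear_NFkB"] = float(np.trapezoid(nn, traj.times))
    if "persistence_index" in wanted:
        t_off = protocol.washout_time()
        row["persistence_index"] = (
            persistence_index(traj, catalog, "nuclear_NFkB", t_off)
            if t_off is not None
            else float("nan")
        )
    return row


def run_sweep(
    net: ReactionNetwork,
    sweep: ScenarioSweep,
    settings: SolverSettings | None = None,
    catalog: PathwayCatalog | None = None,
) -> SweepResult:
    """Apply -> simulate -> measure for every level; deterministic.

    A failed integration at one level is recorded (status column) and the
    sweep continues.  The baseline (unperturbed) row is always included.
    """
    catalog = catalog or default_catalog()
    settings = settings or SolverSettings()
    rows = []
    for role, level in (("baseline", None), *(("level", lv) for lv in sweep.grid)):
        entry: dict = {
            "role": role,
            "level": np.nan if level is None else level,
            "status": "ok",
        }
        try:
            if role == "baseline":
                net_run = net
            else:
                net_run = apply_scenario(net, make_scenario(sweep.family, level))
            traj = simulate(compile_network(net_run), sweep.protocol, settings)
            entry.update(_metrics_row(traj, catalog, sweep.protocol, sweep.metrics))
        except SimulationError as exc:
            entry["status"] = f"failed: {exc}"
            entry.update({m: np.nan for m in sweep.metrics})
        rows.append(entry)
    table = pd.DataFrame(rows)
    return SweepResult(family=sweep.family, table=table, protocol=sweep.protocol)


def compare_scenarios(results: list[SweepResult], metric: str) -> pd.DataFrame:
    """Rank sweeps by the severity of their effect on one metric.

    Severity is the largest fold change versus baseline across the sweep
    grid; ties are broken by the sweep's maximum persistence index, then by
    family name for a deterministic report.
    """
    if not results:
        raise ValueError("no sweep results to compare")
    rows = []
    for res in results:
        if metric not in res.table.columns:
            raise ValueError(f"metric {metric!r} missing from sweep {res.family!r}")
        rows.append(
            {
                "scenario": res.family,
                "fold_change": res.fold_change(metric),
                "max_persistence": res.max_persistence(),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["fold_change", "max_persistence", "scenario"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
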