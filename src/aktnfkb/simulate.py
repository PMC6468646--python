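"""Time integration of compiled models under piecewise-constant EGF protocols.

The stimulation protocol is a list of contiguous segments, each holding the
extracellular EGF level constant.  Integration restarts at every segment
boundary (stiff multistep methods lose order across discontinuities), and the
input species' concentration is clamped to the segment level rather than
integrated -- the input drives the system but is not a state variable.

The default solver is a variable-order implicit stiff multistep method
(LSODA, which runs BDF on stiff stretches) with the analytic Jacobian; an
explicit Runge-Kutta mode is kept as a cross-method testing oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import odeint, solve_ivp

from .errors import SimulationError
from .network import CompiledModel, _mm_rates_fast, _rhs_fast, rhs_jacobian

__all__ = [
    "InputProtocol",
    "SolverSettings",
    "Trajectory",
    "constant_protocol",
    "washout_protocol",
    "default_grid",
    "simulate",
    "observable",
]

#: default output resolution: one point per minute of simulated time
POINTS_PER_HOUR = 60


@dataclass(frozen=True)
class InputProtocol:
    """Ordered contiguous (t_start, t_end, egf_nM) segments starting at 0 h."""

    segments: tuple[tuple[float, float, float], ...]
    description: str = ""

    def __post_init__(self):
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        prev_end = 0.0
        for i, (t0, t1, level) in enumerate(self.segments):
            if i == 0 and t0 != 0.0:
                raise ValueError("first segment must start at t = 0 h")
            if i > 0 and t0 != prev_end:
                raise ValueError("segments must be contiguous and non-overlapping")
            if not t1 > t0:
                raise ValueError(f"segment {i}: t_end must exceed t_start")
            if level < 0:
                raise ValueError(f"segment {i}: EGF level must be >= 0 nM")
            prev_end = t1

    @property
    def t_end(self) -> float:
        return self.segments[-1][1]

    def level_at(self, t: float) -> float:
        for t0, t1, level in self.segments:
            if t0 <= t < t1:
                return level
        if t == self.t_end:
            return self.segments[-1][2]
        raise ValueError(f"t = {t} h outside protocol span [0, {self.t_end}]")

    def washout_time(self) -> float | None:
        """Time at which EGF is removed (level drops to 0), if any."""
        for i in range(1, len(self.segments)):
            if self.segments[i][2] == 0.0 and self.segments[i - 1][2] > 0.0:
                return self.segments[i][0]
        return None


def constant_protocol(egf_nM: float, t_end: float) -> InputProtocol:
    return InputProtocol(
        segments=((0.0, float(t_end), float(egf_nM)),),
        description=f"{egf_nM} nM EGF for {t_end} h",
    )


def washout_protocol(egf_nM: float, t_off: float, t_end: float) -> InputProtocol:
    """EGF at egf_nM on [0, t_off), then removed until t_end."""
    if not 0 < t_off < t_end:
        raise ValueError(f"need 0 < t_off < t_end, got t_off={t_off}, t_end={t_end}")
    return InputProtocol(
        segments=((0.0, float(t_off), float(egf_nM)), (float(t_off), float(t_end), 0.0)),
        description=f"{egf_nM} nM EGF for {t_off} h, washout until {t_end} h",
    )


@dataclass(frozen=True)
class SolverSettings:
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9  # nM
    max_step: float | None = None
    method: str = "stiff_multistep"  # or "explicit_rk"

    def __post_init__(self):
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise ValueError("tolerances must be positive")
        if self.method not in ("stiff_multistep", "explicit_rk"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class Trajectory:
    times: np.ndarray  # (T,) hours
    states: np.ndarray  # (T, n_species) nM
    species_index: dict[str, int]
    protocol: InputProtocol

    def col(self, sid: str) -> np.ndarray:
        return self.states[:, self.species_index[sid]]

    def to_frame(self):
        import pandas as pd

        data = {"time_h": self.times}
        for sid, i in self.species_index.items():
            data[sid] = self.states[:, i]
        return pd.DataFrame(data)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def default_grid(protocol: InputProtocol) -> np.ndarray:
    n = int(round(protocol.t_end * POINTS_PER_HOUR)) + 1
    return np.linspace(0.0, protocol.t_end, max(n, 2))


def _clamped_rhs(model: CompiledModel, u: float):
    ii = model.input_index

    def f(x, t):
        xe = np.maximum(x, 0.0)
        if ii is not None:
            xe[ii] = u
        dx = _rhs_fast(model, xe, u)
        if ii is not None:
            dx[ii] = 0.0
        return dx

    def jac(x, t):
        xe = np.maximum(x, 0.0)
        if ii is not None:
            xe[ii] = u
        J = rhs_jacobian(model, xe, u)
        if ii is not None:
            J[ii, :] = 0.0
            J[:, ii] = 0.0
        return J

    return f, jac


def _integrate_segment(model, x0, t_pts, u, settings):
    f, jac = _clamped_rhs(model, u)
    if settings.method == "stiff_multistep":
        kwargs = {}
        if settings.max_step is not None:
            kwargs["hmax"] = settings.max_step
        out, info = odeint(
            f,
            x0,
            t_pts,
            Dfun=jac,
            rtol=settings.rel_tol,
            # keep the solver's own error band well inside the reporting band
            atol=settings.abs_tol * 1e-2,
            mxstep=20000,
            full_output=True,
            **kwargs,
        )
        if info["message"] != "Integration successful.":
            reached = float(info["tcur"][-1]) if len(info.get("tcur", [])) else t_pts[0]
            raise SimulationError(
                f"stiff integration failed: {info['message']}", last_time=reached
            )
        return out
    # explicit Runge-Kutta oracle
    sol = solve_ivp(
        lambda t, y: f(y, t),
        (t_pts[0], t_pts[-1]),
        x0,
        method="RK45",
        t_eval=t_pts,
        rtol=settings.rel_tol,
        atol=settings.abs_tol * 1e-2,
        max_step=settings.max_step if settings.max_step is not None else np.inf,
    )
    if not sol.success:
        raise SimulationError(f"explicit integration failed: {sol.message}",
                              last_time=float(sol.t[-1]) if sol.t.size else t_pts[0])
    return sol.y.T


def simulate(
    model: CompiledModel,
    protocol: InputProtocol,
    settings: SolverSettings | None = None,
    t_grid: Sequence[float] | None = None,
) -> Trajectory:
    """Integrate the model over the protocol and report states on t_grid.

    Integration proceeds segment by segment with a restart at every EGF-level
    discontinuity.  Small negative excursions (within the solver error band
    abs_tol + rel_tol * max|x|) are zeroed; anything below that band raises a
    SimulationError.
    """
    settings = settings or SolverSettings()
    if t_grid is None:
        t_grid = default_grid(protocol)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly ascending with >= 2 points")
    if t_grid[0] < 0 or t_grid[-1] > protocol.t_end + 1e-12:
        raise ValueError("t_grid must lie within the protocol span")

    out = np.empty((t_grid.size, model.n_species))
    filled = np.zeros(t_grid.size, dtype=bool)

    state = model_initial_state(model)
    prev_t = 0.0
    if model.input_index is not None:
        state = state.copy()
        state[model.input_index] = protocol.segments[0][2]
    for t0, t1, level in protocol.segments:
        if model.input_index is not None:
            state[model.input_index] = level
        sel = (t_grid >= t0 - 1e-12) & (t_grid <= t1 + 1e-12) & ~filled
        pts = np.unique(np.concatenate([[max(t0, prev_t)], t_grid[sel], [t1]]))
        pts = pts[(pts >= t0 - 1e-12) & (pts <= t1 + 1e-12)]
        seg = _integrate_segment(model, state, pts, level, settings)
        # map integrated points back onto the requested grid
        for gi in np.nonzero(sel)[0]:
            pi = int(np.argmin(np.abs(pts - t_grid[gi])))
            out[gi] = seg[pi]
            filled[gi] = True
        state = seg[-1].copy()
        prev_t = t1
        if t1 >= t_grid[-1]:
            break
    if not np.all(filled):
        raise SimulationError("internal error: grid points left unfilled")

    band = settings.abs_tol + settings.rel_tol * float(np.max(np.abs(out)))
    low = out.min()
    if low < -band:
        i, j = np.unravel_index(np.argmin(out), out.shape)
        raise SimulationError(
            f"state went negative beyond tolerance: species index {j} reached "
            f"{low:.3e} nM at t = {t_grid[i]:.4f} h"
        )
    np.clip(out, 0.0, None, out=out)
    if model.input_index is not None:
        out[:, model.input_index] = [protocol.level_at(t) for t in t_grid]

    return Trajectory(
        times=t_grid,
        states=out,
        species_index=dict(model.species_index),
        protocol=protocol,
    )


def model_initial_state(model: CompiledModel) -> np.ndarray:
    if model.x0 is None:
        raise SimulationError("compiled model carries no initial state (x0)")
    return np.asarray(model.x0, dtype=float).copy()


def observable(
    traj: Trajectory,
    catalog,
    oid: str,
    normalize: bool = False,
) -> np.ndarray:
    """Weighted sum of state columns; optionally scaled to its own maximum.

    Normalization mirrors the relative-density convention of densitometry
    readouts: each series is reported relative to its strongest band.
    """
    weights = catalog.observables.get(oid)
    if weights is None:
        raise KeyError(f"unknown observable {oid!r}")
    y = np.zeros(traj.times.size)
    for sid, w in weights.items():
        y += w * traj.col(sid)
    if normalize:
        m = y.max()
        if m > 0:
            y = y / m
    return y
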