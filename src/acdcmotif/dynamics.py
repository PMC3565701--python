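"""Numerical integration, attractor detection and bifurcation scans.

The threshold model has a discontinuous vector field, so trajectories are
integrated piecewise: the Heaviside configuration is frozen, scipy's
``solve_ivp`` runs with terminal events on every switching surface
(P = P_crit1, O = O_crit1, N = N_crit1 for the three-gene model, one event
per distinct threshold edge for generalized circuits), and integration
restarts with the flipped configuration at each crossing.  Between events
the O and N sub-dynamics are linear, so the numerical solution can be (and
is, in the tests) checked against exponential-relaxation closed forms.
The graded model is smooth and integrated in one LSODA call.

Attractors are summarised as fixed points, limit cycles (period estimated
from successive refined peaks of O) or damped oscillations onto a fixed
point; anything else is flagged undecided rather than coerced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

from . import analytic
from .circuit import (
    GRADED,
    THRESHOLD,
    CircuitParameters,
    MultiGeneCircuit,
    _rhs,
    _rhs_sigma,
    _sigma_of,
    _threshold_switches,
)

logger = logging.getLogger("acdcmotif")

__all__ = [
    "Trajectory",
    "AttractorSummary",
    "BifurcationTable",
    "FixedPoint",
    "HysteresisResult",
    "integrate",
    "detect_attractor",
    "scan_bifurcation",
    "sweep_hysteresis",
    "find_fixed_points_graded",
    "classify_regime_by_simulation",
]

#: detection tolerances: steady-state RHS norm, relative oscillation
#: amplitude separating cycles from numerical ripple, period agreement
TOL_SS = 1e-8
TOL_AMP = 1e-3
TOL_PER = 5e-3

_MAX_SEGMENTS = 20000


# ---------------------------------------------------------------------------
# Model adapter
# ---------------------------------------------------------------------------

class _System:
    """Uniform view of a CircuitParameters or MultiGeneCircuit model."""

    def __init__(self, model):
        self.model = model
        if isinstance(model, CircuitParameters):
            self.names = ("P", "O", "N")
            self.scales = np.array([model.P_max, model.O_max, model.N_max])
            self.x0_default = np.array([model.P_max, 0.0, 0.0])
            if model.mode == THRESHOLD:
                self.switches = _threshold_switches(model)
                self.f_sigma = lambda x, S, sigma: _rhs_sigma(x, S, model, sigma)
                self.sigma_of = lambda x: _sigma_of(x, model)
            else:
                self.switches = ()
            self.f = lambda x, S: _rhs(x, S, model)
        elif isinstance(model, MultiGeneCircuit):
            self.names = model.names
            self.scales = model.gene_max
            self.x0_default = model.initial_state()
            self.switches = model.threshold_switches
            self.f = model.rhs
            self.f_sigma = lambda x, S, sigma: model.rhs_sigma(x, S, sigma)
            self.sigma_of = model.sigma_of
        else:
            raise TypeError(
                f"expected CircuitParameters or MultiGeneCircuit, got {type(model)!r}")

    @property
    def n(self) -> int:
        return len(self.names)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time samples of one integration, with recorded switching events."""

    t: np.ndarray
    y: np.ndarray              # shape (len(t), n_genes)
    names: tuple
    S: float
    model: object
    events: list = field(default_factory=list)

    @property
    def final_state(self) -> np.ndarray:
        return self.y[-1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"t": self.t})
        for i, name in enumerate(self.names):
            frame[name] = self.y[:, i]
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _make_event(idx: int, level: float):
    def g(t, x, idx=idx, level=level):
        return x[idx] - level

    g.terminal = True
    g.direction = 0
    return g


def _integrate_threshold(sys: _System, S: float, x0: np.ndarray, t_end: float,
                         rtol: float, atol: float, grid: np.ndarray):
    """Event-aware piecewise integration of a threshold-mode circuit."""
    sigma = list(sys.sigma_of(x0))
    x = np.array(x0, dtype=float)
    t0 = 0.0
    ts: list = [0.0]
    ys: list = [x.copy()]
    events: list = []
    ev_funs = [_make_event(idx, level) for idx, level in sys.switches]
    stalls = 0
    for _ in range(_MAX_SEGMENTS):
        if t0 >= t_end:
            break
        t_eval = grid[(grid > t0 + 1e-13) & (grid <= t_end)]
        if t_eval.size == 0:
            t_eval = np.array([t_end])
        frozen = tuple(sigma)
        sol = solve_ivp(lambda t, x: sys.f_sigma(x, S, frozen),
                        (t0, t_end), x, t_eval=t_eval, events=ev_funs,
                        method="RK45", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"solver failed at t={t0:.6g}, state={x.tolist()}: {sol.message}")
        sol_t = np.atleast_1d(np.asarray(sol.t, dtype=float))
        if sol_t.size:
            ts.extend(sol_t.tolist())
            ys.extend(list(np.asarray(sol.y, dtype=float).T))
        fired = [(j, te[0]) for j, te in enumerate(sol.t_events) if te.size]
        if not fired:
            break
        te = min(t for _, t in fired)
        xe = None
        for j, tj in fired:
            if abs(tj - te) <= 1e-12 * max(1.0, te):
                if xe is None:
                    xe = np.array(sol.y_events[j][0], dtype=float)
                idx, level = sys.switches[j]
                xdot = sys.f_sigma(xe, S, frozen)[idx]
                eps = 1e-12 * max(1.0, abs(level)) * (10.0 ** stalls)
                if xdot > 0.0:
                    sigma[j] = 0.0          # rising through the threshold
                    xe[idx] = level + eps
                elif xdot < 0.0:
                    sigma[j] = 1.0          # falling through the threshold
                    xe[idx] = level - eps
                else:
                    sigma[j] = 1.0          # tangent contact: H(0) = 1
                    logger.debug("tangential contact with %s=%g at t=%g",
                                 sys.names[idx], level, te)
                events.append({"time": te, "variable": sys.names[idx],
                               "level": level,
                               "direction": int(np.sign(xdot))})
        if ts[-1] < te - 1e-13:
            ts.append(te)
            ys.append(xe.copy())
        if te <= t0 + 1e-10:
            stalls += 1
            if stalls > 6:
                raise RuntimeError(
                    f"integration stalled on a switching surface at t={te:.6g}, "
                    f"state={xe.tolist()}")
        else:
            stalls = 0
        t0, x = te, xe
    else:
        raise RuntimeError(
            f"exceeded {_MAX_SEGMENTS} switching events at t={t0:.6g} "
            f"(state={x.tolist()}); possible chattering")
    t = np.asarray(ts)
    y = np.asarray(ys)
    keep = np.concatenate(([True], np.diff(t) > 0))
    return t[keep], y[keep], events


def integrate(model, S: float, init=None, t_end: float = 60.0, *,
              rtol: float = 1e-9, atol: float = 1e-12,
              n_samples: int | None = None) -> Trajectory:
    """Integrate a circuit at fixed signal level ``S`` from ``init``.

    ``init`` defaults to the pre-signal state (constitutive gene at its
    maximum, everything else zero).  Threshold circuits use event-aware
    stepping with integration restarted at every switching-surface
    crossing; smooth (graded) circuits use a single LSODA call.  Sampling
    is dense enough (>= 20 samples per time unit) to resolve oscillation
    extrema.
    """
    if t_end <= 0.0:
        raise ValueError(f"t_end must be > 0, got {t_end!r}")
    if not (math.isfinite(S) and S >= 0.0):
        raise ValueError(f"signal level must be finite and >= 0, got {S!r}")
    sys = _System(model)
    if init is None:
        x0 = sys.x0_default
    else:
        if hasattr(init, "to_array"):
            init = init.to_array()
        x0 = np.asarray(init, dtype=float).reshape(-1)
    if x0.shape != (sys.n,):
        raise ValueError(f"init must have {sys.n} components")
    if np.any(x0 < -1e-9):
        raise ValueError("initial state must be nonnegative")
    x0 = np.maximum(x0, 0.0)   # forgive integrator round-off
    if n_samples is None:
        n_samples = int(max(1001, 20 * t_end + 1))
    grid = np.linspace(0.0, t_end, n_samples)

    if sys.switches:
        t, y, events = _integrate_threshold(sys, S, x0, t_end, rtol, atol, grid)
    else:
        sol = solve_ivp(lambda t, x: sys.f(x, S), (0.0, t_end), x0,
                        t_eval=grid, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"solver failed at t={sol.t[-1] if sol.t.size else 0:.6g}: "
                f"{sol.message}")
        t, y, events = sol.t, sol.y.T, []
    return Trajectory(t=t, y=y, names=tuple(sys.names), S=S, model=model,
                      events=events)


# ---------------------------------------------------------------------------
# Attractor detection
# ---------------------------------------------------------------------------

@dataclass
class AttractorSummary:
    """Classification of a trajectory's long-time behaviour."""

    type: str                   # fixed_point | limit_cycle |
    #                             damped_oscillation_to_fixed_point | undecided
    state: np.ndarray | None = None
    period: float | None = None
    extrema: dict = field(default_factory=dict)   # name -> (min, max)
    residual: float = math.nan
    amplitude: float = math.nan
    n_cycles: int = 0
    period_spread: float = math.nan   # relative spread of the last 5 periods
    period_variable: str | None = None

    @property
    def is_oscillatory(self) -> bool:
        return self.type == "limit_cycle"


def _refined_peak_times(t: np.ndarray, y: np.ndarray,
                        prominence: float) -> np.ndarray:
    idx, _ = find_peaks(y, prominence=prominence)
    times = []
    for i in idx:
        if 0 < i < len(t) - 1:
            coeff = np.polyfit(t[i - 1:i + 2], y[i - 1:i + 2], 2)
            if coeff[0] < 0.0:
                tv = -coeff[1] / (2.0 * coeff[0])
                if t[i - 1] <= tv <= t[i + 1]:
                    times.append(tv)
                    continue
        times.append(t[i])
    return np.asarray(times)


def detect_attractor(traj: Trajectory, *, tol_ss: float = TOL_SS,
                     tol_amp: float = TOL_AMP,
                     tol_per: float = TOL_PER) -> AttractorSummary:
    """Classify the long-time behaviour of a trajectory.

    The first half of the horizon is treated as burn-in.  A fixed point
    requires both a terminal RHS norm below ``tol_ss`` and a window
    amplitude below ``tol_amp`` (relative to each variable's scale); a
    limit cycle requires successive refined peak times whose last five
    inter-peak intervals agree within ``tol_per``; a damped oscillation
    is a converged endpoint preceded by at least three peaks of decaying
    height.  Anything else is reported as undecided.

    The cycle period is shared by every variable, so it is estimated from
    whichever oscillating variable gives the most consistent peak
    sequence: in threshold mode the extrema of O and N sit on switching
    corners where parabolic peak refinement is biased by the sampling
    phase, while the always-graded P peaks smoothly.
    """
    sys = _System(traj.model)
    t, y = traj.t, traj.y
    burn = t >= t[-1] / 2.0
    tw, yw = t[burn], y[burn]
    scales = np.maximum(np.max(np.abs(y), axis=0), 1e-12)
    rel_amp = (yw.max(axis=0) - yw.min(axis=0)) / scales
    amplitude = float(rel_amp.max())
    residual = float(np.max(np.abs(sys.f(traj.final_state, traj.S))))
    # O is the conventional oscillation readout; fall back to the most
    # oscillatory variable for generalized circuits
    osc_var = 1 if sys.n >= 2 else 0
    if rel_amp[osc_var] < 0.5 * amplitude:
        osc_var = int(np.argmax(rel_amp))

    if amplitude < tol_amp and residual < tol_ss:
        full_peaks = _refined_peak_times(
            t, y[:, osc_var], prominence=10.0 * tol_amp * scales[osc_var])
        heights = np.interp(full_peaks, t, y[:, osc_var])
        damped = (len(full_peaks) >= 3
                  and np.all(np.diff(heights) < 0.0))
        kind = "damped_oscillation_to_fixed_point" if damped else "fixed_point"
        return AttractorSummary(type=kind, state=traj.final_state.copy(),
                                residual=residual, amplitude=amplitude)

    best = None
    for var in range(sys.n):
        if rel_amp[var] < tol_amp:
            continue
        span = yw[:, var].max() - yw[:, var].min()
        peaks = _refined_peak_times(tw, yw[:, var], prominence=0.25 * span)
        if len(peaks) < 6:
            continue
        last = np.diff(peaks)[-5:]
        spread = float((last.max() - last.min()) / last.mean())
        if best is None or spread < best[0]:
            best = (spread, var, peaks, last)
    if best is not None:
        spread, var, peaks, last = best
        if spread <= tol_per and amplitude >= tol_amp:
            period = float(last.mean())
            window = tw >= peaks[-1] - 5.0 * period
            extrema = {name: (float(yw[window, i].min()),
                              float(yw[window, i].max()))
                       for i, name in enumerate(traj.names)}
            return AttractorSummary(type="limit_cycle", period=period,
                                    extrema=extrema, residual=residual,
                                    amplitude=amplitude,
                                    n_cycles=len(peaks) - 1,
                                    period_spread=spread,
                                    period_variable=traj.names[var])
    logger.debug("undecided attractor at S=%g (amplitude=%g, residual=%g)",
                 traj.S, amplitude, residual)
    return AttractorSummary(type="undecided", state=traj.final_state.copy(),
                            residual=residual, amplitude=amplitude)


# ---------------------------------------------------------------------------
# Bifurcation scans
# ---------------------------------------------------------------------------

@dataclass
class BifurcationTable:
    """Per-signal-level attractor summaries over an increasing S grid."""

    frame: pd.DataFrame
    summaries: list = field(default_factory=list)
    fixed_points: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        cols = ["S", "attractor_type", "O_ss", "O_max", "O_min", "period"]
        self.frame[cols].to_csv(path, index=False)

    @property
    def oscillatory_interval(self) -> tuple | None:
        """(S_lo, S_hi) spanned by limit-cycle rows, or None."""
        osc = self.frame.loc[self.frame.attractor_type == "limit_cycle", "S"]
        if osc.empty:
            return None
        return (float(osc.min()), float(osc.max()))


def scan_bifurcation(model, S_values, *, t_end: float = 500.0,
                     init_policy: str = "fixed", rtol: float = 1e-8,
                     atol: float = 1e-11, compute_unstable: bool = False,
                     fixed_point_seed: int = 0) -> BifurcationTable:
    """Attractor summary at every level of an increasing S grid.

    ``init_policy`` is "fixed" (every cell starts from the pre-signal state,
    as in the bifurcation diagrams) or "adiabatic" (each level starts from
    the previous endpoint).  With ``compute_unstable`` (graded mode) the
    roots of the RHS are located at every level and annotated with their
    Jacobian eigenvalues.
    """
    S_values = np.asarray(S_values, dtype=float)
    if S_values.ndim != 1 or np.any(np.diff(S_values) <= 0.0):
        raise ValueError("S grid must be one-dimensional and strictly increasing")
    if init_policy not in ("fixed", "adiabatic"):
        raise ValueError(f"unknown init policy {init_policy!r}")
    sys = _System(model)
    threshold3 = isinstance(model, CircuitParameters) and model.mode == THRESHOLD

    rows, summaries, fp_col = [], [], []
    state = None
    for S in S_values:
        init = state if (init_policy == "adiabatic" and state is not None) else None
        traj = integrate(model, S, init=init, t_end=t_end, rtol=rtol, atol=atol)
        summ = detect_attractor(traj)
        state = traj.final_state
        o_idx = 1 if sys.n >= 2 else 0
        row = {"S": S, "attractor_type": summ.type,
               "O_ss": math.nan, "O_max": math.nan, "O_min": math.nan,
               "period": math.nan, "residual": summ.residual}
        if summ.type == "limit_cycle":
            name = traj.names[o_idx]
            row["O_min"], row["O_max"] = summ.extrema[name]
            row["period"] = summ.period
        elif summ.state is not None:
            row["O_ss"] = float(summ.state[o_idx])
        if threshold3:
            row["branches"] = "|".join(analytic.existing_branches(S, model))
        fps = []
        if compute_unstable and isinstance(model, CircuitParameters) \
                and model.mode == GRADED:
            fps = find_fixed_points_graded(model, S, seed=fixed_point_seed)
            row["n_fixed_points"] = len(fps)
            row["n_unstable"] = sum(not fp.stable for fp in fps)
        rows.append(row)
        summaries.append(summ)
        fp_col.append(fps)
    table = BifurcationTable(frame=pd.DataFrame(rows), summaries=summaries,
                             fixed_points=fp_col)
    n_undecided = int((table.frame.attractor_type == "undecided").sum())
    if n_undecided:
        logger.warning("%d undecided rows in bifurcation scan", n_undecided)
    return table


# ---------------------------------------------------------------------------
# Hysteresis sweeps
# ---------------------------------------------------------------------------

@dataclass
class HysteresisResult:
    up_transitions: list        # (S, from_label, to_label) on the up-sweep
    down_transitions: list
    up_labels: pd.DataFrame
    down_labels: pd.DataFrame


def _nearest_branch(state: np.ndarray, S: float,
                    params: CircuitParameters) -> str:
    labels = analytic.existing_branches(S, params)
    if not labels:
        return "none"
    scale = max(params.P_max, params.O_max, params.N_max)
    best, dist = None, math.inf
    for label in labels:
        value = analytic.branch_value(label, S, params).to_array()
        err = np.max(np.abs(value - state)) / scale
        if err < dist:
            best, dist = label, err
    return best if dist < 1e-3 else "osc"


def sweep_hysteresis(params: CircuitParameters, S_max: float, *,
                     n_steps: int = 301, t_relax: float = 40.0,
                     rtol: float = 1e-9) -> HysteresisResult:
    """Adiabatic up- and down-sweeps, recording branch-change signal levels.

    The up-sweep starts from the pre-signal state at S = 0 and carries each
    endpoint to the next level; the down-sweep starts from the relaxed state
    at ``S_max``.  Because stable branches persist until they cease to
    exist, the up-transition out of B1 occurs at a higher S than the
    down-transition into it (hysteresis).
    """
    if params.mode != THRESHOLD:
        raise ValueError("hysteresis sweeps are defined for the threshold model")
    S_grid = np.linspace(0.0, S_max, n_steps)

    def sweep(levels):
        state = None
        records, transitions = [], []
        prev_label = None
        for S in levels:
            traj = integrate(params, S, init=state, t_end=t_relax, rtol=rtol,
                             n_samples=301)
            state = traj.final_state
            amp = (np.ptp(traj.y[traj.t >= t_relax / 2.0], axis=0)
                   / np.maximum(np.max(np.abs(traj.y), axis=0), 1e-12)).max()
            label = ("osc" if amp > 1e-5
                     else _nearest_branch(state, S, params))
            records.append({"S": S, "branch": label})
            if prev_label is not None and label != prev_label:
                transitions.append((float(S), prev_label, label))
            prev_label = label
        return transitions, pd.DataFrame(records)

    up_tr, up_df = sweep(S_grid)
    down_tr, down_df = sweep(S_grid[::-1])
    return HysteresisResult(up_transitions=up_tr, down_transitions=down_tr,
                            up_labels=up_df, down_labels=down_df)


# ---------------------------------------------------------------------------
# Fixed points of the graded model
# ---------------------------------------------------------------------------

@dataclass
class FixedPoint:
    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool
    residual: float


def _jacobian_fd(f, x: np.ndarray, scale: np.ndarray) -> np.ndarray:
    n = len(x)
    jac = np.empty((n, n))
    for j in range(n):
        h = 1e-7 * max(scale[j], 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        jac[:, j] = (f(xp) - f(xm)) / (xp[j] - xm[j])
    return jac


def find_fixed_points_graded(params: CircuitParameters, S: float, *,
                             n_random: int = 24, seed: int = 0,
                             tol: float = 1e-10) -> list:
    """All roots of the graded RHS, found by multi-start root solving.

    Starts combine the threshold-model branch values with Latin-ish random
    points in the expression box; duplicate roots are merged and each root
    is annotated with finite-difference Jacobian eigenvalues (an unstable
    focus, i.e. a complex pair with positive real part, accompanies a limit
    cycle).
    """
    if params.mode != GRADED:
        raise ValueError("find_fixed_points_graded expects graded-mode parameters")
    d = params.drive(S)
    scale = np.array([params.P_max, params.O_max, params.N_max])
    f = lambda x: _rhs(x, S, params)

    starts = [np.array([params.P_max, 0.0, 0.0]),
              np.array([params.P_max * 0.04, params.O_max * d, 0.0]),
              np.array([params.P_max * 0.04, 0.0, params.N_max * d]),
              np.array([params.P_max * 0.04, params.O_max * d,
                        params.N_max * d])]
    rng = np.random.default_rng(seed)
    starts.extend(rng.uniform(0.0, 1.0, size=(n_random, 3)) * scale)

    roots: list[FixedPoint] = []
    for x0 in starts:
        sol = root(f, x0, method="hybr", tol=1e-13)
        if not sol.success:
            logger.debug("root start %s did not converge: %s", x0, sol.message)
            continue
        x = np.maximum(sol.x, 0.0)
        res = float(np.max(np.abs(f(x))))
        if res > max(tol, 1e-9):
            continue
        if any(np.max(np.abs(r.state - x) / np.maximum(scale, 1.0)) < 1e-6
               for r in roots):
            continue
        eig = np.linalg.eigvals(_jacobian_fd(f, x, scale))
        roots.append(FixedPoint(state=x, eigenvalues=eig,
                                stable=bool(np.all(eig.real < 0.0)),
                                residual=res))
    roots.sort(key=lambda r: r.state[2])   # by N level, low to high
    return roots


# ---------------------------------------------------------------------------
# Simulation-only regime classification
# ---------------------------------------------------------------------------

def _phase_of(state: np.ndarray, params: CircuitParameters) -> str:
    """Phase of a converged threshold-model state by which genes are on.

    In threshold mode silenced genes decay to exactly zero, so a tiny
    relative tolerance separates the phases unambiguously.
    """
    o_on = state[1] > 1e-6 * params.O_max
    n_on = state[2] > 1e-6 * params.N_max
    if n_on and o_on:
        return "B3"
    if n_on:
        return "B2"
    return "B1"


def _probe_stable_state(params: CircuitParameters, S: float,
                        t_relax: float, rtol: float):
    """Search for a stable steady state at fixed S from generic starts.

    Returns the first converged endpoint of a small battery of initial
    conditions (pre-signal, N-high, co-expression-high), or None when every
    start keeps oscillating — the simulation analogue of a gap in the
    steady states.
    """
    d = params.drive(S)
    scales = np.array([params.P_max, params.O_max, params.N_max])
    battery = [np.array([0.0, 0.0, params.N_max * d]),
               np.array([0.0, params.O_max * d, params.N_max * d]),
               np.array([params.P_max, 0.0, 0.0])]
    for x0 in battery:
        traj = integrate(params, S, init=x0, t_end=t_relax, rtol=rtol,
                         n_samples=301)
        window = traj.t >= t_relax / 2.0
        amp = (np.ptp(traj.y[window], axis=0) / scales).max()
        if amp <= 1e-5:
            return np.maximum(traj.final_state, 0.0)
    return None


def classify_regime_by_simulation(params: CircuitParameters, *,
                                  n_grid: int = 81, d_max: float = 0.99,
                                  t_relax: float = 40.0,
                                  rtol: float = 1e-7) -> dict:
    """Classify the behaviour sequence purely from simulation.

    Sweeps the induction drive up over a uniform grid, carrying the state
    between levels, and records the steady phase at each level: no-N
    (B1-like), co-expression (B3) or N-only (B2).  When the carried
    trajectory fails to converge the level is only an oscillation phase if
    no stable steady state exists at all, which is checked by integrating a
    battery of generic initial conditions; a limit cycle that merely
    coexists with a stable state (so that the sweeping trajectory is
    captured by the cycle's basin) is recorded as that state's phase with a
    ``cycle_coexists`` annotation, since the behaviour sequences are
    defined by the succession of steady states and their gaps.  No
    closed-form branch information is used anywhere.
    """
    if params.mode != THRESHOLD:
        raise ValueError("the sweep classifier expects the threshold model")
    d_grid = np.linspace(d_max / n_grid, d_max, n_grid)
    state = np.array([params.P_max, 0.0, 0.0])
    scales = np.array([params.P_max, params.O_max, params.N_max])
    phases: list = []
    cycle_coexists: list = []
    undecided = False
    in_gap = False
    for d in d_grid:
        S = analytic.signal_at_drive(d, params.S_half)
        traj = integrate(params, S, init=state, t_end=t_relax, rtol=rtol,
                         n_samples=301)
        state = np.maximum(traj.final_state, 0.0)
        window = traj.t >= t_relax / 2.0
        amp = (np.ptp(traj.y[window], axis=0) / scales).max()
        if amp > 1e-5:
            if amp < 1e-3:
                # neither converged nor a full-blown cycle: flag, don't coerce
                undecided = True
                phases.append("undecided")
                continue
            if in_gap:
                # once a genuine gap has opened, the only steady state that
                # can (re)appear at larger S is B2, and its appearance no
                # longer changes the behaviour sequence: skip the probe
                phases.append("osc")
                continue
            steady = _probe_stable_state(params, S, t_relax, rtol)
            if steady is None:
                in_gap = True
                phases.append("osc")
                continue
            phase = _phase_of(steady, params)
            cycle_coexists.append((float(S), phase))
            phases.append(phase)
            if phase == "B2":
                break
            continue
        in_gap = False
        phase = _phase_of(state, params)
        phases.append(phase)
        if phase == "B2":
            break            # once attained, B2 persists for larger S
    saw_b3 = "B3" in phases
    saw_osc = "osc" in phases
    possibility = 1 + (1 if saw_b3 else 0) + (2 if saw_osc else 0)
    return {"possibility": possibility, "route": 2 if saw_b3 else 1,
            "phases": phases, "undecided": undecided,
            "cycle_coexists": cycle_coexists}
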