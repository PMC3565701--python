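"""Closed-form steady states and regime classification of the threshold model.

With Heaviside cross-repression on O and N the steady states can be written
down explicitly.  Writing ``d = d(S) = S / (S_half + S)`` and
``R(c; c_half, h) = 1 / (1 + (c/c_half)^h)`` the three branches are

    B1:  N = 0,          O = O_max d,   P = P_max R(O; O_crit, h2)
    B2:  O = 0,          N = N_max d,   P = P_max R(N; N_crit, h1)
    B3:  O = O_max d,    N = N_max d,   P = P_max D(N, O)

where ``D`` is the combined N/O repression of P (shared denominator by
default, a product of the two Hill terms as an option; on B1 and B2 the
forms coincide).

Each branch exists exactly where its value is self-consistent with the
Heaviside configuration it assumes, and where it exists it is a stable node
(the Jacobian eigenvalues are -k1, -k2, -k3).  As the signal rises the system
tracks B1 until that branch is lost, passing either directly to B2 (route 1)
or through the co-expression branch B3 (route 2); each hand-off happens with
either a bistable overlap (hysteresis) or a gap with no stable state, in
which case the circuit runs as a repressilator-style limit cycle.  That gives
the four possible behaviour sequences as S increases:

    1. route 1, no gap:  N off -> O off
    2. route 2, no gap:  N off -> co-expressed -> O off
    3. route 1, gap:     N off -> oscillate -> O off
    4. route 2, gap:     N off -> co-expressed -> oscillate -> O off

Critical signal levels are computed by inverting the Michaelis-Menten drive
at the analytically known threshold crossings (exact, since every branch
component is monotone in d).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .circuit import (
    GRADED,
    THRESHOLD,
    CircuitParameters,
    ExpressionState,
    _p_repression_factor,
    hill_repressor,
    induction_drive,
)

logger = logging.getLogger("acdcmotif")

__all__ = [
    "BRANCHES",
    "SteadyStateBranch",
    "ValidityReport",
    "RegimeLabel",
    "branch_value",
    "branch_exists",
    "existing_branches",
    "validity_conditions",
    "classify_route",
    "oscillation_gap",
    "critical_signals",
    "classify_regime",
    "signal_at_drive",
]

BRANCHES = ("B1", "B2", "B3")

#: behaviour sequences of the four possibilities, keyed by (route, has_gap)
POSSIBILITIES = {
    (1, False): 1,  # N off -> O off
    (2, False): 2,  # N off -> co-expressed -> O off
    (1, True): 3,   # N off -> oscillate -> O off
    (2, True): 4,   # N off -> co-expressed -> oscillate -> O off
}


def signal_at_drive(d: float, S_half: float = 1.0) -> float:
    """Invert the induction drive: the S with S / (S_half + S) = d."""
    if d < 0.0:
        raise ValueError(f"drive must be >= 0, got {d!r}")
    if d >= 1.0:
        return math.inf
    return S_half * d / (1.0 - d)


def _require_threshold(params: CircuitParameters) -> None:
    if params.mode != THRESHOLD:
        raise ValueError("analytic branches are defined for the threshold model; "
                         "use dynamics.find_fixed_points_graded for the graded variant")


# ---------------------------------------------------------------------------
# Branch values and existence
# ---------------------------------------------------------------------------

def branch_value(label: str, S: float, params: CircuitParameters) -> ExpressionState:
    """Closed-form steady state of branch ``label`` at signal level ``S``."""
    _require_threshold(params)
    if label not in BRANCHES:
        raise ValueError(f"unknown branch {label!r}; expected one of {BRANCHES}")
    d = induction_drive(S, params.S_half)
    if label == "B1":
        O = params.O_max * d
        P = params.P_max * hill_repressor(O, params.O_crit, params.h2)
        return ExpressionState(P=P, O=O, N=0.0)
    if label == "B2":
        N = params.N_max * d
        P = params.P_max * hill_repressor(N, params.N_crit, params.h1)
        return ExpressionState(P=P, O=0.0, N=N)
    O = params.O_max * d
    N = params.N_max * d
    P = params.P_max * _p_repression_factor(N, O, params)
    return ExpressionState(P=P, O=O, N=N)


def branch_exists(label: str, S: float, params: CircuitParameters) -> bool:
    """Self-consistency of a branch with its Heaviside configuration.

    H(0) = 1, so a repressor sitting exactly at its threshold still permits
    production: the "production off" requirements below are strict and the
    "production on" ones non-strict.  Boundary equalities are logged.
    """
    state = branch_value(label, S, params)
    p = params
    for name, value, level in (("P", state.P, p.P_crit1),
                               ("O", state.O, p.O_crit1),
                               ("N", state.N, p.N_crit1)):
        if value == level:
            logger.debug("branch %s at S=%g sits exactly on the %s=%g switching "
                         "surface; resolved with the H(0)=1 convention",
                         label, S, name, level)
    if label == "B1":
        # N production must be genuinely off at the B1 state
        return state.P > p.P_crit1 or state.O > p.O_crit1
    if label == "B2":
        # O production off (N above its switch) and N production on
        return state.N > p.N_crit1 and state.P <= p.P_crit1
    # B3: both productions on
    return (state.N <= p.N_crit1 and state.P <= p.P_crit1
            and state.O <= p.O_crit1)


def existing_branches(S: float, params: CircuitParameters) -> tuple:
    return tuple(b for b in BRANCHES if branch_exists(b, S, params))


@dataclass(frozen=True)
class SteadyStateBranch:
    """A labelled steady-state branch with its S-dependent value."""

    label: str
    params: CircuitParameters

    def value(self, S: float) -> ExpressionState:
        return branch_value(self.label, S, self.params)

    def exists(self, S: float) -> bool:
        return branch_exists(self.label, S, self.params)

    @property
    def eigenvalues(self) -> tuple:
        """Jacobian eigenvalues wherever the branch exists (a stable node)."""
        return (-self.params.k1, -self.params.k2, -self.params.k3)


# ---------------------------------------------------------------------------
# Parameter validity
# ---------------------------------------------------------------------------

@dataclass
class ValidityReport:
    """Pass/fail record of the tripartite-switch parameter constraints."""

    conditions: dict = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return all(c["passed"] for c in self.conditions.values())

    def failures(self) -> list:
        return [k for k, c in self.conditions.items() if not c["passed"]]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"condition": k, **c} for k, c in self.conditions.items()]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(self.conditions, indent=2)


def validity_conditions(params: CircuitParameters) -> ValidityReport:
    """The four constraints for a biologically sensible tripartite switch.

    (i)   P_max > P_crit1 : N stays silent before any signal;
    (ii)  P_max R(O_max; O_crit, h2) < P_crit1 : B1 is eventually lost;
    (iii) N_max > N_crit1 and P_max R(N_max; N_crit, h1) < P_crit1 : B2 is
          reachable and holds at high signal;
    (iv)  O_max <= O_crit1 : O never shuts N down, otherwise the sharp
          repression would keep N off at arbitrarily high signal.
    """
    _require_threshold(params)
    p = params
    report = ValidityReport()

    def add(key, passed, lhs, rhs, description):
        report.conditions[key] = {
            "passed": bool(passed), "lhs": float(lhs), "rhs": float(rhs),
            "description": description,
        }

    add("i_N_silent_at_zero_signal", p.P_max > p.P_crit1, p.P_max, p.P_crit1,
        "P_max > P_crit1")
    p_at_omax = p.P_max * hill_repressor(p.O_max, p.O_crit, p.h2)
    add("ii_B1_eventually_lost", p_at_omax < p.P_crit1, p_at_omax, p.P_crit1,
        "P_max R(O_max) < P_crit1")
    p_at_nmax = p.P_max * hill_repressor(p.N_max, p.N_crit, p.h1)
    add("iii_B2_attained", (p.N_max > p.N_crit1) and (p_at_nmax < p.P_crit1),
        min(p.N_max - p.N_crit1, p.P_crit1 - p_at_nmax), 0.0,
        "N_max > N_crit1 and P_max R(N_max) < P_crit1")
    add("iv_O_never_represses_N", p.O_max <= p.O_crit1, p.O_max, p.O_crit1,
        "O_max <= O_crit1")
    return report


# ---------------------------------------------------------------------------
# Critical drives / signals
# ---------------------------------------------------------------------------

def _o_dagger(p: CircuitParameters) -> float:
    """O level at which the B1 value of P falls to P_crit1."""
    return p.O_crit * (p.P_max / p.P_crit1 - 1.0) ** (1.0 / p.h2)


def _n_dagger(p: CircuitParameters) -> float:
    """N level at which the B2 value of P falls to P_crit1."""
    return p.N_crit * (p.P_max / p.P_crit1 - 1.0) ** (1.0 / p.h1)


def _d_b3_gain(p: CircuitParameters) -> float:
    """Smallest drive at which the B3 value of P reaches P_crit1 (bisection)."""

    def f(d):
        s = branch_value("B3", signal_at_drive(d, p.S_half), p)
        return s.P - p.P_crit1

    lo, hi = 0.0, 1.0 - 1e-12
    if f(hi) > 0.0:   # P never drops to P_crit1 (validity (ii) fails)
        return math.inf
    return brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)


def critical_signals(params: CircuitParameters) -> dict:
    """Drive and signal levels of every branch hand-off.

    Keys: ``d_B1_loss``/``S_B1_loss`` (B1 ceases), ``d_B2_gain``/``S_B2_gain``
    (B2 becomes self-consistent), ``d_B3_loss``/``S_B3_loss`` (N crosses
    N_crit1, route 2 only in practice) and ``d_B3_gain``/``S_B3_gain``
    (B3 becomes self-consistent).
    """
    _require_threshold(params)
    p = params
    d1 = _o_dagger(p) / p.O_max
    d2 = max(p.N_crit1, _n_dagger(p)) / p.N_max
    d3 = p.N_crit1 / p.N_max
    db3 = max(_d_b3_gain(p), 0.0)
    out = {"d_B1_loss": d1, "d_B2_gain": d2, "d_B3_loss": d3, "d_B3_gain": db3}
    return {**out, **{"S" + k[1:]: signal_at_drive(min(v, 1.0), p.S_half)
                      if v <= 1.0 else math.inf
                      for k, v in out.items()}}


# ---------------------------------------------------------------------------
# Routes, gaps, regimes
# ---------------------------------------------------------------------------

def classify_route(params: CircuitParameters) -> str:
    """Which branch sequence the adiabatic up-sweep takes: route1 or route2.

    Route 2 (through the co-expression branch B3) is taken iff B3 exists at
    the signal where B1 is lost, i.e. N_max d(S1) < N_crit1.
    """
    _require_threshold(params)
    if not validity_conditions(params).all_pass:
        return "invalid"
    p = params
    crit = critical_signals(p)
    n_at_loss = p.N_max * crit["d_B1_loss"]
    if n_at_loss == p.N_crit1:
        logger.debug("N sits exactly at N_crit1 when B1 is lost; H(0)=1 keeps "
                     "O production on, classifying as route1")
    return "route2" if n_at_loss < p.N_crit1 else "route1"


def oscillation_gap(params: CircuitParameters):
    """Open S-interval with no stable steady state, or None.

    On route 1 a gap opens iff B2 only becomes self-consistent after B1 has
    been lost (for h1 = h2 this reduces to N_max/N_crit < O_max/O_crit); on
    route 2 iff the co-expression branch loses N-on-O repression before B2
    can hold P down, i.e. P_max/P_crit1 > 1 + (N_crit1/N_crit)^h1.  Inside
    the gap the circuit cycles N -> P -> O.
    """
    route = classify_route(params)
    if route == "invalid":
        return None
    p = params
    crit = critical_signals(p)
    if route == "route1":
        if crit["d_B2_gain"] > crit["d_B1_loss"]:
            return (crit["S_B1_loss"], crit["S_B2_gain"])
        return None
    # route 2: the gap starts where N crosses N_crit1 (B3 lost)
    if p.P_max / p.P_crit1 > 1.0 + (p.N_crit1 / p.N_crit) ** p.h1:
        return (crit["S_B3_loss"], crit["S_B2_gain"])
    return None


@dataclass
class RegimeLabel:
    """Route, behaviour possibility and annotated transition signals."""

    route: object            # 1, 2 or "invalid"
    possibility: object      # 1-4, or None when invalid
    transitions: dict = field(default_factory=dict)
    bistable_overlap: tuple | None = None
    oscillation_interval: tuple | None = None
    valid: bool = True
    failures: list = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return {
            1: "N off -> O off",
            2: "N off -> co-expressed -> O off",
            3: "N off -> oscillate -> O off",
            4: "N off -> co-expressed -> oscillate -> O off",
        }.get(self.possibility, "invalid parameters")

    def to_dict(self) -> dict:
        return {
            "route": self.route,
            "possibility": self.possibility,
            "sequence": self.sequence,
            "transitions": dict(self.transitions),
            "bistable_overlap": self.bistable_overlap,
            "oscillation_interval": self.oscillation_interval,
            "valid": self.valid,
            "failures": list(self.failures),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [{"quantity": k, "S": v} for k, v in self.transitions.items()]
        return pd.DataFrame(rows)


def classify_regime(params: CircuitParameters) -> RegimeLabel:
    """Combine route and gap analysis into one of the four possibilities."""
    _require_threshold(params)
    report = validity_conditions(params)
    if not report.all_pass:
        return RegimeLabel(route="invalid", possibility=None, valid=False,
                           failures=report.failures())
    p = params
    crit = critical_signals(p)
    route = classify_route(params)
    route_no = 1 if route == "route1" else 2
    gap = oscillation_gap(params)
    possibility = POSSIBILITIES[(route_no, gap is not None)]

    transitions = {"S_B1_loss": crit["S_B1_loss"], "S_B2_gain": crit["S_B2_gain"]}
    overlap = None
    if route_no == 1:
        if gap is None and crit["d_B2_gain"] < crit["d_B1_loss"]:
            overlap = (crit["S_B2_gain"], crit["S_B1_loss"])
    else:
        transitions["S_B3_gain"] = crit["S_B3_gain"]
        transitions["S_B3_loss"] = crit["S_B3_loss"]
        # hysteresis around N activation: B1 coexists with B3
        if crit["d_B3_gain"] < crit["d_B1_loss"]:
            overlap = (crit["S_B3_gain"], crit["S_B1_loss"])
    return RegimeLabel(route=route_no, possibility=possibility,
                       transitions=transitions, bistable_overlap=overlap,
                       oscillation_interval=gap, valid=True)
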