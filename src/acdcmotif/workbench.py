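"""Presets, config I/O, parameter sampling and the regime census.

The shipped presets are the complete parameter sets printed in the figure
captions: the fig2/fig3 pairs differ only in ``N_crit`` (which side of the
oscillation condition N_max/N_crit vs O_max/O_crit they fall on, and the
route-2 gap inequality for fig3), and the fig4/fig5 presets are the fig2
values rerun in graded mode with h3 = h4 = h5 set to 2 or 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import analytic, dynamics
from .circuit import GRADED, THRESHOLD, CircuitParameters

logger = logging.getLogger("acdcmotif")

__all__ = [
    "PRESETS",
    "CensusResult",
    "load_preset",
    "preset_names",
    "save_config",
    "load_config",
    "sample_parameters",
    "run_census",
    "setup_run_log",
]

_CONFIG_KEYS = ("alpha", "beta", "gamma", "k1", "k2", "k3", "N_crit", "O_crit",
                "h1", "h2", "P_crit1", "O_crit1", "N_crit1", "h3", "h4", "h5",
                "S_half", "mode")

_FIG2_BASE = dict(alpha=5.0, beta=5.0, gamma=5.0, h1=2.0, h2=2.0, O_crit=1.0,
                  P_crit1=0.5, O_crit1=5.0, N_crit1=2.0,
                  k1=1.0, k2=1.0, k3=1.0, S_half=1.0)
_FIG3_BASE = dict(alpha=3.0, beta=5.0, gamma=4.0, h1=2.0, h2=2.0, O_crit=1.0,
                  P_crit1=1.0, O_crit1=5.0, N_crit1=2.0,
                  k1=1.0, k2=1.0, k3=1.0, S_half=1.0)

#: name -> (constants, provenance note)
PRESETS: dict = {
    "fig2a": ({**_FIG2_BASE, "N_crit": 0.9, "mode": THRESHOLD},
              "sharp-switch threshold preset (direct B1 -> B2 with overlap)"),
    "fig2b": ({**_FIG2_BASE, "N_crit": 1.1, "mode": THRESHOLD},
              "oscillating threshold preset (gap between B1 and B2)"),
    "fig3a": ({**_FIG3_BASE, "N_crit": 1.0, "mode": THRESHOLD},
              "sharp-switch threshold preset through co-expression "
              "(B1 -> B3 -> B2)"),
    "fig3b": ({**_FIG3_BASE, "N_crit": 2.0, "mode": THRESHOLD},
              "oscillating threshold preset through co-expression"),
    "fig4a": ({**_FIG2_BASE, "N_crit": 0.9, "mode": GRADED,
               "h3": 2.0, "h4": 2.0, "h5": 2.0},
              "graded variant of fig2a with soft repression (h = 2)"),
    "fig4b": ({**_FIG2_BASE, "N_crit": 1.1, "mode": GRADED,
               "h3": 2.0, "h4": 2.0, "h5": 2.0},
              "graded variant of fig2b with soft repression (h = 2); "
              "no oscillatory window"),
    "fig5a": ({**_FIG2_BASE, "N_crit": 0.9, "mode": GRADED,
               "h3": 5.0, "h4": 5.0, "h5": 5.0},
              "graded variant of fig2a with sharper repression (h = 5); "
              "oscillations appear"),
    "fig5b": ({**_FIG2_BASE, "N_crit": 1.1, "mode": GRADED,
               "h3": 5.0, "h4": 5.0, "h5": 5.0},
              "graded variant of fig2b with sharper repression (h = 5); "
              "widened oscillatory window"),
}


def preset_names() -> tuple:
    return tuple(PRESETS)


def load_preset(name: str) -> CircuitParameters:
    """Load a shipped parameter preset by name."""
    try:
        constants, _ = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{', '.join(preset_names())}") from None
    return CircuitParameters(**constants)


# ---------------------------------------------------------------------------
# Config files (flat key: value)
# ---------------------------------------------------------------------------

def save_config(params: CircuitParameters, path) -> None:
    values = params.to_dict()
    payload = {key: values[key] for key in _CONFIG_KEYS}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> CircuitParameters:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ValueError(f"config {path!r} must be a flat key: value mapping")
    unknown = set(payload) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = set(_CONFIG_KEYS) - set(payload)
    if missing:
        raise ValueError(f"missing config keys: {sorted(missing)}")
    return CircuitParameters(**payload)


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

#: log-uniform sampling ranges; they bracket every shipped preset
DEFAULT_RANGES = {"rate": (0.1, 10.0), "threshold": (0.1, 10.0)}
DEFAULT_HILL_CHOICES = (1, 2, 3, 4, 5)


def sample_parameters(n: int, seed: int, *, ranges: dict | None = None,
                      hill_choices=DEFAULT_HILL_CHOICES,
                      max_draws: int = 4_000_000) -> list:
    """Draw random parameter sets passing all four validity constraints.

    Rates and thresholds are log-uniform, the shared Hill coefficient
    h1 = h2 is drawn from ``hill_choices`` and decay constants are fixed at
    1 (as in every printed preset, so time is measured in protein-lifetime
    units).  Rejection sampling is vectorised; the draw budget guards
    against pathological ranges.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    rng = np.random.default_rng(seed)
    lo_r, hi_r = ranges["rate"]
    lo_t, hi_t = ranges["threshold"]

    accepted: list[CircuitParameters] = []
    drawn = rejected = 0
    batch = max(2048, 8 * n)
    while len(accepted) < n:
        if drawn >= max_draws:
            raise RuntimeError(
                f"failed to find {n} valid parameter sets within {max_draws} "
                f"draws ({len(accepted)} found, {rejected} rejected); "
                f"widen the ranges or relax the constraints")
        m = min(batch, max_draws - drawn)
        drawn += m
        logu = lambda lo, hi, size: np.exp(rng.uniform(np.log(lo), np.log(hi), size))
        alpha, beta, gamma = (logu(lo_r, hi_r, m) for _ in range(3))
        N_crit, O_crit, P_crit1, N_crit1, O_crit1 = (
            logu(lo_t, hi_t, m) for _ in range(5))
        h = rng.choice(hill_choices, size=m).astype(float)
        # decay constants are 1, so P_max = alpha etc.
        ok = (
            (alpha > P_crit1)
            & (alpha / (1.0 + (beta / O_crit) ** h) < P_crit1)
            & (gamma > N_crit1)
            & (alpha / (1.0 + (gamma / N_crit) ** h) < P_crit1)
            & (beta <= O_crit1)
        )
        rejected += int(m - ok.sum())
        for i in np.flatnonzero(ok):
            accepted.append(CircuitParameters(
                alpha=float(alpha[i]), beta=float(beta[i]), gamma=float(gamma[i]),
                N_crit=float(N_crit[i]), O_crit=float(O_crit[i]),
                h1=float(h[i]), h2=float(h[i]),
                P_crit1=float(P_crit1[i]), O_crit1=float(O_crit1[i]),
                N_crit1=float(N_crit1[i]), mode=THRESHOLD))
            if len(accepted) == n:
                break
    logger.info("parameter sampler: %d accepted, %d rejected (%d drawn)",
                len(accepted), rejected, drawn)
    return accepted


# ---------------------------------------------------------------------------
# Regime census
# ---------------------------------------------------------------------------

@dataclass
class CensusResult:
    """Analytic vs simulated regime label per sampled parameter set."""

    frame: pd.DataFrame
    agreement: float
    inventory: tuple
    n_undecided: int
    exclusivity_ok: bool

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def run_census(n: int = 500, seed: int = 0, *, ranges: dict | None = None,
               n_grid: int = 81, t_relax: float = 40.0) -> CensusResult:
    """Classify sampled valid parameter sets twice and compare.

    Each draw is labelled by the closed-form classifier and, independently,
    by an adiabatic simulation sweep that sees only trajectories.  The
    result records the agreement rate over decided draws, the inventory of
    distinct analytic regimes observed and whether the B2/B3 exclusivity
    held at every probed signal level.
    """
    params_list = sample_parameters(n, seed, ranges=ranges)
    d_probe = np.linspace(0.02, 0.98, 33)
    rows = []
    exclusivity_ok = True
    for i, params in enumerate(params_list):
        label = analytic.classify_regime(params)
        sim = dynamics.classify_regime_by_simulation(
            params, n_grid=n_grid, t_relax=t_relax)
        for d in d_probe:
            S = analytic.signal_at_drive(d, params.S_half)
            if (analytic.branch_exists("B2", S, params)
                    and analytic.branch_exists("B3", S, params)):
                exclusivity_ok = False
        rows.append({
            "draw": i,
            "possibility_analytic": label.possibility,
            "route_analytic": label.route,
            "possibility_sim": sim["possibility"],
            "route_sim": sim["route"],
            "undecided": sim["undecided"],
            "agree": (not sim["undecided"]
                      and label.possibility == sim["possibility"]),
        })
    frame = pd.DataFrame(rows)
    decided = frame.loc[~frame.undecided]
    agreement = float(decided.agree.mean()) if len(decided) else float("nan")
    inventory = tuple(sorted(frame.possibility_analytic.unique()))
    n_undecided = int(frame.undecided.sum())
    if n_undecided:
        logger.warning("census: %d undecided simulation sweeps excluded from "
                       "the agreement denominator", n_undecided)
    return CensusResult(frame=frame, agreement=agreement, inventory=inventory,
                        n_undecided=n_undecided, exclusivity_ok=exclusivity_ok)


# ---------------------------------------------------------------------------
# Run logging
# ---------------------------------------------------------------------------

def setup_run_log(path, level: str = "INFO") -> logging.Handler:
    """Attach a run-log file recording parameters, seeds and solver events."""
    handler = logging.FileHandler(path)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper()))
    return handler
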