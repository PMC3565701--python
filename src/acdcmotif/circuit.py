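"""Cross-repression circuit model for ventral neural tube patterning.

The dynamical system tracks the concentrations of the transcription factors
Pax6 (``P``), Olig2 (``O``) and Nkx2.2 (``N``) in a single cell exposed to a
Sonic hedgehog signal, quantified by the downstream Gli transcriptional
activity ``S``.  P is produced constitutively and repressed by N and O through
declining Hill functions; O and N are induced by S with Michaelis-Menten
kinetics and repressed through all-or-nothing threshold (Heaviside) switches.
In the ``graded`` variant the three threshold repressions are replaced by Hill
functions with coefficients ``h3`` (P on N), ``h4`` (N on O) and ``h5``
(O on N).

The right-hand side is

    dP/dt = alpha * D(N, O)                              - k1 * P
    dO/dt = beta  * d(S) * rep_{N->O}(N)                 - k2 * O
    dN/dt = gamma * d(S) * rep_{P->N}(P) * rep_{O->N}(O) - k3 * N

with combined repression ``D(N, O) = 1 / (1 + (N/N_crit)^h1 +
(O/O_crit)^h2)`` by default (a product of two independent declining Hill
functions as an option; the forms agree whenever one repressor is absent),
drive ``d(S) = S / (S_half + S)`` and, in threshold mode,
``rep_{X->Y}(X) = H(X_crit - X)`` with ``H(0) = 1``.

The module also provides a builder for generalized n-gene stripe circuits
(two-gene switch, the symmetric three-gene alternative, the AC-DC motif and
its four-gene extension).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields, replace
from functools import cached_property
from typing import Sequence

import numpy as np

logger = logging.getLogger("acdcmotif")

__all__ = [
    "THRESHOLD",
    "GRADED",
    "CircuitParameters",
    "ExpressionState",
    "Repression",
    "MultiGeneCircuit",
    "heaviside",
    "hill_repressor",
    "induction_drive",
    "rhs",
    "build_multigene_circuit",
    "acdc_from_parameters",
    "fig7bi_from_parameters",
    "fig8_demo_circuit",
]

THRESHOLD = "threshold"
GRADED = "graded"

_GENE_NAMES = ("P", "O", "N", "Q")


# ---------------------------------------------------------------------------
# Elementary regulatory functions
# ---------------------------------------------------------------------------

def heaviside(x: float) -> int:
    """Unit step with the on-at-threshold convention: H(x) = 1 iff x >= 0."""
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"heaviside requires a finite argument, got {x!r}")
    return 1 if x >= 0.0 else 0


def hill_repressor(c: float, c_half: float, h: float) -> float:
    """Declining Hill function 1 / (1 + (c / c_half)**h).

    ``c_half`` is the repressor concentration at which the target's
    production is half-maximal; ``h`` sets the sharpness.  Monotone
    decreasing in ``c`` with value 1 at ``c = 0``.
    """
    c = float(c)
    if c < 0.0 or not math.isfinite(c):
        raise ValueError(f"repressor concentration must be finite and >= 0, got {c!r}")
    if c_half <= 0.0:
        raise ValueError(f"half-maximal constant must be > 0, got {c_half!r}")
    if h < 1.0:
        raise ValueError(f"Hill coefficient must be >= 1, got {h!r}")
    if c == 0.0:
        return 1.0
    # work in log space so very sharp coefficients (h ~ 200) cannot overflow
    t = h * math.log(c / c_half)
    if t > 700.0:
        return 0.0
    if t < -700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(t))


def induction_drive(S: float, S_half: float = 1.0) -> float:
    """Michaelis-Menten induction drive d(S) = S / (S_half + S) in [0, 1)."""
    S = float(S)
    if S < 0.0 or math.isnan(S):
        raise ValueError(f"signal level must be >= 0, got {S!r}")
    if S_half <= 0.0:
        raise ValueError(f"S_half must be > 0, got {S_half!r}")
    if math.isinf(S):
        return 1.0
    return S / (S_half + S)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircuitParameters:
    """All rate, threshold and Hill constants of the three-gene circuit.

    Rates are in concentration/time, decay constants in 1/time, thresholds
    and half-maximal constants in concentration units; the model is
    dimensionless and the presets set all decay constants to 1 so that time
    is measured in protein half-life units (up to ln 2).
    """

    alpha: float   # maximal production rate of P
    beta: float    # maximal production rate of O
    gamma: float   # maximal production rate of N
    N_crit: float  # N concentration half-repressing P
    O_crit: float  # O concentration half-repressing P
    h1: float      # Hill coefficient of N-on-P repression
    h2: float      # Hill coefficient of O-on-P repression
    P_crit1: float  # P level switching off N production
    O_crit1: float  # O level switching off N production
    N_crit1: float  # N level switching off O production
    k1: float = 1.0
    k2: float = 1.0
    k3: float = 1.0
    h3: float = 2.0  # graded variant: P-on-N repression
    h4: float = 2.0  # graded variant: N-on-O repression
    h5: float = 2.0  # graded variant: O-on-N repression
    S_half: float = 1.0  # shared half-maximal signal of O and N induction
    mode: str = THRESHOLD
    p_repression: str = "additive"  # "additive" (default) or "product"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "k1", "k2", "k3",
                     "N_crit", "O_crit", "P_crit1", "O_crit1", "N_crit1",
                     "S_half"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0.0):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        for name in ("h1", "h2", "h3", "h4", "h5"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 1.0):
                raise ValueError(f"{name} must be >= 1, got {value!r}")
        if self.mode not in (THRESHOLD, GRADED):
            raise ValueError(f"mode must be {THRESHOLD!r} or {GRADED!r}, got {self.mode!r}")
        if self.p_repression not in ("product", "additive"):
            raise ValueError(
                f"p_repression must be 'product' or 'additive', got {self.p_repression!r}")

    # derived expression maxima ------------------------------------------------
    @property
    def P_max(self) -> float:
        return self.alpha / self.k1

    @property
    def O_max(self) -> float:
        return self.beta / self.k2

    @property
    def N_max(self) -> float:
        return self.gamma / self.k3

    def drive(self, S: float) -> float:
        return induction_drive(S, self.S_half)

    def with_mode(self, mode: str, **overrides) -> "CircuitParameters":
        return replace(self, mode=mode, **overrides)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ExpressionState:
    """Nonnegative concentrations of the three transcription factors."""

    P: float
    O: float
    N: float

    def __post_init__(self) -> None:
        for name in ("P", "O", "N"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0.0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "ExpressionState":
        x = np.asarray(x, dtype=float)
        # forgive tiny negative round-off from the integrator
        x = np.where((x < 0.0) & (x > -1e-9), 0.0, x)
        return cls(float(x[0]), float(x[1]), float(x[2]))

    def to_array(self) -> np.ndarray:
        return np.array([self.P, self.O, self.N], dtype=float)

    def __iter__(self):
        return iter((self.P, self.O, self.N))


# ---------------------------------------------------------------------------
# Right-hand side of the three-gene model
# ---------------------------------------------------------------------------

def _p_repression_factor(N: float, O: float, p: CircuitParameters) -> float:
    """Combined repression of P production by N and O.

    The default shares one denominator, 1 / (1 + (N/N_crit)^h1 +
    (O/O_crit)^h2), as for competing repressors at a single regulatory
    site; the "product" option multiplies two independent declining Hill
    functions instead.  The two coincide whenever either repressor is
    absent (so on the B1 and B2 branches) and differ only during
    co-expression and oscillation, where the shared-denominator form is
    the one that matches the printed graded-model behaviour.
    """
    if p.p_repression == "product":
        return (hill_repressor(N, p.N_crit, p.h1)
                * hill_repressor(O, p.O_crit, p.h2))
    return 1.0 / (1.0 + (N / p.N_crit) ** p.h1 + (O / p.O_crit) ** p.h2)


def _rhs(x: np.ndarray, S: float, p: CircuitParameters) -> np.ndarray:
    """Fast RHS on a raw (P, O, N) array; no input validation."""
    P, O, N = float(x[0]), float(x[1]), float(x[2])
    P = max(P, 0.0)
    O = max(O, 0.0)
    N = max(N, 0.0)
    d = induction_drive(S, p.S_half)
    if p.mode == THRESHOLD:
        rep_no = 1.0 if N <= p.N_crit1 else 0.0      # H(N_crit1 - N)
        rep_pn = 1.0 if P <= p.P_crit1 else 0.0      # H(P_crit1 - P)
        rep_on = 1.0 if O <= p.O_crit1 else 0.0      # H(O_crit1 - O)
    else:
        rep_no = hill_repressor(N, p.N_crit1, p.h4)
        rep_pn = hill_repressor(P, p.P_crit1, p.h3)
        rep_on = hill_repressor(O, p.O_crit1, p.h5)
    dP = p.alpha * _p_repression_factor(N, O, p) - p.k1 * P
    dO = p.beta * d * rep_no - p.k2 * O
    dN = p.gamma * d * rep_pn * rep_on - p.k3 * N
    return np.array([dP, dO, dN])


def _rhs_sigma(x: np.ndarray, S: float, p: CircuitParameters,
               sigma: tuple) -> np.ndarray:
    """RHS with the three Heaviside switch states frozen.

    ``sigma = (bP, bO, bN)`` are the values of H(P_crit1 - P),
    H(O_crit1 - O) and H(N_crit1 - N); freezing them makes the vector field
    smooth inside a switching region, which is how the event-aware
    integrator steps between threshold crossings.
    """
    P, O, N = float(x[0]), float(x[1]), float(x[2])
    bP, bO, bN = sigma
    d = induction_drive(S, p.S_half)
    dP = p.alpha * _p_repression_factor(max(N, 0.0), max(O, 0.0), p) - p.k1 * P
    dO = p.beta * d * bN - p.k2 * O
    dN = p.gamma * d * bP * bO - p.k3 * N
    return np.array([dP, dO, dN])


def _threshold_switches(p: CircuitParameters) -> tuple:
    """Switching surfaces of the threshold model as (variable index, level)."""
    return ((0, p.P_crit1), (1, p.O_crit1), (2, p.N_crit1))


def _sigma_of(x: np.ndarray, p: CircuitParameters) -> tuple:
    """Heaviside configuration at a state (H(0)=1: at-threshold means on)."""
    return tuple(1.0 if x[idx] <= level else 0.0
                 for idx, level in _threshold_switches(p))


def rhs(state, S: float, params: CircuitParameters) -> np.ndarray:
    """Time derivatives (dP/dt, dO/dt, dN/dt) at a state and signal level.

    ``state`` may be an :class:`ExpressionState` or any length-3 sequence of
    nonnegative concentrations.
    """
    if isinstance(state, ExpressionState):
        x = state.to_array()
    else:
        x = np.asarray(state, dtype=float)
        if x.shape != (3,):
            raise ValueError(f"state must have 3 components, got shape {x.shape}")
        if not np.all(np.isfinite(x)) or np.any(x < -1e-9):
            raise ValueError(f"state must be finite and nonnegative, got {x!r}")
    if not (math.isfinite(S) and S >= 0.0):
        raise ValueError(f"signal level must be finite and >= 0, got {S!r}")
    return _rhs(x, S, params)


# ---------------------------------------------------------------------------
# Generalized n-gene stripe circuits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Repression:
    """A repressive edge: ``source`` shuts down production of ``target``.

    ``form`` is "threshold" (Heaviside at ``constant``) or "graded"
    (declining Hill with half-max ``constant`` and coefficient ``hill``).
    """

    source: int
    target: int
    form: str
    constant: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in (THRESHOLD, GRADED):
            raise ValueError(f"unknown repression form {self.form!r}")
        if self.constant <= 0.0:
            raise ValueError("repression constant must be > 0")
        if self.form == GRADED and self.hill < 1.0:
            raise ValueError("Hill coefficient must be >= 1")
        if self.source == self.target:
            raise ValueError("self-repression is not part of this circuit family")


@dataclass(frozen=True)
class MultiGeneCircuit:
    """An ordered gene list with signal induction and repressive edges.

    Gene 0 is constitutive; genes 1..n-1 are induced by the signal through
    the shared Michaelis-Menten drive.  The canonical build (``topology``
    "canonical") has every gene repressing all earlier ones, with gene 0
    additionally repressing genes 2..n-1; repressions acting on gene 0 are
    graded and all others are thresholds, so n = 3 reproduces the AC-DC
    motif and n = 2 the two-gene switch.
    """

    names: tuple
    production: tuple
    decay: tuple
    induced: tuple
    repressions: tuple
    S_half: float = 1.0
    topology: str = "canonical"
    combine: str = "additive"   # how several graded repressors on one
    #                             target combine: shared denominator
    #                             ("additive") or product of Hill terms

    def __post_init__(self) -> None:
        n = len(self.names)
        if n < 2:
            raise ValueError("a stripe circuit needs at least 2 genes")
        for seq_name in ("production", "decay", "induced"):
            if len(getattr(self, seq_name)) != n:
                raise ValueError(f"{seq_name} must have one entry per gene")
        if any(r <= 0 for r in self.production) or any(k <= 0 for k in self.decay):
            raise ValueError("production and decay rates must be > 0")
        for e in self.repressions:
            if not (0 <= e.source < n and 0 <= e.target < n):
                raise ValueError(f"edge {e} references an unknown gene")
        if self.combine not in ("additive", "product"):
            raise ValueError(f"combine must be 'additive' or 'product', "
                             f"got {self.combine!r}")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def gene_max(self) -> np.ndarray:
        """Maximal attainable expression level of each gene (rate / decay)."""
        return np.asarray(self.production) / np.asarray(self.decay)

    def initial_state(self) -> np.ndarray:
        """Pre-signal steady state: gene 0 at its maximum, the rest at zero."""
        x0 = np.zeros(self.n)
        x0[0] = self.gene_max[0]
        return x0

    def edge_set(self) -> set:
        """Edges as human-readable (source, target) name pairs."""
        return {(self.names[e.source], self.names[e.target]) for e in self.repressions}

    # --- switching structure ------------------------------------------------
    @cached_property
    def threshold_switches(self) -> tuple:
        """Distinct (source index, level) switching surfaces."""
        seen: list = []
        for e in self.repressions:
            if e.form == THRESHOLD and (e.source, e.constant) not in seen:
                seen.append((e.source, e.constant))
        return tuple(seen)

    @cached_property
    def _switch_index(self) -> dict:
        return {key: i for i, key in enumerate(self.threshold_switches)}

    def sigma_of(self, x: np.ndarray) -> tuple:
        return tuple(1.0 if x[src] <= level else 0.0
                     for src, level in self.threshold_switches)

    def _production_factors(self, x: np.ndarray, sigma=None) -> np.ndarray:
        factors = np.ones(self.n)
        denom = np.ones(self.n)
        for e in self.repressions:
            if e.form == GRADED:
                c = max(float(x[e.source]), 0.0)
                if self.combine == "additive":
                    if c > 0.0:
                        t = e.hill * math.log(c / e.constant)
                        denom[e.target] += math.exp(min(t, 700.0))
                else:
                    factors[e.target] *= hill_repressor(c, e.constant, e.hill)
            else:
                if sigma is None:
                    bit = 1.0 if x[e.source] <= e.constant else 0.0
                else:
                    bit = sigma[self._switch_index[(e.source, e.constant)]]
                factors[e.target] *= bit
        return factors / denom

    def rhs(self, x: np.ndarray, S: float) -> np.ndarray:
        """Discontinuous RHS, evaluating threshold switches from the state."""
        return self.rhs_sigma(x, S, None)

    def rhs_sigma(self, x: np.ndarray, S: float, sigma) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        d = induction_drive(S, self.S_half)
        drive = np.where(np.asarray(self.induced), d, 1.0)
        factors = self._production_factors(x, sigma)
        return (np.asarray(self.production) * drive * factors
                - np.asarray(self.decay) * np.maximum(x, 0.0))


_TOPOLOGIES = ("canonical", "fig7a", "fig7bi")


def build_multigene_circuit(
    n: int = 3,
    topology: str = "canonical",
    *,
    production: Sequence[float] | None = None,
    decay: Sequence[float] | None = None,
    graded_half: dict | None = None,
    graded_hill: dict | None = None,
    thresholds: dict | None = None,
    S_half: float = 1.0,
    names: Sequence[str] | None = None,
    combine: str = "additive",
) -> MultiGeneCircuit:
    """Construct a generalized stripe circuit.

    Parameters
    ----------
    n
        Number of genes (>= 2).
    topology
        "canonical" (the AC-DC family: gene i represses all earlier genes,
        gene 0 additionally represses genes 2..; the four-gene build adds
        the highest-signal gene Q), "fig7a" (two-gene switch, equivalent to
        canonical n = 2) or "fig7bi" (the symmetric alternative: the signal
        induces O and N which mutually repress each other through thresholds
        and both repress the constitutive gene, with no repression of N by
        the constitutive gene).
    graded_half, graded_hill
        Per-source half-max constants / Hill coefficients for the graded
        repressions acting on gene 0 (defaults 1.0 and 2.0).
    thresholds
        Mapping (source, target) -> switching level for threshold edges
        (default 2.0 between induced genes, 0.5 for gene-0 thresholds).
    """
    if n < 2:
        raise ValueError(f"a stripe circuit needs at least 2 genes, got n={n}")
    if topology not in _TOPOLOGIES:
        raise ValueError(
            f"unknown topology {topology!r}; available: {', '.join(_TOPOLOGIES)}")
    if topology == "fig7a" and n != 2:
        raise ValueError("topology 'fig7a' is the two-gene circuit (n = 2)")
    if topology == "fig7bi" and n != 3:
        raise ValueError("topology 'fig7bi' is a three-gene circuit (n = 3)")

    if names is None:
        names = tuple(_GENE_NAMES[i] if i < len(_GENE_NAMES) else f"G{i}"
                      for i in range(n))
    production = tuple(production) if production is not None else (5.0,) * n
    decay = tuple(decay) if decay is not None else (1.0,) * n
    graded_half = dict(graded_half or {})
    graded_hill = dict(graded_hill or {})
    thresholds = dict(thresholds or {})

    def graded_edge(src: int, tgt: int) -> Repression:
        return Repression(src, tgt, GRADED,
                          graded_half.get(src, 1.0), graded_hill.get(src, 2.0))

    def threshold_edge(src: int, tgt: int) -> Repression:
        default = 0.5 if src == 0 else 2.0
        return Repression(src, tgt, THRESHOLD, thresholds.get((src, tgt), default))

    edges: list[Repression] = []
    if topology == "fig7bi":
        induced = (False, True, True)
        edges = [graded_edge(1, 0), graded_edge(2, 0),
                 threshold_edge(1, 2), threshold_edge(2, 1)]
    else:
        induced = (False,) + (True,) * (n - 1)
        for i in range(1, n):
            for j in range(i):
                edges.append(graded_edge(i, j) if j == 0 else threshold_edge(i, j))
        for i in range(2, n):
            edges.append(threshold_edge(0, i))

    return MultiGeneCircuit(names=tuple(names), production=production,
                            decay=decay, induced=induced,
                            repressions=tuple(edges), S_half=S_half,
                            topology=topology, combine=combine)


def acdc_from_parameters(params: CircuitParameters) -> MultiGeneCircuit:
    """The AC-DC motif (no O-on-N repression) built from circuit parameters.

    Function-value equal to :func:`rhs` with ``O_crit1`` sent to infinity;
    in graded mode the non-gene-0 edges carry the h3/h4 coefficients.
    """
    graded_edges_everywhere = params.mode == GRADED
    edges = [
        Repression(1, 0, GRADED, params.O_crit, params.h2),   # O -| P
        Repression(2, 0, GRADED, params.N_crit, params.h1),   # N -| P
        (Repression(2, 1, GRADED, params.N_crit1, params.h4)
         if graded_edges_everywhere
         else Repression(2, 1, THRESHOLD, params.N_crit1)),   # N -| O
        (Repression(0, 2, GRADED, params.P_crit1, params.h3)
         if graded_edges_everywhere
         else Repression(0, 2, THRESHOLD, params.P_crit1)),   # P -| N
    ]
    return MultiGeneCircuit(
        names=("P", "O", "N"),
        production=(params.alpha, params.beta, params.gamma),
        decay=(params.k1, params.k2, params.k3),
        induced=(False, True, True),
        repressions=tuple(edges),
        S_half=params.S_half,
        topology="canonical",
        combine=params.p_repression,
    )


def fig7bi_from_parameters(params: CircuitParameters,
                           o_threshold: float) -> MultiGeneCircuit:
    """The symmetric three-gene alternative topology.

    The signal induces both O and N; they mutually repress each other through
    thresholds (N at ``N_crit1``, O at ``o_threshold``) and both repress the
    constitutive gene through the graded constants; the constitutive gene
    does not repress N.
    """
    return build_multigene_circuit(
        3, "fig7bi",
        production=(params.alpha, params.beta, params.gamma),
        decay=(params.k1, params.k2, params.k3),
        graded_half={1: params.O_crit, 2: params.N_crit},
        graded_hill={1: params.h2, 2: params.h1},
        thresholds={(2, 1): params.N_crit1, (1, 2): o_threshold},
        S_half=params.S_half,
        combine=params.p_repression,
    )


def fig8_demo_circuit() -> MultiGeneCircuit:
    """Four-gene demonstration circuit producing four ordered stripes.

    Thresholds are staggered so that consecutive transition signal levels
    are separated by at least a factor of two: the O domain opens near
    S ~ 0.7, N takes over near S = 1.5 and Q near S ~ 7.
    """
    return build_multigene_circuit(
        4, "canonical",
        production=(5.0, 5.0, 5.0, 5.0),
        decay=(1.0, 1.0, 1.0, 1.0),
        graded_half={1: 1.0, 2: 0.9, 3: 0.3},
        graded_hill={1: 2.0, 2: 2.0, 3: 2.0},
        thresholds={(2, 1): 2.0, (3, 1): 1.5, (3, 2): 1.5,
                    (0, 2): 0.5, (0, 3): 0.2},
    )
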