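# Methods

## The model and its assumptions

The package models the Pax6/Olig2/Nkx2.2 cross-repression circuit of the
ventral neural tube as three coupled ODEs for protein concentrations
`P(t), O(t), N(t)` in a single cell, driven by a scalar signal `S`
(Shh-induced Gli activity).  Production saturates at `α, β, γ`; decay is
first-order with rates `k1, k2, k3` (dilution and more elaborate turnover
are folded into these constants).  Induction of O and N uses a shared
Michaelis–Menten drive `d(S) = S/(S_half + S)`; cooperativity in the
induction is deliberately omitted (it does not change the qualitative
behaviour) and the shared `S_half` reflects the observation that O and N
respond to the same signal range.  Stochastic transcription/decay,
transcriptional time delays and cell–cell coupling are out of scope.

Two repression forms are supported:

* **threshold** — the repressions acting on O and N are all-or-nothing
  Heaviside switches at `N_crit1` (N silences O), `P_crit1` and `O_crit1`
  (P and O silence N), with the convention `H(0) = 1`: a repressor sitting
  exactly at its threshold still permits production.  This makes the model
  piecewise-smooth and analytically tractable.
* **graded** — the same three interactions as declining Hill functions with
  coefficients `h3, h4, h5`, recovering the threshold model as
  `h3, h4, h5 → ∞`.

The repression of P by N and O is always graded (Pax6 is observed in graded
levels).  Two functional forms are implemented for the combined effect:
a **shared-denominator** form `1/(1 + (N/N_crit)^h1 + (O/O_crit)^h2)`
(the default, as for repressors competing for one regulatory site) and a
**product** of two independent Hill functions (`p_repression="product"`).
The forms coincide whenever either repressor is absent — hence on the B1
and B2 branches and in every existence/route condition — and differ only
during co-expression and oscillation.  The shared-denominator default was
chosen because it is the form under which the graded variant reproduces the
expected behaviour of the sharp-repression presets: with the product form
the `fig5a` parameter set (`h = 5`, `N_crit = 0.9`) has a stable focus at
every signal level and never oscillates, and the `fig5b` cycle window opens
*below* the threshold-model gap instead of above it; with the
shared-denominator form `fig4b` has no cycle window, `fig5a` oscillates on
a contiguous intermediate window that excludes `S = 5`, and `fig5b`
oscillates on a wide window containing `S = 5` that exceeds the
threshold-model gap — the qualitative fingerprint the graded variant is
supposed to show.

## Analytic branches and regime classification

With threshold repression the steady states are the branches B1 (N silent),
B2 (O silent) and B3 (co-expression), each stable wherever it exists (the
frozen-switch Jacobian is triangular with `−k1, −k2, −k3` on the diagonal).
Existence is self-consistency with the assumed switch configuration, with
strict inequalities on the "production off" side (per `H(0) = 1`); B2 and
B3 are mutually exclusive because they share the same N value and need it
on opposite sides of `N_crit1`.

Validity of a parameter set for tripartite patterning requires
(i) `P_max > P_crit1`, (ii) `P_max/(1 + (O_max/O_crit)^h2) < P_crit1`,
(iii) `N_max > N_crit1` and `P_max/(1 + (N_max/N_crit)^h1) < P_crit1`, and
(iv) `O_max ≤ O_crit1` (with all-or-nothing repression, an O that can
silence N at intermediate signal would keep silencing it at high signal).

All critical signal levels are obtained exactly by inverting the drive,
`S = S_half·d/(1 − d)`, at analytically known crossings: B1 is lost at
`d1 = O†/O_max` with `O† = O_crit·(P_max/P_crit1 − 1)^{1/h2}`; B2 appears
at `d2 = max(N_crit1, N†)/N_max` with the analogous `N†`; B3 is lost at
`d3 = N_crit1/N_max`, and its onset is the single bisection in the module
(the B3 value of P is monotone in `d`).  Route 2 is taken iff B3 exists at
`d1`; a gap (and hence oscillation) opens on route 1 iff `d2 > d1` — for
`h1 = h2` exactly `N_max/N_crit < O_max/O_crit` — and on route 2 iff
`P_max/P_crit1 > 1 + (N_crit1/N_crit)^h1`.  Route and gap combine into the
four behaviour sequences (1: switch, 2: switch via co-expression,
3: oscillating, 4: co-expression then oscillating).

## Numerical integration

The threshold vector field is discontinuous, so trajectories are integrated
piecewise: the switch configuration is frozen, `scipy.solve_ivp` (RK45,
default `rtol 1e-9 / atol 1e-12`) runs with a terminal event on every
switching surface, and integration restarts with the flipped configuration;
the crossing direction decides the new switch state, tangential contacts
fall back to `H(0) = 1` and are logged.  Because no gene's production
depends on its own threshold, sliding modes cannot occur in this circuit
family; a segment cap and a stall guard protect against pathological
chattering anyway.  Between events the O and N sub-dynamics are linear, and
the tests verify the numerical solution against their exponential closed
forms to 1e-8.  The graded variant is smooth and integrated in one LSODA
call.  Sampling is at least 20 points per time unit so oscillation extrema
and peak times are resolved.

Attractor detection treats the first half of the horizon as burn-in.
Defaults: a fixed point needs terminal RHS norm `< 1e-8` *and* window
amplitude `< 1e-3` relative to each variable's scale; a limit cycle needs
at least six refined (parabolically interpolated) peaks of O whose last
five inter-peak intervals agree within 0.5%; a converged endpoint preceded
by three or more decaying peaks is a damped oscillation; anything else is
reported `undecided`, never coerced.  Bifurcation scans default to 201
signal levels and `t_end = 500` from the pre-signal state
`(P_max, 0, 0)`; hysteresis sweeps carry the endpoint adiabatically up
from `S = 0` and down from `S_max` (301 levels, 40 time units per level).

Graded-model fixed points are located by multi-start `scipy.optimize.root`
(hybrid Powell) from the threshold-branch values plus 24 seeded random
starts, de-duplicated at 1e-6 relative distance and annotated with
central-difference Jacobian eigenvalues.

## The simulation-only regime classifier

The census cross-checks the closed-form classification against a
classifier that sees only trajectories: an adiabatic up-sweep over 81
uniform drive levels (up to `d = 0.99`, 40 time units per level, carrying
the state) recording at each level whether the converged state has N
silent (B1-like), both O and N on (B3) or O silent (B2) — silenced genes
decay to exactly zero in threshold mode, so phases separate cleanly.
When the carried trajectory does not converge, the level counts as an
oscillation phase only if *no* stable state exists at that signal, checked
by integrating a small battery of generic initial conditions (pre-signal,
N-high, co-expression-high).  This distinction matters: the behaviour
sequences are defined by the succession of steady states and their gaps,
and the threshold model turns out to support limit cycles that *coexist*
with a stable B2 branch — the sweeping trajectory can be captured by the
cycle's basin well after B2 exists.  Such levels are recorded as the
stable state's phase with a `cycle_coexists` annotation rather than as a
gap.  The capture phenomenon is real and visible elsewhere in the package:
in fixed-initial-condition bifurcation scans of the oscillating presets
the cycle block extends one or two grid steps beyond the analytic gap
before the B2 basin takes over.

## Parameter sampling and the census

The sampler draws rates and thresholds log-uniformly from `[0.1, 10]`
(bracketing every shipped preset), shares one integer Hill coefficient
`h1 = h2 ∈ {1,…,5}`, fixes `k_i = 1` (as in all presets, making time
protein-lifetime units) and rejection-samples against the four validity
conditions in vectorised batches with a draw budget and logged rejection
counts.  The census classifies 500 such sets with both classifiers and
reports the agreement rate over decided draws, the inventory of observed
sequences (all four occur) and a B2/B3 exclusivity check.

## Spatial patterning

A row of uncoupled cells, indexed from the high-signal (ventral) end, reads
an exponential `S_max·exp(−x/λ)` or linear profile (profiles are inputs;
gradient formation is not modelled).  Each cell is integrated from the
pre-signal state and labelled two ways: the *dominance* rule (arg-max gene,
`coexpressed` when the top two levels are within a ratio `r = 2`,
`oscillatory` for non-converged cells) and a *purity* rule (exactly one
gene above a fraction `θ = 0.2` of its own attainable maximum).  Stripe
counts are maximal runs.  The purity rule is the one used for topology
comparison, because "three domains" means three mutually exclusive
expression territories: the symmetric alternative topology (signal induces
O and N, which mutually repress and both repress P) can place an arg-max-O
band between P and N territories even while N is clearly expressed there.
Under the purity rule, with one relative θ for all genes and a shared
induction drive, the symmetric threshold circuit can never show pure O and
pure N domains at different signal levels — whichever gene silences the
other first at low signal keeps doing so at high signal — so its pure
stripe count is capped at 2, while the AC–DC circuit reaches 3 for a wide
parameter range.  Its O-on-N switching level is sampled independently of
the AC–DC validity constraints, whose condition (iv) concerns the edge the
AC–DC reduction discards and would otherwise silence the symmetric
circuit's essential edge.

The four-gene demonstration circuit follows the canonical construction
(every gene represses all earlier ones; the constitutive gene additionally
represses genes 2 and 3; repressions on the constitutive gene graded, all
others thresholds) with rates 5, decays 1, graded half-maxima
`1.0 / 0.9 / 0.3` for O/N/Q on P, Hill coefficient 2, and thresholds
`N⊣O = 2`, `Q⊣O = Q⊣N = 1.5`, `P⊣N = 0.5`, `P⊣Q = 0.2`.  The staggering
puts consecutive domain transitions at `S ≈ 0.7, 1.5, 7` (factors > 2
apart) so the demo robustly yields four ordered stripes; only the stripe
count and order are asserted, the constants themselves are illustrative.

## What the synthetic conditions do and do not show

All inputs are parameter sets and signal profiles; there is no external
data.  The shipped presets are complete published parameterisations of the
figure scenarios and the sampler brackets them, so passing tests show the
implementation reproduces the circuit family's qualitative repertoire and
its internal consistency (closed forms vs. integration vs. sweeps).  They
do not show quantitative fidelity to real neural-tube expression: the
model ignores noise, delays, growth, TF movement and gradient dynamics,
and the repression constants are not measured quantities.

## Known limitations

* Cycle/steady-state coexistence means single-trajectory protocols
  (fixed-init scans, adiabatic sweeps) report basin structure, not just
  attractor existence; the package surfaces this via `cycle_coexists`
  annotations instead of hiding it.
* Oscillation windows are detected on signal grids; windows narrower than
  one grid step can be missed (the grid-refinement test bounds this).
* No continuation-grade bifurcation tracking (Floquet/Hopf normal forms);
  cycles are detected and tabulated, not continued.
* `undecided` attractor rows can appear near cycle onset where convergence
  within the scan horizon is slow; they are flagged and excluded from
  agreement denominators.
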