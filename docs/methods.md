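# Methods

## Model

The package simulates an 8-state ODE system: tumor volume `x` growing
logistically (rate `λ`, capacity `K`), three T-cell pools — cytotoxic
`y1`, reversibly exhausted `y2`, terminally exhausted `y3` — an
aggregate inflammation signal `F`, and three drug amounts `D_SC`, `D_p`,
`D_t` (subcutaneous depot, central, peripheral). Tumor kill by `y1` and
(weakly) `y3` is ratio-dependent: per tumor cell it saturates in the
killer-to-target ratio, `b·y1/(ξ1·x + y1)`. Kill feeds back twice: it
expands `y1` (coefficients `b1`, `c1`) and produces inflammation
(coefficient `b2`). Crossing the threshold `F1` switches `y1 → y2`
transition on (rate `g1`) and reversion `y2 → y1` off (rate `g2`);
crossing `F2 > F1` switches the irreversible `y2 → y3` transition on
(rate `g3`). The drug converts `y2 → y1` at rate `kd·D_p` — it acts
*only* on the reversibly exhausted pool, which is the mechanistic crux:
scheduling matters exactly insofar as it controls how much of the
immune system sits in `y2` while drug is present, and whether `F` is
held above `F2`, draining `y2` into the unresponsive `y3`.

A variant (`driver_mode="antigen"`) replaces the inflammation source
with antigen load proportional to tumor volume, `dF/dt = b̄2·x − d4·F`,
with `b̄2 = 2.7027e-4` chosen so the signal has the same magnitude as
the inflammation-driven default at the untreated attractor.

### Switching convention

The published switching factors have the form `(F − Fi)+/(F − Fi)`,
which is 0/0 at the threshold. We implement them as strict indicators
(1 iff `F > Fi`, the limit from below at equality), avoiding the
undefined division. No smoothing is applied anywhere: the right-hand
side is genuinely discontinuous and the integrator is configured for
that (below).

### Degenerate states

Ratio-dependent terms are defined as 0 when their denominator vanishes
(no killers ⇒ no kill), making the extinction state an exact fixed
point. Inside the solver, infinitesimally negative excursions of
populations are clamped to zero when evaluating the vector field; the
public `rhs_*` functions instead reject negative states loudly.

## Numerics

Integration is piecewise between bolus events with LSODA
(stiff-capable, adaptive), `rtol = 1e-8`, `atol = 1e-10`, and a maximum
internal step of 0.1 day so that indicator switches are resolved by
step-size control rather than explicit event location. Output is
sampled at 0.05-day resolution (which also bounds the trapezoid error
of all integral metrics). A dose adds `dose_per_admin` to `D_SC`
(subcutaneous) or `D_p` (IV) instantaneously; the trajectory retains
the duplicated time point so the jump is explicit in exports.

Two independent cross-checks guard the integration: an R `deSolve`
implementation reproduced the untreated trajectory to all compared
digits during development, and the test suite verifies agreement with a
hand-written fixed-step RK4 integrator to 1e-4 relative over a 30-day
window, plus the closed-form PK invariants (mass balance
`k10·∫D_p dt = dose` to 0.1%, superposition, `AUC_ss = dose/k10`).

## Default study conditions

- Initial state `(x, y1) = (50, 0.1)`, all other states 0; treatment
  starts at day 0. Doses are added in the stated units with no volume
  conversion.
- Horizon: `t_end = max(last dose + 200 d, 400 d)`; sweeps share the
  maximal horizon of their grid so burden integrals are comparable
  across cells. The inflammation-burden statistic grows without bound
  on failing trajectories, so every report states its horizon.
- Elimination: terminal tumor volume below `eps = 1` (two orders below
  the initial tumor volume). A trajectory must extend at least the
  follow-up window past the last dose before it is classified.
- Fractionation grid: 2–12 doses × 1–10 day spacings (single-dose
  protocols are excluded by default because the per-interval AUC is
  undefined for them).
- PK metrics are evaluated on the final inter-dose interval, taken as
  the steady-state interval: with ≥ 25 doses and a 2.4-day central
  half-life the final interval is within 1% of periodic steady state,
  and no convergence criterion is otherwise defined.
- Virtual population: the 21 "patients" are the integer values
  `F2 ∈ {15, …, 35}`, equally weighted — a deterministic construction,
  so population analyses involve no randomness and no seed.
- Flip-point sensitivity: fractions `f ∈ (0, 1]` scale one of the 18
  disease parameters up (`·(1+f)`) and down (`·(1−f)`); a coarse ladder
  (step 0.05) brackets the first verdict flip in each direction and
  bisection refines it to 0.01. The search assumes at most one flip per
  direction; an optional full-ladder mode evaluates every rung, flags
  non-monotone responses and falls back to the ladder minimum.
  Perturbations that would make a parameter nonpositive, or violate
  `F2 > F1`, are skipped in that direction. No flip within ±100% is
  reported censored at 1.
- Drug half-life variants rescale the central clearance so that
  `ln2·V1/Cl1` matches the target. This is one of several defensible
  half-life definitions for a two-compartment model (the terminal
  β-phase and absorption half-lives differ); it is the documented
  package reading.

## What this parameterization does and does not reproduce

The structural behavior of the model is as described above and fully
tested. However, the *quantitative* treated-outcome claims associated
with this parameter table are not attainable from these defaults, and
the end-to-end tests in `tests/test_acceptance.py` honestly fail rather
than encode unreachable numbers:

- From the default initial state, the signal `F` cannot reach `F1 = 10`
  during the first weeks of treatment (its source is bounded by
  `b2·b·x`, so reaching `F1` within a week would require a tumor ~20×
  larger than the initial one). Consequently `y2 ≡ 0` while any short
  protocol's drug is present, and `kd·D_p·y2 ≡ 0`: scheduling cannot
  change the outcome of early, short courses under these defaults.
- The untreated attractor is `x* ≈ 1027` (analytically: the
  steady-state immune-to-tumor ratio solves
  `b1/(1+u) + 4.5·c1/(1+4.5u) = g1 + d1`, giving `u ≈ 0.158`), not
  `K/2 = 1500`. `x*` is extremely sensitive to `b1/(g1+d1)` — a 4%
  change moves it by ~45% — which also explains why the growth,
  expansion and clearance parameters dominate the sensitivity maps.
- With no protocol eliminating the tumor under these defaults, the
  outcome-separation analyses (PK-metric overlap, burden separation,
  population percentages) are degenerate; the machinery computes them
  faithfully and the reports state the empty outcome class explicitly.

To keep any alternative reading one configuration change away, the
dose-unit handling, initial state, horizons, cutoffs and every model
constant are first-class configurables of the public API, the YAML
config format and the CLI.

## Problem sizes used in the shipped analyses

The default test-and-report scale was chosen to keep a full run on one
CPU comfortable: the 110-cell fractionation sweep on a shared 400-day
horizon; 21-patient populations per protocol; a reduced sensitivity
subset (4 parameters × 9 protocol cells) for the qualitative pattern
checks with the brute-force ladder oracle exercised on 3 parameters ×
2 cells; the antigen-variant population on a 6 × 5 protocol subgrid.
The full 18-parameter × 110-cell sensitivity battery is available
through `icidose sensitivity` (roughly 10^4–10^5 short solves).

## Known limitations

Well-mixed populations (no spatial structure, vasculature or
infiltration gradients); bolus-only dosing (no infusions or loading
schedules); no target-mediated drug disposition; parameters are
conceptual rather than calibrated, so all outputs are qualitative
statements about the mechanism, not predictions for any real drug.
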