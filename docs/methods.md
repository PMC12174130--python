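# Methods

## Problem and model

The package builds a composite index that quantifies the disparity between
evaluation units (provinces) in their capacity to safeguard life-safety.
Inputs are a three-level indicator scheme — 6 grade-1 components, 21
grade-2 groups, 65 grade-3 leaf indicators in the packaged scheme — and a
unit × leaf-indicator raw data matrix. Output is one index per grade-1
component and a composite (LDI), each on a best-unit-100 scale, plus a
rank and one of five security-zone labels per unit.

Weighting is endogenous, via a two-stage model per grade-1 block on
normalized values `y ∈ [0,1]`:

1. **Benefit-of-the-doubt DEA (Stage 1).** For each unit `k`,
   `s*_k = max_w Σ_j w_j y_kj` subject to `Σ_j w_j y_ij ≤ 1` for every
   unit `i` and `w_j ≥ ε`. This is the standard composite-indicator DEA
   specification with no inputs (equivalently, a single dummy input of 1):
   each unit is scored under the weights most favorable to itself, and the
   optima form the ideal score vector. Solved exactly as an LP (HiGHS).
   A unit on the frontier — including one expressible as a convex
   combination of frontier units — attains exactly 1; at least one unit
   always does.
2. **Compromise programming, L2 norm (Stage 2).**
   `w* = argmin_w Σ_k (s*_k − Σ_j w_j y_kj)²` over the same feasible
   domain. The single `w*` scores all units, eliminating DEA's
   weight-dispersion/fairness problem. Because `w*` lies in every unit's
   Stage-1 feasible region, common scores are bounded above by ideal
   scores — an invariant the tests assert on random instances.

Aggregation: block common scores are rescaled so the block's best unit is
100 (kept at full precision); the composite is the grade-1-weighted sum of
the six block indices, rescaled to best = 100. Rounding (half-up, 2
decimals) happens at report time only. Ranks are assigned on the
pre-rounding composite, descending, with ties broken by row order (a dense
tie mode is available). Zones use half-open bands with the top band closed
below: ≥ 84 high, [75, 84) medium-to-high, [70, 75) medium, [65, 70)
low-to-medium, < 65 low. Zone labels are derived from the rounded
(printed-precision) composite, matching how published tables are read.

## Numerical choices

- **Stage-2 QP.** Seeded by scipy's SLSQP (default) or trust-constr from a
  nonnegative-least-squares warm start, then refined by a primal
  active-set iteration that solves the KKT system of the identified active
  set exactly and checks Lagrange-multiplier signs. The refinement removes
  solver-dependent convergence error; both seed backends land on the same
  optimum to well below 1e-6.
- **Tie-break under rank deficiency.** When the fit does not pin the
  weights down (e.g. proportional columns), the minimum-norm optimum is
  selected by an exact projection: minimize `‖w‖²` subject to keeping the
  fitted scores `Y w` fixed and `w ≥ ε`. This is deterministic and makes
  the reported weights unique.
- **Weight floor ε.** Default 0. The published leaf weights of order 1e-8
  suggest the original optimizer used a tiny positive floor, but its value
  is not stated; ε is exposed in `DeaConfig` rather than guessed.
- **Objective scale.** The L2 objective is evaluated on the [0,1] score
  scale (values ÷ 100) for conditioning; results are scale-equivalent.
- **Tolerances.** LP feasibility/optimality requested at 1e-9; invariants
  asserted at 1e-6 on the 0–100 scale.
- **Grid oracle.** An independent Stage-1 check for ≤ 3 indicators:
  enumerate weight directions on a simplex grid, scale each to the
  feasibility boundary, take the best. Every grid point is feasible, so
  the oracle approaches the LP optimum strictly from below; at grid
  resolutions of 10⁴ (2 indicators) and ~1.5·10³ (3 indicators) it agrees
  with the LP to better than 1e-3 on the unit ([0,1]) score scale.

## Normalization

Cost indicators (mortality, pollutant emissions, altitude, ...) are
reflected (`max + min − x`, after shifting a negative minimum to zero)
rather than inverted, avoiding reciprocal blow-ups near zero; `min/x` is
available behind `cost_transform="reciprocal"`. Columns are then scaled so
the best unit is exactly 100. A constant column normalizes to all-100 (no
disparity, no penalty) with a logged warning. Missing cells are imputed
with the column median of observed units by default (`drop_unit` and
`error` policies available); imputation is logged. Normalization is
invariant to positive rescaling of any raw column, which propagates to
unit-invariance of every downstream output.

Polarity is not part of the source material; the packaged scheme assigns
it from indicator semantics (capacity/coverage → benefit; mortality,
incidence, emissions, disaster losses, personal-expenditure share, average
length of stay, altitude, population aged 65+, natural population growth →
cost), flags every leaf row "polarity assumed", and lets the input file
override it.

## Packaged fixtures

`fixtures/table1_scheme.csv` carries the published 6/21/65 scheme with
grade-1 and grade-3 weights at full printed precision (15 decimals,
never re-rounded — the composite consistency check depends on them;
grade-2 rows are structural only and carry no weights).
`fixtures/table2_scores.csv` carries the published 31-province table
(composite + six component indices + zone). The consistency check
recomputes each composite as the grade-1-weighted sum of printed component
indices with best-unit-100 rescale; all 31 agree within the 0.01 printing
precision (one province, Hainan, sits exactly on that bound). Whether the
published composite was produced by this weighted sum or by a flat
DEA-CP over all 65 indicators cannot be decided from the printed numbers;
the package asserts the numerical consistency, not the generative claim.
The published best/worst spread (100.00 / 54.75, ratio 1.83) and all 31
zone memberships are reproduced.

## Synthetic generator

Since the provincial yearbook data is unpublished, end-to-end estimation
is validated on generated matrices. Each unit draws one latent lognormal
ability per block (σ = 0.5); every indicator is a positive multiple of its
block's ability (random lognormal column scales exercise unit invariance),
with multiplicative lognormal cell noise. Cost columns are built as
`scale · (A − ability·noise)` with `A` = column max + min of the noisy
ability, so the reflection orientation recovers the ability image exactly.
Defaults mirror the study layout: 31 units, block sizes (9, 21, 7, 13, 11,
4), `noise_sd = 0.05` and `cost_fraction = 0.2` — chosen once as a mild,
realistic noise regime; the source states no values. An additive-Gaussian
noise mode exists behind a flag.

At `noise_sd = 0` every block is rank-1 after orientation/normalization:
Stage 2 reaches all ideal scores with objective ~0, the planted ranking is
recovered exactly (Spearman ρ = 1.0), and with uniform planted weights the
minimum-norm tie-break recovers the uniform weight direction. With noise,
recovery degrades gracefully (median ρ ≈ 0.99 at σ = 0.05, ≈ 0.94 at
σ = 0.2 on the small test layout).

What the generator does **not** emulate: the marginal distributions of
real yearbook indicators, cross-block ability correlation, multi-factor
structure within a block, or systematic missingness. Passing recovery
tests therefore demonstrate correctness of the optimization and
aggregation machinery, not field validity of the index on real data.

## Problem sizes in the test and acceptance runs

The property suite checks the LP against the grid oracle on 100+ seeded
instances of ≤ 8 units × ≤ 3 indicators, Stage-2 invariants on random
blocks up to 8 × 4, noise sweeps on a 10-unit (3, 4, 2)-block layout over
12 seeds per noise level, and the full 31 × 65 layout for the end-to-end
scenario. The published-table checks are exact desk-scale recomputations.

## Known limitations

- The leaf-level weight table cannot be reproduced: the exact
  feasible-domain constraints (e.g. assurance-region bounds) behind the
  published weights are not recoverable from the text. The engine
  implements the canonical benefit-of-the-doubt + L2 compromise model and
  validates its structural properties instead.
- Stage-1 ideal scores treat convex combinations of frontier units as
  efficient (standard DEA behaviour); weak efficiency is not
  distinguished from strong.
- Zone cut points are fixed to the published 84/75/70/65 by default;
  alternative band schemes are supported but unvalidated.
- No outlier treatment or distributional transforms are applied to raw
  columns.
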