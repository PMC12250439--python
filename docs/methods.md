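# Methods

## Model and assumptions

The model values earlier elective surgery by the *incremental* difference
between an early-surgery arm and its counterfactual (delayed, missed, or
no-surgery) arm; it never attempts absolute lifetime QALYs or total
programme costs. Each patient's timeline is partitioned into segments on
which the two arms' health states differ, utilities are piecewise
constant within segments, and incremental QALYs are areas between the two
discounted utility curves. The three subgroup scenarios nest: the
missed-surgery model is the general three-segment model with the
post-surgery-difference interval empty, and the lifesaving model empties
the waiting interval too. These collapses are enforced in tests as
structural equivalences on randomized parameter sweeps, and every
closed-form segment total is checked against an independent fine-grid
midpoint integration of the raw arm-difference curves.

Key assumptions inherited by every analysis:

- **Lifesaving counterfactual death coincides with the scheduled early
  surgery date.** This keeps the lifesaving scenario to a single
  parameterizable segment; the equality is enforced at validation and
  propagated as a hard tie in sensitivity analyses.
- **Costs are episodic lump sums** discounted at explicit incurrence
  times, not continuous flows. Productivity losses enter as pre-computed
  per-patient monetary amounts (human-capital style inputs), not as wage
  × duration computed internally.
- **Discounting is continuous-time**: the factor `(1+r)^(−t)` is
  integrated in closed form, so segment boundaries may be arbitrary
  non-integer years. A discrete annual-cycle mode is deliberately not
  offered; one canonical semantics keeps results auditable against the
  quadrature oracle. The closed form is implemented with `expm1` so that
  tiny rates and short intervals do not suffer cancellation.
- No half-cycle correction, no age-dependent utility decrements, no
  parametric survival curves, and one timeline per subgroup (no age
  stratification).

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| `discount.annual_rate` | fraction/yr | 0.035 | applied to QALYs and costs alike |
| `economy.wtp_threshold` | EGP/QALY | config | 56,000 in the shipped fixtures (one GDP per capita) |
| `economy.gdp_per_capita` | EGP | config | monetizes QALYs in the benefit–cost ratio |
| utilities | — | config | in [−1, 1]; `u_wait` already includes pre-operative stress |
| timelines | years | config | ordered: `t_early ≤ t_delayed ≤ t_death_counterfactual ≤ t_death_early` |
| costs | EGP | config | non-negative lumps; `direct_delayed` defaults to 0 so missed-surgery counterfactuals pay nothing unless overridden |
| `n_patients` | count | config | non-negative real; fractional counts are expected-value cohort sizes and make exact calibration possible |

ICERs are kept unrounded internally and rounded to the nearest currency
unit for display. When incremental QALYs are non-positive the ICER is an
explicit undefined/dominated marker, never an exception; the net monetary
benefit column (ΔQ×WTP − ΔC, not a headline outcome) exists because it
stays finite there.

## Sensitivity analyses

**DSA.** Each addressed parameter is set to mean×(1±δ), δ = 0.10 by
default, the whole pipeline re-evaluated, and parameters ranked by the
induced swing in the composite societal ICER. A perturbation that breaks
a timeline invariant flags the entry infeasible rather than clamping.

**PSA.** Distributions are assigned by family convention — beta for
utilities, normal for event times, gamma for monetary amounts — matched
to (mean, SE) by the method of moments. When no uncertainty magnitude is
supplied, the SE defaults to 10% of the mean, mirroring the DSA band; a
zero SE degenerates to a point mass. Parameters are sampled
independently (no correlation structure); patient counts are fixed unless
a distribution is explicitly assigned. Draws violating the timeline
ordering are rejected and redrawn with a logged count, and a rejection
rate above 50% aborts, naming the worst-offending parameter. Results are
summarized as draw-level (ΔQALYs, Δcost) pairs and their ratio of means —
never a mean of per-draw ICERs, which diverges near ΔQ = 0.

**Structural ties.** Three equalities are treated as model structure, not
as sampleable uncertainty: the lifesaving counterfactual death date
(always `t_early`); a counterfactual death date equal to the early-arm
one in the base case (a "no survival gap" scenario feature — sampling the
two dates independently would reject half of all draws whenever the gap
is zero); and the unused `t_delayed` bookkeeping field of non-RWT
subgroups, which tracks `t_early`. Explicitly assigning a distribution to
a tied field overrides the tie, except the lifesaving one, which is
refused.

**Caveat.** Because utilities are sampled independently, the sampled
post-surgery utility *difference* can change sign when the base-case gap
is small relative to its spread; a minority of draws can then lose QALYs
overall, which places the cost-effectiveness acceptability curve outside
its monotone regime. This is a faithful consequence of independent
sampling, not an artifact; the CEAC monotonicity guarantee holds whenever
every draw gains QALYs.

## Catastrophic health expenditure

Budget-share method only: a payment is catastrophic when it strictly
exceeds the threshold share (10% or 25%; 25% base case) of a household's
annual total expenditure — "strictly" because the definition says
*exceeding*, and pinning the boundary makes results bit-reproducible.
The population proportion is the expenditure-distribution mass strictly
below `oop/threshold`, computed exactly for empirical samples and via the
CDF for the lognormal parametric form. The normative and
partial-normative variants (subsistence-adjusted capacity to pay) are
named extension points and intentionally unimplemented.

## Synthetic data

No real payment or household data ships with the package; all fixtures
are generated.

- The `egypt_like` profile emulates a five-surgery national waiting-list
  initiative with invented but clinically plausible parameters chosen to
  reproduce the qualitative pattern such programmes show: cochlear
  implantation dominant from the societal perspective (modest direct-cost
  increase swamped by lifetime patient and caregiver productivity
  savings), retinal surgery above the willingness-to-pay threshold
  (small utility gain, no survival effect), both cardiac cohorts below
  it. Mortality effects live in the MA subgroups; RWT subgroups carry no
  survival gap.
- The `randomized` profile draws uniformly from documented ranges
  (utilities 0.2–0.95, waiting gaps 0.1–3 years, survival 5–40 years,
  costs 10⁴–10⁶ EGP), ordered by construction so every fixture is valid.
- The calibrated fixture scales all patient counts by one common factor
  (hitting a target total ΔQALYs exactly, by linearity) and then solves a
  one-dimensional linear equation for a single direct-cost knob (hitting
  the target societal Δcost); the result is re-verified through the full
  pipeline to 0.01% relative. Calibration deliberately touches only
  counts and one cost so that no recovered real-world inputs are implied.
- Household expenditures are lognormal (default log-mean 10.5, log-sd
  0.8 — median ≈ EGP 36,000/year, a plausible lower-middle-income
  household budget), under which most of the five procedures are
  catastrophic for >90% of households out of pocket.

What these fixtures do **not** emulate: real per-surgery case mix,
correlated parameter uncertainty, within-cohort heterogeneity, or any
actual ministry payment data — so passing tests demonstrate the engine's
arithmetic, invariants and contracts, not country-specific conclusions.

## Numerical choices

- Oracle integration uses the midpoint rule with grid edges snapped to
  the utility-curve breakpoints (Δt = 10⁻⁴ yr for the worked example,
  10⁻³ yr for the 1000-draw sweeps, both far inside the asserted
  tolerances); `discounted_exposure` is additionally checked against
  adaptive quadrature at 10⁻⁸ relative.
- PSA evaluation is vectorized across draws through the same closed-form
  kernels the deterministic engine uses (they accept scalars or arrays),
  so draw-level results are bit-identical to scalar re-evaluation.
- Determinism: every stochastic routine takes an explicit integer seed
  (numpy `default_rng`); identical (seed, draw count, distribution
  assignment) reproduce identical outputs, and the CLI records seeds in
  the run manifest.
- Ties at the WTP boundary count as cost-effective (≤ convention);
  the CHE boundary is strict (>). Both are documented contracts.
- Problem sizes in the shipped tests — 1000-draw oracle sweeps, 5000-draw
  PSA, 10⁵-household CHE samples — were chosen as the smallest sizes at
  which the corresponding statistical tolerances are comfortably
  resolved.

## Known limitations

- Independent sampling can be conservative or anti-conservative for
  near-tied utilities (see the PSA caveat); correlated or
  increment-parameterized sampling is future work.
- The budget-share CHE method ignores capacity to pay; the normative
  variants would require a subsistence basket the package does not model.
- Costs are single lumps per arm; recurring post-operative cost streams
  must be pre-aggregated by the user.
- The payer-perspective ICER is reported wherever the societal one is,
  but no payer-specific sensitivity analysis is offered.
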