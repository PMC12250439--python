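"""Reported outcomes: ICERs (societal and payer), benefit–cost ratio,
dominance classification, net monetary benefit, and population aggregation.

Aggregation follows the population-sum convention: total QALYs and total
costs are summed across all cohorts first, and a single composite ICER is
formed from the sums.  Per-cohort ICERs are never averaged — the composite
is the weighted mediant of the per-cohort ratios.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

from .config import DiscountSettings, ModelRun, SubgroupParameters, SurgeryCohort
from .costs import CostBreakdown, subgroup_costs
from .qaly import SegmentBreakdown, subgroup_qalys


class Dominance(str, enum.Enum):
    """Cost-effectiveness quadrant classification."""

    none = "none"
    dominant = "dominant"      # gains QALYs while saving money
    dominated = "dominated"    # loses QALYs while costing money


@dataclass
class IcerResult:
    """An incremental cost-effectiveness ratio with its dominance marker.

    ``value`` is the unrounded ratio, defined only when incremental QALYs
    are strictly positive (None otherwise); degenerate cases are encoded
    in ``dominance``/``defined`` rather than raised.
    """

    value: Optional[float]
    dominance: Dominance
    defined: bool

    @property
    def rounded(self) -> Optional[int]:
        """Ratio rounded to the nearest currency unit, for display."""
        return None if self.value is None else round(self.value)


def compute_icer(delta_cost: float, delta_qalys: float) -> IcerResult:
    """Classify and compute an ICER from population deltas.

    A positive-QALY, negative-cost pair is dominant (cost saving); a
    negative-QALY, positive-cost pair is dominated; zero incremental QALYs
    yield an undefined marker, never a division error.
    """
    if not math.isfinite(delta_qalys):
        raise ValueError("delta_qalys must be finite")
    if delta_qalys > 0:
        dom = Dominance.dominant if delta_cost < 0 else Dominance.none
        return IcerResult(value=delta_cost / delta_qalys, dominance=dom, defined=True)
    if delta_qalys == 0:
        return IcerResult(value=None, dominance=Dominance.none, defined=False)
    dom = Dominance.dominated if delta_cost > 0 else Dominance.none
    return IcerResult(value=None, dominance=dom, defined=False)


@dataclass
class BcrResult:
    """Benefit–cost ratio: monetized QALY gains over societal incremental cost.

    When the denominator is negative (the programme saves money) the plain
    signed ratio is kept and ``cost_saving`` is flagged, so both the ratio
    arithmetic and the dominant outcome remain representable.
    """

    value: Optional[float]
    cost_saving: bool
    defined: bool


def compute_bcr(delta_qalys: float, gdp_per_capita: float,
                delta_total_societal: float) -> BcrResult:
    """``(ΔQALYs × GDP per capita) / societal Δcost``."""
    if delta_total_societal == 0:
        return BcrResult(value=None, cost_saving=False, defined=False)
    value = (delta_qalys * gdp_per_capita) / delta_total_societal
    return BcrResult(value=value, cost_saving=delta_total_societal < 0, defined=True)


@dataclass
class OutcomeSet:
    """Population-level outcomes for one cohort (or the composite)."""

    label: str
    n_patients: float
    total_delta_qalys: float
    costs: CostBreakdown               # population scale
    icer_societal: IcerResult
    icer_payer: IcerResult
    bcr_societal: BcrResult
    dominance_flag: Dominance
    cost_effective_at_wtp: bool
    net_monetary_benefit: float        # auxiliary: ΔQALYs × WTP − societal Δcost
    segment_totals: dict[str, float] = field(default_factory=dict)


@dataclass
class SubgroupResult:
    """Per-subgroup detail: QALY segment breakdown and cost components."""

    cohort: str
    kind: str
    n_patients: float
    qalys_per_patient: float
    qalys_population: float
    segments: SegmentBreakdown
    costs_per_patient: CostBreakdown
    costs_population: CostBreakdown


@dataclass
class RunResults:
    """Full evaluation of a model run."""

    composite: OutcomeSet
    per_cohort: list[OutcomeSet]
    per_subgroup: list[SubgroupResult]


def classify_cost_effectiveness(outcome: "OutcomeSet | IcerResult", wtp: float) -> bool:
    """True iff the (societal) result is dominant or its ICER is ≤ WTP.

    Boundary convention: an ICER exactly equal to the threshold counts as
    cost-effective.
    """
    icer = outcome.icer_societal if isinstance(outcome, OutcomeSet) else outcome
    if icer.dominance is Dominance.dominant:
        return True
    return icer.defined and icer.value is not None and icer.value <= wtp


def _make_outcome(label: str, n_patients: float, dq: float, costs: CostBreakdown,
                  run: ModelRun, segment_totals: dict[str, float]) -> OutcomeSet:
    d_soc = costs.delta_total_societal
    icer_soc = compute_icer(d_soc, dq)
    icer_pay = compute_icer(costs.delta_total_payer, dq)
    bcr = compute_bcr(dq, run.economy.gdp_per_capita, d_soc)
    if dq > 0 and d_soc < 0:
        dom = Dominance.dominant
    elif dq < 0 and d_soc > 0:
        dom = Dominance.dominated
    else:
        dom = Dominance.none
    wtp = run.economy.wtp_threshold
    return OutcomeSet(
        label=label,
        n_patients=n_patients,
        total_delta_qalys=dq,
        costs=costs,
        icer_societal=icer_soc,
        icer_payer=icer_pay,
        bcr_societal=bcr,
        dominance_flag=dom,
        cost_effective_at_wtp=classify_cost_effectiveness(icer_soc, wtp),
        net_monetary_benefit=dq * wtp - d_soc,
        segment_totals=segment_totals,
    )


def evaluate_subgroup(sp: SubgroupParameters, d: DiscountSettings,
                      cohort_name: str = "") -> SubgroupResult:
    """Evaluate QALYs and costs for one subgroup."""
    per_patient_q, population_q, breakdown = subgroup_qalys(sp, d)
    per_patient_c, population_c = subgroup_costs(sp, d)
    return SubgroupResult(
        cohort=cohort_name,
        kind=sp.kind.value,
        n_patients=sp.n_patients,
        qalys_per_patient=per_patient_q,
        qalys_population=population_q,
        segments=breakdown,
        costs_per_patient=per_patient_c,
        costs_population=population_c,
    )


def _sum_costs(parts: list[CostBreakdown]) -> CostBreakdown:
    return CostBreakdown(
        delta_direct=sum(p.delta_direct for p in parts),
        delta_indirect_patient=sum(p.delta_indirect_patient for p in parts),
        delta_indirect_caregiver=sum(p.delta_indirect_caregiver for p in parts),
    )


def evaluate_cohort(cohort: SurgeryCohort, run: ModelRun) -> tuple[OutcomeSet, list[SubgroupResult]]:
    """Population outcomes for one cohort, summed over its subgroups."""
    details = [evaluate_subgroup(sg, run.discount, cohort.name) for sg in cohort.subgroups]
    dq = sum(r.qalys_population for r in details)
    costs = _sum_costs([r.costs_population for r in details])
    n = sum(r.n_patients for r in details)
    seg_totals: dict[str, float] = {}
    for r in details:
        for name, value in r.segments.segments.items():
            seg_totals[name] = seg_totals.get(name, 0.0) + value * r.n_patients
    return _make_outcome(cohort.name, n, dq, costs, run, seg_totals), details


def aggregate_outcomes(run: ModelRun) -> RunResults:
    """Evaluate every cohort and form the composite from population sums.

    The composite ICER divides total incremental cost by total incremental
    QALYs across all cohorts (never an average of per-cohort ICERs).
    """
    if not run.cohorts:
        raise ValueError("aggregate_outcomes: model run has no cohorts")
    per_cohort: list[OutcomeSet] = []
    per_subgroup: list[SubgroupResult] = []
    for cohort in run.cohorts:
        outcome, details = evaluate_cohort(cohort, run)
        per_cohort.append(outcome)
        per_subgroup.extend(details)
    dq = sum(o.total_delta_qalys for o in per_cohort)
    costs = _sum_costs([o.costs for o in per_cohort])
    n = sum(o.n_patients for o in per_cohort)
    seg_totals: dict[str, float] = {}
    for o in per_cohort:
        for name, value in o.segment_totals.items():
            seg_totals[name] = seg_totals.get(name, 0.0) + value
    composite = _make_outcome("composite", n, dq, costs, run, seg_totals)
    return RunResults(composite=composite, per_cohort=per_cohort, per_subgroup=per_subgroup)


def evaluate_run(run: ModelRun) -> RunResults:
    """Alias for :func:`aggregate_outcomes`; the main entry point."""
    return aggregate_outcomes(run)
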