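"""Discounted incremental QALY computation, by timeline segment.

The model compares an early-surgery arm with a counterfactual (delayed,
missed, or no-surgery) arm.  Utilities are piecewise constant, so the
incremental QALY gain is a sum of segment contributions, each a utility
difference multiplied by the discounted person-time of the segment:

* reduced waiting time — segment A (waiting gap, early vs. still waiting),
  segment B (post-surgery utility difference until counterfactual death),
  segment C (survival gap valued at the post-early-surgery utility);
* missed surgery — segment V (post-surgery vs. living unoperated, up to
  counterfactual death) and segment W (survival gap); this is the general
  model with segment B's interval empty;
* lifesaving — segment X only (the whole early-arm survival valued at
  post-surgery utility), with counterfactual death pinned to the early
  surgery date.

Discounting uses the continuous-time factor ``(1+r)^(-t)`` integrated in
closed form, so segment boundaries may be arbitrary non-integer years.
All kernels accept scalars or numpy arrays (broadcasting elementwise),
which is what the probabilistic sensitivity analysis relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .config import (
    DiscountSettings,
    ScenarioKind,
    SubgroupParameters,
    Timeline,
    UtilityProfile,
)

ArrayLike = Union[float, np.ndarray]


def discounted_exposure(t_start: ArrayLike, t_end: ArrayLike, rate: float) -> ArrayLike:
    """Discounted person-time over ``[t_start, t_end]`` (years).

    Closed form of the integral of ``(1+rate)^(-t)``:

    ``[(1+r)^(-t_start) - (1+r)^(-t_end)] / ln(1+r)``

    reducing to ``t_end - t_start`` at rate 0.  Raises ``ValueError`` when
    any interval is reversed.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must lie in [0, 1), got {rate}")
    if np.any(np.asarray(t_start) > np.asarray(t_end)):
        raise ValueError("discounted_exposure: t_start must not exceed t_end")
    if np.any(np.asarray(t_start) < 0):
        raise ValueError("discounted_exposure: times must be non-negative")
    if rate == 0.0:
        return t_end - t_start
    # (exp(-a·t0) − exp(-a·t1))/a with a = ln(1+r), written via expm1 so the
    # cancellation for tiny rates or short intervals stays benign
    a = math.log1p(rate)
    t_start = np.asarray(t_start, dtype=float)
    gap = np.asarray(t_end, dtype=float) - t_start
    result = -np.exp(-a * t_start) * np.expm1(-a * gap) / a
    return result if result.ndim else float(result)


@dataclass
class SegmentBreakdown:
    """Discounted QALY contributions of the segments active in a scenario."""

    scenario: ScenarioKind
    segments: dict[str, ArrayLike] = field(default_factory=dict)

    @property
    def total(self) -> ArrayLike:
        """Sum of all segment contributions (incremental QALYs per patient)."""
        return sum(self.segments.values())


# -- raw kernels (scalars or arrays) ----------------------------------------

def _segments_reduced_wait(u_wait, u_post_early, u_post_delayed,
                           t_early, t_delayed, t_death_cf, t_death_early,
                           rate):
    a = (u_post_early - u_wait) * discounted_exposure(t_early, t_delayed, rate)
    b = (u_post_early - u_post_delayed) * discounted_exposure(t_delayed, t_death_cf, rate)
    c = u_post_early * discounted_exposure(t_death_cf, t_death_early, rate)
    return {"A": a, "B": b, "C": c}


def _segments_missed_surgery(u_missed, u_post_early,
                             t_early, t_death_cf, t_death_early, rate):
    v = (u_post_early - u_missed) * discounted_exposure(t_early, t_death_cf, rate)
    w = u_post_early * discounted_exposure(t_death_cf, t_death_early, rate)
    return {"V": v, "W": w}


def _segments_lifesaving(u_post_early, t_early, t_death_early, rate):
    return {"X": u_post_early * discounted_exposure(t_early, t_death_early, rate)}


# -- public scenario engines -------------------------------------------------

def qalys_reduced_wait(u: UtilityProfile, tl: Timeline, d: DiscountSettings) -> SegmentBreakdown:
    """Incremental QALYs per patient for a reduced-waiting-time subgroup."""
    segs = _segments_reduced_wait(
        u.u_wait, u.u_post_early, u.u_post_delayed,
        tl.t_early, tl.t_delayed, tl.t_death_counterfactual, tl.t_death_early,
        d.annual_rate,
    )
    return SegmentBreakdown(ScenarioKind.reduced_wait, segs)


def qalys_missed_surgery(u: UtilityProfile, tl: Timeline, d: DiscountSettings) -> SegmentBreakdown:
    """Incremental QALYs per patient for an avoided-missed-surgery subgroup.

    Requires ``u_missed`` (utility of living without the operation).
    """
    if u.u_missed is None:
        raise ValueError("missed-surgery scenario requires utilities.u_missed")
    segs = _segments_missed_surgery(
        u.u_missed, u.u_post_early,
        tl.t_early, tl.t_death_counterfactual, tl.t_death_early,
        d.annual_rate,
    )
    return SegmentBreakdown(ScenarioKind.missed_surgery, segs)


def qalys_lifesaving(u: UtilityProfile, tl: Timeline, d: DiscountSettings) -> SegmentBreakdown:
    """Incremental QALYs per patient for a mortality-averted subgroup.

    The counterfactual patient is assumed to die on the scheduled early
    surgery date, so ``t_death_counterfactual`` must equal ``t_early``.
    """
    if not math.isclose(tl.t_death_counterfactual, tl.t_early, rel_tol=0.0, abs_tol=1e-12):
        raise ValueError(
            "lifesaving scenario assumes death in the no-surgery arm coincides "
            "with the scheduled early surgery date "
            f"(t_death_counterfactual={tl.t_death_counterfactual}, t_early={tl.t_early})"
        )
    segs = _segments_lifesaving(u.u_post_early, tl.t_early, tl.t_death_early, d.annual_rate)
    return SegmentBreakdown(ScenarioKind.lifesaving, segs)


_ENGINES = {
    ScenarioKind.reduced_wait: qalys_reduced_wait,
    ScenarioKind.missed_surgery: qalys_missed_surgery,
    ScenarioKind.lifesaving: qalys_lifesaving,
}


def scenario_qalys(u: UtilityProfile, tl: Timeline, d: DiscountSettings,
                   scenario: ScenarioKind) -> SegmentBreakdown:
    """Dispatch to the engine for ``scenario``."""
    try:
        engine = _ENGINES[scenario]
    except KeyError:
        raise ValueError(f"unknown scenario {scenario!r}") from None
    return engine(u, tl, d)


def subgroup_qalys(sp: SubgroupParameters, d: DiscountSettings):
    """Per-patient and population incremental QALYs for one subgroup.

    Returns ``(per_patient_total, population_total, breakdown)``; the
    population total is simply per-patient × ``n_patients``.
    """
    breakdown = scenario_qalys(sp.utilities, sp.timeline, d, sp.scenario)
    per_patient = breakdown.total
    return per_patient, per_patient * sp.n_patients, breakdown
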