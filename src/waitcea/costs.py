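"""Discounted incremental costs, decomposed by component and perspective.

Costs are lump sums incurred at declared times and discounted to present
value with the same ``(1+r)^(-t)`` factor used for QALYs.  Every delta is
early-arm minus counterfactual-arm, so a saving is negative.  The payer
perspective counts direct medical costs only; the societal perspective
adds patient and caregiver productivity losses.

Scenario handling of the counterfactual arm:

* reduced waiting time — counterfactual components as configured
  (the delayed surgery still happens and still costs money);
* missed surgery — no counterfactual operation, so the counterfactual
  direct cost is whatever ``direct_delayed`` says (0 by default, but
  overridable for e.g. ongoing palliative care), while counterfactual
  indirect losses are kept (living unoperated still costs productivity);
* lifesaving — the counterfactual patient dies at the early surgery date,
  so every counterfactual component is zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DiscountSettings, ScenarioKind, SubgroupParameters
from .qaly import ArrayLike


def discount_lump(amount: ArrayLike, at_time: ArrayLike, rate: float) -> ArrayLike:
    """Present value of a lump sum incurred ``at_time`` years from start."""
    if np.any(np.asarray(at_time) < 0):
        raise ValueError("discount_lump: at_time must be non-negative")
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must lie in [0, 1), got {rate}")
    return amount * (1.0 + rate) ** (-np.asarray(at_time, dtype=float))


@dataclass
class CostBreakdown:
    """Incremental discounted costs (early minus counterfactual), per component."""

    delta_direct: ArrayLike
    delta_indirect_patient: ArrayLike
    delta_indirect_caregiver: ArrayLike

    @property
    def delta_total_societal(self) -> ArrayLike:
        """Direct plus both indirect components."""
        return (
            self.delta_direct
            + self.delta_indirect_patient
            + self.delta_indirect_caregiver
        )

    @property
    def delta_total_payer(self) -> ArrayLike:
        """Direct medical costs only."""
        return self.delta_direct

    def scaled(self, factor: ArrayLike) -> "CostBreakdown":
        return CostBreakdown(
            self.delta_direct * factor,
            self.delta_indirect_patient * factor,
            self.delta_indirect_caregiver * factor,
        )


def _cost_deltas(direct_e, direct_d, ip_e, ip_d, ic_e, ic_d, t_e, t_d,
                 rate, scenario: ScenarioKind):
    """Raw kernel; accepts scalars or arrays for every monetary/time input."""
    if scenario is ScenarioKind.lifesaving:
        direct_d = ip_d = ic_d = 0.0
    df_e = discount_lump(1.0, t_e, rate)
    df_d = discount_lump(1.0, t_d, rate)
    return CostBreakdown(
        delta_direct=direct_e * df_e - direct_d * df_d,
        delta_indirect_patient=ip_e * df_e - ip_d * df_d,
        delta_indirect_caregiver=ic_e * df_e - ic_d * df_d,
    )


def subgroup_costs(sp: SubgroupParameters, d: DiscountSettings):
    """Per-patient and population incremental cost breakdown for one subgroup.

    Returns ``(per_patient, population)`` where the population breakdown is
    the per-patient one scaled by ``n_patients``.
    """
    c = sp.costs
    per_patient = _cost_deltas(
        c.direct_early, c.direct_delayed,
        c.indirect_patient_early, c.indirect_patient_delayed,
        c.indirect_caregiver_early, c.indirect_caregiver_delayed,
        c.incurrence_time_early, c.incurrence_time_delayed,
        d.annual_rate, sp.scenario,
    )
    return per_patient, per_patient.scaled(sp.n_patients)
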