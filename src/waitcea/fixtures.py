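"""Synthetic parameter sets: illustrative, randomized and calibrated.

No patient-level or ministry payment data ships with this package.  This
module generates three kinds of synthetic model-run configurations:

* ``egypt_like`` — five cohorts named after the surgical interventions of
  a national waiting-list initiative (open-heart surgery, cardiac
  catheterization, cochlear implantation, retinal surgery, joint
  replacement), with invented but clinically plausible parameters chosen
  to reproduce the qualitative pattern such programmes show: cochlear
  implantation dominant from the societal perspective (large caregiver
  productivity savings over a childhood-onset lifetime), retinal surgery
  above the willingness-to-pay threshold (small utility gain, little
  mortality effect), and the cardiac cohorts comfortably below it;
* ``randomized`` — uniform draws from documented, invariant-respecting
  ranges (utilities 0.2–0.95, waiting gaps 0.1–3 years, survival 5–40
  years, costs 10⁴–10⁶ currency units), for property testing;
* calibrated — a fixture whose population totals hit prescribed aggregate
  ΔQALYs and societal Δcost exactly, by globally scaling patient counts
  and solving for a single direct-cost knob.  The composite ICER then
  equals the target ratio by construction, and is verified through the
  real pipeline.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .config import ModelRun
from .costs import discount_lump
from .outcomes import evaluate_run

#: Documented sampling ranges for the randomized profile.
RANDOM_RANGES = {
    "utility": (0.2, 0.95),
    "wait_gap_years": (0.1, 3.0),
    "survival_years": (5.0, 40.0),
    "cost": (1e4, 1e6),
}

_DEFAULT_ECONOMY = dict(gdp_per_capita=56000.0, wtp_threshold=56000.0, currency_label="EGP")


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: profile, size, seed, optional calibration targets."""

    seed: int = 0
    n_cohorts: int = 5
    profile: str = "egypt_like"
    calibration_targets: Optional[tuple[float, float]] = None  # (ΔQALYs, societal Δcost)

    def __post_init__(self):
        if self.profile not in ("egypt_like", "randomized"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be at least 1")


def _sg(kind, n, u, tl, c) -> dict:
    return {"kind": kind, "n_patients": n, "utilities": u, "timeline": tl, "costs": c}


def _egypt_like_cohorts() -> list[dict]:
    """Hand-written parameter blocks for the five-surgery illustrative run."""
    return [
        {
            "name": "open_heart_surgery",
            "subgroups": [
                _sg("RWT", 20000,
                    dict(u_wait=0.60, u_post_early=0.80, u_post_delayed=0.78),
                    dict(t_early=0.2, t_delayed=1.5, t_death_counterfactual=19.0, t_death_early=19.0),
                    dict(direct_early=230000, direct_delayed=200000,
                         indirect_patient_early=15000, indirect_patient_delayed=40000,
                         indirect_caregiver_early=5000, indirect_caregiver_delayed=15000,
                         incurrence_time_early=0.2, incurrence_time_delayed=1.5)),
                _sg("AMS", 2000,
                    dict(u_wait=0.60, u_post_early=0.80, u_post_delayed=0.78, u_missed=0.45),
                    dict(t_early=0.2, t_delayed=0.2, t_death_counterfactual=12.0, t_death_early=19.0),
                    dict(direct_early=230000, direct_delayed=0,
                         indirect_patient_early=15000, indirect_patient_delayed=250000,
                         indirect_caregiver_early=5000, indirect_caregiver_delayed=80000,
                         incurrence_time_early=0.2, incurrence_time_delayed=0.2)),
                _sg("MA", 800,
                    dict(u_wait=0.60, u_post_early=0.80, u_post_delayed=0.80),
                    dict(t_early=0.2, t_delayed=0.2, t_death_counterfactual=0.2, t_death_early=19.0),
                    dict(direct_early=230000, direct_delayed=0,
                         indirect_patient_early=15000, indirect_patient_delayed=0,
                         indirect_caregiver_early=5000, indirect_caregiver_delayed=0,
                         incurrence_time_early=0.2, incurrence_time_delayed=0.2)),
            ],
        },
        {
            "name": "cardiac_catheterization",
            "subgroups": [
                _sg("RWT", 60000,
                    dict(u_wait=0.65, u_post_early=0.82, u_post_delayed=0.80),
                    dict(t_early=0.1, t_delayed=1.0, t_death_counterfactual=20.5, t_death_early=20.5),
                    dict(direct_early=50000, direct_delayed=38000,
                         indirect_patient_early=8000, indirect_patient_delayed=12000,
                         indirect_caregiver_early=2000, indirect_caregiver_delayed=4000,
                         incurrence_time_early=0.1, incurrence_time_delayed=1.0)),
                _sg("AMS", 5000,
                    dict(u_wait=0.65, u_post_early=0.82, u_post_delayed=0.80, u_missed=0.50),
                    dict(t_early=0.1, t_delayed=0.1, t_death_counterfactual=13.0, t_death_early=20.5),
                    dict(direct_early=50000, direct_delayed=0,
                         indirect_patient_early=8000, indirect_patient_delayed=120000,
                         indirect_caregiver_early=2000, indirect_caregiver_delayed=30000,
                         incurrence_time_early=0.1, incurrence_time_delayed=0.1)),
                _sg("MA", 1500,
                    dict(u_wait=0.65, u_post_early=0.82, u_post_delayed=0.82),
                    dict(t_early=0.1, t_delayed=0.1, t_death_counterfactual=0.1, t_death_early=20.5),
                    dict(direct_early=50000, direct_delayed=0,
                         indirect_patient_early=8000, indirect_patient_delayed=0,
                         indirect_caregiver_early=2000, indirect_caregiver_delayed=0,
                         incurrence_time_early=0.1, incurrence_time_delayed=0.1)),
            ],
        },
        {
            "name": "cochlear_implantation",
            "subgroups": [
                _sg("RWT", 1500,
                    dict(u_wait=0.55, u_post_early=0.85, u_post_delayed=0.80),
                    dict(t_early=0.3, t_delayed=2.0, t_death_counterfactual=45.0, t_death_early=45.0),
                    dict(direct_early=400000, direct_delayed=380000,
                         indirect_patient_early=0, indirect_patient_delayed=50000,
                         indirect_caregiver_early=20000, indirect_caregiver_delayed=150000,
                         incurrence_time_early=0.3, incurrence_time_delayed=2.0)),
                _sg("AMS", 500,
                    dict(u_wait=0.55, u_post_early=0.85, u_post_delayed=0.80, u_missed=0.45),
                    dict(t_early=0.3, t_delayed=0.3, t_death_counterfactual=45.0, t_death_early=45.0),
                    dict(direct_early=400000, direct_delayed=0,
                         indirect_patient_early=0, indirect_patient_delayed=600000,
                         indirect_caregiver_early=20000, indirect_caregiver_delayed=300000,
                         incurrence_time_early=0.3, incurrence_time_delayed=0.3)),
            ],
        },
        {
            "name": "retinal_surgery",
            "subgroups": [
                _sg("RWT", 30000,
                    dict(u_wait=0.68, u_post_early=0.72, u_post_delayed=0.715),
                    dict(t_early=0.2, t_delayed=1.2, t_death_counterfactual=15.0, t_death_early=15.0),
                    dict(direct_early=30000, direct_delayed=22000,
                         indirect_patient_early=3000, indirect_patient_delayed=4000,
                         indirect_caregiver_early=1000, indirect_caregiver_delayed=1500,
                         incurrence_time_early=0.2, incurrence_time_delayed=1.2)),
                _sg("AMS", 300,
                    dict(u_wait=0.68, u_post_early=0.72, u_post_delayed=0.715, u_missed=0.60),
                    dict(t_early=0.2, t_delayed=0.2, t_death_counterfactual=15.0, t_death_early=15.0),
                    dict(direct_early=30000, direct_delayed=0,
                         indirect_patient_early=3000, indirect_patient_delayed=20000,
                         indirect_caregiver_early=1000, indirect_caregiver_delayed=3000,
                         incurrence_time_early=0.2, incurrence_time_delayed=0.2)),
            ],
        },
        {
            "name": "orthopedic_joint_replacement",
            "subgroups": [
                _sg("RWT", 40000,
                    dict(u_wait=0.55, u_post_early=0.75, u_post_delayed=0.73),
                    dict(t_early=0.3, t_delayed=1.8, t_death_counterfactual=14.0, t_death_early=14.0),
                    dict(direct_early=120000, direct_delayed=110000,
                         indirect_patient_early=20000, indirect_patient_delayed=30000,
                         indirect_caregiver_early=4000, indirect_caregiver_delayed=6000,
                         incurrence_time_early=0.3, incurrence_time_delayed=1.8)),
                _sg("AMS", 1500,
                    dict(u_wait=0.55, u_post_early=0.75, u_post_delayed=0.73, u_missed=0.50),
                    dict(t_early=0.3, t_delayed=0.3, t_death_counterfactual=14.0, t_death_early=14.0),
                    dict(direct_early=120000, direct_delayed=0,
                         indirect_patient_early=20000, indirect_patient_delayed=150000,
                         indirect_caregiver_early=4000, indirect_caregiver_delayed=25000,
                         incurrence_time_early=0.3, incurrence_time_delayed=0.3)),
            ],
        },
    ]


def _random_subgroup(rng: np.random.Generator, kind: str) -> dict:
    u_lo, u_hi = RANDOM_RANGES["utility"]
    w_lo, w_hi = RANDOM_RANGES["wait_gap_years"]
    s_lo, s_hi = RANDOM_RANGES["survival_years"]
    c_lo, c_hi = RANDOM_RANGES["cost"]

    u_post_early = rng.uniform(0.5, u_hi)
    u_wait = rng.uniform(u_lo, u_post_early)
    u_post_delayed = rng.uniform(u_wait, u_post_early)
    u_missed = rng.uniform(u_lo, u_wait)

    t_early = rng.uniform(0.05, 0.5)
    if kind == "RWT":
        t_delayed = t_early + rng.uniform(w_lo, w_hi)
    else:
        t_delayed = t_early
    if kind == "MA":
        t_death_cf = t_early
    else:
        t_death_cf = t_delayed + rng.uniform(s_lo, s_hi)
    t_death_early = t_death_cf + rng.uniform(0.0, 10.0) if kind != "MA" else (
        t_early + rng.uniform(s_lo, s_hi)
    )

    def cost():
        return float(rng.uniform(c_lo, c_hi))

    costs = dict(
        direct_early=cost(),
        direct_delayed=cost() if kind == "RWT" else 0.0,
        indirect_patient_early=cost() * 0.1,
        indirect_patient_delayed=cost() * 0.1 if kind != "MA" else 0.0,
        indirect_caregiver_early=cost() * 0.05,
        indirect_caregiver_delayed=cost() * 0.05 if kind != "MA" else 0.0,
        incurrence_time_early=t_early,
        incurrence_time_delayed=min(t_delayed, t_death_early),
    )
    utilities = dict(u_wait=u_wait, u_post_early=u_post_early, u_post_delayed=u_post_delayed)
    if kind == "AMS":
        utilities["u_missed"] = u_missed
    return _sg(
        kind,
        float(rng.integers(100, 50000)),
        utilities,
        dict(t_early=t_early, t_delayed=t_delayed,
             t_death_counterfactual=t_death_cf, t_death_early=t_death_early),
        costs,
    )


def generate_fixture(spec: FixtureSpec) -> ModelRun:
    """Generate a fully valid model run for the requested profile.

    The output is deterministic for a fixed spec (byte-identical when
    serialized).  ``egypt_like`` ignores ``n_cohorts`` beyond truncation;
    ``randomized`` draws ``n_cohorts`` cohorts from the documented ranges.
    """
    if spec.calibration_targets is not None:
        return generate_calibrated_fixture(*spec.calibration_targets, seed=spec.seed)
    if spec.profile == "egypt_like":
        cohorts = _egypt_like_cohorts()[: spec.n_cohorts]
    else:
        rng = np.random.default_rng(spec.seed)
        cohorts = [
            {
                "name": f"surgery_{i + 1}",
                "subgroups": [_random_subgroup(rng, k) for k in ("RWT", "AMS", "MA")],
            }
            for i in range(spec.n_cohorts)
        ]
    return ModelRun.model_validate(
        {
            "cohorts": cohorts,
            "discount": {"annual_rate": 0.035},
            "economy": dict(_DEFAULT_ECONOMY),
        }
    )


#: Relative tolerance to which calibrated population sums must reproduce
#: their targets when re-evaluated through the pipeline.
CALIBRATION_RTOL = 1e-4


def generate_calibrated_fixture(
    target_qalys: float, target_cost: float, seed: int = 0
) -> ModelRun:
    """A multi-cohort run whose population sums equal the given targets.

    Starts from the egypt_like profile, scales every patient count by a
    common factor so total ΔQALYs hit ``target_qalys`` (QALYs are linear
    in counts), then solves the one-dimensional linear equation for one
    direct-cost parameter (the first cohort's RWT ``direct_early``, or its
    ``direct_delayed`` when non-negativity forces the other side) so the
    societal cost sum hits ``target_cost``.  The result is verified by
    re-evaluating the full pipeline.
    """
    if target_qalys <= 0:
        raise ValueError("target_qalys must be positive")
    run = generate_fixture(FixtureSpec(seed=seed, profile="egypt_like"))
    base = evaluate_run(run)
    q0 = base.composite.total_delta_qalys
    if q0 <= 0:
        raise ValueError("base fixture has non-positive total QALYs; cannot scale")
    scale = target_qalys / q0

    data = run.model_dump(mode="python", exclude_none=True)
    for cdata in data["cohorts"]:
        for sdata in cdata["subgroups"]:
            sdata["n_patients"] *= scale
    run = ModelRun.model_validate(data)

    scaled = evaluate_run(run)
    c1 = scaled.composite.costs.delta_total_societal
    knob_sg = run.cohorts[0].subgroups[0]
    rate = run.discount.annual_rate
    deficit = target_cost - c1

    df_early = discount_lump(1.0, knob_sg.costs.incurrence_time_early, rate)
    x_new = knob_sg.costs.direct_early + deficit / (knob_sg.n_patients * df_early)
    data = run.model_dump(mode="python", exclude_none=True)
    knob = data["cohorts"][0]["subgroups"][0]["costs"]
    if x_new >= 0:
        knob["direct_early"] = x_new
    else:
        # raise the counterfactual cost instead: each extra unit lowers the sum
        df_del = discount_lump(1.0, knob_sg.costs.incurrence_time_delayed, rate)
        y_new = knob_sg.costs.direct_delayed - (
            deficit + knob_sg.n_patients * df_early * knob_sg.costs.direct_early
        ) / (knob_sg.n_patients * df_del)
        if y_new < 0:
            raise ValueError(
                "calibration targets unreachable under non-negative costs"
            )
        knob["direct_early"] = 0.0
        knob["direct_delayed"] = y_new
    run = ModelRun.model_validate(data)

    final = evaluate_run(run).composite
    for got, want, label in (
        (final.total_delta_qalys, target_qalys, "QALY"),
        (final.costs.delta_total_societal, target_cost, "cost"),
    ):
        if abs(got - want) > CALIBRATION_RTOL * max(abs(want), 1.0):
            raise ValueError(
                f"calibration failed to reproduce the {label} target: "
                f"got {got!r}, wanted {want!r}"
            )
    return run


def generate_expenditure_sample(
    log_mean: float, log_sd: float, n: int, seed: int = 0
) -> np.ndarray:
    """Draw ``n`` lognormal household annual expenditures (seeded)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if log_sd <= 0:
        raise ValueError("log_sd must be positive")
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=log_mean, sigma=log_sd, size=n)


def write_expenditure_file(
    values: np.ndarray, path: Union[str, pathlib.Path]
) -> pathlib.Path:
    """Write one expenditure per line (plain text)."""
    path = pathlib.Path(path)
    path.write_text("\n".join(f"{v:.6f}" for v in np.asarray(values)) + "\n")
    return path


__all__ = [
    "FixtureSpec",
    "RANDOM_RANGES",
    "generate_fixture",
    "generate_calibrated_fixture",
    "generate_expenditure_sample",
    "write_expenditure_file",
]
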