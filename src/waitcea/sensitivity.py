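"""Deterministic and probabilistic sensitivity analysis.

Parameters are addressed by slash paths into the model run::

    <cohort name>/<subgroup kind>/<block>/<field>
    <cohort name>/<subgroup kind>/n_patients

e.g. ``cochlear_implantation/RWT/costs/direct_early`` or
``open_heart_surgery/MA/timeline/t_early``.

One-way DSA re-evaluates the full pipeline with each parameter at
mean×(1−δ) and mean×(1+δ) (δ = 10% by default) and ranks parameters by
the width of the induced swing in the composite societal ICER (a tornado
diagram).  A perturbation that violates a structural invariant flags the
entry infeasible rather than silently clamping.

PSA assigns a probability distribution to every sampled parameter — beta
for utilities and proportions, normal for time variables, gamma for costs,
matched to (mean, standard error) by the method of moments — and runs
Monte Carlo (5000 draws by default), re-evaluating the composite
population outcome per draw.  Draws that invert the event timeline are
rejected and redrawn, with a logged count.  Patient counts are treated as
fixed unless a distribution is explicitly assigned to them.

Structural ties during sampling and perturbation: for a lifesaving (MA)
subgroup the counterfactual death date always tracks the early surgery
date (that equality is the scenario's defining assumption); a subgroup
whose base case has no survival gap (``t_death_counterfactual ==
t_death_early``) keeps that gap at zero — the absence of a mortality
effect is a scenario feature, so the counterfactual death date tracks the
early-arm one rather than being sampled or perturbed independently; and
the unused ``t_delayed`` of non-RWT subgroups is kept at ``t_early`` so
that bookkeeping fields never trigger rejections.  Explicitly addressing
a tied field overrides the tie (except the MA one, which is hard).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .config import (
    ModelRun,
    ScenarioKind,
    SubgroupKind,
    model_run_from_dict,
)
from .outcomes import evaluate_run

_BLOCKS = ("utilities", "timeline", "costs")

_TIME_FIELDS = {
    "t_early", "t_delayed", "t_death_early", "t_death_counterfactual",
    "incurrence_time_early", "incurrence_time_delayed",
}

#: Fields actually used by each scenario's formulas (others are bookkeeping).
_USED_FIELDS = {
    ScenarioKind.reduced_wait: {
        "utilities": ("u_wait", "u_post_early", "u_post_delayed"),
        "timeline": ("t_early", "t_delayed", "t_death_counterfactual", "t_death_early"),
        "costs": (
            "direct_early", "direct_delayed",
            "indirect_patient_early", "indirect_patient_delayed",
            "indirect_caregiver_early", "indirect_caregiver_delayed",
            "incurrence_time_early", "incurrence_time_delayed",
        ),
    },
    ScenarioKind.missed_surgery: {
        "utilities": ("u_missed", "u_post_early"),
        "timeline": ("t_early", "t_death_counterfactual", "t_death_early"),
        "costs": (
            "direct_early", "direct_delayed",
            "indirect_patient_early", "indirect_patient_delayed",
            "indirect_caregiver_early", "indirect_caregiver_delayed",
            "incurrence_time_early", "incurrence_time_delayed",
        ),
    },
    ScenarioKind.lifesaving: {
        "utilities": ("u_post_early",),
        "timeline": ("t_early", "t_death_early"),
        "costs": (
            "direct_early", "indirect_patient_early",
            "indirect_caregiver_early", "incurrence_time_early",
        ),
    },
}


# -- parameter paths ---------------------------------------------------------

def _split_path(path: str):
    parts = path.split("/")
    if len(parts) == 3 and parts[2] == "n_patients":
        return parts[0], parts[1], None, "n_patients"
    if len(parts) == 4 and parts[2] in _BLOCKS:
        return parts[0], parts[1], parts[2], parts[3]
    raise KeyError(
        f"malformed parameter path {path!r}; expected "
        "'<cohort>/<kind>/<block>/<field>' or '<cohort>/<kind>/n_patients'"
    )


def resolve_path(run: ModelRun, path: str) -> float:
    """Current value of the parameter addressed by ``path``."""
    cohort, kind, block, field = _split_path(path)
    sg = run.subgroup(cohort, kind)
    obj = sg if block is None else getattr(sg, block)
    value = getattr(obj, field)
    if value is None:
        raise KeyError(f"parameter {path!r} is unset")
    return float(value)


def with_path_set(run: ModelRun, path: str, value: float) -> ModelRun:
    """A new, revalidated model run with one parameter replaced.

    Applies the structural ties documented in the module docstring, then
    revalidates every invariant; an infeasible value raises
    ``ModelValidationError``.
    """
    cohort_name, kind, block, field = _split_path(path)
    run.subgroup(cohort_name, kind)  # raise KeyError early if absent
    data = run.model_dump(mode="python", exclude_none=True)
    for cdata in data["cohorts"]:
        if cdata["name"] != cohort_name:
            continue
        for sdata in cdata["subgroups"]:
            if sdata["kind"] != SubgroupKind(kind).value:
                continue
            target = sdata if block is None else sdata[block]
            tl = sdata["timeline"]
            no_gap = tl["t_death_counterfactual"] == tl["t_death_early"]
            target[field] = value
            if block == "timeline" and field == "t_early":
                if sdata["kind"] == SubgroupKind.MA.value:
                    tl["t_death_counterfactual"] = value
                    tl["t_delayed"] = value
                elif sdata["kind"] == SubgroupKind.AMS.value and tl["t_delayed"] < value:
                    tl["t_delayed"] = value
            if block == "timeline" and field == "t_death_early" and no_gap:
                if sdata["kind"] != SubgroupKind.MA.value:
                    tl["t_death_counterfactual"] = value
    return model_run_from_dict(data)


def list_parameter_paths(run: ModelRun, include_counts: bool = False) -> list[str]:
    """Enumerate the paths of all independent parameters of each subgroup.

    Fields that are structurally tied — the lifesaving counterfactual
    death date, or a counterfactual death date equal to the early-arm one
    (no survival gap) — are not independent and are omitted.
    """
    paths = []
    for cohort in run.cohorts:
        for sg in cohort.subgroups:
            prefix = f"{cohort.name}/{sg.kind.value}"
            used = _USED_FIELDS[sg.scenario]
            tied_cf = sg.timeline.t_death_counterfactual == sg.timeline.t_death_early
            if include_counts:
                paths.append(f"{prefix}/n_patients")
            for block in _BLOCKS:
                for field in used.get(block, ()):
                    if field == "t_death_counterfactual" and tied_cf:
                        continue
                    paths.append(f"{prefix}/{block}/{field}")
    return paths


# -- deterministic sensitivity analysis --------------------------------------

@dataclass
class DsaSpec:
    """Which parameters to vary, and by how much (relative ±δ)."""

    parameter_paths: list[str]
    relative_delta: float = 0.10

    def __post_init__(self):
        if not 0.0 < self.relative_delta < 1.0:
            raise ValueError("relative_delta must lie in (0, 1)")


@dataclass
class TornadoEntry:
    """One tornado bar: composite societal ICER at −δ and +δ."""

    parameter_path: str
    icer_low: float
    icer_high: float
    infeasible: bool = False

    @property
    def bar_width(self) -> float:
        if self.infeasible:
            return math.nan
        return abs(self.icer_high - self.icer_low)


@dataclass
class DsaResult:
    base_icer: float
    entries: list[TornadoEntry]


def run_dsa(run: ModelRun, spec: DsaSpec) -> DsaResult:
    """One-way ±δ sensitivity of the composite societal ICER.

    Each parameter is perturbed alone, the whole pipeline re-evaluated,
    and entries returned sorted by bar width, widest first (infeasible
    entries, where a perturbation breaks a timeline invariant, sort last).
    """
    base = evaluate_run(run).composite
    if not base.icer_societal.defined or base.icer_societal.value is None:
        raise ValueError("run_dsa requires a base case with positive incremental QALYs")
    base_icer = base.icer_societal.value

    entries: list[TornadoEntry] = []
    for path in spec.parameter_paths:
        value = resolve_path(run, path)
        icers = []
        infeasible = False
        for sign in (-1.0, +1.0):
            try:
                perturbed = with_path_set(run, path, value * (1.0 + sign * spec.relative_delta))
                res = evaluate_run(perturbed).composite.icer_societal
            except ValueError:
                infeasible = True
                icers.append(math.nan)
                continue
            icers.append(res.value if res.value is not None else math.nan)
        if any(math.isnan(x) for x in icers):
            infeasible = True
        entries.append(TornadoEntry(path, icers[0], icers[1], infeasible))

    entries.sort(key=lambda e: -1.0 if e.infeasible else e.bar_width, reverse=True)
    return DsaResult(base_icer=base_icer, entries=entries)


# -- distributions and moment matching ---------------------------------------

_FAMILIES = ("beta", "normal", "gamma")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling family plus first two moments for one parameter.

    ``spread`` is the standard error; a spread of 0 yields a point mass.
    """

    family: str
    mean: float
    spread: float

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        if self.spread < 0:
            raise ValueError("spread must be non-negative")


def moment_match(spec: DistributionSpec) -> dict:
    """Translate (mean, standard error) into sampler parameters.

    beta: method-of-moments shapes (requires spread² < mean·(1−mean));
    gamma: shape = mean²/spread², scale = spread²/mean; normal: identity.
    A zero spread always degenerates to a point mass at the mean.
    """
    if spec.spread == 0.0:
        return {"family": "degenerate", "value": spec.mean}
    var = spec.spread**2
    if spec.family == "beta":
        m = spec.mean
        if not 0.0 < m < 1.0:
            raise ValueError(f"beta mean must lie in (0, 1), got {m}")
        if var >= m * (1.0 - m):
            raise ValueError(
                f"beta moments infeasible: spread² ({var:g}) must be below "
                f"mean·(1−mean) ({m * (1 - m):g})"
            )
        nu = m * (1.0 - m) / var - 1.0
        return {"family": "beta", "a": m * nu, "b": (1.0 - m) * nu}
    if spec.family == "gamma":
        if spec.mean <= 0.0:
            raise ValueError(f"gamma mean must be positive, got {spec.mean}")
        return {"family": "gamma", "shape": spec.mean**2 / var, "scale": var / spec.mean}
    return {"family": "normal", "loc": spec.mean, "scale": spec.spread}


def _sample(rng: np.random.Generator, params: dict, size: int) -> np.ndarray:
    fam = params["family"]
    if fam == "degenerate":
        return np.full(size, params["value"], dtype=float)
    if fam == "beta":
        return rng.beta(params["a"], params["b"], size)
    if fam == "gamma":
        return rng.gamma(params["shape"], params["scale"], size)
    return rng.normal(params["loc"], params["scale"], size)


def family_for_path(path: str) -> str:
    """Conventional family assignment: beta for utilities and proportions,
    normal for time variables, gamma for monetary amounts."""
    _, _, block, field = _split_path(path)
    if block == "utilities":
        return "beta"
    if field in _TIME_FIELDS or field == "n_patients":
        return "normal"
    return "gamma"


#: Default parameter standard error as a fraction of the mean when no
#: uncertainty magnitude is supplied.
DEFAULT_SPREAD_FRACTION = 0.10


def default_distributions(
    run: ModelRun,
    spread_fraction: float = DEFAULT_SPREAD_FRACTION,
    paths: Optional[list[str]] = None,
) -> dict[str, DistributionSpec]:
    """Assign a distribution to every used parameter (counts stay fixed).

    The spread defaults to ``spread_fraction`` of each mean.  The tied MA
    counterfactual death date is never sampled.
    """
    if paths is None:
        paths = list_parameter_paths(run, include_counts=False)
    dists: dict[str, DistributionSpec] = {}
    for path in paths:
        cohort, kind, block, field = _split_path(path)
        if field == "t_death_counterfactual":
            sg = run.subgroup(cohort, kind)
            tied = (
                SubgroupKind(kind) is SubgroupKind.MA
                or sg.timeline.t_death_counterfactual == sg.timeline.t_death_early
            )
            if tied:
                continue
        mean = resolve_path(run, path)
        spec = DistributionSpec(family_for_path(path), mean, spread_fraction * mean)
        try:
            moment_match(spec)
        except ValueError as exc:
            raise ValueError(f"parameter {path!r}: {exc}") from exc
        dists[path] = spec
    return dists


# -- probabilistic sensitivity analysis --------------------------------------

@dataclass
class PsaResult:
    """Draw-level composite outcomes of a Monte Carlo PSA."""

    n_draws: int
    seed: int
    delta_qalys: np.ndarray          # population ΔQALYs per draw
    delta_cost_societal: np.ndarray  # population societal Δcost per draw
    delta_cost_payer: np.ndarray
    wtp: float
    n_rejected: int = 0

    @property
    def mean_delta_qalys(self) -> float:
        return float(np.mean(self.delta_qalys))

    @property
    def mean_delta_cost(self) -> float:
        return float(np.mean(self.delta_cost_societal))

    @property
    def icer_of_means(self) -> float:
        """Composite ICER formed from mean Δcost over mean ΔQALYs.

        Per-draw ICERs are deliberately never averaged: they blow up when a
        draw's ΔQALYs is near zero.
        """
        return self.mean_delta_cost / self.mean_delta_qalys

    @property
    def net_monetary_benefit(self) -> np.ndarray:
        return self.delta_qalys * self.wtp - self.delta_cost_societal

    def fraction_cost_effective(self, wtp: Optional[float] = None) -> float:
        """Share of draws with non-negative net monetary benefit at ``wtp``."""
        wtp = self.wtp if wtp is None else wtp
        return float(np.mean(self.delta_qalys * wtp - self.delta_cost_societal >= 0.0))

    def ceac(self, wtp_grid: np.ndarray) -> np.ndarray:
        """Cost-effectiveness acceptability curve over a WTP grid."""
        return np.array([self.fraction_cost_effective(w) for w in np.asarray(wtp_grid)])


def _subgroup_param_arrays(sg, sampled: dict[str, np.ndarray], prefix: str, n: int):
    """Effective parameter arrays for one subgroup, ties applied."""

    def get(block, field, base):
        return sampled.get(f"{prefix}/{block}/{field}", base)

    u, tl, c = sg.utilities, sg.timeline, sg.costs
    p = {
        "u_wait": get("utilities", "u_wait", u.u_wait),
        "u_post_early": get("utilities", "u_post_early", u.u_post_early),
        "u_post_delayed": get("utilities", "u_post_delayed", u.u_post_delayed),
        "u_missed": get("utilities", "u_missed", u.u_missed),
        "t_early": get("timeline", "t_early", tl.t_early),
        "t_delayed": get("timeline", "t_delayed", tl.t_delayed),
        "t_death_counterfactual": get("timeline", "t_death_counterfactual", tl.t_death_counterfactual),
        "t_death_early": get("timeline", "t_death_early", tl.t_death_early),
        "direct_early": get("costs", "direct_early", c.direct_early),
        "direct_delayed": get("costs", "direct_delayed", c.direct_delayed),
        "indirect_patient_early": get("costs", "indirect_patient_early", c.indirect_patient_early),
        "indirect_patient_delayed": get("costs", "indirect_patient_delayed", c.indirect_patient_delayed),
        "indirect_caregiver_early": get("costs", "indirect_caregiver_early", c.indirect_caregiver_early),
        "indirect_caregiver_delayed": get("costs", "indirect_caregiver_delayed", c.indirect_caregiver_delayed),
        "incurrence_time_early": get("costs", "incurrence_time_early", c.incurrence_time_early),
        "incurrence_time_delayed": get("costs", "incurrence_time_delayed", c.incurrence_time_delayed),
        "n_patients": sampled.get(f"{prefix}/n_patients", sg.n_patients),
    }
    if sg.kind is SubgroupKind.MA:
        p["t_death_counterfactual"] = p["t_early"]
    elif (
        tl.t_death_counterfactual == tl.t_death_early
        and f"{prefix}/timeline/t_death_counterfactual" not in sampled
    ):
        p["t_death_counterfactual"] = p["t_death_early"]
    if sg.kind is not SubgroupKind.RWT and f"{prefix}/timeline/t_delayed" not in sampled:
        p["t_delayed"] = p["t_early"]
    return p


def _invalid_mask(p: dict, n: int) -> np.ndarray:
    """Draws whose sampled parameters violate a structural invariant."""
    def arr(x):
        return np.broadcast_to(np.asarray(x, dtype=float), (n,))

    t_e, t_d = arr(p["t_early"]), arr(p["t_delayed"])
    t_cf, t_de = arr(p["t_death_counterfactual"]), arr(p["t_death_early"])
    bad = (t_e < 0) | (t_e > t_d) | (t_d > t_cf) | (t_cf > t_de)
    for f in ("incurrence_time_early", "incurrence_time_delayed"):
        t = arr(p[f])
        bad |= (t < 0) | (t > t_de)
    for f in ("u_wait", "u_post_early", "u_post_delayed", "u_missed"):
        if p[f] is None:
            continue
        u = arr(p[f])
        bad |= (u < -1.0) | (u > 1.0)
    bad |= arr(p["n_patients"]) < 0
    return bad


def run_psa(
    run: ModelRun,
    dists: dict[str, DistributionSpec],
    n_draws: int = 5000,
    seed: int = 0,
) -> PsaResult:
    """Monte Carlo PSA of the composite population outcome.

    All parameters are sampled independently; each draw re-evaluates the
    composite population ΔQALYs and Δcost through the same closed-form
    kernels as the deterministic pipeline (vectorised across draws).
    Identical ``(seed, n_draws, dists)`` reproduce bit-identical results.
    Draws violating a timeline invariant are rejected and redrawn in full;
    a rejection rate above 50% aborts with a diagnostic naming the most
    frequently violating parameter.
    """
    from .costs import _cost_deltas
    from .qaly import (
        _segments_lifesaving,
        _segments_missed_surgery,
        _segments_reduced_wait,
    )

    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    for path, spec in dists.items():
        _, kind, block, field = _split_path(path)
        if SubgroupKind(kind) is SubgroupKind.MA and field == "t_death_counterfactual":
            raise ValueError(
                f"parameter {path!r} cannot be sampled: the lifesaving scenario "
                "ties the counterfactual death date to the early surgery date"
            )
        try:
            moment_match(spec)
        except ValueError as exc:
            raise ValueError(f"parameter {path!r}: {exc}") from exc
        resolve_path(run, path)  # every sampled path must resolve

    rng = np.random.default_rng(seed)
    matched = {path: moment_match(spec) for path, spec in dists.items()}
    sampled = {path: _sample(rng, params, n_draws) for path, params in matched.items()}

    subgroups = [
        (f"{cohort.name}/{sg.kind.value}", sg)
        for cohort in run.cohorts
        for sg in cohort.subgroups
    ]

    n_rejected = 0
    violations: dict[str, int] = {}
    max_rounds = 1000
    for _ in range(max_rounds):
        invalid = np.zeros(n_draws, dtype=bool)
        for prefix, sg in subgroups:
            p = _subgroup_param_arrays(sg, sampled, prefix, n_draws)
            bad = _invalid_mask(p, n_draws)
            if bad.any():
                for path in sampled:
                    if path.startswith(prefix + "/"):
                        violations[path] = violations.get(path, 0) + int(bad.sum())
            invalid |= bad
        n_bad = int(invalid.sum())
        if n_bad == 0:
            break
        n_rejected += n_bad
        if n_rejected > max(n_draws, 20):
            worst = max(violations, key=violations.get) if violations else "<unknown>"
            raise RuntimeError(
                f"PSA rejection rate exceeded 50% ({n_rejected} rejections for "
                f"{n_draws} draws); worst-offending parameter: {worst}"
            )
        idx = np.nonzero(invalid)[0]
        for path, params in matched.items():
            sampled[path][idx] = _sample(rng, params, idx.size)
    else:
        raise RuntimeError("PSA rejection sampling failed to converge")

    dq = np.zeros(n_draws)
    dc_soc = np.zeros(n_draws)
    dc_pay = np.zeros(n_draws)
    for prefix, sg in subgroups:
        p = _subgroup_param_arrays(sg, sampled, prefix, n_draws)
        rate = run.discount.annual_rate
        if sg.scenario is ScenarioKind.reduced_wait:
            segs = _segments_reduced_wait(
                p["u_wait"], p["u_post_early"], p["u_post_delayed"],
                p["t_early"], p["t_delayed"], p["t_death_counterfactual"],
                p["t_death_early"], rate,
            )
        elif sg.scenario is ScenarioKind.missed_surgery:
            segs = _segments_missed_surgery(
                p["u_missed"], p["u_post_early"],
                p["t_early"], p["t_death_counterfactual"], p["t_death_early"], rate,
            )
        else:
            segs = _segments_lifesaving(
                p["u_post_early"], p["t_early"], p["t_death_early"], rate
            )
        qpp = sum(segs.values())
        cb = _cost_deltas(
            p["direct_early"], p["direct_delayed"],
            p["indirect_patient_early"], p["indirect_patient_delayed"],
            p["indirect_caregiver_early"], p["indirect_caregiver_delayed"],
            p["incurrence_time_early"], p["incurrence_time_delayed"],
            rate, sg.scenario,
        )
        n_pat = p["n_patients"]
        dq = dq + qpp * n_pat
        dc_soc = dc_soc + cb.delta_total_societal * n_pat
        dc_pay = dc_pay + cb.delta_total_payer * n_pat

    return PsaResult(
        n_draws=n_draws,
        seed=seed,
        delta_qalys=np.broadcast_to(dq, (n_draws,)).copy(),
        delta_cost_societal=np.broadcast_to(dc_soc, (n_draws,)).copy(),
        delta_cost_payer=np.broadcast_to(dc_pay, (n_draws,)).copy(),
        wtp=run.economy.wtp_threshold,
        n_rejected=n_rejected,
    )
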