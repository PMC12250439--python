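"""Parameter data model and configuration I/O.

A full model run — every surgery cohort, its patient subgroups, utilities,
event timelines, cost items, the discount rate and the economy settings —
is described by one declarative YAML document.  This module defines the
validated data model (pydantic), loads and serializes such documents, and
is the single source of truth for structural invariants used by every
downstream computation.

Schema sketch (``schema_version: 1``)::

    schema_version: 1
    discount: {annual_rate: 0.035}
    economy: {gdp_per_capita: 56000, wtp_threshold: 56000, currency_label: EGP}
    cohorts:
      - name: open_heart_surgery
        subgroups:
          - kind: RWT                 # or AMS / MA
            n_patients: 20000
            utilities: {u_wait: 0.6, u_post_early: 0.8, u_post_delayed: 0.78}
            timeline:  {t_early: 0.2, t_delayed: 1.5,
                        t_death_counterfactual: 18.0, t_death_early: 19.0}
            costs:     {direct_early: 230000, direct_delayed: 200000,
                        indirect_patient_early: 15000, ...,
                        incurrence_time_early: 0.2, incurrence_time_delayed: 1.5}

Subgroup kinds map one-to-one onto scenarios: RWT (reduced waiting time)
-> ``reduced_wait``, AMS (avoided missed surgery) -> ``missed_surgery``,
MA (mortality averted) -> ``lifesaving``.  The ``scenario`` key may be
given explicitly but must agree with the kind.
"""

from __future__ import annotations

import enum
import math
import pathlib
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

SCHEMA_VERSION = 1

#: Annual discount rate applied to both costs and QALYs when the config
#: omits the ``discount`` block (3.5%/year, the conventional national
#: guideline value the base case uses).
DEFAULT_DISCOUNT_RATE = 0.035


class ConfigError(ValueError):
    """Raised when a configuration file cannot be parsed or fails validation."""


class ModelValidationError(ValueError):
    """Raised when model parameters violate a structural invariant."""


class ScenarioKind(str, enum.Enum):
    """Which incremental pathway comparison a subgroup follows."""

    reduced_wait = "reduced_wait"
    missed_surgery = "missed_surgery"
    lifesaving = "lifesaving"


class SubgroupKind(str, enum.Enum):
    """Clinical subgroup labels: reduced waiting time, avoided missed
    surgery, mortality averted."""

    RWT = "RWT"
    AMS = "AMS"
    MA = "MA"


#: Enforced one-to-one mapping between subgroup kind and scenario.
SCENARIO_FOR_KIND = {
    SubgroupKind.RWT: ScenarioKind.reduced_wait,
    SubgroupKind.AMS: ScenarioKind.missed_surgery,
    SubgroupKind.MA: ScenarioKind.lifesaving,
}


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DiscountSettings(_Model):
    """Annual discount rate applied to both QALYs and costs."""

    annual_rate: float = Field(default=DEFAULT_DISCOUNT_RATE, ge=0.0, lt=1.0)


class UtilityProfile(_Model):
    """Health-state utilities for one subgroup.

    ``u_wait`` is the utility while on the waiting list and already folds
    in any pre-operative stress decrement; ``u_missed`` is the utility of
    living without the surgery and is required only for missed-surgery
    subgroups.
    """

    u_wait: float = Field(ge=-1.0, le=1.0)
    u_post_early: float = Field(ge=-1.0, le=1.0)
    u_post_delayed: float = Field(ge=-1.0, le=1.0)
    u_missed: Optional[float] = Field(default=None, ge=-1.0, le=1.0)


class Timeline(_Model):
    """Event times in years from model start.

    ``t_death_counterfactual`` is death in the delayed/missed/no-surgery
    arm; for the lifesaving scenario it must coincide with ``t_early``
    (the counterfactual patient is assumed to die on the scheduled early
    surgery date).
    """

    t_early: float = Field(ge=0.0)
    t_delayed: float = Field(ge=0.0)
    t_death_early: float = Field(ge=0.0)
    t_death_counterfactual: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _ordering(self) -> "Timeline":
        if self.t_early > self.t_delayed:
            raise ValueError(
                f"Timeline: t_early ({self.t_early}) must not exceed "
                f"t_delayed ({self.t_delayed})"
            )
        if self.t_delayed > self.t_death_counterfactual:
            raise ValueError(
                f"Timeline: t_delayed ({self.t_delayed}) must not exceed "
                f"t_death_counterfactual ({self.t_death_counterfactual})"
            )
        if self.t_death_counterfactual > self.t_death_early:
            raise ValueError(
                f"Timeline: t_death_counterfactual ({self.t_death_counterfactual}) "
                f"must not exceed t_death_early ({self.t_death_early})"
            )
        return self


class CostSet(_Model):
    """Per-patient lump-sum costs (currency units) and their incurrence times.

    Each component exists in an "early" and a counterfactual ("delayed")
    variant; the engine discounts each lump to present value at its
    incurrence time.  ``direct_delayed`` defaults to 0 so that
    missed-surgery subgroups — where no counterfactual operation happens —
    need not state it, while remaining overridable (e.g. ongoing palliative
    care in the counterfactual arm).
    """

    direct_early: float = Field(ge=0.0)
    direct_delayed: float = Field(default=0.0, ge=0.0)
    indirect_patient_early: float = Field(default=0.0, ge=0.0)
    indirect_patient_delayed: float = Field(default=0.0, ge=0.0)
    indirect_caregiver_early: float = Field(default=0.0, ge=0.0)
    indirect_caregiver_delayed: float = Field(default=0.0, ge=0.0)
    incurrence_time_early: float = Field(default=0.0, ge=0.0)
    incurrence_time_delayed: float = Field(default=0.0, ge=0.0)


class SubgroupParameters(_Model):
    """All parameters for one clinical subgroup of one surgery cohort."""

    kind: SubgroupKind
    scenario: Optional[ScenarioKind] = None
    n_patients: float = Field(ge=0.0)
    utilities: UtilityProfile
    timeline: Timeline
    costs: CostSet

    @model_validator(mode="after")
    def _cross_checks(self) -> "SubgroupParameters":
        expected = SCENARIO_FOR_KIND[self.kind]
        if self.scenario is None:
            object.__setattr__(self, "__dict__", {**self.__dict__, "scenario": expected})
        elif self.scenario != expected:
            raise ValueError(
                f"SubgroupParameters: kind {self.kind.value} requires scenario "
                f"{expected.value}, got {self.scenario.value}"
            )
        if self.kind is SubgroupKind.AMS and self.utilities.u_missed is None:
            raise ValueError(
                "SubgroupParameters: missed-surgery (AMS) subgroup requires "
                "utilities.u_missed"
            )
        if self.kind is SubgroupKind.MA:
            tl = self.timeline
            if not math.isclose(
                tl.t_death_counterfactual, tl.t_early, rel_tol=0.0, abs_tol=1e-12
            ):
                raise ValueError(
                    "SubgroupParameters: lifesaving (MA) subgroup assumes death in "
                    "the no-surgery arm coincides with the scheduled early surgery "
                    f"date; t_death_counterfactual ({tl.t_death_counterfactual}) "
                    f"must equal t_early ({tl.t_early})"
                )
        for label in ("incurrence_time_early", "incurrence_time_delayed"):
            t = getattr(self.costs, label)
            if t > self.timeline.t_death_early:
                raise ValueError(
                    f"CostSet: {label} ({t}) lies beyond t_death_early "
                    f"({self.timeline.t_death_early})"
                )
        return self


class SurgeryCohort(_Model):
    """One surgical intervention with its patient subgroups."""

    name: str = Field(min_length=1)
    subgroups: list[SubgroupParameters] = Field(min_length=1)

    @model_validator(mode="after")
    def _unique_kinds(self) -> "SurgeryCohort":
        kinds = [sg.kind for sg in self.subgroups]
        if len(set(kinds)) != len(kinds):
            raise ValueError(
                f"SurgeryCohort '{self.name}': subgroup kinds must be unique, "
                f"got {[k.value for k in kinds]}"
            )
        return self


class EconomySettings(_Model):
    """Economy-wide valuation inputs: GDP per capita (for the benefit–cost
    ratio) and the willingness-to-pay threshold per QALY."""

    gdp_per_capita: float = Field(gt=0.0)
    wtp_threshold: float = Field(gt=0.0)
    currency_label: str = "EGP"


class ModelRun(_Model):
    """A fully specified model run: cohorts plus global settings."""

    schema_version: int = SCHEMA_VERSION
    cohorts: list[SurgeryCohort] = Field(min_length=1)
    discount: DiscountSettings = Field(default_factory=DiscountSettings)
    economy: EconomySettings

    def subgroup(self, cohort_name: str, kind: Union[SubgroupKind, str]) -> SubgroupParameters:
        """Look up one subgroup by cohort name and kind."""
        kind = SubgroupKind(kind)
        for cohort in self.cohorts:
            if cohort.name == cohort_name:
                for sg in cohort.subgroups:
                    if sg.kind is kind:
                        return sg
                raise KeyError(f"cohort '{cohort_name}' has no {kind.value} subgroup")
        raise KeyError(f"no cohort named '{cohort_name}'")


def _format_pydantic_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def model_run_from_dict(data: dict) -> ModelRun:
    """Validate a raw mapping into a :class:`ModelRun`.

    Raises :class:`ModelValidationError` naming the offending field and rule.
    """
    try:
        return ModelRun.model_validate(data)
    except ValidationError as exc:
        raise ModelValidationError(_format_pydantic_error(exc)) from exc


def load_model_run(path: Union[str, pathlib.Path]) -> ModelRun:
    """Load and fully validate a model-run configuration file (YAML).

    Parse failures raise :class:`ConfigError` carrying the YAML position;
    invariant violations raise :class:`ModelValidationError` naming the
    field and the violated rule.  The discount block may be omitted, in
    which case the 3.5%/year default applies.
    """
    path = pathlib.Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read configuration file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ConfigError(f"cannot parse {path}{where}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(data).__name__}")
    return model_run_from_dict(data)


def serialize_model_run(run: ModelRun) -> str:
    """Render a model run back to its canonical YAML form (lossless)."""
    data = run.model_dump(mode="json", exclude_none=True)
    return yaml.safe_dump(data, sort_keys=False, default_flow_style=False)


def dump_model_run(run: ModelRun, path: Union[str, pathlib.Path]) -> pathlib.Path:
    """Write a model run to ``path`` as YAML; returns the path."""
    path = pathlib.Path(path)
    path.write_text(serialize_model_run(run))
    return path


def validate_model_run(run: ModelRun) -> list[str]:
    """Return soft warnings for a structurally valid run.

    Hard invariants are enforced at construction time; this reports
    consistency smells that are legal but usually indicate mistaken
    inputs (e.g. waiting-list utility above post-surgery utility).
    """
    warnings: list[str] = []
    for cohort in run.cohorts:
        for sg in cohort.subgroups:
            where = f"{cohort.name}/{sg.kind.value}"
            u = sg.utilities
            if u.u_wait > u.u_post_early:
                warnings.append(
                    f"{where}: u_wait ({u.u_wait}) exceeds u_post_early "
                    f"({u.u_post_early}); waiting is usually worse than the "
                    "post-surgery state"
                )
            if sg.kind is SubgroupKind.MA:
                c = sg.costs
                nonzero = [
                    f
                    for f in (
                        "direct_delayed",
                        "indirect_patient_delayed",
                        "indirect_caregiver_delayed",
                    )
                    if getattr(c, f) > 0
                ]
                if nonzero:
                    warnings.append(
                        f"{where}: lifesaving scenario ignores counterfactual "
                        f"cost components, but {', '.join(nonzero)} are nonzero"
                    )
            if sg.kind is not SubgroupKind.AMS and u.u_missed is not None:
                warnings.append(f"{where}: u_missed is set but unused outside AMS")
    return warnings
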