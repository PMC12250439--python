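"""Result writers: CSV/JSON tables, run manifest, and best-effort plots.

Numeric CSVs are the canonical, byte-reproducible output surface; the
tornado and cost-effectiveness-plane images are rendering conveniences
and are never compared numerically.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .config import ModelRun, serialize_model_run
from .outcomes import OutcomeSet, RunResults
from .sensitivity import DsaResult, PsaResult

_SEGMENT_ORDER = ("A", "B", "C", "V", "W", "X")


@dataclass
class RunManifest:
    """Audit record of one tool invocation."""

    tool_version: str
    config_checksum: str
    seeds: dict[str, int] = field(default_factory=dict)
    created_utc: str = ""
    emitted_files: list[str] = field(default_factory=list)

    def write(self, path: Union[str, pathlib.Path]) -> pathlib.Path:
        path = pathlib.Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
        return path


def config_checksum(run: ModelRun) -> str:
    """SHA-256 of the canonical serialized configuration."""
    return hashlib.sha256(serialize_model_run(run).encode()).hexdigest()


def new_manifest(run: ModelRun, seeds: Optional[dict[str, int]] = None) -> RunManifest:
    return RunManifest(
        tool_version=__version__,
        config_checksum=config_checksum(run),
        seeds=seeds or {},
        created_utc=datetime.now(timezone.utc).isoformat(),
    )


def _outcome_row(o: OutcomeSet, variant: str) -> dict:
    n = o.n_patients
    row = {
        "label": o.label,
        "variant": variant,
        "n_patients": n,
        "delta_qalys_population": o.total_delta_qalys,
        "delta_direct_population": o.costs.delta_direct,
        "delta_indirect_patient_population": o.costs.delta_indirect_patient,
        "delta_indirect_caregiver_population": o.costs.delta_indirect_caregiver,
        "delta_total_societal_population": o.costs.delta_total_societal,
        "delta_total_payer_population": o.costs.delta_total_payer,
        "delta_qalys_per_patient": o.total_delta_qalys / n if n else np.nan,
        "delta_total_societal_per_patient": o.costs.delta_total_societal / n if n else np.nan,
        "icer_societal": o.icer_societal.value,
        "icer_societal_rounded": o.icer_societal.rounded,
        "icer_payer": o.icer_payer.value,
        "icer_payer_rounded": o.icer_payer.rounded,
        "bcr_societal": o.bcr_societal.value,
        "bcr_cost_saving": o.bcr_societal.cost_saving,
        "dominance": o.dominance_flag.value,
        "cost_effective_at_wtp": o.cost_effective_at_wtp,
        "net_monetary_benefit": o.net_monetary_benefit,
    }
    for seg in _SEGMENT_ORDER:
        row[f"segment_{seg}_qalys_population"] = o.segment_totals.get(seg, 0.0)
    return row


def results_frame(discounted: RunResults, undiscounted: Optional[RunResults] = None) -> pd.DataFrame:
    """Tabulate per-cohort and composite outcomes, one row per variant."""
    rows = []
    for variant, res in (("discounted", discounted), ("undiscounted", undiscounted)):
        if res is None:
            continue
        for o in res.per_cohort:
            rows.append(_outcome_row(o, variant))
        rows.append(_outcome_row(res.composite, variant))
    return pd.DataFrame(rows)


def write_results_csv(
    discounted: RunResults,
    path: Union[str, pathlib.Path],
    undiscounted: Optional[RunResults] = None,
) -> pathlib.Path:
    path = pathlib.Path(path)
    results_frame(discounted, undiscounted).to_csv(path, index=False, float_format="%.10g")
    return path


def summary_dict(res: RunResults) -> dict:
    """Compact JSON-ready summary of the composite outcome."""
    c = res.composite

    def num(x):
        return None if x is None else float(x)

    return {
        "total_delta_qalys": num(c.total_delta_qalys),
        "delta_total_societal": num(c.costs.delta_total_societal),
        "delta_total_payer": num(c.costs.delta_total_payer),
        "icer_societal": num(c.icer_societal.value),
        "icer_payer": num(c.icer_payer.value),
        "bcr_societal": num(c.bcr_societal.value),
        "dominance": c.dominance_flag.value,
        "cost_effective_at_wtp": bool(c.cost_effective_at_wtp),
    }


def dsa_frame(dsa: DsaResult) -> pd.DataFrame:
    rows = [
        {
            "parameter_path": e.parameter_path,
            "icer_low": e.icer_low,
            "icer_high": e.icer_high,
            "bar_width": e.bar_width,
            "infeasible": e.infeasible,
        }
        for e in dsa.entries
    ]
    return pd.DataFrame(rows)


def write_dsa_csv(dsa: DsaResult, path: Union[str, pathlib.Path]) -> pathlib.Path:
    path = pathlib.Path(path)
    dsa_frame(dsa).to_csv(path, index=False, float_format="%.10g")
    return path


def psa_frame(psa: PsaResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seed": psa.seed,
            "draw": np.arange(psa.n_draws),
            "delta_qalys": psa.delta_qalys,
            "delta_cost_societal": psa.delta_cost_societal,
            "delta_cost_payer": psa.delta_cost_payer,
            "net_monetary_benefit": psa.net_monetary_benefit,
        }
    )


def write_psa_csv(psa: PsaResult, path: Union[str, pathlib.Path]) -> pathlib.Path:
    path = pathlib.Path(path)
    psa_frame(psa).to_csv(path, index=False, float_format="%.10g")
    return path


def write_che_csv(rows: list[dict], path: Union[str, pathlib.Path]) -> pathlib.Path:
    path = pathlib.Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    return path


# -- plots (best effort) -----------------------------------------------------

def plot_tornado(dsa: DsaResult, path: Union[str, pathlib.Path], top: int = 15) -> pathlib.Path:
    """Horizontal tornado diagram of the widest ICER swings."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = [e for e in dsa.entries if not e.infeasible][:top][::-1]
    fig, ax = plt.subplots(figsize=(9, max(3, 0.4 * len(entries))))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(i, hi - lo, left=lo, color="#4878b0")
    ax.axvline(dsa.base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.parameter_path for e in entries], fontsize=7)
    ax.set_xlabel("composite societal ICER")
    ax.legend()
    fig.tight_layout()
    path = pathlib.Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_ce_plane(psa: PsaResult, path: Union[str, pathlib.Path]) -> pathlib.Path:
    """Cost-effectiveness plane scatter: incremental QALYs vs incremental cost."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(psa.delta_qalys, psa.delta_cost_societal, s=4, alpha=0.35)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    xs = np.linspace(*ax.get_xlim(), 10)
    ax.plot(xs, xs * psa.wtp, "r--", lw=1, label=f"WTP = {psa.wtp:g}/QALY")
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (societal)")
    ax.legend()
    fig.tight_layout()
    path = pathlib.Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
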