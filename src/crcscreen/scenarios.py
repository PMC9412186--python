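"""Scenario analysis: regional costs, earlier start age, incomplete cure.

Three presets derive from a base parameter set:

* ``shenzhen`` — region-specific CRC treatment costs and locally adjusted
  prevalence;
* ``start40`` — cohort enters the model at age 40 (horizon extends to 36
  cycles with the default exit at 75);
* ``incomplete_treatment`` — diagnosed cancer keeps progressing, with the
  post-diagnosis channels installed and the lineage-split ``scenario3``
  state space engaged.

``apply_scenario`` is pure: the base parameter set is never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .cea import icer_matrix, run_strategy_suite
from .economics import OutcomeSummary
from .parameters import (
    POST_DIAGNOSIS_KEYS,
    PREVALENCE_KEYS,
    ParameterSet,
    UncertainParameter,
)

__all__ = ["ScenarioSpec", "SCENARIO_IDS", "apply_scenario", "run_scenario_suite", "counters_frame"]

SCENARIO_IDS = ("shenzhen", "start40", "incomplete_treatment")


@dataclass
class ScenarioSpec:
    """A named scenario: parameter overrides plus the state-space variant."""

    id: str
    overrides: dict[str, Any] = field(default_factory=dict)
    variant: str = "base"


def _as_uncertain(node: Any, family: str) -> UncertainParameter:
    from .parameters import _parse_uncertain  # shared schema parsing

    return _parse_uncertain(node, "scenario override", family, "reference_placeholder")


def apply_scenario(base: ParameterSet, spec: ScenarioSpec | str) -> tuple[ParameterSet, str]:
    """Return a scenario-adjusted copy of ``base`` and the variant to run.

    String ids resolve through the parameter file's ``scenarios`` block.
    """
    if isinstance(spec, str):
        spec = build_scenario_spec(base, spec)
    params = base.copy()
    variant = spec.variant
    for path, value in spec.overrides.items():
        if path == "cohort.start_age":
            params.start_age = int(value)
        elif path == "cohort.end_age":
            params.end_age = int(value)
        elif path.startswith("transitions.post_diagnosis."):
            key = path.rsplit(".", 1)[1]
            if key not in POST_DIAGNOSIS_KEYS:
                raise KeyError(f"unknown post-diagnosis channel {key!r}")
            params.transitions.post_diagnosis[key] = _as_uncertain(value, "beta")
        elif isinstance(value, dict):
            # replace the full parameter (value + bounds) at an existing path
            fam = base.get_parameter(path).spec.family
            _replace_leaf(params, path, _as_uncertain(value, fam))
        else:
            params.set_value(path, float(value))
    params.validate()
    return params, variant


def _replace_leaf(params: ParameterSet, path: str, new: UncertainParameter) -> None:
    parts = path.split(".")
    containers = {
        "costs": params.costs.entries,
        "utilities": params.utilities.by_state,
        "prevalence": params.prevalence,
        "visits": params.visits.by_stage,
    }
    if parts[0] in containers and len(parts) == 2:
        d = containers[parts[0]]
        if parts[1] not in d:
            raise KeyError(f"no parameter at path {path!r}")
        d[parts[1]] = new
        return
    if parts[0] == "transitions" and len(parts) == 3:
        table = getattr(params.transitions, parts[1], None)
        if isinstance(table, dict) and parts[2] in table:
            table[parts[2]] = new
            return
    raise KeyError(f"cannot replace parameter at path {path!r}")


def build_scenario_spec(base: ParameterSet, scenario_id: str) -> ScenarioSpec:
    """Materialize a preset from the parameter file's ``scenarios`` block."""
    if scenario_id not in SCENARIO_IDS:
        raise KeyError(f"unknown scenario {scenario_id!r} (expected one of {SCENARIO_IDS})")
    block = base.scenario_data.get(scenario_id, {})
    overrides: dict[str, Any] = {}
    if scenario_id == "shenzhen":
        for key, node in block.get("costs", {}).items():
            overrides[f"costs.{key}"] = node
        for key, node in block.get("prevalence", {}).items():
            if key not in PREVALENCE_KEYS:
                raise KeyError(f"unknown prevalence key {key!r} in shenzhen scenario")
            overrides[f"prevalence.{key}"] = node
        return ScenarioSpec("shenzhen", overrides, "base")
    if scenario_id == "start40":
        overrides["cohort.start_age"] = block.get("start_age", 40)
        return ScenarioSpec("start40", overrides, "base")
    # incomplete_treatment
    post = block.get("post_diagnosis", {})
    for key, node in post.items():
        overrides[f"transitions.post_diagnosis.{key}"] = node
    return ScenarioSpec("incomplete_treatment", overrides, "scenario3")


def run_scenario_suite(
    base: ParameterSet,
    scenario_ids: list[str] | None = None,
    strategy_ids: list[str] | None = None,
) -> dict[str, dict[str, Any]]:
    """Run every strategy under each scenario (plus pairwise comparisons).

    Returns ``{scenario: {"summaries": ..., "matrix": ..., "params": ...,
    "variant": ...}}``; an empty scenario list yields an empty map.
    """
    if scenario_ids is None:
        scenario_ids = list(SCENARIO_IDS)
    out: dict[str, dict[str, Any]] = {}
    for sid in scenario_ids:
        params, variant = apply_scenario(base, sid)
        summaries = run_strategy_suite(params, strategy_ids, variant)
        out[sid] = {
            "params": params,
            "variant": variant,
            "summaries": summaries,
            "matrix": icer_matrix(summaries) if len(summaries) > 1 else {},
        }
    return out


def counters_frame(summaries: dict[str, OutcomeSummary], reference: str = "none") -> pd.DataFrame:
    """Cumulative stage-IV cases and deaths per strategy, with the number
    prevented relative to the reference (no-screening) strategy."""
    ref = summaries[reference]
    rows = []
    for sid, s in summaries.items():
        rows.append(
            {
                "strategy": sid,
                "crc_stage4_cases": s.crc_stage4_cases,
                "cases_prevented": ref.crc_stage4_cases - s.crc_stage4_cases,
                "total_deaths": s.total_deaths,
                "deaths_prevented": ref.total_deaths - s.total_deaths,
                "crc_deaths": s.crc_deaths,
                "crc_deaths_prevented": ref.crc_deaths - s.crc_deaths,
            }
        )
    return pd.DataFrame(rows)
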