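"""Discounted cost and QALY accrual over a cohort trace.

Costing convention: state membership is valued at cycle start, events
(screens, colonoscopies, excisions, diagnoses) in the cycle they occur, and
both are discounted at ``(1 + r)^-t`` with ``t`` the cycle index from 0. No
half-cycle correction is applied by default (``half_cycle=True`` switches it
on for the QALY stream), matching spreadsheet-style cohort models.

Cost components per cycle:

* programme organisation fee, once per screening round;
* unit costs of FIT kits, colonoscopies (screening, confirmatory, and
  diagnostic), polypectomies, histopathology, and the post-polypectomy
  surveillance colonoscopy;
* adenoma treatment episodes for every excised lesion;
* first-year stage treatment cost for every new diagnosis (and every
  post-diagnosis progression in the incomplete-cure variant, which triggers
  a new round of treatment);
* annual CRC surveillance follow-up for the first ``followup_horizon_years``
  years after each diagnosis, realized through the tunnel states.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import Trace
from .parameters import CANCER_STAGES, ParameterSet

__all__ = ["OutcomeSummary", "discount_factor", "accrue"]


def discount_factor(t: int, rate: float) -> float:
    """Present-value factor ``(1 + rate)^-t`` for cycle ``t`` (from 0)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-t)


@dataclass
class OutcomeSummary:
    """Per-person discounted outcomes and cumulative epidemiological counters."""

    strategy: str
    discounted_cost_pp: float
    discounted_qaly_pp: float
    undiscounted_life_years_pp: float
    crc_stage4_cases: float  # cumulative entries into stage IV (preclinical or diagnosed)
    total_deaths: float
    crc_deaths: float

    def as_dict(self) -> dict[str, float | str]:
        return {
            "strategy": self.strategy,
            "discounted_cost_pp": self.discounted_cost_pp,
            "discounted_qaly_pp": self.discounted_qaly_pp,
            "undiscounted_life_years_pp": self.undiscounted_life_years_pp,
            "crc_stage4_cases": self.crc_stage4_cases,
            "total_deaths": self.total_deaths,
            "crc_deaths": self.crc_deaths,
        }


def _utility_by_compartment(trace: Trace, params: ParameterSet) -> list[float]:
    """Utility weight per compartment; preclinical stages carry the stage weight."""
    u = params.utilities
    out = []
    for nm in trace.space.names:
        if nm == "normal":
            out.append(u["normal"])
        elif nm in ("lr_adenoma", "hr_adenoma"):
            out.append(u[nm])
        elif nm.startswith("ud_"):
            out.append(u[f"crc_{nm[3:]}"])
        elif nm.startswith("d_"):
            stage = nm[2:].split("_")[0]
            out.append(u[f"crc_{stage}"])
        elif nm == "false_positive":
            out.append(u["false_positive"])
        else:  # death compartments
            out.append(u["death"])
    return out


def accrue(
    trace: Trace,
    params: ParameterSet,
    strategy_id: str = "",
    half_cycle: bool = False,
) -> OutcomeSummary:
    """Convert a :class:`~crcscreen.engine.Trace` into an :class:`OutcomeSummary`."""
    if trace.start_age != params.start_age or len(trace.tallies) != params.n_cycles:
        raise ValueError("trace horizon does not match the parameter set")
    space = trace.space
    rate = params.discount_rate.value
    costs = params.costs
    utilities = _utility_by_compartment(trace, params)
    i_crc = space.index["die_crc"]
    i_oth = space.index["die_other"]
    cohort = params.cohort_size

    total_cost = 0.0
    total_qaly = 0.0
    life_years = 0.0
    stage4 = float(trace.snapshots[0][space.index["ud_IV"]])

    for t, tally in enumerate(trace.tallies):
        df = discount_factor(t, rate)
        snap = trace.snapshots[t]

        qaly_t = float(sum(m * u for m, u in zip(snap, utilities)))
        if half_cycle:
            nxt = trace.snapshots[t + 1]
            qaly_next = float(sum(m * u for m, u in zip(nxt, utilities)))
            qaly_t = 0.5 * (qaly_t + qaly_next)
        alive_t = float(snap.sum() - snap[i_crc] - snap[i_oth])

        cost_t = 0.0
        if tally.screening_round:
            cost_t += costs["project_total"]
        cost_t += costs["fit_unit"] * tally.fit_performed
        cost_t += costs["colonoscopy_unit"] * tally.colonoscopies_performed
        cost_t += costs["excision_unit"] * tally.excisions
        cost_t += costs["pathology_unit"] * tally.pathology_exams
        cost_t += costs["surveillance_followup_unit"] * tally.adenoma_surveillance
        cost_t += costs["lr_adenoma_treat"] * tally.excisions_lr
        cost_t += costs["hr_adenoma_treat"] * tally.excisions_hr
        for s in CANCER_STAGES:
            episodes = tally.new_diagnoses[s] + tally.retreatments[s]
            cost_t += costs[f"crc_{s}_treat"] * episodes
        cost_t += costs["crc_followup_annual"] * tally.followup_person_years

        total_cost += df * cost_t
        total_qaly += df * qaly_t
        life_years += alive_t
        stage4 += tally.stage_iv_entries

    final = trace.snapshots[-1]
    return OutcomeSummary(
        strategy=strategy_id,
        discounted_cost_pp=total_cost / cohort,
        discounted_qaly_pp=total_qaly / cohort,
        undiscounted_life_years_pp=life_years / cohort,
        crc_stage4_cases=stage4,
        total_deaths=float(final[i_crc] + final[i_oth]),
        crc_deaths=float(final[i_crc]),
    )
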