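"""Synthetic parameter sets and an individual-level microsimulation oracle.

``generate_parameter_set`` emits complete, internally consistent parameter
sets with the statistical structure the analysis assumes — annual transition
probabilities on the adenoma–carcinoma chain, stage-ordered costs and
utilities, Beta/Gamma uncertainty with ±25% bounds — so every stage of the
pipeline is testable without external data. It emulates structure, not any
particular population's epidemiology.

``microsim_oracle`` is a brute-force validator for the cohort engine: it
pushes independent simulated individuals through the *identical* cycle and
event order using per-person Bernoulli draws, and reports mean outcomes with
Monte-Carlo standard errors. The cohort engine computes the expectation of
this process, so the two must agree within sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .economics import OutcomeSummary, discount_factor
from .parameters import (
    CANCER_STAGES,
    CostTable,
    DistributionSpec,
    MortalityTable,
    ParameterSet,
    ScreeningTechProfile,
    StrategyConfig,
    TransitionTable,
    UncertainParameter,
    UtilityTable,
    VisitRateTable,
    mortality_for_age,
)

__all__ = ["GeneratorConfig", "generate_parameter_set", "microsim_oracle", "MicrosimResult"]


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    realism: str = "paper_like"  # "paper_like" | "stress"
    cohort_size_override: float | None = None


def _up(v: float, family: str, source: str = "reference_placeholder") -> UncertainParameter:
    """Probability-or-cost parameter with conventional ±25% bounds.

    Degenerate probabilities (0 or 1) become point specs, since a Beta
    distribution cannot have its mean on the boundary.
    """
    if family == "beta" and not (0.0 < v < 1.0):
        return UncertainParameter.point(v, source)
    return UncertainParameter.of(v, family, source)


#: documented plausible ranges for parameters the source article cites
#: without printing (annual probabilities unless noted); "stress" widens the
#: probability ranges to the boundaries
_PAPER_LIKE_RANGES: dict[str, tuple[float, float]] = {
    "normal_to_lr": (0.005, 0.030),
    "lr_to_hr": (0.010, 0.050),
    "hr_to_ud_I": (0.020, 0.050),
    "ud_progression": (0.30, 0.60),
    "mu_I": (0.010, 0.050),
    "visit_ud_I": (0.10, 0.30),
    "visit_ud_II": (0.20, 0.40),
    "visit_ud_III": (0.40, 0.70),
    "prev_lr": (0.10, 0.20),
    "prev_hr": (0.02, 0.06),
    "prev_ud": (0.0001, 0.001),
    "fit_sens_adenoma": (0.03, 0.30),
    "fit_sens_crc": (0.30, 0.99),
    "fit_spec": (0.90, 0.99),
    "colo_sens": (0.80, 0.99),
    "miss_rate": (0.10, 0.30),
    "participation": (0.30, 0.90),
    "compliance": (0.50, 1.00),
    "cost_adenoma": (300.0, 900.0),
    "cost_crc_base": (8_000.0, 16_000.0),
    "cost_crc_step": (500.0, 3_000.0),
    "cost_followup": (1_000.0, 3_000.0),
}


def generate_parameter_set(cfg: GeneratorConfig) -> ParameterSet:
    """Draw a complete, valid :class:`ParameterSet` (deterministic in seed)."""
    if cfg.realism not in ("paper_like", "stress"):
        raise ValueError(f"unknown realism level {cfg.realism!r}")
    rng = np.random.default_rng(cfg.seed)
    R = dict(_PAPER_LIKE_RANGES)
    if cfg.realism == "stress":
        for k in ("fit_sens_adenoma", "fit_sens_crc", "participation", "compliance"):
            R[k] = (0.0, 1.0)
        R["visit_ud_I"] = R["visit_ud_II"] = R["visit_ud_III"] = (0.0, 1.0)

    def u(key: str) -> float:
        lo, hi = R[key]
        return float(rng.uniform(lo, hi))

    nh = {
        "normal_to_lr": _up(u("normal_to_lr"), "beta"),
        "lr_to_hr": _up(u("lr_to_hr"), "beta"),
        "hr_to_ud_I": _up(u("hr_to_ud_I"), "beta"),
        "ud_I_to_ud_II": _up(u("ud_progression"), "beta"),
        "ud_II_to_ud_III": _up(u("ud_progression"), "beta"),
        "ud_III_to_ud_IV": _up(u("ud_progression"), "beta"),
    }
    # stage-increasing CRC mortality, capped so combined exits stay below 1
    mu = [u("mu_I")]
    for step_hi in (0.08, 0.12, 0.25):
        mu.append(min(mu[-1] + rng.uniform(0.005, step_hi), 0.45))
    crc_mortality = {f"crc_{s}": _up(m, "beta") for s, m in zip(CANCER_STAGES, mu)}

    visits = VisitRateTable(
        {
            "lr_adenoma": UncertainParameter.point(0.0),
            "hr_adenoma": UncertainParameter.point(0.0),
            "ud_I": _up(u("visit_ud_I"), "beta"),
            "ud_II": _up(u("visit_ud_II"), "beta"),
            "ud_III": _up(u("visit_ud_III"), "beta"),
            "ud_IV": UncertainParameter.point(1.0),
        }
    )

    # utilities strictly ordered normal >= adenoma >= stage I >= ... >= IV
    decs = rng.uniform(0.02, 0.08, size=6)
    vals = 1.0 - np.cumsum(decs)
    utilities = UtilityTable(
        {
            "normal": UncertainParameter.point(1.0),
            "lr_adenoma": _up(float(vals[0]), "beta"),
            "hr_adenoma": _up(float(vals[0]) , "beta"),
            "crc_I": _up(float(vals[1]), "beta"),
            "crc_II": _up(float(vals[2]), "beta"),
            "crc_III": _up(float(vals[3]), "beta"),
            "crc_IV": _up(float(vals[4]), "beta"),
            "false_positive": UncertainParameter.point(1.0),
            "death": UncertainParameter.point(0.0),
        }
    )

    # stage-monotone treatment costs
    base = u("cost_crc_base")
    steps = [u("cost_crc_step") for _ in range(3)]
    crc_costs = [base, base + steps[0], base + steps[0] + steps[1], base + sum(steps)]
    adenoma_cost = u("cost_adenoma")
    costs = CostTable(
        {
            "lr_adenoma_treat": _up(adenoma_cost, "gamma"),
            "hr_adenoma_treat": _up(adenoma_cost, "gamma"),
            **{f"crc_{s}_treat": _up(c, "gamma") for s, c in zip(CANCER_STAGES, crc_costs)},
            "crc_followup_annual": _up(u("cost_followup"), "gamma"),
            "project_total": _up(float(rng.uniform(50_000, 250_000)), "gamma"),
            "fit_unit": _up(float(rng.uniform(1.0, 10.0)), "gamma"),
            "colonoscopy_unit": _up(float(rng.uniform(80.0, 250.0)), "gamma"),
            "excision_unit": _up(float(rng.uniform(150.0, 450.0)), "gamma"),
            "pathology_unit": _up(float(rng.uniform(10.0, 60.0)), "gamma"),
            "surveillance_followup_unit": _up(float(rng.uniform(80.0, 250.0)), "gamma"),
        }
    )

    fit_ad = u("fit_sens_adenoma")
    crc_sens = np.sort(rng.uniform(*R["fit_sens_crc"], size=4))
    fit = ScreeningTechProfile(
        name="FIT",
        sensitivity={
            "lr_adenoma": _up(min(fit_ad * rng.uniform(0.3, 0.8), 1.0), "beta"),
            "hr_adenoma": _up(fit_ad, "beta"),
            **{f"crc_{s}": _up(float(v), "beta") for s, v in zip(CANCER_STAGES, crc_sens)},
        },
        specificity=_up(u("fit_spec"), "beta"),
        miss_rate=UncertainParameter.point(0.0),
    )
    colo_sens = u("colo_sens")
    colonoscopy = ScreeningTechProfile(
        name="colonoscopy",
        sensitivity={
            "lr_adenoma": _up(colo_sens, "beta"),
            "hr_adenoma": _up(colo_sens, "beta"),
            **{f"crc_{s}": _up(min(colo_sens + 0.01, 1.0), "beta") for s in CANCER_STAGES},
        },
        specificity=UncertainParameter.point(1.0),
        miss_rate=_up(u("miss_rate"), "beta"),
    )

    part = u("participation")
    comp = u("compliance")
    strategies = {
        "none": StrategyConfig("none", "none", 0, UncertainParameter.point(0.0), UncertainParameter.point(1.0)),
        "FIT1": StrategyConfig("FIT1", "fit_then_colonoscopy", 1, _up(part, "beta"), _up(comp, "beta")),
        "FIT2": StrategyConfig("FIT2", "fit_then_colonoscopy", 2, _up(part, "beta"), _up(comp, "beta")),
        "eCSPY10": StrategyConfig("eCSPY10", "colonoscopy", 10, _up(part, "beta"), UncertainParameter.point(1.0)),
        "eCSPY5": StrategyConfig("eCSPY5", "colonoscopy", 5, _up(part, "beta"), UncertainParameter.point(1.0)),
    }

    mortality = MortalityTable(
        [
            (40, 44, 0.0018),
            (45, 49, 0.0026),
            (50, 54, 0.0042),
            (55, 59, 0.0062),
            (60, 64, 0.0103),
            (65, 69, 0.0172),
            (70, 74, 0.0306),
        ]
    )

    prevalence = {
        "lr_adenoma": _up(u("prev_lr"), "beta"),
        "hr_adenoma": _up(u("prev_hr"), "beta"),
        **{f"ud_{s}": _up(u("prev_ud"), "beta") for s in CANCER_STAGES},
    }

    ps = ParameterSet(
        cohort_size=float(cfg.cohort_size_override or 100_000),
        start_age=50,
        end_age=75,
        discount_rate=UncertainParameter(0.05, DistributionSpec("beta", 0.05, 0.0375, 0.0625), "paper_table"),
        followup_horizon_years=5,
        prevalence=prevalence,
        mortality=mortality,
        costs=costs,
        utilities=utilities,
        transitions=TransitionTable(nh, crc_mortality),
        visits=visits,
        tech={"FIT": fit, "colonoscopy": colonoscopy},
        strategies=strategies,
    )
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# Individual-level microsimulation oracle

# state codes
_NORMAL, _LR, _HR = 0, 1, 2
_UD = {s: 3 + i for i, s in enumerate(CANCER_STAGES)}  # 3..6
_D = {s: 7 + i for i, s in enumerate(CANCER_STAGES)}  # 7..10
_FP, _DIE_CRC, _DIE_OTH = 11, 12, 13


@dataclass
class MicrosimResult:
    """Mean outcomes with Monte-Carlo standard errors (same scale as the
    cohort engine's :class:`~crcscreen.economics.OutcomeSummary`)."""

    summary: OutcomeSummary
    se: dict[str, float]
    n_agents: int


def microsim_oracle(
    params: ParameterSet,
    strategy: StrategyConfig | str,
    n_agents: int,
    seed: int,
    variant: str = "base",
) -> MicrosimResult:
    """Simulate ``n_agents`` independent individuals through the cohort
    engine's exact event order with per-person Bernoulli draws."""
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    if isinstance(strategy, str):
        strategy = params.strategies[strategy]
    rng = np.random.default_rng(seed)
    n = n_agents
    h = params.followup_horizon_years
    rate = params.discount_rate.value
    costs = params.costs
    colo = params.tech["colonoscopy"]
    q_by_cycle = [mortality_for_age(params.mortality, params.start_age + t) for t in range(params.n_cycles)]

    # per-code lookup tables
    util = np.zeros(14)
    util[_NORMAL] = params.utilities["normal"]
    util[_LR] = params.utilities["lr_adenoma"]
    util[_HR] = params.utilities["hr_adenoma"]
    for s in CANCER_STAGES:
        util[_UD[s]] = util[_D[s]] = params.utilities[f"crc_{s}"]
    util[_FP] = params.utilities["false_positive"]

    mu = np.zeros(14)
    for s in CANCER_STAGES:
        mu[_UD[s]] = mu[_D[s]] = params.transitions.crc_mortality[f"crc_{s}"].value

    nh = params.transitions.natural_history
    prog = np.zeros(14)
    prog[_NORMAL] = nh["normal_to_lr"].value
    prog[_LR] = nh["lr_to_hr"].value
    prog[_HR] = nh["hr_to_ud_I"].value
    prog[_UD["I"]] = nh["ud_I_to_ud_II"].value
    prog[_UD["II"]] = nh["ud_II_to_ud_III"].value
    prog[_UD["III"]] = nh["ud_III_to_ud_IV"].value

    visit = np.zeros(14)
    for s in CANCER_STAGES:
        visit[_UD[s]] = params.visits[f"ud_{s}"]

    treat_cost = np.zeros(14)
    for s in CANCER_STAGES:
        treat_cost[_D[s]] = costs[f"crc_{s}_treat"]

    # initial states by prevalence (multinomial assignment)
    probs = [params.prevalence[k].value for k in ("lr_adenoma", "hr_adenoma")]
    probs += [params.prevalence[f"ud_{s}"].value for s in CANCER_STAGES]
    codes = [_LR, _HR] + [_UD[s] for s in CANCER_STAGES]
    r0 = rng.random(n)
    state = np.full(n, _NORMAL, dtype=np.int8)
    cum = 0.0
    for p0, code in zip(probs, codes):
        mask = (r0 >= cum) & (r0 < cum + p0)
        state[mask] = code
        cum += p0

    slot = np.zeros(n, dtype=np.int16)  # tunnel slot, 0 = not diagnosed
    origin = np.full(n, -1, dtype=np.int8)  # stage index at first diagnosis
    cost = np.zeros(n)
    qaly = np.zeros(n)
    life = np.zeros(n)
    stage4 = state == _UD["IV"]

    scenario3 = variant == "scenario3" and bool(params.transitions.post_diagnosis)
    post = params.transitions.post_diagnosis

    def post_prob(stage_code: int, orig: np.ndarray) -> np.ndarray:
        """Per-agent post-diagnosis progression probability."""
        pr = np.zeros(len(orig))
        get = lambda k: post[k].value if k in post else 0.0
        if stage_code == _D["I"]:
            pr[:] = get("d_I_to_d_II")
        elif stage_code == _D["II"]:
            pr[orig == 1] = get("d_II_to_d_III")
            pr[orig == 0] = get("d_II_to_d_III_from_I")
        elif stage_code == _D["III"]:
            pr[orig == 2] = get("d_III_to_d_IV")
            pr[orig == 1] = get("d_III_to_d_IV_from_II")
            pr[orig == 0] = get("d_III_to_d_IV_from_I")
        return pr

    project_share = costs["project_total"] / params.cohort_size

    for t in range(params.n_cycles):
        df = discount_factor(t, rate)
        alive = state < _DIE_CRC
        # membership valued at cycle start
        qaly += df * util[state] * alive  # death utilities are zero anyway
        life += alive

        # step 0: false positives return to normal
        state[state == _FP] = _NORMAL

        # step 1: scheduled screening
        if strategy.modality != "none" and t % strategy.interval_years == 0:
            cost += df * project_share  # programme fee, amortized per person
            p = strategy.participation.value
            elig = state <= _UD["IV"]
            part = elig & (rng.random(n) < p)
            if strategy.modality == "fit_then_colonoscopy":
                fit = params.tech["FIT"]
                c = strategy.colonoscopy_compliance.value
                cost[part] += df * costs["fit_unit"]
                pos_p = np.zeros(14)
                pos_p[_NORMAL] = 1.0 - fit.specificity.value
                pos_p[_LR] = fit.sensitivity["lr_adenoma"].value
                pos_p[_HR] = fit.sensitivity["hr_adenoma"].value
                for s in CANCER_STAGES:
                    pos_p[_UD[s]] = fit.sensitivity[f"crc_{s}"].value
                positive = part & (rng.random(n) < pos_p[state])
                scoped = positive & (rng.random(n) < c)
                cost[scoped] += df * costs["colonoscopy_unit"]
                # FIT false positives: negative confirmatory colonoscopy
                m = scoped & (state == _NORMAL)
                state[m] = _FP
                for lesion, code, ckey in (
                    ("lr_adenoma", _LR, "lr_adenoma_treat"),
                    ("hr_adenoma", _HR, "hr_adenoma_treat"),
                ):
                    det = scoped & (state == code) & (rng.random(n) < colo.adenoma_detection(lesion))
                    state[det] = _NORMAL
                    cost[det] += df * (
                        costs["excision_unit"]
                        + costs["pathology_unit"]
                        + costs["surveillance_followup_unit"]
                        + costs[ckey]
                    )
                for i, s in enumerate(CANCER_STAGES):
                    det = scoped & (state == _UD[s]) & (rng.random(n) < colo.cancer_detection(s))
                    state[det] = _D[s]
                    slot[det] = 1
                    origin[det] = i
                    cost[det] += df * costs[f"crc_{s}_treat"]
            else:  # primary colonoscopy
                cost[part] += df * costs["colonoscopy_unit"]
                m = part & (state == _NORMAL) & (rng.random(n) < 1.0 - colo.specificity.value)
                state[m] = _FP
                for lesion, code, ckey in (
                    ("lr_adenoma", _LR, "lr_adenoma_treat"),
                    ("hr_adenoma", _HR, "hr_adenoma_treat"),
                ):
                    det = part & (state == code) & (rng.random(n) < colo.adenoma_detection(lesion))
                    state[det] = _NORMAL
                    cost[det] += df * (
                        costs["excision_unit"]
                        + costs["pathology_unit"]
                        + costs["surveillance_followup_unit"]
                        + costs[ckey]
                    )
                for i, s in enumerate(CANCER_STAGES):
                    det = part & (state == _UD[s]) & (rng.random(n) < colo.cancer_detection(s))
                    state[det] = _D[s]
                    slot[det] = 1
                    origin[det] = i
                    cost[det] += df * costs[f"crc_{s}_treat"]

        # step 2: symptomatic clinic presentation
        presenting = (rng.random(n) < visit[state]) & (state >= _UD["I"]) & (state <= _UD["IV"])
        for i, s in enumerate(CANCER_STAGES):
            m = presenting & (state == _UD[s])
            state[m] = _D[s]
            slot[m] = 1
            origin[m] = i
            cost[m] += df * (costs["colonoscopy_unit"] + costs[f"crc_{s}_treat"])

        # step 3: natural history
        die1 = (rng.random(n) < mu[state]) & (state < _DIE_CRC)
        state[die1] = _DIE_CRC
        slot[die1] = 0
        q = q_by_cycle[t]
        die2 = (rng.random(n) < q) & (state < _DIE_CRC)
        state[die2] = _DIE_OTH
        slot[die2] = 0

        old = state.copy()
        advance = (rng.random(n) < prog[old]) & (old <= _UD["III"])
        state[advance] = old[advance] + 1
        newly4 = advance & (old == _UD["III"])
        stage4 |= newly4

        if scenario3:
            r = rng.random(n)
            for code in (_D["III"], _D["II"], _D["I"]):  # order immaterial: based on `old`
                m = (old == code) & (r < post_prob(code, origin))
                if not m.any():
                    continue
                state[m] = code + 1
                slot[m] = 1
                cost[m] += df * treat_cost[code + 1]
                if code == _D["III"]:
                    stage4 |= m
            # (origin unchanged: lineage is the stage at first diagnosis)

        # tunnel advancement; advancing mass pays the year's surveillance
        diagnosed = (state >= _D["I"]) & (state <= _D["IV"])
        paying = diagnosed & (slot >= 1) & (slot <= h)
        cost[paying] += df * costs["crc_followup_annual"]
        slot[diagnosed] = np.minimum(slot[diagnosed] + 1, h + 1)

    dead = state >= _DIE_CRC
    crc_dead = state == _DIE_CRC
    scale = params.cohort_size

    def mean_se(x: np.ndarray) -> tuple[float, float]:
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    cost_m, cost_se = mean_se(cost)
    qaly_m, qaly_se = mean_se(qaly)
    life_m, life_se = mean_se(life)
    dead_m, dead_se = mean_se(dead.astype(float))
    crc_m, crc_se = mean_se(crc_dead.astype(float))
    s4_m, s4_se = mean_se(stage4.astype(float))

    summary = OutcomeSummary(
        strategy=strategy.id,
        discounted_cost_pp=cost_m,
        discounted_qaly_pp=qaly_m,
        undiscounted_life_years_pp=life_m,
        crc_stage4_cases=s4_m * scale,
        total_deaths=dead_m * scale,
        crc_deaths=crc_m * scale,
    )
    se = {
        "discounted_cost_pp": cost_se,
        "discounted_qaly_pp": qaly_se,
        "undiscounted_life_years_pp": life_se,
        "crc_stage4_cases": s4_se * scale,
        "total_deaths": dead_se * scale,
        "crc_deaths": crc_se * scale,
    }
    return MicrosimResult(summary=summary, se=se, n_agents=n)
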