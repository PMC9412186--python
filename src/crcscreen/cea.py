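"""Incremental cost-effectiveness analysis and sensitivity analyses.

* pairwise ICER / dominance classification across strategies;
* one-way deterministic sensitivity analysis (tornado entries sorted by
  swing), rerunning the full model at each parameter's low and high bound;
* probabilistic sensitivity analysis: joint independent draws from every
  parameter's Beta/Gamma spec, one full model run per strategy per
  iteration, summarised as net-monetary-benefit acceptability curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import OutcomeSummary, accrue
from .engine import run_cohort
from .parameters import ParameterSet, make_sampler

__all__ = [
    "ComparisonResult",
    "TornadoEntry",
    "PSAResult",
    "compare",
    "icer_matrix",
    "icer_frame",
    "nmb",
    "one_way_dsa",
    "run_psa",
    "ceac",
    "run_strategy_suite",
]


def run_strategy_suite(
    params: ParameterSet,
    strategy_ids: list[str] | None = None,
    variant: str = "base",
) -> dict[str, OutcomeSummary]:
    """Run and accrue every requested strategy on one parameter set."""
    if strategy_ids is None:
        strategy_ids = list(params.strategies)
    out = {}
    for sid in strategy_ids:
        if sid not in params.strategies:
            raise KeyError(f"unknown strategy id {sid!r}")
        trace = run_cohort(params, sid, variant)
        out[sid] = accrue(trace, params, strategy_id=sid)
    return out


@dataclass
class ComparisonResult:
    """Incremental comparison of ``comparator`` against ``reference``.

    ``verdict`` is "dominant" when the comparator saves money and gains
    QALYs, "dominated" in the reverse case, "icer" when a trade-off exists,
    and "indeterminate" when the QALY difference is zero. ``icer`` holds
    ΔC/ΔE whenever ΔE ≠ 0 (reported alongside dominance verdicts, matching
    the convention of printing the ratio with a dominance note).
    """

    reference: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    verdict: str
    icer: float | None

    def as_dict(self) -> dict:
        return {
            "reference": self.reference,
            "comparator": self.comparator,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "verdict": self.verdict,
            "icer": self.icer,
        }


def compare(ref: OutcomeSummary, comp: OutcomeSummary) -> ComparisonResult:
    """Incremental cost, incremental QALYs, and ICER/dominance verdict."""
    dc = comp.discounted_cost_pp - ref.discounted_cost_pp
    de = comp.discounted_qaly_pp - ref.discounted_qaly_pp
    icer = dc / de if de != 0.0 else None
    if de > 0 and dc < 0:
        verdict = "dominant"
    elif de < 0 and dc > 0:
        verdict = "dominated"
    elif de == 0.0:
        verdict = "indeterminate"
    else:
        verdict = "icer"
    return ComparisonResult(ref.strategy, comp.strategy, dc, de, verdict, icer)


def icer_matrix(
    summaries: dict[str, OutcomeSummary]
) -> dict[tuple[str, str], ComparisonResult]:
    """All ordered pairwise comparisons (reference, comparator)."""
    if len(summaries) < 2:
        raise ValueError("need at least two strategies to compare")
    out = {}
    for ref_id, ref in summaries.items():
        for comp_id, comp in summaries.items():
            if ref_id == comp_id:
                continue
            out[(ref_id, comp_id)] = compare(ref, comp)
    return out


def icer_frame(summaries: dict[str, OutcomeSummary]) -> pd.DataFrame:
    """Pairwise comparisons as a tidy DataFrame (one row per ordered pair)."""
    matrix = icer_matrix(summaries)
    return pd.DataFrame([c.as_dict() for c in matrix.values()])


def nmb(cost_pp: float, qaly_pp: float, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp`` (USD/QALY)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return qaly_pp * wtp - cost_pp


# ---------------------------------------------------------------------------
# Deterministic sensitivity analysis


@dataclass
class TornadoEntry:
    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_value(params: ParameterSet, ref_id: str, comp_id: str, variant: str) -> float:
    summaries = run_strategy_suite(params, [ref_id, comp_id], variant)
    res = compare(summaries[ref_id], summaries[comp_id])
    if res.icer is None:
        return float("nan")
    return res.icer


def one_way_dsa(
    params: ParameterSet,
    comparison: tuple[str, str],
    parameter_ids: list[str] | None = None,
    variant: str = "base",
) -> list[TornadoEntry]:
    """One-way sensitivity of the (reference, comparator) ICER.

    Each listed parameter is set to its low and high bound in turn (all
    others at base), the full model rerun for both strategies, and the ICER
    recomputed. Entries come back sorted by descending swing. Parameters
    without usable bounds are skipped with a warning.
    """
    ref_id, comp_id = comparison
    if parameter_ids is None:
        parameter_ids = [path for path, _ in params.iter_uncertain()]
    entries = []
    for path in parameter_ids:
        try:
            p = params.get_parameter(path)
        except KeyError:
            warnings.warn(f"skipping unknown parameter {path!r}", stacklevel=2)
            continue
        low, high = p.spec.low, p.spec.high
        icers = []
        for bound in (low, high):
            trial = params.copy()
            trial.set_value(path, bound)
            icers.append(_icer_value(trial, ref_id, comp_id, variant))
        entries.append(TornadoEntry(path, icers[0], icers[1]))
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "swing": e.swing,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass
class PSAResult:
    """Stored per-iteration (strategy → cost, QALY) draws."""

    strategies: list[str]
    seed: int
    #: strategy -> arrays of shape (n_iterations,)
    cost: dict[str, np.ndarray] = field(default_factory=dict)
    qaly: dict[str, np.ndarray] = field(default_factory=dict)
    #: parameter path -> sampled values, shape (n_iterations,)
    draws: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return len(next(iter(self.cost.values()))) if self.cost else 0

    def scatter_frame(self) -> pd.DataFrame:
        rows = []
        for sid in self.strategies:
            for i in range(self.n_iterations):
                rows.append((i, sid, self.cost[sid][i], self.qaly[sid][i]))
        return pd.DataFrame(rows, columns=["iteration", "strategy", "cost_pp", "qaly_pp"])


def run_psa(
    params: ParameterSet,
    strategy_ids: list[str] | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    variant: str = "base",
) -> PSAResult:
    """Monte-Carlo probabilistic sensitivity analysis.

    Per iteration one joint draw is taken (independently across parameters:
    Beta for probabilities and utilities, Gamma for costs; point specs stay
    fixed), the full model is run for every strategy, and per-person cost
    and QALYs are stored. Fully reproducible from ``seed``.
    """
    if strategy_ids is None:
        strategy_ids = list(params.strategies)
    sampled_paths = []
    samplers = []
    root = np.random.SeedSequence(seed)
    for (path, p), child in zip(
        list(params.iter_uncertain()),
        root.spawn(sum(1 for _ in params.iter_uncertain())),
    ):
        if p.spec.family == "point" or p.spec.sd == 0.0:
            continue
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        samplers.append(make_sampler(p.spec, sub_seed))
        sampled_paths.append(path)

    draws = {path: np.asarray(s(n_iter), dtype=float) for path, s in zip(sampled_paths, samplers)}
    result = PSAResult(strategies=list(strategy_ids), seed=seed, draws=draws)
    cost = {sid: np.empty(n_iter) for sid in strategy_ids}
    qaly = {sid: np.empty(n_iter) for sid in strategy_ids}

    for i in range(n_iter):
        trial = params.copy()
        for path in sampled_paths:
            trial.set_value(path, float(draws[path][i]))
        summaries = run_strategy_suite(trial, strategy_ids, variant)
        for sid in strategy_ids:
            cost[sid][i] = summaries[sid].discounted_cost_pp
            qaly[sid][i] = summaries[sid].discounted_qaly_pp

    result.cost = cost
    result.qaly = qaly
    return result


def ceac(psa: PSAResult, wtp_grid: list[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    At each willingness-to-pay value, the probability that each strategy has
    the highest net monetary benefit across iterations (ties split equally).
    Returns a tidy frame (wtp, strategy, probability).
    """
    if len(wtp_grid) == 0:
        raise ValueError("willingness-to-pay grid must be non-empty")
    if psa.n_iterations == 0:
        raise ValueError("PSA result is empty")
    n = psa.n_iterations
    sids = psa.strategies
    cost = np.stack([psa.cost[s] for s in sids])  # (S, n)
    qaly = np.stack([psa.qaly[s] for s in sids])
    rows = []
    for wtp in wtp_grid:
        benefit = qaly * wtp - cost
        best = benefit.max(axis=0)
        is_best = np.isclose(benefit, best[None, :], rtol=0.0, atol=1e-12)
        weights = is_best / is_best.sum(axis=0, keepdims=True)
        probs = weights.sum(axis=1) / n
        for sid, pr in zip(sids, probs):
            rows.append((wtp, sid, float(pr)))
    return pd.DataFrame(rows, columns=["wtp", "strategy", "probability"])
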