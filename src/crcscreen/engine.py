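"""Cohort state-transition engine.

The model tracks a closed cohort through the adenoma–carcinoma sequence in
annual cycles: normal → low-risk adenoma → high-risk adenoma → preclinical
(undiagnosed) cancer stages I–IV, with stage-matched diagnosed compartments,
a transient false-positive compartment, and two absorbing death compartments
(CRC death, other-cause death). Diagnosed compartments are tunnel states
indexed by years since diagnosis (1..h+1 for a follow-up horizon of h years;
the top band absorbs in time) so that post-treatment surveillance costs stop
after exactly h years. In the incomplete-cure variant the diagnosed stage II
and III compartments are additionally split by the stage at first diagnosis
("lineage"), because each prior round of treatment raises the onward
progression probability.

Within a cycle events happen in a fixed order: (0) last cycle's false
positives return to normal, (1) scheduled screening, (2) symptomatic clinic
presentation, (3) natural history — CRC mortality, then other-cause
mortality, then stage progression of survivors and tunnel advancement.
Competing risks are resolved sequentially in that order, so cohort mass is
conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    CANCER_STAGES,
    ParameterSet,
    StrategyConfig,
    ValidationError,
    mortality_for_age,
)

__all__ = [
    "StateSpace",
    "StateVector",
    "CycleTally",
    "Trace",
    "build_state_space",
    "initialize_cohort",
    "screening_event",
    "clinical_presentation",
    "natural_history_step",
    "run_cohort",
]

MACRO_STATES = (
    "normal",
    "lr_adenoma",
    "hr_adenoma",
    "ud_I",
    "ud_II",
    "ud_III",
    "ud_IV",
    "d_I",
    "d_II",
    "d_III",
    "d_IV",
    "die_crc",
    "die_other",
)


@dataclass(frozen=True)
class StateSpace:
    """Ordered compartment enumeration for one model variant."""

    variant: str  # "base" | "scenario3"
    followup_horizon: int
    names: tuple[str, ...]
    index: dict[str, int]
    #: diagnosed compartment groups as (stage, origin); origin None = native
    diag_groups: tuple[tuple[str, str | None], ...]
    #: (stage, origin) -> index array of tunnel slots 1..h+1, in slot order
    diag_slots: dict[tuple[str, str | None], np.ndarray]

    @property
    def n(self) -> int:
        return len(self.names)

    def macro_mass(self, masses: np.ndarray, macro: str) -> float:
        """Total mass of a macro-state, summing tunnel/lineage substates."""
        if macro.startswith("d_"):
            stage = macro[2:]
            return float(
                sum(masses[sl].sum() for (s, o), sl in self.diag_slots.items() if s == stage)
            )
        return float(masses[self.index[macro]])


def _diag_name(stage: str, origin: str | None, slot: int) -> str:
    mid = f"_from_{origin}" if origin else ""
    return f"d_{stage}{mid}_y{slot}"


def build_state_space(variant: str, followup_horizon: int) -> StateSpace:
    """Enumerate compartments for ``variant`` with the given follow-up horizon.

    ``base`` carries one diagnosed lineage per stage; ``scenario3`` splits
    diagnosed stage II into {native, from_I} and stage III into
    {native, from_II, from_I}, realizing the incomplete-cure progression
    channels.
    """
    if variant not in ("base", "scenario3"):
        raise ValueError(f"unknown state-space variant {variant!r}")
    if followup_horizon < 1:
        raise ValueError("followup_horizon must be >= 1")
    h = followup_horizon

    if variant == "base":
        groups: list[tuple[str, str | None]] = [(s, None) for s in CANCER_STAGES]
    else:
        groups = [
            ("I", None),
            ("II", None),
            ("II", "I"),
            ("III", None),
            ("III", "II"),
            ("III", "I"),
            ("IV", None),
        ]

    names: list[str] = ["normal", "lr_adenoma", "hr_adenoma", "ud_I", "ud_II", "ud_III", "ud_IV"]
    for stage, origin in groups:
        for k in range(1, h + 2):
            names.append(_diag_name(stage, origin, k))
    names += ["false_positive", "die_crc", "die_other"]

    index = {nm: i for i, nm in enumerate(names)}
    diag_slots = {
        (stage, origin): np.array(
            [index[_diag_name(stage, origin, k)] for k in range(1, h + 2)], dtype=np.intp
        )
        for stage, origin in groups
    }
    return StateSpace(
        variant=variant,
        followup_horizon=h,
        names=tuple(names),
        index=index,
        diag_groups=tuple(groups),
        diag_slots=diag_slots,
    )


@dataclass
class StateVector:
    """Nonnegative cohort masses over a :class:`StateSpace`."""

    space: StateSpace
    masses: np.ndarray

    def __getitem__(self, name: str) -> float:
        return float(self.masses[self.space.index[name]])

    def total(self) -> float:
        return float(self.masses.sum())

    def copy(self) -> "StateVector":
        return StateVector(self.space, self.masses.copy())


@dataclass
class CycleTally:
    """Per-cycle event counts (fractional persons)."""

    screens_offered: float = 0.0
    fit_performed: float = 0.0
    colonoscopies_performed: float = 0.0
    excisions_lr: float = 0.0
    excisions_hr: float = 0.0
    pathology_exams: float = 0.0
    adenoma_surveillance: float = 0.0
    false_positives_created: float = 0.0
    new_diagnoses: dict[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in CANCER_STAGES}
    )
    #: incomplete-cure variant: post-diagnosis progressions triggering a new
    #: round of stage treatment
    retreatments: dict[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in CANCER_STAGES}
    )
    followup_person_years: float = 0.0
    stage_iv_entries: float = 0.0
    crc_deaths: float = 0.0
    other_deaths: float = 0.0
    screening_round: bool = False

    @property
    def excisions(self) -> float:
        return self.excisions_lr + self.excisions_hr


@dataclass
class Trace:
    """Cycle-by-cycle record of a cohort run.

    ``snapshots[k]`` is the state vector at the start of cycle ``k`` (age
    ``start_age + k``); ``tallies[k]`` are the events of cycle ``k``. There
    are ``n_cycles`` tallies and ``n_cycles + 1`` snapshots.
    """

    space: StateSpace
    start_age: int
    snapshots: list[np.ndarray]
    tallies: list[CycleTally]

    def __len__(self) -> int:
        return len(self.snapshots)

    @property
    def ages(self) -> list[int]:
        return [self.start_age + k for k in range(len(self.snapshots))]

    def states_frame(self) -> pd.DataFrame:
        """Tidy per-(age, compartment) masses."""
        rows = []
        for k, snap in enumerate(self.snapshots):
            age = self.start_age + k
            for i, nm in enumerate(self.space.names):
                rows.append((age, nm, snap[i]))
        return pd.DataFrame(rows, columns=["age", "compartment", "mass"])

    def tallies_frame(self) -> pd.DataFrame:
        """Tidy per-(age, event) counts."""
        rows = []
        for k, t in enumerate(self.tallies):
            age = self.start_age + k
            events = {
                "screens_offered": t.screens_offered,
                "fit_performed": t.fit_performed,
                "colonoscopies_performed": t.colonoscopies_performed,
                "excisions": t.excisions,
                "pathology_exams": t.pathology_exams,
                "adenoma_surveillance": t.adenoma_surveillance,
                "false_positives_created": t.false_positives_created,
                "followup_person_years": t.followup_person_years,
                "stage_iv_entries": t.stage_iv_entries,
                "crc_deaths": t.crc_deaths,
                "other_deaths": t.other_deaths,
                "screening_round": float(t.screening_round),
            }
            for s in CANCER_STAGES:
                events[f"new_diagnoses_{s}"] = t.new_diagnoses[s]
                events[f"retreatments_{s}"] = t.retreatments[s]
            for ev, val in events.items():
                rows.append((age, ev, val))
        return pd.DataFrame(rows, columns=["age", "event", "count"])


# ---------------------------------------------------------------------------
# Cycle steps


def initialize_cohort(params: ParameterSet, space: StateSpace) -> StateVector:
    """Distribute the cohort per initial prevalence; diagnosed start empty."""
    m = np.zeros(space.n)
    total = params.cohort_size
    prev_sum = 0.0
    for key in ("lr_adenoma", "hr_adenoma", "ud_I", "ud_II", "ud_III", "ud_IV"):
        p = params.prevalence[key].value
        prev_sum += p
        m[space.index[key]] = total * p
    if prev_sum >= 1.0:
        raise ValidationError(["prevalence: proportions must sum to < 1"])
    m[space.index["normal"]] = total * (1.0 - prev_sum)
    return StateVector(space, m)


_ELIGIBLE = ("normal", "lr_adenoma", "hr_adenoma", "ud_I", "ud_II", "ud_III", "ud_IV")


def screening_event(
    v: StateVector,
    strategy: StrategyConfig,
    params: ParameterSet,
    age: int,
) -> tuple[StateVector, CycleTally]:
    """Apply one scheduled screening round.

    Eligible mass (alive, undiagnosed, not in the false-positive state)
    participates with the strategy's uptake. Under FIT-then-colonoscopy,
    FIT positives proceed to a confirmatory colonoscopy with the stated
    compliance; under primary colonoscopy the participants are scoped
    directly. Detected adenomas are excised (excision rate 100%) and return
    to normal; detected preclinical cancers move to the stage-matched
    diagnosed tunnel slot 1; test-negative and non-compliant mass stays put.
    False positives arise only through imperfect specificity.
    """
    sp = v.space
    m = v.masses.copy()
    tally = CycleTally(screening_round=True)
    tally.screens_offered = float(sum(m[sp.index[c]] for c in _ELIGIBLE))

    if strategy.modality == "none":
        tally.screening_round = False
        return StateVector(sp, m), tally

    p = strategy.participation.value
    colo = params.tech["colonoscopy"]
    i_norm = sp.index["normal"]
    i_fp = sp.index["false_positive"]
    scopes = 0.0

    def excise(lesion: str, detected: float) -> None:
        m[sp.index[lesion]] -= detected
        m[i_norm] += detected
        if lesion == "lr_adenoma":
            tally.excisions_lr += detected
        else:
            tally.excisions_hr += detected
        tally.pathology_exams += detected
        tally.adenoma_surveillance += detected

    def diagnose(stage: str, detected: float) -> None:
        m[sp.index[f"ud_{stage}"]] -= detected
        m[sp.diag_slots[(stage, None)][0]] += detected
        tally.new_diagnoses[stage] += detected

    if strategy.modality == "fit_then_colonoscopy":
        fit = params.tech["FIT"]
        c = strategy.colonoscopy_compliance.value
        tally.fit_performed = p * tally.screens_offered
        # truly normal, FIT false positive, compliant -> negative colonoscopy
        fp_mass = m[i_norm] * p * (1.0 - fit.specificity.value) * c
        m[i_norm] -= fp_mass
        m[i_fp] += fp_mass
        tally.false_positives_created = fp_mass
        scopes += fp_mass
        for lesion in ("lr_adenoma", "hr_adenoma"):
            scoped = m[sp.index[lesion]] * p * fit.sensitivity[lesion].value * c
            scopes += scoped
            excise(lesion, scoped * colo.adenoma_detection(lesion))
        for s in CANCER_STAGES:
            scoped = m[sp.index[f"ud_{s}"]] * p * fit.sensitivity[f"crc_{s}"].value * c
            scopes += scoped
            diagnose(s, scoped * colo.cancer_detection(s))
    elif strategy.modality == "colonoscopy":
        scopes += p * tally.screens_offered
        fp_mass = m[i_norm] * p * (1.0 - colo.specificity.value)
        m[i_norm] -= fp_mass
        m[i_fp] += fp_mass
        tally.false_positives_created = fp_mass
        for lesion in ("lr_adenoma", "hr_adenoma"):
            excise(lesion, m[sp.index[lesion]] * p * colo.adenoma_detection(lesion))
        for s in CANCER_STAGES:
            diagnose(s, m[sp.index[f"ud_{s}"]] * p * colo.cancer_detection(s))
    else:
        raise ValueError(f"unknown screening modality {strategy.modality!r}")

    tally.colonoscopies_performed = scopes
    return StateVector(sp, m), tally


def clinical_presentation(
    v: StateVector, params: ParameterSet
) -> tuple[StateVector, CycleTally]:
    """Symptomatic clinic visits: stage-matched diagnosis of preclinical mass.

    Each presenting person undergoes a diagnostic colonoscopy (counted in the
    colonoscopy tally). Adenoma visit rates are zero; stage IV presents fully.
    """
    sp = v.space
    m = v.masses.copy()
    tally = CycleTally()
    for s in CANCER_STAGES:
        rate = params.visits[f"ud_{s}"]
        flow = m[sp.index[f"ud_{s}"]] * rate
        if flow:
            m[sp.index[f"ud_{s}"]] -= flow
            m[sp.diag_slots[(s, None)][0]] += flow
            tally.new_diagnoses[s] += flow
            tally.colonoscopies_performed += flow
    return StateVector(sp, m), tally


#: incomplete-cure progression channels:
#: (source stage, source origin, probability key, target stage, target origin)
_POST_DIAG_CHANNELS = (
    ("I", None, "d_I_to_d_II", "II", "I"),
    ("II", None, "d_II_to_d_III", "III", "II"),
    ("II", "I", "d_II_to_d_III_from_I", "III", "I"),
    ("III", None, "d_III_to_d_IV", "IV", None),
    ("III", "II", "d_III_to_d_IV_from_II", "IV", None),
    ("III", "I", "d_III_to_d_IV_from_I", "IV", None),
)


def natural_history_step(
    v: StateVector,
    params: ParameterSet,
    age: int,
    variant: str | None = None,
) -> tuple[StateVector, CycleTally]:
    """One year of disease natural history and death.

    Sequential competing risks: stage-specific CRC mortality on every cancer
    compartment (preclinical and diagnosed), then age-specific other-cause
    mortality on all living compartments, then stepwise stage progression of
    the survivors. Diagnosed compartments do not progress in the base variant
    (diagnosis halts the disease); the ``scenario3`` variant applies the
    post-diagnosis channels with lineage bookkeeping, each progression
    counting as a new round of treatment at the new stage (tunnel clock
    restarts). Finally every tunnel advances one slot, the top band
    absorbing; the advancing mass is the year's surveilled person-years.
    """
    sp = v.space
    if variant is None:
        variant = sp.variant
    m = v.masses.copy()
    tally = CycleTally()
    nh = params.transitions.natural_history
    mu = {s: params.transitions.crc_mortality[f"crc_{s}"].value for s in CANCER_STAGES}
    q = mortality_for_age(params.mortality, age)

    # guard: nominal combined exit probability per compartment
    prog = {
        "normal": nh["normal_to_lr"].value,
        "lr_adenoma": nh["lr_to_hr"].value,
        "hr_adenoma": nh["hr_to_ud_I"].value,
        "ud_I": nh["ud_I_to_ud_II"].value,
        "ud_II": nh["ud_II_to_ud_III"].value,
        "ud_III": nh["ud_III_to_ud_IV"].value,
        "ud_IV": 0.0,
    }
    for comp, pr in prog.items():
        stage_mu = mu[comp[3:]] if comp.startswith("ud_") else 0.0
        if pr + q + stage_mu > 1.0 + 1e-9:
            raise ValidationError([f"combined exit probability at {comp} exceeds 1"])

    i_crc = sp.index["die_crc"]
    i_oth = sp.index["die_other"]

    # 1. CRC-specific mortality (preclinical and diagnosed)
    for s in CANCER_STAGES:
        idxs = [sp.index[f"ud_{s}"]]
        idxs += [int(i) for (st, o), sl in sp.diag_slots.items() if st == s for i in sl]
        for i in idxs:
            d = m[i] * mu[s]
            m[i] -= d
            m[i_crc] += d
            tally.crc_deaths += d

    # 2. other-cause mortality on every living compartment
    alive = [i for i in range(sp.n) if i not in (i_crc, i_oth)]
    for i in alive:
        d = m[i] * q
        m[i] -= d
        m[i_oth] += d
        tally.other_deaths += d

    # 3. stepwise progression, simultaneous from post-mortality masses
    chain = ("normal", "lr_adenoma", "hr_adenoma", "ud_I", "ud_II", "ud_III", "ud_IV")
    flows = {c: m[sp.index[c]] * prog[c] for c in chain[:-1]}
    for src, dst in zip(chain[:-1], chain[1:]):
        m[sp.index[src]] -= flows[src]
        m[sp.index[dst]] += flows[src]
    tally.stage_iv_entries += flows["ud_III"]

    # 4. post-diagnosis progression (incomplete-cure variant only)
    if variant == "scenario3" and params.transitions.post_diagnosis:
        post = params.transitions.post_diagnosis
        moves = []
        for src_s, src_o, key, dst_s, dst_o in _POST_DIAG_CHANNELS:
            pr = post[key].value if key in post else 0.0
            if pr == 0.0 or (src_s, src_o) not in sp.diag_slots:
                continue
            slots = sp.diag_slots[(src_s, src_o)]
            flow = m[slots] * pr
            moves.append((slots, flow, dst_s, dst_o))
        for slots, flow, dst_s, dst_o in moves:
            m[slots] -= flow
            total = float(flow.sum())
            m[sp.diag_slots[(dst_s, dst_o)][0]] += total
            tally.retreatments[dst_s] += total
            if dst_s == "IV":
                tally.stage_iv_entries += total

    # 5. tunnel advancement (top band absorbs); the mass flowing into slots
    # 2..h+1 is this year's post-treatment surveillance person-years
    for group, slots in sp.diag_slots.items():
        advancing = m[slots[:-1]].copy()
        tally.followup_person_years += float(advancing.sum())
        m[slots[:-1]] = 0.0
        m[slots[1:]] += advancing

    return StateVector(sp, m), tally


def _merge_tallies(into: CycleTally, other: CycleTally) -> None:
    into.screens_offered += other.screens_offered
    into.fit_performed += other.fit_performed
    into.colonoscopies_performed += other.colonoscopies_performed
    into.excisions_lr += other.excisions_lr
    into.excisions_hr += other.excisions_hr
    into.pathology_exams += other.pathology_exams
    into.adenoma_surveillance += other.adenoma_surveillance
    into.false_positives_created += other.false_positives_created
    into.followup_person_years += other.followup_person_years
    into.stage_iv_entries += other.stage_iv_entries
    into.crc_deaths += other.crc_deaths
    into.other_deaths += other.other_deaths
    into.screening_round = into.screening_round or other.screening_round
    for s in CANCER_STAGES:
        into.new_diagnoses[s] += other.new_diagnoses[s]
        into.retreatments[s] += other.retreatments[s]


def run_cohort(
    params: ParameterSet,
    strategy: StrategyConfig | str,
    variant: str = "base",
) -> Trace:
    """Run the full cohort from ``start_age`` to ``end_age`` under a strategy.

    Screening fires at model entry and every ``interval_years`` thereafter.
    Returns the complete :class:`Trace` (initial snapshot plus one snapshot
    and tally per cycle).
    """
    if isinstance(strategy, str):
        strategy = params.strategies[strategy]
    space = build_state_space(variant, params.followup_horizon_years)
    v = initialize_cohort(params, space)
    snapshots = [v.masses.copy()]
    tallies: list[CycleTally] = []
    i_fp = space.index["false_positive"]
    i_norm = space.index["normal"]

    for t in range(params.n_cycles):
        age = params.start_age + t
        cycle = CycleTally()
        # step 0: last cycle's false positives return to normal
        fp_mass = v.masses[i_fp]
        if fp_mass:
            v.masses[i_fp] = 0.0
            v.masses[i_norm] += fp_mass
        if strategy.modality != "none" and t % strategy.interval_years == 0:
            v, st = screening_event(v, strategy, params, age)
            _merge_tallies(cycle, st)
        v, ct = clinical_presentation(v, params)
        _merge_tallies(cycle, ct)
        v, nt = natural_history_step(v, params, age, variant)
        _merge_tallies(cycle, nt)
        snapshots.append(v.masses.copy())
        tallies.append(cycle)

    return Trace(space=space, start_age=params.start_age, snapshots=snapshots, tallies=tallies)
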