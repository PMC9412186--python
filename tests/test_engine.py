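"""Cohort engine: state space, cycle steps, conservation and absorption."""

import numpy as np
import pytest

from crcscreen.engine import (
    MACRO_STATES,
    StateVector,
    build_state_space,
    clinical_presentation,
    initialize_cohort,
    natural_history_step,
    run_cohort,
    screening_event,
)
from crcscreen.parameters import CANCER_STAGES, ValidationError


def zero_disease(ps):
    """All transition, mortality, and visit probabilities set to zero."""
    out = ps.copy()
    for key in out.transitions.natural_history:
        out.set_value(f"transitions.natural_history.{key}", 0.0)
    for key in out.transitions.crc_mortality:
        out.set_value(f"transitions.crc_mortality.{key}", 0.0)
    out.mortality.bands = [(lo, hi, 0.0) for lo, hi, _ in out.mortality.bands]
    for key in out.visits.by_stage:
        out.visits.by_stage[key].value = 0.0
    return out


class TestStateSpace:
    def test_base_variant_macro_states(self):
        sp = build_state_space("base", 5)
        for macro in MACRO_STATES:
            if macro.startswith("d_"):
                continue
            assert macro in sp.index
        assert len(MACRO_STATES) == 13
        assert "false_positive" in sp.index
        for s in CANCER_STAGES:
            assert len(sp.diag_slots[(s, None)]) == 6  # horizon 5 -> slots 1..6

    def test_minimal_horizon_two_slots(self):
        sp = build_state_space("base", 1)
        for s in CANCER_STAGES:
            assert len(sp.diag_slots[(s, None)]) == 2

    def test_scenario3_lineage_compartments(self):
        sp = build_state_space("scenario3", 5)
        # the stage III from-I compartment realizes the most-treated pathway
        assert ("III", "I") in sp.diag_slots
        assert ("III", "II") in sp.diag_slots
        assert ("II", "I") in sp.diag_slots
        assert "d_III_from_I_y1" in sp.index

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_state_space("bogus", 5)
        with pytest.raises(ValueError):
            build_state_space("base", 0)


class TestInitializeCohort:
    def test_zero_prevalence_everyone_normal(self, params):
        for key in params.prevalence:
            params.prevalence[key].value = 0.0
        sp = build_state_space("base", 5)
        v = initialize_cohort(params, sp)
        assert v["normal"] == params.cohort_size
        assert v.total() == params.cohort_size

    def test_prevalence_arithmetic(self, params):
        for key in params.prevalence:
            params.prevalence[key].value = 0.0
        params.prevalence["lr_adenoma"].value = 0.1
        v = initialize_cohort(params, build_state_space("base", 5))
        assert v["lr_adenoma"] == pytest.approx(10_000)
        assert v["normal"] == pytest.approx(90_000)

    def test_diagnosed_compartments_start_empty(self, base_params):
        sp = build_state_space("base", 5)
        v = initialize_cohort(base_params, sp)
        for (s, o), slots in sp.diag_slots.items():
            assert np.all(v.masses[slots] == 0.0)


class TestScreeningEvent:
    def test_zero_participation_is_identity(self, params):
        sp = build_state_space("base", 5)
        v = initialize_cohort(params, sp)
        strat = params.strategies["FIT1"]
        strat.participation.value = 0.0
        out, tally = screening_event(v, strat, params, age=50)
        assert np.allclose(out.masses, v.masses)
        assert tally.colonoscopies_performed == 0
        assert tally.false_positives_created == 0
        assert tally.excisions == 0

    def test_perfect_specificity_creates_no_false_positives(self, base_params):
        sp = build_state_space("base", 5)
        v = initialize_cohort(base_params, sp)
        out, tally = screening_event(v, base_params.strategies["eCSPY10"], base_params, 50)
        assert tally.false_positives_created == 0.0
        assert out["false_positive"] == 0.0

    def test_fit_detection_matches_per_person_expectation(self, params):
        """Expected stage-I diagnoses under FIT = N * participation *
        FIT sensitivity * colonoscopy compliance (confirmation certain)."""
        sp = build_state_space("base", 5)
        masses = np.zeros(sp.n)
        masses[sp.index["ud_I"]] = 1000.0
        v = StateVector(sp, masses)
        strat = params.strategies["FIT1"]
        p, s, c = 0.6, 0.75, 0.8
        strat.participation.value = p
        strat.colonoscopy_compliance.value = c
        params.tech["FIT"].sensitivity["crc_I"].value = s
        assert params.tech["colonoscopy"].cancer_detection("I") == 1.0
        out, tally = screening_event(v, strat, params, 50)
        assert tally.new_diagnoses["I"] == pytest.approx(1000 * p * s * c)
        assert out.masses[sp.diag_slots[("I", None)][0]] == pytest.approx(1000 * p * s * c)
        assert out.total() == pytest.approx(1000.0)

    def test_mass_conserved_under_screening(self, base_params):
        sp = build_state_space("base", 5)
        v = initialize_cohort(base_params, sp)
        for sid in ("FIT1", "eCSPY5"):
            out, _ = screening_event(v, base_params.strategies[sid], base_params, 50)
            assert out.total() == pytest.approx(v.total(), abs=1e-6)


class TestClinicalPresentation:
    def test_stage_iv_always_presents_adenomas_never(self, params):
        sp = build_state_space("base", 5)
        for s in CANCER_STAGES:
            params.visits.by_stage[f"ud_{s}"].value = 0.0
        params.visits.by_stage["ud_IV"].value = 1.0
        masses = np.zeros(sp.n)
        for name in ("lr_adenoma", "hr_adenoma", "ud_I", "ud_IV"):
            masses[sp.index[name]] = 100.0
        out, tally = clinical_presentation(StateVector(sp, masses), params)
        assert out["ud_IV"] == 0.0
        assert out.masses[sp.diag_slots[("IV", None)][0]] == 100.0
        assert out["ud_I"] == 100.0 and out["lr_adenoma"] == 100.0
        assert tally.new_diagnoses["IV"] == 100.0

    def test_visit_rate_arithmetic(self, params):
        sp = build_state_space("base", 5)
        params.visits.by_stage["ud_II"].value = 0.3
        masses = np.zeros(sp.n)
        masses[sp.index["ud_II"]] = 500.0
        out, tally = clinical_presentation(StateVector(sp, masses), params)
        assert tally.new_diagnoses["II"] == pytest.approx(150.0)
        assert out.masses[sp.diag_slots[("II", None)][0]] == pytest.approx(150.0)

    def test_empty_preclinical_is_identity(self, base_params):
        sp = build_state_space("base", 5)
        masses = np.zeros(sp.n)
        masses[sp.index["normal"]] = 1.0
        out, tally = clinical_presentation(StateVector(sp, masses), base_params)
        assert np.array_equal(out.masses, masses)
        assert sum(tally.new_diagnoses.values()) == 0


class TestNaturalHistoryStep:
    def test_zero_probabilities_identity_apart_from_tunnel(self, base_params):
        ps = zero_disease(base_params)
        sp = build_state_space("base", 5)
        masses = np.zeros(sp.n)
        masses[sp.index["normal"]] = 10.0
        masses[sp.diag_slots[("II", None)][0]] = 5.0  # slot 1
        out, _ = natural_history_step(StateVector(sp, masses), ps, 50)
        assert out["normal"] == 10.0
        assert out.masses[sp.diag_slots[("II", None)][0]] == 0.0
        assert out.masses[sp.diag_slots[("II", None)][1]] == 5.0

    def test_progression_arithmetic(self, base_params):
        ps = zero_disease(base_params)
        q = 0.07
        ps.set_value("transitions.natural_history.hr_to_ud_I", q)
        sp = build_state_space("base", 5)
        masses = np.zeros(sp.n)
        masses[sp.index["hr_adenoma"]] = 1000.0
        out, _ = natural_history_step(StateVector(sp, masses), ps, 50)
        assert out["ud_I"] == pytest.approx(1000 * q)
        assert out["hr_adenoma"] == pytest.approx(1000 * (1 - q))

    def test_single_step_progression_per_cycle(self, base_params):
        """Mass cannot traverse two chain links within one cycle."""
        ps = zero_disease(base_params)
        ps.set_value("transitions.natural_history.lr_to_hr", 1.0)
        ps.set_value("transitions.natural_history.hr_to_ud_I", 1.0)
        sp = build_state_space("base", 5)
        masses = np.zeros(sp.n)
        masses[sp.index["lr_adenoma"]] = 100.0
        out, _ = natural_history_step(StateVector(sp, masses), ps, 50)
        assert out["hr_adenoma"] == 100.0
        assert out["ud_I"] == 0.0

    def test_combined_exit_above_one_rejected(self, base_params):
        ps = zero_disease(base_params)
        ps.set_value("transitions.natural_history.ud_III_to_ud_IV", 0.8)
        ps.set_value("transitions.crc_mortality.crc_III", 0.3)
        sp = build_state_space("base", 5)
        v = StateVector(sp, np.zeros(sp.n))
        with pytest.raises(ValidationError):
            natural_history_step(v, ps, 50)

    def test_mortality_ordering_crc_before_background(self, base_params):
        """Sequential risks: CRC death claims its share first."""
        ps = zero_disease(base_params)
        ps.set_value("transitions.crc_mortality.crc_IV", 0.5)
        ps.mortality.bands = [(40, 74, 0.1)]
        sp = build_state_space("base", 5)
        masses = np.zeros(sp.n)
        masses[sp.index["ud_IV"]] = 100.0
        ps.visits.by_stage["ud_IV"].value = 0.0
        out, tally = natural_history_step(StateVector(sp, masses), ps, 50)
        assert tally.crc_deaths == pytest.approx(50.0)
        assert tally.other_deaths == pytest.approx(5.0)  # 10% of the survivors
        assert out["ud_IV"] == pytest.approx(45.0)


class TestRunCohort:
    def test_trace_shape_and_mass_conservation(self, base_params):
        for sid in base_params.strategies:
            trace = run_cohort(base_params, sid)
            assert len(trace) == base_params.end_age - base_params.start_age + 1 == 26
            for snap in trace.snapshots:
                assert snap.sum() == pytest.approx(base_params.cohort_size, abs=1e-6)
                assert np.all(snap >= -1e-9)

    def test_death_compartments_are_absorbing(self, base_params):
        trace = run_cohort(base_params, "FIT1")
        sp = trace.space
        deaths = [s[sp.index["die_crc"]] + s[sp.index["die_other"]] for s in trace.snapshots]
        assert all(b >= a - 1e-9 for a, b in zip(deaths, deaths[1:]))
        crc = [s[sp.index["die_crc"]] for s in trace.snapshots]
        assert all(b >= a - 1e-9 for a, b in zip(crc, crc[1:]))

    def test_zero_participation_fit_equals_no_screening(self, params):
        params.strategies["FIT1"].participation.value = 0.0
        t_fit = run_cohort(params, "FIT1")
        t_none = run_cohort(params, "none")
        for a, b in zip(t_fit.snapshots, t_none.snapshots):
            assert np.allclose(a, b)

    def test_decennial_screening_fires_at_entry_then_every_ten_years(self, base_params):
        trace = run_cohort(base_params, "eCSPY10")
        fired = [trace.start_age + t for t, tl in enumerate(trace.tallies) if tl.screening_round]
        assert fired == [50, 60, 70]

    def test_no_diagnoses_without_screening_or_visits(self, base_params):
        ps = base_params.copy()
        for key in ps.visits.by_stage:
            ps.visits.by_stage[key].value = 0.0
        trace = run_cohort(ps, "none")
        sp = trace.space
        for snap in trace.snapshots:
            for (s, o), slots in sp.diag_slots.items():
                assert np.all(snap[slots] == 0.0)

    def test_screening_reduces_cumulative_stage_iv(self, base_params):
        def stage4(sid):
            tr = run_cohort(base_params, sid)
            return sum(t.stage_iv_entries for t in tr.tallies)

        none = stage4("none")
        for sid in ("FIT1", "FIT2", "eCSPY10", "eCSPY5"):
            assert stage4(sid) <= none

    def test_scenario3_with_zero_channels_matches_base(self, base_params):
        ps = base_params.copy()
        from crcscreen.parameters import POST_DIAGNOSIS_KEYS, UncertainParameter

        ps.transitions.post_diagnosis = {
            k: UncertainParameter.point(0.0) for k in POST_DIAGNOSIS_KEYS
        }
        t3 = run_cohort(ps, "FIT1", variant="scenario3")
        tb = run_cohort(base_params, "FIT1", variant="base")
        for s3, sb in zip(t3.snapshots, tb.snapshots):
            for macro in MACRO_STATES:
                assert t3.space.macro_mass(s3, macro) == pytest.approx(
                    tb.space.macro_mass(sb, macro), abs=1e-9
                ), macro
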