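# Methods

## Model structure

The model is a deterministic cohort state-transition (Markov) model with a
1-year cycle. A closed cohort (default 100,000 people) enters at
`start_age` (default 50) and is simulated until `end_age` (default 75), i.e.
25 cycles with 26 state snapshots. Compartments:

* `normal`, `lr_adenoma`, `hr_adenoma` — the adenoma–carcinoma precursor
  chain. Low-risk adenomas are polyps < 10 mm; high-risk adenomas are
  ≥ 10 mm or villous. Serrated and de-novo pathways are excluded.
* `ud_I` … `ud_IV` — preclinical (undiagnosed, asymptomatic) cancer by TNM
  stage. Progression is strictly stepwise: a compartment can advance at
  most one link per cycle.
* `d_I` … `d_IV` — diagnosed cancer, expanded into tunnel slots
  `1..h+1` where `h = followup_horizon_years` (default 5). Slot 1 is the
  diagnosis year; the top band absorbs in time. In the base case diagnosis
  halts progression (treatment is fully effective).
* `false_positive` — a transient state for test-positive, disease-free
  people; occupied for exactly one cycle.
* `die_crc`, `die_other` — absorbing death states.

The incomplete-cure variant (`scenario3`) additionally splits diagnosed
stage II into lineages {native, from_I} and stage III into
{native, from_II, from_I}, where the lineage records the stage at first
diagnosis. Each lineage has its own onward progression probability,
increasing with the number of prior treatment rounds (25–45%/year); a
progression places the patient in slot 1 of the next stage's compartment,
is costed as a fresh round of stage treatment, and restarts the follow-up
clock. Stage IV needs no lineage split because it has no onward
progression; stage-specific CRC mortality applies to every lineage at its
current stage.

## Cycle order and competing risks

Each cycle applies, in a fixed, documented order:

0. last cycle's false positives return to `normal`;
1. scheduled screening (first offer at model entry, then every
   `interval_years`);
2. symptomatic clinic presentation: fraction `visit_rate(stage)` of each
   preclinical compartment is diagnosed (with a diagnostic colonoscopy);
   adenomas never present (rate 0), stage IV always does (rate 1);
3. natural history: stage-specific CRC mortality on every cancer
   compartment (preclinical and diagnosed), then age-specific other-cause
   mortality on all living compartments, then stepwise progression of the
   survivors (flows evaluated simultaneously from post-mortality masses),
   then the scenario-3 post-diagnosis channels, then tunnel advancement.

Competing risks are resolved sequentially (CRC death first, then background
death, then progression), each applying to the survivors of the previous
step, so cohort mass is conserved identically — mirroring spreadsheet-style
cohort models and making every intermediate quantity auditable. A guard
raises if the nominal sum of exit probabilities at any compartment exceeds
1. Screening precedes that year's presentation and progression because a
screen detects prevalent disease before it can progress within the year.

The false-positive return is implemented as step 0 of the *next* cycle
rather than inside the natural-history step: with screening first in the
cycle, a same-cycle return would empty the state before it was ever
observed, contradicting the one-year false-positive treatment assumption.

## Screening mechanics

Eligible mass = alive, undiagnosed, not currently in the false-positive
state. A fraction `participation` is tested each scheduled round
(independently across rounds; the cohort model carries no participation
memory).

* **FIT then colonoscopy**: test-positive fractions are
  `1 − specificity` for normals and the lesion-specific FIT sensitivity
  otherwise. Positives undergo confirmatory colonoscopy with probability
  `colonoscopy_compliance`; non-compliant positives are untreated.
  Colonoscopy then confirms cancer with certainty (gold standard), detects
  adenomas with `sensitivity × (1 − miss_rate)`, and clears disease-free
  positives, who occupy the false-positive state for one cycle.
* **Primary colonoscopy**: participants are scoped directly; colonoscopy
  specificity is fixed at 1, so no false positives arise.

Detected adenomas are excised (excision rate 100%) and return to `normal`;
each excision is costed as colonoscopy + excision + histopathology + one
surveillance colonoscopy + the adenoma treatment episode. Detected
preclinical cancers move to the stage-matched diagnosed slot 1. The
colonoscopy polyp-miss fraction (19.39%) discounts adenoma detection only;
a config switch (`miss_applies_to_cancer`) extends it to cancer.

## Economics

Costs and QALYs are accrued per cycle and discounted at `(1+r)^-t`
(default r = 5%/year), with state membership valued at cycle start and
events valued in the cycle they occur; no half-cycle correction by default
(an `accrue(..., half_cycle=True)` flag enables it for the QALY stream).
Cost components: programme organisation fee once per screening round
(amortized over the cohort), FIT kits, colonoscopies (screening,
confirmatory, diagnostic), excision/pathology/surveillance units, adenoma
treatment episodes, first-year stage treatment per diagnosis (and per
scenario-3 progression), and the annual CRC surveillance cost for the first
`h` years after each diagnosis. The surveillance cost is paid on the tunnel
advancement flows into slots `2..h+1` — the top band's self-loop pays
nothing — which yields exactly `h` annual payments per surviving diagnosed
patient and lets surveillance stop after the horizon without an extra
compartment.

Utilities: `normal` = 1 and `death` = 0 exactly; adenomas and cancer stages
carry weights from an SF-6D-based patient study. Preclinical stage *s*
carries the same weight as diagnosed stage *s* — a disease-burden reading
chosen because the alternative (utility 1 for asymptomatic preclinical
cancer) would make early detection mechanically QALY-negative at equal
survival. False positives keep the normal weight (their colonoscopy is
negative, so no treatment beyond the scope is plausible).

Epidemiological counters: cumulative stage-IV entries (initial prevalent
`ud_IV` mass, `ud_III→ud_IV` flows, and scenario-3 entries into `d_IV`) and
cumulative all-cause and CRC-specific deaths at the end of simulation. The
published "number of CRC patients / deaths" counters are of all-cause
magnitude (~30,000 deaths per 100,000 over 25 years), so the all-cause
total is the headline counter and CRC deaths are reported separately.

## Uncertainty analysis

Every scalar input carries a `(value, low, high, family, provenance)`
record. The printed tables use mean ± 25% bounds; sampling reads
`(low, high)` as a central 95% interval, so `sd = (high − low)/(2×1.96)`,
and parameterizes Beta (probabilities, utilities) or Gamma (costs) by
method of moments. Degenerate probabilities (0 or 1) are point masses.

* **DSA**: each parameter is set to its low and high bound in turn (all
  else at base), the full model rerun for both strategies, and entries
  sorted by ICER swing. The baseline is recomputed per run, never cached.
* **PSA**: per iteration one joint draw, independent across parameters (no
  correlation structure is specified), full model run per strategy;
  reproducible from a single seed via per-parameter substreams
  (`numpy` `SeedSequence.spawn`). CEAC: at each willingness-to-pay value
  the fraction of iterations in which a strategy has the highest net
  monetary benefit, ties split equally.
* The discount rate is treated like any other bounded parameter.

## Scenarios

* `shenzhen` — replaces the four CRC stage-treatment costs with the
  regional block and raises prevalence by the local detection-rate ratio
  (placeholder factor 1.08); screening unit costs are unchanged, as only
  treatment costs are tabulated regionally.
* `start40` — entry age 40 (36 snapshots; the mortality table's 40–49
  bands engage).
* `incomplete_treatment` — installs the post-diagnosis progression table
  and switches to the lineage-split state space. With all channels at 0 it
  reproduces the base variant exactly (a tested invariant).

`apply_scenario` is pure; scenario data live in the parameter file's
`scenarios` block.

## Packaged parameters and calibration

The packaged file `crcscreen/data/base_case.yaml` tags every entry:

* `paper_table` — the printed cost tables, mortality bands, scenario-3
  transition probabilities, colonoscopy miss rate and perfect specificity,
  discount rate;
* `supplementary_sm1` — screening performance and uptake;
* `reference_placeholder` — quantities the source literature cites without
  tabulating (natural-history transitions, CRC mortality, utilities,
  prevalence, visit rates).

Placeholder values were set once, by grid search within literature-typical
ranges, so that the packaged base case reproduces the published qualitative
pattern (FIT schedules dominant over no screening, annual dominant over
biennial, colonoscopy schedules cost- and QALY-increasing versus FIT with
ICERs under the threshold, all strategies dominant under incomplete cure,
and more cancers prevented when starting at 40):
normal→lr 0.02, lr→hr 0.04, hr→CRC 0.045/yr; preclinical stage progression
0.45/0.50/0.55; CRC mortality 0.02/0.06/0.13/0.45; visit rates
0.10/0.25/0.45 (stages I–III); prevalence at 50: 15% low-risk, 6% high-risk
adenoma, 0.2% preclinical cancer; FIT sensitivity 0.02 (low-risk), 0.35
(high-risk — far below colonoscopy, as the source stresses), 0.70–0.85 by
cancer stage, specificity 0.985; FIT participation 0.65 with 90%
colonoscopy compliance after a positive test; colonoscopy participation
0.65. Quantitative published values (per-person deltas, ICER magnitudes,
case counts) are therefore *not* reproduced exactly and are never asserted;
only ordering and dominance patterns are.

## Synthetic generator and microsimulation oracle

`generate_parameter_set` draws complete, validated parameter sets from
documented plausible ranges (one table in `synthetic.py`): adenoma-chain
transitions 0.5–5%/yr, preclinical progression 30–60%/yr, stage-monotone
mortality, costs ordered I ≤ II ≤ III ≤ IV, utilities strictly decreasing
with stage, screening sensitivities 30–99% (FIT polyp sensitivity well
below colonoscopy). The `stress` level widens probability ranges to the
boundaries. The generator emulates the *structure* the analysis assumes,
not Chinese epidemiology; passing tests on generated sets demonstrates
engine correctness, not real-world predictive validity.

`microsim_oracle` simulates independent individuals through the identical
event order with per-person Bernoulli draws and reports means with
Monte-Carlo standard errors. Because the cohort engine computes the exact
expectation of this stochastic process, the two must agree within sampling
error; the test suite checks cost, QALYs and deaths within 3 SE at 10⁶
agents on three generated parameter sets (and at smaller scale in the unit
tests), which bounds any systematic engine/oracle discrepancy at roughly
0.1% of the outcome scale.

## Numerical choices and problem sizes

* All cohort arithmetic is float64; mass conservation is asserted to 1e-6
  absolute on a cohort of 100,000.
* Screening calendars anchor at model entry (ages 50, 60, 70 for e-CSPY10).
* Sampler moment-recovery tests use 10⁵ draws (3-SE criterion); PSA-based
  tests run at 25–400 iterations, the acceptance script at 10,000; the
  microsimulation cross-check uses 10⁶ agents (≈2–7 s per run) in the
  acceptance suite and 1.5×10⁵ in unit tests.
* The tornado for (no screening vs FIT1) varies all 69 uncertain
  parameters (≈1 s for 276 model runs).

## Known limitations

* No individual heterogeneity beyond age; no sex stratification; no
  adverse-event mortality from colonoscopy; no serrated/de-novo pathways;
  no correlation between sampled parameters in the PSA.
* Placeholder parameters make absolute outputs (costs, QALYs, case counts)
  indicative only; orderings were the calibration target.
* Participation is redrawn independently each round; persistent
  never-attender behaviour would lower screening effectiveness.
* The programme organisation fee is amortized per round over the whole
  cohort; alternative allocations (one-off, per participant) change FIT's
  cost advantage and are exposed only through the cost table itself.
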