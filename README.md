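# crcscreen

A Markov cohort model for the cost-effectiveness of colorectal-cancer (CRC)
screening in an average-risk Chinese population, written for health
economists and screening-programme analysts. It compares four strategies —
annual and biennial fecal immunochemical testing (FIT1, FIT2) and electronic
colonoscopy every 10 or 5 years (e-CSPY10, e-CSPY5) — against no screening,
from the healthcare-system perspective, in 2021 USD.

## The model

A closed cohort of 100,000 people enters at age 50 and is followed in annual
cycles to age 75 through the adenoma–carcinoma sequence

```
normal → low-risk adenoma → high-risk adenoma → preclinical CRC I → II → III → IV
```

with stage-matched diagnosed states, a transient false-positive state, and
two absorbing death states (CRC death, other-cause death) — 13 health states
in all. Preclinical cancer is found either by screening or by a symptomatic
clinic visit; adenomas found at colonoscopy are excised and the person
returns to normal; diagnosis halts progression in the base case. Diagnosed
states are tunnel states (years since diagnosis) so post-treatment
surveillance costs stop after 5 years.

Per strategy the model accrues discounted (5%/year) per-person costs `C` and
quality-adjusted life years `E`, and classifies each pairwise comparison by
the incremental cost-effectiveness ratio

```
ICER = (C_b − C_a) / (E_b − E_a)   [USD/QALY]
```

or by dominance (cheaper *and* more effective). Uncertainty is handled by
one-way deterministic sensitivity analysis (tornado) and probabilistic
sensitivity analysis (Beta for probabilities/utilities, Gamma for costs;
method-of-moments from the tabulated mean and ±25% bounds), summarised as
net-monetary-benefit acceptability curves against the willingness-to-pay
threshold of China's 2021 GDP per capita (12,554.42 USD/QALY). Three
scenario presets modify the base case: Shenzhen treatment costs and
prevalence, screening from age 40, and incompletely successful treatment
(diagnosed cancer keeps progressing, faster with each treatment round).

Parameters the source literature does not tabulate ship as flagged
placeholders in the packaged parameter file; see `docs/methods.md` for every
value, its provenance tag, and the calibration rationale.

## Worked example

```python
import crcscreen as c

params = c.base_case_parameter_set()
summaries = c.run_strategy_suite(params)          # 5 strategies, 25 cycles
matrix = c.icer_matrix(summaries)

for sid in ("FIT1", "FIT2", "eCSPY10", "eCSPY5"):
    r = matrix[("none", sid)]
    print(f"{sid:8s} dCost {r.delta_cost:+8.2f} USD  dQALY {r.delta_qaly:+.4f}  "
          f"{r.verdict:8s} ratio {r.icer:8.2f}")
r = matrix[("FIT2", "eCSPY10")]
print(f"e-CSPY10 vs FIT2: ICER = {r.icer:.2f} USD/QALY (threshold 12554.42)")
```

prints

```
FIT1     dCost   -92.22 USD  dQALY +0.2067  dominant ratio  -446.23
FIT2     dCost   -41.88 USD  dQALY +0.1453  dominant ratio  -288.29
eCSPY10  dCost   +60.61 USD  dQALY +0.2568  icer     ratio   236.04
eCSPY5   dCost  +136.40 USD  dQALY +0.3379  icer     ratio   403.72
e-CSPY10 vs FIT2: ICER = 919.18 USD/QALY (threshold 12554.42)
```

Read: both FIT schedules save money and gain QALYs relative to no screening
(dominant — the negative ratio is reported only for completeness), while the
colonoscopy schedules buy additional QALYs at a cost per QALY far below the
willingness-to-pay threshold.

The same pipeline is scriptable from the shell:

```bash
crcscreen run --outdir out/base                 # traces, outcomes, ICER matrix
crcscreen run --scenario start40 --outdir out/s2
crcscreen dsa --comparator FIT1 --outdir out/dsa
crcscreen psa --n-iter 10000 --seed 1 --outdir out/psa
crcscreen generate --seed 7 --out synth.yaml    # synthetic parameter file
```

Every output directory contains a `manifest.json` sufficient to reproduce
the run.

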