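# afcea — cost-effectiveness of catheter ablation for atrial fibrillation

`afcea` is a Python implementation of a Canadian health-economic model
comparing **catheter (pulmonary-vein) ablation** with **antiarrhythmic drug
therapy** (amiodarone 200 mg/day) for rhythm control of paroxysmal atrial
fibrillation (AF) in patients who have already failed one antiarrhythmic.
It is written for health-economics and HTA analysts who want a tested,
scriptable version of the model: every input is a named parameter, every
analysis is a plain function, and the whole pipeline is deterministic given
a seed.

## The model

The analysis chains a **one-year decision tree** to a **Markov cohort
model** with 3-month cycles over a 5-year horizon (costs in 2010 CAD,
costs and QALYs discounted at 5%/year after the first year):

* **Year 1.** Ablation patients face per-procedure complication risks
  (stroke 0.003, TIA 0.002, tamponade 0.008, PV stenosis 0.016, scaled by
  1.27 procedures/patient) and the procedure cost $9,590 × 1.27 = $12,179;
  drug patients face amiodarone pulmonary toxicity (0.00832/yr; fatal in
  0.091, irreversible in 0.25). At 12 months patients are in normal sinus
  rhythm (NSR) with probability *p*<sub>NSR</sub> = 0.26 on drugs — pooled
  from five randomized trials by DerSimonian–Laird random-effects
  meta-analysis of raw proportions — and min(2.93 × 0.26, 1) = 0.756 after
  ablation.
* **Markov phase.** States {NSR, AF, post-ischemic-stroke year 1 (tunnel),
  post-stroke later, post-ICH year 1 (tunnel), post-ICH later, dead}. Each
  cycle patients risk ischemic stroke (annual 0.04 at CHADS₂ = 2 in AF,
  × 1/1.6 in NSR), major bleeds (0.0129/yr on warfarin, 0.0058 off; 33.2%
  intracranial), AF recurrence (0.036/yr after ablation, 0.221/yr on
  drugs), and death (life table, with stroke-state multipliers 1.78/2.3 and
  1.2 for ICH year 1). AF carries a utility decrement of 0.046.
* **Outputs.** Expected discounted cost and QALYs per strategy, expected
  strokes, and the incremental cost-effectiveness ratio
  ICER = ΔCost/ΔQALY, plus probabilistic sensitivity analysis (1000
  Monte-Carlo draws over the published beta/gamma/lognormal distributions)
  with cost-effectiveness acceptability curves, and a one-way sensitivity
  grid (age, sex, CHADS₂, horizon, discount rate, AF disutility, recurrence,
  structural switches).

Three external tables the model needs (a life table, age/sex 28–30-day
stroke and ICH case fatality, age/sex population utilities) are not in the
public domain of the model's printed inputs; the package ships deterministic
**synthetic stand-ins** (`afcea.fixtures`) with the right structure and
magnitudes, and loads real tables from CSV (`age,sex,value`) when you have
them — headline numbers below therefore differ a few percent from the
original report.

## Worked example

```python
from afcea.cea import run_basecase
print(run_basecase().summary())
```

prints (with the shipped synthetic tables):

```
ablation: cost $21,285, QALYs 3.326, strokes 0.134
aad:      cost $12,203, QALYs 3.189, strokes 0.164
incremental: cost $9,082, QALYs 0.137, strokes -0.029, $66,478/QALY
```

Read: over five years ablation costs $9,082 more per patient, prevents
0.029 strokes and gains 0.137 quality-adjusted life years, so a decision
maker pays about $66k per QALY gained — cost-effective at a $100k/QALY
threshold, borderline at $50k. The `examples/` scripts walk through each
capability (evidence pooling, basecase, PSA/CEAC, sensitivity grid), and a
thin CLI mirrors them:

```bash
afcea basecase --out results/
afcea psa --n-draws 1000 --seed 1 --out results/
afcea owsa --out results/
```

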