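# Methods

This note documents the model as implemented: its structure, the reasoning
behind the discretionary choices, what the synthetic stand-in tables do and
do not emulate, and the numerical conventions. Parameter values and their
sources-of-record are listed field by field in
`afcea.parameters.ParameterSet`; nothing here states a number the test
suite or `scripts/acceptance.py` does not itself compute.

## Model structure

The cohort is simulated with a single cycle engine (3-month cycles) over a
5-year horizon. The first model year is implemented as the first four
cycles of that engine with strategy-specific overlays rather than as a
separate tree evaluation, so stroke, bleeding and mortality risk accrue
during year 1 exactly as in later years:

* The 12-month rhythm outcome is applied as the cycle-0 split (probability
  of sinus rhythm: pooled drug value 0.2578; × 2.93, capped at 1, for
  ablation). The failure fraction therefore carries the AF utility
  decrement, AF-level stroke risk, and (drug arm) amiodarone exposure from
  the start of the year. AF recurrence dynamics begin after cycle 4.
* Ablation overlays: procedure + first-year follow-up costs at cycle 0;
  complication probabilities treated as per-procedure values scaled by the
  expected 1.27 procedures per patient (configurable via
  `scale_complications_by_procedures`); procedural strokes enter the
  first-year stroke tunnel permanently; TIA/tamponade/PV-stenosis incur a
  one-off cost and 7 days of full disutility; warfarin is carried only for
  cycle 0 (`warfarin_stop_cycle_ablation = 1`, i.e. discontinuation three
  months after the procedure).
* Drug-arm overlays: amiodarone, warfarin (44% of the cohort) and
  monitoring costs all year; pulmonary-toxicity hazard from cycle 0.

Whether the stated 5-year horizon contains the first year (20 cycles
total) or precedes five further Markov years (24 cycles) is ambiguous in
the source description. The default is 20 cycles: it reproduces the
published per-arm expectations far better (expected costs 21,285/12,203 vs
published 21,150/12,611; QALYs 3.33/3.19 vs 3.42/3.27) than the 24-cycle
reading (22,762/14,347; 3.82/3.65). `include_first_year_in_horizon=False`
selects the longer reading.

### States and transitions

States: NSR, AF, a four-cycle tunnel for the first year after ischemic
stroke, post-stroke later years, a four-cycle ICH tunnel, post-ICH later
years, dead. Stroke states are permanent (no exit to rhythm states, no
recurrent strokes), so rhythm-dependent stroke risk no longer applies after
a first event; ICH counts are reported separately from ischemic strokes.

Within a cycle, rhythm-state occupants face events in a fixed order —
background death, ischemic stroke, major bleed (split 33.2% ICH, which
changes state, vs gastrointestinal, which costs $6,023 but does not),
pulmonary-toxicity death (amiodarone-treated occupants only), AF
recurrence — composed multiplicatively so each row sums to one by
construction. The ordering is a convention; at 3-month probabilities its
effect is below the resolution of the 10,000-individual microsimulation
oracle the tests compare against (agreement required within 3 Monte-Carlo
standard errors on an 8-cycle instance).

Annual probabilities convert to cycle probabilities by constant-hazard
compounding, `1 − (1 − p)^0.25`, the standard cohort-model conversion; the
inverse round-trips to 1e-9 in the property tests.

Treatment switching: ablation patients who fail at 12 months or recur
later move to drug therapy — they acquire amiodarone cost, the
pulmonary-toxicity hazard and warfarin at the cohort proportion (0.44)
from the AF state onward. Drug-arm patients in AF remain on amiodarone
(the `amiodarone_stop_in_af` switch implements the scenario where the drug
is stopped outside sinus rhythm, removing both its cost and its toxicity
hazard).

### Mortality

Background mortality comes from the (stand-in) life table. Stroke-state
mortality replaces (rather than adds to) background risk in the first
post-event year: the 28-day ischemic case fatality × 1.78, or the 30-day
ICH case fatality × 1.2, is treated as the total first-year probability
and spread over the four tunnel cycles as a constant hazard. Later years
use background mortality × 2.3 after ischemic stroke and background
mortality (× 1) after ICH, since only a first-year factor is available for
ICH.

### Rewards, discounting, counting

State rewards accrue on the end-of-cycle occupancy: an event takes effect —
state, cost, utility — within the cycle it occurs, so a counted stroke
always carries stroke costs. This choice, rather than beginning-of-cycle
accrual, also matches the published per-arm cost levels distinctly better.
No half-cycle correction is applied (`half_cycle_correction=True` averages
start- and end-of-cycle occupancy for exploration). One boundary
adjustment follows from the convention: procedural strokes are seeded into
the tunnel at cycle 0 rather than occurring in-cycle, so one quarter of
the (first-year − later) stroke cost is added as a one-off to restore a
full year of stroke cost.

First-year quantities are undiscounted; later cycles discount at
`(1 + r)^(−t)` with t in years from model start (5%/yr default). Stroke
and ICH counts are undiscounted expectations; "strokes" means procedural
plus incident ischemic strokes, with ICH reported separately.

Utilities: NSR uses the age/sex population utility; AF subtracts 0.046;
stroke states use 0.46 (ischemic) and 0.28 (ICH) flat. Irreversible
pulmonary toxicity is tracked as an aggregate prevalence overlay — a
scalar mass scaled each cycle by cohort survival — whose utility is
*replaced* by 0.6 (relative to the population utility at that age) and
which accrues $3,799/yr. Because prevalence stays below ~0.5% of the
cohort, the aggregate treatment (rather than a full state expansion) and
the use of the population utility as the replaced baseline are negligible
approximations. Acute toxicity adds a $20,436 one-off and 13 days of full
disutility per case.

## Evidence pooling

The drug-arm 12-month sinus-rhythm probability is pooled from the five
shipped trial arms by DerSimonian–Laird random-effects meta-analysis on
the untransformed proportion scale with binomial within-study variance
p(1−p)/n. This scale (not logit) reproduces both the published pooled
value (0.26, CI 0.17–0.34) and the published per-study weights; the tests
verify this and cross-check the estimator against R's `metafor`
(`rma(method = "DL")`). Boundary event counts use a 0.5/(n+1) continuity
adjustment (never triggered by the shipped table).

## Synthetic stand-in tables

Three inputs are emulated because the original external tables are not
reproducible here:

* **Life table** — Gompertz–Makeham hazard `c + a·e^{b·age}` (a = 8e-5,
  b = 0.08/yr, c = 5e-4, female = 0.65 × male), giving a 65-year-old male
  an annual death probability of 0.015 and ≈ 0.92 five-year survival, the
  magnitude general-population tables show.
* **Event case fatality** — age-banded 28/30-day death probabilities
  anchored at 0.189 (ischemic stroke) and 0.48 (ICH) for the 60–69 band,
  rising with age, identical across sexes.
* **Population utilities** — linear in age, 0.83 at 65 declining 0.03 per
  decade, clamped to [0, 1].

All three are deterministic parametric curves (regeneration is
bit-identical) and can be replaced by real registry/statistical-agency
tables via CSV files in the documented schema. Consequences for validation:
results that depend only on printed parameters (derived-value arithmetic,
pooling, distribution calibration, orderings of the sensitivity grid)
reproduce exactly, while absolute cost/QALY levels shift a few percent —
the shipped tables give a basecase ICER of $66,478/QALY against the
published $59,194 (within 15%), with all incremental signs agreeing. Two
published results are **not** reproduced under the stand-ins and are left
failing in the acceptance suite rather than tuned toward: strict cost
dominance of ablation at a 20-year horizon (the model yields a decreasing
ICER, ≈$10k/QALY at 20 years, but incremental cost stays ≈ +$4.9k — the
printed drug and stroke cost differentials appear arithmetically unable to
close an $8.5k gap over 15 discounted years), and the acceptability
probability 0.89 at $100k/QALY (the model gives ≈0.71, consistent with
the deterministic ICER sitting 12% above the published value). CHADS₂
scores other than 2 likewise ship as editable literature-typical stand-in
rates (score 2 → 0.04 is the modelled value).

## Probabilistic sensitivity analysis

Each of 1000 draws samples all uncertain parameters independently
(beta for probabilities/proportions/utilities, gamma(shape, scale) for
costs, lognormal for relative risks; fixed values untouched), including
the warfarin uptake of the cohort profile and the CHADS₂ = 2 stroke rate,
then re-runs both arms deterministically. The acceptability curve uses the
net-monetary-benefit rule — ablation preferred when λ·ΔQALY − ΔCost > 0 —
which handles negative deltas coherently; no correlation structure is
imposed because none is published. Three tabulated values were corrected
after failing arithmetic verification (each documented in the code): the
NSR beta's second parameter (76.11, not 176.11, to match its own printed
mean/CI and the pooled estimate), one transposed CI bound (10,079 printed
as 10,709), and the two AF-recurrence rows whose printed labels/CIs are
swapped or scrambled — their α/β are assigned per the narrative text
(ablation 0.036, drug 0.221) and they are excluded from CI calibration.
Where the narrative text and the distribution table disagree on a cost,
the basecase uses the text value and the PSA samples the tabulated
distribution, with a warning logged at build time; both are retained in
configuration.

## Sensitivity grid

`afcea.owsa.builtin_scenarios()` ships the full one-way grid: starting age
{55…75} × sex (life-table/utility lookups move; stroke risk held at the
profile's CHADS₂ rate), CHADS₂ 0–4, horizons {3, 5, 10, 20} years,
discount {0, 3, 5}%, AF disutility {0–0.08}, ablation recurrence {0–0.05},
no-stroke-benefit-of-NSR, and amiodarone-discontinuation-in-AF. An
age-varying stroke-risk hook (`rr_stroke_by_age`, a step function of age)
exists for users with age-specific relative risks; no values are shipped.

## Problem sizes and determinism

Default analyses use the published sizes: 1000 PSA draws, 20 model cycles
(80 at the longest horizon). The validation microsimulation uses 10,000
individuals over 8 cycles. All randomness flows through a single
`numpy.random.Generator` seeded by the caller; repeated runs are
byte-identical, and the fixture generators contain no randomness at all.

## Known limitations

No recurrent strokes, no aspirin or novel-anticoagulant arms, no
correlation between sampled parameters, no currency-inflation engine, and
no individual-level heterogeneity beyond the branch probabilities. Cycle
length is fixed at 3 months (the first-year tunnels assume four cycles per
year). Warfarin and bleed risk stop applying after a first stroke or ICH,
and procedural TIA is modelled as fully transient; both are
simplifications the source description leaves open.
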