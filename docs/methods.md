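# Methods

This note records the model, the conventions the package had to pin down
where the published material is qualitative, the simulator's scope, and
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The classification model

Classification is a walk of binary decision trees. The *basic* tree routes
on menarche, age, contraception and bleed recency; the *natural-cycle*
subtree assigns one leaf per closed cycle from length, annual bleed count,
urinary LH results and mid-luteal serum progesterone. The tree adjacency is
shipped as data (`src/mhm/data/trees.yaml`), not code: the original figures
are images, so the exact question order is a reconstruction; shipping it as
data keeps alternative orders loadable and auditable. Every result carries
the ordered list of (question, answer) pairs actually walked.

### Thresholds and boundary semantics

All printed clinical values live in one overridable `Thresholds` record
(YAML-configurable; defaults are the published numbers):

| quantity | default | semantics |
| --- | --- | --- |
| regular cycle range | 21–35 d | inclusive; prolonged strictly > 35 d |
| annual bleeds (regular) | > 9/yr | oligomenorrheic at ≤ 9 in a fully observed year |
| short luteal phase | < 14 d | luteal = `length − lh_day + 1` (counts the LH day) |
| eumenorrheic mid-luteal P4 | > 16 nmol/L | ≤ 16 is the low-progesterone defect; any measured P4 still confirms ovulation |
| secondary amenorrhea | ≥ 3 months | 30-day months, so 90 days |
| primary amenorrhea | age ≥ 15 | or ≥ 14 with no secondary sex characteristics |
| heavy menstrual bleeding | > 80 ml | strictly; persistent beyond (strictly) 7 flagged cycles |

The source tables state the oligomenorrhea boundary both as "> 35 days" and
as "35 days or more"; the strict form was adopted (matching the complement
of the 21–35-day regular range) and the value is a config key, so the other
reading is one override away.

### Tier caps (the privacy contract)

Each event kind has a monitoring tier: 0 bleed dates and contraception
context, 1 symptoms/BBT/mucus/loss ratings, 2 urinary LH, 3 serum
progesterone. `classify(log, cap)` deletes events above the cap before
anything is computed, so classifying a capped log and classifying a
pre-stripped log are identical by construction — and verified by test.
Consequences: at cap < 2 a cycle can reach at most B1 (naturally
menstruating, untested); at cap 2 a positive LH test yields
`B1_PROBABLE_OV` — ovulation *probable*, never confirmed, because
confirmation requires the tier-3 blood test. Raising the cap can only
sharpen a result, never coarsen it (tier monotonicity, tested exhaustively
over phenotypes × caps on noise-free logs).

### Individual-level aggregation

Status is per cycle; the individual-level leaf is the most recent closed
cycle's leaf, with two deliberate exceptions:

* **Oligomenorrhea is an annual judgement.** The F leaf stands at the
  individual level only when the fully observed 365-day bleed count is at
  or below the threshold. A single > 35-day cycle inside an otherwise
  regular year keeps its per-cycle F but holds the individual at the
  conservative B1 node with an `OLIGO` review flag. Annualized counts from
  partial logs are flagged `EXTRAPOLATED` and never trigger F on their own.
* **A log with no closed cycle** (one open cycle, or none) classifies
  conservatively as B1/UNKNOWN rather than erroring, so short logs are
  usable from day one.

When either exception rewrites the leaf, the recorded node path is re-walked
with the conservative answers so it remains a valid root-to-leaf trail.

Review flags (`HMB`, `HMB_PERSISTENT`, `SHORT_LUTEAL`, `LOW_P4`, `OLIGO`,
`AMENORRHEA`, `EXTRAPOLATED_COUNT`, `MEDICAL_REVIEW`) are non-diagnostic;
each carries the instruction string "medical review required" and nothing
else.

## Segmentation conventions

* Cycle days are 1-based; day 1 is the first bleed day. A bleed onset is a
  bleed day with no bleed the previous calendar day (multi-day menses
  merge; spotting is not distinguished).
* The per-menses blood-loss estimate attaches to the menses' first day.
* The biphasic BBT rule is the "three over six" convention: the first day
  whose temperature and the next two (consecutive, recorded) all exceed the
  maximum of the previous six recorded temperatures by ≥ 0.2 °C. The
  source material gives direction only, no algorithm; threshold, baseline
  window and run length are config arguments. Detected shifts are advisory
  evidence only — they never substitute for LH or progesterone in the
  trees. Under the simulator's default noise (shift +0.35 °C, σ 0.05 °C)
  the rule detects within ±1 day of the true shift in roughly 79% of
  replicates (computed in the test suite): the margin over the 0.2 °C
  threshold is small relative to the noise in the max-of-six baseline, so
  imperfect sensitivity is expected, which is exactly why the rule is
  advisory.

## Contraception schedules

Dose levels are ordinal labels (constant / step-up) because no published
concentrations exist; brands are free text. The standard combined pill is
21 active / 7 hormone-free; extended use with `k` repeats runs `k+1` active
blocks back to back (more than 3 repeats raises `EXTENDED_USE_REVIEW`).
Expected withdrawal bleeds are marked on days 2–4 of each hormone-free
window — an artifact convention for "typically begins 2–3 days after the
last active pill" — and are never counted as menstrual bleeds. The
progestin-only pill is 28 active days with an optional pill-free variant
carried as a flag. Injections redose every 13 weeks; hormonal IUD and
implant expansions yield only a 5-year replacement milestone (the copper
IUD milestone defaults to 5 of its 3/5/10-year options). Method
compatibility follows the published usability table: urinary LH and blood
progesterone are excluded for every hormonal method; BBT remains available
to pill users (with the caveat that natural temperature changes may
persist); cervical mucus is additionally informative for hormonal IUD and
implant users; copper-IUD users are naturally menstruating for every
purpose.

## Planner conventions

"Quarterly" = every 91 days from plan start, "monthly" = every 30 days.
Urinary LH testing is scheduled from cycle day 8 through
`min(19, expected_length − 7)` — at most 12 tests — and re-planning
truncates at the first recorded positive. The confirmatory blood test
targets the earliest day of the +7..+9 window (maximizing the chance of a
genuinely mid-luteal draw when the luteal phase is short) and is capped at
one per quarter. Cervical-mucus items are emitted as a per-cycle
free-window note because the published frequency ("~1–4 days per cycle")
names no particular days. Disorder profiles add their published items; a
profile whose required method is excluded for the group or sits above the
tier cap fails fast with a structured `INCOMPATIBLE_PROFILE` error.
Life-cycle stages beyond the premenopausal trees (pregnancy, postpartum,
peri-menopause, menopause) are enumerated stubs that raise
`NOT_IMPLEMENTED`.

## The simulator

The generator's defaults are the study conditions, chosen once as
field-realistic values: eumenorrheic cycle lengths N(28, 2) truncated to
[26, 32] days with ovulation ~N(14, 1.5) truncated so the luteal phase is
≥ 14 days and the surge falls inside the scheduled test block; the
short-luteal phenotype pins the luteal length to 11–13 days (subject to the
same observability constraint); oligomenorrhea draws N(45, 5) truncated to
[42, 60]; mid-luteal serum plateaus of 30 / 10 / 18 nmol/L for the
eumenorrheic / low-P4 / short-luteal phenotypes; menses of 5 days losing
N(40, 10) ml; a BBT shift of +0.35 °C the day after ovulation. The default
`NoiseSpec` is BBT σ 0.05 °C, progesterone σ 0.5 nmol/L, LH false
positive/negative rates 2%, and a 10% independent miss rate per scheduled
observation (survey fatigue); `NoiseSpec.none()` gives the noise-free
conditions used by recovery tests. Hormone curves are arbitrary-unit
piecewise shapes constrained only by ordinal relations (E1G peaks before
the LH spike; PdG and serum progesterone peak after it, centred near
ovulation + 7); the LH surge renders 10× above the positivity threshold
margin so noise-free tests are unambiguous.

What the simulator does **not** emulate: intra-individual trends, spotting,
cycle-to-cycle autocorrelation, measurement drift, pharmacokinetics of
synthetic hormones, pregnancy and the other life stages, or behavioural
missingness patterns (missingness is independent per observation). Passing
recovery tests therefore show that the decision logic is faithful to its
stated criteria under its own data model — not that real-world logs of this
fidelity are easy to collect.

A caveat the missingness experiments expose: when the single surge-day test
is missed, the remaining negative tests read as an anovulatory cycle (E)
under the all-tests-negative rule, so at high miss rates the error mass
moves toward E rather than toward the conservative B1. That is a property
of the published rule, not of the implementation; the practical mitigation
is daily testing adherence inside the scheduled block.

## Numerical and degenerate-input choices

Dates are ISO-8601 calendar dates without time of day. Event ordering is
total and deterministic (date, then kind name, then canonical payload), so
parsing is row-order-insensitive and identical inputs serialize
byte-identically. Duplicate same-day measurements (bleed, LH, BBT, serum
P4) are hard errors naming the offending row — auditability over
convenience. BBT outside 30–45 °C and negative progesterone/loss values are
rejected at parse time. A log with no events classifies only if an as-of
date and (for pre-menarche individuals) an age are supplied; a missing age
with `menarche_reached = false` is a structured `MISSING_AGE` error rather
than a silent unknown. Sex/gender free-text notes are carried through
untouched and never influence classification.

## Known limitations

* The tree adjacency is a reconstruction: leaves and thresholds are exactly
  the printed ones, but the internal question order within the natural and
  contraception trees is the package's own (data-file) choice.
* `B1_PROBABLE_OV` is a package-defined refinement for "positive LH test,
  normal length, no blood test": the published material requires the blood
  test to confirm ovulation, so the case deliberately stays at the
  naturally-menstruating node annotated PROBABLE instead of being promoted.
* Cervical mucus and BBT are recorded and reported as evidence but never
  drive a leaf assignment.
* No diagnosis, no treatment or contraception advice, no efficacy
  modelling, no brand database.
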