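# mhm — menstrual health monitoring decision trees

`mhm` is a deterministic, auditable implementation of published menstrual
cycle status decision trees and monitoring tables for sport and exercise
settings: athletes, coaches and support staff who want to agree on *what*
menstrual health data is collected, *what* it can and cannot say, and *how
deep* the monitoring should go. It is an educational classification and
planning engine — **not a diagnostic tool**: the strongest output it ever
produces is a leaf code, an evidence trail, and a "medical review required"
flag.

## What it computes

Given a longitudinal self-monitoring event log (bleed days, urinary LH
tests, basal body temperature, serum progesterone, cervical mucus ratings,
symptoms, contraception records), the package:

1. **Segments** the log into cycles (a cycle starts at each bleed onset)
   and extracts per-cycle evidence: length, luteal length
   `L − d_LH + 1`, mid-luteal progesterone, annual bleed count, biphasic
   BBT shift (three consecutive temperatures ≥ 0.2 °C above the maximum of
   the prior six).
2. **Classifies** cycle status by walking binary decision trees whose
   printed clinical thresholds are:
   regular cycle 21–35 days; oligomenorrheic > 35 days or ≤ 9 bleeds/year;
   short luteal phase < 14 days from the LH surge to the next bleed;
   eumenorrheic mid-luteal progesterone > 16 nmol/L (lower values, being
   progesterone nonetheless, still *confirm* ovulation); secondary
   amenorrhea after ≥ 3 months without bleeding; primary amenorrhea at
   age ≥ 15 (or ≥ 14 without secondary sex characteristics); heavy
   menstrual bleeding > 80 ml per menses, persistent beyond 7 cycles.
   A **tier cap** (0 = bleed dates, 1 = + symptoms/BBT/mucus, 2 = + urinary
   LH, 3 = + blood tests) guarantees evidence above the cap is never read —
   users can stop at a conservative node for privacy or cultural safety.
3. **Maps contraception** records to the method taxonomy (mono/bi/triphasic
   combined pill, progestin-only pill, hormonal IUD, implant, ring,
   injection, copper IUD), models each schedule (21/7 pill tiling with
   extended-use repeats, 13-week injection redose, 5-year device
   replacement) and marks expected *withdrawal* bleeds, which are never
   counted as menstrual bleeds.
4. **Plans monitoring** at the published frequencies: daily tracking,
   urinary LH tests from cycle day 8 until a positive (≤ 12 per cycle), a
   confirmatory blood draw 7–9 days after a positive (at most quarterly),
   monthly pill-schedule and quarterly brand reviews, plus disorder
   profiles (endometriosis, PCOS, PMS/PMDD, heavy bleeding).
5. **Simulates** every phenotype on the hormonal continuum with ground
   truth, so each decision path is testable end to end without real health
   data.

## Worked example

```python
from mhm.classifier import classify
from mhm.simulate import regular_history_log

# A year of regular bleeds, then a 28-day cycle with a positive LH test on
# day 14 and mid-luteal progesterone of 20.1 nmol/L.
log, as_of = regular_history_log(28, lh_day=14, p4=20.1)
for cap in (0, 1, 2, 3):
    r = classify(log, cap=cap, as_of=as_of)
    print(cap, r.leaf.value, r.ovulation_status.value)
```

prints

```
0 B1 UNKNOWN
1 B1 UNKNOWN
2 B1_PROBABLE_OV PROBABLE
3 C1 CONFIRMED
```

Bleed dates alone support only "naturally menstruating" (B1). The positive
urinary LH test makes ovulation *probable* but cannot confirm it; the blood
test 7 days later can, and with progesterone above 16 nmol/L the cycle is
eumenorrheic (C1). Every result carries its root-to-leaf evidence trail
(`result.node_path`), so each answer is auditable.

More narrative scripts live in `examples/` (one per capability), and a thin
CLI mirrors the library:

```bash
mhm simulate --phenotype eumenorrheic --cycles 6 --seed 7 --out log.csv
mhm validate log.csv
mhm classify log.csv --tier 3 --explain
mhm plan --group NATURAL --tier 2 --horizon 28 --start 2024-03-01
```

## Layout

| Path | Contents |
| --- | --- |
| `src/mhm/model.py` | domain types, event-log parsing/validation, CSV/JSON I/O |
| `src/mhm/segmentation.py` | cycles, annual counts, luteal arithmetic, BBT shift |
| `src/mhm/classifier.py` | decision trees, thresholds, tier caps, review flags |
| `src/mhm/contraception.py` | method taxonomy, schedules, method compatibility |
| `src/mhm/planner.py` | dated monitoring plans, disorder profiles |
| `src/mhm/simulate.py` | phenotype simulator with ground truth |
| `src/mhm/data/trees.yaml` | the tree adjacency, shipped as data |
| `docs/methods.md` | model assumptions, conventions, limitations |
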