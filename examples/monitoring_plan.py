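"""Build a dated monitoring plan for a naturally menstruating individual.

A 28-day expected cycle at full monitoring: daily symptom and BBT items,
urinary LH tests from cycle day 8 (truncated at the recorded positive on
day 14), and one confirmatory blood test scheduled 7 days after the
positive (window +7 to +9), capped at quarterly frequency.
"""

from datetime import date, timedelta

from mhm.contraception import MonitoringMethod
from mhm.planner import build_plan

start = date(2024, 3, 1)
positive = start + timedelta(days=13)  # recorded positive on cycle day 14

plan = build_plan(
    start=start,
    horizon_days=28,
    tier_cap=3,
    expected_cycle_length=28,
    lh_positives=[positive],
)

by_method = {}
for item in plan.items:
    by_method.setdefault(item.method, []).append(item)

for method, items in sorted(by_method.items(), key=lambda kv: kv[0].value):
    days = [(i.date - start).days + 1 for i in items]
    shown = days if len(days) <= 14 else f"daily (cycle days {days[0]}-{days[-1]})"
    print(f"{method.value:<14} tier {items[0].tier}  cycle days: {shown}")

blood = plan.items_of(MonitoringMethod.BLOOD_P4)[0]
print(f"\nblood test on {blood.date} -- {blood.note}")
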