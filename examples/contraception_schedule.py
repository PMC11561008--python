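"""Classify a contraception record and expand its pill schedule.

A monophasic combined pill with two extended-use repeats (three 21-day
active blocks back to back before each 7-day hormone-free window).  The
expansion shows the first hormone-free day landing on day 64 and marks the
days on which a withdrawal bleed -- not a menstrual bleed -- is expected.
"""

from datetime import date

from mhm.contraception import DayType, classify_contraception, expand_schedule
from mhm.model import ContraceptionCategory, ContraceptionRecord

rec = ContraceptionRecord(
    category=ContraceptionCategory.OCP_COMBINED_MONO,
    start_date=date(2024, 1, 1),
    extended_use_repeats=2,
)
leaf = classify_contraception(rec)
print(f"leaf {leaf.code.value}: ovulation suppressed = {leaf.ovulation_suppressed.value}")
print(
    f"regimen: {leaf.schedule.active_days} active / "
    f"{leaf.schedule.hormone_free_days} hormone-free, "
    f"{leaf.schedule.repeat_extended} extended repeats"
)

expansion = expand_schedule(leaf, rec.start_date, horizon_days=84)
free_days = [d for d in expansion.days if d.day_type == DayType.HORMONE_FREE]
withdrawal = [d for d in expansion.days if "EXPECTED_WITHDRAWAL_BLEED" in d.flags]
print(f"first hormone-free day: day {free_days[0].day_index}")
print(
    "expected withdrawal-bleed days:",
    [d.day_index for d in withdrawal],
    "(all inside the hormone-free window)",
)
print("review flags:", sorted(expansion.flags) or "none (<= 3 repeats)")
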