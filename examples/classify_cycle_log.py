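"""Classify a tracked cycle log at increasing monitoring tiers.

Builds one individual's event log (a year of regular bleeds, then a cycle
with a positive urinary LH test on day 14 and a mid-luteal blood
progesterone of 20.1 nmol/L) and classifies it at each tier cap.  Watch the
leaf sharpen as deeper evidence becomes readable: bleed dates alone support
only "naturally menstruating" (B1); urinary LH makes ovulation probable;
the blood test confirms a eumenorrheic biphasic cycle (C1).
"""

from mhm.classifier import classify, leaf_info
from mhm.simulate import regular_history_log

log, as_of = regular_history_log(28, lh_day=14, p4=20.1)

for cap in (0, 1, 2, 3):
    result = classify(log, cap=cap, as_of=as_of)
    print(
        f"tier cap {cap}: leaf {result.leaf.value:<14} "
        f"ovulation {result.ovulation_status.value:<9} "
        f"flags {sorted(f.value for f in result.review_flags) or '-'}"
    )

final = classify(log, cap=3, as_of=as_of)
info = leaf_info(final.leaf)
print(f"\n{final.leaf.value}: {info.clinical}")
print(info.non_clinical)
print("\nEvidence trail (root to leaf):")
for question, answer in final.node_path:
    print(f"  {question} -> {answer}")
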