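"""Independent flat re-implementation of the per-cycle leaf criteria.

This oracle evaluates the printed leaf predicates directly as a flat chain
of boolean tests on scalar evidence -- no Cycle objects, no tree walk, no
shared code with the classifier -- so agreement between the two routes is
a meaningful check rather than a tautology.
"""

from __future__ import annotations

from typing import Optional


def flat_cycle_leaf(
    length: int,
    annual_count: float,
    annual_extrapolated: bool,
    cap: int,
    n_lh_tests: int,
    lh_positive_day: Optional[int],
    p4: Optional[float],
) -> tuple[str, str]:
    """(leaf code, ovulation status) from the printed criteria.

    Evidence readability: urinary LH only at cap >= 2, serum progesterone
    only at cap >= 3.  Extrapolated annual counts never count as
    oligomenorrheic evidence.
    """
    lh_readable = cap >= 2 and n_lh_tests > 0
    surge = lh_readable and lh_positive_day is not None
    p4_readable = cap >= 3 and p4 is not None

    # Oligomenorrheic: prolonged cycle (> 35 d) or <= 9 bleeds in a fully
    # observed year.
    if length > 35 or (annual_count <= 9 and not annual_extrapolated):
        return "F", "UNKNOWN"
    # Short cycle (< 21 d): luteal phase defect branch.
    if length < 21:
        return "D2", ("PROBABLE" if surge else "UNKNOWN")
    # No readable ovulation testing: naturally menstruating, untested.
    if not lh_readable:
        return "B1", "UNKNOWN"
    # All tests negative: anovulatory.
    if not surge:
        return "E", "ABSENT"
    luteal = length - lh_positive_day + 1
    # Next bleed < 14 days after the surge: short luteal phase.
    if luteal < 14:
        return "D2", ("CONFIRMED" if (p4_readable and p4 > 0) else "PROBABLE")
    # Surge seen but no confirming blood test.
    if not p4_readable:
        return "B1_PROBABLE_OV", "PROBABLE"
    # Mid-luteal progesterone above/below 16 nmol/L.
    if p4 > 16:
        return "C1", "CONFIRMED"
    return "D1", "CONFIRMED"
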