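from __future__ import annotations

from datetime import date, timedelta

import pytest

from mhm.model import Event, EventKind, IndividualMeta, ObservationLog
from mhm.segmentation import Cycle


@pytest.fixture
def adult_meta() -> IndividualMeta:
    return IndividualMeta(
        individual_id="ind-1", age_years=30.0, menarche_reached=True
    )


def make_log(meta: IndividualMeta, events) -> ObservationLog:
    return ObservationLog(meta=meta, events=tuple(events))


def bleed_run(start: date, n_days: int) -> list[Event]:
    return [
        Event(start + timedelta(days=i), EventKind.BLEED, None) for i in range(n_days)
    ]


def make_cycle(
    length: int,
    *,
    index: int = 1,
    lh_day: int | None = None,
    n_lh_tests: int | None = None,
    p4: float | None = None,
    loss: float | None = None,
    onset: date = date(2024, 1, 1),
) -> Cycle:
    if n_lh_tests is None:
        n_lh_tests = 1 if lh_day is not None else 0
    luteal = length - lh_day + 1 if (lh_day is not None and length) else None
    return Cycle(
        index=index,
        onset=onset,
        length_days=length,
        bleed_days=(1,),
        lh_positive_day=lh_day,
        lh_tests_done=n_lh_tests,
        luteal_length_days=luteal,
        midluteal_p4_nmol_l=p4,
        p4_values=(p4,) if p4 is not None else (),
        blood_loss_ml=loss,
    )
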