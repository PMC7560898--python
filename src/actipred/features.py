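"""Per-day regression variables from minute-level activity states.

Activity Time is the largest number of activity-category minutes found in
any contiguous 30-minute window of the daily observation block; Rest Time is
the analogous maximum for rest-category minutes (the two argmax windows may
differ).  PTD (Progress Towards Discharge) normalizes the day of admission
by the total length of stay, so the discharge day maps to 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import ACTIVITY_STATES, ALL_STATES, REST_STATES, Cohort, DayStateSequence

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 30


@dataclass(frozen=True)
class CategoryMap:
    """Assignment of the five recognition labels to activity/rest categories.

    The default is the full partition: activity = {running, walking,
    standing}, rest = {sitting, lying}.  `lying_only()` restricts the rest
    category to lying (sitting then counts toward neither window).
    """

    activity_states: frozenset = frozenset(ACTIVITY_STATES)
    rest_states: frozenset = frozenset(REST_STATES)

    def __post_init__(self):
        known = set(ALL_STATES)
        if not self.activity_states or not self.rest_states:
            raise ValueError("both categories must be non-empty")
        if (self.activity_states | self.rest_states) - known:
            bad = sorted((self.activity_states | self.rest_states) - known)
            raise ValueError(f"unknown state labels in category map: {bad}")
        if self.activity_states & self.rest_states:
            raise ValueError("activity and rest categories must be disjoint")

    @classmethod
    def lying_only(cls) -> "CategoryMap":
        return cls(frozenset(ACTIVITY_STATES), frozenset({"lying"}))


@dataclass(frozen=True)
class DayFeatures:
    patient_id: str
    doa: int
    activity_time: int
    rest_time: int
    ptd: Optional[float] = None
    length_of_stay: Optional[int] = None


def window_max_minutes(binary_seq: Sequence[int], window: int = DEFAULT_WINDOW) -> int:
    """Maximum count of 1-minutes over all contiguous windows of `window` minutes.

    With a 120-minute block and a 30-minute window there are 91 candidate
    windows (step one minute).
    """
    seq = np.asarray(binary_seq, dtype=int)
    if seq.ndim != 1:
        raise ValueError("binary_seq must be one-dimensional")
    if window < 1:
        raise ValueError("window must be >= 1")
    if seq.size < window:
        raise ValueError(
            f"sequence of length {seq.size} shorter than window {window}"
        )
    csum = np.concatenate([[0], np.cumsum(seq)])
    return int((csum[window:] - csum[:-window]).max())


def extract_day_features(
    seq: DayStateSequence,
    cmap: CategoryMap = CategoryMap(),
    window: int = DEFAULT_WINDOW,
) -> DayFeatures:
    """Activity Time and Rest Time for one patient-day.

    The two windowed maxima are computed independently; on a fragmented day
    their best windows can differ, so activity_time + rest_time may exceed
    the window length.
    """
    states = list(seq.states)
    unknown = sorted({s for s in states if s not in ALL_STATES})
    if unknown:
        raise ValueError(f"unknown state label(s): {unknown}")
    act = [1 if s in cmap.activity_states else 0 for s in states]
    rest = [1 if s in cmap.rest_states else 0 for s in states]
    return DayFeatures(
        patient_id=seq.patient_id,
        doa=seq.doa,
        activity_time=window_max_minutes(act, window),
        rest_time=window_max_minutes(rest, window),
    )


def compute_ptd(doa: int, length_of_stay: int) -> float:
    """Progress Towards Discharge: doa / length_of_stay (discharge day -> 1)."""
    if doa < 1:
        raise ValueError("doa must be >= 1")
    if length_of_stay < 1:
        raise ValueError("length_of_stay must be >= 1")
    if doa > length_of_stay:
        raise ValueError(
            f"doa {doa} exceeds length_of_stay {length_of_stay}"
        )
    return doa / length_of_stay


def _iter_day_sequences(states: pd.DataFrame) -> Iterable[DayStateSequence]:
    states = states.sort_values(["patient_id", "doa", "minute_index"])
    for (pid, doa), grp in states.groupby(["patient_id", "doa"], sort=True):
        yield DayStateSequence(str(pid), int(doa), tuple(grp["state"]))


def build_feature_table(
    data: Union[Cohort, pd.DataFrame],
    cmap: CategoryMap = CategoryMap(),
    window: int = DEFAULT_WINDOW,
    lengths_of_stay: Optional[dict] = None,
) -> pd.DataFrame:
    """One DayFeatures row per patient-day, sorted by (patient_id, doa).

    `ptd` is filled where the patient's length of stay is known (taken from
    the Cohort truth or from `lengths_of_stay`).  Days with fewer minutes
    than the window are dropped with a warning; gaps in the day index are
    reported but tolerated.
    """
    if isinstance(data, Cohort):
        day_seqs: Iterable[DayStateSequence] = data.days
        los = {p.patient_id: p.length_of_stay for p in data.patients}
    else:
        day_seqs = _iter_day_sequences(data)
        los = dict(lengths_of_stay or {})
    rows = []
    for seq in day_seqs:
        if len(seq.states) < window:
            warnings.warn(
                f"dropping {seq.patient_id} day {seq.doa}: only "
                f"{len(seq.states)} recorded minutes (< {window})",
                stacklevel=2,
            )
            continue
        feat = extract_day_features(seq, cmap, window)
        length = los.get(seq.patient_id)
        ptd = compute_ptd(seq.doa, length) if length is not None else np.nan
        rows.append(
            (feat.patient_id, feat.doa, feat.activity_time, feat.rest_time,
             ptd, length if length is not None else np.nan)
        )
    table = pd.DataFrame(
        rows,
        columns=["patient_id", "doa", "activity_time", "rest_time", "ptd",
                 "length_of_stay"],
    ).sort_values(["patient_id", "doa"], ignore_index=True)
    for pid, grp in table.groupby("patient_id"):
        days = grp["doa"].to_numpy()
        missing = sorted(set(range(1, int(days.max()) + 1)) - set(days))
        if missing:
            warnings.warn(
                f"patient {pid} has missing day(s): {missing}", stacklevel=2
            )
    return table
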