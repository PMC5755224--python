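"""Risk-interval layouts mapping event histories onto the five Cox-type models.

Each recurrent-event model is an ordinary (possibly stratified) Cox
partial likelihood evaluated on a model-specific long-format data set of
``(start, stop, status, stratum, group)`` risk intervals; intervals are
half-open ``(start, stop]`` and a record is at risk at ``t`` iff
``start < t <= stop``.  The layouts differ only in how a subject's
history is cut into intervals:

COX_FIRST_EVENT
    one record per subject up to the first composite event (or censoring).
AG (Andersen-Gill)
    consecutive total-time intervals between events plus a final censored
    interval; a common, unstratified risk set.
PWP_TT / PWP_GT (Prentice-Williams-Peterson)
    the same intervals tagged with the event order as stratum (total-time
    scale), or restarted at zero with the gap as stop (gap-time scale);
    a subject enters stratum ``j`` only after ``j - 1`` events.
WLW (Wei-Lin-Weissfeld)
    every subject appears in all ``k`` strata from time zero; beyond the
    observed events the subject contributes an "artificial" censored time
    (by default the end of observation).

Records are exchanged as a pandas DataFrame with columns
``subject_id, start, stop, status, stratum, group`` — the same dialect
the CSV reader/writer uses, so external counting-process data can be
analysed with the identical machinery.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .simulate import DEATH, EventHistory, SubjectDesign

__all__ = [
    "LayoutMode",
    "CountingProcessRecord",
    "RECORD_COLUMNS",
    "max_strata",
    "to_records",
    "write_records",
    "read_records",
]

RECORD_COLUMNS = ("subject_id", "start", "stop", "status", "stratum", "group")


class LayoutMode(str, enum.Enum):
    """The five risk-set layouts."""

    COX_FIRST_EVENT = "cox_first_event"
    AG = "ag"
    PWP_TT = "pwp_tt"
    PWP_GT = "pwp_gt"
    WLW = "wlw"


class CountingProcessRecord(NamedTuple):
    """One (start, stop] risk interval of one subject."""

    subject_id: int
    start: float
    stop: float
    status: int
    stratum: int
    group: int


def _analysis_events(hist: EventHistory, events: str) -> tuple[list[float], bool]:
    """Event times entering the analysis and whether the record ends with one.

    ``events="all"`` analyses the composite process (the terminal event is
    an event like any other and closes the record); ``events="nonfatal"``
    analyses the recurrent process only, with death acting purely as
    censoring at ``end_time``.
    """
    if events == "all":
        return list(hist.event_times), hist.terminal == "death"
    if events == "nonfatal":
        return [t for t, ty in zip(hist.event_times, hist.event_types)
                if ty != DEATH], False
    raise ValueError("events must be 'all' or 'nonfatal'")


def max_strata(histories: Sequence[EventHistory], events: str = "all") -> int:
    """Maximum observed number of events per individual (0 if none)."""
    if len(histories) == 0:
        raise ValueError("max_strata needs a nonempty list of histories")
    return max(len(_analysis_events(h, events)[0]) for h in histories)


def _check_history(hist: EventHistory) -> None:
    times = hist.event_times
    for a, b in zip(times, times[1:]):
        if b <= a:
            raise ValueError(
                f"subject {hist.subject_id}: tied or non-increasing event times "
                f"({a}, {b}); zero-length risk intervals are not representable"
            )


def to_records(
    subjects: Sequence[tuple[SubjectDesign, EventHistory]],
    mode: LayoutMode | str,
    k: int | None = None,
    wlw_artificial: str = "end_of_observation",
    events: str = "all",
    cap: int | None = None,
) -> pd.DataFrame:
    """Lay out event histories as model-specific risk intervals.

    Parameters
    ----------
    subjects
        Pairs ``(SubjectDesign, EventHistory)`` as produced by
        :func:`recurtrial.simulate.simulate_dataset`.
    mode
        Target layout.
    k
        Strata count for the stratified layouts; must be at least the
        maximum observed event count.  Defaults to that maximum.
    wlw_artificial
        Censored time a subject contributes to a WLW stratum beyond its
        observed events: ``"end_of_observation"`` (default) or
        ``"last_event"`` (the literal last-event-time reading).
    events
        ``"all"`` analyses the composite process (terminal event counts
        as an event); ``"nonfatal"`` analyses the recurrent process only
        and treats death as censoring at the death time.
    cap
        Maximum number of analysis events per subject entering the
        models.  Under the capped formulation a subject's risk exposure
        ends with their ``cap``-th event, so with ``cap = 1`` every
        layout reduces to the first-event Cox data.  Default: no cap.

    Returns
    -------
    pandas.DataFrame
        Columns :data:`RECORD_COLUMNS`, deterministic row order
        (by subject, then stratum).
    """
    mode = LayoutMode(mode)
    if wlw_artificial not in ("end_of_observation", "last_event"):
        raise ValueError("wlw_artificial must be 'end_of_observation' or 'last_event'")
    if cap is not None and cap < 1:
        raise ValueError("cap must be at least 1")

    prepared = []
    for design, hist in subjects:
        _check_history(hist)
        times, ends_with_event = _analysis_events(hist, events)
        end = hist.end_time
        if cap is not None and len(times) >= cap:
            # capped formulation: exposure ends with the cap-th event
            times = times[:cap]
            end = times[-1]
            ends_with_event = True
        prepared.append((design, times, end, ends_with_event))

    kmax = max(len(t) for _, t, _, _ in prepared) if prepared else 0
    if k is None:
        k = max(kmax, 1)
    if mode in (LayoutMode.PWP_TT, LayoutMode.PWP_GT, LayoutMode.WLW) and k < kmax:
        raise ValueError(f"k = {k} is below the maximum observed event count {kmax}")

    rows: list[CountingProcessRecord] = []
    for design, times, end_time, died_at_last in prepared:
        sid, g = design.subject_id, design.group
        n = len(times)

        if mode is LayoutMode.COX_FIRST_EVENT:
            stop = times[0] if n else end_time
            status = 1 if n else 0
            if stop > 0:
                rows.append(CountingProcessRecord(sid, 0.0, stop, status, 1, g))
            continue

        if mode in (LayoutMode.AG, LayoutMode.PWP_TT):
            prev = 0.0
            for j, t in enumerate(times, start=1):
                stratum = j if mode is LayoutMode.PWP_TT else 1
                rows.append(CountingProcessRecord(sid, prev, t, 1, stratum, g))
                prev = t
            if not died_at_last and end_time > prev:
                stratum = n + 1 if mode is LayoutMode.PWP_TT else 1
                if mode is LayoutMode.AG or stratum <= k:
                    rows.append(
                        CountingProcessRecord(sid, prev, end_time, 0, stratum, g)
                    )
            continue

        if mode is LayoutMode.PWP_GT:
            prev = 0.0
            for j, t in enumerate(times, start=1):
                rows.append(CountingProcessRecord(sid, 0.0, t - prev, 1, j, g))
                prev = t
            if not died_at_last and end_time > prev and n + 1 <= k:
                rows.append(
                    CountingProcessRecord(sid, 0.0, end_time - prev, 0, n + 1, g)
                )
            continue

        # WLW: every subject appears in every stratum 1..k
        for j in range(1, k + 1):
            if j <= n:
                rows.append(CountingProcessRecord(sid, 0.0, times[j - 1], 1, j, g))
            else:
                if wlw_artificial == "last_event" and n > 0:
                    stop = times[n - 1]
                else:
                    stop = end_time
                if stop > 0:
                    rows.append(CountingProcessRecord(sid, 0.0, stop, 0, j, g))

    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return df.astype(
        {"subject_id": np.int64, "start": float, "stop": float,
         "status": np.int64, "stratum": np.int64, "group": np.int64}
    )


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write counting-process records to CSV (the package's exchange dialect)."""
    _validate_records(records)
    records.to_csv(path, index=False, columns=list(RECORD_COLUMNS))


def read_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a counting-process CSV."""
    df = pd.read_csv(path)
    _validate_records(df)
    return df[list(RECORD_COLUMNS)].astype(
        {"subject_id": np.int64, "start": float, "stop": float,
         "status": np.int64, "stratum": np.int64, "group": np.int64}
    )


def _validate_records(df: pd.DataFrame) -> None:
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counting-process data is missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("counting-process data is empty")
    if not set(np.unique(df["status"])) <= {0, 1}:
        raise ValueError("status must be 0 or 1")
    if (df["start"] < 0).any():
        raise ValueError("start times must be nonnegative")
    if (df["stop"] <= df["start"]).any():
        raise ValueError("risk intervals must have stop > start")
    if not set(np.unique(df["group"])) <= {0, 1}:
        raise ValueError("group must be 0 or 1")
    if (df["stratum"] < 1).any():
        raise ValueError("stratum indices start at 1")
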