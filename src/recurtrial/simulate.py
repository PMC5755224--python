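"""Forward simulation of two-arm trials with a recurrent and a terminal event.

Each subject enters the study at a uniform time on ``[0, recruitment_length]``
and is observed on their own clock until administrative censoring at
``recruitment_length + minimal_followup - entry_time`` or until death,
whichever comes first.  Between events the two processes (recurrent MI,
terminal death) run as competing risks: a candidate gap time is drawn for
each by inverting its conditional cumulative hazard against an independent
uniform draw, and the smaller candidate (if it fits inside the remaining
follow-up) becomes the next event.  A non-fatal event updates ``t_prev``
— the total time of the most recent MI — on which both baseline hazards
and both hazard ratios may depend; the hazards are then re-drawn for the
next segment.  Hazards of the power-time forms follow the total-time
clock (conditional increments of the cumulative hazard); all other forms
are constant within a segment.

Randomness is organised as one named substream per subject derived from
``(seed, replicate, subject_id)``, so any subject's history is
reproducible in isolation.  Within a segment the MI uniform is drawn
before the death uniform.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .hazards import (
    HazardForm,
    HazardSpec,
    ScenarioSpec,
    _POWER_FORMS,
    hazard_value,
    hr_value,
)

__all__ = [
    "SubjectDesign",
    "EventHistory",
    "StudyConfig",
    "draw_segment_time",
    "simulate_subject",
    "simulate_dataset",
    "write_event_list",
]

MI = "MI"
DEATH = "D"


@dataclass(frozen=True)
class SubjectDesign:
    """Fixed design quantities of one subject.

    ``entry_time`` is on the calendar clock; ``censor_time`` is the
    administrative follow-up duration on the subject's own clock.
    """

    subject_id: int
    group: int
    entry_time: float
    censor_time: float

    def __post_init__(self) -> None:
        if self.group not in (0, 1):
            raise ValueError("group must be 0 (control) or 1 (experimental)")
        if self.censor_time < 0:
            raise ValueError("censor_time must be nonnegative")


@dataclass
class EventHistory:
    """One subject's observed event record, on the subject clock.

    ``event_times`` are strictly increasing times since entry, with
    parallel ``event_types`` in {"MI", "D"}; at most one death, always
    last.  ``terminal`` records how observation ended ("death" or
    "administrative") and ``end_time`` the time of last observation.
    """

    subject_id: int
    event_times: list[float] = field(default_factory=list)
    event_types: list[str] = field(default_factory=list)
    terminal: str = "administrative"
    end_time: float = 0.0

    @property
    def n_events(self) -> int:
        return len(self.event_times)

    def validate(self) -> None:
        if len(self.event_times) != len(self.event_types):
            raise ValueError("event_times and event_types must be parallel")
        prev = 0.0
        for t in self.event_times:
            if not (prev < t <= self.end_time):
                raise ValueError("event times must be strictly increasing in (0, end_time]")
            prev = t
        n_death = self.event_types.count(DEATH)
        if n_death > 1:
            raise ValueError("at most one death per subject")
        if n_death == 1:
            if self.event_types[-1] != DEATH:
                raise ValueError("death must be the last event")
            if self.terminal != "death" or self.event_times[-1] != self.end_time:
                raise ValueError("a death terminates observation at its own time")
        if self.terminal not in ("death", "administrative"):
            raise ValueError("terminal must be 'death' or 'administrative'")


@dataclass
class StudyConfig:
    """Design parameters of a simulated trial.

    Defaults mirror the reference design: 200 subjects recruited
    uniformly over 1 year with a minimal follow-up of 2 years (so
    individual follow-up lasts between 2 and 3 years).
    """

    n_subjects: int = 200
    recruitment_length: float = 1.0
    minimal_followup: float = 2.0
    max_events_cap: int | None = None
    seed: int = 0
    #: first-event baseline for the ``inv_sqrt_prev`` family: "constant"
    #: uses the level ``rate`` until the first event; "current_time" uses
    #: rate/sqrt(t) on the total-time clock instead.
    first_event_baseline: str = "constant"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.minimal_followup <= 0:
            raise ValueError("minimal_followup must be positive")
        if self.recruitment_length < 0:
            raise ValueError("recruitment_length must be nonnegative")
        if self.first_event_baseline not in ("constant", "current_time"):
            raise ValueError("first_event_baseline must be 'constant' or 'current_time'")


def draw_segment_time(
    spec: HazardSpec,
    hr: float,
    group: int,
    s: float,
    t_prev: float | None,
    first_event: bool,
    u: float,
) -> float:
    """Invert one segment's cumulative hazard against a uniform draw.

    Returns the gap ``g`` solving ``Lambda(g) * hr**group = -ln(u)``
    conditioned on survival to total time ``s``: power-time forms
    integrate on the total-time clock from ``s``; constant-within-gap
    forms integrate from 0 on the gap clock.  A zero hazard yields
    ``math.inf``.
    """
    if not (0.0 < u < 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    if s < 0:
        raise ValueError("s must be nonnegative")
    target = -math.log(u)
    if group == 1:
        target /= hr
    if spec.form in _POWER_FORMS:
        coef = spec.rate_or_base * spec.scale
        if coef == 0.0:
            return math.inf
        p = spec.exponent + 1.0
        return (s**p + p * target / coef) ** (1.0 / p) - s
    level = hazard_value(spec, s, t_prev=t_prev, first_event=first_event)
    if level == 0.0:
        return math.inf
    return target / level


def _effective_baseline(spec: HazardSpec, first: bool, cfg: StudyConfig) -> HazardSpec:
    # optional alternative reading of the undefined first-event baseline
    # for the inv_sqrt_prev family: rate/sqrt(t) on the total-time clock
    if (
        first
        and spec.form is HazardForm.INV_SQRT_PREV
        and cfg.first_event_baseline == "current_time"
    ):
        return HazardSpec(HazardForm.POWER_TIME, spec.rate_or_base, exponent=-0.5)
    return spec


def simulate_subject(
    scenario: ScenarioSpec,
    design: SubjectDesign,
    cfg: StudyConfig,
    rng: np.random.Generator,
) -> EventHistory:
    """Simulate one subject's event history under a scenario.

    Segment-wise competing simulation: at state ``(s, t_prev)`` draw an
    MI candidate and a death candidate gap from the current hazards; the
    minimum of the two candidates and the remaining follow-up determines
    the next record.  An MI updates ``t_prev`` and iterates; death or
    follow-up end terminates.
    """
    hist = EventHistory(subject_id=design.subject_id)
    s = 0.0
    t_prev: float | None = None
    n_mi = 0
    while True:
        remaining = design.censor_time - s
        if remaining <= 0:
            hist.terminal = "administrative"
            hist.end_time = design.censor_time
            break
        first = t_prev is None
        mi_capped = cfg.max_events_cap is not None and n_mi >= cfg.max_events_cap
        u_mi = rng.random()
        u_d = rng.random()
        if mi_capped:
            g_mi = math.inf
        else:
            g_mi = draw_segment_time(
                _effective_baseline(scenario.mi_baseline, first, cfg),
                hr_value(scenario.mi_hr, t_prev),
                design.group, s, t_prev, first, u_mi,
            )
        g_d = draw_segment_time(
            _effective_baseline(scenario.death_baseline, first, cfg),
            hr_value(scenario.death_hr, t_prev),
            design.group, s, t_prev, first, u_d,
        )
        g = min(g_mi, g_d)
        if g >= remaining:
            hist.terminal = "administrative"
            hist.end_time = design.censor_time
            break
        if g_d <= g_mi:  # ties are measure-zero; death wins them
            hist.event_times.append(s + g_d)
            hist.event_types.append(DEATH)
            hist.terminal = "death"
            hist.end_time = s + g_d
            break
        hist.event_times.append(s + g_mi)
        hist.event_types.append(MI)
        n_mi += 1
        t_prev = s + g_mi
        s = t_prev
    hist.validate()
    return hist


def _subject_rng(seed: int, replicate: int, subject_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, replicate, subject_id)))


def simulate_dataset(
    scenario: ScenarioSpec,
    cfg: StudyConfig,
    replicate: int = 0,
) -> list[tuple[SubjectDesign, EventHistory]]:
    """Simulate a full trial: ``cfg.n_subjects`` subjects, 1:1 randomised.

    Groups alternate with subject id (exactly balanced for even ``n``);
    entry times are iid uniform on ``[0, recruitment_length]`` and the
    administrative censor time is ``recruitment_length +
    minimal_followup - entry_time``.  Identical ``(seed, replicate)``
    yields bit-identical output.
    """
    out: list[tuple[SubjectDesign, EventHistory]] = []
    for sid in range(cfg.n_subjects):
        rng = _subject_rng(cfg.seed, replicate, sid)
        entry = rng.uniform(0.0, cfg.recruitment_length)
        design = SubjectDesign(
            subject_id=sid,
            group=sid % 2,
            entry_time=entry,
            censor_time=cfg.recruitment_length + cfg.minimal_followup - entry,
        )
        out.append((design, simulate_subject(scenario, design, cfg, rng)))
    return out


def write_event_list(
    subjects: Sequence[tuple[SubjectDesign, EventHistory]],
    path: str | Path,
) -> None:
    """Write the raw event list as CSV, one row per event.

    Subjects without events contribute a single row with empty event
    fields so that censoring information is preserved.  Row order is
    deterministic (by subject, then event order).
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["subject_id", "group", "entry_time", "event_time", "event_type",
             "end_time", "terminal"]
        )
        for design, hist in subjects:
            if hist.n_events == 0:
                w.writerow([design.subject_id, design.group, f"{design.entry_time:.10g}",
                            "", "", f"{hist.end_time:.10g}", hist.terminal])
                continue
            for t, typ in zip(hist.event_times, hist.event_types):
                w.writerow([design.subject_id, design.group, f"{design.entry_time:.10g}",
                            f"{t:.10g}", typ, f"{hist.end_time:.10g}", hist.terminal])
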