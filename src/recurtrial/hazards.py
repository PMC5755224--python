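"""Parametric baseline-hazard and hazard-ratio families for composite-endpoint trials.

The trial model has two event processes per subject: a recurrent non-fatal
event (labelled ``MI``, e.g. myocardial infarction) and a terminal event
(``D``, death).  Each process is governed by a baseline hazard that may
depend on the current time ``t`` (time since study entry) and/or on the
time ``t_prev`` at which the subject's most recent non-fatal event
occurred, and by a treatment hazard ratio that may drift with ``t_prev``.

All times are in years; hazards are per year.

Six parametric forms are supported:

``constant``
    lambda(t) = rate, independent of ``t`` and ``t_prev``.
``inv_sqrt_prev``
    lambda = rate / sqrt(t_prev) once a non-fatal event has occurred; for
    the first event of a process (no previous event) the hazard equals
    ``rate`` (the hazard only changes *after* an event has occurred).
``power_time`` / ``scaled_power_time``
    lambda(t) = rate * scale * t**exponent on the total-time clock.
``const_hr``
    time-constant hazard ratio exp(beta) = rate_or_base.
``drift_hr``
    hazard ratio base * exp(coef * ln(base) * t_prev); at ``t_prev = 0``
    (or before any event) this equals ``base`` exactly.  A positive
    ``coef`` strengthens the effect as ``t_prev`` grows, a negative one
    lets it decay towards 1.

The 27 catalogued trial scenarios combine these forms into (MI baseline,
death baseline, MI hazard ratio, death hazard ratio) quadruples; see
:data:`SCENARIO_IDS` and :func:`get_scenario`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "HazardForm",
    "HazardSpec",
    "ScenarioSpec",
    "SCENARIO_IDS",
    "get_scenario",
    "list_scenarios",
    "hazard_value",
    "hr_value",
    "cumulative_hazard",
    "load_scenario_file",
]


class HazardForm(str, enum.Enum):
    """Enumerated functional forms for baseline hazards and hazard ratios."""

    CONSTANT = "constant"
    INV_SQRT_PREV = "inv_sqrt_prev"
    POWER_TIME = "power_time"
    SCALED_POWER_TIME = "scaled_power_time"
    CONST_HR = "const_hr"
    DRIFT_HR = "drift_hr"


_BASELINE_FORMS = frozenset(
    {
        HazardForm.CONSTANT,
        HazardForm.INV_SQRT_PREV,
        HazardForm.POWER_TIME,
        HazardForm.SCALED_POWER_TIME,
    }
)
_POWER_FORMS = frozenset({HazardForm.POWER_TIME, HazardForm.SCALED_POWER_TIME})
_HR_FORMS = frozenset({HazardForm.CONST_HR, HazardForm.DRIFT_HR})


@dataclass(frozen=True)
class HazardSpec:
    """One parametric hazard or hazard-ratio function.

    Parameters
    ----------
    form : HazardForm
        Functional form; see the module docstring.
    rate_or_base : float
        Per-year hazard level for baseline forms, or the (unitless)
        hazard ratio at ``t_prev = 0`` for hazard-ratio forms.
    exponent : float
        Power of ``t`` for the power-time forms (0.3 in the catalogue),
        or the drift coefficient for ``drift_hr`` (+/-0.05, -0.5).
    scale : float
        Positive multiplier for ``scaled_power_time`` (1.5 in the
        catalogue); 1 otherwise.
    """

    form: HazardForm
    rate_or_base: float
    exponent: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "form", HazardForm(self.form))
        if self.rate_or_base < 0:
            raise ValueError("rate_or_base must be nonnegative")
        if self.form in _HR_FORMS and self.rate_or_base <= 0:
            raise ValueError("a hazard ratio must be strictly positive")
        if self.scale <= 0:
            raise ValueError("scale must be strictly positive")
        if self.form in _POWER_FORMS and self.exponent <= -1:
            raise ValueError("power-time exponent must exceed -1 for integrability")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "form": self.form.value,
            "rate_or_base": self.rate_or_base,
            "exponent": self.exponent,
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "HazardSpec":
        return cls(
            form=HazardForm(d["form"]),
            rate_or_base=float(d["rate_or_base"]),
            exponent=float(d.get("exponent", 0.0)),
            scale=float(d.get("scale", 1.0)),
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """The four hazard slots of one simulation scenario."""

    scenario_id: str
    mi_baseline: HazardSpec
    death_baseline: HazardSpec
    mi_hr: HazardSpec
    death_hr: HazardSpec

    def __post_init__(self) -> None:
        if self.mi_baseline.form not in _BASELINE_FORMS:
            raise ValueError("mi_baseline must be a baseline-hazard form")
        if self.death_baseline.form not in _BASELINE_FORMS:
            raise ValueError("death_baseline must be a baseline-hazard form")
        if self.mi_hr.form not in _HR_FORMS:
            raise ValueError("mi_hr must be a hazard-ratio form")
        if self.death_hr.form not in _HR_FORMS:
            raise ValueError("death_hr must be a hazard-ratio form")

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "mi_baseline": self.mi_baseline.to_dict(),
            "death_baseline": self.death_baseline.to_dict(),
            "mi_hr": self.mi_hr.to_dict(),
            "death_hr": self.death_hr.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioSpec":
        return cls(
            scenario_id=str(d["scenario_id"]),
            mi_baseline=HazardSpec.from_dict(d["mi_baseline"]),
            death_baseline=HazardSpec.from_dict(d["death_baseline"]),
            mi_hr=HazardSpec.from_dict(d["mi_hr"]),
            death_hr=HazardSpec.from_dict(d["death_hr"]),
        )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _resolve_first_event(t_prev: float | None, first_event: bool | None) -> bool:
    return (t_prev is None) if first_event is None else bool(first_event)


def hazard_value(
    spec: HazardSpec,
    t: float,
    t_prev: float | None = None,
    first_event: bool | None = None,
) -> float:
    """Evaluate a baseline hazard at total time ``t`` given the event history.

    ``t_prev`` is the total time of the most recent non-fatal event, or
    ``None`` before any event; ``first_event`` defaults to ``t_prev is
    None``.  For ``inv_sqrt_prev`` the first event of a process uses the
    constant level ``rate_or_base`` (the hazard changes only after an
    event has occurred).
    """
    if spec.form in _HR_FORMS:
        raise TypeError(f"{spec.form.value} is a hazard-ratio form; use hr_value")
    if t < 0:
        raise ValueError("t must be nonnegative")
    first = _resolve_first_event(t_prev, first_event)
    if spec.form is HazardForm.CONSTANT:
        return float(spec.rate_or_base)
    if spec.form is HazardForm.INV_SQRT_PREV:
        if first:
            return float(spec.rate_or_base)
        if t_prev is None:
            raise ValueError("inv_sqrt_prev needs t_prev when not the first event")
        if t_prev <= 0:
            raise ValueError("inv_sqrt_prev is undefined at t_prev = 0")
        return spec.rate_or_base / math.sqrt(t_prev)
    # power-time forms
    if t == 0 and spec.exponent < 0:
        return math.inf
    return spec.rate_or_base * spec.scale * t**spec.exponent


def hr_value(spec: HazardSpec, t_prev: float | None = None) -> float:
    """Evaluate a hazard ratio given the most recent non-fatal event time.

    ``t_prev = None`` (no previous event) is treated as 0, so the value
    equals ``rate_or_base`` exactly.
    """
    if spec.form not in _HR_FORMS:
        raise TypeError(f"{spec.form.value} is a baseline form; use hazard_value")
    if t_prev is not None and t_prev < 0:
        raise ValueError("t_prev must be nonnegative")
    if spec.form is HazardForm.CONST_HR:
        return float(spec.rate_or_base)
    tp = 0.0 if t_prev is None else float(t_prev)
    return spec.rate_or_base * math.exp(spec.exponent * math.log(spec.rate_or_base) * tp)


def cumulative_hazard(
    spec: HazardSpec,
    a: float,
    b: float,
    t_prev: float | None = None,
    first_event: bool | None = None,
) -> float:
    """Integrated baseline hazard over ``[a, b]`` on the form's own clock.

    Forms that are constant within a risk segment (``constant``,
    ``inv_sqrt_prev``) integrate to ``level * (b - a)``; the power-time
    forms use the closed form ``rate*scale*(b**(e+1) - a**(e+1))/(e+1)``.
    Additive over adjacent intervals and zero when ``a == b``.
    """
    if spec.form in _HR_FORMS:
        raise TypeError(f"{spec.form.value} is a hazard-ratio form")
    if a < 0:
        raise ValueError("a must be nonnegative")
    if a > b:
        raise ValueError("need a <= b")
    if spec.form in _POWER_FORMS:
        p = spec.exponent + 1.0
        return spec.rate_or_base * spec.scale * (b**p - a**p) / p
    level = hazard_value(spec, a, t_prev=t_prev, first_event=first_event)
    return level * (b - a)


# ---------------------------------------------------------------------------
# Scenario catalogue
# ---------------------------------------------------------------------------

def _const(rate: float) -> HazardSpec:
    return HazardSpec(HazardForm.CONSTANT, rate)


def _isp(rate: float) -> HazardSpec:
    return HazardSpec(HazardForm.INV_SQRT_PREV, rate)


def _pow(scale: float = 1.0) -> HazardSpec:
    form = HazardForm.SCALED_POWER_TIME if scale != 1.0 else HazardForm.POWER_TIME
    return HazardSpec(form, 1.0, exponent=0.3, scale=scale)


def _chr(base: float) -> HazardSpec:
    return HazardSpec(HazardForm.CONST_HR, base)


def _dhr(base: float, coef: float) -> HazardSpec:
    return HazardSpec(HazardForm.DRIFT_HR, base, exponent=coef)


# (letter, MI hazard ratio, death hazard ratio) pattern shared by families
_HR_PATTERN = [("a", 0.5, 0.5), ("b", 0.5, 0.7), ("c", 0.7, 0.5),
               ("d", 0.7, 1.5), ("e", 1.5, 0.7)]


def _build_catalogue() -> dict[str, ScenarioSpec]:
    cat: dict[str, ScenarioSpec] = {}

    def add(sid, mi_b, d_b, mi_hr, d_hr):
        cat[sid] = ScenarioSpec(sid, mi_b, d_b, mi_hr, d_hr)

    for letter, hmi, hd in _HR_PATTERN:
        add(f"1{letter}", _const(0.25), _const(0.25), _chr(hmi), _chr(hd))
    for letter, hmi, hd in _HR_PATTERN:
        add(f"2{letter}", _isp(0.25), _isp(0.25), _chr(hmi), _chr(hd))
    for letter, hmi, hd in _HR_PATTERN:
        add(f"3{letter}", _pow(), _pow(), _chr(hmi), _chr(hd))
    add("3f", _pow(1.5), _pow(), _chr(0.5), _chr(0.5))
    for letter, hmi, hd in _HR_PATTERN:
        add(f"4{letter}", _const(0.25), _const(0.25),
            _dhr(hmi, 0.05), _dhr(hd, 0.05))
    for letter, hmi, hd in _HR_PATTERN:
        add(f"5{letter}", _const(0.25), _const(0.25),
            _dhr(hmi, -0.05), _dhr(hd, -0.05))
    add("5f", _const(0.25), _const(0.25), _dhr(0.5, -0.5), _dhr(0.5, -0.5))
    return cat


_CATALOGUE = _build_catalogue()

#: Catalogue labels in table order (families 1-5, letters within family).
SCENARIO_IDS: tuple[str, ...] = tuple(_CATALOGUE)


def list_scenarios() -> list[str]:
    """Return the catalogued scenario labels in table order."""
    return list(SCENARIO_IDS)


def get_scenario(scenario_id: str) -> ScenarioSpec:
    """Look up a catalogued scenario by its label (case-insensitive)."""
    key = str(scenario_id).strip().lower()
    try:
        return _CATALOGUE[key]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; valid labels: {', '.join(SCENARIO_IDS)}"
        ) from None


def load_scenario_file(path: str | Path) -> dict[str, ScenarioSpec]:
    """Load custom scenarios from a YAML or JSON file.

    The file holds a list (or a single mapping) of scenario mappings with
    keys ``scenario_id``, ``mi_baseline``, ``death_baseline``, ``mi_hr``,
    ``death_hr``, each hazard a mapping with ``form`` plus parameters.
    Custom scenarios run through the identical simulation machinery.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, Mapping):
        raw = [raw]
    out: dict[str, ScenarioSpec] = {}
    for entry in raw:
        spec = ScenarioSpec.from_dict(entry)
        out[spec.scenario_id.lower()] = spec
    return out
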