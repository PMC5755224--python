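"""Monte-Carlo orchestration: simulate, lay out, fit, and tabulate.

One *replicate* is one simulated trial: the dataset is generated, the
strata count ``k`` is set to the maximum observed number of events per
individual in that dataset, each requested model is laid out and
fitted, and a two-sided Wald test of no treatment effect is performed
under both the naive and the robust variance.  A *scenario run*
aggregates replicates into the summary statistics of the comparison
table: the mean and SD of the estimated hazard ratios over converged
replicates, the mean delta-method standard errors, the empirical power
under either variance, and the count of non-converged replicates
(excluded from means, counted as non-rejections for power).

Replicates are seeded individually from ``(seed, replicate,
subject)``, so results do not depend on execution order.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cox import FitResult, TiePolicy, fit_common, fit_wlw, wald_test
from .hazards import SCENARIO_IDS, ScenarioSpec, get_scenario
from .layout import LayoutMode, _analysis_events, max_strata, to_records
from .simulate import StudyConfig, simulate_dataset

__all__ = [
    "MODEL_ORDER",
    "StudyPlan",
    "ModelSummary",
    "ScenarioSummary",
    "run_replicate",
    "run_scenario",
    "run_study",
    "write_table2",
    "read_table2",
]

logger = logging.getLogger(__name__)

#: Deterministic model order used in reports.
MODEL_ORDER = (
    LayoutMode.COX_FIRST_EVENT.value,
    LayoutMode.AG.value,
    LayoutMode.PWP_TT.value,
    LayoutMode.PWP_GT.value,
    LayoutMode.WLW.value,
)

_DEFAULT_MODELS = (
    LayoutMode.AG.value,
    LayoutMode.PWP_TT.value,
    LayoutMode.PWP_GT.value,
    LayoutMode.WLW.value,
)


def _normalise_model(name: str) -> str:
    key = str(name).strip().lower().replace("-", "_")
    aliases = {"cox": LayoutMode.COX_FIRST_EVENT.value}
    key = aliases.get(key, key)
    if key not in MODEL_ORDER:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_ORDER}")
    return key


@dataclass
class StudyPlan:
    """A full study: which scenarios, how many replicates, which models."""

    scenarios: Sequence[str]
    n_reps: int = 5000
    cfg: StudyConfig = field(default_factory=StudyConfig)
    models: Sequence[str] = _DEFAULT_MODELS
    alpha: float = 0.05
    #: event set the models are fitted to: "nonfatal" analyses the
    #: recurrent process with death as censoring (the reference study's
    #: configuration); "all" analyses the composite process.
    analysis_events: str = "nonfatal"
    #: "common" fits one shared coefficient across WLW strata with
    #: cluster-robust variance; "stratum_average" averages per-stratum
    #: marginal estimates with a correlation-adjusted variance.
    wlw_method: str = "common"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        self.models = tuple(_normalise_model(m) for m in self.models)
        if self.analysis_events not in ("all", "nonfatal"):
            raise ValueError("analysis_events must be 'all' or 'nonfatal'")
        if self.wlw_method not in ("common", "stratum_average"):
            raise ValueError("wlw_method must be 'common' or 'stratum_average'")


@dataclass
class ModelSummary:
    """Aggregated results of one model under one scenario."""

    mean_hr: float
    geo_mean_hr: float
    mean_se_hr_naive: float
    mean_se_hr_robust: float
    emp_sd_hr: float
    power_robust: float
    power_naive: float
    n_nonconverged: int


@dataclass
class ScenarioSummary:
    """One row of the comparison table.

    ``mean_events`` / ``sd_events`` describe the per-subject event count
    pooled over replicates; ``mean_max_events`` / ``sd_max_events``
    describe the per-replicate maximum events per individual (the strata
    count used by the stratified models), which is the "# events"
    statistic of the reference comparison table.
    """

    scenario_id: str
    n_reps: int
    mean_events: float
    sd_events: float
    mean_max_events: float
    sd_max_events: float
    models: dict[str, ModelSummary]


def run_replicate(
    scenario: ScenarioSpec,
    cfg: StudyConfig,
    models: Sequence[str],
    alpha: float,
    replicate_index: int,
    analysis_events: str = "nonfatal",
    wlw_method: str = "common",
) -> dict:
    """Simulate and analyse one replicate; never raises on degenerate fits."""
    models = [_normalise_model(m) for m in models]
    data = simulate_dataset(scenario, cfg, replicate=replicate_index)
    histories = [h for _, h in data]
    counts = np.array(
        [len(_analysis_events(h, analysis_events)[0]) for h in histories]
    )
    if cfg.max_events_cap is not None:
        counts = np.minimum(counts, cfg.max_events_cap)
    k = max(int(counts.max()), 1)

    out: dict = {
        "replicate": replicate_index,
        "mean_events": float(counts.mean()),
        "max_events": int(counts.max()),
        "models": {},
    }
    for m in models:
        res = {
            "hr": math.nan, "beta": math.nan,
            "se_naive": math.nan, "se_robust": math.nan,
            "converged": False, "reject_naive": False, "reject_robust": False,
        }
        try:
            if m == LayoutMode.WLW.value:
                recs = to_records(data, LayoutMode.WLW, k=k,
                                  events=analysis_events, cap=cfg.max_events_cap)
                if wlw_method == "stratum_average":
                    fit = fit_wlw(recs, k=k)
                else:
                    fit = fit_common(recs, mode=m)
            else:
                recs = to_records(data, m, k=k,
                                  events=analysis_events, cap=cfg.max_events_cap)
                fit = fit_common(recs, mode=m)
            if fit.converged:
                res["beta"] = fit.beta
                res["hr"] = fit.hazard_ratio
                res["se_naive"] = fit.se_naive
                res["se_robust"] = fit.se_robust
                res["converged"] = True
                if fit.se_naive > 0 and math.isfinite(fit.se_naive):
                    res["reject_naive"] = wald_test(fit.beta, fit.se_naive, alpha).reject
                if fit.se_robust > 0 and math.isfinite(fit.se_robust):
                    res["reject_robust"] = wald_test(fit.beta, fit.se_robust, alpha).reject
        except ValueError as exc:  # degenerate likelihood and friends
            logger.debug("replicate %d model %s degenerate: %s", replicate_index, m, exc)
        out["models"][m] = res
    return out


def run_scenario(
    scenario: ScenarioSpec | str,
    cfg: StudyConfig,
    n_reps: int,
    models: Sequence[str] = _DEFAULT_MODELS,
    alpha: float = 0.05,
    analysis_events: str = "nonfatal",
    wlw_method: str = "common",
) -> ScenarioSummary:
    """Run ``n_reps`` replicates of one scenario and aggregate them."""
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    models = [_normalise_model(m) for m in models]
    t0 = time.perf_counter()

    mean_events = np.empty(n_reps)
    max_events = np.empty(n_reps)
    per_model: dict[str, list[dict]] = {m: [] for m in models}
    for rep in range(n_reps):
        r = run_replicate(scenario, cfg, models, alpha, rep,
                          analysis_events=analysis_events, wlw_method=wlw_method)
        mean_events[rep] = r["mean_events"]
        max_events[rep] = r["max_events"]
        for m in models:
            per_model[m].append(r["models"][m])

    summaries: dict[str, ModelSummary] = {}
    for m in models:
        rows = per_model[m]
        conv = [r for r in rows if r["converged"]]
        hrs = np.array([r["hr"] for r in conv])
        betas = np.array([r["beta"] for r in conv])
        se_n = np.array([r["hr"] * r["se_naive"] for r in conv])
        se_r = np.array([r["hr"] * r["se_robust"] for r in conv
                         if math.isfinite(r["se_robust"])])
        summaries[m] = ModelSummary(
            mean_hr=float(hrs.mean()) if hrs.size else math.nan,
            geo_mean_hr=float(np.exp(betas.mean())) if betas.size else math.nan,
            mean_se_hr_naive=float(se_n.mean()) if se_n.size else math.nan,
            mean_se_hr_robust=float(se_r.mean()) if se_r.size else math.nan,
            emp_sd_hr=float(hrs.std(ddof=1)) if hrs.size > 1 else math.nan,
            power_robust=float(sum(r["reject_robust"] for r in rows)) / n_reps,
            power_naive=float(sum(r["reject_naive"] for r in rows)) / n_reps,
            n_nonconverged=len(rows) - len(conv),
        )
    elapsed = time.perf_counter() - t0
    logger.info(
        "scenario %s: %d reps, seed %d, %.1fs, nonconverged %s",
        scenario.scenario_id, n_reps, cfg.seed, elapsed,
        {m: s.n_nonconverged for m, s in summaries.items()},
    )
    return ScenarioSummary(
        scenario_id=scenario.scenario_id,
        n_reps=n_reps,
        mean_events=float(mean_events.mean()),
        sd_events=float(mean_events.std(ddof=1)) if n_reps > 1 else math.nan,
        mean_max_events=float(max_events.mean()),
        sd_max_events=float(max_events.std(ddof=1)) if n_reps > 1 else math.nan,
        models=summaries,
    )


def run_study(plan: StudyPlan) -> list[ScenarioSummary]:
    """Run every scenario of a plan, in the order given."""
    return [
        run_scenario(sid, plan.cfg, plan.n_reps, plan.models, plan.alpha,
                     analysis_events=plan.analysis_events,
                     wlw_method=plan.wlw_method)
        for sid in plan.scenarios
    ]


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

def _summary_frame(summaries: Sequence[ScenarioSummary]) -> pd.DataFrame:
    if not summaries:
        raise ValueError("no summaries to report")
    models = [m for m in MODEL_ORDER if any(m in s.models for s in summaries)]
    rows = []
    for s in summaries:
        row: dict = {
            "scenario": s.scenario_id,
            "n_reps": s.n_reps,
            "mean_events": s.mean_events,
            "sd_events": s.sd_events,
            "mean_max_events": s.mean_max_events,
            "sd_max_events": s.sd_max_events,
        }
        for m in models:
            ms = s.models.get(m)
            for f in ("mean_hr", "geo_mean_hr", "mean_se_hr_naive",
                      "mean_se_hr_robust", "emp_sd_hr", "power_robust",
                      "power_naive", "n_nonconverged"):
                row[f"{m}_{f}"] = getattr(ms, f) if ms is not None else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_table2(summaries: Sequence[ScenarioSummary], path: str | Path) -> None:
    """Write the comparison table as CSV, one row per scenario.

    Columns are emitted in a deterministic order and the file
    round-trips through :func:`read_table2`.
    """
    _summary_frame(summaries).to_csv(path, index=False, float_format="%.10g")


def read_table2(path: str | Path) -> pd.DataFrame:
    """Read a comparison table written by :func:`write_table2`."""
    return pd.read_csv(path)
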