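"""Stratified Cox partial-likelihood engine for a single binary covariate.

All five layouts reduce to the same estimation problem: maximise a
(possibly stratified) Cox partial likelihood over the log hazard ratio
``beta`` of the treatment indicator, with risk sets read off the
``(start, stop]`` intervals of the counting-process records.  With a
single binary covariate the likelihood collapses to sums over event
times of ``beta*d1 - d*log(n0 + n1*exp(beta))`` where ``d``/``d1`` are
the event counts (total / treated) and ``n0``/``n1`` the at-risk counts
per arm, which makes Newton-Raphson iterations O(events) after one
O(n log n) sweep.

Variances:

* naive -- inverse observed information;
* robust (Lin-Wei) -- sandwich ``I^-1 (sum_c U_c^2) I^-1`` over
  per-subject summed score residuals;
* WLW -- per-stratum marginal fits combined as an unweighted average,
  with a correlation-adjusted variance built from the joint sandwich
  covariance of the strata-specific estimates.

Monotone likelihoods (all events in one arm) are not errors: the
estimate is clamped at ``|beta| = 10``, flagged, and reported as
non-converged so that Monte-Carlo studies and WLW stratum averaging
remain well defined.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .layout import LayoutMode

__all__ = [
    "TiePolicy",
    "FitResult",
    "WaldTest",
    "fit_common",
    "fit_wlw",
    "robust_variance",
    "wald_test",
    "log_partial_likelihood",
]

logger = logging.getLogger(__name__)

BETA_CLAMP = 10.0
SCORE_TOL = 1e-9
MAX_ITER = 50


class TiePolicy(str, enum.Enum):
    """Tie handling for coincident event times (Breslow default)."""

    BRESLOW = "breslow"
    EFRON = "efron"


@dataclass
class FitResult:
    """Outcome of one partial-likelihood maximisation.

    ``exp(beta)`` is the estimated (possibly mixed) hazard ratio of the
    experimental arm.  ``per_stratum_betas``, ``per_stratum_se`` and
    ``joint_covariance`` are populated by the WLW combination only;
    ``strata_used`` lists the strata that entered the average.
    """

    beta: float
    se_naive: float
    se_robust: float
    loglik: float
    iterations: int
    converged: bool
    clamped: bool = False
    n_events: int = 0
    model: str = ""
    per_stratum_betas: list[float] | None = None
    per_stratum_se: list[float] | None = None
    joint_covariance: np.ndarray | None = None
    strata_used: list[int] | None = None

    @property
    def hazard_ratio(self) -> float:
        return math.exp(self.beta)


class WaldTest(NamedTuple):
    z: float
    p: float
    reject: bool


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

class _StratumData(NamedTuple):
    """Per-stratum arrays: records plus the event-time summary table."""

    start: np.ndarray
    stop: np.ndarray
    status: np.ndarray
    x: np.ndarray
    subject: np.ndarray
    et: np.ndarray   # unique event times, ascending
    d: np.ndarray    # events per time
    d1: np.ndarray   # treated events per time
    n0: np.ndarray   # control records at risk
    n1: np.ndarray   # treated records at risk


def _prepare(records: pd.DataFrame) -> list[_StratumData]:
    req = {"subject_id", "start", "stop", "status", "stratum", "group"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records are missing columns: {sorted(missing)}")
    start = records["start"].to_numpy(float)
    stop = records["stop"].to_numpy(float)
    status = records["status"].to_numpy(np.int64)
    x = records["group"].to_numpy(np.int64)
    stratum = records["stratum"].to_numpy(np.int64)
    subject = records["subject_id"].to_numpy(np.int64)
    if status.sum() == 0:
        raise ValueError("degenerate likelihood: no events in the data")
    if np.unique(x).size < 2:
        raise ValueError("both treatment groups must be present")

    out = []
    for s in np.unique(stratum):
        m = stratum == s
        st, sp, de, xx, su = start[m], stop[m], status[m], x[m], subject[m]
        ev = sp[de == 1]
        if ev.size == 0:
            # no events: contributes nothing to the likelihood
            continue
        et, inv = np.unique(ev, return_inverse=True)
        d = np.bincount(inv, minlength=et.size)
        d1 = np.bincount(inv, weights=xx[de == 1].astype(float),
                         minlength=et.size).astype(np.int64)
        n = np.empty((2, et.size), dtype=np.int64)
        for g in (0, 1):
            starts_g = np.sort(st[xx == g])
            stops_g = np.sort(sp[xx == g])
            # at risk at t: start < t <= stop
            n[g] = (np.searchsorted(starts_g, et, side="left")
                    - np.searchsorted(stops_g, et, side="left"))
        out.append(_StratumData(st, sp, de, xx, su, et, d, d1, n[0], n[1]))
    return out


def _ll_U_I(beta: float, strata: Sequence[_StratumData], ties: TiePolicy):
    r = math.exp(beta)
    ll = 0.0
    U = 0.0
    I = 0.0
    for sd in strata:
        S0 = sd.n0 + sd.n1 * r
        if ties is TiePolicy.BRESLOW or (sd.d <= 1).all():
            xbar = sd.n1 * r / S0
            ll += beta * sd.d1.sum() - float(sd.d @ np.log(S0))
            U += float(sd.d1.sum() - sd.d @ xbar)
            I += float(sd.d @ (xbar * (1.0 - xbar)))
        else:
            # Efron: deflate the denominator by the tied events' own terms
            d, d1 = sd.d, sd.d1
            idx = np.repeat(np.arange(d.size), d)
            m = np.arange(idx.size) - np.repeat(np.cumsum(d) - d, d)
            frac = m / d[idx]
            Se0 = (d - d1) + d1 * r
            S0m = S0[idx] - frac * Se0[idx]
            S1m = (sd.n1 * r)[idx] - frac * (d1 * r)[idx]
            xb = S1m / S0m
            ll += beta * d1.sum() - float(np.log(S0m).sum())
            U += float(d1.sum() - xb.sum())
            I += float((xb * (1.0 - xb)).sum())
    return ll, U, I


def log_partial_likelihood(
    records: pd.DataFrame, beta: float, ties: TiePolicy = TiePolicy.BRESLOW
) -> float:
    """Evaluate the (stratified) log partial likelihood at ``beta``."""
    strata = _prepare(records)
    return _ll_U_I(beta, strata, TiePolicy(ties))[0]


# ---------------------------------------------------------------------------
# Newton-Raphson
# ---------------------------------------------------------------------------

def _newton(strata: Sequence[_StratumData], ties: TiePolicy):
    D = int(sum(sd.d.sum() for sd in strata))
    D1 = int(sum(sd.d1.sum() for sd in strata))
    if D1 == 0 or D1 == D:
        # monotone likelihood: clamp in the direction the score pushes
        beta = BETA_CLAMP if D1 == D else -BETA_CLAMP
        ll, U, I = _ll_U_I(beta, strata, ties)
        return beta, ll, I, 0, False, True

    beta = 0.0
    ll, U, I = _ll_U_I(beta, strata, ties)
    clamped = False
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        if abs(U) < SCORE_TOL:
            converged = True
            break
        if I <= 0:
            clamped = True
            break
        step = float(np.clip(U / I, -5.0, 5.0))
        new = float(np.clip(beta + step, -BETA_CLAMP, BETA_CLAMP))
        nll, nU, nI = _ll_U_I(new, strata, ties)
        halvings = 0
        while nll < ll - 1e-13 and halvings < 30:
            step *= 0.5
            new = float(np.clip(beta + step, -BETA_CLAMP, BETA_CLAMP))
            nll, nU, nI = _ll_U_I(new, strata, ties)
            halvings += 1
        if new == beta:
            clamped = abs(beta) >= BETA_CLAMP - 1e-12
            break
        beta, ll, U, I = new, nll, nU, nI
    if abs(beta) >= BETA_CLAMP - 1e-12 and not abs(U) < SCORE_TOL:
        clamped = True
        converged = False
    return beta, ll, I, it, converged, clamped


# ---------------------------------------------------------------------------
# Score residuals and sandwich variance
# ---------------------------------------------------------------------------

def _subject_scores(beta: float, strata: Sequence[_StratumData]) -> dict[int, float]:
    """Per-subject summed score residuals at ``beta`` (Breslow increments)."""
    r = math.exp(beta)
    acc: dict[int, float] = {}
    for sd in strata:
        S0 = sd.n0 + sd.n1 * r
        xbar = sd.n1 * r / S0
        a = sd.d / S0                  # baseline-hazard increments
        b = xbar * a
        cumA = np.concatenate(([0.0], np.cumsum(a)))
        cumB = np.concatenate(([0.0], np.cumsum(b)))
        hi = np.searchsorted(sd.et, sd.stop, side="right")
        lo = np.searchsorted(sd.et, sd.start, side="right")
        sumA = cumA[hi] - cumA[lo]
        sumB = cumB[hi] - cumB[lo]
        w = np.where(sd.x == 1, r, 1.0)
        u = -w * (sd.x * sumA - sumB)
        ev = sd.status == 1
        own = np.searchsorted(sd.et, sd.stop[ev], side="left")
        u[ev] += sd.x[ev] - xbar[own]
        for sid, ui in zip(sd.subject, u):
            acc[int(sid)] = acc.get(int(sid), 0.0) + float(ui)
    return acc


def _robust_from_scores(scores: dict[int, float], info: float) -> float:
    b = sum(v * v for v in scores.values())
    return b / (info * info)


def robust_variance(
    fit: FitResult, records: pd.DataFrame, cluster: str = "subject_id"
) -> float:
    """Lin-Wei sandwich variance of ``beta`` with subjects as clusters.

    Recomputed from the records at ``fit.beta``; requires a converged fit.
    """
    if not fit.converged:
        raise RuntimeError("robust variance requires a converged fit")
    if cluster != "subject_id":
        records = records.rename(columns={cluster: "subject_id"})
    strata = _prepare(records)
    _, _, info = _ll_U_I(fit.beta, strata, TiePolicy.BRESLOW)
    if info <= 0:
        raise RuntimeError("observed information is not positive")
    return _robust_from_scores(_subject_scores(fit.beta, strata), info)


# ---------------------------------------------------------------------------
# Fitters
# ---------------------------------------------------------------------------

def fit_common(
    records: pd.DataFrame,
    mode: LayoutMode | str | None = None,
    ties: TiePolicy | str = TiePolicy.BRESLOW,
    compute_robust: bool = True,
) -> FitResult:
    """Maximise the common-``beta`` (stratified) partial likelihood.

    Covers the first-event Cox, Andersen-Gill and both PWP layouts: the
    records' ``stratum`` column defines the within-stratum risk sets and
    a single ``beta`` is shared across strata.  ``mode`` is a label
    carried into the result; the records themselves fix the model.
    """
    ties = TiePolicy(ties)
    strata = _prepare(records)
    beta, ll, info, it, converged, clamped = _newton(strata, ties)
    n_events = int(sum(sd.d.sum() for sd in strata))
    se_naive = 1.0 / math.sqrt(info) if info > 0 else math.inf
    se_robust = math.nan
    if compute_robust and converged and info > 0:
        se_robust = math.sqrt(
            _robust_from_scores(_subject_scores(beta, strata), info)
        )
    return FitResult(
        beta=beta, se_naive=se_naive, se_robust=se_robust, loglik=ll,
        iterations=it, converged=converged, clamped=clamped,
        n_events=n_events,
        model=str(LayoutMode(mode).value) if mode is not None else "",
    )


def fit_wlw(records: pd.DataFrame, k: int | None = None) -> FitResult:
    """Fit the Wei-Lin-Weissfeld marginal model on a WLW layout.

    Each stratum ``j`` is analysed as its own marginal Cox model over
    all subjects.  The combined effect is the unweighted average of the
    strata-specific estimates over the ``k'`` estimable strata; strata
    without events are dropped with a warning and strata with a monotone
    likelihood (all events in one arm, estimate clamped) are reported
    but excluded from the average, which would otherwise be dominated by
    their arbitrary clamp value.  The combined variance is
    ``w' V w`` with ``w = 1/k'`` and ``V`` the joint sandwich covariance
    of the strata-specific estimates built from stacked per-subject
    score residuals.
    """
    strata_labels = np.sort(records["stratum"].unique())
    if k is not None and strata_labels.size and strata_labels.max() > k:
        raise ValueError("records contain strata beyond k")
    subjects = np.sort(records["subject_id"].unique())
    sub_index = {int(s): i for i, s in enumerate(subjects)}

    betas: list[float] = []
    infos: list[float] = []
    logliks: list[float] = []
    score_vecs: list[np.ndarray] = []
    used: list[int] = []
    all_betas: list[float] = []
    iters = 0
    n_events_total = 0
    for j in strata_labels:
        sub = records[records["stratum"] == j]
        n_ev = int(sub["status"].sum())
        n_events_total += n_ev
        if n_ev == 0:
            logger.warning("WLW stratum %d has no events; dropped", j)
            all_betas.append(math.nan)
            continue
        sd = _prepare(sub.assign(stratum=1))
        beta_j, ll_j, info_j, it_j, conv_j, clamp_j = _newton(sd, TiePolicy.BRESLOW)
        iters = max(iters, it_j)
        all_betas.append(beta_j)
        if not conv_j:
            logger.info("WLW stratum %d not estimable (clamped=%s); excluded", j, clamp_j)
            continue
        scores = _subject_scores(beta_j, sd)
        vec = np.zeros(subjects.size)
        for sid, ui in scores.items():
            vec[sub_index[sid]] = ui
        betas.append(beta_j)
        infos.append(info_j)
        logliks.append(ll_j)
        score_vecs.append(vec)
        used.append(int(j))

    if not betas:
        raise ValueError("degenerate likelihood: no estimable WLW stratum")

    kk = len(betas)
    U = np.column_stack(score_vecs)          # n_subjects x k'
    B = U.T @ U
    inv_info = 1.0 / np.asarray(infos)
    V = B * np.outer(inv_info, inv_info)     # joint sandwich covariance
    # enforce exact symmetry against round-off
    V = 0.5 * (V + V.T)
    beta_bar = float(np.mean(betas))
    var_rob = float(V.sum()) / (kk * kk)
    var_naive = float(np.sum(inv_info)) / (kk * kk)
    return FitResult(
        beta=beta_bar,
        se_naive=math.sqrt(var_naive),
        se_robust=math.sqrt(max(var_rob, 0.0)),
        loglik=float(np.sum(logliks)),
        iterations=iters,
        converged=True,
        clamped=False,
        n_events=n_events_total,
        model=LayoutMode.WLW.value,
        per_stratum_betas=all_betas,
        per_stratum_se=list(np.sqrt(np.clip(np.diag(V), 0.0, None))),
        joint_covariance=V,
        strata_used=used,
    )


def wald_test(beta: float, se: float, alpha: float = 0.05) -> WaldTest:
    """Two-sided Wald test of ``beta = 0`` against a normal reference."""
    if not se > 0 or not math.isfinite(se):
        raise ValueError("se must be a positive finite number")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return WaldTest(z=float(z), p=float(p), reject=bool(p < alpha))
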