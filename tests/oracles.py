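"""Independent reference implementations used only by the tests.

Everything here is deliberately naive — explicit loops over risk-set
definitions, dense grid search, adaptive quadrature — so that it shares
no code path with the package's vectorised engine.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate


def quad_cumulative_hazard(hazard_fn, a: float, b: float) -> float:
    """Adaptive-quadrature integral of a pointwise hazard function."""
    val, _ = integrate.quad(hazard_fn, a, b, epsabs=1e-12, epsrel=1e-12)
    return val


def brute_loglik_grid(records, grid: np.ndarray) -> np.ndarray:
    """Breslow log partial likelihood on a beta grid, risk sets by loops.

    ``records`` is a DataFrame with subject_id/start/stop/status/stratum/
    group.  Risk membership is evaluated record by record from the
    definition ``start < t <= stop`` within stratum.
    """
    e_grid = np.exp(grid)
    ll = np.zeros_like(grid)
    rows = records.to_dict("records")
    for ev in rows:
        if ev["status"] != 1:
            continue
        t, s = ev["stop"], ev["stratum"]
        n0 = n1 = 0
        for r in rows:
            if r["stratum"] == s and r["start"] < t <= r["stop"]:
                if r["group"] == 1:
                    n1 += 1
                else:
                    n0 += 1
        ll += ev["group"] * grid - np.log(n0 + n1 * e_grid)
    return ll


def grid_argmax_beta(records, lo=-5.0, hi=5.0, step=1e-4) -> float:
    """Dense grid-search maximiser of the brute-force partial likelihood."""
    grid = np.arange(lo, hi + step / 2, step)
    ll = brute_loglik_grid(records, grid)
    return float(grid[int(np.argmax(ll))])


def sandwich_variance_by_hand(records, beta: float) -> float:
    """Cluster sandwich variance written out term by term (Breslow).

    Score residual of record r:
        status_r * (x_r - xbar(t_r))
        - sum over event times t in (start_r, stop_r]:
              exp(beta*x_r) * (x_r - xbar(t)) * d(t)/S0(t)
    summed within subject, squared, summed over subjects, and divided by
    the squared observed information.
    """
    rows = records.to_dict("records")
    events = sorted(
        {(r["stop"], r["stratum"]) for r in rows if r["status"] == 1}
    )

    def risk(t, s):
        return [r for r in rows if r["stratum"] == s and r["start"] < t <= r["stop"]]

    info = 0.0
    stats = {}
    for t, s in events:
        rs = risk(t, s)
        S0 = sum(math.exp(beta * r["group"]) for r in rs)
        S1 = sum(r["group"] * math.exp(beta * r["group"]) for r in rs)
        d = sum(1 for r in rows
                if r["status"] == 1 and r["stop"] == t and r["stratum"] == s)
        xbar = S1 / S0
        info += d * (xbar - xbar**2)
        stats[(t, s)] = (xbar, d / S0)

    scores = {}
    for r in rows:
        u = 0.0
        if r["status"] == 1:
            xbar, _ = stats[(r["stop"], r["stratum"])]
            u += r["group"] - xbar
        for (t, s), (xbar, dS0) in stats.items():
            if s == r["stratum"] and r["start"] < t <= r["stop"]:
                u -= math.exp(beta * r["group"]) * (r["group"] - xbar) * dS0
        scores[r["subject_id"]] = scores.get(r["subject_id"], 0.0) + u
    b = sum(v * v for v in scores.values())
    return b / info**2


def risk_set_size_from_histories(pairs, mode, j, t, events="all"):
    """Count subjects at risk for the j-th event at time t, by definition.

    Works directly from (design, history) pairs: AG counts subjects with
    any analysis event time or censoring time >= t; PWP total time needs
    T_{j-1} < t <= T_j; PWP gap time needs the j-th gap >= t; WLW counts
    subjects whose j-th (possibly artificial) time is >= t.
    """
    count = 0
    for _, h in pairs:
        times = [tt for tt, ty in zip(h.event_times, h.event_types)
                 if events == "all" or ty != "D"]
        ends_with_event = events == "all" and h.terminal == "death"
        end = h.end_time
        n = len(times)
        if mode == "ag":
            # at risk while under observation
            if end >= t:
                count += 1
        elif mode == "pwp_tt":
            if n < j - 1:
                continue  # never reached stratum j
            prev = times[j - 2] if j >= 2 else 0.0
            tj = times[j - 1] if n >= j else (end if n == j - 1 else None)
            if n == j - 1 and ends_with_event:
                tj = None  # observation closed by the (j-1)th event itself
            if tj is not None and prev < t <= tj:
                count += 1
        elif mode == "pwp_gt":
            if n < j - 1:
                continue
            prev = times[j - 2] if j >= 2 else 0.0
            gap = (times[j - 1] - prev) if n >= j else (
                None if (n != j - 1 or ends_with_event) else end - prev)
            if gap is not None and gap >= t:
                count += 1
        elif mode == "wlw":
            tj = times[j - 1] if n >= j else end
            if tj >= t:
                count += 1
        else:
            raise ValueError(mode)
    return count
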