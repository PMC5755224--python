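import math

import numpy as np
import pandas as pd
import pytest

from recurtrial import (
    LayoutMode,
    StudyConfig,
    TiePolicy,
    fit_common,
    fit_wlw,
    get_scenario,
    log_partial_likelihood,
    max_strata,
    robust_variance,
    simulate_dataset,
    to_records,
    wald_test,
)
from .conftest import make_pairs, random_small_pairs
from .oracles import grid_argmax_beta, sandwich_variance_by_hand


def records_df(rows):
    """Rows of (subject_id, start, stop, status, stratum, group)."""
    return pd.DataFrame(
        rows, columns=["subject_id", "start", "stop", "status", "stratum", "group"]
    )


class TestFitCommon:
    def test_symmetric_data_gives_zero_effect(self):
        # swapping the group labels reproduces the same event pattern
        df = records_df([(0, 0, 1.0, 1, 1, 0), (1, 0, 1.0, 1, 1, 1),
                         (2, 0, 2.0, 1, 1, 0), (3, 0, 2.0, 1, 1, 1),
                         (4, 0, 3.0, 0, 1, 0), (5, 0, 3.0, 0, 1, 1)])
        fit = fit_common(df)
        assert fit.converged
        assert fit.beta == pytest.approx(0.0, abs=1e-9)

    def test_four_subject_example_matches_grid_search(self):
        df = records_df([(0, 0, 1.0, 1, 1, 1), (1, 0, 2.0, 1, 1, 0),
                         (2, 0, 3.0, 1, 1, 1), (3, 0, 4.0, 0, 1, 0)])
        fit = fit_common(df, mode=LayoutMode.COX_FIRST_EVENT)
        assert fit.converged
        assert fit.beta == pytest.approx(grid_argmax_beta(df), abs=1e-3)

    @pytest.mark.parametrize("mode", ["cox_first_event", "ag", "pwp_tt", "pwp_gt"])
    def test_random_instances_match_grid_search(self, mode):
        rng = np.random.default_rng(314)
        checked = 0
        while checked < 25:
            pairs = random_small_pairs(rng)
            k = max(max_strata([h for _, h in pairs]), 1)
            df = to_records(pairs, mode, k=k)
            if df["status"].sum() == 0 or df["group"].nunique() < 2:
                continue
            fit = fit_common(df, mode=mode)
            if not fit.converged:
                continue
            assert fit.beta == pytest.approx(grid_argmax_beta(df), abs=1e-3)
            checked += 1

    def test_score_vanishes_and_loglik_beats_null(self, dataset_1a):
        df = to_records(dataset_1a, LayoutMode.AG)
        fit = fit_common(df)
        assert fit.converged
        eps = 1e-6
        score = (log_partial_likelihood(df, fit.beta + eps)
                 - log_partial_likelihood(df, fit.beta - eps)) / (2 * eps)
        assert abs(score) < 1e-4   # numerical derivative of the analytic optimum
        assert fit.loglik >= log_partial_likelihood(df, 0.0)

    def test_ag_equals_cox_when_no_repeats(self):
        cfg = StudyConfig(n_subjects=80, seed=17, max_events_cap=1)
        data = simulate_dataset(get_scenario("1c"), cfg)
        ag = fit_common(to_records(data, "ag", events="nonfatal", cap=1))
        cox = fit_common(to_records(data, "cox_first_event", events="nonfatal", cap=1))
        assert ag.beta == cox.beta
        assert ag.se_naive == cox.se_naive

    def test_beta_invariant_under_relabeling_and_permutation(self, dataset_1a):
        df = to_records(dataset_1a, LayoutMode.PWP_TT)
        fit = fit_common(df)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["subject_id"] = shuffled["subject_id"] * 7 + 3
        refit = fit_common(shuffled)
        assert refit.beta == pytest.approx(fit.beta, abs=1e-12)
        assert refit.se_robust == pytest.approx(fit.se_robust, rel=1e-10)

    def test_no_events_is_degenerate(self):
        df = records_df([(0, 0, 1.0, 0, 1, 0), (1, 0, 2.0, 0, 1, 1)])
        with pytest.raises(ValueError, match="degenerate"):
            fit_common(df)

    def test_single_group_rejected(self):
        df = records_df([(0, 0, 1.0, 1, 1, 1), (1, 0, 2.0, 1, 1, 1)])
        with pytest.raises(ValueError, match="both treatment groups"):
            fit_common(df)

    def test_monotone_likelihood_clamps_instead_of_raising(self):
        df = records_df([(0, 0, 1.0, 1, 1, 0), (1, 0, 1.5, 1, 1, 0),
                         (2, 0, 3.0, 0, 1, 1), (3, 0, 3.0, 0, 1, 1)])
        fit = fit_common(df)
        assert not fit.converged
        assert fit.clamped
        assert fit.beta == -10.0

    def test_large_sample_recovers_log_rate_ratio(self):
        """Two-arm exponential data without censoring, n = 5000."""
        rng = np.random.default_rng(2)
        n = 5000
        x = np.repeat([0, 1], n // 2)
        t = rng.exponential(1.0, n)
        t[x == 1] = rng.exponential(1 / 1.8, n // 2)  # rate ratio 1.8
        df = records_df(list(zip(range(n), [0.0] * n, t, [1] * n, [1] * n, x)))
        fit = fit_common(df)
        assert fit.converged
        assert fit.beta == pytest.approx(math.log(1.8), abs=3 * fit.se_naive)


class TestTies:
    def test_breslow_and_efron_agree_without_ties(self, dataset_1a):
        df = to_records(dataset_1a, LayoutMode.AG)
        b = fit_common(df, ties=TiePolicy.BRESLOW)
        e = fit_common(df, ties=TiePolicy.EFRON)
        assert b.beta == pytest.approx(e.beta, abs=1e-12)

    def test_efron_matches_lifelines_on_tied_data(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        n = 120
        x = rng.integers(0, 2, n)
        # heavy rounding produces many ties
        t = np.ceil(rng.exponential(np.where(x == 1, 0.6, 1.0)) * 4) / 4
        status = (rng.random(n) < 0.8).astype(int)
        df = records_df(list(zip(range(n), [0.0] * n, t, status, [1] * n, x)))
        fit = fit_common(df, ties=TiePolicy.EFRON)
        cph = lifelines.CoxPHFitter()
        cph.fit(pd.DataFrame({"t": t, "e": status, "x": x}),
                duration_col="t", event_col="e")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se_naive == pytest.approx(cph.standard_errors_["x"], abs=1e-6)


class TestRobustVariance:
    def test_matches_hand_expanded_sandwich_on_three_subjects(self):
        df = records_df([(0, 0, 1.0, 1, 1, 1), (1, 0, 2.0, 1, 1, 0),
                         (2, 0, 3.0, 0, 1, 1)])
        fit = fit_common(df)
        v = robust_variance(fit, df)
        assert v == pytest.approx(sandwich_variance_by_hand(df, fit.beta), abs=1e-10)
        assert fit.se_robust**2 == pytest.approx(v, rel=1e-12)

    def test_matches_hand_sandwich_on_clustered_intervals(self, dataset_1a):
        df = to_records(dataset_1a[:25], LayoutMode.AG)
        fit = fit_common(df)
        assert robust_variance(fit, df) == pytest.approx(
            sandwich_variance_by_hand(df, fit.beta), abs=1e-10
        )

    def test_matches_lifelines_cluster_robust(self, dataset_1a):
        lifelines = pytest.importorskip("lifelines")
        df = to_records(dataset_1a, LayoutMode.COX_FIRST_EVENT)
        fit = fit_common(df, ties=TiePolicy.BRESLOW)
        frame = pd.DataFrame({"t": df["stop"], "e": df["status"],
                              "x": df["group"], "id": df["subject_id"]})
        cph = lifelines.CoxPHFitter()
        cph.fit(frame, duration_col="t", event_col="e", cluster_col="id", robust=True)
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se_robust == pytest.approx(cph.standard_errors_["x"], rel=5e-2)

    def test_duplicating_subjects_halves_naive_variance(self, dataset_1a):
        df = to_records(dataset_1a[:40], LayoutMode.AG)
        dup = df.copy()
        dup["subject_id"] = dup["subject_id"] + 10_000
        both = pd.concat([df, dup], ignore_index=True)
        fit1, fit2 = fit_common(df), fit_common(both)
        assert fit2.beta == pytest.approx(fit1.beta, abs=1e-8)
        assert fit2.se_naive**2 == pytest.approx(fit1.se_naive**2 / 2, rel=1e-6)

    def test_requires_convergence(self):
        df = records_df([(0, 0, 1.0, 1, 1, 0), (1, 0, 3.0, 0, 1, 1)])
        fit = fit_common(df)
        assert not fit.converged
        with pytest.raises(RuntimeError):
            robust_variance(fit, df)

    def test_variance_strictly_positive(self, dataset_1a):
        df = to_records(dataset_1a, LayoutMode.PWP_GT)
        fit = fit_common(df)
        assert robust_variance(fit, df) > 0


class TestWLW:
    def test_single_stratum_reduces_to_plain_cox(self, dataset_1a):
        df = to_records(dataset_1a, LayoutMode.WLW, k=1, cap=1)
        combined = fit_wlw(df, k=1)
        plain = fit_common(to_records(dataset_1a, LayoutMode.COX_FIRST_EVENT, cap=1))
        assert combined.beta == pytest.approx(plain.beta, abs=1e-10)

    def test_identical_strata_average_to_the_common_value(self, dataset_1a):
        base = to_records(dataset_1a, LayoutMode.COX_FIRST_EVENT, cap=1)
        stacked = pd.concat(
            [base.assign(stratum=j) for j in (1, 2, 3)], ignore_index=True
        )
        fit = fit_wlw(stacked, k=3)
        single = fit_common(base)
        assert fit.per_stratum_betas == pytest.approx([single.beta] * 3)
        assert fit.beta == pytest.approx(single.beta, abs=1e-12)
        # three copies of the same stratum are perfectly correlated
        assert fit.se_robust == pytest.approx(single.se_robust, rel=1e-6)

    def test_per_stratum_estimates_match_grid_search(self, dataset_3a):
        pairs = dataset_3a[:50]
        k = max(max_strata([h for _, h in pairs]), 1)
        df = to_records(pairs, LayoutMode.WLW, k=k)
        fit = fit_wlw(df, k=k)
        for j in fit.strata_used[:2]:
            sub = df[df.stratum == j].assign(stratum=1)
            assert fit.per_stratum_betas[j - 1] == pytest.approx(
                grid_argmax_beta(sub), abs=1e-3
            )

    def test_joint_covariance_is_symmetric_psd(self, dataset_3a):
        k = max_strata([h for _, h in dataset_3a])
        fit = fit_wlw(to_records(dataset_3a, LayoutMode.WLW, k=k), k=k)
        V = fit.joint_covariance
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > -1e-10

    def test_all_strata_empty_is_degenerate(self):
        df = records_df([(0, 0, 2.0, 0, 1, 0), (1, 0, 2.0, 0, 1, 1),
                         (0, 0, 2.0, 0, 2, 0), (1, 0, 2.0, 0, 2, 1)])
        with pytest.raises(ValueError, match="degenerate"):
            fit_wlw(df, k=2)


class TestWald:
    def test_null_beta_gives_p_one(self):
        z, p, reject = wald_test(0.0, 1.0)
        assert (z, p, reject) == (0.0, 1.0, False)

    def test_boundary_of_the_five_percent_level(self):
        _, p, _ = wald_test(1.959964, 1.0, alpha=0.05)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)
        with pytest.raises(ValueError):
            wald_test(1.0, -1.0)
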