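import numpy as np
import pytest
from scipy import stats as sps

from synfma.stats import (
    DiagnosticsError,
    duration_reduction,
    group_tests,
    outlier_screened_regression,
    regression_diagnostics,
    robust_regression,
    select_task_subset,
    severity_class,
    two_way_anova,
)
from synfma.types import ValidationError


def irls_bisquare_oracle(x, y, tune=4.685, tol=1e-8, max_iter=100):
    """Independently coded IRLS with Tukey bisquare weights.

    Deliberately written with a different linear-algebra route (scaled
    lstsq on the weighted design) than the implementation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    X = np.column_stack([np.ones(n), x])
    H = X @ np.linalg.pinv(X)
    lev = np.diag(H)
    adj = 1.0 / np.sqrt(np.clip(1 - lev, 1e-8, None))
    beta = np.linalg.pinv(X) @ y
    for _ in range(max_iter):
        r = (y - X @ beta) * adj
        sorted_abs = np.sort(np.abs(r))[2:]
        s = np.median(sorted_abs) / 0.6745
        if s <= 0:
            s = max(np.abs(r).max(), 1e-12)
        u = r / (tune * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            w = np.ones(n)
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) / max(np.max(np.abs(beta_new)), 1e-12) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta


class TestSeverity:
    @pytest.mark.parametrize("score,expected", [
        (29, "severe"), (30, "mild"), (66, "mild"), (0, "severe"),
    ])
    def test_cutoff(self, score, expected):
        assert severity_class(score) == expected

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            severity_class(67)


class TestRobustRegression:
    def test_collinear_matches_ols(self):
        x = np.arange(10, dtype=float)
        y = 3.0 + 0.5 * x
        f = robust_regression(x, y)
        assert f.slope == pytest.approx(0.5, abs=1e-9)
        assert f.intercept == pytest.approx(3.0, abs=1e-9)

    def test_gross_outlier_downweighted(self):
        x = np.arange(20, dtype=float)
        y = 1.0 + 0.3 * x
        y[10] += 50.0
        f = robust_regression(x, y)
        assert f.slope == pytest.approx(0.3, abs=1e-3)
        assert f.weights[10] == 0.0

    def test_matches_independent_irls_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.uniform(0, 66, 20)
            y = rng.normal(0, 1, 20) + 0.02 * x
            f = robust_regression(x, y)
            b = irls_bisquare_oracle(x, y)
            assert f.intercept == pytest.approx(b[0], abs=1e-6)
            assert f.slope == pytest.approx(b[1], abs=1e-6)

    def test_constant_x_rejected(self):
        with pytest.raises(ValidationError):
            robust_regression(np.ones(6), np.arange(6.0))


class TestDiagnostics:
    def test_null_acceptance_rate(self):
        rng = np.random.default_rng(0)
        ok = 0
        for _ in range(100):
            x = rng.uniform(0, 10, 40)
            r = rng.normal(0, 1, 40)
            d = regression_diagnostics(r, x)
            ok += all(p > 0.05 for p in d.values())
        assert ok >= 80   # ~0.95^3 expected under the null

    def test_heteroskedastic_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(50):
            x = rng.uniform(1, 10, 50)
            r = rng.normal(0, 1, 50) * x**2 / 10
            hits += regression_diagnostics(r, x)["breusch_pagan_p"] < 0.05
        assert hits >= 40

    def test_autocorrelation_detected(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(50):
            e = rng.normal(0, 1, 50)
            r = np.zeros(50)
            for i in range(1, 50):
                r[i] = 0.9 * r[i - 1] + e[i]
            hits += regression_diagnostics(r, np.arange(50.0))["durbin_watson_p"] < 0.05
        assert hits >= 40

    def test_degenerate_residuals_rejected(self):
        with pytest.raises(DiagnosticsError):
            regression_diagnostics(np.ones(10), np.arange(10.0))


class TestScreenedRegression:
    def test_clean_data_no_removal(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 66, 20)
        y = 2 - 0.02 * x + rng.normal(0, 0.05, 20)
        e = outlier_screened_regression(x, y)
        assert e.removed_subjects == []
        assert e.assumptions_met

    def test_planted_outlier_removed(self):
        rng = np.random.default_rng(0)
        x = np.linspace(6, 66, 20)
        y = 2 + 0.05 * x + rng.normal(0, 0.1, 20)
        y[7] += 5.0
        e = outlier_screened_regression(x, y, [f"s{i}" for i in range(20)])
        assert e.removed_subjects == ["s7"]
        assert e.assumptions_met

    def test_irreparable_data_flagged(self):
        # strongly AR(1) residual structure cannot be fixed by removing two
        # points; the screen must flag the failure but keep the fit
        rng = np.random.default_rng(1)
        x = np.linspace(0, 66, 40)
        r = np.zeros(40)
        e0 = rng.normal(0, 1, 40)
        for i in range(1, 40):
            r[i] = 0.95 * r[i - 1] + 0.1 * e0[i]
        e = outlier_screened_regression(x, r)
        if not e.assumptions_met:
            assert len(e.removed_subjects) == 2


def anova_bruteforce(groups):
    """Textbook one-way ANOVA from sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((g - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, sps.f.sf(F, df_b, df_w), ss_within / df_w, df_w


def tukey_kramer_bruteforce(groups):
    """Pairwise studentized-range P-values with the Kramer unequal-n term."""
    F, _, mse, df_w = anova_bruteforce(groups)
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ni, nj = len(groups[i]), len(groups[j])
            se = np.sqrt(mse / 2 * (1 / ni + 1 / nj))
            q = abs(np.mean(groups[i]) - np.mean(groups[j])) / se
            out[(i, j)] = sps.studentized_range.sf(q, len(groups), df_w)
    return out


class TestGroupTests:
    def test_identical_groups(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        rep = group_tests(g)
        assert rep.anova_f == pytest.approx(0.0, abs=1e-12)
        for p in rep.tukey_p.values():
            assert p > 0.99

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 1, n) for m, n in [(0, 7), (1, 13), (2.5, 6)]]
        rep = group_tests({"h": groups[0], "m": groups[1], "s": groups[2]})
        F, p, _, _ = anova_bruteforce(groups)
        assert rep.anova_f == pytest.approx(F, abs=1e-6)
        assert rep.anova_p == pytest.approx(p, abs=1e-6)
        oracle = tukey_kramer_bruteforce(groups)
        assert rep.tukey_p[("h", "m")] == pytest.approx(oracle[(0, 1)], abs=1e-6)
        assert rep.tukey_p[("m", "s")] == pytest.approx(oracle[(1, 2)], abs=1e-6)

    def test_tukey_at_least_unadjusted_t(self):
        rng = np.random.default_rng(10)
        groups = {"a": rng.normal(0, 1, 8), "b": rng.normal(0.5, 1, 12),
                  "c": rng.normal(1, 1, 9)}
        rep = group_tests(groups)
        for pair, p_tukey in rep.tukey_p.items():
            assert p_tukey >= rep.ttest[pair][1] - 1e-9

    def test_two_way_row_effect_only(self):
        rng = np.random.default_rng(3)
        rows, cols, vals = [], [], []
        for r, mu in [("r1", 0.0), ("r2", 3.0)]:
            for c in ["c1", "c2", "c3"]:
                for _ in range(6):
                    rows.append(r)
                    cols.append(c)
                    vals.append(mu + rng.normal(0, 0.5))
        res = two_way_anova(vals, rows, cols)
        assert res["factor_a"][1] < 0.01
        assert res["factor_b"][1] > 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            group_tests({"a": [1.0, 2.0], "b": []})


class TestTaskSubset:
    def test_eleven_failures_leave_26(self):
        p = np.full(37, 0.001)
        failing = [12, 13, 14, 37, 1, 2, 3, 10, 11, 27, 29]
        for i in failing:
            p[i - 1] = 0.2
        subset = select_task_subset(p)
        assert len(subset.retained) == 26
        assert sorted(subset.removed) == sorted(failing)

    def test_all_significant_retains_all(self):
        subset = select_task_subset(np.full(37, 0.001))
        assert len(subset.retained) == 37

    def test_alpha_zero_retains_none(self):
        subset = select_task_subset(np.full(37, 0.001), alpha=0.0)
        assert subset.retained == []

    def test_missing_flagged_separately(self):
        p = np.full(37, 0.001)
        p[4] = np.nan
        subset = select_task_subset(p)
        assert subset.missing == [5]
        assert len(subset.retained) == 36


class TestDurationReduction:
    def test_paper_totals(self):
        # 646 s total vs 501 s retained -> 22.4% reduction
        durations = np.empty(37)
        removed = [12, 13, 14, 37, 1, 2, 3, 10, 11, 27, 29]
        retained = [i for i in range(1, 38) if i not in removed]
        for i in removed:
            durations[i - 1] = 145.0 / len(removed)
        for i in retained:
            durations[i - 1] = 501.0 / len(retained)
        assert duration_reduction(durations, removed) == pytest.approx(
            22.4, abs=0.05)

    def test_uniform_eleven_of_37(self):
        durations = np.full(37, 10.0)
        assert duration_reduction(durations, list(range(1, 12))) == pytest.approx(
            100 * 11 / 37, abs=1e-9)

    def test_remove_nothing(self):
        assert duration_reduction(np.full(37, 5.0), []) == 0.0

    def test_nonpositive_duration_rejected(self):
        d = np.full(37, 1.0)
        d[0] = 0.0
        with pytest.raises(ValidationError):
            duration_reduction(d, [])
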