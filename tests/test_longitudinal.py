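"""Longitudinal statistics: RM ANOVA + GG, mixed model, Dunnett, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mecfstrial.longitudinal import (
    DunnettContrast,
    dunnett_vs_baseline,
    gg_epsilon,
    groupwise_dunnett,
    mixed_model_reml,
    qq_residuals,
    rm_anova_gg,
    shapiro_wilk,
    two_way_interaction,
)


def rm_anova_bruteforce(y):
    """Independent sums-of-squares oracle: explicit loops, textbook formulas."""
    n, k = y.shape
    grand = y.mean()
    ss_time = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (y[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_time - ss_subj
    f = (ss_time / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    # epsilon from the sample covariance, double-centered
    s = np.cov(y, rowvar=False)
    c = np.eye(k) - np.ones((k, k)) / k
    sc = c @ s @ c
    eps = np.trace(sc) ** 2 / ((k - 1) * np.sum(sc * sc))
    return f, max(min(eps, 1.0), 1.0 / (k - 1))


def to_long(y, drop=()):
    rows = []
    for i in range(y.shape[0]):
        for j in range(y.shape[1]):
            if (i, j) in drop:
                continue
            rows.append((f"p{i:02d}", f"T{j}", y[i, j]))
    return pd.DataFrame(rows, columns=["participant", "timepoint", "value"])


class TestShapiroWilk:
    def test_bimodal_sample_is_strongly_non_normal(self):
        x = np.r_[np.zeros(50), np.full(50, 100.0)]
        w, p = shapiro_wilk(x)
        assert p < 1e-3

    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(2024)
        rejections = sum(shapiro_wilk(rng.normal(size=200))[1] <= 0.05
                         for _ in range(500))
        assert rejections / 500 <= 0.10

    def test_preconditions(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk([3.0, 3.0, 3.0, 3.0])


class TestRMAnovaGG:
    def test_constant_matrix_gives_null_result(self):
        res = rm_anova_gg(np.full((6, 4), 7.0))
        assert res.F == 0.0 and res.p == 1.0

    def test_toy_matrix_against_bruteforce(self):
        y = np.array([
            [3.0, 5.0, 6.0],
            [4.0, 4.0, 7.0],
            [2.0, 6.0, 5.0],
            [5.0, 7.0, 9.0],
        ])
        res = rm_anova_gg(y)
        f, eps = rm_anova_bruteforce(y)
        assert res.F == pytest.approx(f, rel=1e-12)
        assert res.epsilon == pytest.approx(eps, rel=1e-12)

    def test_random_matrices_match_bruteforce(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            y = rng.normal(size=(5, 4)) + rng.normal(size=(5, 1))
            res = rm_anova_gg(y)
            f, eps = rm_anova_bruteforce(y)
            assert res.F == pytest.approx(f, rel=1e-10)
            assert res.epsilon == pytest.approx(eps, rel=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        y = rng.normal(size=(8, 4)) + rng.normal(size=(8, 1))
        res = rm_anova_gg(y)
        long = to_long(y)
        tab = pg.rm_anova(data=long, dv="value", within="timepoint",
                          subject="participant", correction=True)
        assert res.F == pytest.approx(float(tab["F"].iloc[0]), rel=1e-9)
        assert res.epsilon == pytest.approx(float(tab["eps"].iloc[0]), rel=1e-6)

    def test_two_timepoint_epsilon_is_one(self):
        rng = np.random.default_rng(0)
        res = rm_anova_gg(rng.normal(size=(6, 2)))
        assert res.epsilon == 1.0

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.normal(size=(7, 4))
            eps = gg_epsilon(np.cov(y, rowvar=False))
            assert 1.0 / 3.0 <= eps <= 1.0

    def test_rejects_missing_cells(self):
        y = np.ones((4, 3))
        y[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_gg(y)


class TestMixedModel:
    def test_balanced_complete_equals_rm_anova(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(10, 4)) + 1.5 * rng.normal(size=(10, 1))
        f_rm = rm_anova_gg(y).F
        res = mixed_model_reml(to_long(y), apply_gg=False)
        assert res.F == pytest.approx(f_rm, rel=1e-6)

    def test_two_timepoints_equal_paired_t(self):
        # clear between-subject variance keeps the REML variance estimate
        # interior, where the mixed-model F algebraically equals paired t^2
        rng = np.random.default_rng(3)
        y = rng.normal(size=(12, 2)) + 3.0 * rng.normal(size=(12, 1))
        res = mixed_model_reml(to_long(y), apply_gg=False)
        t, p = stats.ttest_rel(y[:, 1], y[:, 0])
        assert res.p == pytest.approx(p, rel=1e-4)
        assert res.F == pytest.approx(t**2, rel=1e-4)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(21)
        y = rng.normal(size=(9, 3)) + 2.0 * rng.normal(size=(9, 1))
        long = to_long(y, drop={(0, 2), (3, 1)})
        shuffled = long.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = mixed_model_reml(long)
        b = mixed_model_reml(shuffled)
        assert a.F == pytest.approx(b.F, rel=1e-6)
        assert a.p == pytest.approx(b.p, rel=1e-6)

    def test_tolerates_missing_cells(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(10, 4))
        res = mixed_model_reml(to_long(y, drop={(0, 3), (1, 3), (2, 2)}))
        assert 0.0 <= res.p <= 1.0 and res.converged

    def test_not_anticonservative_under_monotone_dropout(self):
        """Null simulation (n=40, 4 timepoints, ~20% monotone dropout): the
        omnibus time test's rejection rate does not exceed nominal 0.05
        (+2 MC SEs).  The GG deflation makes it mildly conservative."""
        rng = np.random.default_rng(424)
        reps = 400
        hits = 0
        for _ in range(reps):
            rows = []
            for i in range(40):
                last = 4
                for j in range(1, 4):
                    if rng.random() < 0.2 / 3:
                        last = j
                        break
                b = rng.normal()
                for j in range(last):
                    rows.append((f"p{i}", f"T{j}", b + rng.normal()))
            long = pd.DataFrame(rows, columns=["participant", "timepoint", "value"])
            hits += mixed_model_reml(long).p < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert hits / reps <= 0.05 + 2 * se

    def test_rejects_empty_timepoint(self):
        y = np.ones((3, 2))
        long = to_long(y)
        long.loc[long["timepoint"] == "T1", "value"] = np.nan
        with pytest.raises(ValueError):
            mixed_model_reml(long)


class TestDunnett:
    def test_single_contrast_equals_paired_t(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=(15, 2))
        (c,) = dunnett_vs_baseline(y, seed=1)
        t, p = stats.ttest_rel(y[:, 1], y[:, 0])
        assert c.p_adjusted == pytest.approx(p, rel=1e-10)
        assert c.t == pytest.approx(float(t), rel=1e-10)

    def test_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            y = rng.normal(size=(12, 4))
            for c in dunnett_vs_baseline(y, seed=2):
                assert c.p_adjusted >= c.p_unadjusted - 1e-12
                assert 0.0 <= c.p_adjusted <= 1.0

    def test_seed_reproducible(self):
        rng = np.random.default_rng(31)
        y = rng.normal(size=(20, 4))
        a = dunnett_vs_baseline(y, seed=9)
        b = dunnett_vs_baseline(y, seed=9)
        assert [c.p_adjusted for c in a] == [c.p_adjusted for c in b]

    def test_handles_missing_pairs(self):
        rng = np.random.default_rng(41)
        y = rng.normal(size=(10, 3))
        y[0, 1] = np.nan
        cons = dunnett_vs_baseline(y, seed=0)
        assert cons[0].n == 9 and cons[1].n == 10

    def test_rejects_single_column(self):
        with pytest.raises(ValueError):
            dunnett_vs_baseline(np.ones((5, 1)))


class TestTwoWayInteraction:
    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(55)
        n, k = 20, 4
        rows = []
        for g, slope in (("flat", 0.0), ("improving", 2.0)):
            for i in range(n):
                b = rng.normal()
                for j in range(k):
                    rows.append((f"{g}{i}", f"T{j}", g, b + slope * j + rng.normal()))
        long = pd.DataFrame(rows, columns=["participant", "timepoint", "group", "value"])
        res = two_way_interaction(long)
        assert res.p < 1e-3

    def test_null_interaction_not_spuriously_significant(self):
        rng = np.random.default_rng(56)
        rows = []
        for g in ("a", "b"):
            for i in range(12):
                b = rng.normal()
                for j in range(4):
                    rows.append((f"{g}{i}", f"T{j}", g, b + 0.5 * j + rng.normal()))
        long = pd.DataFrame(rows, columns=["participant", "timepoint", "group", "value"])
        # identical time profiles: p should not be tiny
        assert two_way_interaction(long).p > 1e-3

    def test_single_group_rejected(self):
        rng = np.random.default_rng(57)
        rows = [(f"p{i}", f"T{j}", "only", rng.normal())
                for i in range(6) for j in range(3)]
        long = pd.DataFrame(rows, columns=["participant", "timepoint", "group", "value"])
        with pytest.raises(ValueError):
            two_way_interaction(long)

    def test_small_group_dropped_with_warning(self):
        rng = np.random.default_rng(58)
        rows = []
        for g, n in (("big", 8), ("alsobig", 8), ("tiny", 1)):
            for i in range(n):
                for j in range(3):
                    rows.append((f"{g}{i}", f"T{j}", g, rng.normal()))
        long = pd.DataFrame(rows, columns=["participant", "timepoint", "group", "value"])
        with pytest.warns(UserWarning, match="tiny"):
            res = two_way_interaction(long)
        assert 0.0 <= res.p <= 1.0

    def test_groupwise_dunnett_families(self):
        rng = np.random.default_rng(59)
        rows = []
        for g in ("a", "b"):
            for i in range(8):
                for j in range(3):
                    rows.append((f"{g}{i}", f"T{j}", g, rng.normal()))
        long = pd.DataFrame(rows, columns=["participant", "timepoint", "group", "value"])
        fams = groupwise_dunnett(long, ["T0", "T1", "T2"], seed=3)
        assert set(fams) == {"a", "b"}
        assert all(len(v) == 2 for v in fams.values())


class TestQQResiduals:
    def test_normal_quantiles_on_identity_line(self):
        probs = (np.arange(1, 101) - 0.375) / 100.25
        resid = stats.norm.ppf(probs)
        theo, samp = qq_residuals(resid)
        assert np.allclose(theo, samp, atol=1e-9)

    def test_pair_count_and_empty(self):
        theo, samp = qq_residuals(np.random.default_rng(0).normal(size=37))
        assert len(theo) == len(samp) == 37
        with pytest.raises(ValueError):
            qq_residuals([])
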