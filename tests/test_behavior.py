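"""Unit and property tests for the behavioral statistics battery.

Every statistic is checked against an independent brute-force oracle
(explicit sums-of-squares or quantile computation) on toy data.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from enigo import behavior as bh


# ---------------------------------------------------------------------------
# oracles


def anova_2x2_oracle(y: np.ndarray, groups: np.ndarray) -> dict:
    """Brute-force GLM fit of the split-plot model via the two strata.

    Between stratum: OLS of subject averages on the group indicator.
    Within stratum: OLS of subject differences on [1, group indicator]
    with effect coding; F = squared coefficient t statistic.
    """
    y = np.asarray(y, float)
    levels = np.unique(groups)
    g = np.where(groups == levels[0], 1.0, -1.0)
    n = len(g)
    a = y.mean(axis=1)
    d = y[:, 1] - y[:, 0]

    def ols_f(z):
        x = np.column_stack([np.ones(n), g])
        beta, *_ = np.linalg.lstsq(x, z, rcond=None)
        resid = z - x @ beta
        df = n - 2
        sigma2 = resid @ resid / df
        xtx_inv = np.linalg.inv(x.T @ x)
        t_int = beta[0] / np.sqrt(sigma2 * xtx_inv[0, 0])
        t_grp = beta[1] / np.sqrt(sigma2 * xtx_inv[1, 1])
        return t_int**2, t_grp**2, df

    _, f_between, dfb = ols_f(a)
    f_within, f_inter, dfw = ols_f(d)
    return {
        "between": (f_between, dfb),
        "within": (f_within, dfw),
        "interaction": (f_inter, dfw),
    }


def levene_oracle(*samples) -> float:
    """One-way ANOVA F on absolute deviations from group means."""
    devs = [np.abs(np.asarray(s) - np.mean(s)) for s in samples]
    allv = np.concatenate(devs)
    grand = allv.mean()
    k = len(devs)
    n = allv.size
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in devs)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in devs)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def ks_stat_oracle(x: np.ndarray) -> float:
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    n = z.size
    cdf = stats.norm.cdf(z)
    return max(
        float(np.max(np.arange(1, n + 1) / n - cdf)),
        float(np.max(cdf - np.arange(n) / n)),
    )


# ---------------------------------------------------------------------------
# outlier rejection


def make_log(rts, stim="GO", subject="s1"):
    n = len(rts)
    return pd.DataFrame(
        {
            "subject": subject,
            "group": "SI",
            "block": 1,
            "trial": np.arange(1, n + 1),
            "stim": stim,
            "response": [0 if np.isnan(r) else 1 for r in rts],
            "rt_ms": rts,
            "outcome": ["MISS" if np.isnan(r) else "HIT" for r in rts],
        }
    )


def test_outlier_rejection_five_point_set():
    rts = np.array([300.0, 310.0, 320.0, 330.0, 900.0])
    # direct recomputation decides membership: |900 - 432| = 468 is *below*
    # 2 * sample SD (523.7), so nothing is removed
    mean, sd = rts.mean(), rts.std(ddof=1)
    expected_removed = np.abs(rts - mean) > 2 * sd
    assert not expected_removed.any()
    out, frac = bh.reject_rt_outliers(make_log(rts))
    assert len(out) == 5
    assert frac == 0.0


def test_outlier_rejection_matches_oracle_on_random_sets(rng):
    for _ in range(20):
        rts = rng.normal(350, 40, size=40)
        rts[rng.integers(40)] += rng.choice([-1, 1]) * 300
        mean, sd = rts.mean(), rts.std(ddof=1)
        keep = np.abs(rts - mean) <= 2 * sd
        out, _ = bh.reject_rt_outliers(make_log(rts))
        assert np.allclose(np.sort(out["rt_ms"]), np.sort(rts[keep]))


def test_outlier_rejection_all_equal_removes_none():
    out, frac = bh.reject_rt_outliers(make_log([300.0] * 10))
    assert len(out) == 10 and frac == 0.0


def test_outlier_rejection_typical_fraction():
    from enigo import synth

    study = synth.simulate_group_study(6, 6, seed=11)
    fracs = []
    for _, sub in study.groupby("subject"):
        _, f = bh.reject_rt_outliers(sub.reset_index(drop=True))
        fracs.append(f)
    assert 0.02 < np.mean(fracs) < 0.08


def test_outlier_rejection_degenerate_errors():
    with pytest.raises(ValueError):
        bh.reject_rt_outliers(make_log([np.nan, np.nan]))


# ---------------------------------------------------------------------------
# summaries and signal detection


def test_summarize_fa_rate():
    go = make_log(np.full(30, 300.0))
    nogo = pd.DataFrame(
        {
            "subject": "s1",
            "group": "SI",
            "block": 1,
            "trial": np.arange(31, 61),
            "stim": "NOGO",
            "response": [1] * 6 + [0] * 24,
            "rt_ms": [280.0] * 6 + [np.nan] * 24,
            "outcome": ["FA"] * 6 + ["CR"] * 24,
        }
    )
    log = pd.concat([go, nogo], ignore_index=True)
    s = bh.summarize(log, (1,), session="BEG")
    assert s.fa_rate == pytest.approx(0.20)
    assert s.hit_rate == pytest.approx(1.0)
    assert s.rt_mean == pytest.approx(300.0)


def test_summarize_requires_nogo_trials():
    with pytest.raises(ValueError):
        bh.summarize(make_log([300.0] * 5), (1,))


def test_sdt_null():
    d, c = bh.sdt_scores(0.5, 0.5, 120, 120)
    assert d == pytest.approx(0.0, abs=1e-12)
    assert c == pytest.approx(0.0, abs=1e-12)


def test_sdt_worked_example_independent_quantiles():
    from statistics import NormalDist

    zh = NormalDist().inv_cdf(0.95)
    zf = NormalDist().inv_cdf(0.20)
    d, c = bh.sdt_scores(0.95, 0.20, 120, 120)
    assert d == pytest.approx(zh - zf, abs=1e-9)
    assert d == pytest.approx(2.4865, abs=1e-4)
    assert c == pytest.approx((zh + zf) / 2, abs=1e-9)
    assert c == pytest.approx(0.4016, abs=1e-4)


def test_sdt_boundary_correction():
    from statistics import NormalDist

    d, _ = bh.sdt_scores(0.9, 0.0, 120, 120)
    zf = NormalDist().inv_cdf(1.0 / 240.0)
    assert d == pytest.approx(NormalDist().inv_cdf(0.9) - zf, abs=1e-9)
    d1, _ = bh.sdt_scores(1.0, 0.1, 50, 120)
    assert d1 == pytest.approx(
        NormalDist().inv_cdf(1 - 1 / 100.0) - NormalDist().inv_cdf(0.1), abs=1e-9
    )


def test_sdt_c_sign_switch():
    _, c_paper = bh.sdt_scores(0.95, 0.2, 120, 120, c_sign="paper")
    _, c_std = bh.sdt_scores(0.95, 0.2, 120, 120, c_sign="standard")
    assert c_std == pytest.approx(-c_paper)


@given(
    h=st.floats(0.01, 0.99),
    f=st.floats(0.01, 0.99),
)
@settings(max_examples=50, deadline=None)
def test_sdt_antisymmetry(h, f):
    d1, _ = bh.sdt_scores(h, f, 100, 100)
    d2, _ = bh.sdt_scores(f, h, 100, 100)
    assert d1 == pytest.approx(-d2, abs=1e-10)


# ---------------------------------------------------------------------------
# t tests


def test_pooled_t_summary_worked_examples():
    t = bh.pooled_t(23.1, 11.3, 15, 15.8, 6.8, 17)
    # brute-force oracle
    sp2 = (14 * 11.3**2 + 16 * 6.8**2) / 30
    t_oracle = (23.1 - 15.8) / np.sqrt(sp2 * (1 / 15 + 1 / 17))
    assert t.t == pytest.approx(t_oracle, abs=1e-10)
    assert t.df == 30
    assert t.cohens_d == pytest.approx((23.1 - 15.8) / np.sqrt(sp2), abs=1e-10)

    t2 = bh.pooled_t(1.0, 1.0, 10, 0.0, 1.0, 10)
    assert t2.t == pytest.approx(1.0 / np.sqrt(2.0 / 10.0), abs=1e-10)
    assert t2.df == 18


def test_pooled_t_identical_summaries():
    t = bh.pooled_t(5.0, 1.0, 10, 5.0, 1.0, 12)
    assert t.t == 0.0 and t.p == pytest.approx(1.0)


def test_pooled_t_zero_variance():
    assert bh.pooled_t(3.0, 0.0, 5, 3.0, 0.0, 5).t == 0.0
    assert np.isinf(bh.pooled_t(3.0, 0.0, 5, 2.0, 0.0, 5).t)


def test_pooled_t_raw_samples_match_scipy(rng):
    x = rng.normal(0, 1, 14)
    y = rng.normal(0.4, 1.3, 19)
    t = bh.pooled_t(x, y)
    ts, ps = stats.ttest_ind(x, y)
    assert t.t == pytest.approx(ts, abs=1e-10)
    assert t.p == pytest.approx(ps, abs=1e-10)


def test_welch_worked_example():
    w = bh.welch_t(23.1, 11.3, 15, 15.8, 6.8, 17)
    v1, v2 = 11.3**2 / 15, 6.8**2 / 17
    t_oracle = (23.1 - 15.8) / np.sqrt(v1 + v2)
    df_oracle = (v1 + v2) ** 2 / (v1**2 / 14 + v2**2 / 16)
    assert w.t == pytest.approx(t_oracle, abs=1e-10)
    assert w.df == pytest.approx(df_oracle, abs=1e-10)


def test_welch_equals_pooled_when_balanced():
    p = bh.pooled_t(1.2, 2.0, 10, 0.5, 2.0, 10)
    w = bh.welch_t(1.2, 2.0, 10, 0.5, 2.0, 10)
    assert w.t == pytest.approx(p.t, abs=1e-12)
    assert w.df == pytest.approx(p.df, abs=1e-12)


@given(
    sd1=st.floats(0.1, 10),
    sd2=st.floats(0.1, 10),
    n1=st.integers(2, 50),
    n2=st.integers(2, 50),
)
@settings(max_examples=100, deadline=None)
def test_satterthwaite_df_bound(sd1, sd2, n1, n2):
    w = bh.welch_t(0.0, sd1, n1, 1.0, sd2, n2)
    assert w.df <= n1 + n2 - 2 + 1e-9


# ---------------------------------------------------------------------------
# mixed ANOVA


def test_anova_all_equal_gives_zero_f():
    y = np.full((8, 2), 3.0)
    g = np.array(["A"] * 4 + ["B"] * 4)
    res = bh.mixed_anova_2x2(y, g)
    assert res.between.F == 0.0
    assert res.within.F == 0.0
    assert res.interaction.F == 0.0


def test_anova_matches_glm_oracle(rng):
    for n1, n2 in ((2, 2), (5, 7), (15, 17)):
        y = rng.normal(size=(n1 + n2, 2))
        g = np.array(["A"] * n1 + ["B"] * n2)
        res = bh.mixed_anova_2x2(y, g)
        ora = anova_2x2_oracle(y, g)
        for eff in ("between", "within", "interaction"):
            f, df = ora[eff]
            got = getattr(res, eff)
            assert got.F == pytest.approx(f, abs=1e-10, rel=1e-10)
            assert got.df_den == df
            assert got.p == pytest.approx(stats.f.sf(f, 1, df), abs=1e-12)
            assert got.partial_eta_sq == pytest.approx(f / (f + df), abs=1e-12)


def test_anova_constant_difference_kills_interaction(rng):
    base = rng.normal(size=10)
    y = np.column_stack([base, base + 2.0])
    g = np.array(["A"] * 5 + ["B"] * 5)
    res = bh.mixed_anova_2x2(y, g)
    assert res.interaction.F == pytest.approx(0.0, abs=1e-20)
    assert res.within.F > 0


def test_anova_interaction_equals_squared_t(rng):
    y = rng.normal(size=(12, 2))
    g = np.array(["A"] * 5 + ["B"] * 7)
    res = bh.mixed_anova_2x2(y, g)
    d = y[:, 1] - y[:, 0]
    t = bh.pooled_t(d[:5], d[5:])
    assert res.interaction.F == pytest.approx(t.t**2, abs=1e-10, rel=1e-10)


def test_anova_missing_cell_errors():
    y = np.array([[1.0, np.nan], [0.0, 1.0], [1.0, 2.0], [0.0, 0.0]])
    with pytest.raises(ValueError):
        bh.mixed_anova_2x2(y, np.array(["A", "A", "B", "B"]))


def test_vectorized_anova_matches_scalar(rng):
    y = rng.normal(size=(10, 2, 4, 5))
    g = np.array(["A"] * 5 + ["B"] * 5)
    vec = bh.mixed_anova_2x2_vectorized(y, g)
    for i in range(4):
        for j in range(5):
            res = bh.mixed_anova_2x2(y[:, :, i, j], g)
            assert vec["interaction"]["F"][i, j] == pytest.approx(
                res.interaction.F, abs=1e-12, rel=1e-12
            )


# ---------------------------------------------------------------------------
# Levene, Holm, SAT, KS


def test_levene_identical_groups():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    f, p = bh.levene_test(x, x.copy())
    assert f == pytest.approx(0.0, abs=1e-12)


def test_levene_matches_oracle(rng):
    a = rng.normal(0, 1, 15)
    b = rng.normal(0, 3, 17)
    f, p = bh.levene_test(a, b)
    assert f == pytest.approx(levene_oracle(a, b), abs=1e-10, rel=1e-10)


def test_levene_p_decreases_with_scale(rng):
    a = rng.normal(0, 1, 20)
    b = rng.normal(0, 1, 20)
    ps = [bh.levene_test(a, b * s)[1] for s in (1.0, 2.0, 5.0, 10.0)]
    assert all(p2 < p1 for p1, p2 in zip(ps, ps[1:]))


def test_levene_degenerate_errors():
    with pytest.raises(ValueError):
        bh.levene_test(np.array([1.0]), np.array([1.0, 2.0]))


def test_holm_step_down_by_hand():
    # by hand: 0.001 <= .05/4 = .0125; 0.02 > .05/3 = .0167 -> stop
    keep = bh.holm_bonferroni([0.001, 0.02, 0.03, 0.8], alpha=0.05)
    assert list(keep) == [True, False, False, False]
    keep2 = bh.holm_bonferroni([0.001, 0.012, 0.02, 0.8], alpha=0.05)
    assert list(keep2) == [True, True, True, False]


def make_summaries(rng, n=8, r=0.0):
    rows = []
    for group in ("SI", "II"):
        for session in ("BEG", "END"):
            cov = np.array([[1.0, r], [r, 1.0]])
            xy = rng.multivariate_normal([350, 0.2], cov * [[900, 3], [3, 0.01]], n)
            for i in range(n):
                rows.append(
                    {
                        "subject": f"{group}{i}",
                        "group": group,
                        "session": session,
                        "rt_mean": xy[i, 0],
                        "fa_rate": xy[i, 1],
                    }
                )
    return pd.DataFrame(rows)


def test_sat_perfect_anticorrelation():
    rows = []
    for i, rt in enumerate([300.0, 320, 340, 360]):
        for group in ("SI", "II"):
            for session in ("BEG", "END"):
                rows.append(
                    {
                        "subject": f"{group}{i}",
                        "group": group,
                        "session": session,
                        "rt_mean": rt,
                        "fa_rate": 0.5 - 0.001 * rt,
                    }
                )
    res = bh.sat_correlations(pd.DataFrame(rows))
    assert np.allclose(res["r"], -1.0)


def test_sat_family_wise_error(rng):
    n_reject = 0
    n_reps = 2000
    for _ in range(n_reps):
        res = bh.sat_correlations(make_summaries(rng, n=8, r=0.0))
        n_reject += bool(res["holm_significant"].any())
    fwe = n_reject / n_reps
    assert fwe <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_reps)


def test_sat_too_few_subjects_errors(rng):
    s = make_summaries(rng, n=2)
    with pytest.raises(ValueError):
        bh.sat_correlations(s)


def test_ks_statistic_matches_oracle(rng):
    x = rng.normal(2.0, 3.0, 57)
    d, _ = bh.ks_normality(x)
    assert d == pytest.approx(ks_stat_oracle(x), abs=1e-12)
    assert 0.0 <= d <= 1.0


def test_ks_calibration_normal_samples(rng):
    accept = 0
    for _ in range(1000):
        _, p = bh.ks_normality(rng.standard_normal(100))
        accept += p > 0.05
    assert accept >= 940


def test_ks_rejects_uniform(rng):
    reject = 0
    for _ in range(200):
        _, p = bh.ks_normality(rng.random(100))
        reject += p < 0.05
    assert reject / 200 > 0.5


def test_ks_monte_carlo_null_agrees(rng):
    x = rng.standard_normal(60)
    d1, p_tab = bh.ks_normality(x)
    d2, p_mc = bh.ks_normality(x, n_mc=2000, seed=9)
    assert d1 == d2
    assert p_mc == pytest.approx(p_tab, abs=0.08)


def test_ks_constant_sample_errors():
    with pytest.raises(ValueError):
        bh.ks_normality(np.ones(10))
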