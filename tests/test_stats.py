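"""Group-level inference: t-test conventions, the 2x2 between-subjects
ANOVA/ANCOVA, correlations, Holm adjustment and chi-square, each checked
against closed-form or simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import lexigaze as lg


# --- one-sample t and Cohen's d -------------------------------------------

@pytest.mark.parametrize("t,n,d2", [(2.389, 23, 0.50), (3.607, 21, 0.79)])
def test_cohens_d_convention_t_over_sqrt_n(t, n, d2):
    """d = t / sqrt(n) reproduces printed (t, d) pairs to two decimals."""
    assert round(t / np.sqrt(n), 2) == d2


def test_one_sample_closed_form():
    vals = [0.6, 0.55, 0.65, 0.6]
    r = lg.one_sample_test(vals, mu0=0.5)
    # by-hand oracle: mean 0.6, sd 0.0408
    sd = np.std(vals, ddof=1)
    assert sd == pytest.approx(0.040825, abs=1e-6)
    assert r.t == pytest.approx((0.6 - 0.5) / (sd / 2), rel=1e-10)
    assert r.t == pytest.approx(4.899, abs=1e-3)
    assert r.df == 3
    assert r.cohens_d == pytest.approx(r.t / 2, rel=1e-12)
    assert r.cohens_d == pytest.approx((0.6 - 0.5) / sd, rel=1e-10)


def test_one_sample_zero_variance_error():
    with pytest.raises(ValueError):
        lg.one_sample_test([0.5, 0.5, 0.5])


def test_one_sample_matches_independent_formula():
    rng = np.random.default_rng(0)
    v = rng.normal(0.55, 0.1, 23)
    r = lg.one_sample_test(v, 0.5)
    t_ref = (v.mean() - 0.5) / (v.std(ddof=1) / np.sqrt(23))
    p_ref = 2 * sps.t.sf(abs(t_ref), 22)
    assert r.t == pytest.approx(t_ref, rel=1e-10)
    assert r.p == pytest.approx(p_ref, rel=1e-10)


# --- paired t -------------------------------------------------------------

def test_paired_closed_form():
    r = lg.paired_test([2, 3, 4], [1, 1, 2])
    assert r.t == pytest.approx(5.0, rel=1e-10)
    assert r.df == 2
    d_ref = np.mean([1, 2, 2]) / np.std([1, 2, 2], ddof=1)
    assert r.cohens_d == pytest.approx(d_ref, rel=1e-12)


def test_paired_symmetry_and_errors():
    a, b = [2.0, 3.0, 4.0], [1.0, 1.0, 2.0]
    r1 = lg.paired_test(a, b)
    r2 = lg.paired_test(b, a)
    assert r1.t == pytest.approx(-r2.t)
    with pytest.raises(ValueError):
        lg.paired_test([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        lg.paired_test([1.0, 2.0], [1.0, 2.0])  # identical -> zero variance


def test_paired_alternative_d_convention():
    a = np.array([2.0, 3.0, 4.0, 6.0])
    b = np.array([1.0, 1.0, 2.0, 3.0])
    r = lg.paired_test(a, b, d_convention="av_sd")
    d_ref = (a - b).mean() / ((a.std(ddof=1) + b.std(ddof=1)) / 2)
    assert r.cohens_d == pytest.approx(d_ref)


# --- ANOVA ----------------------------------------------------------------

def _anova_frame(sizes=(23, 21, 20, 23), seed=0, cue_effect=0.0, noise=0.05):
    rng = np.random.default_rng(seed)
    rows = []
    cells = [("vowel", "action"), ("vowel", "object"),
             ("consonant", "action"), ("consonant", "object")]
    for (cue, wt), n in zip(cells, sizes):
        mu = 0.55 + (cue_effect if cue == "vowel" else 0.0)
        for _ in range(n):
            rows.append({"phonemic_cue": cue, "word_type": wt,
                         "mean_tlt_p": rng.normal(mu, noise),
                         "age_months": rng.normal(8, 0.4)})
    return pd.DataFrame(rows)


def test_anova_error_df_unbalanced_2x2():
    """Group sizes 23/21/20/23 give error df = 87 - 4 = 83."""
    df = _anova_frame()
    tab = lg.two_way_anova(df, "mean_tlt_p")
    assert set(tab["df2"]) == {83}
    assert (tab["df1"] == 1).all()
    assert ((tab["eta_p2"] >= 0) & (tab["eta_p2"] <= 1)).all()


def test_anova_detects_additive_cue_effect_only():
    df = _anova_frame(seed=1, cue_effect=0.08)
    tab = lg.two_way_anova(df, "mean_tlt_p")
    assert tab.loc["phonemic_cue", "p"] < 1e-6
    assert tab.loc["phonemic_cue x word_type", "p"] > 0.01
    assert tab.loc["phonemic_cue", "eta_p2"] > tab.loc["word_type", "eta_p2"]


def test_anova_constant_dv_gives_zero_F():
    df = _anova_frame()
    df["mean_tlt_p"] = 0.5
    tab = lg.two_way_anova(df, "mean_tlt_p")
    assert (tab["F"] == 0.0).all()


def test_anova_empty_cell_rejected():
    df = _anova_frame()
    df = df[~((df.phonemic_cue == "vowel") & (df.word_type == "object"))]
    with pytest.raises(ValueError):
        lg.two_way_anova(df, "mean_tlt_p")


def test_anova_matches_manual_ols_partial_eta():
    """eta_p2 = SS_effect / (SS_effect + SS_error) against statsmodels SS."""
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    df = _anova_frame(seed=3, cue_effect=0.05)
    tab = lg.two_way_anova(df, "mean_tlt_p")
    ref = anova_lm(
        ols("mean_tlt_p ~ C(phonemic_cue) * C(word_type)", df).fit(), typ=2
    )
    ss_err = ref.loc["Residual", "sum_sq"]
    for eff_pkg, eff_ref in [("phonemic_cue", "C(phonemic_cue)"),
                             ("word_type", "C(word_type)")]:
        ss = ref.loc[eff_ref, "sum_sq"]
        assert tab.loc[eff_pkg, "eta_p2"] == pytest.approx(ss / (ss + ss_err), rel=1e-10)


# --- ANCOVA ---------------------------------------------------------------

def test_ancova_uncorrelated_covariate_preserves_effects():
    df = _anova_frame(seed=5, cue_effect=0.08)
    a = lg.two_way_anova(df, "mean_tlt_p")
    c = lg.ancova(df, "mean_tlt_p")
    assert c.loc["phonemic_cue", "F"] == pytest.approx(
        a.loc["phonemic_cue", "F"], rel=0.25
    )
    assert c.loc["phonemic_cue", "p"] < 1e-4


def test_ancova_dv_equal_to_covariate_removes_effects():
    df = _anova_frame(seed=6, cue_effect=0.08)
    df["mean_tlt_p"] = df["age_months"]
    c = lg.ancova(df, "mean_tlt_p")
    assert c.loc["phonemic_cue", "F"] == pytest.approx(0.0, abs=1e-12)


def test_ancova_constant_covariate_falls_back():
    df = _anova_frame(seed=7)
    df["age_months"] = 8.0
    with pytest.warns(UserWarning):
        c = lg.ancova(df, "mean_tlt_p")
    a = lg.two_way_anova(df, "mean_tlt_p")
    assert c.loc["phonemic_cue", "F"] == pytest.approx(a.loc["phonemic_cue", "F"])


# --- correlations ---------------------------------------------------------

def test_correlation_perfectly_linear():
    df = pd.DataFrame({"age_months": np.arange(10.0),
                       "mean_tlt_p": 0.4 + 0.02 * np.arange(10.0)})
    tab = lg.correlations(df, "age_months", metrics=("mean_tlt_p",))
    assert tab.loc["mean_tlt_p", "r"] == pytest.approx(1.0)


def test_correlation_null_calibration_by_permutation():
    rng = np.random.default_rng(0)
    rejections = 0
    rs = []
    for _ in range(200):
        df = pd.DataFrame({"age_months": rng.normal(8, 0.4, 40),
                           "mean_tlt_p": rng.normal(0.55, 0.1, 40)})
        tab = lg.correlations(df, "age_months", metrics=("mean_tlt_p",))
        rs.append(tab.loc["mean_tlt_p", "r"])
        rejections += tab.loc["mean_tlt_p", "p"] < 0.05
    assert abs(np.mean(rs)) < 0.05
    assert 0.005 < rejections / 200 < 0.12  # wide band around alpha = 0.05


def test_correlation_recovers_planted_rho():
    rng = np.random.default_rng(1)
    n, rho = 43, 0.336
    x = rng.normal(0, 1, n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
    df = pd.DataFrame({"age_months": x, "mean_tlt_p": y})
    tab = lg.correlations(df, "age_months", metrics=("mean_tlt_p",))
    r = tab.loc["mean_tlt_p", "r"]
    # Fisher-z 95% interval must cover the planted correlation
    z = np.arctanh(r)
    half = 1.96 / np.sqrt(n - 3)
    assert np.tanh(z - half) < rho < np.tanh(z + half)


def test_correlation_zero_variance_gives_null():
    df = pd.DataFrame({"age_months": [8.0] * 5, "mean_tlt_p": np.arange(5.0)})
    with pytest.warns(UserWarning):
        tab = lg.correlations(df, "age_months", metrics=("mean_tlt_p",))
    assert np.isnan(tab.loc["mean_tlt_p", "r"])


# --- multiple comparisons, normality, chi-square --------------------------

def test_holm_adjustment_by_hand():
    np.testing.assert_allclose(
        lg.multiple_comparison_adjust([0.01, 0.04]), [0.02, 0.04]
    )
    np.testing.assert_allclose(lg.multiple_comparison_adjust([0.03]), [0.03])
    np.testing.assert_allclose(
        lg.multiple_comparison_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0]
    )


def test_holm_monotone_and_not_below_raw():
    rng = np.random.default_rng(0)
    p = rng.uniform(0, 1, 10)
    adj = lg.multiple_comparison_adjust(p)
    assert (adj >= p).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_normality_check_behaviour():
    rng = np.random.default_rng(0)
    _, p_norm = lg.normality_check(rng.normal(0, 1, 50))
    assert p_norm > 0.001
    _, p_mass = lg.normality_check(rng.choice([0.0, 1.0], 50))
    assert p_mass < 0.01
    with pytest.raises(ValueError):
        lg.normality_check([1.0, 1.0, 1.0])


def test_chi_square_cases():
    chi2, df, p = lg.chi_square_test([12, 12])
    assert chi2 == 0.0 and df == 1 and p == pytest.approx(1.0)
    chi2, df, p = lg.chi_square_test([20, 4])
    assert chi2 == pytest.approx(64 / 12 + 64 / 12, rel=1e-12)
    assert df == 1
    with pytest.raises(ValueError):
        lg.chi_square_test([5, 0], expected=[5, 0])


# --- item preference ------------------------------------------------------

def test_item_preference_neutral_and_biased(design, schedule, aois):
    rng = np.random.default_rng(4)
    infants = [f"i{k}" for k in range(20)]
    neutral = pd.DataFrame(
        [{"infant_id": i, "word": w, "tlt_ms": rng.normal(1400, 200)}
         for i in infants for w in ("cued1", "cued2")]
    )
    tab = lg.item_preference_check(neutral, "word", "tlt_ms")
    assert tab is not None and tab["p_adj"].iloc[0] > 0.05
    biased = neutral.copy()
    biased.loc[biased.word == "cued1", "tlt_ms"] += 500
    tab2 = lg.item_preference_check(biased, "word", "tlt_ms")
    assert tab2["p_adj"].iloc[0] < 0.001


def test_item_preference_single_level_skipped():
    df = pd.DataFrame({"infant_id": ["a", "b"], "word": ["w", "w"],
                       "tlt_ms": [1.0, 2.0]})
    with pytest.warns(UserWarning):
        assert lg.item_preference_check(df, "word", "tlt_ms") is None
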