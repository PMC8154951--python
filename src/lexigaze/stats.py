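"""Group-level inference for the looking-time metrics.

Per experiment: one-sample t-tests of TLT-p / TLT-acc / LF-p / LF-acc / FG
against chance (0.5) with Cohen's d = t / sqrt(n), and the paired t-test of
TLT on correct vs incorrect images.  Across experiments: a 2x2
between-subjects ANOVA (phonemic cue x word type) with partial eta squared,
the ANCOVA adding age, and Pearson correlations of the metrics with age,
familiarization engagement and valid-trial counts.  Multiple comparisons
are Holm-adjusted by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TTestResult",
    "one_sample_test",
    "paired_test",
    "two_way_anova",
    "ancova",
    "correlations",
    "multiple_comparison_adjust",
    "normality_check",
    "chi_square_test",
    "item_preference_check",
]

CHANCE_METRICS = ("mean_tlt_p", "mean_tlt_acc", "mean_lf_p", "mean_lf_acc", "mean_fg")


def _anova_row(eff: str, tab: pd.DataFrame, ss_err: float, df_err: int,
               factors: tuple[str, str]) -> dict:
    ss = float(tab.loc[eff, "sum_sq"])
    F = float(tab.loc[eff, "F"])
    p = float(tab.loc[eff, "PR(>F)"])
    # numerically-null sums of squares (constant dv, exactly collinear
    # covariate) leave floating-point residue; treat them as zero effects
    ss_tot = float(tab["sum_sq"].sum())
    if ss <= 1e-12 * max(ss_tot, 1.0):
        ss, F, p = 0.0, 0.0, 1.0
    if not np.isfinite(F):
        F = 0.0 if ss == 0 else float("inf")
        p = 1.0 if ss == 0 else 0.0
    eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
    return {
        "effect": _clean_effect_name(eff, factors),
        "F": F,
        "df1": int(tab.loc[eff, "df"]),
        "df2": df_err,
        "p": p,
        "eta_p2": float(eta),
    }


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    n: int
    mean: float = float("nan")


def one_sample_test(values, mu0: float = 0.5) -> TTestResult:
    """Two-sided one-sample t-test; Cohen's d = t / sqrt(n) = (m - mu0)/sd."""
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 finite values")
    if np.ptp(v) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(v, popmean=mu0)
    n = v.size
    return TTestResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        cohens_d=float(res.statistic) / np.sqrt(n),
        n=n,
        mean=float(v.mean()),
    )


def paired_test(
    correct, incorrect, d_convention: str = "diff_sd"
) -> TTestResult:
    """Paired t-test on correct - incorrect differences.

    ``d_convention``: "diff_sd" (mean difference / SD of differences, the
    default) or "av_sd" (mean difference / average of the two SDs).
    """
    a = np.asarray(correct, dtype=float)
    b = np.asarray(incorrect, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.ptp(diff) == 0:
        raise ValueError("zero variance of differences: t statistic undefined")
    res = sps.ttest_rel(a, b)
    if d_convention == "diff_sd":
        d = diff.mean() / diff.std(ddof=1)
    elif d_convention == "av_sd":
        d = diff.mean() / ((a.std(ddof=1) + b.std(ddof=1)) / 2.0)
    else:
        raise ValueError(f"unknown d convention {d_convention!r}")
    return TTestResult(
        t=float(res.statistic),
        df=a.size - 1,
        p=float(res.pvalue),
        cohens_d=float(d),
        n=a.size,
        mean=float(diff.mean()),
    )


def _check_cells(data: pd.DataFrame, factors: tuple[str, str]) -> None:
    counts = data.groupby(list(factors), observed=True).size()
    levels_a = data[factors[0]].nunique()
    levels_b = data[factors[1]].nunique()
    if len(counts) < levels_a * levels_b or (counts == 0).any():
        raise ValueError("empty design cell in the between-subjects ANOVA")


def two_way_anova(
    data: pd.DataFrame,
    dv: str,
    factors: tuple[str, str] = ("phonemic_cue", "word_type"),
    ss_type: int = 2,
) -> pd.DataFrame:
    """2x2 between-subjects ANOVA with partial eta squared per effect.

    Uses Type-II sums of squares by default (Type III via ``ss_type=3``),
    appropriate for the unbalanced cell sizes of cross-experiment data.
    Returns a frame indexed by effect with F, df, p and eta_p2; the error
    df equals total n minus the number of cells.
    """
    d = data.dropna(subset=[dv, *factors])
    _check_cells(d, factors)
    a, b = factors
    model = smf.ols(f"{dv} ~ C({a}) * C({b})", data=d).fit()
    if ss_type == 3:
        model = smf.ols(
            f"{dv} ~ C({a}, Sum) * C({b}, Sum)", data=d
        ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(model, typ=ss_type)
    ss_err = float(tab.loc["Residual", "sum_sq"])
    df_err = int(tab.loc["Residual", "df"])
    rows = [
        _anova_row(eff, tab, ss_err, df_err, factors)
        for eff in tab.index
        if eff != "Residual"
    ]
    return pd.DataFrame(rows).set_index("effect")


def _clean_effect_name(name: str, factors: tuple[str, str]) -> str:
    out = name
    for f in factors:
        out = out.replace(f"C({f}, Sum)", f).replace(f"C({f})", f)
    return out.replace(":", " x ")


def ancova(
    data: pd.DataFrame,
    dv: str,
    factors: tuple[str, str] = ("phonemic_cue", "word_type"),
    covariate: str = "age_months",
    ss_type: int = 2,
) -> pd.DataFrame:
    """Between-subjects ANOVA with a continuous covariate (ANCOVA).

    A constant covariate cannot adjust anything; the model falls back to
    the plain ANOVA with a warning in that case.
    """
    d = data.dropna(subset=[dv, covariate, *factors])
    if d[covariate].nunique() <= 1:
        warnings.warn("constant covariate; falling back to ANOVA")
        return two_way_anova(d, dv, factors, ss_type)
    _check_cells(d, factors)
    a, b = factors
    model = smf.ols(f"{dv} ~ {covariate} + C({a}) * C({b})", data=d).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(model, typ=ss_type)
    ss_err = float(tab.loc["Residual", "sum_sq"])
    df_err = int(tab.loc["Residual", "df"])
    rows = [
        _anova_row(eff, tab, ss_err, df_err, factors)
        for eff in tab.index
        if eff != "Residual"
    ]
    return pd.DataFrame(rows).set_index("effect")


def correlations(
    data: pd.DataFrame,
    x: str,
    metrics: tuple[str, ...] = CHANCE_METRICS,
) -> pd.DataFrame:
    """Pearson correlations of each metric with ``x`` (two-sided p).

    Zero-variance variables yield a null row with a warning rather than an
    error, since degenerate metrics can arise in small simulated cohorts.
    """
    rows = []
    for m in metrics:
        d = data.dropna(subset=[x, m])
        if len(d) < 3:
            rows.append({"metric": m, "r": np.nan, "p": np.nan, "n": len(d)})
            continue
        if d[x].std() == 0 or d[m].std() == 0:
            warnings.warn(f"zero variance in correlation {m} ~ {x}")
            rows.append({"metric": m, "r": np.nan, "p": np.nan, "n": len(d)})
            continue
        r, p = sps.pearsonr(d[x], d[m])
        rows.append({"metric": m, "r": float(r), "p": float(p), "n": len(d)})
    return pd.DataFrame(rows).set_index("metric")


def multiple_comparison_adjust(
    p_values, method: str = "holm"
) -> np.ndarray:
    """Adjusted p-values; Holm step-down by default ('bonferroni', 'none')."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    _, adj, _, _ = multipletests(p, method=method)
    return adj


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p (diagnostic only; never gates tests)."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(v) == 0:
        raise ValueError("constant sample: normality test degenerate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = sps.shapiro(v)
    return float(w), float(p)


def chi_square_test(observed, expected=None) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    ``observed`` is either a 1-D count vector (tested against ``expected``,
    uniform by default) or a 2-D contingency table.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim == 1:
        exp = (
            np.full_like(obs, obs.sum() / obs.size)
            if expected is None
            else np.asarray(expected, dtype=float)
        )
        if np.any(exp <= 0):
            raise ValueError("zero expected count")
        chi2, p = sps.chisquare(obs, exp)
        return float(chi2), obs.size - 1, float(p)
    chi2, p, dof, exp = sps.chi2_contingency(obs, correction=False)
    if np.any(exp <= 0):
        raise ValueError("zero expected count")
    return float(chi2), int(dof), float(p)


def item_preference_check(
    per_item: pd.DataFrame,
    item_col: str,
    value_col: str,
    infant_col: str = "infant_id",
    method: str = "holm",
) -> pd.DataFrame | None:
    """Paired comparison of a looking metric between the two items of a
    grouping (word, face, gesture or pair), across infants.

    ``per_item`` holds one row per infant x item with the infant's mean
    metric for that item.  Groupings with a single level are skipped with a
    warning.  Returns a one-row frame with t, df, raw and adjusted p.
    """
    levels = sorted(per_item[item_col].dropna().unique())
    if len(levels) < 2:
        warnings.warn(f"grouping {item_col!r} has a single level; skipped")
        return None
    wide = per_item.pivot_table(
        index=infant_col, columns=item_col, values=value_col
    ).dropna()
    if len(wide) < 2:
        warnings.warn(f"grouping {item_col!r}: fewer than 2 complete infants")
        return None
    res = paired_test(wide[levels[0]], wide[levels[1]])
    adj = multiple_comparison_adjust([res.p], method=method)[0]
    return pd.DataFrame(
        [
            {
                "grouping": item_col,
                "level_a": levels[0],
                "level_b": levels[1],
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "p_adj": float(adj),
                "n": res.n,
            }
        ]
    )
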