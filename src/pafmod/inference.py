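"""Parametric inference layer: mixed ANOVA, Tukey HSD, hierarchical regression.

The design throughout is 2 (Sex, between) x 4 (Task type, within): every
subject contributes one observation per task type, so the degrees of freedom
are (1, n-2) for Sex and (3, 3(n-2)) for Task type and the interaction before
any sphericity correction. Mauchly's test is run on the within factor and
Greenhouse-Geisser-corrected df/p are reported whenever it rejects at 0.05.

Effect size is generalized eta squared (SS_effect over SS_effect plus the sum
of all error strata), which is comparable across between- and within-subject
effects in mixed designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)


@dataclass
class AnovaTable:
    """Mixed-design ANOVA summary with sphericity diagnostics."""

    table: pd.DataFrame              # Source, SS, df1, df2, F, p_unc, ges, df1_corr, df2_corr, p_corr
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    corrected: bool                  # True when Mauchly rejected and GG was applied
    degenerate: bool = False


def mixed_anova(cohort: pd.DataFrame, outcome: str, subject: str = "subject",
                between: str = "sex", within: str = "task_type") -> AnovaTable:
    """2 (between) x k (within) mixed ANOVA on a long-format cohort table.

    Subjects missing any within-cell are dropped (listwise) with a warning.
    A constant outcome yields a degenerate table (NaN F) rather than an error.
    """
    df = cohort[[subject, between, within, outcome]].dropna().copy()
    cells = df.groupby(subject)[within].nunique()
    k = df[within].nunique()
    complete = cells[cells == k].index
    dropped = cells.index.difference(complete)
    if len(dropped):
        logger.warning("mixed_anova: dropped %d subject(s) with missing cells", len(dropped))
        df = df[df[subject].isin(complete)]
    if df.groupby(between)[subject].nunique().min() < 2:
        raise ValueError("each between-group needs at least 2 complete subjects")

    def _degenerate(reason: str) -> AnovaTable:
        logger.warning("mixed_anova: degenerate design (%s); F undefined", reason)
        tab = pd.DataFrame({"Source": [between, within, "Interaction"],
                            "SS": 0.0, "df1": [1, k - 1, k - 1],
                            "df2": np.nan, "F": np.nan, "p_unc": np.nan,
                            "ges": np.nan, "df1_corr": np.nan,
                            "df2_corr": np.nan, "p_corr": np.nan})
        return AnovaTable(table=tab, mauchly_w=np.nan, mauchly_p=np.nan,
                          gg_epsilon=np.nan, corrected=False, degenerate=True)

    if np.isclose(df[outcome].var(ddof=0), 0.0):
        return _degenerate("constant outcome")

    with np.errstate(all="ignore"):
        try:
            aov = pg.mixed_anova(data=df, dv=outcome, within=within,
                                 subject=subject, between=between)
        except Exception as exc:  # zero error variance on coarse-grid outcomes
            return _degenerate(str(exc))
        try:
            sph = pg.sphericity(df, dv=outcome, within=within, subject=subject)
            eps = float(pg.epsilon(df, dv=outcome, within=within, subject=subject,
                                   correction="gg"))
            mauchly_w, mauchly_p = float(sph.W), float(sph.pval)
        except Exception:
            mauchly_w = mauchly_p = eps = float("nan")
    if not np.isfinite(aov["F"]).all():
        return _degenerate("non-finite F (zero error variance)")
    corrected = bool(mauchly_p < 0.05)

    rows = []
    # error SS per stratum recovered from SS, F and df (MS_err = MS_eff / F)
    err_ss = {}
    for _, r in aov.iterrows():
        ms_eff = r["SS"] / r["DF1"]
        err_ss[r["Source"]] = (ms_eff / r["F"]) * r["DF2"] if r["F"] > 0 else np.nan
    ss_err_between = err_ss.get(between, np.nan)
    ss_err_within = err_ss.get(within, np.nan)
    total_err = ss_err_between + ss_err_within

    for _, r in aov.iterrows():
        src = r["Source"]
        ges = r["SS"] / (r["SS"] + total_err) if np.isfinite(total_err) else np.nan
        is_within = src != between
        if corrected and is_within:
            d1, d2 = r["DF1"] * eps, r["DF2"] * eps
            p_corr = float(stats.f.sf(r["F"], d1, d2))
        else:
            d1 = d2 = p_corr = np.nan
        rows.append({"Source": src, "SS": r["SS"], "df1": int(r["DF1"]),
                     "df2": int(r["DF2"]), "F": r["F"], "p_unc": r["p_unc"],
                     "ges": ges, "df1_corr": d1, "df2_corr": d2, "p_corr": p_corr})
    return AnovaTable(table=pd.DataFrame(rows), mauchly_w=mauchly_w,
                      mauchly_p=mauchly_p, gg_epsilon=eps, corrected=corrected)


@dataclass
class TukeyResult:
    pairwise: pd.DataFrame           # group1, group2, meandiff, p_adj, lower, upper, reject
    letters: dict[str, str]          # compact letter display
    alpha: float


def tukey_hsd(values, groups, alpha: float = 0.05) -> TukeyResult:
    """All-pairwise Tukey HSD (Tukey-Kramer under unequal cell sizes).

    Returns adjusted p-values and a compact letter display: cells sharing a
    letter are not separated at ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if uniq.size < 2:
        raise ValueError("Tukey HSD needs at least 2 cells")
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    tab = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    tab.columns = ["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"]

    # compact letter display: greedy assignment in descending-mean order
    means = pd.Series(values).groupby(pd.Series(groups)).mean()
    order = list(means.sort_values(ascending=False).index)
    differ = {frozenset((r.group1, r.group2)) for r in tab.itertuples() if r.reject}
    classes: list[set] = []
    for g in order:
        placed = False
        for cls in classes:
            if all(frozenset((g, other)) not in differ for other in cls):
                cls.add(g)
                placed = True
        if not placed:
            classes.append({g})
    letters = {str(g): "" for g in order}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", classes):
        for g in cls:
            letters[str(g)] += letter
    return TukeyResult(pairwise=tab, letters=letters, alpha=alpha)


@dataclass
class ModelComparison:
    """Nested OLS comparison: outcome ~ task vs outcome ~ task (x) PAF."""

    r2_step1: float
    r2_step2: float
    f_change: float
    df_change: tuple[float, float]
    p_change: float
    f_full: float
    df_full: tuple[float, float]
    p_full: float
    variant: str                     # 'full_interaction' or 'pooled_interaction'


def _fit_pair(df: pd.DataFrame, outcome: str, step2_formula: str,
              variant: str, task_col: str) -> ModelComparison:
    m1 = smf.ols(f"{outcome} ~ C({task_col})", data=df).fit()
    m2 = smf.ols(step2_formula, data=df).fit()
    if m2.df_resid >= m1.df_resid:
        raise ValueError("step-2 model did not add parameters (singular fit?)")
    cmp = anova_lm(m1, m2)
    f_change = float(cmp["F"].iloc[1])
    df_change = (float(cmp["df_diff"].iloc[1]), float(cmp["df_resid"].iloc[1]))
    p_change = float(cmp["Pr(>F)"].iloc[1])
    return ModelComparison(
        r2_step1=float(m1.rsquared), r2_step2=float(m2.rsquared),
        f_change=f_change, df_change=df_change, p_change=p_change,
        f_full=float(m2.fvalue), df_full=(float(m2.df_model), float(m2.df_resid)),
        p_full=float(m2.f_pvalue), variant=variant)


def hierarchical_compare(group_df: pd.DataFrame, outcome: str, paf_column: str,
                         task_col: str = "task_type"
                         ) -> dict[str, ModelComparison]:
    """Two-step hierarchical regression for one sex group.

    Step 1 predicts the outcome from task type alone; step 2 adds PAF as an
    interacting predictor. Two step-2 parameterizations are fit and both
    returned: ``full_interaction`` (PAF main effect plus a PAF x task slope
    per task type, 4 added parameters) and ``pooled_interaction`` (PAF main
    effect plus a single PAF x Precise-vs-Relative slope, 2 added
    parameters). The nested models are compared with an F-change test.
    """
    df = group_df[[task_col, outcome, paf_column]].dropna().copy()
    counts = df[task_col].value_counts()
    if counts.size < 2 or counts.min() < 2:
        raise ValueError("need >= 2 observations per task type")
    if np.isclose(df[paf_column].var(ddof=0), 0.0):
        raise ValueError(f"{paf_column} is constant; step-2 fit is singular")
    df["_relative"] = df[task_col].astype(str).str.endswith("R")
    out = {
        "full_interaction": _fit_pair(
            df, outcome, f"{outcome} ~ C({task_col}) * {paf_column}",
            "full_interaction", task_col),
        "pooled_interaction": _fit_pair(
            df, outcome,
            f"{outcome} ~ C({task_col}) + {paf_column} + {paf_column}:C(_relative)",
            "pooled_interaction", task_col),
    }
    return out
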