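"""Mixed ANOVA, Tukey HSD and hierarchical regression layer."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from pafmod.config import TASK_TYPES
from pafmod.inference import hierarchical_compare, mixed_anova, tukey_hsd

K = len(TASK_TYPES)


def long_table(n_f, n_m, y=None, rng=None):
    n = n_f + n_m
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(n), K),
        "sex": np.repeat(["F"] * n_f + ["M"] * n_m, K),
        "task_type": np.tile(TASK_TYPES, n),
    })
    df["y"] = y if y is not None else rng.standard_normal(len(df))
    return df


def split_plot_oracle(df):
    """Hand-computed split-plot decomposition for equal group sizes.

    Textbook sums of squares for one between-subject factor (2 levels) and
    one within-subject factor (k levels), one observation per cell.
    """
    gm = df["y"].mean()
    k = df["task_type"].nunique()
    n = df["subject"].nunique()
    subj_means = df.groupby("subject")["y"].mean()
    grp_of_subj = df.groupby("subject")["sex"].first()
    grp_means = df.groupby("sex")["y"].mean()
    task_means = df.groupby("task_type")["y"].mean()
    cell_means = df.groupby(["sex", "task_type"])["y"].mean()

    ss_between_subj = k * ((subj_means - gm) ** 2).sum()
    ss_sex = k * sum(df.groupby("sex")["subject"].nunique()[g]
                     * (grp_means[g] - gm) ** 2 for g in grp_means.index)
    ss_subj_within = ss_between_subj - ss_sex
    ss_task = n * ((task_means - gm) ** 2).sum()
    ss_int = sum(df.groupby("sex")["subject"].nunique()[g]
                 * (cell_means[g, t] - grp_means[g] - task_means[t] + gm) ** 2
                 for g, t in cell_means.index)
    ss_total = ((df["y"] - gm) ** 2).sum()
    ss_res = ss_total - ss_between_subj - ss_task - ss_int

    f_sex = (ss_sex / 1) / (ss_subj_within / (n - 2))
    f_task = (ss_task / (k - 1)) / (ss_res / ((k - 1) * (n - 2)))
    f_int = (ss_int / (k - 1)) / (ss_res / ((k - 1) * (n - 2)))
    ges = {
        "sex": ss_sex / (ss_sex + ss_subj_within + ss_res),
        "task_type": ss_task / (ss_task + ss_subj_within + ss_res),
        "Interaction": ss_int / (ss_int + ss_subj_within + ss_res),
    }
    return {"sex": f_sex, "task_type": f_task, "Interaction": f_int}, ges


def test_df_structure_reproduces_design_counts(rng):
    aov = mixed_anova(long_table(77, 33, rng=rng), outcome="y")
    t = aov.table.set_index("Source")
    assert (t.loc["sex", "df1"], t.loc["sex", "df2"]) == (1, 108)
    assert (t.loc["task_type", "df1"], t.loc["task_type", "df2"]) == (3, 324)
    assert (t.loc["Interaction", "df1"], t.loc["Interaction", "df2"]) == (3, 324)


@pytest.mark.parametrize("n_f,n_m", [(5, 4), (10, 10), (20, 7)])
def test_df_formula_holds_for_any_group_sizes(n_f, n_m, rng):
    aov = mixed_anova(long_table(n_f, n_m, rng=rng), outcome="y")
    n = n_f + n_m
    t = aov.table.set_index("Source")
    assert t.loc["sex", "df2"] == n - 2
    assert t.loc["task_type", "df2"] == 3 * (n - 2)


def test_f_and_ges_match_hand_split_plot_oracle(rng):
    df = long_table(8, 8, rng=rng)
    aov = mixed_anova(df, outcome="y")
    f_oracle, ges_oracle = split_plot_oracle(df)
    t = aov.table.set_index("Source")
    for src in ("sex", "task_type", "Interaction"):
        assert t.loc[src, "F"] == pytest.approx(f_oracle[src], rel=1e-8)
        assert t.loc[src, "ges"] == pytest.approx(ges_oracle[src], rel=1e-8)
        assert 0.0 <= t.loc[src, "ges"] <= 1.0


def test_constant_outcome_is_degenerate(rng):
    df = long_table(4, 4, y=np.ones(8 * K))
    aov = mixed_anova(df, outcome="y")
    assert aov.degenerate
    assert np.isnan(aov.table["F"]).all()


def test_injected_sex_effect_detected(rng):
    df = long_table(20, 20, rng=rng)
    df.loc[df["sex"] == "F", "y"] += 2.0
    aov = mixed_anova(df, outcome="y")
    t = aov.table.set_index("Source")
    assert t.loc["sex", "p_unc"] < 1e-4
    assert aov.mauchly_w <= 1.0 and np.isfinite(aov.gg_epsilon)


def test_missing_cells_dropped_and_small_group_rejected(rng):
    df = long_table(5, 4, rng=rng)
    df = df.drop(df[(df["subject"] == 0) & (df["task_type"] == "3R")].index)
    aov = mixed_anova(df, outcome="y")
    # subject 0 dropped listwise: 8 complete subjects remain -> df2 = 8 - 2
    assert aov.table.set_index("Source").loc["sex", "df2"] == 6
    with pytest.raises(ValueError):
        mixed_anova(long_table(5, 1, rng=rng), outcome="y")


def test_gg_correction_applied_on_sphericity_violation(rng):
    # strongly heterogeneous within-level variances violate sphericity
    n = 30
    df = long_table(15, 15, rng=rng)
    scale = df["task_type"].map({"2P": 0.1, "2R": 0.1, "3P": 1.0, "3R": 8.0})
    df["y"] = rng.standard_normal(len(df)) * scale
    aov = mixed_anova(df, outcome="y")
    if aov.corrected:  # Mauchly should reject here virtually always
        t = aov.table.set_index("Source")
        assert t.loc["task_type", "df1_corr"] < 3
        assert np.isfinite(t.loc["task_type", "p_corr"])
    assert aov.mauchly_p < 0.05


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

def test_equal_cells_share_a_letter(rng):
    vals = np.concatenate([rng.standard_normal(30), rng.standard_normal(30)])
    groups = np.array(["a"] * 30 + ["b"] * 30)
    res = tukey_hsd(vals, groups)
    assert set(res.letters["a"]) & set(res.letters["b"])
    assert not res.pairwise["reject"].any()


def test_tasktype_accuracy_grouping(rng):
    """Accuracy with realistic task-type means/SDs at n = 110 separates the
    3-Sample Precise cell from all others."""
    means = {"2P": 0.915, "2R": 0.925, "3P": 0.71, "3R": 0.86}
    vals, groups = [], []
    for task, m in means.items():
        vals.append(m + 0.08 * rng.standard_normal(110))
        groups += [task] * 110
    res = tukey_hsd(np.concatenate(vals), np.array(groups))
    others = ("2P", "2R", "3R")
    assert all(not set(res.letters["3P"]) & set(res.letters[o]) for o in others)
    assert set(res.letters["2P"]) & set(res.letters["2R"])
    assert not set(res.letters["3R"]) & set(res.letters["2P"])


def test_single_cell_rejected(rng):
    with pytest.raises(ValueError):
        tukey_hsd(rng.standard_normal(5), np.array(["a"] * 5))


# ---------------------------------------------------------------------------
# hierarchical regression
# ---------------------------------------------------------------------------

def male_like_table(rng, n=33, coupling=0.0, subject_sd=0.05):
    rows = []
    for s in range(n):
        paf = 10.4 + 1.2 * rng.standard_normal()
        z = rng.standard_normal()
        for task in TASK_TYPES:
            base = {"2P": 0.915, "2R": 0.925, "3P": 0.71, "3R": 0.86}[task]
            eff = coupling * (paf - 10.4) / 1.2 if task.endswith("R") else 0.0
            acc = (base + subject_sd * z + 0.05 * eff
                   + 0.02 * rng.standard_normal())
            rows.append({"subject": s, "task_type": task, "accuracy": acc,
                         "Baseline": paf})
    return pd.DataFrame(rows)


def test_full_interaction_df_structure(rng):
    df = male_like_table(rng)
    res = hierarchical_compare(df, "accuracy", "Baseline")
    full = res["full_interaction"]
    assert full.df_full == (7.0, 124.0)       # 8-parameter model on 132 records
    assert full.df_change == (4.0, 124.0)
    pooled = res["pooled_interaction"]
    assert pooled.df_change == (2.0, 126.0)
    assert full.r2_step2 >= full.r2_step1


def test_f_change_equals_t_squared_for_single_added_parameter(rng):
    df = male_like_table(rng, coupling=0.8)
    m1 = smf.ols("accuracy ~ C(task_type)", data=df).fit()
    m2 = smf.ols("accuracy ~ C(task_type) + Baseline", data=df).fit()
    cmp = anova_lm(m1, m2)
    assert cmp["F"].iloc[1] == pytest.approx(m2.tvalues["Baseline"] ** 2, rel=1e-10)


def test_constant_paf_is_singular(rng):
    df = male_like_table(rng)
    df["Baseline"] = 10.5
    with pytest.raises(ValueError, match="constant"):
        hierarchical_compare(df, "accuracy", "Baseline")


def test_null_f_change_rejection_rate_near_alpha(rng):
    """Under iid errors (the OLS assumption) the F-change size is nominal."""
    hits = 0
    reps = 200
    for _ in range(reps):
        df = male_like_table(rng, n=20, coupling=0.0, subject_sd=0.0)
        res = hierarchical_compare(df, "accuracy", "Baseline")
        hits += res["full_interaction"].p_change < 0.05
    # binomial 95% band around 0.05 at 200 reps
    assert 0.019 <= hits / reps <= 0.081


def test_injected_coupling_detected_in_majority_of_cohorts():
    detected = 0
    for seed in range(20):
        rng = np.random.default_rng(500 + seed)
        df = male_like_table(rng, n=33, coupling=0.6)
        res = hierarchical_compare(df, "accuracy", "Baseline")
        detected += res["full_interaction"].p_change < 0.05
    assert detected > 10
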