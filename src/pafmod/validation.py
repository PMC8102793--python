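"""Simulation-based validation harnesses.

These run the package end-to-end on seeded synthetic data to measure the
properties the method is supposed to have: ground-truth recovery of the
injected peak alpha frequencies and their sex-specific modulation, type-I
error of the mixed-ANOVA sex effect under the null, and joint coverage of the
shift-function confidence intervals. Tests and the acceptance script both
call these so the measured numbers come from one code path.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .config import RunConfig, SimConfig, TASK_TYPES, default_posterior_labels
from .inference import mixed_anova
from .pipeline import analyze_cohort, analyze_session, _subject_means
from .robust import shift_function
from .synth import simulate_session


def reduced_sim_config(seed: int, n_females: int = 77, n_males: int = 33,
                       n_blocks: int = 1, trials_per_block: int = 4,
                       n_channels: int = 14) -> SimConfig:
    """Study-condition cohort at reduced trial/channel counts for recovery runs.

    Keeps the injected statistical structure (sampling rate, injected PAF and
    modulation distributions, artifact rates) while shrinking the per-subject
    recording so whole-cohort Monte Carlo runs stay tractable.
    """
    return SimConfig(n_females=n_females, n_males=n_males, n_blocks=n_blocks,
                     trials_per_block=trials_per_block, n_channels=n_channels,
                     posterior_channels=default_posterior_labels(n_channels),
                     seed=seed)


def recover_cohort_modulation(sim: SimConfig, run_cfg: RunConfig | None = None
                              ) -> pd.DataFrame:
    """Run the full pipeline on one cohort; return per-subject true vs estimated
    modulation (pooled over all correct trials)."""
    cfg = run_cfg or RunConfig(sim=sim, seed=sim.seed)
    cfg = replace(cfg, sim=sim)
    res = analyze_cohort(cfg)
    est = _subject_means(res.cohort_table(), "modulation_hz").rename(
        columns={"modulation_hz": "est_modulation_hz"})
    truth = res.truth[["subject", "modulation_hz"]].rename(
        columns={"modulation_hz": "true_modulation_hz"})
    return est.merge(truth, on="subject")


def modulation_recovery_summary(n_cohorts: int = 20, base_seed: int = 1000,
                                **reduced_kwargs) -> pd.DataFrame:
    """Per-cohort recovered group mean modulations over ``n_cohorts`` seeds."""
    rows = []
    for i in range(n_cohorts):
        sim = reduced_sim_config(seed=base_seed + i, **reduced_kwargs)
        rec = recover_cohort_modulation(sim)
        g = rec.groupby(rec["sex"])["est_modulation_hz"].mean()
        rows.append({"cohort": i, "seed": sim.seed,
                     "mean_f": g.get("F", np.nan), "mean_m": g.get("M", np.nan),
                     "diff_f_minus_m": g.get("F", np.nan) - g.get("M", np.nan)})
    return pd.DataFrame(rows)


def paf_recovery_errors(n_subjects: int = 100, seed: int = 0,
                        fmin: float = 8.25, fmax: float = 13.75) -> pd.DataFrame:
    """Per-subject |estimated - injected| PAF at default SNR.

    Injected baseline frequencies are drawn uniformly across the interior of
    the alpha band (the estimator's grid is defined on 8-14 Hz, so frequencies
    outside the band are unrecoverable by construction); maintenance
    frequencies add the sex-appropriate modulation draw. Each subject gets a
    short session (one block) at otherwise default signal parameters.
    """
    rng = np.random.default_rng(seed)
    rows = []
    run_cfg = RunConfig()
    for i in range(n_subjects):
        sex = "F" if i % 2 == 0 else "M"
        base = rng.uniform(fmin, fmax)
        sim = reduced_sim_config(seed=seed, n_blocks=1, trials_per_block=8)
        sim.baseline_paf_mean = base
        sim.baseline_paf_sd = 0.0
        mod = float(np.clip(rng.normal(0.3 if sex == "F" else 0.0,
                                       0.5), fmin - base, fmax - base))
        sim.modulation_mean_f = sim.modulation_mean_m = mod
        sim.modulation_sd_f = sim.modulation_sd_m = 0.0
        sess = simulate_session(sim, f"s{i:03d}", sex, rng)
        cfg = replace(run_cfg, sim=sim)
        paf_tab, _ = analyze_session(sess, cfg)
        pooled = paf_tab[(paf_tab["task_type"] == "pooled")]
        est_b = pooled.loc[pooled["window"] == "Baseline", "paf_hz"].iloc[0]
        est_m = pooled.loc[pooled["window"] == "Maintenance", "paf_hz"].iloc[0]
        rows.append({"subject": i, "sex": sex,
                     "true_baseline": base, "est_baseline": est_b,
                     "true_maintenance": base + mod, "est_maintenance": est_m,
                     "err_baseline": abs(est_b - base),
                     "err_maintenance": abs(est_m - (base + mod))})
    return pd.DataFrame(rows)


def sex_effect_type1_rate(n_reps: int = 1000, n_f: int = 77, n_m: int = 33,
                          alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the mixed-ANOVA Sex effect on iid-normal outcomes."""
    rng = np.random.default_rng(seed)
    n = n_f + n_m
    base = pd.DataFrame({
        "subject": np.repeat(np.arange(n), len(TASK_TYPES)),
        "sex": np.repeat(["F"] * n_f + ["M"] * n_m, len(TASK_TYPES)),
        "task_type": np.tile(TASK_TYPES, n),
    })
    rejections = 0
    for _ in range(n_reps):
        base["y"] = rng.standard_normal(len(base))
        aov = mixed_anova(base, outcome="y")
        p_sex = aov.table.loc[aov.table["Source"] == "sex", "p_unc"].iloc[0]
        rejections += p_sex < alpha
    return rejections / n_reps


def shift_coverage(n_reps: int = 200, n_x: int = 77, n_y: int = 33,
                   n_boot: int = 2000, alpha: float = 0.05, seed: int = 0) -> float:
    """Joint coverage of the simultaneous shift-function CIs under the null.

    Both samples are drawn from the same normal distribution; a replication
    "covers" when every decile's CI contains the true difference (zero).
    """
    rng = np.random.default_rng(seed)
    covered = 0
    for i in range(n_reps):
        x = rng.standard_normal(n_x)
        y = rng.standard_normal(n_y)
        sf = shift_function(x, y, n_boot=n_boot, alpha=alpha,
                            seed=int(rng.integers(2**31)))
        covered += bool(np.all((sf.ci_low <= 0) & (0 <= sf.ci_high)))
    return covered / n_reps
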