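"""Config-driven orchestration: simulate -> preprocess -> tfr -> paf -> stats -> report.

Each stage reads only its declared inputs from the run directory and stamps
every table it writes with the config hash, seed and package version, so a
run is reproducible from (config, seed) alone. :func:`analyze_session` is the
in-memory per-subject path (filter, segment, screen, decompose, extract PAF)
that the disk stages and the validation harnesses share.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, TASK_TYPES
from .inference import hierarchical_compare, mixed_anova, tukey_hsd
from .paf import DEFAULT_WINDOWS, paf_records, subject_paf
from .preprocess import (EpochSet, bandlimit, preprocess_epochs, segment,
                         select_correct_by_tasktype)
from .robust import fdr_adjust, fisher_z_compare, ks_2samp, pearson_r, shift_function
from .spectral import induced_by_group
from .synth import Session, generate_cohort, iter_cohort_sessions

logger = logging.getLogger(__name__)

WINDOW_NAMES = [w.name for w in DEFAULT_WINDOWS]


# ---------------------------------------------------------------------------
# per-subject analysis
# ---------------------------------------------------------------------------

def clean_epochs(session: Session, cfg: RunConfig, ica_hook=None
                 ) -> tuple[EpochSet, dict]:
    """Filter, segment and artifact-screen one session into clean epochs."""
    filt = bandlimit(session.data, session.sampling_rate,
                     cfg.preproc.hp_hz, cfg.preproc.lp_hz)
    epochs, seg_log = segment(filt, session.sampling_rate, session.trial_onsets,
                              cfg.sim.timeline.segment_span,
                              session.channel_labels, session.channel_roles,
                              trial_meta=session.trials)
    epochs, logs = preprocess_epochs(epochs, cfg.preproc.eog_threshold_uv,
                                     cfg.preproc.spike_factor, ica_hook=ica_hook)
    logs["segment"] = seg_log
    return epochs, logs


def subject_paf_table(epochs: EpochSet, cfg: RunConfig, subject: str,
                      sex: str) -> pd.DataFrame:
    """PAF records for one subject: per task type and pooled over all correct trials.

    The pooled record is the PAF of the all-correct-trials induced power (not
    the mean of the per-task PAFs). Only the posterior channels enter the
    weighted PAF computation, so the decomposition is restricted to them and
    performed in a single streaming pass over the correct trials.
    """
    posterior = epochs.posterior_labels
    # validate the partition (flags empty cells) before the pooled pass
    select_correct_by_tasktype(epochs)
    correct_all = epochs.take_trials(
        np.flatnonzero(epochs.trial_meta["correct"].astype(bool)))
    tfrs = induced_by_group(correct_all.take_channels(posterior),
                            correct_all.trial_meta["task_type"].to_numpy(),
                            cfg.spectral)
    paf_by_task = {}
    for task in TASK_TYPES:
        if task in tfrs:
            paf_by_task[task] = subject_paf(tfrs[task], posterior, band=cfg.alpha_band)
        else:
            paf_by_task[task] = {w.name: float("nan") for w in DEFAULT_WINDOWS}
            paf_by_task[task]["Modulation"] = float("nan")
    paf_by_task["pooled"] = subject_paf(tfrs["pooled"], posterior, band=cfg.alpha_band)
    return paf_records(subject, sex, paf_by_task)


def analyze_session(session: Session, cfg: RunConfig, ica_hook=None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-subject analysis: returns (PAF table rows, behavior summary rows)."""
    epochs, _ = clean_epochs(session, cfg, ica_hook=ica_hook)
    paf_tab = subject_paf_table(epochs, cfg, session.subject_id, session.sex)
    beh = behavior_summary(session.trials, session.subject_id, session.sex)
    return paf_tab, beh


def behavior_summary(trials: pd.DataFrame, subject: str, sex: str) -> pd.DataFrame:
    """Per task type: proportion correct and mean correct-trial response time."""
    rows = []
    for task in TASK_TYPES:
        sub = trials[trials["task_type"] == task]
        correct = sub["correct"].astype(bool)
        rows.append({
            "subject": subject, "sex": sex, "task_type": task,
            "n_trials": len(sub),
            "accuracy": correct.mean() if len(sub) else np.nan,
            "rt_ms": sub.loc[correct, "rt_ms"].mean() if correct.any() else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Long-format cohort tables feeding all inferential models."""

    paf_table: pd.DataFrame       # subject, sex, task_type, window, paf_hz, modulation_hz
    behavior: pd.DataFrame        # subject, sex, task_type, accuracy, rt_ms
    truth: pd.DataFrame | None = None

    def cohort_table(self) -> pd.DataFrame:
        """subject x task-type records: accuracy, RT and PAF per window wide."""
        wide = (self.paf_table[self.paf_table["task_type"] != "pooled"]
                .pivot_table(index=["subject", "sex", "task_type"],
                             columns="window", values="paf_hz", observed=True)
                .reset_index())
        mod = (self.paf_table[self.paf_table["task_type"] != "pooled"]
               .groupby(["subject", "sex", "task_type"], observed=True)["modulation_hz"]
               .first().reset_index())
        out = wide.merge(mod, on=["subject", "sex", "task_type"])
        return out.merge(self.behavior, on=["subject", "sex", "task_type"], how="left")


def analyze_cohort(cfg: RunConfig, ica_hook=None) -> CohortResult:
    """Simulate and analyze a whole cohort in memory (no disk intermediates)."""
    paf_rows, beh_rows, truth_rows = [], [], []
    for sess in iter_cohort_sessions(cfg.sim):
        p, b = analyze_session(sess, cfg, ica_hook=ica_hook)
        paf_rows.append(p)
        beh_rows.append(b)
        truth_rows.append({"subject": sess.subject_id, "sex": sess.sex,
                           **{k: v for k, v in sess.truth.items()
                              if isinstance(v, (int, float))}})
    return CohortResult(paf_table=pd.concat(paf_rows, ignore_index=True),
                        behavior=pd.concat(beh_rows, ignore_index=True),
                        truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# statistics stage
# ---------------------------------------------------------------------------

def _subject_means(df: pd.DataFrame, value: str) -> pd.DataFrame:
    """One row per subject: the across-task-type mean of ``value``."""
    return (df.groupby(["subject", "sex"], observed=True)[value]
            .mean().reset_index())


def run_statistics(result: CohortResult, cfg: RunConfig) -> dict:
    """The full inferential battery on a cohort table.

    Group (F vs M) KS tests and shift functions for accuracy, response time
    and PAF modulation; 2 x 4 mixed ANOVAs with Tukey HSD post hocs;
    baseline-maintenance PAF correlations per sex with a Fisher z comparison;
    per-sex two-step hierarchical regressions; and the task x window
    accuracy-PAF correlation table with FDR-adjusted p-values.
    """
    table = result.cohort_table()
    seed = cfg.seed
    n_boot, alpha = cfg.stats.n_boot, cfg.stats.alpha
    out: dict = {"group_comparisons": {}, "anova": {}, "tukey": {},
                 "correlation": {}, "hierarchical": {}}

    # --- distribution-level group comparisons (subject-level means) -------
    for name, col in (("accuracy", "accuracy"), ("rt_ms", "rt_ms"),
                      ("modulation_hz", "modulation_hz")):
        means = _subject_means(table, col).dropna()
        x = means.loc[means["sex"] == "F", col].to_numpy()
        y = means.loc[means["sex"] == "M", col].to_numpy()
        ks = ks_2samp(x, y)
        entry = {"ks_d": ks.d_statistic, "ks_p": ks.p_value,
                 "n_f": int(x.size), "n_m": int(y.size), "_samples": (x, y, None)}
        if x.size >= 10 and y.size >= 10:
            sf = shift_function(x, y, n_boot=n_boot, alpha=alpha, seed=seed)
            entry["shift"] = sf.to_frame()
            entry["_samples"] = (x, y, sf)
        out["group_comparisons"][name] = entry

    # --- 2 x 4 mixed ANOVAs ------------------------------------------------
    for name, col in (("accuracy", "accuracy"), ("rt_ms", "rt_ms"),
                      ("modulation", "modulation_hz"),
                      ("baseline_paf", "Baseline"), ("maintenance_paf", "Maintenance")):
        if col not in table.columns:
            continue
        try:
            out["anova"][name] = mixed_anova(table, outcome=col)
        except ValueError as exc:
            logger.warning("ANOVA %s skipped: %s", name, exc)
    for name, col in (("accuracy", "accuracy"), ("rt_ms", "rt_ms")):
        sub = table.dropna(subset=[col])
        out["tukey"][name] = tukey_hsd(sub[col].to_numpy(),
                                       sub["task_type"].to_numpy(), alpha=alpha)

    # --- baseline-maintenance PAF coupling, per sex ------------------------
    per_sex_r = {}
    for sex in ("F", "M"):
        sub = table[(table["sex"] == sex)].dropna(subset=["Baseline", "Maintenance"])
        per_sex_r[sex] = {"r": pearson_r(sub["Baseline"], sub["Maintenance"]),
                          "n": len(sub)}
    z, p = fisher_z_compare(per_sex_r["M"]["r"], per_sex_r["M"]["n"],
                            per_sex_r["F"]["r"], per_sex_r["F"]["n"])
    out["correlation"]["baseline_maintenance"] = {
        **per_sex_r, "fisher_z_m_minus_f": z, "fisher_p": p}

    # --- per-sex hierarchical regressions ----------------------------------
    for sex in ("F", "M"):
        sub = table[table["sex"] == sex]
        for outcome in ("accuracy", "rt_ms"):
            for win in WINDOW_NAMES:
                if win not in sub.columns:
                    continue
                key = f"{sex}:{outcome}:{win}"
                try:
                    out["hierarchical"][key] = hierarchical_compare(
                        sub.dropna(subset=[outcome, win]), outcome, win)
                except ValueError as exc:
                    logger.warning("hierarchical %s skipped: %s", key, exc)

    # --- accuracy-PAF correlation table with FDR ---------------------------
    rows = []
    for sex in ("F", "M"):
        for task in TASK_TYPES:
            sub = table[(table["sex"] == sex) & (table["task_type"] == task)]
            for win in WINDOW_NAMES:
                if win not in sub.columns:
                    continue
                cell = sub.dropna(subset=["accuracy", win])
                if len(cell) < 4:
                    continue
                if np.isclose(cell[win].var(ddof=0), 0.0) or \
                        np.isclose(cell["accuracy"].var(ddof=0), 0.0):
                    continue  # constant column: correlation undefined
                from scipy import stats as sps
                r, p_unc = sps.pearsonr(cell[win], cell["accuracy"])
                if not np.isfinite(p_unc):
                    continue
                rows.append({"sex": sex, "task_type": task, "window": win,
                             "r": float(r), "p_unc": float(p_unc), "n": len(cell)})
    corr = pd.DataFrame(rows)
    if len(corr):
        corr["p_fdr"] = fdr_adjust(corr["p_unc"].to_numpy())
    out["correlation"]["accuracy_paf_table"] = corr
    return out


# ---------------------------------------------------------------------------
# report / serialization helpers
# ---------------------------------------------------------------------------

def _stamp(cfg: RunConfig) -> str:
    return (f"# pafmod v{__version__} | config_hash={cfg.hash()} | "
            f"seed={cfg.seed}\n")


def write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(cfg))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable({k: getattr(obj, k) for k in obj.__dataclass_fields__})
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def summary_tables(result: CohortResult) -> dict[str, pd.DataFrame]:
    """Median/mean/SD by sex x task type for behavior and PAF measures."""
    out = {}
    beh = result.behavior
    out["behavior_summary"] = (beh.groupby(["sex", "task_type"], observed=True)
                               [["accuracy", "rt_ms"]]
                               .agg(["median", "mean", "std"]).round(3)
                               .reset_index())
    table = result.cohort_table()
    cols = [c for c in ("Baseline", "Maintenance", "modulation_hz") if c in table]
    out["paf_summary"] = (table.groupby(["sex", "task_type"], observed=True)[cols]
                          .agg(["median", "mean", "std"]).round(3).reset_index())
    return out


# ---------------------------------------------------------------------------
# staged disk pipeline
# ---------------------------------------------------------------------------

STAGES = ("simulate", "preprocess", "tfr", "paf", "stats", "report")


def _sessions_from_disk(cfg: RunConfig, sess_dir: Path):
    from .edf import read_edf_uv

    for sidecar_path in sorted(sess_dir.glob("sub*.json")):
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        data, fs, labels = read_edf_uv(sidecar_path.with_suffix(".edf"))
        trials = pd.DataFrame({"task_type": meta["task_type"],
                               "correct": meta["correct"],
                               "rt_ms": meta["rt_ms"]})
        yield Session(subject_id=meta["subject_id"], sex=meta["sex"], data=data,
                      sampling_rate=fs, channel_labels=labels,
                      channel_roles=meta["channel_roles"],
                      trial_onsets=np.asarray(meta["trial_onsets_s"]),
                      trials=trials, truth={})


def run(cfg: RunConfig, stages=STAGES, from_disk: bool = False) -> dict:
    """Execute the pipeline and write a report bundle under ``cfg.out_dir``.

    ``stages`` selects which stages run; earlier outputs are read from the run
    directory when a stage is re-run in isolation (e.g. ``stages=('stats',
    'report')`` on a saved PAF table). With ``from_disk=True`` the analysis
    stages re-read the EDF sessions written by ``simulate`` instead of
    re-simulating in memory.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest = {"version": __version__, "config_hash": cfg.hash(),
                "seed": cfg.seed, "stages": list(stages)}

    try:
        if "simulate" in stages and from_disk:
            generate_cohort(cfg.sim, out / "sessions")

        analysis_stages = {"preprocess", "tfr", "paf"}
        if analysis_stages & set(stages):
            sessions = (_sessions_from_disk(cfg, out / "sessions") if from_disk
                        else iter_cohort_sessions(cfg.sim))
            paf_rows, beh_rows, truth_rows = [], [], []
            for sess in sessions:
                p, b = analyze_session(sess, cfg)
                paf_rows.append(p)
                beh_rows.append(b)
                if sess.truth:
                    truth_rows.append({"subject": sess.subject_id, "sex": sess.sex,
                                       **{k: v for k, v in sess.truth.items()
                                          if isinstance(v, (int, float))}})
            result = CohortResult(paf_table=pd.concat(paf_rows, ignore_index=True),
                                  behavior=pd.concat(beh_rows, ignore_index=True),
                                  truth=pd.DataFrame(truth_rows) if truth_rows else None)
            write_table(result.paf_table, out / "tables" / "paf_table.tsv", cfg)
            write_table(result.behavior, out / "tables" / "behavior.tsv", cfg)
            if result.truth is not None:
                write_table(result.truth, out / "tables" / "ground_truth.tsv", cfg)
        else:
            result = CohortResult(
                paf_table=read_table(out / "tables" / "paf_table.tsv"),
                behavior=read_table(out / "tables" / "behavior.tsv"))

        stats_out = None
        if "stats" in stages:
            stats_out = run_statistics(result, cfg)
            with open(out / "tables" / "statistics.json", "w") as fh:
                json.dump({"_meta": manifest, **_jsonable(stats_out)}, fh, indent=1)

        if "report" in stages:
            for name, df in summary_tables(result).items():
                with open(out / "tables" / f"{name}.tsv", "w") as fh:
                    fh.write(_stamp(cfg))
                    df.to_csv(fh, sep="\t")
            if result.truth is not None and "modulation_hz" in result.truth:
                rec = _subject_means(result.cohort_table(), "modulation_hz").merge(
                    result.truth[["subject", "modulation_hz"]]
                    .rename(columns={"modulation_hz": "true_modulation_hz"}),
                    on="subject")
                write_table(rec, out / "tables" / "modulation_recovery.tsv", cfg)
            if stats_out:
                from .plots import shift_panels, stripchart
                for name, entry in stats_out["group_comparisons"].items():
                    x, y, sf = entry["_samples"]
                    fig_path = out / "figures" / f"shift_{name}.png"
                    if sf is not None:
                        shift_panels(x, y, sf, outcome=name, path=fig_path)
                    else:
                        stripchart(x, y, outcome=name, path=fig_path)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {"out_dir": str(out), "manifest": manifest, "result": result,
            "stats": stats_out}
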