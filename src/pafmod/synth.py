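"""Synthetic working-memory EEG cohort generator.

Each simulated subject performs ``n_blocks x trials_per_block`` trials of the
four-condition visuospatial task while a multichannel recording is synthesized
at ``sampling_rate``. The signal model per channel is

    x(t) = 1/f^chi aperiodic background + alpha oscillation (posterior only)
           [+ blink transients on the EOG channels]

where the alpha oscillation is a fixed-frequency sinusoid with random
per-trial phase at the subject's baseline peak alpha frequency during the
pre-cue fixation window and at baseline + modulation during the memory delay
(a frequency step, not a ramp). Subject-level parameters:

* baseline PAF ~ Normal(baseline_paf_mean, baseline_paf_sd)
* modulation ~ Normal(modulation_mean_<sex>, modulation_sd_<sex>)
* behavioral accuracy: Binomial per task type around ``accuracy_means`` with a
  logit-scale subject ability effect; in males the ability component entering
  Relative task types is coupled to baseline PAF through a Gaussian copula at
  the configured correlation.
* response time: lognormal with a subject-level and a trial-level factor.

The generator is fully determined by ``SimConfig.seed``; every subject draws
from an independently spawned child stream so cohorts are reproducible and
order-independent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.signal.windows import hann
from scipy.special import expit, logit

from .config import ROLE_EOG, SimConfig, TASK_TYPES
from .preprocess import EpochSet, segment

logger = logging.getLogger(__name__)

LEAD_IN_S = 2.5   # recording before the first trial onset (covers the 2 s buffer)
TAIL_S = 6.0      # recording after the last trial onset (covers the 5.5 s epoch)
BLINK_DURATION_S = 0.3


@dataclass
class Session:
    """One subject's continuous synthetic recording plus behavior and ground truth."""

    subject_id: str
    sex: str
    data: np.ndarray                 # channels x samples, uV
    sampling_rate: float
    channel_labels: list[str]
    channel_roles: dict[str, str]
    trial_onsets: np.ndarray         # s, cue+sample onset per trial
    trials: pd.DataFrame             # block, trial, task_type, correct, rt_ms
    truth: dict                      # injected subject-level parameters


def _aperiodic_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                     fs: float, exponent: float, rms: float) -> np.ndarray:
    """1/f^chi-shaped Gaussian noise via spectral shaping, normalized to ``rms``."""
    out = np.empty((n_channels, n_samples))
    if rms == 0:
        out[:] = 0.0
        return out
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    for ch in range(n_channels):  # per-channel to bound peak memory
        spec = shape * (rng.standard_normal(freqs.size)
                        + 1j * rng.standard_normal(freqs.size))
        x = np.fft.irfft(spec, n=n_samples)
        sd = x.std()
        out[ch] = x * (rms / sd) if sd > 0 else 0.0
    return out


def _task_schedule(rng: np.random.Generator, n_blocks: int,
                   trials_per_block: int) -> np.ndarray:
    """Task types pseudorandomized within each block, as balanced as possible."""
    blocks = []
    for _ in range(n_blocks):
        reps = int(np.ceil(trials_per_block / len(TASK_TYPES)))
        block = np.tile(np.array(TASK_TYPES), reps)[:trials_per_block]
        rng.shuffle(block)
        blocks.append(block)
    return np.concatenate(blocks)


def _subject_parameters(config: SimConfig, sex: str, rng: np.random.Generator) -> dict:
    z_paf = rng.standard_normal()
    z_ability = rng.standard_normal()
    z_rt = rng.standard_normal()
    baseline_paf = config.baseline_paf_mean + config.baseline_paf_sd * z_paf
    if sex == "F":
        mod = rng.normal(config.modulation_mean_f, config.modulation_sd_f)
    elif sex == "M":
        mod = rng.normal(config.modulation_mean_m, config.modulation_sd_m)
    else:
        raise ValueError("sex must be 'F' or 'M'")
    r = config.paf_accuracy_r_male_relative
    p_task = {}
    for task in TASK_TYPES:
        if sex == "M" and task.endswith("R"):
            # Gaussian copula: the ability component feeding Relative-task
            # accuracy shares correlation r with the baseline-PAF z-score
            z_eff = r * z_paf + np.sqrt(1.0 - r ** 2) * z_ability
        else:
            z_eff = z_ability
        p_task[task] = float(expit(logit(config.accuracy_means[task])
                                   + config.accuracy_logit_sd * z_eff))
    return {
        "baseline_paf_hz": float(baseline_paf),
        "modulation_hz": float(mod),
        "maintenance_paf_hz": float(baseline_paf + mod),
        "p_correct": p_task,
        "rt_subject_factor": float(np.exp(config.rt_subject_sigma * z_rt)),
    }


def _behavior(config: SimConfig, params: dict, tasks: np.ndarray,
              rng: np.random.Generator) -> pd.DataFrame:
    n = tasks.size
    p = np.array([params["p_correct"][t] for t in tasks])
    correct = rng.random(n) < p
    mu = np.array([config.rt_means[t] for t in tasks])
    sig = config.rt_trial_sigma
    rt = (mu * params["rt_subject_factor"]
          * np.exp(sig * rng.standard_normal(n) - sig ** 2 / 2.0))
    return pd.DataFrame({
        "block": np.repeat(np.arange(config.n_blocks), config.trials_per_block),
        "trial": np.arange(n),
        "task_type": tasks,
        "correct": correct,
        "rt_ms": rt,
    })


def simulate_session(config: SimConfig, subject_id: str, sex: str,
                     rng: np.random.Generator) -> Session:
    """Generate one subject's continuous recording, behavior and ground truth."""
    config.validate()
    if sex not in ("F", "M"):
        raise ValueError("sex must be 'F' or 'M'")
    fs = config.sampling_rate
    tl = config.timeline
    n_trials = config.trials_per_subject
    params = _subject_parameters(config, sex, rng)
    tasks = _task_schedule(rng, config.n_blocks, config.trials_per_block)
    trials = _behavior(config, params, tasks, rng)

    onsets = LEAD_IN_S + tl.trial_spacing * np.arange(n_trials)
    n_samples = int(round((LEAD_IN_S + tl.trial_spacing * (n_trials - 1) + TAIL_S) * fs))
    labels = config.all_labels
    roles = config.channel_roles
    n_scalp = config.n_channels
    n_total = len(labels)

    data = np.zeros((n_total, n_samples))
    data[:n_scalp] = _aperiodic_noise(rng, n_scalp, n_samples, fs,
                                      config.aperiodic_exponent, config.noise_amplitude)
    data[n_scalp:] = _aperiodic_noise(rng, n_total - n_scalp, n_samples, fs,
                                      config.aperiodic_exponent,
                                      config.eog_noise_amplitude)

    post_idx = np.array([labels.index(lab) for lab in config.posterior_channels])
    # per-subject posterior channel gains so channel weighting is exercised
    gains = rng.uniform(0.7, 1.3, size=post_idx.size)
    params["posterior_gains"] = gains.tolist()

    if config.alpha_amplitude > 0:
        t_all = np.arange(n_samples) / fs
        delay_lo = tl.sample_duration
        delay_hi = tl.test_onset
        for onset in onsets:
            for (w_lo, w_hi, base_freq) in (
                (tl.baseline_onset, 0.0, params["baseline_paf_hz"]),
                (delay_lo, delay_hi, params["maintenance_paf_hz"]),
            ):
                f = base_freq
                if config.paf_trial_sd > 0:
                    f = f + rng.normal(0.0, config.paf_trial_sd)
                phase = rng.uniform(0.0, 2 * np.pi)
                i0 = int(round((onset + w_lo) * fs))
                i1 = int(round((onset + w_hi) * fs))
                wave = config.alpha_amplitude * np.sin(
                    2 * np.pi * f * t_all[i0:i1] + phase)
                data[post_idx, i0:i1] += gains[:, None] * wave[None, :]

    if config.blink_rate > 0 and config.blink_amplitude > 0:
        eog_idx = np.array([i for i, lab in enumerate(labels) if roles[lab] == ROLE_EOG])
        blink = config.blink_amplitude * hann(int(round(BLINK_DURATION_S * fs)))
        blink_trials = rng.random(n_trials) < config.blink_rate
        params["blink_trials"] = np.flatnonzero(blink_trials).tolist()
        for onset in onsets[blink_trials]:
            t_blink = onset + rng.uniform(tl.baseline_onset, delay_hi + 0.5)
            i0 = int(round(t_blink * fs))
            i1 = min(i0 + blink.size, n_samples)
            data[eog_idx, i0:i1] += blink[: i1 - i0]
    else:
        params["blink_trials"] = []

    return Session(subject_id=subject_id, sex=sex, data=data, sampling_rate=fs,
                   channel_labels=labels, channel_roles=roles,
                   trial_onsets=onsets, trials=trials, truth=params)


def generate_subject(config: SimConfig, subject_id: str, sex: str,
                     rng: np.random.Generator | int | None = None
                     ) -> tuple[EpochSet, pd.DataFrame, dict]:
    """Generate one subject and return raw (unfiltered) epochs plus behavior.

    Epochs span the full 7.5 s segment around every trial onset.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    sess = simulate_session(config, subject_id, sex, rng)
    epochs, _ = segment(sess.data, sess.sampling_rate, sess.trial_onsets,
                        config.timeline.segment_span, sess.channel_labels,
                        sess.channel_roles, trial_meta=sess.trials)
    return epochs, sess.trials, sess.truth


def cohort_subjects(config: SimConfig) -> list[tuple[str, str]]:
    """(subject_id, sex) for every cohort member: females first, then males."""
    ids = []
    for i in range(config.n_females):
        ids.append((f"sub{i + 1:03d}", "F"))
    for j in range(config.n_males):
        ids.append((f"sub{config.n_females + j + 1:03d}", "M"))
    return ids


def iter_cohort_sessions(config: SimConfig) -> Iterator[Session]:
    """Lazily yield every subject's session (one independent child stream each)."""
    if config.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects)
    for (sid, sex), child in zip(cohort_subjects(config), children):
        yield simulate_session(config, sid, sex, np.random.default_rng(child))


def generate_cohort(config: SimConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write every subject session to disk and return the ground-truth table.

    Per subject: an EDF recording, a JSON sidecar (trial onsets, task types,
    correctness, response times, subject metadata), and a behavior TSV. A
    cohort-level ``ground_truth.tsv`` logs the injected parameters for later
    recovery checks.
    """
    from .edf import write_edf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sess in iter_cohort_sessions(config):
        base = out / sess.subject_id
        write_edf(f"{base}.edf", sess.data, sess.sampling_rate, sess.channel_labels)
        sidecar = {
            "subject_id": sess.subject_id,
            "sex": sess.sex,
            "sampling_rate": sess.sampling_rate,
            "channel_roles": sess.channel_roles,
            "trial_onsets_s": sess.trial_onsets.tolist(),
            "task_type": sess.trials["task_type"].tolist(),
            "correct": sess.trials["correct"].astype(bool).tolist(),
            "rt_ms": sess.trials["rt_ms"].round(3).tolist(),
        }
        with open(f"{base}.json", "w") as fh:
            json.dump(sidecar, fh)
        sess.trials.to_csv(f"{base}_behavior.tsv", sep="\t", index=False)
        rows.append({"subject": sess.subject_id, "sex": sess.sex,
                     "baseline_paf_hz": sess.truth["baseline_paf_hz"],
                     "modulation_hz": sess.truth["modulation_hz"],
                     "maintenance_paf_hz": sess.truth["maintenance_paf_hz"]})
    truth = pd.DataFrame(rows)
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    logger.info("wrote %d subject sessions to %s", len(rows), out)
    return truth


def load_truth(out_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(out_dir) / "ground_truth.tsv", sep="\t")
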