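"""Continuous-to-epoch preprocessing: filtering, segmentation, artifact screens.

Pipeline order is fixed: band-limit -> segment -> (optional external ICA hook)
-> EOG peak-to-peak rejection -> voltage-spike rejection -> correct-trial sort
by task type. All rejection steps filter the trial axis only; retained voltage
data are never modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .config import ROLE_EOG, ROLE_POSTERIOR, ROLE_SCALP, TASK_TYPES

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Trials x channels x samples voltage array with channel roles and trial metadata.

    ``data`` is in microvolts. ``time_axis`` is in seconds relative to trial
    (cue+sample) onset and spans the 7.5 s segment [-2.0, 5.5). ``trial_meta``
    is a DataFrame with one row per trial carrying at least ``task_type``
    (one of 2P/2R/3P/3R), ``correct`` (bool) and ``rt_ms``.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    channel_roles: dict[str, str]
    time_axis: np.ndarray
    trial_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis does not match labels")
        if self.data.shape[2] != self.time_axis.size:
            raise ValueError("sample axis does not match time axis")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial_meta rows do not match trial axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def _role_indices(self, role: str) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.channel_labels)
                         if self.channel_roles.get(lab) == role], dtype=int)

    @property
    def eog_indices(self) -> np.ndarray:
        return self._role_indices(ROLE_EOG)

    @property
    def scalp_indices(self) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.channel_labels)
                         if self.channel_roles.get(lab) in (ROLE_SCALP, ROLE_POSTERIOR)],
                        dtype=int)

    @property
    def posterior_labels(self) -> list[str]:
        return [lab for lab in self.channel_labels
                if self.channel_roles.get(lab) == ROLE_POSTERIOR]

    def take_trials(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return replace(self, data=self.data[idx],
                       trial_meta=self.trial_meta.iloc[idx].reset_index(drop=True))

    def take_channels(self, labels: list[str]) -> "EpochSet":
        idx = [self.channel_labels.index(lab) for lab in labels]
        return replace(self, data=self.data[:, idx, :],
                       channel_labels=list(labels),
                       channel_roles={lab: self.channel_roles[lab] for lab in labels})


def _butter_sos(order: int, cutoff: float, btype: str, fs: float):
    return signal.butter(order, cutoff, btype=btype, fs=fs, output="sos")


def bandlimit(continuous: np.ndarray, sampling_rate: float,
              hp: float = 0.5, lp: float = 30.0, order: int = 4) -> np.ndarray:
    """High-pass, de-mean, and low-pass a channels x samples array.

    Zero-phase forward-backward Butterworth filtering (``order`` poles per
    pass) so that window boundaries downstream are not latency-shifted.
    """
    if not 0 < hp < lp < sampling_rate / 2:
        raise ValueError("need 0 < hp < lp < Nyquist")
    x = np.asarray(continuous, dtype=float)
    # the high-pass rings for ~1/hp seconds; pad accordingly so edge
    # transients settle inside the reflected padding, not the recording
    padlen = min(x.shape[-1] - 1, int(round(3 * sampling_rate / hp)))
    x = signal.sosfiltfilt(_butter_sos(order, hp, "highpass", sampling_rate), x,
                           axis=-1, padlen=padlen)
    x = x - x.mean(axis=-1, keepdims=True)
    x = signal.sosfiltfilt(_butter_sos(order, lp, "lowpass", sampling_rate), x,
                           axis=-1, padlen=padlen)
    return x


def segment(continuous: np.ndarray, sampling_rate: float, trial_onsets,
            span: tuple[float, float], channel_labels: list[str],
            channel_roles: dict[str, str],
            trial_meta: pd.DataFrame | None = None) -> tuple[EpochSet, pd.DataFrame]:
    """Cut a continuous recording into one epoch per trial onset.

    ``span`` is (start, stop) in seconds relative to each onset; epochs may
    overlap. Onsets whose epoch would run past either edge of the recording
    are dropped with a warning and recorded in the returned drop log.
    """
    x = np.asarray(continuous, dtype=float)
    onsets = np.asarray(trial_onsets, dtype=float)
    lo, hi = span
    n_samp = int(round((hi - lo) * sampling_rate))
    time_axis = lo + np.arange(n_samp) / sampling_rate

    starts = np.round((onsets + lo) * sampling_rate).astype(int)
    ok = (starts >= 0) & (starts + n_samp <= x.shape[-1])
    dropped = np.flatnonzero(~ok)
    if dropped.size:
        logger.warning("segment: dropped %d trial(s) too close to recording edge", dropped.size)
    log = pd.DataFrame({"trial": np.arange(onsets.size),
                        "onset_s": onsets,
                        "kept": ok})

    kept = np.flatnonzero(ok)
    data = np.stack([x[:, s:s + n_samp] for s in starts[kept]], axis=0) \
        if kept.size else np.empty((0, x.shape[0], n_samp))
    if trial_meta is None:
        trial_meta = pd.DataFrame(index=np.arange(onsets.size))
    meta = trial_meta.iloc[kept].reset_index(drop=True)
    return EpochSet(data=data, sampling_rate=sampling_rate,
                    channel_labels=list(channel_labels),
                    channel_roles=dict(channel_roles),
                    time_axis=time_axis, trial_meta=meta), log


def reject_eog_trials(epochs: EpochSet, threshold: float = 18.75
                      ) -> tuple[EpochSet, pd.DataFrame]:
    """Remove trials whose EOG peak-to-peak voltage strictly exceeds ``threshold``.

    A trial is removed iff max-minus-min over the full epoch in ANY EOG
    channel is > threshold (strict: a shift of exactly the threshold value is
    retained). Returns the screened epochs and a per-trial log of peak-to-peak
    values. The screen is applied to the data as given (post-filtering in the
    standard pipeline order).
    """
    eog = epochs.eog_indices
    if eog.size == 0:
        raise ValueError("no EOG channels present; cannot run ocular screening")
    if epochs.n_trials == 0:
        return epochs, pd.DataFrame(columns=["trial", "eog_ptp_uv", "rejected"])
    ptp = epochs.data[:, eog, :]
    ptp = (ptp.max(axis=-1) - ptp.min(axis=-1)).max(axis=-1)
    rejected = ptp > threshold
    log = pd.DataFrame({"trial": np.arange(epochs.n_trials),
                        "eog_ptp_uv": ptp, "rejected": rejected})
    if rejected.any():
        logger.info("EOG screen: removed %d/%d trials (> %.2f uV)",
                    int(rejected.sum()), epochs.n_trials, threshold)
    return epochs.take_trials(np.flatnonzero(~rejected)), log


def reject_spike_trials(epochs: EpochSet, factor: float = 10.0
                        ) -> tuple[EpochSet, pd.DataFrame]:
    """Remove trials with grossly outlying scalp voltage spikes.

    A trial is removed when its peak absolute scalp voltage exceeds
    ``factor`` times the median of per-trial peaks. With fewer than 3 trials
    the median is unstable and the screen is skipped with a warning.
    """
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    n = epochs.n_trials
    cols = ["trial", "peak_abs_uv", "rejected"]
    if n < 3:
        logger.warning("spike screen skipped: only %d trial(s)", n)
        return epochs, pd.DataFrame(columns=cols)
    peaks = np.abs(epochs.data[:, epochs.scalp_indices, :]).max(axis=(1, 2))
    med = np.median(peaks)
    rejected = peaks > factor * med
    log = pd.DataFrame({"trial": np.arange(n), "peak_abs_uv": peaks,
                        "rejected": rejected})
    if rejected.any():
        logger.info("spike screen: removed %d/%d trials", int(rejected.sum()), n)
    return epochs.take_trials(np.flatnonzero(~rejected)), log


def select_correct_by_tasktype(epochs: EpochSet) -> dict[str, EpochSet]:
    """Partition correct trials by the four task types.

    Incorrect trials are excluded. A task type with zero correct trials maps
    to an empty EpochSet (downstream PAF for that cell is marked missing).
    """
    meta = epochs.trial_meta
    for col in ("task_type", "correct"):
        if col not in meta.columns:
            raise ValueError(f"trial_meta lacks required column {col!r}")
    out: dict[str, EpochSet] = {}
    for task in TASK_TYPES:
        idx = np.flatnonzero((meta["task_type"] == task) & meta["correct"].astype(bool))
        if idx.size == 0:
            logger.warning("task %s has no correct trials; PAF cell will be missing", task)
        out[task] = epochs.take_trials(idx)
    return out


def preprocess_epochs(epochs: EpochSet, eog_threshold: float = 18.75,
                      spike_factor: float = 10.0, ica_hook=None
                      ) -> tuple[EpochSet, dict[str, pd.DataFrame]]:
    """Artifact-screening stage on already-segmented epochs.

    ``ica_hook`` is an optional callable ``EpochSet -> EpochSet`` slotted in
    before threshold screening (component-based ocular cleanup is delegated to
    external tooling and is off by default).
    """
    logs: dict[str, pd.DataFrame] = {}
    if ica_hook is not None:
        epochs = ica_hook(epochs)
    epochs, logs["eog"] = reject_eog_trials(epochs, eog_threshold)
    epochs, logs["spike"] = reject_spike_trials(epochs, spike_factor)
    return epochs, logs
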