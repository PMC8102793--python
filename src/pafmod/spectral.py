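"""Time-frequency decomposition of epochs into power matrices.

Power at channel c, frequency f and time t is the squared magnitude of the
Hann-tapered windowed Fourier coefficient at f, the window (2 s by default)
centered at t. Windows whose span extends past the epoch edges are computed
with zero-padding, never dropped. The frequency axis is the fixed 0.5 Hz grid
from 2.0 to 20.0 Hz (37 bins); with a 2 s window this grid equals the native
DFT resolution, so no interpolation is involved.

Induced power is the average of per-trial power over (correct) trials — power
is taken before averaging, so non-phase-locked activity survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .config import SpectralConfig
from .preprocess import EpochSet


@dataclass
class TFRMatrix:
    """channels x frequencies x times induced-power array (uV^2 amplitude scale)."""

    power: np.ndarray
    freqs: np.ndarray            # Hz
    times: np.ndarray            # s, same reference as the source epoch axis
    channel_labels: list[str]
    window_s: float
    taper: str = "hann"
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.channel_labels), self.freqs.size, self.times.size):
            raise ValueError("power shape does not match axes")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def frequency_grid(cfg: SpectralConfig) -> np.ndarray:
    n = int(round((cfg.fmax - cfg.fmin) / cfg.fstep)) + 1
    return cfg.fmin + cfg.fstep * np.arange(n)


def _plan(n_samples: int, fs: float, cfg: SpectralConfig):
    freqs = frequency_grid(cfg)
    if freqs[-1] >= fs / 2:
        raise ValueError("frequency axis exceeds the Nyquist frequency")
    n_win = int(round(cfg.window_s * fs))
    if n_win > n_samples:
        raise ValueError("analysis window longer than the epoch")
    mfft = int(round(fs / cfg.fstep))
    if mfft < n_win:
        raise ValueError("fstep too coarse for the window length")
    idx = np.round(freqs * mfft / fs).astype(int)
    if np.max(np.abs(idx * fs / mfft - freqs)) > 1e-9:
        raise ValueError("frequency grid does not align with the DFT bins")
    hop = max(1, int(round(cfg.stride_s * fs)))
    centers = np.arange(0, n_samples, hop)
    taper = hann(n_win, sym=False)
    return freqs, idx, n_win, mfft, hop, centers, taper


def stft_power(data: np.ndarray, fs: float, cfg: SpectralConfig,
               t0: float = 0.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window Hann power of a (..., samples) array.

    Returns ``(power, freqs, times)`` with power shaped ``(..., n_freq,
    n_time)``. ``times`` are window-center times: ``t0 + k * hop / fs``.
    Amplitude-normalized so a full-window sinusoid of amplitude A yields power
    ~A^2 at its bin.
    """
    data = np.asarray(data, dtype=float)
    n_samples = data.shape[-1]
    freqs, idx, n_win, mfft, hop, centers, taper = _plan(n_samples, fs, cfg)
    half = n_win // 2

    lead = data.shape[:-1]
    flat = data.reshape(-1, n_samples)
    padded = np.pad(flat, [(0, 0), (half, n_win - half)])
    power = np.empty((flat.shape[0], freqs.size, centers.size))
    norm = 2.0 / taper.sum()
    chunk = max(1, int(2**22 // (centers.size * n_win)))  # bound scratch memory
    for s in range(0, flat.shape[0], chunk):
        block = padded[s:s + chunk]
        wins = np.lib.stride_tricks.sliding_window_view(block, n_win, axis=-1)
        wins = wins[:, centers, :] * taper
        coef = np.fft.rfft(wins, n=mfft, axis=-1)[..., idx] * norm
        power[s:s + chunk] = np.moveaxis(np.abs(coef) ** 2, -1, -2)
    times = t0 + centers / fs
    return power.reshape(*lead, freqs.size, centers.size), freqs, times


def tfr_epochs(epochs: EpochSet, cfg: SpectralConfig | None = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial power: (trials, channels, freqs, times) plus axes."""
    cfg = cfg or SpectralConfig()
    return stft_power(epochs.data, epochs.sampling_rate, cfg,
                      t0=float(epochs.time_axis[0]))


def induced_tfr(epochs: EpochSet, cfg: SpectralConfig | None = None) -> TFRMatrix:
    """Trial-averaged (induced) power of an epoch set as a TFRMatrix.

    Trials are processed in chunks so only the running mean is held for large
    epoch counts.
    """
    cfg = cfg or SpectralConfig()
    n = epochs.n_trials
    if n == 0:
        freqs, idx, n_win, mfft, hop, centers, taper = _plan(
            epochs.time_axis.size, epochs.sampling_rate, cfg)
        power = np.zeros((len(epochs.channel_labels), freqs.size, centers.size))
        times = float(epochs.time_axis[0]) + centers / epochs.sampling_rate
        return TFRMatrix(power=power, freqs=freqs, times=times,
                         channel_labels=list(epochs.channel_labels),
                         window_s=cfg.window_s, n_trials=0)
    acc = None
    step = 16
    for s in range(0, n, step):
        p, freqs, times = stft_power(epochs.data[s:s + step], epochs.sampling_rate,
                                     cfg, t0=float(epochs.time_axis[0]))
        p = p.sum(axis=0)
        acc = p if acc is None else acc + p
    return TFRMatrix(power=acc / n, freqs=freqs, times=times,
                     channel_labels=list(epochs.channel_labels),
                     window_s=cfg.window_s, n_trials=n)


def tfr_by_tasktype(epochs_by_task: dict[str, EpochSet],
                    cfg: SpectralConfig | None = None) -> dict[str, TFRMatrix]:
    """Induced TFR per task type (empty task cells yield zero-trial TFRs)."""
    return {task: induced_tfr(ep, cfg) for task, ep in epochs_by_task.items()}


def induced_by_group(epochs: EpochSet, groups, cfg: SpectralConfig | None = None,
                     pooled_key: str = "pooled") -> dict[str, TFRMatrix]:
    """Induced TFR per trial group plus the pooled average, in one STFT pass.

    ``groups`` is one label per trial; the per-trial power is computed once
    (in chunks, so only running sums are held) and accumulated into one
    average per distinct label and one over all trials. Equivalent to calling
    :func:`induced_tfr` on each trial subset, at a fraction of the cost.
    """
    cfg = cfg or SpectralConfig()
    groups = np.asarray(groups)
    if groups.size != epochs.n_trials:
        raise ValueError("one group label per trial required")
    labels = pd.unique(groups) if groups.size else np.array([])
    n_ch = len(epochs.channel_labels)
    freqs, idx, n_win, mfft, hop, centers, taper = _plan(
        epochs.time_axis.size, epochs.sampling_rate, cfg)
    times = float(epochs.time_axis[0]) + centers / epochs.sampling_rate
    sums = {lab: np.zeros((n_ch, freqs.size, centers.size)) for lab in labels}
    pooled = np.zeros((n_ch, freqs.size, centers.size))
    counts = {lab: int((groups == lab).sum()) for lab in labels}
    step = 16
    for s in range(0, epochs.n_trials, step):
        p, _, _ = stft_power(epochs.data[s:s + step], epochs.sampling_rate, cfg,
                             t0=float(epochs.time_axis[0]))
        pooled += p.sum(axis=0)
        for lab in labels:
            sel = groups[s:s + step] == lab
            if sel.any():
                sums[lab] += p[sel].sum(axis=0)

    def _wrap(total, n):
        return TFRMatrix(power=total / n if n else total, freqs=freqs, times=times,
                         channel_labels=list(epochs.channel_labels),
                         window_s=cfg.window_s, n_trials=n)

    out = {str(lab): _wrap(sums[lab], counts[lab]) for lab in labels}
    out[pooled_key] = _wrap(pooled, epochs.n_trials)
    return out
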