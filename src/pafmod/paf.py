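"""Channel-weighted peak alpha frequency (PAF) and its task modulation.

The estimator follows the center-of-gravity weighting scheme: at each time
point the 8-14 Hz power of the posterior channels is summed across channels,
each channel's share of that sum is its weight, and the weighted power is
averaged over channels. PAF for an analysis window is the frequency (on the
0.5 Hz grid, 13 bins) at which the time-averaged weighted power is largest;
ties break toward the lowest frequency. Because the weights are proportions
and argmax is monotone-invariant, PAF is invariant to any common positive
rescaling of channel power.

Modulation is Maintenance PAF minus Baseline PAF, in Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import TFRMatrix

logger = logging.getLogger(__name__)

ALPHA_BAND = (8.0, 14.0)


@dataclass(frozen=True)
class AnalysisWindow:
    """Named half-open time span [start, stop) in seconds relative to trial onset."""

    name: str
    span: tuple[float, float]

    def __post_init__(self) -> None:
        if self.span[1] <= self.span[0]:
            raise ValueError("window span must be non-empty")


#: Baseline = last 500 ms of fixation; Maintenance = last 1,500 ms of the
#: delay; PreTestTask spans both (including the intervening sample period).
BASELINE = AnalysisWindow("Baseline", (-0.5, 0.0))
MAINTENANCE = AnalysisWindow("Maintenance", (1.0, 2.5))
PRETEST = AnalysisWindow("PreTestTask", (-0.5, 2.5))
DEFAULT_WINDOWS = (BASELINE, MAINTENANCE, PRETEST)


def channel_weights(power_at_t: np.ndarray) -> np.ndarray:
    """Each channel's proportional share of the summed power at one time point.

    All-zero input is degenerate: uniform weights are returned with a warning.
    """
    p = np.asarray(power_at_t, dtype=float)
    if np.any(p < 0):
        raise ValueError("power must be non-negative")
    total = p.sum()
    if total == 0:
        logger.warning("all-zero power at a time point; using uniform weights")
        return np.full(p.shape, 1.0 / p.size)
    return p / total


def _band_indices(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    idx = np.flatnonzero((freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9))
    if idx.size == 0:
        raise ValueError("alpha band outside the TFR frequency axis")
    return idx


def weighted_alpha_power(tfr: TFRMatrix, posterior_channels: list[str],
                         band: tuple[float, float] = ALPHA_BAND
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Channel-weighted band power: (freqs_in_band x times, band freqs, times).

    Weights are recomputed at every time point from the band-summed power of
    the selected posterior channels; the output at (f, t) is the mean over
    channels of weight x power.
    """
    if not posterior_channels:
        raise ValueError("empty posterior channel selection")
    missing = set(posterior_channels) - set(tfr.channel_labels)
    if missing:
        raise ValueError(f"channels not in TFR: {sorted(missing)}")
    ch_idx = [tfr.channel_labels.index(c) for c in posterior_channels]
    f_idx = _band_indices(tfr.freqs, band)
    sel = tfr.power[np.ix_(ch_idx, f_idx)]          # ch x f x t
    band_sum = sel.sum(axis=1)                       # ch x t
    total = band_sum.sum(axis=0)                     # t
    n_ch = len(ch_idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(total > 0, band_sum / total, 1.0 / n_ch)
    if np.any(total == 0):
        logger.warning("weighted_alpha_power: %d time point(s) with zero band "
                       "power; uniform weights used there", int((total == 0).sum()))
    weighted = (w[:, None, :] * sel).mean(axis=0)    # f x t
    return weighted, tfr.freqs[f_idx], tfr.times


def extract_paf(weighted: np.ndarray, band_freqs: np.ndarray, times: np.ndarray,
                window: AnalysisWindow, method: str = "argmax") -> float:
    """PAF of a weighted power matrix within one analysis window.

    Time bins whose window center falls in the half-open span are averaged;
    ``method='argmax'`` (default) returns the grid frequency with the largest
    averaged weighted power (ties toward the lowest frequency, logged);
    ``method='cog'`` returns the spectral center of gravity
    sum(f * P(f)) / sum(P(f)) over the band, for sensitivity analysis.
    """
    lo, hi = window.span
    t_idx = np.flatnonzero((times >= lo - 1e-9) & (times < hi - 1e-9))
    if t_idx.size == 0:
        raise ValueError(f"window {window.name} contains no time bins")
    profile = weighted[:, t_idx].mean(axis=1)
    if method == "argmax":
        top = np.flatnonzero(profile == profile.max())
        if top.size > 1:
            logger.info("PAF tie among %s Hz in window %s; lowest taken",
                        band_freqs[top].tolist(), window.name)
        return float(band_freqs[top[0]])
    if method == "cog":
        total = profile.sum()
        if total == 0:
            return float(band_freqs[0])
        return float((band_freqs * profile).sum() / total)
    raise ValueError(f"unknown method {method!r}")


def modulation(paf_maintenance: float, paf_baseline: float) -> float:
    """Task modulation of PAF: Maintenance PAF minus Baseline PAF (Hz)."""
    return paf_maintenance - paf_baseline


def subject_paf(tfr: TFRMatrix, posterior_channels: list[str],
                band: tuple[float, float] = ALPHA_BAND,
                windows=DEFAULT_WINDOWS, method: str = "argmax") -> dict[str, float]:
    """PAF for each analysis window of one induced TFR, plus the modulation.

    Returns ``{window name: PAF Hz, ..., 'Modulation': Hz}``; an all-NaN dict
    when the TFR averages zero trials (missing cell).
    """
    names = [w.name for w in windows]
    if tfr.n_trials == 0:
        out = {name: float("nan") for name in names}
        out["Modulation"] = float("nan")
        return out
    weighted, band_freqs, times = weighted_alpha_power(tfr, posterior_channels, band)
    out = {w.name: extract_paf(weighted, band_freqs, times, w, method=method)
           for w in windows}
    if "Baseline" in out and "Maintenance" in out:
        out["Modulation"] = modulation(out["Maintenance"], out["Baseline"])
    return out


def paf_records(subject: str, sex: str, paf_by_task: dict[str, dict[str, float]]
                ) -> pd.DataFrame:
    """Long-format PAF table rows for one subject.

    ``paf_by_task`` maps task type (or 'pooled') to the dict returned by
    :func:`subject_paf`. Columns: subject, sex, task_type, window, paf_hz,
    modulation_hz.
    """
    rows = []
    for task, vals in paf_by_task.items():
        mod = vals.get("Modulation", float("nan"))
        for win, hz in vals.items():
            if win == "Modulation":
                continue
            rows.append({"subject": subject, "sex": sex, "task_type": task,
                         "window": win, "paf_hz": hz, "modulation_hz": mod})
    return pd.DataFrame(rows)
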