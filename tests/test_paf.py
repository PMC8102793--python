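"""Channel-weighted PAF extraction: weights, weighting oracle, argmax, modulation."""

import numpy as np
import pytest

from pafmod.config import RunConfig, SimConfig, default_posterior_labels
from pafmod.paf import (ALPHA_BAND, AnalysisWindow, BASELINE, MAINTENANCE,
                        channel_weights, extract_paf, modulation, subject_paf,
                        weighted_alpha_power)
from pafmod.pipeline import clean_epochs, subject_paf_table
from pafmod.spectral import TFRMatrix
from pafmod.synth import simulate_session


def make_tfr(power, freqs=None, times=None):
    n_ch, n_f, n_t = power.shape
    freqs = np.asarray(freqs) if freqs is not None else 8.0 + 0.5 * np.arange(n_f)
    times = np.asarray(times) if times is not None else 0.1 * np.arange(n_t)
    return TFRMatrix(power=power, freqs=freqs, times=times,
                     channel_labels=[f"c{i}" for i in range(n_ch)],
                     window_s=2.0, n_trials=1)


@pytest.mark.parametrize("power,expected", [
    (np.ones(14), np.full(14, 1 / 14)),
    (np.array([3.0, 1.0]), np.array([0.75, 0.25])),
    (np.array([2.0, 6.0, 2.0]), np.array([0.2, 0.6, 0.2])),
])
def test_channel_weights_are_proportional_shares(power, expected):
    np.testing.assert_allclose(channel_weights(power), expected)
    assert channel_weights(power).sum() == pytest.approx(1.0)


def test_zero_power_gives_uniform_weights(caplog):
    w = channel_weights(np.zeros(5))
    np.testing.assert_allclose(w, 0.2)


def brute_weighted(power, ch_idx, f_idx):
    """Oracle: literal per-time-point weight-and-average loops."""
    n_t = power.shape[2]
    out = np.empty((len(f_idx), n_t))
    for t in range(n_t):
        band = power[np.ix_(ch_idx, f_idx)][:, :, t]
        sums = band.sum(axis=1)
        w = sums / sums.sum() if sums.sum() > 0 else np.full(len(ch_idx),
                                                            1 / len(ch_idx))
        for i in range(len(f_idx)):
            out[i, t] = np.mean(w * band[:, i])
    return out


def test_weighted_alpha_power_matches_brute_force(rng):
    for _ in range(20):
        power = rng.random((4, 13, 6))
        tfr = make_tfr(power)
        got, freqs, _ = weighted_alpha_power(tfr, ["c0", "c1", "c2", "c3"])
        expected = brute_weighted(power, [0, 1, 2, 3], list(range(13)))
        np.testing.assert_allclose(got, expected, rtol=1e-10)


def test_weighting_symmetry_and_scale_equivariance(rng):
    common = rng.random((1, 13, 5))
    tfr = make_tfr(np.tile(common, (3, 1, 1)))
    got, _, _ = weighted_alpha_power(tfr, ["c0", "c1", "c2"])
    # identical channels: uniform weights, output = spectrum / n_ch
    np.testing.assert_allclose(got, common[0] / 3, rtol=1e-12)

    power = rng.random((3, 13, 5))
    base, _, _ = weighted_alpha_power(make_tfr(power), ["c0", "c1", "c2"])
    scaled, _, _ = weighted_alpha_power(make_tfr(7.5 * power), ["c0", "c1", "c2"])
    np.testing.assert_allclose(scaled, 7.5 * base, rtol=1e-12)
    assert np.argmax(scaled.mean(axis=1)) == np.argmax(base.mean(axis=1))


def test_dominant_channel_dominates_weighted_matrix():
    power = np.zeros((2, 13, 4))
    power[0, 2, :] = 100.0   # channel A: all power at 9 Hz
    power[1, 8, :] = 1.0     # channel B: all power at 12 Hz
    got, freqs, times = weighted_alpha_power(make_tfr(power), ["c0", "c1"])
    win = AnalysisWindow("all", (times[0], times[-1] + 0.05))
    assert extract_paf(got, freqs, times, win) == 9.0


def test_empty_selection_rejected(rng):
    with pytest.raises(ValueError):
        weighted_alpha_power(make_tfr(rng.random((2, 13, 3))), [])


def test_flat_spectrum_ties_break_low():
    weighted = np.ones((13, 6))
    freqs = 8.0 + 0.5 * np.arange(13)
    times = 0.1 * np.arange(6)
    win = AnalysisWindow("w", (0.0, 0.6))
    assert extract_paf(weighted, freqs, times, win) == 8.0


def test_window_outside_axis_rejected():
    weighted = np.ones((13, 4))
    freqs = 8.0 + 0.5 * np.arange(13)
    times = np.array([0.0, 0.1, 0.2, 0.3])
    with pytest.raises(ValueError):
        extract_paf(weighted, freqs, times, AnalysisWindow("late", (5.0, 6.0)))


def test_half_open_window_selection():
    # power peaks at different frequencies before/after t = 1.0
    weighted = np.zeros((13, 4))
    times = np.array([0.8, 0.9, 1.0, 1.1])
    freqs = 8.0 + 0.5 * np.arange(13)
    weighted[4, :2] = 1.0   # 10.0 Hz before 1.0
    weighted[5, 2:] = 1.0   # 10.5 Hz from 1.0 on
    assert extract_paf(weighted, freqs, times, AnalysisWindow("a", (0.8, 1.0))) == 10.0
    assert extract_paf(weighted, freqs, times, AnalysisWindow("b", (1.0, 1.2))) == 10.5


def test_cog_variant_is_band_center_of_gravity():
    weighted = np.zeros((13, 2))
    freqs = 8.0 + 0.5 * np.arange(13)
    weighted[0] = 1.0   # 8 Hz
    weighted[12] = 1.0  # 14 Hz
    got = extract_paf(weighted, freqs, np.array([0.0, 0.1]),
                      AnalysisWindow("w", (0.0, 0.2)), method="cog")
    assert got == pytest.approx(11.0)


@pytest.mark.parametrize("maint,base,expected", [
    (10.5, 10.5, 0.0),
    (10.63, 10.30, 0.33),    # female 2-Sample Relative period means
    (10.53, 10.67, -0.14),   # male 2-Sample Precise period means
])
def test_modulation_is_signed_difference(maint, base, expected):
    assert modulation(maint, base) == pytest.approx(expected)


def test_injected_frequencies_recovered_through_full_stack():
    """Baseline 10.0 Hz / delay 10.5 Hz injected on-grid -> PAF exact."""
    sim = SimConfig(n_females=1, n_males=1, n_blocks=1, trials_per_block=8,
                    n_channels=14, posterior_channels=default_posterior_labels(14),
                    baseline_paf_mean=10.0, baseline_paf_sd=0.0,
                    modulation_mean_f=0.5, modulation_sd_f=0.0, seed=21)
    cfg = RunConfig(sim=sim, seed=21)
    sess = simulate_session(sim, "s1", "F", np.random.default_rng(21))
    epochs, _ = clean_epochs(sess, cfg)
    tab = subject_paf_table(epochs, cfg, "s1", "F")
    pooled = tab[tab["task_type"] == "pooled"].set_index("window")["paf_hz"]
    assert pooled["Baseline"] == 10.0
    assert pooled["Maintenance"] == 10.5
    assert tab[tab["task_type"] == "pooled"]["modulation_hz"].iloc[0] == 0.5


def test_paf_invariant_to_common_rescaling(rng):
    power = rng.random((3, 13, 8))
    for scale in (1e-6, 1.0, 1e6):
        tfr = make_tfr(scale * power)
        got, freqs, times = weighted_alpha_power(tfr, ["c0", "c1", "c2"])
        win = AnalysisWindow("w", (times[0], times[-1] + 0.05))
        if scale == 1e-6:
            ref = extract_paf(got, freqs, times, win)
        else:
            assert extract_paf(got, freqs, times, win) == ref
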