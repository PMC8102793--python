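"""Robust group-comparison machinery vs independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from pafmod.robust import (DECILES, fdr_adjust, fisher_z_compare, hd_quantile,
                           ks_2samp, pearson_r, shift_function)


# ---------------------------------------------------------------------------
# Harrell-Davis quantiles
# ---------------------------------------------------------------------------

def hd_oracle(x, q):
    """Literal Beta-CDF weighted sum over order statistics, scalar loops."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    a, b = (n + 1) * q, (n + 1) * (1 - q)
    total = 0.0
    for i in range(1, n + 1):
        w = stats.beta.cdf(i / n, a, b) - stats.beta.cdf((i - 1) / n, a, b)
        total += w * x[i - 1]
    return total


def test_hd_quantile_worked_examples():
    assert hd_quantile([1.0, 2.0, 3.0], 0.5) == pytest.approx(2.0)
    for q in (0.1, 0.5, 0.9):
        assert hd_quantile([5.0, 5.0, 5.0, 5.0], q) == pytest.approx(5.0)
    x = [1.0, 2.0, 3.0, 10.0]
    assert hd_quantile(x, 0.75) > hd_quantile(x, 0.25)


def test_hd_quantile_matches_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(2, 40))
        x = rng.standard_normal(n) * rng.uniform(0.5, 5)
        q = float(rng.uniform(0.05, 0.95))
        assert hd_quantile(x, q) == pytest.approx(hd_oracle(x, q), rel=1e-10)


def test_hd_quantile_guards():
    with pytest.raises(ValueError):
        hd_quantile([1.0], 0.5)
    with pytest.raises(ValueError):
        hd_quantile([1.0, 2.0], 1.0)


# ---------------------------------------------------------------------------
# shift function
# ---------------------------------------------------------------------------

def test_identical_samples_give_zero_shift(rng):
    x = rng.standard_normal(40)
    sf = shift_function(x, x.copy(), n_boot=500, seed=0)
    np.testing.assert_allclose(sf.difference, 0.0, atol=1e-12)
    assert np.all((sf.ci_low <= 0) & (0 <= sf.ci_high))
    assert not sf.significant.any()
    assert np.all(sf.ci_low <= sf.ci_high)


def test_location_shift_detected_at_every_decile(rng):
    x = rng.standard_normal(200)
    y = x + 1.0
    sf = shift_function(x, y, n_boot=1000, seed=1)
    np.testing.assert_allclose(sf.difference, -1.0, atol=0.05)
    assert sf.significant.all()
    assert np.all(sf.ci_high < 0)


def test_shift_function_determinism_and_guards(rng):
    x, y = rng.standard_normal(30), rng.standard_normal(30)
    a = shift_function(x, y, n_boot=300, seed=9)
    b = shift_function(x, y, n_boot=300, seed=9)
    np.testing.assert_array_equal(a.ci_low, b.ci_low)
    with pytest.raises(ValueError):
        shift_function(rng.standard_normal(5), y)
    assert a.to_frame().shape[0] == 9


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def ks_oracle(x, y):
    """Brute-force sup over the pooled support of |ECDF_x - ECDF_y|."""
    pooled = np.concatenate([x, y])
    d = 0.0
    for v in pooled:
        fx = np.mean(np.asarray(x) <= v)
        fy = np.mean(np.asarray(y) <= v)
        d = max(d, abs(fx - fy))
    return d


def test_ks_worked_examples():
    assert ks_2samp([1, 2, 3], [1, 2, 3]).d_statistic == 0.0
    assert ks_2samp([1, 2, 3], [4, 5, 6]).d_statistic == 1.0
    res = ks_2samp([1, 3, 5, 7], [2, 4, 6, 8])
    assert res.d_statistic == pytest.approx(0.25)
    assert res.d_statistic == pytest.approx(ks_oracle([1, 3, 5, 7], [2, 4, 6, 8]))


def test_ks_matches_oracle_on_random_fixtures(rng):
    for _ in range(25):
        x = rng.standard_normal(int(rng.integers(3, 30)))
        y = rng.standard_normal(int(rng.integers(3, 30))) + rng.uniform(-1, 1)
        assert ks_2samp(x, y).d_statistic == pytest.approx(ks_oracle(x, y),
                                                           rel=1e-10)


def test_ks_empty_sample_rejected():
    with pytest.raises(ValueError):
        ks_2samp([], [1.0])


# ---------------------------------------------------------------------------
# correlations and Fisher z
# ---------------------------------------------------------------------------

def test_fisher_z_reproduces_headline_comparison():
    """r = 0.82 (n=132) vs r = 0.58 (n=308) differ at z = 4.71."""
    z, p = fisher_z_compare(0.82, 132, 0.58, 308)
    assert round(z, 2) == 4.71
    assert p < 0.0001


def test_fisher_z_closed_form_and_symmetries():
    z, _ = fisher_z_compare(0.5, 28, 0.0, 28)
    assert z == pytest.approx(np.arctanh(0.5) / np.sqrt(2 / 25), rel=1e-12)
    assert round(z, 2) == 1.94
    assert fisher_z_compare(0.3, 50, 0.3, 120)[0] == 0.0
    z1, p1 = fisher_z_compare(0.7, 40, 0.2, 60)
    z2, p2 = fisher_z_compare(0.2, 60, 0.7, 40)
    assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)
    with pytest.raises(ValueError):
        fisher_z_compare(1.0, 30, 0.5, 30)
    with pytest.raises(ValueError):
        fisher_z_compare(0.5, 3, 0.5, 30)


def test_pearson_r_basic(rng):
    x = rng.standard_normal(50)
    assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_oracle(p):
    """Hand step-up: p_(i) * n / i, cumulative min from the largest, cap 1."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def test_fdr_worked_examples():
    np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(fdr_adjust([0.2]), [0.2])
    np.testing.assert_allclose(fdr_adjust([0.5, 0.5, 0.5]), [0.5, 0.5, 0.5])


def test_fdr_matches_hand_stepup_on_random_fixtures(rng):
    for _ in range(25):
        p = rng.uniform(size=int(rng.integers(1, 25)))
        np.testing.assert_allclose(fdr_adjust(p), fdr_oracle(p), rtol=1e-10)


def test_fdr_guards():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.5])
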