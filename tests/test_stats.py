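"""Chi-squared randomness tests, Monte-Carlo null, paired method comparison."""

import numpy as np
import pytest
from scipy import stats as sps

from spermtopo.stats import (
    chisq_gof,
    monte_carlo_region_null,
    paired_method_comparison,
    subject_homogeneity,
)


def test_uniform_counts_give_chi2_zero():
    res = chisq_gof([100, 100, 100])
    assert res.chi2 == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.degrees_of_freedom == 2


def test_reported_2d_longitudinal_counts_reject_equal_thirds():
    # hand computation: E = 964/3, chi2 = sum (O-E)^2 / E = 164.75
    counts = np.array([509, 235, 220])
    E = counts.sum() / 3
    expected_chi2 = float(np.sum((counts - E) ** 2 / E))
    res = chisq_gof(counts)
    assert res.chi2 == pytest.approx(expected_chi2, abs=1e-9)
    assert res.chi2 == pytest.approx(164.75, abs=0.05)
    assert res.p_value < 0.05


def test_fully_concentrated_counts():
    with pytest.warns(UserWarning, match="below 5"):
        res = chisq_gof([10, 0, 0])
    assert res.chi2 == pytest.approx(20.0)
    assert res.p_value == pytest.approx(sps.chi2.sf(20.0, 2), rel=1e-6)


def test_zero_total_raises():
    with pytest.raises(ValueError, match="zero"):
        chisq_gof([0, 0, 0])


def test_invalid_expected_fractions_raise():
    with pytest.raises(ValueError):
        chisq_gof([5, 5, 5], expected_fractions=[0.5, 0.5, 0.0])
    with pytest.raises(ValueError):
        chisq_gof([5, 5, 5], expected_fractions=[0.5, 0.4])


def test_type_one_error_rate_under_the_null():
    """Equal-thirds draws rejected ~5% of the time at alpha = 0.05."""
    rng = np.random.default_rng(12345)
    counts = rng.multinomial(300, [1 / 3] * 3, size=1000)
    rejections = sum(chisq_gof(c).p_value < 0.05 for c in counts)
    assert abs(rejections / 1000 - 0.05) <= 0.015


def test_power_against_mid_heavy_alternative():
    """Fractions (0.50, 0.25, 0.25) at n = 300 are detected essentially always."""
    rng = np.random.default_rng(7)
    counts = rng.multinomial(300, [0.5, 0.25, 0.25], size=200)
    rejections = sum(chisq_gof(c).p_value < 0.05 for c in counts)
    assert rejections / 200 >= 0.99


def test_monte_carlo_null_fractions_sum_to_one(sphere_nucleus):
    mc = monte_carlo_region_null(sphere_nucleus, n_points=5000, seed=1)
    assert mc.fractions.sum() == pytest.approx(1.0)
    assert np.all(mc.standard_errors >= 0)


def test_monte_carlo_null_converges(sphere_nucleus):
    a = monte_carlo_region_null(sphere_nucleus, n_points=20_000, seed=2)
    b = monte_carlo_region_null(sphere_nucleus, n_points=20_000, seed=3)
    # independent replicates agree within a few standard errors
    assert np.all(np.abs(a.fractions - b.fractions) < 5 * (a.standard_errors + 1e-9))
    big = monte_carlo_region_null(sphere_nucleus, n_points=80_000, seed=4)
    assert np.all(big.standard_errors[:2] < a.standard_errors[:2])


def test_paired_identical_vectors_p_one():
    res = paired_method_comparison([0.5, 0.4, 0.3], [0.5, 0.4, 0.3])
    assert res.mean_difference == 0.0
    assert res.p_value == 1.0


def test_paired_closed_form_t():
    # differences (1, 2, 3): t = 2 / (1 / sqrt(3)), df = 2, p ~ 0.0742
    res = paired_method_comparison([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
    assert res.t_statistic == pytest.approx(2 * np.sqrt(3), rel=1e-9)
    assert res.df == 2
    assert res.p_value == pytest.approx(0.0742, abs=0.0005)


def test_paired_single_pair_raises():
    with pytest.raises(ValueError):
        paired_method_comparison([1.0], [0.0])


def test_paired_zero_variance_nonzero_mean_is_degenerate():
    res = paired_method_comparison([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
    assert res.degenerate
    assert res.p_value == 0.0


def test_homogeneity_identical_rows():
    res = subject_homogeneity(np.array([[10, 20, 30]] * 4))
    assert res.chi2 == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 6


def test_homogeneity_2x2_closed_form():
    res = subject_homogeneity(np.array([[10, 0], [0, 10]]))
    assert res.chi2 == pytest.approx(20.0)  # no continuity correction
    assert res.p_value == pytest.approx(sps.chi2.sf(20.0, 1), rel=1e-6)


def test_homogeneity_single_subject_raises():
    with pytest.raises(ValueError):
        subject_homogeneity(np.array([[5, 5, 5]]))


def test_homogeneity_drops_zero_rows_with_warning():
    with pytest.warns(UserWarning, match="zero"):
        res = subject_homogeneity(np.array([[5, 5], [0, 0], [6, 4]]))
    assert res.n_subjects == 2
    assert res.dropped_rows == (1,)
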