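"""Multiplicative binomial distribution: exactness against enumeration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mbndiallel import (
    MbnParams,
    mbn_log_pmf,
    mbn_mean_var,
    mbn_normalizer,
    mbn_pmf_vector,
    mbn_sample,
    mbn_success_prob,
)


def enum_pmf(nb: int, phi: float, theta: float) -> np.ndarray:
    """Independent brute-force pmf via direct summation (no log tricks)."""
    x = np.arange(nb + 1)
    w = np.array(
        [math.comb(nb, int(j)) * phi**j * (1 - phi) ** (nb - j) * theta ** (j * (nb - j)) for j in x]
    )
    return w / w.sum()


@pytest.mark.parametrize(
    "x, nb, phi, theta, expected",
    [
        (1, 2, 0.5, 1.0, math.log(0.5)),
        (0, 5, 0.2, 1.0, 5 * math.log(0.8)),
        (1, 2, 0.5, 0.9, math.log(0.45 / 0.95)),
    ],
)
def test_log_pmf_hand_values(x, nb, phi, theta, expected):
    assert mbn_log_pmf(x, MbnParams(nb, phi, theta)) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "nb, phi, theta, a, expected",
    [
        (2, 0.5, 0.9, 0, 0.95),
        (2, 0.5, 0.9, 1, 0.95),  # 0.5*0.9 + 0.5*1
        (7, 0.3, 1.0, 0, 1.0),
    ],
)
def test_normalizer(nb, phi, theta, a, expected):
    assert mbn_normalizer(MbnParams(nb, phi, theta), a) == pytest.approx(expected, rel=1e-12)


def test_normalization_and_binomial_reduction_on_grid():
    for nb in (0, 1, 3, 10, 30):
        for phi in (0.05, 0.25, 0.5, 0.75, 0.95):
            for theta in (0.5, 0.8, 1.0, 1.3, 2.0):
                params = MbnParams(nb, phi, theta)
                pmf = mbn_pmf_vector(params)
                assert abs(pmf.sum() - 1.0) < 1e-12
                if theta == 1.0:
                    ref = stats.binom.pmf(np.arange(nb + 1), nb, phi)
                    assert np.abs(pmf - ref).max() < 1e-12


def test_success_prob_equals_enumeration_mean():
    for nb in (1, 2, 3, 10, 25):
        for phi in (0.05, 0.3, 0.5, 0.9):
            for theta in (0.6, 0.82, 1.0, 1.5):
                params = MbnParams(nb, phi, theta)
                pmf = enum_pmf(nb, phi, theta)
                expected = float(pmf @ np.arange(nb + 1)) / nb
                assert mbn_success_prob(params) == pytest.approx(expected, rel=1e-12)


def test_success_prob_hand_values():
    assert mbn_success_prob(MbnParams(10, 0.25, 1.0)) == pytest.approx(0.25, rel=1e-12)
    assert mbn_success_prob(MbnParams(2, 0.5, 0.9)) == pytest.approx(0.5, rel=1e-12)


def test_dispersion_direction_at_matched_success_prob():
    """theta < 1 inflates and theta > 1 shrinks the variance at matched p, nb=10."""
    from scipy.optimize import brentq

    nb = 10
    for theta, comparison in ((0.90, np.greater), (1.10, np.less)):
        for p_target in (0.25, 0.5):
            phi = brentq(
                lambda f: mbn_success_prob(MbnParams(nb, f, theta)) - p_target, 1e-6, 1 - 1e-6
            )
            _, var = mbn_mean_var(MbnParams(nb, phi, theta))
            assert comparison(var, nb * p_target * (1 - p_target))


@given(
    nb=st.integers(0, 30),
    phi=st.floats(0.01, 0.99),
    theta=st.floats(0.5, 2.0),
)
@settings(max_examples=80, deadline=None, derandomize=True)
def test_pmf_properties_hold_everywhere(nb, phi, theta):
    """Normalization, support bounds and mean/success-prob consistency."""
    params = MbnParams(nb, phi, theta)
    pmf = mbn_pmf_vector(params)
    assert abs(pmf.sum() - 1.0) < 1e-10
    assert np.all(pmf >= 0)
    if nb >= 1:
        p = mbn_success_prob(params)
        assert 0 < p < 1
        mean, var = mbn_mean_var(params)
        assert mean == pytest.approx(nb * p, rel=1e-9)
        assert 0 <= var <= nb**2


def test_domain_errors():
    with pytest.raises(ValueError):
        mbn_log_pmf(3, MbnParams(2, 0.5, 0.9))
    with pytest.raises(ValueError):
        mbn_log_pmf(-1, MbnParams(2, 0.5, 0.9))
    with pytest.raises(ValueError):
        MbnParams(2, 1.5, 0.9)
    with pytest.raises(ValueError):
        MbnParams(2, 0.5, -1.0)
    with pytest.raises(ValueError):
        mbn_normalizer(MbnParams(2, 0.5, 0.9), a=2)
    with pytest.raises(ValueError):
        mbn_success_prob(MbnParams(0, 0.5, 0.9))


def test_sampling_matches_pmf_and_is_reproducible():
    params = MbnParams(2, 0.5, 0.9)
    n = 10**6
    draws = mbn_sample(params, rng=np.random.default_rng(42), size=n)
    freq = np.bincount(draws, minlength=3) / n
    expected = np.array([0.25, 0.45, 0.25]) / 0.95
    se = np.sqrt(expected * (1 - expected) / n)
    assert np.all(np.abs(freq - expected) < 4 * se)
    # degenerate litter and reproducibility
    assert mbn_sample(MbnParams(0, 0.5, 0.9), rng=1) == 0
    a = mbn_sample(params, rng=np.random.default_rng(7), size=100)
    b = mbn_sample(params, rng=np.random.default_rng(7), size=100)
    assert np.array_equal(a, b)
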