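"""Unit and property tests for the shrinkage (threshold) functions.

The frozen expected values were computed with an independent
arbitrary-precision evaluation of the printed formulas (mpmath, 30 digits);
one test re-derives them through that oracle to keep the route honest.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waveshrink import (
    FAMILIES,
    ShrinkageSpec,
    apply_shrinkage,
    s_core,
    shrink_adaptive_hard,
    shrink_adaptive_soft,
    shrink_aggd,
    shrink_hard,
    shrink_improved_aggd,
    shrink_soft,
    shrink_zhang_hard,
    shrink_zhang_soft,
    solve_aggd_threshold,
)

# mpmath oracle outputs, 30 significant digits, frozen:
S_CORE_1_1 = 1.14872127070012814684865078781      # e^{1/2} - 1/2
ZHANG_SOFT_1_1_1 = 0.381966011250105151795413165634  # 1 + (1 - sqrt(5))/2
ADAPT_1_1 = 0.648721270700128146848650787814     # e^{1/2} - 1
ADAPT_SOFT_3_1 = 2.64872127070012814684865078781  # 3 - (1 - (e^{1/2}-1))
TSTAR_1 = 1.28588870250989357038918633693         # root of e^{u^2/2}-1 = u
IAGGD_10_1 = 10.6413021052232648300140316854      # sigmoid(10-t*)*10 + t*/2


def test_frozen_constants_match_arbitrary_precision_oracle():
    """Re-derive every frozen constant with mpmath, independent of the package."""
    import mpmath as mp

    mp.mp.dps = 30
    assert float(mp.e**0.5 - 0.5) == pytest.approx(S_CORE_1_1, abs=1e-15)
    assert float(1 + (mp.sqrt(1) - mp.sqrt(5)) / 2) == pytest.approx(
        ZHANG_SOFT_1_1_1, abs=1e-15)
    assert float(mp.e**0.5 - 1) == pytest.approx(ADAPT_1_1, abs=1e-15)
    t = mp.findroot(lambda u: mp.expm1(u * u / 2) - u, mp.mpf("1.3"))
    assert float(t) == pytest.approx(TSTAR_1, abs=1e-15)
    val = (1 / (1 + mp.exp(-(10 - t)))) * 10 + t / 2
    assert float(val) == pytest.approx(IAGGD_10_1, abs=1e-12)


@pytest.mark.parametrize("x, sigma, expected", [
    (0.0, 1.0, 0.5),       # s(0) = sigma/2
    (0.0, 2.0, 1.0),
    (1.0, 1.0, S_CORE_1_1),
    (-1.0, 1.0, S_CORE_1_1),  # even in x
])
def test_s_core_values(x, sigma, expected):
    assert s_core(x, sigma) == pytest.approx(expected, abs=1e-12)


def test_s_core_rejects_bad_parameters():
    with pytest.raises(ValueError):
        s_core(1.0, 0.0)
    with pytest.raises(ValueError):
        s_core(np.nan, 1.0)


@pytest.mark.parametrize("func, args, x, expected", [
    (shrink_hard, dict(t=1), 3.0, 3.0),
    (shrink_hard, dict(t=1), 0.5, 0.0),
    (shrink_hard, dict(t=1), -3.0, -3.0),
    (shrink_soft, dict(t=1), 3.0, 2.0),
    (shrink_soft, dict(t=1), -0.5, 0.0),
    (shrink_soft, dict(t=1), -3.0, -2.0),
    (shrink_zhang_soft, dict(t=1, lam=0), 3.0, 2.0),
    (shrink_zhang_soft, dict(t=1, lam=0.5), 0.0, 0.0),
    (shrink_zhang_soft, dict(t=1, lam=1), 1.0, ZHANG_SOFT_1_1_1),
    (shrink_zhang_hard, dict(t=1, mu=0.1), 0.0, 0.0),
    (shrink_zhang_hard, dict(t=1, mu=0.1), 100.0, 100.0),
    (shrink_zhang_hard, dict(t=1, mu=0.01), 0.5, 0.0),
    (shrink_adaptive_hard, dict(sigma_n=1), 0.0, 0.0),
    (shrink_adaptive_hard, dict(sigma_n=1), 2.0, 2.0),
    (shrink_adaptive_hard, dict(sigma_n=1), 1.0, ADAPT_1_1),
    (shrink_adaptive_soft, dict(sigma_n=1), 0.0, 0.0),
    (shrink_adaptive_soft, dict(sigma_n=1), 1.0, ADAPT_1_1),
    (shrink_adaptive_soft, dict(sigma_n=1), 3.0, ADAPT_SOFT_3_1),
    (shrink_aggd, dict(sigma_n=1, t=TSTAR_1), 0.0, 0.0),
    (shrink_aggd, dict(sigma_n=1, t=TSTAR_1), 5.0, 5.0),
    (shrink_aggd, dict(sigma_n=1, t=TSTAR_1), 1.0, ADAPT_1_1),
    (shrink_improved_aggd, dict(sigma_n=1, t=TSTAR_1), 0.0, 0.0),
    (shrink_improved_aggd, dict(sigma_n=1, t=TSTAR_1), TSTAR_1, TSTAR_1),
    (shrink_improved_aggd, dict(sigma_n=1, t=TSTAR_1), 10.0, IAGGD_10_1),
])
def test_pointwise_values(func, args, x, expected):
    assert func(x, **args) == pytest.approx(expected, abs=1e-9)


def test_zhang_hard_overflow_safe():
    """Huge |x +- t| / mu must not overflow the sigmoids."""
    with np.errstate(over="raise"):
        assert shrink_zhang_hard(1e6, t=1, mu=1e-3) == pytest.approx(1e6)
        assert shrink_zhang_hard(-1e6, t=1, mu=1e-3) == pytest.approx(-1e6)


def test_improved_aggd_overflow_safe():
    with np.errstate(over="raise"):
        out = shrink_improved_aggd(1e4, sigma_n=1.0, t=TSTAR_1)
    assert out == pytest.approx(1e4 + TSTAR_1 / 2, rel=1e-12)


def _eval(family, x, t, sigma):
    if family == "hard":
        return shrink_hard(x, t)
    if family == "soft":
        return shrink_soft(x, t)
    if family == "zhang_soft":
        return shrink_zhang_soft(x, t, lam=0.1)
    if family == "zhang_hard":
        return shrink_zhang_hard(x, t, mu=0.05)
    if family == "adaptive_hard":
        return shrink_adaptive_hard(x, sigma)
    if family == "adaptive_soft":
        return shrink_adaptive_soft(x, sigma)
    if family == "aggd":
        return shrink_aggd(x, sigma, t)
    return shrink_improved_aggd(x, sigma, t)


@pytest.mark.parametrize("family", FAMILIES)
def test_odd_symmetry(family):
    """eta(-x) = -eta(x) for every family on a wide grid."""
    sigma = 1.0
    t = solve_aggd_threshold(sigma) if family in ("aggd", "improved_aggd") \
        else sigma
    x = np.linspace(0.0, 10 * t, 4001)
    np.testing.assert_allclose(_eval(family, -x, t, sigma),
                               -_eval(family, x, t, sigma), atol=1e-12)


@pytest.mark.parametrize("family", ["soft", "zhang_soft", "zhang_hard",
                                    "adaptive_soft", "aggd", "improved_aggd"])
def test_soft_type_families_are_continuous(family):
    """Adjacent-value jumps vanish with the grid spacing (continuity)."""
    sigma = 1.0
    t = solve_aggd_threshold(sigma) if family in ("aggd", "improved_aggd") \
        else sigma
    x = np.linspace(-3 * t, 3 * t, 1_000_001)
    y = _eval(family, x, t, sigma)
    spacing = x[1] - x[0]
    # local slope never exceeds ~ max(1, s'(t)) ~ 3 for these parameters
    assert np.max(np.abs(np.diff(y))) < 10 * spacing * 5.0


@pytest.mark.parametrize("family", ["hard", "adaptive_hard"])
def test_hard_type_families_jump_at_threshold(family):
    """Hard-type rules have a genuine jump of size t - eta(t-) at |x| = t."""
    sigma = t = 1.0
    eps = 1e-9
    below = _eval(family, t - eps, t, sigma)
    above = _eval(family, t + eps, t, sigma)
    assert above - below > 0.3  # hard: jump = 1; adaptive_hard: 1 - 0.6487


def test_zhang_soft_lambda_zero_equals_soft():
    x = np.linspace(-10, 10, 20001)
    np.testing.assert_allclose(shrink_zhang_soft(x, t=1.5, lam=0.0),
                               shrink_soft(x, t=1.5), atol=1e-12)


def test_zhang_hard_mu_to_zero_converges_to_hard():
    x = np.array([-5.0, -2.0, -0.9, -0.3, 0.4, 0.99, 1.01, 3.0])
    np.testing.assert_allclose(shrink_zhang_hard(x, t=1.0, mu=1e-6),
                               shrink_hard(x, t=1.0), atol=1e-9)


@pytest.mark.parametrize("family", ["hard", "adaptive_hard", "aggd"])
def test_identity_tail_is_exact(family):
    sigma = 1.0
    t = solve_aggd_threshold(sigma) if family == "aggd" else sigma
    x = np.linspace(t * (1 + 1e-9), 10 * t, 1001)
    np.testing.assert_array_equal(_eval(family, x, t, sigma), x)


@pytest.mark.parametrize("family", ["adaptive_hard", "adaptive_soft",
                                    "aggd", "improved_aggd"])
def test_kill_zone_tunes_instead_of_zeroing(family):
    """Inside |x| <= t the adaptive rules attenuate but never zero x != 0."""
    sigma = 1.0
    t = solve_aggd_threshold(sigma) if family in ("aggd", "improved_aggd") \
        else sigma
    x = np.linspace(1e-3, t, 500)
    y = np.asarray(_eval(family, x, t, sigma))
    bound = s_core(t, sigma) - s_core(0.0, sigma)
    assert np.all(np.abs(y) <= bound + 1e-12)
    assert np.all(y != 0.0)
    # contrast: the standard rules kill this zone entirely
    np.testing.assert_array_equal(shrink_hard(x, t), np.zeros_like(x))
    np.testing.assert_array_equal(shrink_soft(x, t), np.zeros_like(x))


@given(st.floats(-50, 50), st.floats(0.1, 5), st.floats(0, 2))
@settings(deadline=None, max_examples=200, derandomize=True)
def test_zhang_soft_monotone_between_soft_and_identity(x, t, lam):
    """Zhang soft lies between the soft rule and the identity, odd in x."""
    y = shrink_zhang_soft(x, t, lam)
    lo, hi = sorted((shrink_soft(x, t), float(x)))
    assert lo - 1e-9 <= y <= hi + 1e-9
    assert shrink_zhang_soft(-x, t, lam) == pytest.approx(-y, abs=1e-9)


class TestApplyShrinkage:
    def test_elementwise_soft(self):
        spec = ShrinkageSpec("soft", t=1.0)
        np.testing.assert_allclose(apply_shrinkage([3.0, 0.5, -3.0], spec),
                                   [2.0, 0.0, -2.0])

    def test_empty_array(self):
        assert apply_shrinkage([], ShrinkageSpec("hard", t=1.0)).size == 0

    def test_adaptive_hard_mixed(self):
        spec = ShrinkageSpec("adaptive_hard", t=1.0, sigma_n=1.0)
        np.testing.assert_allclose(apply_shrinkage([1.0, 2.0], spec),
                                   [ADAPT_1_1, 2.0], atol=1e-12)

    def test_input_not_mutated_and_shape_preserved(self, rng):
        arr = rng.normal(size=(7, 5))
        before = arr.copy()
        spec = ShrinkageSpec("improved_aggd", t=TSTAR_1, sigma_n=1.0)
        out = apply_shrinkage(arr, spec)
        np.testing.assert_array_equal(arr, before)
        assert out.shape == arr.shape

    def test_degenerate_spec_is_identity(self, rng):
        arr = rng.normal(size=20)
        spec = ShrinkageSpec("adaptive_soft", t=0.0, sigma_n=0.0)
        np.testing.assert_array_equal(apply_shrinkage(arr, spec), arr)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ShrinkageSpec("wiener", t=1.0)


class TestSpecValidation:
    def test_adaptive_requires_t_equal_sigma(self):
        with pytest.raises(ValueError, match="t == sigma_n"):
            ShrinkageSpec("adaptive_soft", t=2.0, sigma_n=1.0)

    def test_aggd_requires_t_at_least_sigma(self):
        with pytest.raises(ValueError, match="t >= sigma_n"):
            ShrinkageSpec("aggd", t=0.5, sigma_n=1.0)

    def test_shape_params_only_for_zhang(self):
        with pytest.raises(ValueError):
            ShrinkageSpec("soft", t=1.0, lam=0.1)
        with pytest.raises(ValueError):
            ShrinkageSpec("zhang_soft", t=1.0)  # missing lam
        with pytest.raises(ValueError):
            ShrinkageSpec("zhang_hard", t=1.0, mu=0.0)
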