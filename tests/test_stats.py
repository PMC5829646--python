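import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.special import kolmogorov as scipy_kolmogorov
from statsmodels.stats.proportion import proportions_ztest

from admitleak import bonferroni, format_p, kolmogorov_sf, ks_two_sample, prop_two_sample


def brute_force_D(x, y):
    """Independent oracle: maximize |F1(t) - F2(t)| over the pooled support."""
    x, y = list(x), list(y)
    best = 0.0
    for t in sorted(set(x) | set(y)):
        f1 = sum(v <= t for v in x) / len(x)
        f2 = sum(v <= t for v in y) / len(y)
        best = max(best, abs(f1 - f2))
    return best


# --- KS statistic ----------------------------------------------------------

def test_identical_samples_give_zero_D_and_p_one():
    res = ks_two_sample([0, 1, 1, 3], [0, 1, 1, 3])
    assert res.D == 0.0
    assert res.p_value == 1.0


def test_small_example_matches_hand_computation():
    # F1 jumps to 2/3 at 0 while F2 is 0 there; at 1 the gap is 1 - 1/3.
    res = ks_two_sample([0, 0, 1], [1, 2, 3])
    assert res.D == pytest.approx(2 / 3)


def test_disjoint_supports_give_D_one():
    res = ks_two_sample([0] * 5, [1] * 5)
    assert res.D == 1.0


def test_ks_symmetry():
    rng = np.random.default_rng(0)
    x, y = rng.integers(0, 10, 40), rng.integers(0, 6, 25)
    assert ks_two_sample(x, y).D == ks_two_sample(y, x).D


def test_empty_sample_raises():
    with pytest.raises(ValueError):
        ks_two_sample([], [1])


@settings(max_examples=150, derandomize=True)
@given(
    st.lists(st.integers(0, 3), min_size=1, max_size=8),
    st.lists(st.integers(0, 3), min_size=1, max_size=8),
)
def test_D_equals_bruteforce_on_small_multisets(x, y):
    assert ks_two_sample(x, y).D == pytest.approx(brute_force_D(x, y), abs=1e-12)


def test_matches_scipy_reference():
    """Independent cross-check: D against scipy's two-sample KS and the
    p-value against the limiting Kolmogorov distribution (kstwobign) at
    effective size n1*n2/(n1+n2)."""
    rng = np.random.default_rng(3)
    for n1, n2 in [(30, 40), (200, 150), (500, 500)]:
        x = rng.geometric(0.3, n1)
        y = rng.geometric(0.25, n2)
        ours = ks_two_sample(x, y)
        ref = sps.ks_2samp(x, y, method="asymp")
        assert ours.D == pytest.approx(ref.statistic, abs=1e-12)
        en = math.sqrt(n1 * n2 / (n1 + n2))
        assert ours.p_value == pytest.approx(
            float(sps.kstwobign.sf(en * ours.D)), rel=1e-9, abs=1e-12
        )


def test_matches_r_ks_test_asymptotic():
    """Independent oracle: R's ks.test in its asymptotic (large-sample)
    regime agrees on D and p."""
    rng = np.random.default_rng(44)
    x = rng.geometric(0.2, 500)
    y = rng.geometric(0.25, 480)
    ours = ks_two_sample(x, y)
    script = (
        "x <- c(%s); y <- c(%s); "
        "r <- suppressWarnings(ks.test(x, y)); "
        "cat(sprintf('%%.12g %%.12g', r$statistic, r$p.value))"
        % (",".join(map(str, x)), ",".join(map(str, y)))
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    d_ref, p_ref = map(float, out.stdout.split())
    assert ours.D == pytest.approx(d_ref, abs=1e-10)
    assert ours.p_value == pytest.approx(p_ref, rel=1e-6)


def test_kolmogorov_sf_matches_scipy_special():
    for x in np.linspace(0.0, 3.0, 61):
        assert kolmogorov_sf(float(x)) == pytest.approx(float(scipy_kolmogorov(x)), abs=1e-10)


def test_null_calibration_on_continuous_data():
    """On tie-free samples the asymptotic p-value is well calibrated: the
    rejection rate at alpha=0.05 over 4,000 null pairs of n=500 sits near the
    nominal level. (Heavily tied integer offsets make the same test
    conservative; see the discrete-law calibration check in the acceptance
    suite.)"""
    rng = np.random.default_rng(12)
    n, rejected, trials = 500, 0, 4000
    for _ in range(trials):
        res = ks_two_sample(rng.random(n), rng.random(n))
        rejected += res.p_value < 0.05
    assert 0.04 <= rejected / trials <= 0.065


# --- proportion test -------------------------------------------------------

def test_equal_proportions_give_zero_z():
    res = prop_two_sample(30, 100, 15, 50)
    assert res.z == 0.0
    assert res.p_value == 1.0


def test_pooled_z_closed_form():
    # direct evaluation: z = 0.25 / sqrt(0.375*0.625*(1/100+1/100))
    res = prop_two_sample(50, 100, 25, 100)
    assert res.z == pytest.approx(3.6514837167011076, abs=1e-12)
    assert res.p_value == pytest.approx(2.607296328553168e-4, rel=1e-12)


def test_continuity_corrected_variant():
    res = prop_two_sample(50, 100, 25, 100, continuity_correction=True)
    assert res.z == pytest.approx(3.5054243680330632, abs=1e-12)
    assert res.p_value == pytest.approx(4.558800052056136e-4, rel=1e-12)


def test_degenerate_pooled_proportions():
    for x in (0, 10):
        res = prop_two_sample(x, 10, x, 10)
        assert res.degenerate and res.p_value == 1.0


def test_antisymmetric_under_argument_swap():
    a = prop_two_sample(40, 90, 20, 80)
    b = prop_two_sample(20, 80, 40, 90)
    assert a.z == pytest.approx(-b.z)
    assert a.p_value == pytest.approx(b.p_value)


@pytest.mark.parametrize("x1,n1,x2,n2", [(50, 100, 25, 100), (10, 30, 22, 40), (1, 50, 4, 60)])
def test_matches_statsmodels_pooled_ztest(x1, n1, x2, n2):
    ours = prop_two_sample(x1, n1, x2, n2)
    z_ref, p_ref = proportions_ztest([x1, x2], [n1, n2])
    assert ours.z == pytest.approx(z_ref, abs=1e-10)
    assert ours.p_value == pytest.approx(p_ref, rel=1e-9)


def test_invalid_counts_raise():
    with pytest.raises(ValueError):
        prop_two_sample(5, 0, 1, 10)
    with pytest.raises(ValueError):
        prop_two_sample(11, 10, 1, 10)


# --- bonferroni ------------------------------------------------------------

def test_bonferroni_published_worked_value():
    assert bonferroni([0.007], m=15) == [0.105]


def test_bonferroni_caps_at_one_and_fixes_zero():
    assert bonferroni([0.5, 0.0], m=15) == [1.0, 0.0]


def test_bonferroni_m_defaults_to_count_and_validates():
    assert bonferroni([0.01, 0.02]) == [0.02, 0.04]
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2, 0.3], m=2)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(0, 1), max_size=10), st.integers(0, 50))
def test_bonferroni_monotone_cap_property(ps, extra):
    m = len(ps) + extra
    out = bonferroni(ps, m=m)
    for p, q in zip(ps, out):
        assert p <= q <= 1.0


# --- display ---------------------------------------------------------------

def test_p_value_floor_display():
    assert format_p(1e-20) == "< 2.2e-16"
    assert format_p(0.0137) == "0.0137"
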