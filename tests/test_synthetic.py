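"""Generators: exact identities, determinism, and distributional sanity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndviscaling.series import SLOTS_PER_YEAR
from ndviscaling.synthetic import (
    SimSpec,
    SimSpecError,
    cascade_h_theory,
    fgn_autocovariance,
    gen_binomial_cascade,
    gen_brownian,
    gen_fgn,
    gen_ndvi_like,
    generate,
)


def brute_cascade(p, levels):
    """Binary-expansion oracle for the binomial measure."""
    out = []
    for k in range(2**levels):
        ones = bin(k).count("1")
        out.append(p**ones * (1 - p) ** (levels - ones))
    return np.asarray(out)


class TestBrownian:
    def test_cumulative_sum_identity_via_hook(self):
        s = gen_brownian(SimSpec(generator="brownian", n_points=4), increments=[1, 1, 1, 1])
        assert np.array_equal(s.values, [1, 2, 3, 4])

    def test_increment_moments_over_seeds(self):
        means, variances = [], []
        for seed in range(20):
            x = gen_brownian(SimSpec(generator="brownian", n_points=8192, seed=seed)).values
            inc = np.diff(x, prepend=0.0)
            means.append(inc.mean())
            variances.append(inc.var(ddof=1))
        n_tot = 20 * 8192
        assert abs(np.mean(means)) < 5 / np.sqrt(n_tot)          # s.e. of the mean
        assert abs(np.mean(variances) - 1) < 5 * np.sqrt(2 / n_tot)  # s.e. of the variance

    def test_short_series_rejected(self):
        with pytest.raises(SimSpecError):
            gen_brownian(SimSpec(generator="brownian", n_points=8))


@pytest.mark.parametrize("generator", ["white_noise", "brownian", "fgn", "binomial_cascade", "ndvi_like"])
def test_identical_spec_gives_bit_identical_output(generator):
    spec = SimSpec(generator=generator, n_points=256, seed=42, cascade_levels=8)
    a, b = generate(spec), generate(spec)
    assert np.array_equal(a.values, b.values)
    assert np.array_equal(a.missing_mask, b.missing_mask)


class TestFgn:
    @pytest.mark.parametrize("hurst, rho1", [(0.5, 0.0), (0.8, 2**0.6 - 1), (0.2, 2**-0.6 - 1)])
    def test_lag1_autocorrelation_matches_closed_form(self, hurst, rho1):
        x = gen_fgn(SimSpec(generator="fgn", n_points=4096, hurst=hurst, seed=3)).values
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(rho1, abs=0.05)
        assert fgn_autocovariance(1, hurst) == pytest.approx(rho1, abs=1e-12)

    def test_unit_variance_across_seeds(self):
        v = [gen_fgn(SimSpec(generator="fgn", n_points=4096, hurst=0.7, seed=s)).values.var(ddof=1)
             for s in range(20)]
        # fGn(0.7) samples are correlated, so allow a generous 5-sigma band
        assert abs(np.mean(v) - 1.0) < 5 * np.std(v) / np.sqrt(len(v)) + 0.02

    @pytest.mark.parametrize("hurst", [-0.1, 0.0, 1.0, 1.3])
    def test_hurst_outside_unit_interval_rejected(self, hurst):
        with pytest.raises(SimSpecError):
            gen_fgn(SimSpec(generator="fgn", n_points=64, hurst=hurst))


class TestCascade:
    def test_oracle_values_and_small_case_products(self):
        # measure values at two binary levels, by direct product expansion
        assert np.allclose(brute_cascade(0.3, 2), [0.49, 0.21, 0.21, 0.09])
        for levels in (4, 6):
            s = gen_binomial_cascade(
                SimSpec(generator="binomial_cascade", cascade_p=0.3, cascade_levels=levels)
            )
            assert np.allclose(s.values, brute_cascade(0.3, levels), atol=1e-15)

    @given(p=st.floats(0.05, 0.95), levels=st.integers(4, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_measure_sums_to_one_and_reversal_symmetry(self, p, levels):
        a = gen_binomial_cascade(SimSpec(generator="binomial_cascade", cascade_p=p, cascade_levels=levels))
        b = gen_binomial_cascade(SimSpec(generator="binomial_cascade", cascade_p=1 - p, cascade_levels=levels))
        assert a.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(np.sort(a.values), np.sort(b.values))

    def test_p_half_is_uniform(self):
        s = gen_binomial_cascade(SimSpec(generator="binomial_cascade", cascade_p=0.5, cascade_levels=6))
        assert np.allclose(s.values, 2.0**-6)

    def test_too_few_levels_rejected(self):
        with pytest.raises(SimSpecError):
            gen_binomial_cascade(SimSpec(generator="binomial_cascade", cascade_levels=3))


class TestCascadeTheory:
    def test_monofractal_limit_is_q_independent(self):
        vals = [cascade_h_theory(q, 0.5) for q in (0.25, 1, 2, 4)]
        assert np.allclose(vals, 1.0)

    def test_known_points(self):
        assert cascade_h_theory(1, 0.3) == pytest.approx(1.0, abs=1e-12)
        # frozen from independent high-precision arithmetic
        assert cascade_h_theory(4, 0.3) == pytest.approx(0.7526062448548, abs=1e-10)

    def test_q_zero_is_domain_error(self):
        with pytest.raises(ValueError):
            cascade_h_theory(0.0, 0.3)


class TestNdviLike:
    def test_no_gaps_when_gap_fraction_zero(self):
        s = gen_ndvi_like(SimSpec(seed=1, gap_fraction=0.0))
        assert s.n_missing == 0

    def test_pure_trend_is_nondecreasing(self):
        s = gen_ndvi_like(SimSpec(seed=1, trend_slope=0.01, noise_sd=0.0,
                                  seasonal_amplitude=0.0, changepoint_shift=0.0,
                                  gap_fraction=0.0))
        assert np.all(np.diff(s.values) >= 0)

    def test_default_length_is_18_years_of_46(self):
        s = gen_ndvi_like(SimSpec(seed=0))
        assert len(s) == 18 * SLOTS_PER_YEAR == 828

    def test_values_on_ndvi_scale_and_gap_count(self):
        s = gen_ndvi_like(SimSpec(seed=2, gap_fraction=0.01))
        assert np.all((s.values >= 0) & (s.values <= 100))
        assert s.n_missing == round(0.01 * 828)

    def test_changepoint_outside_series_rejected(self):
        with pytest.raises(SimSpecError):
            gen_ndvi_like(SimSpec(changepoint_index=900))
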