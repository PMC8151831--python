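"""NDVI construction, gap filling, smoothing and anomaly."""

import numpy as np
import pytest
from fractions import Fraction

from ndviscaling.preprocessing import (
    PreprocessingError,
    ReflectancePair,
    compute_anomaly,
    compute_ndvi,
    fill_gaps,
    preprocess,
    savgol_smooth,
)
from ndviscaling.series import EvenSeries, SeriesError
from ndviscaling.synthetic import SimSpec, gen_ndvi_like


def make_series(values, missing=None):
    return EvenSeries.from_values(np.asarray(values, float), missing_mask=missing)


class TestComputeNdvi:
    @pytest.mark.parametrize("nir, red, expected", [
        (0.5, 0.25, 100 * 0.25 / 0.75),
        (0.4, 0.4, 0.0),
        (0.6, 0.0, 100.0),
    ])
    def test_formula(self, nir, red, expected):
        pair = ReflectancePair(red=[red] * 16, nir=[nir] * 16, quality_ok=[True] * 16)
        s = compute_ndvi(pair)
        assert s.values[0] == pytest.approx(expected, abs=1e-9)

    def test_bad_quality_becomes_missing(self):
        ok = np.ones(16, bool)
        ok[5] = False
        pair = ReflectancePair(red=np.full(16, 0.2), nir=np.full(16, 0.5), quality_ok=ok)
        s = compute_ndvi(pair)
        assert s.missing_mask[5] and s.n_missing == 1

    def test_zero_total_reflectance_rejected(self):
        red = np.full(16, 0.2)
        nir = np.full(16, 0.5)
        red[3] = nir[3] = 0.0
        with pytest.raises(PreprocessingError, match="position 3"):
            compute_ndvi(ReflectancePair(red=red, nir=nir, quality_ok=np.ones(16, bool)))

    def test_range_bounds_for_nonnegative_reflectance(self):
        rng = np.random.default_rng(0)
        red, nir = rng.uniform(0.001, 1, 64), rng.uniform(0.001, 1, 64)
        s = compute_ndvi(ReflectancePair(red=red, nir=nir, quality_ok=np.ones(64, bool)))
        assert np.all((s.values >= -100) & (s.values <= 100))


class TestFillGaps:
    def test_two_neighbour_mean(self):
        s = make_series([1, np.nan, 3])
        assert np.allclose(fill_gaps(s).values, [1, 2, 3])

    def test_identity_without_gaps(self):
        s = make_series([5.0, 6.0, 7.0, 8.0])
        assert np.array_equal(fill_gaps(s).values, s.values)

    def test_double_gap_windowed_mean(self):
        s = make_series([10, 10, np.nan, np.nan, 10, 10])
        out = fill_gaps(s)
        assert np.allclose(out.values, 10.0) and out.n_missing == 0

    def test_iterative_fill_uses_previous_pass(self):
        # positions 4..6 missing; 6 is beyond the first pass's reach from the right alone
        vals = np.array([1.0] * 4 + [np.nan] * 3 + [8.0] * 4)
        out = fill_gaps(vals_series := make_series(vals))
        assert out.n_missing == 0
        assert vals_series.n_missing == 3  # input untouched

    def test_wide_gap_fills_iteratively_from_both_sides(self):
        # later passes reuse earlier fills, so a gap wider than the window closes
        vals = np.full(20, np.nan)
        vals[:4] = 1.0
        vals[-4:] = 2.0
        with pytest.warns(UserWarning, match="25%"):
            out = fill_gaps(make_series(vals))
        assert out.n_missing == 0
        assert np.all((out.values >= 1.0) & (out.values <= 2.0))

    def test_unfillable_gap_names_position(self):
        vals = np.full(20, np.nan)  # nothing to average from anywhere
        with pytest.warns(UserWarning, match="25%"):
            with pytest.raises(PreprocessingError, match="position 0"):
                fill_gaps(make_series(vals))

    def test_excessive_missing_fraction_warns(self):
        vals = np.arange(20.0)
        mask = np.zeros(20, bool)
        mask[::3] = True
        with pytest.warns(UserWarning, match="25%"):
            fill_gaps(make_series(vals, missing=mask))


def sg_center_weight_oracle(window=9, order=3):
    """Exact rational center weight of the SG smoother via least squares."""
    half = window // 2
    t = range(-half, half + 1)
    A = [[Fraction(x) ** k for k in range(order + 1)] for x in t]
    ata = [[sum(A[i][r] * A[i][c] for i in range(window)) for c in range(order + 1)]
           for r in range(order + 1)]
    e_center = [Fraction(1 if x == 0 else 0) for x in t]
    atb = [sum(A[i][r] * e_center[i] for i in range(window)) for r in range(order + 1)]
    # Gaussian elimination in exact rationals
    for i in range(order + 1):
        piv = ata[i][i]
        ata[i] = [v / piv for v in ata[i]]
        atb[i] /= piv
        for j in range(order + 1):
            if j != i:
                f = ata[j][i]
                ata[j] = [a - f * b for a, b in zip(ata[j], ata[i])]
                atb[j] -= f * atb[i]
    return float(atb[0])  # fitted value at the center = constant coefficient


class TestSavgolSmooth:
    def test_cubic_polynomial_reproduced(self):
        i = np.arange(40.0)
        vals = 0.001 * i**3 - 0.05 * i**2 + i + 2
        out = savgol_smooth(make_series(vals))
        assert np.allclose(out.values, vals, atol=1e-9)

    def test_constant_preserved(self):
        out = savgol_smooth(make_series(np.full(30, 7.0)))
        assert np.allclose(out.values, 7.0)

    def test_impulse_center_weight_matches_exact_least_squares(self):
        vals = np.zeros(21)
        vals[10] = 1.0
        out = savgol_smooth(make_series(vals), window=9, poly_order=3)
        assert out.values[10] == pytest.approx(sg_center_weight_oracle(9, 3), abs=1e-12)
        assert sg_center_weight_oracle(9, 3) == pytest.approx(59 / 231)

    def test_missing_values_enforce_pipeline_order(self):
        s = make_series([1, np.nan, 3, 4, 5, 6, 7, 8, 9, 10])
        with pytest.raises(SeriesError, match="gap"):
            savgol_smooth(s)


class TestComputeAnomaly:
    def test_periodic_series_gives_zero_anomaly(self):
        vals = np.tile(np.sin(np.arange(46) / 3.0) * 20 + 40, 4)
        out = compute_anomaly(make_series(vals))
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_two_year_slot_split(self):
        vals = np.concatenate([np.full(46, 10.0), np.full(46, 30.0)])
        out = compute_anomaly(make_series(vals))
        assert np.allclose(out.values[:46], -10) and np.allclose(out.values[46:], 10)

    def test_per_slot_means_zero_and_idempotent(self, ndvi_like_series):
        a1 = compute_anomaly(ndvi_like_series)
        for slot in range(1, 47):
            sel = a1.calendar_slot == slot
            assert abs(a1.values[sel].mean()) < 1e-12
        a2 = compute_anomaly(a1)
        assert np.allclose(a2.values, a1.values, atol=1e-9)

    def test_single_observation_slot_warns_and_zeroes(self):
        vals = np.arange(50.0)  # 46 + 4: slots 5..46 observed once
        with pytest.warns(UserWarning, match="once"):
            out = compute_anomaly(make_series(vals))
        assert out.values[10] == 0.0

    def test_seasonal_power_removed(self):
        s = gen_ndvi_like(SimSpec(seed=4, gap_fraction=0.0))
        _, anom = preprocess(s)

        def power_at_annual(v):
            f = np.fft.rfft(v - v.mean())
            freqs = np.fft.rfftfreq(len(v))
            return np.abs(f[np.argmin(np.abs(freqs - 1 / 46))]) ** 2

        assert power_at_annual(anom.values) < 0.05 * power_at_annual(s.values)
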