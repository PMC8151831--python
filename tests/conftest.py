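"""Shared fixtures and independently coded brute-force oracles."""

import numpy as np
import pytest

from ndviscaling.synthetic import SimSpec, generate


@pytest.fixture(scope="session")
def ndvi_like_series():
    """Default-condition NDVI-like series, gap-free, for downstream stages."""
    return generate(SimSpec(seed=11, gap_fraction=0.0))


@pytest.fixture(scope="session")
def cascade_series():
    """Binomial multiplicative cascade, p=0.3, 2**13 points."""
    return generate(SimSpec(generator="binomial_cascade", cascade_p=0.3, cascade_levels=13))


def brute_structure_moments(x, q_grid, lags):
    """Double-loop structure-function oracle (kept deliberately naive)."""
    x = np.asarray(x, float)
    out = np.empty((len(q_grid), len(lags)))
    for qi, q in enumerate(q_grid):
        for ti, tau in enumerate(lags):
            acc = [abs(x[i + tau] - x[i]) ** q for i in range(len(x) - tau)]
            out[qi, ti] = sum(acc) / len(acc)
    return out


def brute_mfdfa_fluct(x, q_grid, scales, order=1):
    """Double-loop MF-DFA oracle: explicit per-segment polynomial fits."""
    x = np.asarray(x, float)
    n = len(x)
    y = np.cumsum(x - x.mean())
    out = np.empty((len(q_grid), len(scales)))
    for si, s in enumerate(scales):
        ns = n // s
        f2 = []
        for start in [lambda v: v * s, lambda v: n - ns * s + v * s]:
            for v in range(ns):
                seg = y[start(v): start(v) + s]
                t = np.arange(s, dtype=float)
                coef = np.polynomial.polynomial.polyfit(t, seg, order)
                resid = seg - np.polynomial.polynomial.polyval(t, coef)
                f2.append(np.mean(resid**2))
        f2 = np.asarray(f2)
        for qi, q in enumerate(q_grid):
            out[qi, si] = np.mean(f2 ** (q / 2.0)) ** (1.0 / q)
    return out
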