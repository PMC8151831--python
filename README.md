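# ndviscaling

Scaling and multifractal analysis of vegetation-index time series.

Rangeland ecologists monitor vegetation with satellite indices such as
NDVI (Normalized Difference Vegetation Index). Beyond trends and
seasonal cycles, the *scaling* structure of an NDVI record — how the
moments of its fluctuations grow with time lag — carries information
about persistence and about the interplay of processes acting on
different time scales. This package implements that analysis chain for
regularly sampled (8-day composite, 46 samples/year) univariate series:

- **Preprocessing** — NDVI = 100·(NIR − RED)/(NIR + RED) with quality
  screening, centered 7-date running-average gap filling,
  Savitzky–Golay smoothing (window 9), and the calendar-slot anomaly
  NDVIa = NDVI − μ_NDVI (the across-years mean for the same composite
  date), which removes seasonality.
- **Trend tests** — Mann–Kendall monotonic trend and the Pettitt
  change-point test, implemented from first principles.
- **Corrected R/S Hurst index** — rescaled-range analysis
  R(τ)/S(τ) = c·τ^H over dyadic segment lengths with the Anis–Lloyd
  small-sample correction; H > 0.5 persistent, H < 0.5 antipersistent,
  H = 0.5 uncorrelated.
- **Generalized structure functions (GSF)** —
  M_q(τ) = ⟨|x(i+τ) − x(i)|^q⟩ ∝ τ^ζ(q), generalized Hurst exponents
  H(q) = ζ(q)/q, multifractality width ΔH = H(0.25) − H(4).
- **MF-DFA** — multifractal detrended fluctuation analysis:
  F_q(s) ∝ s^H(q) on the polynomially detrended integrated profile,
  ζ(q) = q·H(q), same ΔH; robust to the slow trends that bias the GSF.
- **Sources of multifractality** — ensembles of shuffled series
  (destroy temporal structure, keep the value distribution) and IAAFT
  surrogates (keep the spectrum and the exact amplitudes):
  Hcor = ΔH − mean ΔH_shuffle (long-range-correlation part) and
  Hpdf = ΔH − mean ΔH_surrogate (broad-distribution part).
- **Synthetic data** — exact fractional Gaussian noise (circulant
  embedding), Brownian motion, the binomial multiplicative cascade with
  closed-form H(q), and an NDVI-like generator (seasonality + trend +
  level shift + persistent noise + sparse gaps) that gives every
  estimator a ground-truth target.

See `docs/methods.md` for conventions, numerical choices and caveats.

## Worked example

Simulate an NDVI-like record, preprocess it, and compare the scaling of
the seasonal (NDVI) and deseasonalized (NDVIa) series:

```python
import numpy as np
from ndviscaling import SimSpec, generate
from ndviscaling.preprocessing import preprocess
from ndviscaling.rs_hurst import hurst_rs
from ndviscaling.mfdfa import MfdfaConfig, mfdfa_spectrum
from ndviscaling.sources import decompose_sources

series = generate(SimSpec(seed=11))          # 18 y x 46 composites
ndvi, ndvia = preprocess(series)             # gap fill, smooth, anomaly

print("HI (corrected R/S):", round(hurst_rs(ndvia).hurst, 3))
spec = mfdfa_spectrum(ndvia)                 # scales 32..512 days
print("MF-DFA H(2):", round(spec.h_at(2.0), 3), " DeltaH:", round(spec.delta_h, 3))
dec = decompose_sources(ndvia, config=MfdfaConfig(), seed=11)
print("Hcor:", round(dec.h_cor, 3), " Hpdf:", round(dec.h_pdf, 3))
```

prints

```
HI (corrected R/S): 0.804
MF-DFA H(2): 1.133  DeltaH: 0.107
Hcor: 0.017  Hpdf: -0.02
```

The anomaly series is persistent (HI ≈ 0.80, consistent with its H = 0.7
noise plus residual low-frequency structure), its multifractality width
is modest (ΔH ≈ 0.11), and the decomposition attributes essentially none
of it to a broad value distribution (Hpdf ≈ 0) — as expected for a
Gaussian-noise-driven simulation, where whatever width exists comes from
correlations, not from heavy tails.

The same stages are available as a CLI
(`ndviscaling simulate | preprocess | trend | hurst | gsf | mfdfa |
sources | run`), and `analysis/01_simulate_series.py` →
`02_run_pipeline.py` → `03_validate_estimators.py` run the whole chain
as a scripted analysis, writing tables under `results/`
(`trend_summary.csv`, `hurst_summary.csv`, `delta_h_summary.csv`,
`sources_summary.csv`, `spectra.csv`, `estimator_validation.csv`).

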