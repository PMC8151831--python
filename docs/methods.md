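# Methods

This package implements a scaling analysis chain for area-averaged
vegetation-index time series on the MODIS 8-day compositing calendar
(46 composites per year), together with a synthetic-data generator that
provides ground truth for every estimator. This note records the models,
the numerical choices, and what the synthetic conditions do and do not
establish about real satellite records.

## Series model and preprocessing

An `EvenSeries` holds values on a strict 46-slot annual calendar with an
explicit missing mask; quality screening marks samples missing rather
than deleting them, so downstream positions never shift.

**NDVI.** From RED/NIR surface reflectance, NDVI = 100·(NIR − RED)/(NIR +
RED), kept on the 0–100 scale. Samples not flagged ideal quality become
missing.

**Gap filling.** Each missing value is replaced by the mean of available
values in a centered 7-date window (3 dates each side). Passes repeat,
so later passes may average previously filled values; a value is
unfillable only when no pass can reach it. The phrase "running average
with an interval of seven dates" admits other readings (e.g. a maximum
gap length); the centered-window mean was chosen because it is
symmetric and order-independent. Missingness above 25% triggers a
warning — running means become unreliable there — but the operation
still proceeds, since the windowed mean remains well defined.

**Smoothing.** Savitzky–Golay least-squares polynomial smoothing,
window 9, default polynomial order 3 (the order is a config knob; 3 is
common practice for vegetation-index smoothing and reproduces cubic
segments exactly). Edges are fitted on truncated windows
(`scipy.signal.savgol_filter`, `mode="interp"`).

**Anomaly (NDVIa).** Each sample minus the across-years mean of its
calendar slot. This removes any strictly calendar-periodic component
regardless of shape, which is why the generator's single sinusoid
suffices to exercise it; per-slot means of the output are zero to
machine precision and the operation is idempotent. Slots observed in
only one year carry no cross-year information and get anomaly 0 with a
warning.

The pipeline order is enforced: quality mask → gap fill → smooth →
anomaly. Smoothing and all estimators refuse series with missing values.

## Trend and change point

**Mann–Kendall**: S = Σ_{i<j} sign(x_j − x_i), Kendall's tau-b with the
standard tie corrections, continuity-corrected normal approximation,
two-sided p. **Pettitt**: U_t = 2 Σ_{i≤t} r_i − t(n+1) on midranks
(identical to the sign double-sum), K = max|U_t|, earliest argmax on
ties, p ≈ 2·exp(−6K²/(n³ + n²)). Both are rank-based and therefore
invariant under monotone transformations. On white noise (n = 200,
2000 replicates) both reject at 5% ± 2% at α = 0.05 — the classical
Pettitt tail approximation is adequate in that regime. The tests are
run on the smoothed series, matching how such records are usually
reported.

## Corrected R/S Hurst index

For dyadic segment lengths τ ∈ {8, 16, …, n/2}, the series is split into
⌊n/τ⌋ non-overlapping segments; each segment's rescaled range is the
range of the cumulative sum of its mean-centered values divided by its
sample (n−1) standard deviation, and R/S(τ) is the segment average.
The raw estimate is the slope of log R/S against log τ. Because E[R/S]
under i.i.d. Gaussian values exceeds the asymptote at small τ, the
corrected estimate regresses log(R/S − E[R/S] + √(πτ/2)) instead, with
the Anis–Lloyd expectation (gamma form for τ ≤ 340, Stirling limit
above, and the Peters (τ−½)/τ factor) — the same convention as the R
`pracma` "corrected empirical Hurst exponent", which is the lineage of
the "corrected Hurst index" in this literature. The estimator is fed
the stationary series itself (it integrates internally): i.i.d.
Gaussian input — the increments of a Brownian motion — is the H = 0.5
reference. The corrected-vs-raw gap decays only like 1/log n (the
short-τ bias is a fixed offset on a growing lever arm): measured means
are 0.073 at n = 1024 and 0.036 at n = 65536, so the two estimates
approach each other slowly; the corrected one is already unbiased at
moderate n.

## Generalized structure functions

M_q(τ) = ⟨|x(i+τ) − x(i)|^q⟩ over all n − τ overlapping increments
(absolute values make non-integer q well defined; q > 0 only, since
negative moments of increments diverge). ζ(q) is the per-q slope of
log M_q(τ) vs log τ, fitted by default over τ = 1…8 samples (8–64 days
at the 8-day cadence — dense integer lags rather than only the four
dyadic ones, both supported); H(q) = ζ(q)/q and ΔH = H(0.25) − H(4) on
the q grid 0.25…4 step 0.25. Fits with R² < 0.97 are kept but warned
about. There is no detrending here: a trend in the series biases the
GSF, which is exactly the contrast with MF-DFA the chain is built to
expose.

## MF-DFA

Profile y(i) = Σ_{k≤i}(x(k) − x̄); 2⌊N/s⌋ segments of length s taken
from both profile ends so the trailing remainder is never discarded
(this is what the 1/(2N_s) normalization presumes); least-squares
polynomial detrending of order 1 by default (configurable);
F_q(s) = {(1/2N_s) Σ [F²(s,ν)]^{q/2}}^{1/q}. H(q) is the per-q slope of
log F_q(s) vs log s; ζ(q) = q·H(q) (the product form — the alternative
H(q)/q found in some descriptions is dimensionally inconsistent with a
concave ζ(q) and is treated as a transcription slip); ΔH as above. For
8-day NDVI series the default scale grid is the dyadic {4, 8, 16, 32,
64} samples = 32–512 days. For benchmark recovery on long synthetic
series the validation and acceptance runs use dyadic scales from 16 up
to N/4: DFA with linear detrending carries a known small-scale bias, so
scales below ~16 samples are excluded there. With these grids, MF-DFA
H(2) recovers the fGn Hurst parameter within ±0.05 at n = 4096
(20-seed means) and the binomial-cascade H(q) matches the closed form
1/q − log₂(p^q + (1−p)^q)/q within 0.05 at q ∈ {0.25, 1, 2, 4}.

## Sources of multifractality

Shuffling permutes values uniformly (destroys all temporal structure,
keeps the distribution); IAAFT surrogates iterate Fourier-magnitude
replacement against rank-remapping onto the original amplitudes,
ending on the amplitude step, so the sorted values are preserved
exactly and the power spectrum to iteration accuracy. The iteration
stops when the achieved magnitude spectrum stalls between iterations
(relative change < 1e-8) or at `max_iter`; the discrepancy *to the
target* plateaus at a data-dependent level — measured ~4·10⁻³ at
n = 828 and <10⁻³ at n ≥ 4096 — which is a property of the algorithm,
not of the stopping rule. Ten shuffles and ten surrogates (seeded from
a deterministic ladder off the master seed) are analyzed with the same
MF-DFA configuration as the original; ΔH is averaged across
realizations (not the H(q) curves), and

    Hcor = ΔH_original − mean ΔH_shuffle
    Hpdf = ΔH_original − mean ΔH_surrogate

This orientation follows the internally consistent published
tabulation of the decomposition; prose descriptions pairing the names
the other way exist, so the convention string is carried in the result
metadata.

Two caveats the tests make explicit. First, i.i.d. heavy-tailed values
mimic multifractality at small scales (finite-size effect), so the
"shuffled cascade collapses" property is asserted on a large-scale fit
(s ≥ 128 of 8192, where the shuffled ΔH falls below 40% of the
original); at small-scale-inclusive grids the shuffle retains roughly
two thirds of the width. Second, the monofractal-fGn check (|Hcor|,
|Hpdf| < 0.08 at n = 828) is averaged over 30 independent series —
enough for a standard error well under the band given single-series
values around 0.03.

## Synthetic data: what it does and does not establish

The NDVI-like generator produces 18 years × 46 composites = 828 samples:
base level 35 (0–100 NDVI scale), annual sinusoid of amplitude 15, a
slow linear trend (−0.005 units/sample by default), one abrupt level
shift (−3 units at sample 230, i.e. year five), fGn noise (H = 0.7,
s.d. 3) generated by exact Davies–Harte circulant embedding (so
estimator-recovery results are not confounded by generator
approximation error), clipping to [0, 100], and a vanishing fraction
(10⁻⁴, under 0.01%) of positions masked missing. These defaults are
fixed study conditions, not tuning knobs.

What passing tests show: the estimators recover known exponents, the
preprocessing removes exactly the calendar-periodic component, the
decomposition separates correlation-driven from distribution-driven
width on fixtures where the answer is known. What they do not show:
real MODIS reflectance has cloud-correlated (not uniform-random) gaps,
non-sinusoidal and drifting phenology, spatially averaged heterogeneous
pixels, and retrieval noise that is neither Gaussian nor stationary —
so numerical values obtained on real series will differ from any
synthetic figure here, and agreement of the pipeline's outputs with a
particular study area cannot be claimed from these tests.

## Problem sizes

Defaults used by the validation and acceptance runs: 20 seeds per
stochastic baseline; n = 8192 for R/S and structure-function baselines
and for the cascade (2¹³); n = 4096 for fGn recovery; 2000 replicates
at n = 200 for test calibration; 10 + 10 realizations per source
decomposition. The full test suite runs in well under a minute of CPU.
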