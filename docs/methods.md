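# Methods

## Signal model and estimators

An fNIRS channel is modelled as a linear time-invariant system: the observed
hemoglobin series `y(t)` is the discrete convolution of a latent neural
event series with the channel's hemodynamic response function (HRF), plus
noise. Both unknowns are recovered by regularized linear inversion of the
convolution, written with a Toeplitz design matrix `H` (`H[i, j] =
driver[i - j]` for `i >= j`, else 0):

    x̂ = argmin ‖Hx − y‖² + λ‖Lx‖² = (HᵀH + λLᵀL)⁻¹Hᵀy

solved through a symmetric positive-definite factorization of the normal
equations, never an explicit inverse.

**HRF estimation.** The driver is the event impulse train (unit amplitude
by default; weighted impulses and boxcars as consecutive impulses are
honoured), and `x` is the kernel over a fixed window (30 s default). The
pipeline is: z-score the signal (population SD; a numerically constant
channel returns zeros with a warning instead of dividing by a tiny SD),
expand the kernel window, centre the design columns, check conditioning,
solve, trim the window back. Three details matter:

* *Edge expansion.* Toeplitz deconvolution tends to produce erratic values
  at the first and last kernel samples. The window is widened by
  `edge_fraction` (default 0.25) of the kernel duration on each side —
  events are shifted earlier by the pad and the kernel length grows by two
  pads — and the pad regions are discarded after the solve. Events whose
  shifted onset falls before the scan are dropped with a warning.
* *Implicit intercept.* z-scoring (and upstream baseline correction) leaves
  a constant offset in `y` that an event convolution cannot produce; left
  unmodelled it biases the kernel. The design columns are mean-centred
  before the solve, which is algebraically identical to adding an
  unpenalized intercept column. With this step, noiseless simulated data are
  recovered to r > 0.999 at λ = 1e-6; without it the correlation plateaus
  around 0.996.
* *Drop policy.* A channel is excluded (a recoverable error, not a crash)
  when the 2-norm condition number of `HᵀH + λLᵀL` exceeds
  `cond_threshold` (default 1e8) or a cooperative per-channel time limit
  (default 60 s) is exceeded — a failed inversion is worse than a missing
  channel.

Per-subject kernels for a channel are pooled with a per-sample trimmed mean
(`trim_prop` 0.1 per tail; `floor(trim_prop·n)` values discarded at each
tail after sorting) and a per-sample untrimmed standard deviation (ddof = 1
across subjects) kept as the spread. Subject kernels are preserved for ROI
meta-analysis.

**Activity estimation.** The driver is an HRF that has been resampled to
the recording's rate and scaled so its dominant extremum has magnitude 1
(division by `extremum + ε`, ε = 1e-7; negative-going HbR kernels scale by
the trough with sign preserved). `H` is the full n × n convolution matrix of
the zero-padded kernel, so the activity estimate spans the whole scan; it
replaces the hemoglobin samples in the recording container with arbitrary
units while metadata are preserved. Because an SVD of an n × n matrix would
dominate the runtime, this path estimates the condition number with the
LAPACK `dpocon` reciprocal-1-norm estimator on the Cholesky factor already
needed for the solve; the exposed `assess_conditioning` keeps the exact
2-norm definition.

Regularization smears recovered activity in time: at λ = 0.01 each impulse
becomes a symmetric bump centred on the true onset (peak alignment is exact
in noiseless simulations), so correlation with the raw impulse train is
moderate (~0.3 at λ = 0.01, ~0.85 at λ = 1e-6) even when event timing is
recovered perfectly. Activity norms are monotonically non-increasing in λ.

## The HRF store

Estimates are held in a hybrid structure designed for two query types:

* **Spatial.** A hand-written k-d tree over 3-D optode coordinates (mm),
  axis = depth mod 3, incremental insertion without rebalancing plus an
  optional median-split `rebuild()`. Nearest-neighbour search (default
  maximum distance 1 mm) and spherical radius search prune branches by the
  axis distance. Both are verified against exhaustive linear scans in the
  test suite. One node carries both chromophore payloads; a query for a
  chromophore the nearest nodes lack falls back to the canonical kernel of
  matching polarity.
* **Context.** Every context entry (task, study, DOI, age range, stimulus
  duration/intensity, …) is registered in a hash table: key =
  `lowercase(group) + "-" + lowercase(value)`, base slot = first 8 bytes of
  SHA3-256 mod a prime table size, collisions resolved by quadratic probing
  `(base + i²) mod m`, resize to the next prime above twice the size at load
  factor 0.7. Numeric values and ranges are discretized into fixed-width
  bins (age 1 year, duration 1.0 s, intensity 0.1, otherwise 1.0) and every
  covering bin is registered; range queries enumerate bins centre-out
  (closest to the range midpoint first, lower bin first on ties — ages 4–7
  yield 5, 6, 4, 7). `branch()` gathers candidates through these lookups and
  keeps nodes whose weighted query-side similarity reaches the threshold
  (default 0.95). Similarity counts only what the query asks about: extra
  node context does not penalize.

Location-free ("global") HRFs are placed uniformly in [359, 361]³ so they
form their own subtree far outside head space; the canonical double-gamma
node is pinned at exactly (359, 359, 359) and is the universal fallback.

The canonical kernel is `g(t; a₁, b₁) − c·g(t; a₂, b₂)` with gamma densities
and defaults a₁ = 6, b₁ = 1, a₂ = 16, b₂ = 1, c = 1/6 (peak ≈ 5 s,
undershoot ≈ 1/6 of peak) — the conventional double-gamma parameterization;
all parameters are configurable and recorded in the estimate's context.

**Serialization.** Stores round-trip through JSON keyed by `doi|channel`
(kept unique to prevent clashes), with sorted keys and fixed indentation so
re-serializing a parsed document is byte-identical. The canonical node is
reconstructed on load (its duration/rate live in metadata) rather than
stored. Merging builds the union of nodes and rebuilds the tree and table;
key collisions follow a policy (`error` listing the keys, `keep_a`,
`keep_b`).

**Resampling.** Kernels move between sampling rates via a natural cubic
spline (second derivative zero at the endpoints — the end condition is a
choice; nothing in the data determines it) through knots `i/src_sfreq`,
evaluated at `j/dst_sfreq` on the half-open [0, duration) grid. Destination
points beyond the last source knot are clamped to the endpoint value with a
warning rather than extrapolated.

## Preprocessing and metrics

Minimal, deconvolution-oriented preprocessing: optical density
`−log10(raw/reference)` (reference = temporal mean; natural-log variant by
option), first-order polynomial detrend plus mean subtraction (deliberately
*not* a band-pass filter, whose dephasing would distort frequencies the HRF
occupies). Full Beer–Lambert chromophore conversion is out of scope; the
package consumes hemoglobin series produced upstream.

Signal quality is the PSD-band SNR: Welch periodogram (segments of
min(n, 2048) samples, 50% overlap — the estimator is a choice), power in
0.01–0.2 Hz divided by power outside it (DC excluded); channels below 5.0
are flagged for exclusion. Shape metrics are skewness `m₃/m₂^1.5` and excess
kurtosis `m₄/m₂² − 3` from population central moments (0 = Gaussian).
Deconvolution should *sharpen* a signal — recovered activity is sparser than
the smooth convolved input — so the excess kurtosis rises; the acceptance
suite confirms this direction in 100/100 seeded simulations.

## Synthetic data

The generator produces event-related recordings with known truth: a
double-gamma HRF (default adult parameters; a "child-like" preset delays the
peak to ~8 s and blunts the undershoot) convolved with a randomized event
schedule, plus sinusoidal physiology at 1 Hz (cardiac), 0.3 Hz (respiratory)
and 0.1 Hz (Mayer waves — deliberately *inside* the hemodynamic band),
white noise, and a linear drift. Default study conditions: 560 s scans at
10 Hz, 20 events with ISI ≥ 25 s, a 10 s initial rest baseline (standard in
event-related protocols; it also keeps early events inside the
edge-expansion pad), the task running to the end of the scan (so the last
responses are truncated, as in real recordings), and noise scaled by root
finding until the measured PSD-band SNR equals a target (default 5.0, the
exclusion boundary — the worst data that would still enter an analysis).

What the simulations do not emulate: motion artifacts, superficial/systemic
physiology with spatial structure, nonlinear or history-dependent
hemodynamics, and between-channel correlation. Passing recovery tests on
these simulations therefore demonstrates correctness of the inversion and
pooling machinery under realistic stationary noise, not robustness to every
artifact class in real data.

Problem sizes in the test and acceptance suites — up to 5600-sample designs
for HRF estimation and 750–3000-sample square designs for activity — were
chosen as comfortable desk-scale analyses; all reported quantities are
computed at those sizes.

## A negative result: edge expansion under these conditions

With this pipeline and these study conditions, edge expansion does **not**
reduce the edge-region error of the pooled kernel; it increases it roughly
tenfold (least-squares-scaled edge MSE ≈ 0.011 expanded vs ≈ 0.0012 plain at
50 subjects, SNR 5). Two mechanisms explain this. First, the 45 s expanded
window exceeds the 25 s minimum ISI, so neighbouring events' design columns
overlap and the solve spreads variance across 50% more parameters. Second,
the artifact expansion targets is already absorbed elsewhere: the implicit
intercept removes the baseline offset that would otherwise pile into edge
columns, and ridge shrinkage is nearly unbiased at the window edges because
the true kernel is close to zero there. The comparison (each pooled kernel
least-squares scaled to truth before measuring the outer 10% of samples per
side — estimates from z-scored signals have arbitrary scale) is asserted as
an expected-benefit test in the acceptance suite and currently fails by
design of honesty; the feature remains available and defaults to +25%.

## Defaults at a glance

| parameter | default | meaning |
| --- | --- | --- |
| `lam` | 1.0 | Tikhonov weight λ |
| `reg_matrix` | identity | `L` (first-difference available) |
| `edge_fraction` | 0.25 | expansion per side, fraction of kernel duration |
| `eps` | 1e-7 | peak-scaling denominator guard |
| `cond_threshold` | 1e8 | drop channel above this condition number |
| `time_limit_s` | 60 | cooperative per-channel solve limit |
| `trim_prop` | 0.1 | trimmed-mean proportion per tail |
| `max_dist` | 1 mm | nearest-neighbour search radius |
| similarity threshold | 0.95 | context filter |
| SNR band / threshold | 0.01–0.2 Hz / 5.0 | exclusion rule |

## Known limitations

* Channels are processed independently; no spatial regularization or
  short-separation regression.
* The linear time-invariant convolution model ignores hemodynamic
  nonlinearity at short ISIs.
* Quadratic probing over a prime table is not guaranteed to visit every
  slot; the 0.7 load-factor cap plus resize-and-retry keeps insertion safe
  in practice.
* Coordinate frames are carried as labels only — no registration is
  attempted between stores from different frames.
* Motion correction and scalp-coupling quality control are expected to
  happen upstream.
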