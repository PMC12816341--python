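# Methods

This note documents the models, estimators and numerical choices behind
`bim`, what the synthetic benchmarks do and do not emulate, and the known
limitations.

## Model and assumptions

All measures assume two jointly wide-sense-stationary, zero-mean series
sampled uniformly at rate `fs`.  The linear route additionally assumes
that a finite-order bivariate VAR captures the second-order structure;
the information-theoretic reading of the log-ratio measures (nats,
factor-of-two relation between the `F` and `I`/`T` quantities) further
assumes joint Gaussianity.  None of these assumptions are enforced on the
data: the preprocessing step (`bim.dataio.preprocess`) removes means,
optionally normalizes variance and removes slow trends with a first-order
Butterworth high-pass applied forward and backward (zero phase, length
preserving); stationarity beyond that is the user's responsibility.

## Restricted models: two routes

Granger-causality measures need the innovation variance `lambda2` of the
univariate (restricted) description of each process, which has infinite
AR order in general.  Two routes recover it from the full-model
parameters without refitting:

- **State space (exact).**  The VAR is embedded in innovations form; the
  restricted submodel observing a single channel has innovation variance
  `C P C' + R` where `P` solves the filtering discrete algebraic Riccati
  equation with cross-covariance term (`scipy.linalg.solve_discrete_are`
  on the dual problem).
- **Yule–Walker (truncated).**  The process autocovariance is obtained
  from a discrete Lyapunov equation on the companion form
  (`scipy.linalg.solve_discrete_lyapunov`) plus the lag recursion, and
  the univariate normal equations are solved at truncation lag `q`.
  Default `q = max(20, 2p)`: the measures stabilize by `q ≈ 10` for
  comfortably stable models, and the margin covers spectral radii up to
  ~0.9.  The two routes agree to better than 1e-4 relative at `q = 50`
  (verified over random stable models).

Estimated (finite-sample) Granger causalities can be marginally
negative; `time_domain_measures` keeps the raw values and exposes an
optional clip for reporting, so the decomposition identity
`F_td = F_gc_12 + F_gc_21 + F_ic` always holds exactly on the returned
values.

## Spectral measures and a minimum-phase caveat

The spectral matrix comes from factorization `P = H Sigma_U H*` on a
uniform grid of 1001 points over normalized frequency [0, 1/2], endpoints
included; band integrals use the trapezoidal rule with band edges
interpolated onto the grid (adjacent bands therefore tile exactly, and
smooth AR spectra integrate to ~1e-3 accuracy or better).  The
frequency-wise decomposition of the total-dependence profile into the two
causal profiles and the instantaneous profile is exact by construction at
every grid point.

The spectral integration property for the *directional* profiles —
`F_gc = 2∫ f_gc` — additionally requires each process's self-regression
polynomial `1 − Σ_k a_ii,k z^{-k}` to be minimum phase.  A stable VAR can
violate this (the companion matrix is non-normal), in which case the
one-process Wold variance picks up the outside roots and the integral
undershoots the time-domain value by `Σ ln|r|²` over the offending roots.
The random-model generator used for property testing rejects such draws;
`geweke_spectral` itself computes the profiles for any stable model.

When the innovation covariance is not diagonal (no strict causality),
directed coherence is computed from the diagonal innovation variances
only, with a warning: its interpretation as a normalized share of the
target spectrum then fails.  The Geweke causal/instantaneous profiles are
computed exactly and may go negative at some frequencies; that is a
documented property of the decomposition, not an error.

The non-parametric spectral estimator is the weighted-covariance
(Blackman–Tukey) method with biased (1/L) correlation estimates and a
Parzen lag window (piecewise cubic, `w(0)=1`, non-negative spectral
estimates); Hanning and Hamming lag windows are available but
non-default.  The Parzen bandwidth relation `tau = 1.273 fs / Bw` is
implemented verbatim and reported both raw and ceiled to an integer lag
≥ 1; callers asking for bandwidths above `fs/2` get the formula's answer
unchanged, since the relation itself places no constraint there.

## Model-free estimators

- **KNN.**  Shared-radius construction: the k-th neighbour Chebyshev
  distance in the full joint space `[Y1_n, Y2_n, past_1, past_2]` fixes a
  per-sample radius; all projected neighbour counts use that radius with
  strict inequality (`scipy.spatial.cKDTree`, radius shrunk by one ULP).
  This cancels the dimension-dependent digamma biases across entropy
  differences and makes `MIR = T_12 + T_21 + IT` an exact identity of the
  estimator.  Each series is standardized internally, so estimates are
  invariant under affine rescaling of either channel.  Duplicate joint
  points are an error unless seeded jitter (amplitude 1e-10 sd) is
  enabled; jitter is off by default because it is only needed for
  discrete-valued inputs.  Defaults `k = 10`, `q = 3`, `tau = 1`.  On
  short-memory benchmarks, matching the embedding length to the known
  generator memory (e.g. `q = 1` for a lag-1 coupling) removes most of
  the residual dimensionality bias; this is what the consistency checks
  use.
- **Binning.**  Uniform quantization of each series over its own range
  into `b` bins (top bin closed), plug-in entropies of the symbol
  blocks; a warning fires when `b^(2q+1)` exceeds the sample count.
  Defaults `b = 3`, `q = 2`.
- **Permutation.**  Ordinal patterns of each process's embedding window
  (length `q` for past, `q+1` with the present value); ties give the
  later element the smaller rank.  Default `q = 3`, the smallest length
  giving useful pattern variability.

For all three, `MIR` is composed as `T_12 + T_21 + IT`, so the
decomposition holds exactly by construction.

Non-uniform embedding selects past terms greedily by conditional mutual
information (same shared-radius KNN estimator, `k = 10` by default — the
procedure itself does not prescribe an estimator) with a shuffle stopping
rule: a candidate is kept only if its CMI beats the 95th percentile of
CMIs under random permutation of the target series (100 shuffles,
alpha = 0.05, per step).  Because the tested candidate is the *maximum*
over the candidate set while the null is per-candidate, the per-step
false-inclusion rate exceeds alpha (roughly 1 − 0.95^m for m
candidates); an occasional spurious term on unpredictable targets is
expected behaviour of the published procedure.

## Surrogate testing

Random time-shift surrogates rotate one series circularly by a shift
drawn uniformly from `{tau_min, …, L − tau_min}` (default
`tau_min = 20`), preserving its value multiset and autocorrelation while
destroying the coupling.  The threshold is the m-th largest of the `n_s`
surrogate values with `m = floor(alpha (n_s + 1))` — for `n_s = 100`,
`alpha = 0.05` the 5th largest — giving an exact exchangeable type-I rate
`m/(n_s+1) ≈ alpha`.  The observed value is not pooled into the
surrogate sample.  One master seed drives the whole surrogate stream, so
runs are bit-reproducible.

## Synthetic benchmarks: what they do and do not show

`benchmark_unidirectional` (Y1 white, `Y2_n = c·Y1_{n−1} + U2`) has
closed-form population measures and anchors the exactness tests.
`benchmark_physio` couples two AR(2) stochastic oscillators — defaults
place them at normalized frequencies 0.1 and 0.25 with pole radii 0.8
and 0.9, unit-variance innovations — emulating the band-limited rhythms
of cardiovascular variability.  `random_stable_model` draws generic
stable VARs (spectral radius < 0.9, minimum-phase diagonals, optionally
correlated innovations) for identity and cross-method property tests.
Innovations are Gaussian by default (the regime where linear and
information measures coincide); a uniform-innovation option probes
robustness.  Burn-in is 1000 samples, at least an order of magnitude
above the slowest benchmark time constant.

These generators are linear and stationary by construction.  Passing
tests therefore demonstrate correctness of the algebra and calibration of
the estimators *under the linear Gaussian model* — they do not certify
behaviour on nonstationary, heavy-tailed or strongly nonlinear real
recordings, where the model-free estimators and the preprocessing
choices carry the weight.

## Problem sizes used in the checks

Estimation-accuracy checks use realizations of length 8192 (20 seeds)
for the KNN/linear comparison, 10 000 for coefficient recovery, 1000
(100 seeds) for order selection, and 300 (200 replicates, 100 surrogates
each) for type-I calibration — lengths representative of the short
physiological and monthly climate records the pipeline targets.

## Known limitations

- Strictly bivariate: no conditioning on further processes, no
  multivariate extensions.
- No modelling of instantaneous (lag-0) regression effects; instantaneous
  association is measured, not attributed a direction.
- The Yule–Walker route is truncation-approximate (controlled by `q`);
  the state-space route is exact but requires a solvable Riccati
  equation.
- Time-shift surrogates test the independence null only; they do not
  separate linear from nonlinear coupling.
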