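# Methods

## Model

`pfconn` estimates the time-varying coefficients of a first-order vector
autoregressive (VAR(1)) model of an R-node multivariate time series
(typically fMRI ROI signals):

    x(t) = a(t) x(t-1) + eta(t),        eta_i ~ N(0, sigma_eta_i^2)

The entry `a_ij(t)` quantifies the directed (effective-connectivity)
influence of node j at time t-1 on node i at time t. The coefficients are
hidden states following a random walk,

    a_ij(t) = a_ij(t-1) + nu_ij(t),     nu_ij ~ N(0, sigma_nu_ij(t)^2)

Because the likelihood of the observation `x_i(t)` involves only row i of
`a(t)`, the estimator factorizes per node: each node runs an independent
particle filter over its R incoming coefficients.

## Particle filter

Per repetition and node, N particles (candidate coefficient rows) start
uniform on `[-init_range, +init_range]` and evolve as:

1. **Propagation.** Each particle's each coefficient is perturbed by
   zero-mean Gaussian noise. The per-coefficient standard deviation adapts
   to the absolute difference of the two previous posterior means, clamped
   to `[innovation_min, innovation_max] = [0.1, 0.4]`; with fewer than two
   previous estimates the upper bound is used (wide exploration before any
   history exists).
2. **Weighting.** The predicted observation under particle n is
   `a_i^(n) · x(t-1)`; the weight is multiplied by the Gaussian likelihood
   of the actual `x_i(t)` (sequential importance sampling). Weights are
   carried in the log domain with max-subtraction.
3. **Estimation.** The posterior mean (weighted particle mean) is the
   coefficient estimate at time t. The first estimable transition is
   x(1)→x(2); index 0 of the trajectory duplicates it.
4. **Resampling.** When the effective sample size `1/Σw²` falls below
   `resample_fraction·N` (default 30%), systematic resampling replaces
   low-weight particles by copies of high-weight ones and resets all
   weights to 1/N.

The procedure is repeated `Nr` times with independent random streams
(repetition r seeds its generator with `seed + r`, combined with the node
index so nodes do not share a stream); the reported trajectory is the
across-repetition mean, with the across-repetition standard deviation as a
per-entry spread.

### Observation-noise scale

The likelihood width `sigma_eta` is the one genuinely open numerical
choice of the algorithm. Per node, `"auto"` (default) uses the residual
standard deviation of an
ordinary least-squares lag-1 fit of the whole series. At each step the
width is additionally floored at `obs_noise_rel_floor · ||x(t-1)||₂`
(default 0.06). The floor matters on noise-free data, where a stable VAR(1)
realization decays geometrically: an absolute width would either underflow
(OLS residuals are ~1e-15) or lose all selection pressure once the signal
drops below it, whereas a width proportional to the current regressor norm
keeps the relative discrimination between particles constant as the signal
decays. The default 0.06 came from a coarse scan of the noise-free
recovery benchmark; recovery is flat within ±0.02 of it.

### Defaults

| parameter | default | meaning |
|---|---|---|
| `n_particles` (N) | 2000 | particles per node per repetition |
| `n_repetitions` (Nr) | 100 | independent filter repetitions averaged |
| `resample_fraction` | 0.30 | Neff threshold as a fraction of N |
| `innovation_min/max` | 0.1 / 0.4 | clamp on the adaptive random-walk std |
| `obs_noise_sigma` | "auto" | per-node OLS lag-1 residual std |
| `obs_noise_rel_floor` | 0.06 | likelihood-width floor, × ‖x(t-1)‖₂ |
| `init_range` | 1.0 | half-width of the uniform particle start |

Runtime scales linearly in T, N, Nr and quadratically in R. At the default
configuration a 6-node, 100-point series takes on the order of ten seconds
per node-repetition batch on one core; the validation scripts use the full
Nr = 100, while the test suite runs the same experiments at Nr ≤ 20, which
changes only Monte-Carlo smoothness, not the estimator.

## Synthetic benchmarks

The generator produces the three regimes used for validation; these are the
only data the tests need.

**Stationary random networks.** Coefficients are drawn iid uniform(-1, 1)
and rescaled so the spectral radius is `0.9 · uniform(0.5, 1)`; the start
is standard normal. The matrix and start are drawn identically for every
SNR, so one seed yields the same network observed at different noise
levels. With `snr_db = inf` the series is the noise-free decaying
transient. At finite SNR the per-node noise std is calibrated against that
transient, `sigma_i² = var_t((a x_clean(t-1))_i) / 10^(snr/10)`, and the
noise is fed back through the recursion. Note a structural property of
feedback noise: asymptotically the ratio `var(a·x(t-1))/var(eta)` is
scale-invariant in the noise and determined by the matrix alone, so the
nominal SNR here is a calibration against the clean transient, not an
asymptotic property of the noisy process. Consequently the noisy series
remains persistently excited long after the transient has decayed, and
coefficient recovery at "6 dB" is only mildly harder than in the noise-free
case (pooled correlation ≈0.9 vs ≈0.9; see the limitations note below).

**Switching network.** Two nodes; `a_21(t)` starts at +1 and flips sign
every `switch_period` points; all other coefficients are zero. Node 1 is
driven by unit-variance noise; node 2's noise is scaled so its realized
SNR equals the request exactly (the triangular structure makes this an
honest asymptotic per-node SNR; node 1 receives no signal, so its SNR is
undefined).

**Stimulus-modulated network.** The designated edge's target node is a
sink (zero column), receiving couplings from an autonomous stationary
subnetwork (spectral radius 0.5, unit driving noise); the designated entry
equals `baseline_coefficient` during OFF and `baseline_coefficient +
effect_size` during ON blocks. The sink structure makes the target node's
SNR exactly tunable, calibrated in the OFF state (realized 10.09 dB at a
nominal 10 in a 5000-point check). Instantaneous matrices are checked for
stability in both states.

What the generator does *not* emulate: hemodynamic convolution and its
regional variability, physiological noise spectra, scanner drift (the
preprocessing module removes drifts but the generator does not inject
them), and spatial structure. Passing tests therefore demonstrate correct
recovery of VAR(1) dynamics at fMRI-like lengths and noise levels, not
robustness to haemodynamic confounds.

## Baselines and statistics

* **Delayed correlation**: Pearson correlation of `x_i(t)` with
  `x_j(t-1)`; affine-invariant per node; zero-variance nodes yield NaN.
* **Stationary VAR fit**: ordinary least squares on the demeaned series,
  no intercept; explicit lagged-design least squares (SVD), cross-checked
  against statsmodels' VAR in the tests. Demeaning uses the full-series
  mean once; on short decaying transients this leaves an O(mean) constant
  in the regression, so exact-interpolation checks use `demean=False`.
* **Order selection**: Schwartz/BIC over a common sample,
  `log det(Sigma_ML) + log(n)/n · p·R²`; all candidate orders drop the
  first `max_order` observations.
* **Sliding window**: VAR(1) refit on overlapping blocks (default 20
  points, stride 1), indexed to window centers and held between them.
* **Permutation null**: the same random time permutation applied to all
  nodes (destroying temporal order, preserving cross-sections), the filter
  rerun per permutation, time-averaged matrices collected; two-sided
  add-one empirical p-values.
* **Stimulus-locked test**: Welch t-test of trajectory values at ON vs OFF
  time points, gated by a second test against the half-period-shifted
  control; `significant` requires p < 0.05 on the true pattern and
  p ≥ 0.05 on the control. `StimulusPattern.period` is the duration of one
  ON or OFF block, so the control shift (period/2, half a block) puts the
  control in quadrature with the stimulus — a half-*cycle* shift of a 50%
  duty-cycle wave would merely complement it and duplicate the primary
  test. An optional `lag` shifts the pattern before alignment; the
  estimator needs ≈ effect/innovation_max steps to traverse a switch, and
  aligning by that delay (≈4 steps for a 0.5 effect) is the analogue of
  accounting for hemodynamic delay.
* **Quality parameter**: `Q = T / sigma` with sigma pooled over all nodes
  and time points.

## Known limitations

* The per-time-point t-test treats serially correlated trajectory values
  as independent. Null-coefficient trajectories have lag-10
  autocorrelation ≈0.4, so the raw test is strongly anti-conservative
  (empirically, a ~0.3 gated false-positive rate at nominal 5% on the
  stimulus benchmark); repetition averaging does not help because the t
  statistic is scale-invariant. The control gate and cross-dataset
  consistency are the practical mitigations; no autocorrelation correction
  is applied, and no multiple-comparison correction is made across the R²
  coefficients.
* Coefficients of a noise-free decaying transient are identifiable only
  through its first ~R-to-tens of steps; the trajectory then collapses
  onto the dominant eigen-direction, and both OLS and the filter recover
  weakly-excited directions imperfectly (exact-interpolation tests use
  rotating dynamics, which stay well conditioned).
* Under feedback noise the 6 dB benchmark is easier than a
  measurement-noise reading of the same nominal SNR would be; both
  interpretations were examined and the feedback reading (noise as the
  process innovation, per the observation equation) was kept.
* No Rao-Blackwellization, no symmetric-coupling constraint, no smoothing,
  and no parallelization; repetitions run serially.
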