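# pfconn

Particle-filter estimation of **time-varying effective connectivity** from
multivariate brain time series.

Most fMRI connectivity analyses assume the coupling between regions is
constant over a scan. `pfconn` drops that assumption: it models R region
time series as a first-order vector autoregression whose coefficient matrix
is itself a hidden, slowly varying state,

```
x(t) = a(t) x(t-1) + η(t)            (observation equation)
a_ij(t) = a_ij(t-1) + ν_ij(t)        (state equation, random walk)
```

and estimates the full trajectory `a_ij(t)` — the directed influence of
region j on region i at every time point — by sequential Monte Carlo. Each
node runs an independent filter of N particles over its incoming
coefficients: particles are propagated with an adaptive random-walk
innovation (std clamped to [0.1, 0.4]), reweighted by the Gaussian
likelihood of each new observation, and systematically resampled when the
effective sample size `1/Σw²` drops below 30% of N. The whole pass is
repeated Nr times and averaged. Alongside the estimator the package ships
the stationary baselines it is judged against (delayed correlation, OLS
VAR fits, BIC order selection, sliding-window regression), stimulus-locked
statistics (ON/OFF Welch t-test with a shifted-control gate, temporal
permutation null, quality parameter Q = T/σ), a synthetic-network
generator covering the validation regimes, and NIfTI ROI extraction.

Audience: researchers analyzing task or resting-state fMRI ROI time series
who want directed, time-resolved coupling estimates without specifying the
timing of connectivity changes in advance.

## Worked example

Simulate the 2-node benchmark whose only nonzero coefficient `a_21`
square-waves between +1 and −1 every 125 time points (SNR 10 dB), then
estimate its trajectory:

```
$ pfconn simulate --mode switching --nodes 2 --timepoints 250 --snr-db 10 \
      --switch-period 125 --seed 7 --out sw
wrote sw_series.tsv and sw_truth.json
$ pfconn fit --input sw_series.tsv --particles 1000 --repetitions 10 \
      --seed 1 --out sw
wrote sw_trajectory.tsv (0.7s)
```

Summarizing `sw_trajectory.tsv` (long-format TSV: t, target, source,
estimate, spread):

```python
>>> import numpy as np
>>> from pfconn.io import read_trajectory
>>> v = read_trajectory("sw_trajectory.tsv").values
>>> np.round(v[:, :, 1:].mean(axis=2), 3)      # time-averaged a_ij
array([[-0.018,  0.025],
       [ 0.031, -0.014]])
>>> round(v[1, 0, 1:125].mean(), 3)            # a_21 before the switch
0.982
>>> round(v[1, 0, 125:].mean(), 3)             # a_21 after the switch
-0.912
```

The filter tracks the hidden coefficient through its sign flip (+0.98 →
−0.91 against the true +1 → −1) while the three truly-zero coefficients
stay near 0 — note the full-series time average of `a_21` (0.031) is
meaningless for a switching coefficient, which is exactly why a
time-resolved estimate is needed. The same `fit` API accepts any T×R
delimited table, e.g. ROI series extracted from a 4-D NIfTI volume with
`pfconn extract-roi`. Stimulus-locked modulation of the estimates is then
tested with `pfconn analyze stimulus`, and causal structure can be
validated against a time-shuffled null with `pfconn analyze permute`.

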