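"""Unit and property tests for the sequential Monte Carlo machinery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as stn
from hypothesis.extra import numpy as hnp

import pfconn
from pfconn import (
    FilterConfig,
    ParticleEnsemble,
    adapt_innovation_sigma,
    effective_sample_size,
    likelihood,
    propagate,
    resample,
    update_weights,
)


def make_ensemble(particles, weights=None):
    particles = np.asarray(particles, dtype=float)
    n = particles.shape[0]
    if weights is None:
        weights = np.full(n, 1.0 / n)
    return ParticleEnsemble(particles, np.asarray(weights, dtype=float))


# ---------------------------------------------------------------------------
# effective sample size


@pytest.mark.parametrize(
    "weights, expected",
    [
        (np.full(2000, 1 / 2000), 2000.0),
        (np.r_[1.0, np.zeros(99)], 1.0),
        (np.array([0.5, 0.25, 0.25]), 1.0 / 0.375),
    ],
)
def test_effective_sample_size_known_values(weights, expected):
    assert effective_sample_size(weights) == pytest.approx(expected)


@given(
    hnp.arrays(
        float,
        stn.integers(1, 50),
        elements=stn.floats(1e-6, 1.0),
    )
)
def test_effective_sample_size_bounds(raw):
    w = raw / raw.sum()
    neff = effective_sample_size(w)
    assert 1.0 - 1e-9 <= neff <= len(w) + 1e-9


# ---------------------------------------------------------------------------
# likelihood


def test_likelihood_peak_symmetry_and_ratio():
    pred = np.array([1.0, 1.0 + 0.3, 1.0 - 0.3, 1.0 + 0.3])
    lik = likelihood(1.0, pred, sigma_eta=0.3)
    assert lik[0] == pytest.approx(1.0)  # exact prediction attains the max
    assert lik[1] == pytest.approx(lik[2])  # symmetric residuals tie
    # residuals {0, sigma}: ratio is exp(-1/2)
    assert lik[1] / lik[0] == pytest.approx(np.exp(-0.5))


def test_likelihood_rejects_nonpositive_sigma():
    with pytest.raises(ValueError):
        likelihood(0.0, np.zeros(3), sigma_eta=0.0)


# ---------------------------------------------------------------------------
# weight update


def test_update_weights_hand_computation():
    ens = make_ensemble(np.zeros((2, 1)), [0.5, 0.5])
    out = update_weights(ens, np.array([1.0, 3.0]))
    np.testing.assert_allclose(out.weights, [0.25, 0.75])


def test_update_weights_equal_likelihoods_keep_uniform():
    ens = make_ensemble(np.zeros((5, 2)))
    out = update_weights(ens, np.full(5, 0.7))
    np.testing.assert_allclose(out.weights, 0.2)


def test_update_weights_all_zero_resets_with_warning():
    ens = make_ensemble(np.zeros((4, 1)), [0.1, 0.2, 0.3, 0.4])
    with pytest.warns(RuntimeWarning, match="underflow"):
        out = update_weights(ens, np.zeros(4))
    np.testing.assert_allclose(out.weights, 0.25)


@given(
    hnp.arrays(float, 8, elements=stn.floats(1e-3, 1.0)),
    hnp.arrays(float, 8, elements=stn.floats(0.0, 5.0)),
)
def test_update_weights_normalization_property(raw_w, lik):
    ens = make_ensemble(np.zeros((8, 1)), raw_w / raw_w.sum())
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = update_weights(ens, lik)
    assert abs(out.weights.sum() - 1.0) < 1e-12
    assert 1.0 - 1e-9 <= effective_sample_size(out.weights) <= 8 + 1e-9


# ---------------------------------------------------------------------------
# innovation adaptation and propagation


@pytest.mark.parametrize(
    "diff, expected",
    [(0.25, 0.25), (0.01, 0.1), (2.0, 0.4)],
)
def test_adapt_innovation_sigma_clamps(diff, expected):
    prev = np.array([0.5 + diff])
    prev2 = np.array([0.5])
    out = adapt_innovation_sigma(prev, prev2, (0.1, 0.4))
    np.testing.assert_allclose(out, expected)


def test_adapt_innovation_sigma_without_history_uses_max():
    out = adapt_innovation_sigma(np.zeros(3), None, (0.1, 0.4))
    np.testing.assert_allclose(out, 0.4)


def test_propagate_zero_sigma_is_identity(rng):
    ens = make_ensemble(rng.normal(size=(50, 3)))
    out = propagate(ens, np.zeros(3), rng)
    np.testing.assert_array_equal(out.particles, ens.particles)
    np.testing.assert_array_equal(out.weights, ens.weights)


def test_propagate_monte_carlo_std(rng):
    ens = make_ensemble(np.zeros((100_000, 1)))
    out = propagate(ens, np.array([0.2]), rng)
    assert out.particles.std() == pytest.approx(0.2, rel=0.01)


# ---------------------------------------------------------------------------
# resampling


def test_resample_degenerate_weights_copies_winner(rng):
    particles = np.arange(10, dtype=float).reshape(10, 1)
    w = np.zeros(10)
    w[3] = 1.0
    out = resample(make_ensemble(particles, w), rng)
    np.testing.assert_array_equal(out.particles, 3.0)
    np.testing.assert_allclose(out.weights, 0.1)


def test_resample_uniform_weights_is_a_permutation(rng):
    particles = np.arange(20, dtype=float).reshape(20, 1)
    out = resample(make_ensemble(particles), rng)
    # systematic resampling with equal weights keeps each particle exactly once
    np.testing.assert_array_equal(np.sort(out.particles.ravel()), particles.ravel())


def test_resample_preserves_weighted_mean_in_expectation(rng):
    particles = rng.normal(size=(30, 2))
    raw = rng.uniform(0.05, 1.0, 30)
    w = raw / raw.sum()
    ens = make_ensemble(particles, w)
    target = w @ particles
    draws = np.array([resample(ens, rng).particles.mean(axis=0) for _ in range(1000)])
    se = draws.std(axis=0) / np.sqrt(len(draws))
    assert np.all(np.abs(draws.mean(axis=0) - target) < 3 * se + 1e-12)


# ---------------------------------------------------------------------------
# full per-node filter and fit


def test_filter_node_zero_series_stays_near_prior_mean():
    series = pfconn.TimeSeriesMatrix(np.zeros((50, 2)), ["a", "b"])
    cfg = FilterConfig(n_particles=1000, n_repetitions=1, seed=0)
    est = pfconn.filter_node(series, 0, cfg, rep_seed=0)
    assert np.all(np.abs(est) < 0.2)


def test_filter_node_recovers_constant_scalar_coefficient():
    spec = pfconn.SyntheticNetworkSpec(
        n_nodes=1, n_timepoints=200, snr_db=np.inf, seed=6,
        coefficient_override=np.array([[0.5]]),
    )
    series, _ = pfconn.generate(spec)
    cfg = FilterConfig(n_particles=2000, n_repetitions=1, seed=3)
    est = pfconn.filter_node(series, 0, cfg, rep_seed=3)
    last_quarter = est[0, 150:].mean()
    assert abs(last_quarter - 0.5) < 0.1


def test_fit_is_deterministic_and_single_rep_matches_filter_node(small_noisy_series):
    series, _ = small_noisy_series
    cfg = FilterConfig(n_particles=300, n_repetitions=3, seed=9)
    t1 = pfconn.fit(series, cfg)
    t2 = pfconn.fit(series, cfg)
    np.testing.assert_array_equal(t1.values, t2.values)
    np.testing.assert_array_equal(t1.spread, t2.spread)

    cfg1 = FilterConfig(n_particles=300, n_repetitions=1, seed=9)
    single = pfconn.fit(series, cfg1)
    from pfconn.filtering import _resolve_sigma_eta

    sig = _resolve_sigma_eta(series, cfg1)
    for node in range(series.n_nodes):
        np.testing.assert_array_equal(
            single.values[node],
            pfconn.filter_node(series, node, cfg1, cfg1.seed, sigma_eta=sig[node]),
        )


def test_fit_spread_is_nonnegative_and_first_step_finite(small_noisy_series):
    series, _ = small_noisy_series
    traj = pfconn.fit(series, FilterConfig(n_particles=200, n_repetitions=4, seed=2))
    assert np.all(traj.spread >= 0)
    assert np.isfinite(traj.values[:, :, 0]).all()


def test_filter_tracks_switching_coefficient_sign():
    spec = pfconn.SyntheticNetworkSpec(
        n_nodes=2, n_timepoints=250, snr_db=10.0, seed=1,
        coefficient_mode="switching", switch_period=125,
    )
    series, truth = pfconn.generate(spec)
    cfg = FilterConfig(n_particles=1000, n_repetitions=10, seed=0)
    traj = pfconn.fit(series, cfg)
    est = traj.values[1, 0, :]
    true = truth.coefficients.values[1, 0, :]
    # exclude a 15-step transient after the start and after each switch
    keep = np.ones(250, dtype=bool)
    keep[:15] = False
    keep[125:140] = False
    agree = np.mean(np.sign(est[keep]) == np.sign(true[keep]))
    assert agree >= 0.7


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(resample_fraction=0.0)
    with pytest.raises(ValueError):
        FilterConfig(innovation_min=0.5, innovation_max=0.4)
    with pytest.raises(ValueError):
        FilterConfig(obs_noise_sigma=-1.0)
    with pytest.raises(ValueError):
        FilterConfig(obs_noise_sigma="bogus")


def test_ensemble_validation():
    with pytest.raises(ValueError):
        ParticleEnsemble(np.zeros((3, 2)), np.array([0.5, 0.4, 0.2]))
    with pytest.raises(ValueError):
        ParticleEnsemble(np.zeros((3, 2)), np.array([1.2, -0.1, -0.1]))


def test_filter_node_rejects_nonfinite_series():
    x = np.zeros((20, 2))
    x[5, 1] = np.nan
    series = pfconn.TimeSeriesMatrix(x, ["a", "b"])
    with pytest.raises(ValueError, match="non-finite"):
        pfconn.filter_node(series, 0, FilterConfig(n_repetitions=1), rep_seed=0)
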