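"""Bayesian truncated-normal regression: density oracle, diagnostics,
closed-form cross-checks and predictive behaviour."""
import numpy as np
import pytest
from scipy import stats

from hlos import (ModelSpec, PosteriorSamples, PriorSpec, assign_level,
                  build_model, max_rhat, predict, rhat, sample_posterior,
                  summarize_coefficients)


class TestAssignLevel:
    @pytest.mark.parametrize("los,expected", [
        (0, 0), (5, 0), (9.99, 0), (10, 1), (15, 1), (20, 2),
        (29.5, 2), (30, 3), (65, 3),
    ])
    def test_half_open_bins(self, los, expected):
        assert assign_level(los) == expected

    def test_vectorized_and_negative_rejected(self):
        np.testing.assert_array_equal(assign_level([5, 12, 31]), [0, 1, 3])
        with pytest.raises(ValueError, match="negative"):
            assign_level(-1)


def _toy_spec(kind="HBM", n=60, p=3, seed=0, **kw):
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, p))
    levels = rng.integers(0, 4, n) if kind == "HBM" else None
    y = rng.uniform(1, 40, n)
    return ModelSpec(kind=kind, X=X, y=y, level_of_record=levels, **kw)


class TestBuildModel:
    def test_hbm_node_counts_on_44_features(self):
        spec = _toy_spec(n=120, p=44)
        m = build_model(spec)
        assert m.n_intercept_nodes == 4
        assert m.n_coefficient_nodes == 176
        assert m.parameter_nodes["beta"] == (4, 44)
        assert m.parameter_nodes["sigma"] == ()

    def test_sbm_node_counts(self):
        m = build_model(_toy_spec(kind="SBM", p=44, n=120))
        assert m.n_intercept_nodes == 1
        assert m.n_coefficient_nodes == 44

    def test_bad_inputs_rejected(self):
        spec = _toy_spec()
        spec.level_of_record = np.full(60, 7)
        with pytest.raises(ValueError, match="level index"):
            build_model(spec)
        spec2 = _toy_spec()
        spec2.X = spec2.X.copy()
        spec2.X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            build_model(spec2)
        spec3 = _toy_spec(kind="HBM")
        spec3.level_of_record = None
        with pytest.raises(ValueError, match="level_of_record"):
            build_model(spec3)

    def test_single_level_hbm_matches_sbm_log_density(self):
        """With every record in level 0 the hierarchical likelihood reduces
        to the pooled one at matching parameter values."""
        rng = np.random.default_rng(1)
        n, p = 40, 3
        X = rng.uniform(size=(n, p))
        y = rng.uniform(2, 12, n)
        hbm = build_model(ModelSpec(kind="HBM", X=X, y=y,
                                    level_of_record=np.zeros(n, dtype=int)))
        sbm = build_model(ModelSpec(kind="SBM", X=X, y=y))
        th_s = sbm.initial_point()
        th_h = np.zeros(hbm.n_parameters)
        # copy shared coordinates; unused levels get arbitrary values
        th_h[hbm.slices["beta0"]] = np.array([th_s[sbm.slices["beta0"]][0]] * 4)
        th_h[hbm.slices["beta"]] = np.tile(th_s[sbm.slices["beta"]], 4)
        th_h[hbm.slices["log_sigma"]] = th_s[sbm.slices["log_sigma"]]
        ll_h = hbm.log_likelihood(th_h[None, :])[0]
        ll_s = sbm.log_likelihood(th_s[None, :])[0]
        assert ll_h == pytest.approx(ll_s, abs=1e-10)


def test_log_density_matches_independent_evaluator():
    """The vectorized truncated-normal likelihood equals a naive per-record
    scipy.stats.truncnorm evaluation at 50 random parameter points."""
    rng = np.random.default_rng(5)
    n, p, L = 30, 3, 4
    X = rng.uniform(size=(n, p))
    levels = rng.integers(0, L, n)
    y = rng.uniform(1, 38, n)
    m = build_model(ModelSpec(kind="HBM", X=X, y=y, level_of_record=levels))

    def oracle(beta0, beta, sigma):
        total = 0.0
        for i in range(n):
            mu = beta0[levels[i]] + float(X[i] @ beta[levels[i]])
            a = (0.0 - mu) / sigma
            total += stats.truncnorm.logpdf(y[i], a, np.inf, loc=mu, scale=sigma)
        return total

    for _ in range(50):
        th = rng.normal(0, 1, m.n_parameters)
        th[m.slices["beta0"]] = rng.uniform(1, 30, L)
        th[m.slices["log_sigma"]] = rng.uniform(-0.5, 1.5)
        beta0 = th[m.slices["beta0"]]
        beta = th[m.slices["beta"]].reshape(L, p)
        sigma = float(np.exp(th[m.slices["log_sigma"]])[0])
        assert m.log_likelihood(th[None, :])[0] == pytest.approx(
            oracle(beta0, beta, sigma), abs=1e-8)


class TestRhat:
    def _samples(self, arr):
        return PosteriorSamples(draws={"x": arr}, chains=arr.shape[0],
                                n_draws=arr.shape[1], tune=0,
                                divergence_count=0, seed=0)

    def test_constant_chains_exactly_one(self):
        s = self._samples(np.full((4, 100), 3.0))
        assert rhat(s)["x"] == 1.0

    def test_iid_chains_near_one(self, rng):
        s = self._samples(rng.normal(size=(4, 3000)))
        assert rhat(s)["x"] == pytest.approx(1.0, abs=0.01)

    def test_shifted_chains_flagged(self, rng):
        arr = rng.normal(size=(2, 500))
        arr[1] += 5.0
        s = self._samples(arr)
        diag = rhat(s)
        assert diag["x"] > 1.1
        assert ("x", (0,)) in diag["flagged"] or diag["flagged"]

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            rhat(self._samples(np.zeros((1, 50))))


def test_untruncated_limit_matches_conjugate_posterior():
    """Data far from zero, fixed sigma, fixed Gaussian priors: posterior
    coefficient means match (X'X/s^2 + I/t^2)^-1 X'y/s^2 within 3 MC
    standard errors."""
    rng = np.random.default_rng(9)
    n, p = 200, 3
    X = rng.uniform(size=(n, p))
    beta_true = np.array([2.0, -1.0, 0.5])
    sigma = 1.0
    y = 50.0 + X @ beta_true + rng.normal(0, sigma, n)

    tau = 10.0
    priors = PriorSpec(hierarchical=False, fixed_beta_scale=tau,
                       fixed_beta0_scale=tau * 10, fixed_sigma=sigma,
                       truncated=False)
    m = build_model(ModelSpec(kind="SBM", X=X, y=y, priors=priors))
    s = sample_posterior(m, chains=4, draws=1000, tune=600, seed=0, thin=5)
    assert max_rhat(s) < 1.05

    Xa = np.column_stack([np.ones(n), X])
    prior_prec = np.diag([1 / (tau * 10) ** 2] + [1 / tau ** 2] * p)
    A = Xa.T @ Xa / sigma ** 2 + prior_prec
    post_mean = np.linalg.solve(A, Xa.T @ y / sigma ** 2)
    post_sd = np.sqrt(np.diag(np.linalg.inv(A)))

    got_b0 = s.flat("beta0")[:, 0]
    got_b = s.flat("beta")[:, 0, :]
    S = got_b0.size
    # conservative effective sample size for the MC error of the mean
    ess = S / 20
    for j, (mu_ref, sd_ref) in enumerate(zip(post_mean, post_sd)):
        got = got_b0 if j == 0 else got_b[:, j - 1]
        mc_err = got.std(ddof=1) / np.sqrt(ess)
        assert abs(got.mean() - mu_ref) < 3 * max(mc_err, 1e-6) + 0.02 * sd_ref, j


def test_sampler_seeded_determinism():
    m = build_model(_toy_spec(kind="SBM", n=40, p=2, seed=3))
    s1 = sample_posterior(m, chains=2, draws=100, tune=100, seed=4, thin=1)
    s2 = sample_posterior(m, chains=2, draws=100, tune=100, seed=4, thin=1)
    for k in s1.draws:
        np.testing.assert_array_equal(s1.draws[k], s2.draws[k])
    assert s1.divergence_count == 0


def test_tight_zero_priors_on_zero_data_keep_coefficients_near_zero():
    rng = np.random.default_rng(2)
    n, p = 80, 2
    X = rng.uniform(size=(n, p))
    y = np.zeros(n) + 1e-6
    priors = PriorSpec(hierarchical=False, fixed_beta_scale=0.01,
                       fixed_beta0_scale=0.01, fixed_sigma=1.0, truncated=False)
    m = build_model(ModelSpec(kind="SBM", X=X, y=y, priors=priors))
    s = sample_posterior(m, chains=2, draws=400, tune=300, seed=0, thin=2)
    assert np.all(np.abs(s.flat("beta").mean(axis=0)) < 0.02)
    assert abs(s.flat("beta0").mean()) < 0.02


def test_log_target_variant_recovers_multiplicative_signal():
    """The log-scale option fits log(LoS) with an untruncated normal and
    back-transforms predictions to days."""
    rng = np.random.default_rng(6)
    n = 300
    X = rng.uniform(size=(n, 2))
    y = np.exp(1.8 + 0.6 * X[:, 0] + rng.normal(0, 0.05, n))
    spec = ModelSpec(kind="SBM", X=X, y=y, log_target=True,
                     priors=PriorSpec(hierarchical=False, fixed_beta_scale=5,
                                      fixed_beta0_scale=5))
    m = build_model(spec)
    assert not m.spec.priors.truncated
    s = sample_posterior(m, chains=2, draws=400, tune=400, seed=0, thin=2)
    assert s.log_target
    b = s.flat("beta")[:, 0, 0].mean()
    assert b == pytest.approx(0.6, abs=0.1)
    out = predict(s, X[:20], level_mode="oracle", y_test=y[:20], seed=0)
    assert np.all(out.mean > 0)
    # back-transformed predictions track the observed scale
    assert np.corrcoef(out.mean, y[:20])[0, 1] > 0.9


class TestPredict:
    def _inject(self, beta0, beta, sigma, chains=2, draws=50):
        L, p = beta.shape
        d = {"beta0": np.tile(beta0, (chains, draws, 1)),
             "beta": np.tile(beta, (chains, draws, 1, 1)),
             "sigma": np.full((chains, draws), sigma)}
        return PosteriorSamples(draws=d, chains=chains, n_draws=draws, tune=0,
                                divergence_count=0, seed=0)

    def test_noiseless_oracle_equals_linear_predictor(self):
        beta0 = np.array([5.0, 15.0, 25.0, 34.0])
        beta = np.array([[1.0, -0.5]] * 4)
        s = self._inject(beta0, beta, 1e-9)
        X = np.array([[0.2, 0.4], [0.8, 0.1]])
        y = np.array([5.0, 15.0])       # levels 0 and 1
        out = predict(s, X, level_mode="oracle", y_test=y, seed=0)
        expect = beta0[[0, 1]] + X @ beta[0]
        np.testing.assert_allclose(out.mean, expect, atol=1e-6)
        np.testing.assert_allclose(out.lower, expect, atol=1e-4)
        np.testing.assert_allclose(out.upper, expect, atol=1e-4)

    def test_single_level_oracle_equals_marginal(self):
        beta0 = np.array([8.0])
        beta = np.array([[0.5, 0.5]])
        s = self._inject(beta0, beta, 0.3)
        X = np.array([[0.3, 0.6], [0.9, 0.2]])
        o = predict(s, X, level_mode="oracle", y_test=np.array([8.0, 9.0]),
                    seed=1)
        m = predict(s, X, level_mode="marginal",
                    train_level_frequencies=np.array([1.0]), seed=1)
        np.testing.assert_allclose(o.mean, m.mean, atol=1e-9)

    def test_marginal_mixture_weights_and_positivity(self):
        beta0 = np.array([5.0, 15.0, 25.0, 34.0])
        beta = np.zeros((4, 2))
        s = self._inject(beta0, beta, 0.5, draws=400)
        w = np.array([0.7, 0.2, 0.08, 0.02])
        X = np.zeros((3, 2))
        out = predict(s, X, level_mode="marginal", train_level_frequencies=w,
                      seed=0)
        np.testing.assert_allclose(out.mean, (w * beta0).sum(), rtol=1e-3)
        assert np.all(out.lower >= 0) and np.all(out.mean >= 0)
        assert np.all(out.lower <= out.mean) and np.all(out.mean <= out.upper)

    def test_oracle_requires_y_test(self):
        s = self._inject(np.array([8.0]), np.zeros((1, 2)), 0.5)
        with pytest.raises(ValueError, match="y_test"):
            predict(s, np.zeros((2, 2)), level_mode="oracle")


class TestSummarize:
    def test_constant_draws(self):
        d = {"beta0": np.full((2, 10, 1), 1.0),
             "beta": np.full((2, 10, 1, 3), 0.5),
             "sigma": np.full((2, 10), 1.0)}
        s = PosteriorSamples(draws=d, chains=2, n_draws=10, tune=0,
                             divergence_count=0, seed=0,
                             feature_names=["a", "b", "c"])
        tables = summarize_coefficients(s)
        assert list(tables) == [0]
        assert (tables[0]["mean"] == 0.5).all()
        assert (tables[0]["sd"] == 0.0).all()
        assert tables[0]["summary"].iloc[0] == "0.500 ± 0.000"

    def test_two_point_draws_sample_sd(self):
        vals = np.zeros((2, 2, 1, 1))
        vals[:, 1] = 1.0     # draws alternate 0 and 1
        d = {"beta0": np.zeros((2, 2, 1)), "beta": vals,
             "sigma": np.ones((2, 2))}
        s = PosteriorSamples(draws=d, chains=2, n_draws=2, tune=0,
                             divergence_count=0, seed=0)
        t = summarize_coefficients(s)[0]
        assert t["mean"].iloc[0] == pytest.approx(0.5)
        assert t["sd"].iloc[0] == pytest.approx(np.std([0, 1, 0, 1], ddof=1))

    def test_four_levels_by_44_features_structure(self):
        rng = np.random.default_rng(0)
        d = {"beta0": rng.normal(size=(2, 5, 4)),
             "beta": rng.normal(size=(2, 5, 4, 44)),
             "sigma": np.ones((2, 5))}
        s = PosteriorSamples(draws=d, chains=2, n_draws=5, tune=0,
                             divergence_count=0, seed=0)
        tables = summarize_coefficients(s)
        assert len(tables) == 4
        assert all(len(t) == 44 for t in tables.values())
        # sorted by |mean| descending
        for t in tables.values():
            m = t["mean"].abs().to_numpy()
            assert np.all(m[:-1] >= m[1:] - 1e-12)
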