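"""Gaussian-process regression and the multi-fidelity (NARGP) surrogate."""

import numpy as np
import pytest

from bcsheal.gp import (
    GPModel,
    InputScaler,
    MFGPModel,
    SEKernel,
    _split_sizes,
    nargp_kernel,
    prediction_maps,
    fit_visibility_classifier,
    predict_visibility,
)

RNG = np.random.default_rng(42)


def forrester(x):
    return (6 * x - 2) ** 2 * np.sin(12 * x - 4)


def forrester_low(x):
    return 0.5 * forrester(x) + 10 * (x - 0.5) - 5


class TestGPRegression:
    def test_mll_matches_dense_oracle(self):
        """Marginal log-likelihood equals a direct dense evaluation
        (solve + slogdet, no Cholesky shortcuts) to 1e-10."""
        X = RNG.uniform(0, 1, (3, 2))
        y = np.array([0.3, -1.2, 0.8])
        gp = GPModel(SEKernel([0, 1]))
        theta = np.array([0.2, -0.3, 0.4, np.log(1e-3)])
        K = gp.kernel.cross(theta[:-1], X, X) + (1e-3 + gp.noise_floor) * np.eye(3)
        direct = (-0.5 * y @ np.linalg.solve(K, y)
                  - 0.5 * np.linalg.slogdet(K)[1]
                  - 1.5 * np.log(2 * np.pi))
        assert gp.log_marginal_likelihood(theta, X, y) == pytest.approx(direct, abs=1e-10)

    def test_gradient_matches_finite_differences(self):
        X = RNG.uniform(0, 1, (12, 3))
        y = np.sin(X.sum(axis=1))
        gp = GPModel(nargp_kernel(2))
        theta = RNG.normal(0, 0.5, gp.kernel.n_params + 1)
        _, g = gp.log_marginal_likelihood(theta, X, y, with_grad=True)
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += 1e-6
            tm[i] -= 1e-6
            fd = (gp.log_marginal_likelihood(tp, X, y)
                  - gp.log_marginal_likelihood(tm, X, y)) / 2e-6
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_noise_free_interpolation(self):
        X = RNG.uniform(0, 1, (15, 1))
        y = np.sin(4 * X[:, 0])
        gp = GPModel(SEKernel([0])).fit(X, y, fix_noise=1e-10, seed=0)
        m, v = gp.predict(X)
        np.testing.assert_allclose(m, y, atol=1e-6)
        assert v.max() < 1e-4 * y.var()

    def test_prior_reversion_far_from_data(self):
        X = RNG.uniform(0, 0.2, (10, 1))
        y = 1.0 + np.sin(9 * X[:, 0])
        gp = GPModel(SEKernel([0])).fit(X, y, seed=1)
        m, v = gp.predict(np.array([[50.0]]))
        assert m[0] == pytest.approx(gp.y_mean, abs=1e-6)  # standardized prior mean 0
        prior_var = np.exp(gp.params[0]) * gp.y_std**2
        assert v[0] == pytest.approx(prior_var, rel=1e-6)

    def test_one_point_closed_form(self):
        """Two-point noise-free model against the hand-evaluated posterior."""
        X = np.array([[0.3], [0.9]])
        y = np.array([1.0, -0.5])
        gp = GPModel(SEKernel([0]))
        gp.fit(X, y, restarts=1, init_noise=1e-8, seed=0)
        xs = np.array([[0.5]])
        m, _ = gp.predict(xs)
        th = gp.params
        K = gp.kernel.cross(th[:-1], X, X) + (np.exp(th[-1]) + gp.noise_floor) * np.eye(2)
        k = gp.kernel.cross(th[:-1], xs, X)
        ys = (y - gp.y_mean) / gp.y_std
        hand = (k @ np.linalg.solve(K, ys))[0] * gp.y_std + gp.y_mean
        assert m[0] == pytest.approx(hand, rel=1e-10)

    def test_conflicting_duplicates_force_noise(self):
        X = np.array([[0.5], [0.5], [0.1], [0.9]])
        y = np.array([1.0, -1.0, 0.0, 0.0])
        gp = GPModel(SEKernel([0])).fit(X, y, seed=0)
        assert gp.noise_variance > 1e-3

    def test_posterior_matches_sklearn(self):
        """Independent cross-check against scikit-learn's GP with the same
        kernel family on the same data."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        rng = np.random.default_rng(99)
        X = rng.uniform(0, 1, (25, 2))
        y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2
        ours = GPModel(SEKernel([0, 1])).fit(X, y, seed=0, fix_noise=1e-6)
        sk = GaussianProcessRegressor(
            ConstantKernel() * RBF([1.0, 1.0]) + WhiteKernel(1e-6, (1e-10, 1e-2)),
            normalize_y=True, n_restarts_optimizer=3, random_state=0).fit(X, y)
        Xs = rng.uniform(0, 1, (50, 2))
        m_ours, _ = ours.predict(Xs)
        m_sk = sk.predict(Xs)
        np.testing.assert_allclose(m_ours, m_sk, atol=0.02)


class TestMultiFidelity:
    @pytest.fixture(scope="class")
    def forrester_data(self):
        x1 = np.linspace(0, 1, 21)[:, None]
        x2 = np.array([0.05, 0.3, 0.55, 0.8, 0.95])[:, None]
        return x1, forrester_low(x1).ravel(), x2, forrester(x2).ravel()

    def test_beats_single_fidelity_on_benchmark(self, forrester_data):
        """On the classic 1-D bi-fidelity benchmark the multi-fidelity model
        strictly beats a single-fidelity GP trained on the same 5
        high-fidelity points, for every one of 10 seeds."""
        x1, y1, x2, y2 = forrester_data
        xs = np.linspace(0, 1, 100)[:, None]
        truth = forrester(xs).ravel()
        for seed in range(10):
            mf = MFGPModel().fit(x1, y1, x2, y2, seed=seed)
            m, _ = mf.predict(xs, n_mc=200, seed=seed)
            rmse_mf = np.sqrt(np.mean((m - truth) ** 2))
            sf = GPModel(SEKernel([0])).fit(x2, y2, seed=seed)
            m_sf, _ = sf.predict(xs)
            rmse_sf = np.sqrt(np.mean((m_sf - truth) ** 2))
            assert rmse_mf < rmse_sf

    def test_degenerate_fidelity(self):
        """If high fidelity equals low fidelity as a function, the MF
        prediction matches the level-1 prediction within 2% RMS."""
        x1 = np.linspace(0, 1, 25)[:, None]
        x2 = np.linspace(0.05, 0.95, 8)[:, None]
        f = lambda x: np.sin(5 * x).ravel()
        mf = MFGPModel().fit(x1, f(x1), x2, f(x2), seed=0)
        xs = np.linspace(0, 1, 60)[:, None]
        m, _ = mf.predict(xs, n_mc=200, seed=0)
        m1, _ = mf.gp1.predict(xs)
        assert np.sqrt(np.mean((m - m1) ** 2)) < 0.02 * np.std(f(x1))

    def test_linear_link_recovery(self):
        """y2 = 2 y1 + 1: the autoregressive level learns the link from 10
        high-fidelity points (test RMSE below 5% of output SD)."""
        x1 = np.linspace(0, 1, 50)[:, None]
        x2 = np.linspace(0.02, 0.98, 10)[:, None]
        f1 = lambda x: np.sin(6 * x).ravel()
        f2 = lambda x: 2 * f1(x) + 1
        mf = MFGPModel().fit(x1, f1(x1), x2, f2(x2), seed=3)
        xs = np.linspace(0, 1, 80)[:, None]
        m, _ = mf.predict(xs, n_mc=200, seed=0)
        rmse = np.sqrt(np.mean((m - f2(xs)) ** 2))
        assert rmse < 0.05 * f2(xs).std()

    def test_mc_determinism(self, forrester_data):
        x1, y1, x2, y2 = forrester_data
        mf = MFGPModel().fit(x1, y1, x2, y2, seed=0)
        xs = np.linspace(0, 1, 20)[:, None]
        a, va = mf.predict(xs, n_mc=150, seed=9)
        b, vb = mf.predict(xs, n_mc=150, seed=9)
        assert np.array_equal(a, b) and np.array_equal(va, vb)

    def test_mc_collapses_when_level1_certain(self, forrester_data):
        """Zero level-1 posterior variance makes the MC estimate equal
        direct level-2 conditioning."""
        x1, y1, x2, y2 = forrester_data
        mf = MFGPModel().fit(x1, y1, x2, y2, seed=0)
        m_mc, v_mc = mf.predict(x1[:5], n_mc=400, seed=0)
        mu1, var1 = mf.gp1.predict(x1[:5])
        assert var1.max() < 1e-3  # near-interpolation at training lows
        Xaug = np.column_stack([x1[:5], mu1 / mf.f_scale])
        m_dir, _ = mf.gp2.predict(Xaug)
        np.testing.assert_allclose(m_mc, m_dir, atol=0.05 * np.std(y2))

    def test_variance_nonnegative(self, forrester_data):
        x1, y1, x2, y2 = forrester_data
        mf = MFGPModel().fit(x1, y1, x2, y2, seed=0)
        _, v = mf.predict(RNG.uniform(0, 1, (30, 1)), n_mc=100, seed=0)
        assert (v >= 0).all()


class TestValidationProtocol:
    def test_split_sizes_paper_scale(self):
        assert _split_sizes(163) == (150, 13)

    def test_bookkeeping_260_predictions(self):
        """20 repeats x 13-point test sets record exactly 260 predictions at
        the full-study scale (run on cheap synthetic outcome stubs)."""
        from bcsheal.gp import validate
        from bcsheal.outcomes import SimulationOutcome
        from bcsheal.cohort import PatientCharacteristics, TABLE_RANGES

        def stub(i, n):
            rng = np.random.default_rng(i)
            vals = {k: rng.uniform(*TABLE_RANGES[k]) for k in TABLE_RANGES}
            ch = PatientCharacteristics(vals["breast_density"],
                                        min(vals["cavity_volume"], vals["breast_volume"] / 2),
                                        vals["breast_volume"], vals["cavity_depth"], 0.0, seed=i)
            pbsd = 100.0 / (1 + np.exp(-(vals["cavity_volume"] / 8000 - 2)))
            days = np.array([0.0, 14.0, 28.0])
            contraction = np.array([100.0, 40.0 + 30 * vals["breast_density"], 55.0])
            return SimulationOutcome(days=days, contraction=contraction, pbsd=pbsd,
                                     week4_skin_displacement=np.zeros(1),
                                     cavity_depth=vals["cavity_depth"],
                                     characteristics=ch)

        low = [stub(i, 0) for i in range(30)]
        high = [stub(1000 + i, 0) for i in range(163)]
        rep = validate(low, high, n_repeats=20, seed=0, restarts=1, n_mc=20,
                       surrogates=("bsd",))
        assert rep.n_test == 13
        assert rep.n_predictions == 260
        assert len(rep.mae_bsd) == 20

    def test_metrics_match_hand_arithmetic(self):
        preds = np.array([1.0, 2.0, 4.0])
        truth = np.array([1.5, 1.0, 4.5])
        mae = np.mean(np.abs(preds - truth))
        rmse = np.sqrt(np.mean((preds - truth) ** 2))
        assert mae == pytest.approx((0.5 + 1.0 + 0.5) / 3)
        assert rmse == pytest.approx(np.sqrt((0.25 + 1.0 + 0.25) / 3))


class TestClassifierAndMaps:
    def test_all_zero_scores_predict_zero(self):
        X = RNG.uniform(0, 1, (12, 4)) * np.array([0.7, 30000, 3e6, 50]) + np.array(
            [0.05, 100, 1e5, 7])
        model, sc = fit_visibility_classifier(X, np.zeros(12), seed=0)
        lik, _ = predict_visibility(model, sc, X + RNG.uniform(0, 0.01, X.shape))
        np.testing.assert_allclose(lik, 0.0, atol=1e-6)

    def test_training_point_reproduced(self):
        X = RNG.uniform(0, 1, (10, 4)) * np.array([0.6, 30000, 3e6, 45]) + np.array(
            [0.05, 100, 1.2e5, 7])
        scores = RNG.uniform(0, 1, 10)
        model, sc = fit_visibility_classifier(X, scores, seed=0)
        lik, _ = predict_visibility(model, sc, X)
        np.testing.assert_allclose(lik, np.clip(scores, 0, 1), atol=0.05)

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_visibility_classifier(RNG.uniform(0, 1, (5, 4)), np.array([0, 0.5, 2, 0, 0]))

    def test_prediction_maps_shape_and_consistency(self):
        grid_n = 8

        def flat(X):
            return np.full(len(X), 7.0), np.full(len(X), 0.25)

        m = prediction_maps(flat, ("cavity_volume", "breast_density"), grid_n=grid_n)
        assert m["mean"].shape == (grid_n, grid_n)
        np.testing.assert_allclose(m["mean"], 7.0)
        np.testing.assert_allclose(m["sd"], 0.5)
        assert m["axis_1"][0] == pytest.approx(33.41) and m["axis_1"][-1] == pytest.approx(35096.57)

    def test_map_grid_50_gives_2500_points(self):
        calls = {}

        def probe(X):
            calls["n"] = len(X)
            return np.zeros(len(X)), np.zeros(len(X))

        prediction_maps(probe, ("cavity_depth", "breast_density"), grid_n=50)
        assert calls["n"] == 2500

    def test_input_scaler_roundtrip(self):
        sc = InputScaler(with_time=True)
        med = sc.median_point()
        X = np.concatenate([med, [14.0]])[None, :]
        t = sc.transform(X)
        assert t.shape == (1, 5)
        assert (t >= 0).all() and (t <= 1).all()
        assert t[0, 4] == pytest.approx(0.5)
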