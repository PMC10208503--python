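"""Sum-of-trees sampler: fits, priors, missing data, selection, metrics."""

import numpy as np
import pandas as pd
import pytest

from gaitcausal.bart import (
    BARTConfig,
    SumOfTreesPosterior,
    cv_select,
    fit,
    fit_metrics,
    predict,
)


def linear_data(rng, n=200, slope=2.0, noise=0.1):
    x = rng.uniform(0, 1, n)
    return x[:, None], slope * x + rng.normal(0, noise, n)


class TestFit:
    def test_constant_response_degenerate(self, rng, fast_bart):
        X = rng.uniform(0, 1, (60, 2))
        y = np.full(60, 7.0)
        model = fit(X, y, fast_bart)
        np.testing.assert_allclose(predict(model, X), 7.0, atol=1e-6)
        assert model.sigma.mean() < 1e-3

    def test_linear_signal_recovered(self, rng, fast_bart):
        X, y = linear_data(rng)
        model = fit(X, y, fast_bart)
        Xt, yt = linear_data(rng)
        pred = predict(model, Xt)
        r2 = 1 - np.sum((yt - pred) ** 2) / np.sum((yt - yt.mean()) ** 2)
        assert r2 > 0.9
        # contrast between x=1 and x=0 close to the true slope
        delta = predict(model, np.array([[1.0]]))[0] - predict(model, np.array([[0.0]]))[0]
        assert delta == pytest.approx(2.0, rel=0.2)

    def test_sigma_concentrates_near_truth(self, rng):
        X = rng.uniform(0, 1, (1000, 1))
        y = 2 * X[:, 0] + rng.normal(0, 0.5, 1000)
        model = fit(X, y, BARTConfig(num_trees=30, k=2, n_burn=300, n_draws=300, seed=2))
        assert model.sigma.mean() == pytest.approx(0.5, rel=0.25)

    def test_fixed_seed_bit_identical(self, rng, fast_bart):
        X, y = linear_data(rng, n=80)
        m1 = fit(X, y, fast_bart)
        m2 = fit(X, y, fast_bart)
        assert m1.forests == m2.forests
        np.testing.assert_array_equal(m1.sigma, m2.sigma)

    @pytest.mark.parametrize(
        "bad,match",
        [
            (dict(num_trees=0), "num_trees"),
            (dict(k=-1.0), "k > 0"),
            (dict(q=1.5), "q in"),
            (dict(alpha=1.5), "alpha"),
        ],
    )
    def test_config_validation(self, bad, match):
        with pytest.raises(ValueError, match=match):
            BARTConfig(**bad)

    def test_input_validation(self, rng, fast_bart):
        X, y = linear_data(rng, n=30)
        with pytest.raises(ValueError, match="at least 20"):
            fit(X[:10], y[:10], fast_bart)
        y_nan = y.copy()
        y_nan[0] = np.nan
        with pytest.raises(ValueError, match="response contains missing"):
            fit(X, y_nan, fast_bart)
        X_allnan = X.copy()
        X_allnan[:, 0] = np.nan
        with pytest.raises(ValueError, match="all-missing"):
            fit(X_allnan, y, fast_bart)

    def test_missing_requires_flag(self, rng, fast_bart):
        X, y = linear_data(rng, n=50)
        X[0, 0] = np.nan
        cfg = BARTConfig(**{**fast_bart.__dict__, "use_missing_data": False})
        with pytest.raises(ValueError, match="use_missing_data"):
            fit(X, y, cfg)

    def test_missingness_signal_exploited(self, rng, fast_bart):
        # y jumps when x is missing: the MIA fit must beat complete cases
        n = 400
        x = rng.uniform(0, 1, n)
        missing = rng.random(n) < 0.4
        y = np.where(missing, 3.0, 0.0) + x + rng.normal(0, 0.3, n)
        x_obs = x.copy()
        x_obs[missing] = np.nan
        X = pd.DataFrame({"x": x_obs})
        train = np.arange(n) < 300
        mia = fit(X[train], y[train], fast_bart)
        r2_mia = fit_metrics(mia, X[~train], y[~train]).r_squared
        cc_rows = train & ~missing
        cfg_cc = BARTConfig(**{**fast_bart.__dict__, "use_missing_data": False})
        cc = fit(X[cc_rows], y[cc_rows], cfg_cc)
        pred_cc = predict(cc, X[~train].fillna(0.5))
        r2_cc = 1 - np.sum((y[~train] - pred_cc) ** 2) / np.sum(
            (y[~train] - y[~train].mean()) ** 2
        )
        assert r2_mia > r2_cc

    def test_prior_only_chain_matches_tree_prior(self, rng):
        # with the likelihood switched off the chain must sample the
        # alpha(1+d)^-beta structure prior; compare to direct generation
        cfg = BARTConfig(
            num_trees=1, k=2, n_burn=500, n_draws=1500, seed=4, min_leaf=1
        )
        X = rng.uniform(0, 1, (300, 3))
        y = rng.normal(0, 1, 300)
        model = fit(X, y, cfg, _prior_only=True)

        def depth(t):
            return 0 if t[0] == 0 else 1 + max(depth(t[4]), depth(t[5]))

        mcmc_depths = np.array([depth(f[0]) for f in model.forests])

        def gen_depth(g, d=0):
            if g.random() < cfg.alpha * (1 + d) ** -cfg.beta:
                return 1 + max(gen_depth(g, d + 1), gen_depth(g, d + 1))
            return 0

        g = np.random.default_rng(5)
        gen_depths = np.array([gen_depth(g) for _ in range(4000)])
        assert np.mean(mcmc_depths) == pytest.approx(np.mean(gen_depths), abs=0.25)
        assert np.mean(mcmc_depths == 0) == pytest.approx(
            np.mean(gen_depths == 0), abs=0.04
        )


class TestPredict:
    def test_row_order_permutation(self, rng, fast_bart):
        X, y = linear_data(rng, n=60)
        model = fit(X, y, fast_bart)
        perm = rng.permutation(60)
        np.testing.assert_allclose(predict(model, X[perm]), predict(model, X)[perm])

    def test_column_mismatch_rejected(self, rng, fast_bart):
        X = pd.DataFrame({"a": rng.uniform(0, 1, 40), "b": rng.uniform(0, 1, 40)})
        model = fit(X, 2 * X["a"].to_numpy(), fast_bart)
        with pytest.raises(KeyError, match="lacks training column"):
            predict(model, X.rename(columns={"b": "c"}))

    def test_missing_at_predict_requires_missing_training(self, rng, fast_bart):
        X, y = linear_data(rng, n=40)
        model = fit(X, y, fast_bart)
        Xq = X[:5].copy()
        Xq[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            predict(model, Xq)

    def test_serialization_round_trip(self, rng, fast_bart):
        X, y = linear_data(rng, n=60)
        model = fit(X, y, fast_bart)
        restored = SumOfTreesPosterior.from_json(model.to_json())
        np.testing.assert_allclose(predict(restored, X), predict(model, X))


class TestMetricsAndSelection:
    def test_perfect_and_mean_predictions(self, rng, fast_bart):
        X = rng.uniform(0, 1, (60, 1))
        y = np.where(X[:, 0] > 0.5, 1.0, 0.0)  # perfectly separable step
        model = fit(X, y, BARTConfig(num_trees=20, k=1, n_burn=400, n_draws=400, seed=3))
        m = fit_metrics(model, X, y)
        assert m.r_squared > 0.97
        assert m.rmse < 0.1
        with pytest.raises(ValueError, match="zero-variance"):
            fit_metrics(model, X, np.zeros(60))

    def test_in_sample_beats_held_out(self, rng, fast_bart):
        X = rng.uniform(0, 1, (300, 3))
        y = 10 * np.sin(np.pi * X[:, 0] * X[:, 1]) + rng.normal(0, 1, 300)
        model = fit(X[:200], y[:200], fast_bart)
        r2_in = fit_metrics(model, X[:200], y[:200]).r_squared
        r2_out = fit_metrics(model, X[200:], y[200:]).r_squared
        assert r2_in > r2_out

    def test_cv_single_config_returned(self, rng, fast_bart):
        X, y = linear_data(rng, n=100)
        best, table = cv_select(X, y, [fast_bart], folds=2)
        assert best == fast_bart
        assert len(table) == 1

    def test_cv_argmin_property(self, rng):
        X, y = linear_data(rng, n=120, noise=0.3)
        grid = [
            BARTConfig(num_trees=10, k=2, n_burn=100, n_draws=100, seed=1),
            BARTConfig(num_trees=10, k=5, n_burn=100, n_draws=100, seed=1),
        ]
        best, table = cv_select(X, y, grid, folds=2)
        assert table["cv_rmse"].min() == table.loc[
            table["config_index"] == grid.index(best), "cv_rmse"
        ].iloc[0]

    def test_cv_fold_size_guard(self, rng, fast_bart):
        X, y = linear_data(rng, n=30)
        with pytest.raises(ValueError, match="at least 10 rows"):
            cv_select(X, y, [fast_bart], folds=4)
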