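"""GBLUP / BayesB / RF behavior and cross-validation mechanics."""

import numpy as np
import pandas as pd
import pytest

import plustree as pt


def _marker_kinship(X):
    W = X - X.mean(axis=0)
    p = X.mean(axis=0) / 2.0 + 0.5
    return W @ W.T / (2.0 * np.sum(p * (1 - p)))


class TestGBLUP:
    def test_equals_marker_ridge_regression(self, rng):
        """GBLUP with K = WW'/c reproduces ridge-regression (marker-effect)
        test predictions exactly."""
        n, m = 30, 100
        X = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
        y = X @ rng.normal(0, 0.3, m) + rng.normal(0, 1, n)
        W = X - X.mean(0)
        p = X.mean(0) / 2 + 0.5
        c = 2 * np.sum(p * (1 - p))
        K = W @ W.T / c
        train, test = np.arange(20), np.arange(20, 30)
        pred = pt.gblup_fit_predict(y[train], K, train, test, ridge=0.0)
        # oracle: closed-form RR-BLUP at the same REML variance ratio
        from scipy import optimize

        Ktr = K[np.ix_(train, train)]
        S, U = np.linalg.eigh(Ktr)
        S = np.clip(S, 0, None)
        yt, ot = U.T @ y[train], U.T @ np.ones(20)

        def nr(ld):
            w = S + np.exp(ld)
            a, b = ot @ (ot / w), ot @ (yt / w)
            r = yt - (b / a) * ot
            return 19 * np.log(r @ (r / w)) + np.sum(np.log(w)) + np.log(a)

        grid = np.linspace(-8, 8, 33)
        g0 = grid[np.argmin([nr(g) for g in grid])]
        res = optimize.minimize_scalar(nr, bounds=(g0 - 1, g0 + 1), method="bounded")
        delta = np.exp(res.x)
        w = S + delta
        mu = (ot @ (yt / w)) / (ot @ (ot / w))
        beta = W[train].T @ np.linalg.solve(
            W[train] @ W[train].T / c + delta * np.eye(20), y[train] - mu
        ) / c
        oracle = mu + W[test] @ beta
        np.testing.assert_allclose(pred, oracle, atol=1e-6)

    def test_interpolation_limit_with_duplicates(self, rng):
        """Noise-free trait + duplicated genotype: the held-out duplicate's
        prediction reproduces its twin's phenotype."""
        n, m = 40, 300
        X = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
        X[-1] = X[0]
        y = X @ rng.normal(0, 1, m) / np.sqrt(m)
        K = _marker_kinship(X)
        pred = pt.gblup_fit_predict(y[:-1], K, np.arange(n - 1), np.array([n - 1]))
        assert pred[0] == pytest.approx(y[0], abs=0.05 * np.std(y))

    def test_permuted_phenotypes_average_zero_accuracy(self, rng):
        n, m = 100, 200
        X = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
        y = X @ rng.normal(0, 1, m)
        K = _marker_kinship(X)
        accs = []
        for _ in range(20):
            yp = rng.permutation(y)
            pred = pt.gblup_fit_predict(yp[:70], K, np.arange(70), np.arange(70, 100))
            accs.append(np.corrcoef(pred, yp[70:])[0, 1])
        assert abs(np.mean(accs)) < 0.1

    def test_row_order_invariance(self, rng):
        n, m = 50, 150
        X = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
        y = X @ rng.normal(0, 1, m) + rng.normal(0, 1, n)
        K = _marker_kinship(X)
        train, test = np.arange(35), np.arange(35, 50)
        base = pt.gblup_fit_predict(y[train], K, train, test)
        perm = rng.permutation(n)
        Kp = K[np.ix_(perm, perm)]
        inv = np.argsort(perm)
        pred_p = pt.gblup_fit_predict(y[train], Kp, inv[train], inv[test])
        np.testing.assert_allclose(base, pred_p, atol=1e-8)


class TestBayesB:
    def _sim(self, seed, n=300, p=400, n_qtl=5, h2=0.7):
        rng = np.random.default_rng(seed)
        X = rng.choice([-1.0, 0.0, 1.0], size=(n, p))
        qtl = rng.choice(p, n_qtl, replace=False)
        beta = np.zeros(p)
        beta[qtl] = rng.normal(0, 1, n_qtl)
        g = X @ beta
        y = g + rng.normal(0, g.std() * np.sqrt((1 - h2) / h2), n)
        return X, y, qtl

    def _spec(self, seed=0, iterations=3000, burn_in=1000):
        return pt.PredictionModelSpec(
            model="BayesB", burn_in=burn_in, iterations=iterations,
            thinning=5, seed=seed,
        )

    def test_oligogenic_qtls_have_high_inclusion(self):
        """True QTLs sit above the genome-wide median posterior inclusion
        probability (>= 4/5 per replicate, most replicates)."""
        wins = 0
        n_rep = 8
        for rep in range(n_rep):
            X, y, qtl = self._sim(100 + rep)
            _, post = pt.bayesb_fit_predict(X, y, X[:2], self._spec(seed=rep))
            med = np.median(post.inclusion_prob)
            wins += (post.inclusion_prob[qtl] > med).sum() >= 4
        assert wins >= n_rep - 1

    def test_null_trait_shrinks_effects(self, rng):
        X = rng.choice([-1.0, 0.0, 1.0], size=(300, 400))
        y = rng.normal(0, 1, 300)
        _, post = pt.bayesb_fit_predict(X, y, X[:2], self._spec(seed=3))
        assert np.abs(post.beta_mean).mean() < 0.1 * y.std()

    def test_chain_length_stability(self):
        X, y, _ = self._sim(7)
        p1, _ = pt.bayesb_fit_predict(
            X[:200], y[:200], X[200:], self._spec(seed=5)
        )
        p2, _ = pt.bayesb_fit_predict(
            X[:200], y[:200], X[200:],
            self._spec(seed=5, iterations=6000, burn_in=2000),
        )
        assert np.corrcoef(p1, p2)[0, 1] > 0.98

    def test_burn_in_must_precede_iterations(self):
        with pytest.raises(ValueError):
            pt.PredictionModelSpec(model="BayesB", burn_in=100, iterations=100)


class TestRF:
    def test_epistatic_signal_beats_gblup(self):
        """A pure marker-product interaction (no marginal effects) is
        predictable by the forest but invisible to the additive model."""
        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            n, p = 650, 50
            X = rng.choice([-1.0, 0.0, 1.0], size=(n, p))
            y = X[:, 3] * X[:, 7] + rng.normal(0, 0.25, n)
            tr, te = np.arange(500), np.arange(500, 650)
            acc_rf = np.corrcoef(
                pt.rf_fit_predict(
                    X[tr], y[tr], X[te],
                    pt.PredictionModelSpec(model="RF", n_trees=300, seed=rep),
                ),
                y[te],
            )[0, 1]
            acc_g = np.corrcoef(
                pt.gblup_fit_predict(y[tr], _marker_kinship(X), tr, te), y[te]
            )[0, 1]
            wins += (acc_rf > 0.3) and (acc_g < 0.1)
        assert wins >= n_rep - 2

    def test_bagging_reduces_accuracy_variance(self):
        rng = np.random.default_rng(4)
        n, p = 250, 60
        X = rng.choice([-1.0, 0.0, 1.0], size=(n, p))
        y = X @ rng.normal(0, 0.4, p) + rng.normal(0, 1, n)
        tr, te = np.arange(180), np.arange(180, 250)
        accs = {1: [], 200: []}
        for trees, out in accs.items():
            for seed in range(8):
                pred = pt.rf_fit_predict(
                    X[tr], y[tr], X[te],
                    pt.PredictionModelSpec(model="RF", n_trees=trees, seed=seed),
                )
                out.append(np.corrcoef(pred, y[te])[0, 1])
        assert np.var(accs[200]) < np.var(accs[1])

    def test_constant_response_returns_constant(self, rng):
        X = rng.choice([-1.0, 0.0, 1.0], size=(30, 20))
        with pytest.warns(RuntimeWarning):
            pred = pt.rf_fit_predict(X[:20], np.full(20, 3.0), X[20:])
        np.testing.assert_array_equal(pred, np.full(10, 3.0))


class TestCrossValidation:
    def test_noise_free_linear_trait_high_accuracy(self, rng):
        # more genotypes than markers, so training spans the marker space
        n, m = 200, 60
        X = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
        y = X @ rng.normal(0, 1, m)
        cv = pt.cross_validate(
            pt.PredictionModelSpec(model="GBLUP"), X, y, folds=5, replicates=2, seed=0
        )
        assert cv.mean > 0.95

    def test_same_seed_reproduces_result(self, rng):
        n, m = 60, 80
        X = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
        y = X @ rng.normal(0, 1, m) + rng.normal(0, 2, n)
        spec = pt.PredictionModelSpec(model="GBLUP")
        a = pt.cross_validate(spec, X, y, folds=5, replicates=3, seed=42)
        b = pt.cross_validate(spec, X, y, folds=5, replicates=3, seed=42)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        pd.testing.assert_frame_equal(a.per_fold, b.per_fold)

    def test_accuracy_grows_with_training_size(self):
        """Mean CV accuracy increases from n = 150 to n = 450 on an h2 = 0.5
        polygenic trait."""
        means = []
        for n in (150, 450):
            rng = np.random.default_rng(11)
            m = 300
            X = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
            g = X @ rng.normal(0, 1, m)
            g = (g - g.mean()) / g.std()
            y = g + rng.normal(0, 1, n)
            cv = pt.cross_validate(
                pt.PredictionModelSpec(model="GBLUP"), X, y,
                folds=5, replicates=5, seed=1,
            )
            means.append(cv.mean)
        assert means[1] > means[0]

    def test_architecture_matched_models(self):
        """Polygenic traits: GBLUP within 0.05 of BayesB; oligogenic traits:
        BayesB within 0.05 of GBLUP (train/test split comparisons)."""
        diffs = {"poly": [], "oligo": []}
        for rep in range(10):
            rng = np.random.default_rng(500 + rep)
            n, m = 250, 300
            X = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
            for kind, n_qtl in (("poly", 300), ("oligo", 5)):
                beta = np.zeros(m)
                qtl = rng.choice(m, n_qtl, replace=False)
                beta[qtl] = rng.normal(0, 1, n_qtl)
                g = X @ beta
                y = g + rng.normal(0, g.std() * 0.7, n)
                tr, te = np.arange(180), np.arange(180, 250)
                acc_g = np.corrcoef(
                    pt.gblup_fit_predict(y[tr], _marker_kinship(X), tr, te), y[te]
                )[0, 1]
                spec = pt.PredictionModelSpec(
                    model="BayesB", burn_in=500, iterations=1500, seed=rep
                )
                pb, _ = pt.bayesb_fit_predict(X[tr], y[tr], X[te], spec)
                acc_b = np.corrcoef(pb, y[te])[0, 1]
                diffs[kind].append(acc_g - acc_b)
        assert np.mean(diffs["poly"]) >= -0.05   # GBLUP holds up when polygenic
        assert np.mean(diffs["oligo"]) <= 0.05   # BayesB holds up when oligogenic

    def test_fewer_genotypes_than_folds_rejected(self, rng):
        X = rng.choice([-1.0, 0.0, 1.0], size=(5, 10))
        with pytest.raises(ValueError):
            pt.cross_validate(
                pt.PredictionModelSpec(model="GBLUP"), X, np.zeros(5), folds=10
            )
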