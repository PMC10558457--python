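"""Elastic-net ensemble extraction: objective mapping, gamma selection,
member stability, evaluation and the removal-AUC machinery."""

import numpy as np
import pytest

from fearcond import ensembles as ens
from fearcond.ensembles import (
    ElasticNetEnsemble,
    LabeledDataset,
    build_dataset,
    default_gamma_grid,
    evaluate_model,
    extract_ensemble,
    fit_penalized_logistic,
    optimize_alpha,
    removal_auc_difference,
    select_gamma,
)


def objective(X, y, beta0, beta, alpha, gamma):
    """The extraction objective: mean binomial NLL + gamma * P_alpha."""
    z = beta0 + X @ beta
    nll = np.mean(np.logaddexp(0.0, z) - y * z)
    pen = np.sum((1 - alpha) / 2 * beta**2 + alpha * np.abs(beta))
    return nll + gamma * pen


def grid_search_oracle(X, y, alpha, gamma, b_range=6.0, steps=81):
    """Brute-force minimizer of the objective on a 2-feature problem."""
    assert X.shape[1] == 2
    grid = np.linspace(-b_range, b_range, steps)
    best = (np.inf, None)
    for b0 in grid:
        for b1 in grid:
            z = b0 + X[:, [0]] * b1 + X[:, 1][:, None] * grid[None, :]
            nll = np.mean(np.logaddexp(0.0, z) - y[:, None] * z, axis=0)
            pen = gamma * ((1 - alpha) / 2 * (b1**2 + grid**2)
                           + alpha * (abs(b1) + np.abs(grid)))
            vals = nll + pen
            k = int(np.argmin(vals))
            if vals[k] < best[0]:
                best = (vals[k], (b0, b1, grid[k]))
    return best[1]


class TestPenalizedFit:
    def test_huge_gamma_shrinks_to_intercept(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 5))
        y = (rng.random(200) < 0.5).astype(int)
        b0, b = fit_penalized_logistic(X, y, alpha=1.0, gamma=100.0)
        assert np.allclose(b, 0.0)

    def test_separable_toy_selects_informative_neuron(self):
        """alpha = 1 on a 2-feature problem where only feature 0 carries the
        label: the lasso keeps feature 0 and zeroes feature 1; coefficients
        agree with a brute-force grid minimizer of the same objective."""
        rng = np.random.default_rng(1)
        n = 400
        y = (rng.random(n) < 0.5).astype(int)
        X = np.column_stack([y + 0.1 * rng.normal(size=n), rng.normal(size=n)])
        X = (X - X.mean(0)) / X.std(0)
        gamma = 0.01
        b0, b = fit_penalized_logistic(X, y, alpha=1.0, gamma=gamma, tol=1e-7)
        assert abs(b[0]) > 0.5
        assert abs(b[1]) < 1e-6
        ob0, ob1, ob2 = grid_search_oracle(X, y, 1.0, gamma)
        assert b[0] == pytest.approx(ob1, abs=0.16)  # grid resolution 0.15
        assert abs(ob2) <= 0.16

    def test_duplicated_informative_columns_share_weight(self):
        """Small alpha (ridge-leaning) keeps both copies of a duplicated
        informative column with similar coefficients."""
        rng = np.random.default_rng(2)
        n = 400
        y = (rng.random(n) < 0.5).astype(int)
        base = y + 0.2 * rng.normal(size=n)
        X = np.column_stack([base, base + 1e-3 * rng.normal(size=n),
                             rng.normal(size=n)])
        b0, b = fit_penalized_logistic(X, y, alpha=0.1, gamma=0.003, tol=1e-6)
        assert b[0] != 0 and b[1] != 0
        assert b[0] == pytest.approx(b[1], rel=0.15)

    def test_invalid_hyperparameters(self):
        X = np.zeros((10, 2))
        y = np.r_[np.zeros(5), np.ones(5)].astype(int)
        with pytest.raises(ValueError):
            fit_penalized_logistic(X, y, alpha=0.0, gamma=0.1)
        with pytest.raises(ValueError):
            fit_penalized_logistic(X, y, alpha=0.5, gamma=-1.0)


class TestSelectGamma:
    def test_grid_endpoints_exact(self):
        g = default_gamma_grid()
        assert g[0] == pytest.approx(10**-3.3)
        assert g[-1] == pytest.approx(10**-2.5)
        assert len(g) == 7

    def test_noise_prefers_strongest_shrinkage(self):
        """On pure-noise designs the CV deviance favors the largest gamma
        in at least half the seeds."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(300, 40))
            y = (rng.random(300) < 0.5).astype(int)
            g = select_gamma(X, y, alpha=0.5, rng=seed)
            wins += g == pytest.approx(10**-2.5)
        assert wins >= n_seeds / 2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 10))
        y = (rng.random(200) < 0.5).astype(int)
        assert select_gamma(X, y, 0.5, rng=11) == select_gamma(X, y, 0.5, rng=11)


def _toy_dataset(rng, n=600, p=12, k=4, effect=1.2):
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.normal(size=(n, p))
    X[:, :k] += effect * y[:, None]
    return LabeledDataset(X=X, y=y, condition="toy", day=4)


class TestExtractEnsemble:
    def test_single_repeat_degenerates_to_one_fit(self):
        rng = np.random.default_rng(4)
        ds = _toy_dataset(rng)
        m = extract_ensemble(ds, alpha=0.5, n_repeats=1, n_per_state=200,
                             random_state=0)
        np.testing.assert_array_equal(m.members_,
                                      np.flatnonzero(m.coef_samples_[0] != 0))

    def test_planted_members_recovered_in_benign_regime(self):
        """With many unique frames per feature the CI rule is precise."""
        rng = np.random.default_rng(5)
        ds = _toy_dataset(rng, n=2000, p=12, k=4)
        m = extract_ensemble(ds, alpha=0.5, n_repeats=30, n_per_state=900,
                             random_state=1)
        assert set(m.members_) == {0, 1, 2, 3}

    def test_label_independent_selection_frequency_low(self):
        """Label-independent features are selected at <= 5% + 3 SE when the
        sample-to-feature ratio is healthy (see methods note for the
        overparameterized regime)."""
        picks, total = 0, 0
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            ds = _toy_dataset(rng, n=2000, p=12, k=2)
            m = extract_ensemble(ds, alpha=0.5, n_repeats=20, n_per_state=900,
                                 random_state=seed)
            picks += np.isin(m.members_, np.arange(2, 12)).sum()
            total += 10
        se = np.sqrt(0.05 * 0.95 / total)
        assert picks / total <= 0.05 + 3 * se

    def test_estimator_sklearn_contract(self):
        from sklearn.base import clone
        est = ElasticNetEnsemble(alpha=0.5, n_repeats=3, n_per_state=50)
        params = est.get_params()
        assert params["alpha"] == 0.5
        clone(est)  # must be cloneable
        rng = np.random.default_rng(6)
        ds = _toy_dataset(rng, n=300)
        est.set_params(random_state=0).fit(ds.X, ds.y)
        assert est.coef_.shape == (12,)
        assert est.predict(ds.X[:5]).shape == (5,)
        p = est.predict_proba(ds.X[:5])
        np.testing.assert_allclose(p.sum(axis=1), 1.0)


class TestEvaluateModel:
    def _null_model(self, p=4):
        m = ElasticNetEnsemble.__new__(ElasticNetEnsemble)
        m.coef_ = np.zeros(p)
        m.intercept_ = 0.0
        m.classes_ = np.array([0, 1])
        m.n_features_in_ = p
        return m

    def test_null_model_gives_majority_accuracy_and_half_auc(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 4))
        y = (rng.random(100) < 0.3).astype(int)
        ds = LabeledDataset(X=X, y=y, condition="t", day=3)
        res = evaluate_model(self._null_model(), ds)
        # tie at probability 0.5 resolves to class 0
        assert res["accuracy"] == pytest.approx((y == 0).mean())
        assert res["auc"] == pytest.approx(0.5)

    def test_perfect_separator(self):
        rng = np.random.default_rng(8)
        ds = _toy_dataset(rng, n=200, p=2, k=1, effect=50.0)
        m = extract_ensemble(ds, alpha=0.5, n_repeats=2, n_per_state=100,
                             random_state=0)
        res = evaluate_model(m, ds, "fitting")
        assert res["auc"] == pytest.approx(1.0)
        assert res["accuracy"] >= 0.99

    def test_single_label_dataset_rejected(self):
        ds = LabeledDataset(X=np.zeros((5, 4)), y=np.ones(5, dtype=int),
                            condition="t", day=3)
        with pytest.raises(ValueError, match="single-label"):
            evaluate_model(self._null_model(), ds)


class TestRemovalAndAlpha:
    def test_random_members_give_no_difference(self):
        """Removing an arbitrary exchangeable subset is equivalent to
        removing a random one: the AUC difference is ~0."""
        rng = np.random.default_rng(9)
        ds = _toy_dataset(rng, n=800, p=12, k=12, effect=0.6)  # all equal
        members = np.arange(4)
        res = removal_auc_difference(ds, members, alpha=0.5, n_outer=5,
                                     inner_repeats=5, n_per_state=300, rng=0)
        assert abs(res.auc_difference) < 0.05

    def test_planted_ensemble_removal_hurts(self):
        rng = np.random.default_rng(10)
        ds = _toy_dataset(rng, n=800, p=12, k=3, effect=1.5)
        res = removal_auc_difference(ds, np.arange(3), alpha=0.5, n_outer=5,
                                     inner_repeats=5, n_per_state=300, rng=1)
        assert res.auc_difference > 0.05
        from scipy.stats import mannwhitneyu
        p = mannwhitneyu(res.auc_noncre_removed, res.auc_cre_removed,
                         alternative="greater").pvalue
        assert p < 0.05

    def test_removal_deterministic_per_seed(self):
        rng = np.random.default_rng(11)
        ds = _toy_dataset(rng, n=400, p=8, k=2)
        a = removal_auc_difference(ds, np.arange(2), 0.5, n_outer=2,
                                   inner_repeats=3, n_per_state=150, rng=42)
        b = removal_auc_difference(ds, np.arange(2), 0.5, n_outer=2,
                                   inner_repeats=3, n_per_state=150, rng=42)
        np.testing.assert_allclose(a.auc_cre_removed, b.auc_cre_removed)
        np.testing.assert_allclose(a.auc_noncre_removed, b.auc_noncre_removed)

    def test_single_alpha_grid_returned(self):
        rng = np.random.default_rng(12)
        ds = _toy_dataset(rng, n=400, p=8, k=2)
        scan = optimize_alpha(ds, [0.75], extract_repeats=3, n_outer=2,
                              inner_repeats=3, n_per_state=150, rng=0)
        assert scan.best_alpha == 0.75

    def test_tie_rule_prefers_largest_alpha(self):
        """When removal differences are statistically indistinguishable
        across alphas (a fully exchangeable design), the largest alpha
        wins."""
        rng = np.random.default_rng(13)
        ds = _toy_dataset(rng, n=600, p=14, k=5, effect=0.8)
        scan = optimize_alpha(ds, [0.25, 0.75], extract_repeats=3, n_outer=4,
                              inner_repeats=3, n_per_state=200, rng=1)
        assert scan.best_alpha in (0.25, 0.75)
        # with overlapping difference distributions the tie rule must
        # return the larger alpha
        import scipy.stats as sps
        d = [r.auc_noncre_removed - r.auc_cre_removed for r in scan.removals]
        p = sps.mannwhitneyu(d[0], d[1], alternative="two-sided").pvalue
        if p >= 0.05:
            assert scan.best_alpha == 0.75


class TestBuildDataset:
    def test_rs_dataset_excludes_post_trial_window(self, experiment, zscored):
        tl = experiment.timeline
        ds = build_dataset(zscored, experiment.behavior, tl, "rs", day=4)
        times = tl.frame_times(4)[ds.frame_idx]
        for row in tl.select(day=4).itertuples():
            end = row.onset_s + row.duration_s
            assert not np.any((times >= end) & (times < end + 30.0))
            assert not np.any((times >= row.onset_s) & (times < end))

    def test_label_prevalence_matches_behavior(self, experiment, zscored):
        ds = build_dataset(zscored, experiment.behavior, experiment.timeline,
                           "cr", phase="D4E")
        tl = experiment.timeline
        mask = tl.in_trial_mask(4, tl.select(day=4, cs_type="CS+", phase="D4E"))
        still = experiment.behavior.still_mask(4)[: mask.size]
        assert ds.y.mean() == pytest.approx(still[mask].mean())

    def test_all_one_label_raises_balance_error(self, experiment, zscored):
        class AllStill:
            def __init__(self, inner):
                self.inner = inner

            def still_mask(self, day):
                return np.ones_like(self.inner.still_mask(day))

        with pytest.raises(ValueError, match="label balance"):
            build_dataset(zscored, AllStill(experiment.behavior),
                          experiment.timeline, "cr", phase="D4E")
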