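"""Penalized classifiers: labeling rule, elastic-net optimality against a
dense grid-search oracle, AUC as exhaustive pairwise concordance, CV
behavior, SVM-RFE mechanics, linear elastic net."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import lifelipid as ll
from lifelipid.classifiers import (en_linear_objective, en_logistic_kkt_gap,
                                   en_logistic_objective, standardize_columns)


def _species_df(rows):
    return pd.DataFrame(rows).set_index("species_id")


class TestLabeling:
    def test_single_species_clade_is_long_living(self):
        sp = _species_df([
            {"species_id": "a", "clade": "rodent", "mls": 5.0},
            {"species_id": "b", "clade": "bat", "mls": 20.0},
            {"species_id": "c", "clade": "bat", "mls": 10.0},
        ])
        lab = ll.label_long_living(sp)
        assert lab.loc["a", "is_long_living"]  # max > 0.9·max always

    def test_primate_threshold_at_90_years(self):
        """Clade max 100 → threshold 90; 100 is labeled, 85 is not."""
        sp = _species_df([
            {"species_id": "hs", "clade": "primate", "mls": 100.0},
            {"species_id": "pt", "clade": "primate", "mls": 85.0},
            {"species_id": "mm", "clade": "primate", "mls": 30.0},
        ])
        lab = ll.label_long_living(sp)
        assert lab.loc["hs", "threshold"] == pytest.approx(90.0)
        assert lab.loc["hs", "is_long_living"]
        assert not lab.loc["pt", "is_long_living"]

    def test_default_cohort_matches_generator_truth(self, cohort):
        lab = ll.label_long_living(cohort.species)
        from lifelipid.simulate import _long_living_flags
        assert np.array_equal(lab["is_long_living"].to_numpy(),
                              _long_living_flags(cohort.species).astype(bool))

    def test_missing_mls_raises(self):
        sp = _species_df([{"species_id": "a", "clade": "rodent", "mls": np.nan}])
        with pytest.raises(ValueError):
            ll.label_long_living(sp)


class TestAUC:
    def test_equals_exhaustive_pairwise_concordance(self):
        """12-sample fixture: AUC equals the hand-counted fraction of
        concordant positive/negative pairs (ties half)."""
        rng = np.random.default_rng(0)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        s = rng.normal(size=12)
        s[3] = s[4]  # force a tie across classes
        conc = 0.0
        npairs = 0
        for i in np.where(y == 1)[0]:
            for j in np.where(y == 0)[0]:
                npairs += 1
                conc += 1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0
        assert ll.roc_auc(y, s) == pytest.approx(conc / npairs)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        for _ in range(5):
            y = rng.integers(0, 2, size=30)
            if y.min() == y.max():
                continue
            s = rng.normal(size=30)
            assert ll.roc_auc(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_perfect_separation_is_one(self):
        y = np.array([0, 0, 1, 1])
        assert ll.roc_auc(y, [0.0, 0.1, 5.0, 6.0]) == 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            ll.roc_auc([1, 1], [0.1, 0.2])


class TestElasticNetLogistic:
    def _toy(self, n=40, seed=3):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        eta = 1.2 * X[:, 0] - 0.4 * X[:, 1]
        y = (eta + rng.normal(0, 0.7, size=n) > 0).astype(int)
        Z, _, _ = standardize_columns(X)
        return Z, y

    def test_full_shrinkage_gives_prevalence_intercept(self):
        Z, y = self._toy()
        m = ll.fit_elasticnet_logistic(Z, y, alpha=0.5, lam=50.0,
                                       tol=1e-14, max_iter=10**6)
        assert np.allclose(m.coef, 0.0, atol=1e-6)
        assert m.intercept == pytest.approx(logit(y.mean()), abs=1e-3)

    def test_ridge_symmetry_on_duplicated_column(self):
        Z, y = self._toy()
        Zdup = np.column_stack([Z[:, 0], Z[:, 0], Z[:, 1]])
        m = ll.fit_elasticnet_logistic(Zdup, y, alpha=0.0, lam=0.05,
                                       tol=1e-10, max_iter=200000)
        assert m.coef.iloc[0] == pytest.approx(m.coef.iloc[1], abs=1e-5)

    def test_objective_beats_dense_grid_oracle(self):
        """Solution objective is within 1e-3 of the dense grid minimum over
        (intercept, b1, b2)."""
        Z, y = self._toy()
        m = ll.fit_elasticnet_logistic(Z, y, alpha=0.5, lam=0.1,
                                       tol=1e-10, max_iter=200000)
        f_hat = en_logistic_objective(Z, y, m.intercept, m.coef, 0.5, 0.1)
        grid = np.linspace(-2.0, 2.0, 41)
        best = np.inf
        for b0 in grid:
            for b1 in grid:
                for b2 in grid:
                    best = min(best, en_logistic_objective(
                        Z, y, b0, [b1, b2], 0.5, 0.1))
        assert f_hat <= best + 1e-3

    def test_kkt_optimality_gap(self):
        """Subgradient conditions hold to 1e-6 at the solution."""
        Z, y = self._toy(n=30, seed=9)
        for alpha, lam in [(0.5, 0.1), (1.0, 0.05), (0.0, 0.2)]:
            m = ll.fit_elasticnet_logistic(Z, y, alpha=alpha, lam=lam,
                                           tol=1e-14, max_iter=10**6)
            gap = en_logistic_kkt_gap(Z, y, m.intercept, m.coef, alpha, lam)
            assert gap < 1e-6

    def test_one_class_raises(self):
        Z, _ = self._toy()
        with pytest.raises(ValueError):
            ll.fit_elasticnet_logistic(Z, np.ones(len(Z), dtype=int), 0.5, 0.1)

    def test_selection_invariant_to_column_permutation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 8))
        y = (X[:, 2] + 0.5 * X[:, 5] + rng.normal(0, 0.5, 50) > 0).astype(int)
        ids = [f"f{j}" for j in range(8)]
        m1 = ll.select_predictors(X, y, 0.5, 0.05, feature_ids=ids)
        perm = rng.permutation(8)
        m2 = ll.select_predictors(X[:, perm], y, 0.5, 0.05,
                                  feature_ids=[ids[j] for j in perm])
        assert set(m1.selected_peaks) == set(m2.selected_peaks)
        assert np.allclose(m1.coef.sort_index(), m2.coef.sort_index(), atol=1e-4)


class TestCrossValidation:
    def _data(self, effect, n=60, seed=2):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 10))
        y = np.r_[np.ones(n // 3), np.zeros(n - n // 3)].astype(int)
        X[y == 1, 0] += effect
        X[y == 1, 1] += effect
        return X, y

    def test_perfect_feature_gives_auc_one(self):
        X, y = self._data(effect=8.0)
        cv = ll.cross_validate(X, y, folds=5, repeats=2, seed=0)
        assert cv.mean_auc > 0.99

    def test_permuted_labels_near_half(self):
        X, y = self._data(effect=5.0)
        rng = np.random.default_rng(4)
        yp = rng.permutation(y)
        cv = ll.cross_validate(X, yp, folds=5, repeats=3, seed=0)
        assert abs(cv.mean_auc - 0.5) < 0.15

    def test_auc_monotone_in_effect_size(self):
        aucs = []
        for effect in (0.0, 1.0, 3.0):
            X, y = self._data(effect=effect, seed=6)
            cv = ll.cross_validate(X, y, alpha_grid=(0.5,),
                                   lam_grid=(0.1, 0.01), folds=5,
                                   repeats=2, seed=1)
            aucs.append(cv.mean_auc)
        assert aucs[0] - 0.05 <= aucs[1] <= aucs[2] + 0.05
        assert aucs[2] > aucs[0]

    def test_fold_aucs_shape_and_range(self):
        X, y = self._data(effect=2.0)
        cv = ll.cross_validate(X, y, folds=5, repeats=2, seed=0)
        assert len(cv.fold_aucs) == 10
        assert np.all((cv.fold_aucs >= 0) & (cv.fold_aucs <= 1))


class TestSelectPredictors:
    def test_planted_recovery_on_one_tissue(self, cohort):
        """>= 80% of planted predictor peaks get nonzero coefficients."""
        tables, _, truth = ll.generate_lipidome(cohort, n_peaks=150,
                                                n_predictors=20, seed=31)
        norm, _ = ll.normalize_by_internal_standard(tables["cortex"],
                                                    "IS_PC34_0")
        imp = ll.impute_half_minimum(norm)
        y = ll.sample_labels(cohort, imp.sample_ids).to_numpy().astype(int)
        m = ll.select_predictors(imp.values.to_numpy(), y, 0.2, 0.01,
                                 feature_ids=imp.peak_ids)
        rec = len(set(m.selected_peaks) & set(truth.predictor_peaks)) / 20
        assert rec >= 0.8

    def test_huge_lambda_selects_nothing(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 5))
        y = rng.integers(0, 2, size=30)
        y[:3], y[3:6] = 1, 0
        m = ll.select_predictors(X, y, 0.5, 100.0)
        assert m.selected_peaks == []


class TestSvmRfe:
    def _data(self, n_noise=58, seed=12):
        rng = np.random.default_rng(seed)
        n = 60
        X = rng.normal(size=(n, 2 + n_noise))
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        X[y == 1, 0] += 3.0
        X[y == 1, 1] -= 3.0
        return X, y

    def test_halts_at_min_features(self):
        X, y = self._data()
        out = ll.svm_rfe(X, y, folds=3, repeats=1, seed=0)
        assert out["n_features"] <= X.shape[1]
        assert min(out["accuracy_path"]) >= 0  # path explored
        assert min(out["accuracy_path"].keys()) == 10

    def test_one_percent_step_is_one_feature_at_100(self):
        from lifelipid.classifiers import _rfe_path
        X, y = self._data(n_noise=98)
        path = _rfe_path(X, y, 0.01, 10)
        sizes = [len(a) for a in path]
        assert sizes[0] == 100 and sizes[1] == 99  # ceil(0.01·100) = 1

    def test_informative_features_survive(self):
        X, y = self._data()
        out = ll.svm_rfe(X, y, folds=3, repeats=1, seed=0)
        final10 = None
        from lifelipid.classifiers import _rfe_path, standardize_columns
        Z, _, _ = standardize_columns(X)
        final10 = set(_rfe_path(Z, y, 0.01, 10)[-1])
        assert {0, 1} <= final10

    def test_min_features_validated(self):
        X, y = self._data(n_noise=3)
        with pytest.raises(ValueError):
            ll.svm_rfe(X, y, min_features=10)


class TestLinearElasticNet:
    def test_constant_response_gives_zero_coefficients(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 4))
        m = ll.fit_elasticnet_linear(X, np.full(20, 0.7))
        assert np.allclose(m.coef, 0.0)

    def test_clade_max_species_has_response_one(self, cohort):
        y = ll.normalized_mls(cohort, cohort.samples.index)
        lab = ll.label_long_living(cohort.species)
        max_sp = lab.index[lab["mls"] == lab["clade_max_mls"]]
        sids = cohort.samples["species_id"].isin(max_sp)
        assert np.allclose(y[sids.to_numpy()], 1.0)
        assert (y <= 1).all() and (y > 0).all()

    def test_grid_search_oracle(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 2))
        y = 0.4 * X[:, 0] + rng.normal(0, 0.2, 30) + 0.5
        m = ll.fit_elasticnet_linear(X, y, alpha=0.5, lam=0.1,
                                     tol=1e-12, max_iter=10**6)
        f_hat = en_linear_objective(X, y, m.intercept, m.coef, 0.5, 0.1)
        grid = np.linspace(-1.5, 1.5, 61)
        best = np.inf
        for b0 in grid:
            for b1 in grid:
                for b2 in grid:
                    best = min(best, en_linear_objective(
                        X, y, b0, [b1, b2], 0.5, 0.1))
        assert f_hat <= best + 1e-3
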