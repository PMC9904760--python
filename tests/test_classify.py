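import warnings

import numpy as np
import pandas as pd
import pytest

from hspcflow import _glmnet, classify, qc


def _spec(**kw):
    base = dict(n_repetitions=2, n_lambda=15)
    base.update(kw)
    return classify.ElasticNetSpec(**base)


class TestBuildTrainingSet:
    def test_balanced_draw_and_75_25_split(self):
        labels = np.array(["A"] * 100 + ["B"] * 900)
        rng = np.random.default_rng(0)
        tr, va, y_tr, y_va = classify.build_training_set(labels, "A", rng)
        assert len(tr) == 150 and len(va) == 50
        assert y_tr.sum() == 75 and y_va.sum() == 25
        assert len(np.intersect1d(tr, va)) == 0

    def test_negative_pool_saturation_warns(self):
        labels = np.array(["A"] * 600 + ["B"] * 400)
        with pytest.warns(UserWarning, match="non-target"):
            tr, va, y_tr, y_va = classify.build_training_set(
                labels, "A", np.random.default_rng(0)
            )
        assert (y_tr == 0).sum() + (y_va == 0).sum() == 400

    def test_deterministic_given_seed(self):
        labels = np.array(["A"] * 50 + ["B"] * 200)
        a = classify.build_training_set(labels, "A", np.random.default_rng(7))
        b = classify.build_training_set(labels, "A", np.random.default_rng(7))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_rare_or_absent_target_rejected(self):
        labels = np.array(["A"] * 5 + ["B"] * 50)
        rng = np.random.default_rng(0)
        with pytest.raises(classify.ClassifierError):
            classify.build_training_set(labels, "A", rng)
        with pytest.raises(classify.ClassifierError):
            classify.build_training_set(labels, "C", rng)


class TestIntersectFeatures:
    def test_intersection_in_reference_order(self):
        assert classify.intersect_features(
            ["A", "B", "C"], ["B", "C", "D"]
        ) == ["B", "C"]
        assert classify.intersect_features(["A", "B"], ["B", "A"]) == ["A", "B"]

    def test_disjoint_lists_rejected(self):
        with pytest.raises(classify.ClassifierError):
            classify.intersect_features(["A"], ["B"])


class TestBinaryModel:
    def _separable(self, n=200, p=20, seed=0):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        X = rng.normal(size=(n, p))
        # one perfectly separating feature (10 sigma gap), the rest noise
        X[:, 0] = rng.normal(scale=0.3, size=n) + 3 * y
        return X, y

    def test_separating_feature_gives_auc_one(self):
        X, y = self._separable()
        m = classify.fit_binary_model(
            X[::2], y[::2], X[1::2], y[1::2], alpha=1.0, spec=_spec(),
            seed=0, feature_names=[f"g{i}" for i in range(X.shape[1])],
        )
        assert m.metrics.auc == 1.0
        assert m.n_nonzero >= 1

    def test_all_coefficients_zero_at_lambda_max(self):
        X, y = self._separable()
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        lmax = _glmnet.lambda_max(Xs, y, 1.0)
        coefs, _, _ = _glmnet.fit_path(Xs, y, 1.0, np.array([lmax * 1.001]))
        assert np.count_nonzero(coefs[0]) == 0
        coefs2, _, _ = _glmnet.fit_path(Xs, y, 1.0, np.array([lmax * 0.7]))
        assert np.count_nonzero(coefs2[0]) >= 1

    def test_solver_matches_sklearn_saga(self):
        # dual-route check of the coordinate descent against an independent
        # solver at matched penalties
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(3)
        n, p = 250, 40
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:4] = [2.0, -1.5, 1.0, 0.5]
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        for alpha in (1.0, 0.5, 0.1):
            lams = _glmnet.lambda_path(Xs, y, alpha, n_lambda=10)
            coefs, b0s, ok = _glmnet.fit_path(Xs, y, alpha, lams)
            assert ok.all()
            li = 6
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sk = LogisticRegression(
                    C=1 / (n * lams[li]), solver="saga", l1_ratio=alpha,
                    tol=1e-8, max_iter=20000,
                ).fit(Xs, y)
            assert np.abs(sk.coef_.ravel() - coefs[li]).max() < 1e-3

    def test_near_unpenalized_limit_matches_unregularized_fit(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(5)
        n = 400
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < 1 / (1 + np.exp(-(X[:, 0] - X[:, 1])))).astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        coefs, b0s, _ = _glmnet.fit_path(
            Xs, y, 0.5, np.array([1.0, 0.1, 1e-6]), max_irls=60
        )
        sk = LogisticRegression(C=np.inf, tol=1e-10).fit(Xs, y)
        assert np.abs(coefs[-1] - sk.coef_.ravel()).max() < 1e-2

    def test_single_class_input_rejected(self):
        X = np.random.default_rng(0).normal(size=(40, 5))
        y = np.ones(40)
        with pytest.raises(classify.ClassifierError):
            classify.fit_binary_model(
                X, y, X, y, 1.0, _spec(), 0, [f"g{i}" for i in range(5)]
            )


class TestSelectModel:
    def _model(self, nnz, auc, fpr=0.1, fnr=0.1, alpha=1.0):
        return classify.BinaryModel(
            target_type="T", feature_names=["g"], coef=np.zeros(1),
            intercept=0.0, alpha=alpha, lambda_=0.1, n_nonzero=nnz,
            metrics=classify.ValidationMetrics(auc, fpr, fnr, 50),
        )

    def test_variable_window_filters_candidates(self):
        spec = classify.ElasticNetSpec()
        picked = classify.select_model(
            [self._model(10, 0.99), self._model(50, 0.90),
             self._model(200, 0.99)],
            spec,
        )
        assert picked.n_nonzero == 50

    def test_window_dropped_when_nothing_qualifies(self):
        spec = classify.ElasticNetSpec()
        picked = classify.select_model(
            [self._model(5, 0.8), self._model(300, 0.9)], spec
        )
        assert picked.n_nonzero == 300

    def test_auc_then_fpr_then_fnr_then_nvars_cascade(self):
        spec = classify.ElasticNetSpec()
        assert classify.select_model(
            [self._model(30, 0.90), self._model(40, 0.95)], spec
        ).metrics.auc == 0.95
        assert classify.select_model(
            [self._model(30, 0.95, fpr=0.20), self._model(40, 0.95, fpr=0.10)],
            spec,
        ).metrics.fpr == 0.10
        assert classify.select_model(
            [self._model(30, 0.95, fnr=0.20), self._model(40, 0.95, fnr=0.05)],
            spec,
        ).metrics.fnr == 0.05
        assert classify.select_model(
            [self._model(30, 0.95), self._model(40, 0.95)], spec
        ).n_nonzero == 40

    def test_full_tie_breaks_on_alpha_grid_order(self):
        spec = classify.ElasticNetSpec()
        picked = classify.select_model(
            [self._model(30, 0.95, alpha=0.5),
             self._model(30, 0.95, alpha=1.0)],
            spec,
        )
        assert picked.alpha == 1.0  # first entry of the alpha grid

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(classify.ClassifierError):
            classify.select_model([], classify.ElasticNetSpec())


class TestEnsemble:
    @pytest.fixture(scope="class")
    def trained(self, reference_small, query_small):
        adata, truth = reference_small
        qadata, _ = query_small
        norm = qc.log_normalize(adata)
        hvg_r, _ = qc.select_hvg(adata, 150)
        hvg_q, _ = qc.select_hvg(qadata, 150)
        spec = _spec(n_repetitions=2, alpha_grid=(1.0, 0.25))
        ens = classify.train_ensemble(
            norm, truth.cell_labels.to_numpy(), hvg_r, hvg_q, spec, seed=5
        )
        return ens, norm, truth

    def test_model_count_is_types_times_repetitions(self, trained):
        ens, _, _ = trained
        assert len(ens.cell_types) == 5
        assert sum(len(v) for v in ens.models.values()) == 10

    def test_same_master_seed_reproduces_coefficients(
        self, reference_small, query_small
    ):
        adata, truth = reference_small
        qadata, _ = query_small
        norm = qc.log_normalize(adata)
        hvg_r, _ = qc.select_hvg(adata, 100)
        hvg_q, _ = qc.select_hvg(qadata, 100)
        spec = _spec(n_repetitions=1, alpha_grid=(1.0,))
        e1 = classify.train_ensemble(
            norm, truth.cell_labels.to_numpy(), hvg_r, hvg_q, spec, seed=9
        )
        e2 = classify.train_ensemble(
            norm, truth.cell_labels.to_numpy(), hvg_r, hvg_q, spec, seed=9
        )
        for t in e1.cell_types:
            assert np.array_equal(e1.models[t][0].coef, e2.models[t][0].coef)

    def test_prediction_probabilities_match_stored_coefficients(self, trained):
        # brute-force re-evaluation of the stored models
        ens, norm, _ = trained
        ann = classify.predict(ens, norm)
        X = classify._expression_matrix(norm, ens.features)
        for t in ens.cell_types:
            manual = np.mean(
                [1 / (1 + np.exp(-(m.intercept + X @ m.coef)))
                 for m in ens.models[t]],
                axis=0,
            )
            assert np.allclose(ann.probabilities[t].to_numpy(), manual)
        assert ((ann.probabilities.to_numpy() >= 0)
                & (ann.probabilities.to_numpy() <= 1)).all()

    def test_json_roundtrip_preserves_predictions(self, trained, tmp_path):
        ens, norm, _ = trained
        path = ens.to_json(tmp_path / "model.json")
        back = classify.EnsembleClassifier.from_json(path)
        a = classify.predict(ens, norm).probabilities
        b = classify.predict(back, norm).probabilities
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestPredictAssignment:
    def _manual_ensemble(self, intercepts):
        spec = classify.ElasticNetSpec()
        models = {
            t: [
                classify.BinaryModel(
                    target_type=t, feature_names=["g0"], coef=np.zeros(1),
                    intercept=b0, alpha=1.0, lambda_=0.1, n_nonzero=0,
                    metrics=classify.ValidationMetrics(1.0, 0.0, 0.0, 10),
                )
            ]
            for t, b0 in intercepts.items()
        }
        return classify.EnsembleClassifier(
            cell_types=sorted(intercepts), features=["g0"], models=models,
            spec=spec, seed=0,
        )

    def _query(self):
        import anndata as ad
        import scipy.sparse as sp

        return ad.AnnData(
            X=sp.csr_matrix(np.zeros((1, 1))),
            obs=pd.DataFrame(index=["cell"]),
            var=pd.DataFrame(index=["g0"]),
        )

    def test_argmax_type_assigned_when_above_threshold(self):
        ens = self._manual_ensemble({"HSC": 2.2, "MEP": -1.4})
        ann = classify.predict(ens, self._query())
        assert ann.labels.iloc[0] == "HSC"

    def test_cell_below_threshold_is_not_assigned(self):
        # best averaged probability 0.45 < 0.5
        ens = self._manual_ensemble(
            {"HSC": np.log(0.45 / 0.55), "MEP": np.log(0.2 / 0.8)}
        )
        ann = classify.predict(ens, self._query())
        assert ann.labels.iloc[0] == classify.NOT_ASSIGNED

    def test_probability_exactly_at_threshold_is_not_assigned(self):
        ens = self._manual_ensemble({"HSC": 0.0, "MEP": -2.0})
        ann = classify.predict(ens, self._query())
        assert np.isclose(ann.probabilities["HSC"].iloc[0], 0.5)
        assert ann.labels.iloc[0] == classify.NOT_ASSIGNED

    def test_identical_repetition_probabilities_average_exactly(self):
        spec = classify.ElasticNetSpec()
        model = classify.BinaryModel(
            target_type="HSC", feature_names=["g0"], coef=np.zeros(1),
            intercept=1.0, alpha=1.0, lambda_=0.1, n_nonzero=0,
            metrics=classify.ValidationMetrics(1.0, 0.0, 0.0, 10),
        )
        ens = classify.EnsembleClassifier(
            cell_types=["HSC"], features=["g0"],
            models={"HSC": [model] * 5}, spec=spec, seed=0,
        )
        ann = classify.predict(ens, self._query())
        assert np.isclose(
            ann.probabilities["HSC"].iloc[0], 1 / (1 + np.exp(-1.0))
        )

    def test_missing_features_imputed_as_zero_with_warning(self):
        import anndata as ad
        import scipy.sparse as sp

        ens = self._manual_ensemble({"HSC": 1.0, "MEP": -1.0})
        query = ad.AnnData(
            X=sp.csr_matrix(np.ones((1, 1))),
            obs=pd.DataFrame(index=["cell"]),
            var=pd.DataFrame(index=["other_gene"]),
        )
        with pytest.warns(UserWarning, match="imputed"):
            ann = classify.predict(ens, query)
        assert ann.labels.iloc[0] == "HSC"


class TestConfusionProportions:
    def test_perfect_prediction_gives_identity(self):
        idx = [f"c{i}" for i in range(6)]
        truth = pd.Series(["A", "A", "B", "B", "C", "C"], index=idx)
        tab = classify.confusion_proportions(truth.copy(), truth)
        assert np.allclose(np.diag(tab[["A", "B", "C"]].to_numpy()), 1.0)

    def test_all_not_assigned_concentrates_in_last_column(self):
        idx = [f"c{i}" for i in range(4)]
        truth = pd.Series(["A", "A", "B", "B"], index=idx)
        pred = pd.Series([classify.NOT_ASSIGNED] * 4, index=idx)
        tab = classify.confusion_proportions(pred, truth)
        assert (tab[classify.NOT_ASSIGNED] == 1.0).all()

    def test_rows_sum_to_one_for_random_predictions(self):
        rng = np.random.default_rng(0)
        idx = [f"c{i}" for i in range(300)]
        truth = pd.Series(rng.choice(list("ABCD"), 300), index=idx)
        pred = pd.Series(
            rng.choice(list("ABCD") + [classify.NOT_ASSIGNED], 300), index=idx
        )
        tab = classify.confusion_proportions(pred, truth)
        assert np.allclose(tab.sum(axis=1).to_numpy(), 1.0, atol=1e-12)

    def test_mismatched_cells_rejected(self):
        a = pd.Series(["A"], index=["c0"])
        b = pd.Series(["A"], index=["c1"])
        with pytest.raises(classify.ClassifierError):
            classify.confusion_proportions(a, b)
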