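"""OPLS core tests: Pareto scaling, NIPALS (with eigen-decomposition and
reference-PLS oracles), orthogonal filtering, variance bookkeeping,
cross-validation and autofit."""

import numpy as np
import pytest

import trichospec as ts
from trichospec.opls import _fold_assignment


def _center(M):
    return M - M.mean(axis=0)


class TestParetoScaling:
    def test_weight_is_inverse_sqrt_sd(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=50)
        col = (col - col.mean()) / col.std(ddof=1) * 4.0  # sd exactly 4
        scaler = ts.pareto_fit(col[:, None])
        assert scaler.weights[0] == pytest.approx(0.5)

    def test_scaled_columns_mean_zero_and_sqrt_sd(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        X[:, 2] = (X[:, 2] - X[:, 2].mean()) / X[:, 2].std(ddof=1) * 9.0
        scaler = ts.pareto_fit(X)
        Z = ts.pareto_apply(scaler, X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert Z[:, 2].std(ddof=1) == pytest.approx(3.0)
        assert np.allclose(Z.std(axis=0, ddof=1), np.sqrt(scaler.sds))

    def test_constant_column_weight_zero(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 7.0)])
        scaler = ts.pareto_fit(X)
        assert scaler.weights[1] == 0.0
        assert scaler.constant_columns.tolist() == [1]


class TestDummy:
    def test_raw_rows_sum_to_one_and_centered(self):
        dummy = ts.build_dummy(["a", "b", "a", "c"])
        raw = dummy.matrix + dummy.means
        assert np.allclose(raw.sum(axis=1), 1.0)
        assert np.allclose(dummy.matrix.mean(axis=0), 0.0, atol=1e-15)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="not in class_order"):
            ts.build_dummy(["a", "z"], class_order=["a", "b"])


class TestNipals:
    def test_pls1_weight_closed_form(self):
        rng = np.random.default_rng(2)
        X = _center(rng.normal(size=(30, 8)))
        y = _center(rng.normal(size=(30, 1)))
        w, t, p, c = ts.nipals_component(X, y)
        expected = X.T @ y[:, 0]
        expected /= np.linalg.norm(expected)
        assert np.allclose(w * np.sign(w @ expected), expected, atol=1e-10)

    def test_rank_one_exact_representation(self):
        rng = np.random.default_rng(3)
        t0 = _center(rng.normal(size=(20, 1)))[:, 0]
        p0 = rng.normal(size=6)
        X = np.outer(t0, p0)
        w, t, p, c = ts.nipals_component(X, t0[:, None])
        corr = abs(np.corrcoef(t, t0)[0, 1])
        assert corr > 1 - 1e-10
        r2x = (t @ t) * (p @ p) / (X ** 2).sum()
        assert r2x == pytest.approx(1.0, abs=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        """The NIPALS weight solves the dominant-eigenvector problem of
        X'YY'X (10 random 20x10 multi-response instances)."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            X = _center(rng.normal(size=(20, 10)))
            Y = _center(rng.normal(size=(20, 3)))
            w, t, p, c = ts.nipals_component(X, Y, tol=1e-14)
            M = X.T @ Y @ Y.T @ X
            eigvals, eigvecs = np.linalg.eigh(M)
            v = eigvecs[:, -1]
            assert np.allclose(w * np.sign(w @ v), v, atol=1e-6)

    def test_matches_reference_pls_implementation(self):
        """With no orthogonal components and one response column the model
        agrees with an established PLS1 implementation."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(5)
        for _ in range(10):
            X = rng.normal(size=(20, 10))
            y = rng.normal(size=(20, 1))
            model = ts.fit_opls(_center(X), _center(y), n_pred=2, n_orth=0)
            y_hat_mine = model.T @ model.C.T + y.mean()
            ref = sklearn.PLSRegression(n_components=2, scale=False).fit(X, y)
            assert np.allclose(y_hat_mine, ref.predict(X), atol=1e-8)


class TestFitOpls:
    def _fixture(self, seed=6, n=40, p=15):
        rng = np.random.default_rng(seed)
        X = _center(rng.normal(size=(n, p)))
        y = np.array([1.0] * (n // 2) + [-1.0] * (n - n // 2))
        X += np.outer(y, rng.normal(size=p)) * 0.5
        return X, _center(y[:, None])

    def test_n_orth_zero_equals_plain_pls(self):
        X, y = self._fixture()
        opls = ts.fit_opls(X, y, n_pred=2, n_orth=0)
        Xd, Yd = X.copy(), y.copy()
        for a in range(2):
            w, t, p, c = ts.nipals_component(Xd, Yd)
            assert np.allclose(opls.T[:, a], t, atol=1e-10)
            assert np.allclose(opls.P[:, a], p, atol=1e-10)
            Xd = Xd - np.outer(t, p)
            Yd = Yd - np.outer(t, c)

    def test_orthogonal_scores_uncorrelated_with_response(self):
        X, y = self._fixture()
        model = ts.fit_opls(X, y, n_pred=1, n_orth=3)
        assert np.max(np.abs(model.To.T @ y)) < 1e-8
        assert np.max(np.abs(model.T.T @ model.To)) < 1e-8

    def test_planted_orthogonal_structure_recovered(self):
        """X built as predictive + Y-orthogonal rank-one structure: the
        fitted orthogonal score tracks the planted one and the two
        components account for all of X."""
        rng = np.random.default_rng(7)
        n, p = 60, 20
        y = _center(np.array([1.0] * 30 + [-1.0] * 30)[:, None])
        t_orth = _center(rng.normal(size=(n, 1)))[:, 0]
        t_orth -= y[:, 0] * (y[:, 0] @ t_orth) / (y[:, 0] @ y[:, 0])
        p_pred, p_orth = rng.normal(size=p), rng.normal(size=p)
        X = np.outer(y[:, 0], p_pred) + np.outer(t_orth, p_orth)
        model = ts.fit_opls(X, y, n_pred=1, n_orth=1)
        r = np.corrcoef(model.To[:, 0], t_orth)[0, 1]
        assert abs(r) > 0.99
        assert model.r2x_pred[0] + model.r2x_orth[0] == pytest.approx(1.0, abs=1e-8)

    def test_variance_conservation(self):
        X, y = self._fixture(seed=8)
        model = ts.fit_opls(X, y, n_pred=2, n_orth=2)
        X_hat = model.To @ model.Po.T + model.T @ model.P.T
        residual_frac = ((X - X_hat) ** 2).sum() / (X ** 2).sum()
        total = model.r2x_pred.sum() + model.r2x_orth.sum() + residual_frac
        assert total == pytest.approx(1.0, abs=1e-10)
        assert 0 <= model.r2x_cum <= 1

    def test_rank_exceeded_errors(self):
        rng = np.random.default_rng(9)
        t0 = _center(rng.normal(size=(10, 1)))[:, 0]
        X = np.outer(t0, rng.normal(size=5))  # rank 1
        with pytest.raises((ValueError, RuntimeError)):
            ts.fit_opls(X, t0[:, None], n_pred=3, n_orth=2)

    def test_planted_direction_recovered(self, separable_xy):
        X, labels, direction = separable_xy
        dummy = ts.build_dummy(labels)
        model = ts.fit_opls(_center(X), dummy.matrix, n_pred=1, n_orth=1)
        cos = abs(model.W[:, 0] @ direction)
        assert cos >= 0.95


class TestPredict:
    def test_training_set_reproduces_scores_and_accuracy(self, separable_xy):
        X, labels, _ = separable_xy
        model = ts.fit_oplsda(X, labels, n_pred=1, n_orth=1)
        t_new, to_new, y_hat, pred = ts.predict(model, X)
        assert np.allclose(t_new, model.T, atol=1e-8)
        assert np.allclose(to_new, model.To, atol=1e-8)
        assert pred == list(labels)

    def test_single_class_model_always_that_class(self):
        model = ts.OplsModel(
            n_pred=1, n_orth=0,
            W=np.ones((3, 1)), P=np.ones((3, 1)), T=np.zeros((2, 1)),
            C=np.ones((1, 1)), Wo=np.empty((3, 0)), Po=np.empty((3, 0)),
            To=np.empty((2, 0)), r2x_pred=np.array([1.0]),
            r2x_orth=np.array([]), r2y_cum=1.0, class_order=["only"],
            y_means=np.array([1.0]))
        *_, pred = ts.predict(model, np.eye(3), scaled=True)
        assert pred == ["only"] * 3

    def test_variable_mismatch_rejected(self, separable_xy):
        X, labels, _ = separable_xy
        model = ts.fit_oplsda(X, labels, n_pred=1, n_orth=1)
        with pytest.raises(ValueError, match="variables"):
            ts.predict(model, X[:, :5])


class TestCrossValidation:
    def test_loo_each_row_once(self, separable_xy):
        X, labels, _ = separable_xy
        cv = ts.cross_validate(X, labels, 1, 0, ts.CvConfig(k=len(labels), seed=0))
        assert sorted(cv.folds.tolist()) == list(range(len(labels)))
        assert all(p is not None for p in cv.predictions)

    def test_separable_classes_perfect_heldout_accuracy(self, separable_xy):
        X, labels, _ = separable_xy
        cv = ts.cross_validate(X, labels, 1, 1, ts.CvConfig(k=7, seed=1))
        assert cv.predictions == list(labels)
        assert cv.q2 > 0.8

    def test_q2_never_exceeds_r2y(self):
        rng = np.random.default_rng(10)
        for trial in range(20):
            X = rng.normal(size=(24, 8))
            labels = list(rng.permutation(["a"] * 12 + ["b"] * 12))
            model = ts.fit_oplsda(X, labels, n_pred=1, n_orth=0)
            cv = ts.cross_validate(X, labels, 1, 0, ts.CvConfig(k=6, seed=trial))
            assert cv.q2 <= model.r2y_cum + 1e-10

    def test_stratified_folds_deterministic_and_balanced(self):
        labels = ["a"] * 14 + ["b"] * 14
        cfg = ts.CvConfig(k=7, seed=3)
        f1 = _fold_assignment(labels, cfg)
        f2 = _fold_assignment(labels, cfg)
        assert np.array_equal(f1, f2)
        for f in range(7):
            fold_labels = [labels[i] for i in np.flatnonzero(f1 == f)]
            assert fold_labels.count("a") == fold_labels.count("b") == 2

    def test_tiny_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            ts.cross_validate(X, ["a", "a", "a", "a", "b"], 1, 0,
                              ts.CvConfig(k=2, seed=0))


class TestAutofit:
    def test_pure_noise_keeps_minimal_model(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(28, 10))
        labels = list(rng.permutation(["a"] * 14 + ["b"] * 14))
        result = ts.autofit(X, labels, ts.CvConfig(k=7, seed=2))
        assert (result.n_pred, result.n_orth) == (1, 0)
        assert result.q2 <= 0

    def test_planted_single_component_structure(self, separable_xy):
        X, labels, _ = separable_xy
        result = ts.autofit(X, labels, ts.CvConfig(k=7, seed=2))
        assert result.n_pred == 1
        assert result.n_pred + result.n_orth <= 4

    def test_component_cap_respected(self, coarse_design):
        ds = ts.generate_dataset(coarse_design)
        clean = ts.preprocess_dataset(ds, ts.PreprocessConfig(roi=(200, 1000)))
        result = ts.autofit(clean.matrix, clean.labels["class"].tolist(),
                            ts.CvConfig(k=4, seed=0))
        assert result.n_pred + result.n_orth <= 4


def test_model_json_roundtrip(tmp_path, separable_xy):
    X, labels, _ = separable_xy
    model = ts.fit_oplsda(X, labels, n_pred=1, n_orth=1)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = ts.OplsModel.from_json(path)
    assert np.allclose(back.W, model.W)
    assert np.allclose(back.scaler.weights, model.scaler.weights)
    assert back.class_order == model.class_order
    *_, pred_a = ts.predict(model, X)
    *_, pred_b = ts.predict(back, X)
    assert pred_a == pred_b
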