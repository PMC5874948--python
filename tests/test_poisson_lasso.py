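import numpy as np
import pytest

from virtualqa import poisson_lasso as pl
from virtualqa.plans import QADataset, QARecord
from virtualqa.synthetic import GeneratorConfig, generate_qa_dataset


def lbfgs_lasso_oracle(Xs, fr, w, lam):
    """Independent minimizer of the standardized penalized objective via the
    positive/negative-part reformulation (smooth, box-constrained)."""
    from scipy.optimize import minimize

    P = Xs.shape[1]

    def split_obj(z):
        bp, bn = z[:P], z[P:]
        beta = bp - bn
        eta = Xs @ beta
        mu = np.exp(eta)
        nll = -(w @ (fr * eta - mu))
        grad_nll = Xs.T @ (w * (mu - fr))
        pen = lam * (bp[1:].sum() + bn[1:].sum())
        gp = grad_nll.copy()
        gn = -grad_nll.copy()
        gp[1:] += lam
        gn[1:] += lam
        return nll + pen, np.concatenate([gp, gn])

    z0 = np.zeros(2 * P)
    bounds = [(None, None)] + [(0, None)] * (P - 1)
    bounds += [(0, None)] * P
    bounds[P] = (0, 0)  # intercept handled entirely by the positive part
    res = minimize(split_obj, z0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10})
    return res.x[:P] - res.x[P:]


class TestObjective:
    def test_zero_beta_gives_weight_sum(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        beta = np.zeros(ds.X.shape[1])
        assert pl.objective(beta, ds, 5.0) == pytest.approx(ds.weights.sum())

    def test_lambda_zero_is_pure_nll(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 0.1, ds.X.shape[1])
        pen = np.abs(beta[1:]).sum()
        assert pl.objective(beta, ds, 2.0) == pytest.approx(
            pl.objective(beta, ds, 0.0) + 2.0 * pen)

    def test_linear_in_weights(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        doubled = QADataset(records=ds.records, feature_names=ds.feature_names,
                            X=ds.X, d_max=ds.d_max / 2.0)
        beta = np.zeros(ds.X.shape[1])
        assert pl.objective(beta, doubled, 0.0) == pytest.approx(
            2.0 * pl.objective(beta, ds, 0.0))

    def test_overflow_guarded(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        beta = np.full(ds.X.shape[1], 800.0)
        with pytest.raises(OverflowError):
            pl.objective(beta, ds, 0.0)


class TestFitOracles:
    def test_unpenalized_matches_statsmodels_irls(self, small_abstract_dataset):
        import statsmodels.api as sm

        ds, _ = small_abstract_dataset
        ours = pl.fit(ds, 0.0)
        glm = sm.GLM(ds.failing_rates, ds.X,
                     family=sm.families.Poisson(),
                     var_weights=ds.weights).fit()
        np.testing.assert_allclose(ours.beta, glm.params, atol=1e-5)

    @pytest.mark.parametrize("lam_frac", [0.5, 0.1, 0.02])
    def test_penalized_matches_lbfgs_oracle(self, small_abstract_dataset,
                                            lam_frac):
        ds, _ = small_abstract_dataset
        lam = lam_frac * pl.lambda_max(ds)
        ours = pl.fit(ds, lam)
        X, fr, w = pl._design(ds)
        Xs, mean, scale, usable = pl._standardize(X, w)
        oracle = lbfgs_lasso_oracle(Xs, fr, w, lam)
        np.testing.assert_allclose(ours.beta_std, oracle, atol=2e-5)

    def test_intercept_only_closed_form(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        lam = 2.0 * pl.lambda_max(ds)
        f = pl.fit(ds, lam)
        closed = np.log((ds.weights @ ds.failing_rates) / ds.weights.sum())
        assert f.beta[0] == pytest.approx(closed, abs=1e-8)
        assert f.selected == []


class TestLambdaMax:
    def test_just_above_lambda_max_selects_nothing(self, signal_dataset):
        ds, _ = signal_dataset
        f = pl.fit(ds, 1.01 * pl.lambda_max(ds))
        assert f.selected == []
        assert pl.kkt_report(f, ds).ok

    def test_half_lambda_max_selects_signal(self, signal_dataset):
        ds, _ = signal_dataset
        f = pl.fit(ds, 0.5 * pl.lambda_max(ds))
        assert len(f.selected) >= 1

    def test_permuted_outcomes_shrink_lambda_max(self, signal_dataset):
        ds, truth = signal_dataset
        rng = np.random.default_rng(12)
        perm = rng.permutation(len(ds))
        shuffled = QADataset(
            records=[ds.records[i] for i in perm],
            feature_names=ds.feature_names, X=ds.X, d_max=ds.d_max)
        assert pl.lambda_max(shuffled) < 0.5 * pl.lambda_max(ds)


class TestPath:
    def test_first_fit_empty_and_kkt_clean(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        path = pl.fit_path(ds, n_lambda=20, lambda_min_ratio=1e-3)
        assert path.fits[0].selected == []
        assert all(pl.kkt_report(f, ds).ok for f in path.fits)

    def test_each_fit_beats_warm_start_at_its_lambda(self,
                                                     small_abstract_dataset):
        ds, _ = small_abstract_dataset
        path = pl.fit_path(ds, n_lambda=15, lambda_min_ratio=1e-2)
        X, fr, w = pl._design(ds)
        Xs, *_ = pl._standardize(X, w)
        for prev, cur, lam in zip(path.fits, path.fits[1:], path.lambdas[1:]):
            obj_prev_beta = pl._objective_std(Xs, fr, w, prev.beta_std, lam)
            obj_cur = pl._objective_std(Xs, fr, w, cur.beta_std, lam)
            assert obj_cur <= obj_prev_beta + 1e-9

    def test_path_bitwise_reproducible(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        p1 = pl.fit_path(ds, n_lambda=10, lambda_min_ratio=1e-2)
        p2 = pl.fit_path(ds, n_lambda=10, lambda_min_ratio=1e-2)
        for f1, f2 in zip(p1.fits, p2.fits):
            np.testing.assert_array_equal(f1.beta, f2.beta)


class TestWeightSemantics:
    def test_splitting_a_record_leaves_minimizer_unchanged(
            self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        # split a non-maximal record in two; keep d_max fixed explicitly
        i = int(np.argmin([r.detectors_total for r in ds.records]))
        r = ds.records[i]
        half = r.detectors_total // 2
        y1 = r.detectors_failing // 2
        split = ([QARecord(f"{r.unit_id}a", half, y1),
                  QARecord(f"{r.unit_id}b", r.detectors_total - half,
                           r.detectors_failing - y1)]
                 + [q for j, q in enumerate(ds.records) if j != i])
        X_split = np.vstack([ds.X[i], ds.X[i],
                             np.delete(ds.X, i, axis=0)])
        ds_split = QADataset(records=split, feature_names=ds.feature_names,
                             X=X_split, d_max=ds.d_max)
        lam = 0.1 * pl.lambda_max(ds)
        f_orig = pl.fit(ds, lam)
        f_split = pl.fit(ds_split, lam)
        np.testing.assert_allclose(f_split.beta, f_orig.beta, atol=1e-6)

    def test_duplicating_record_equals_doubled_detectors(
            self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        i = 5
        r = ds.records[i]
        dup_records = list(ds.records) + [QARecord("dup", r.detectors_total,
                                                   r.detectors_failing)]
        X_dup = np.vstack([ds.X, ds.X[i]])
        ds_dup = QADataset(records=dup_records,
                           feature_names=ds.feature_names, X=X_dup,
                           d_max=ds.d_max)
        merged_records = ([QARecord(r.unit_id, 2 * r.detectors_total,
                                    2 * r.detectors_failing)]
                          + [q for j, q in enumerate(ds.records) if j != i])
        X_merged = np.vstack([ds.X[i], np.delete(ds.X, i, axis=0)])
        ds_merged = QADataset(records=merged_records,
                              feature_names=ds.feature_names, X=X_merged,
                              d_max=ds.d_max)
        f_dup = pl.fit(ds_dup, 0.0)
        f_merged = pl.fit(ds_merged, 0.0)
        np.testing.assert_allclose(f_dup.beta, f_merged.beta, atol=1e-6)


class TestCrossValidation:
    def test_same_seed_same_result(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        cv1 = pl.cross_validate(ds, k=4, seed=5, n_lambda=12,
                                lambda_min_ratio=1e-2)
        cv2 = pl.cross_validate(ds, k=4, seed=5, n_lambda=12,
                                lambda_min_ratio=1e-2)
        np.testing.assert_array_equal(cv1.fold_assignments,
                                      cv2.fold_assignments)
        np.testing.assert_array_equal(cv1.mean_deviance, cv2.mean_deviance)

    def test_signal_improves_heldout_deviance(self, signal_dataset):
        ds, _ = signal_dataset
        cv = pl.cross_validate(ds, k=5, seed=0, n_lambda=20,
                               lambda_min_ratio=1e-3)
        assert cv.mean_deviance.argmin() > 0
        assert cv.lambda_min < cv.lambdas[0]
        assert cv.lambda_1se >= cv.lambda_min

    def test_folds_partition_dataset(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        cv = pl.cross_validate(ds, k=7, seed=1, n_lambda=5,
                               lambda_min_ratio=0.1)
        assert len(cv.fold_assignments) == len(ds)
        assert set(cv.fold_assignments) == set(range(7))


class TestPrediction:
    def test_zero_beta_unit_rate(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        f = pl.fit(ds, 0.0)
        f.beta = np.zeros_like(f.beta)
        assert pl.predict_failing_rate(f, ds.X)[0] == 1.0
        assert pl.predict_passing_rate(f, ds.X)[0] == 0.0

    def test_intercept_only_five_percent(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        f = pl.fit(ds, 0.0)
        beta = np.zeros_like(f.beta)
        beta[0] = np.log(0.05)
        f.beta = beta
        x = np.zeros(len(beta))
        x[0] = 1.0
        assert pl.predict_failing_rate(f, x) == pytest.approx(0.05)
        assert pl.predict_passing_rate(f, x) == pytest.approx(95.0)

    def test_intercept_shift_scales_rate(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        f = pl.fit(ds, 0.5 * pl.lambda_max(ds))
        fr0 = pl.predict_failing_rate(f, ds.X)
        f.beta = f.beta.copy()
        f.beta[0] += 0.3
        np.testing.assert_allclose(pl.predict_failing_rate(f, ds.X),
                                   fr0 * np.exp(0.3))

    def test_misaligned_features_rejected(self, small_abstract_dataset):
        from virtualqa.features import FeatureVector

        ds, _ = small_abstract_dataset
        f = pl.fit(ds, 0.0)
        bad = FeatureVector(names=["intercept", "bogus"],
                            values=np.array([1.0, 0.5]))
        with pytest.raises(pl.AlignmentError, match="bogus"):
            pl.predict_failing_rate(f, bad)

    def test_reference_level_invariance_at_lambda_zero(self):
        # full one-hot group vs dropped-level encoding: identical predictions
        rng = np.random.default_rng(42)
        n = 150
        level = rng.integers(0, 3, n)
        onehot = np.zeros((n, 3))
        onehot[np.arange(n), level] = 1.0
        cont = rng.uniform(0, 1, n)
        fr_true = np.exp(np.log(0.03) + 0.4 * onehot[:, 0] + 0.5 * cont)
        D = rng.integers(700, 1700, n)
        y = np.minimum(rng.poisson(D * fr_true), D)
        recs = [QARecord(f"u{i}", int(D[i]), int(y[i])) for i in range(n)]

        X_full = np.column_stack([np.ones(n), onehot, cont])
        X_drop = np.column_stack([np.ones(n), onehot[:, :2], cont])
        ds_full = QADataset(records=recs, X=X_full,
                            feature_names=["intercept", "a", "b", "c", "x"])
        ds_drop = QADataset(records=recs, X=X_drop,
                            feature_names=["intercept", "a", "b", "x"])
        f_full = pl.fit(ds_full, 0.0)
        f_drop = pl.fit(ds_drop, 0.0)
        np.testing.assert_allclose(np.exp(X_full @ f_full.beta),
                                   np.exp(X_drop @ f_drop.beta), rtol=1e-4)


class TestKKT:
    def test_perturbation_detected(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        f = pl.fit(ds, 0.05 * pl.lambda_max(ds))
        assert pl.kkt_report(f, ds).ok
        f.beta_std = f.beta_std.copy()
        nz = [j for j in range(1, len(f.beta_std)) if f.beta_std[j] != 0][0]
        f.beta_std[nz] += 1e-2
        assert not pl.kkt_report(f, ds).ok

    def test_lambda_zero_plain_gradient_check(self, small_abstract_dataset):
        ds, _ = small_abstract_dataset
        rep = pl.kkt_report(pl.fit(ds, 0.0), ds)
        assert rep.ok and rep.max_zero_excess <= 0.0


class TestRecoveryAndSerialization:
    def test_sparse_recovery_at_moderate_n(self, signal_dataset):
        ds, truth = signal_dataset
        cv = pl.cross_validate(ds, k=5, seed=0, n_lambda=30,
                               lambda_min_ratio=1e-3)
        f = pl.fit(ds, cv.lambda_min)
        true_support = {n for n, b in zip(truth.feature_names, truth.beta)
                        if b != 0 and n != "intercept"}
        assert true_support <= set(f.selected)
        idx = [truth.feature_names.index(n) for n in true_support]
        rmse = np.sqrt(np.mean((f.beta[idx] - truth.beta[idx]) ** 2))
        assert rmse < 0.15

    def test_save_load_reproduces_predictions(self, small_abstract_dataset,
                                              tmp_path):
        ds, _ = small_abstract_dataset
        f = pl.fit(ds, 0.1 * pl.lambda_max(ds), config_hash="h1",
                   stratum={"energy": "6MV"})
        p = tmp_path / "model.json"
        pl.save_fit(f, p)
        back = pl.load_fit(p)
        np.testing.assert_array_equal(back.beta, f.beta)
        assert back.config_hash == "h1" and back.stratum == {"energy": "6MV"}
        np.testing.assert_array_equal(pl.predict_failing_rate(back, ds.X),
                                      pl.predict_failing_rate(f, ds.X))


class TestDegenerateInputs:
    def test_single_record_rejected(self):
        ds = QADataset(records=[QARecord("a", 100, 3)],
                       feature_names=["intercept", "c"],
                       X=np.array([[1.0, 0.5]]))
        with pytest.raises(pl.DegenerateDataError):
            pl.fit(ds, 0.0)

    def test_all_passing_rejected(self):
        recs = [QARecord(f"u{i}", 100, 0) for i in range(10)]
        X = np.column_stack([np.ones(10), np.linspace(0, 1, 10)])
        ds = QADataset(records=recs, feature_names=["intercept", "c"], X=X)
        with pytest.raises(pl.DegenerateDataError):
            pl.fit(ds, 0.0)
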