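"""Endpoints, pruning, power transform, nested CV contracts and leakage guard."""

import numpy as np
import pandas as pd
import pytest

from srct_radiomics import (
    CorrelationPruner,
    CVConfig,
    build_pipeline,
    make_endpoint,
    make_endpoints,
    nested_cv,
    sample_params,
    tune_on_training,
    yeo_johnson,
)
from srct_radiomics.modeling import (
    FAMILIES,
    ModelingError,
    pipeline_parameters,
    run_model_grid,
)
from srct_radiomics.radiomic_features import FeatureDescriptor, FeatureTable

# Reduced CV protocol for fast unit tests (full protocol is 3x10 inner /
# 2x5 outer with 300 search samples).
FAST_CV = CVConfig(outer_splits=3, outer_repeats=1, inner_splits=3,
                   inner_repeats=1, n_search=4)


def _labels(n_none=20, n_limited=10, n_extensive=8):
    labs = ["none"] * n_none + ["limited"] * n_limited + ["extensive"] * n_extensive
    return pd.Series(labs, index=[f"P{i:03d}" for i in range(len(labs))])


def _qct_table(labels, rng, effect=3.0, sd_effect=0.0):
    """Intensity-moment table with a class-mean shift on hist_mean."""
    n = len(labels)
    shift = labels.map({"none": 0.0, "limited": effect, "extensive": 2 * effect})
    sd_shift = labels.map({"none": 0.0, "limited": sd_effect, "extensive": 2 * sd_effect})
    df = pd.DataFrame(
        {
            "original_hist_mean": -850 + shift + rng.normal(0, 1.5, n),
            "original_hist_sd": 40 + sd_shift + rng.normal(0, 2, n),
            "original_hist_skewness": rng.normal(0, 0.3, n),
            "original_hist_kurtosis": 3 + rng.normal(0, 0.3, n),
        },
        index=labels.index,
    )
    desc = [
        FeatureDescriptor(name=c, family="intensity", sub_band="original", space="2D")
        for c in df.columns
    ]
    return FeatureTable(values=df, descriptors=desc, labels=labels,
                        space="2D", resolution=2.0)


class TestEndpoints:
    def test_study_scale_denominators(self):
        labels = _labels(99, 44, 23)
        eps = make_endpoints(labels)
        diag, stag = eps["diagnosis"], eps["staging"]
        assert len(diag.y) == 166
        assert diag.n_pos == 67 and diag.n_neg == 99
        assert len(stag.y) == 67
        assert stag.n_pos == 23 and stag.n_neg == 44

    def test_all_none_staging_fails(self):
        with pytest.raises(ModelingError):
            make_endpoint(pd.Series(["none"] * 10), "staging")

    def test_permutation_preserves_class_sizes(self, rng):
        labels = _labels()
        perm = pd.Series(rng.permutation(labels.values), index=labels.index)
        a, b = make_endpoint(labels, "diagnosis"), make_endpoint(perm, "diagnosis")
        assert a.n_pos == b.n_pos and a.n_neg == b.n_neg


class TestCorrelationPruner:
    def test_perfectly_correlated_feature_removed(self, rng):
        a = rng.normal(size=50)
        X = pd.DataFrame({"A": a, "B": 2 * a + 1, "C": rng.normal(size=50)})
        pruner = CorrelationPruner(cutoff=0.9, ranking="extraction_order")
        out = pruner.fit_transform(X)
        assert list(out.columns) == ["A", "C"]

    def test_cutoff_one_keeps_all(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        X["f"] = X["a"] * 0.99 + rng.normal(size=30) * 0.01
        out = CorrelationPruner(cutoff=1.0).fit_transform(X)
        assert out.shape[1] == 6

    def test_fscore_ranking_rescues_late_discriminator(self, rng):
        """With the best discriminator extracted last and correlated to an
        earlier noise feature, F-score ranking keeps it, extraction order
        drops it."""
        n = 80
        y = np.arange(n) % 2
        best = y * 4.0 + rng.normal(0, 0.5, n)
        noisy_proxy = best + rng.normal(0, 1.2, n)   # correlated, weak signal
        X = pd.DataFrame({"noise": noisy_proxy, "late_best": best})
        by_order = CorrelationPruner(cutoff=0.7, ranking="extraction_order")
        by_order.fit(X, y)
        assert by_order.columns_ == ["noise"]
        by_f = CorrelationPruner(cutoff=0.7, ranking="f_score")
        by_f.fit(X, y)
        assert by_f.columns_ == ["late_best"]

    def test_invalid_cutoff_errors(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        with pytest.raises(ModelingError):
            CorrelationPruner(cutoff=0.0).fit(X)


class TestYeoJohnson:
    def test_grid_mle_matches_reference_optimizer(self, rng):
        """The vectorized grid MLE recovers the same per-feature lambdas and
        transforms as sklearn's scalar-optimizer PowerTransformer."""
        from sklearn.preprocessing import PowerTransformer, StandardScaler

        from srct_radiomics.modeling import YeoJohnsonTransformer

        X = StandardScaler().fit_transform(
            np.column_stack([
                rng.normal(size=150),
                rng.exponential(size=150),
                -rng.exponential(size=150),
                rng.standard_t(3, size=150),
            ])
        )
        ref = PowerTransformer(method="yeo-johnson", standardize=False).fit(X)
        ours = YeoJohnsonTransformer().fit(X)
        assert np.allclose(ours.lambdas_, ref.lambdas_, atol=0.02)
        assert np.abs(ours.transform(X) - ref.transform(X)).max() < 0.02

    def test_lambda_one_identity(self, rng):
        x = rng.normal(size=20)
        assert np.allclose(yeo_johnson(x, 1.0), x)

    def test_lambda_zero_log_branch(self):
        x = np.array([np.e - 1.0])
        assert yeo_johnson(x, 0.0)[0] == pytest.approx(1.0)

    def test_lambda_two_negative_branch(self):
        assert yeo_johnson(np.array([-1.0]), 2.0)[0] == pytest.approx(-np.log(2))

    def test_monotone_for_any_lambda(self, rng):
        x = np.sort(rng.normal(size=50, scale=3))
        for lam in (-1.0, 0.0, 0.5, 1.0, 2.0, 3.5):
            assert np.all(np.diff(yeo_johnson(x, lam)) > 0)


class TestQCTModels:
    def test_preselected_column_counts(self, rng):
        labels = _labels()
        table = _qct_table(labels, rng)
        ep = make_endpoint(labels, "diagnosis")
        for family, n_cols in (("M", 1), ("MSDSK", 4)):
            pipe = build_pipeline(family)
            pipe.set_params(**sample_params(family, rng))
            pipe.fit(table.values.loc[ep.patient_ids], ep.y)
            assert pipe.named_steps["clf"].coef_.shape[1] == n_cols

    def test_missing_named_feature_errors(self, rng):
        labels = _labels()
        df = pd.DataFrame({"original_hist_sd": rng.normal(size=len(labels))},
                          index=labels.index)
        pipe = build_pipeline("M")
        with pytest.raises(ModelingError):
            pipe.fit(df, (labels != "none").astype(int).values)

    def test_mean_shift_cohort_gives_high_auc(self, rng):
        labels = _labels(24, 12, 10)
        table = _qct_table(labels, rng, effect=4.0)
        ep = make_endpoint(labels, "diagnosis")
        res = nested_cv("M", table, ep, seed=11, cv=FAST_CV)
        assert res.auc_testing_mean > 0.9


class TestNestedCV:
    def test_outer_folds_partition_cohort(self, rng):
        labels = _labels()
        table = _qct_table(labels, rng)
        ep = make_endpoint(labels, "diagnosis")
        cv = CVConfig(outer_splits=5, outer_repeats=2, inner_splits=2,
                      inner_repeats=1, n_search=1)
        res = nested_cv("M", table, ep, seed=0, cv=cv)
        for rep in (0, 1):
            sub = res.predictions[res.predictions["repeat"] == rep]
            assert sorted(sub["patient_id"]) == sorted(ep.patient_ids)
            folds = [set(g["patient_id"]) for _, g in sub.groupby("fold")]
            for i in range(len(folds)):
                for j in range(i + 1, len(folds)):
                    assert not folds[i] & folds[j]

    def test_reproducible_given_seed(self, rng):
        labels = _labels(14, 8, 6)
        table = _qct_table(labels, rng)
        ep = make_endpoint(labels, "staging")
        r1 = nested_cv("MSDSK", table, ep, seed=5, cv=FAST_CV)
        r2 = nested_cv("MSDSK", table, ep, seed=5, cv=FAST_CV)
        assert r1.auc_testing_mean == r2.auc_testing_mean
        assert r1.predictions["score"].equals(r2.predictions["score"])
        assert r1.best_params == r2.best_params

    def test_scores_in_unit_interval_all_families(self, rng):
        labels = _labels(12, 7, 6)
        k = 12
        df = pd.DataFrame(
            rng.normal(size=(len(labels), k)),
            columns=[f"original_hist_f{i}" for i in range(k)],
            index=labels.index,
        )
        df["original_hist_mean"] = rng.normal(size=len(labels))
        df["original_hist_sd"] = rng.normal(size=len(labels))
        df["original_hist_skewness"] = rng.normal(size=len(labels))
        df["original_hist_kurtosis"] = rng.normal(size=len(labels))
        desc = [FeatureDescriptor(c, "intensity", "original", "2D") for c in df.columns]
        table = FeatureTable(values=df, descriptors=desc, labels=labels,
                             space="2D", resolution=2.0)
        ep = make_endpoint(labels, "diagnosis")
        for family in FAMILIES:
            res = nested_cv(family, table, ep, seed=2, cv=FAST_CV)
            s = res.predictions["score"]
            assert ((s >= 0) & (s <= 1)).all()

    def test_tuning_optimism_over_seeds(self, rng):
        """Inner-loop (tuning) AUC exceeds outer-loop (testing) AUC in
        expectation: the winner's inner score is selection-biased."""
        diffs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            labels = _labels(16, 9, 7)
            table = _qct_table(labels, r, effect=1.0)
            ep = make_endpoint(labels, "diagnosis")
            res = nested_cv("MSDSK", table, ep, seed=seed, cv=FAST_CV)
            diffs.append(res.auc_tuning_mean - res.auc_testing_mean)
        assert np.mean(diffs) > -0.02


class TestLeakageGuard:
    def test_outer_test_rows_do_not_influence_fit(self, rng):
        """Replacing held-out rows by noise before tuning+fitting leaves
        every fitted parameter unchanged."""
        labels = _labels(16, 9, 7)
        table = _qct_table(labels, rng)
        ep = make_endpoint(labels, "diagnosis")
        X = table.values.loc[ep.patient_ids]
        y = ep.y
        train_idx = np.arange(0, 24)
        test_idx = np.arange(24, len(y))
        X_perturbed = X.copy()
        X_perturbed.iloc[test_idx] = rng.normal(size=(len(test_idx), X.shape[1])) * 1e3

        for family in ("MSDSK", "LR-LR"):
            params1, scores1, fitted1 = tune_on_training(
                family, X.iloc[train_idx], y[train_idx], FAST_CV, seed=3
            )
            params2, scores2, fitted2 = tune_on_training(
                family, X_perturbed.iloc[train_idx], y[train_idx], FAST_CV, seed=3
            )
            assert params1 == params2
            assert scores1 == scores2
            p1, p2 = pipeline_parameters(fitted1), pipeline_parameters(fitted2)
            assert p1.keys() == p2.keys()
            for k in p1:
                if p1[k].dtype == object:
                    assert list(p1[k]) == list(p2[k])
                else:
                    assert np.array_equal(p1[k], p2[k])


class TestModelGrid:
    def test_grid_shape_and_determinism(self, rng):
        labels = _labels(14, 8, 6)
        table = _qct_table(labels, rng)
        tables = {"2D@2.0": table}
        eps = make_endpoints(labels)
        grid1, res1 = run_model_grid(tables, eps, ["M", "MSDSK"], seed=4, cv=FAST_CV)
        grid2, _ = run_model_grid(tables, eps, ["M", "MSDSK"], seed=4, cv=FAST_CV)
        assert len(grid1) == 1 * 2 * 2
        pd.testing.assert_frame_equal(grid1, grid2)

    def test_single_cell_grid(self, rng):
        labels = _labels(10, 6, 5)
        table = _qct_table(labels, rng)
        grid, res = run_model_grid(
            {"2D@2.0": table}, {"diagnosis": make_endpoint(labels, "diagnosis")},
            ["M"], seed=0, cv=FAST_CV,
        )
        assert len(grid) == 1
        assert set(res) == {("2D@2.0", "diagnosis", "M")}
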