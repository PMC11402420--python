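"""Predictive models and the nested cross-validation protocol.

Two endpoints are modelled from a three-class cohort (none / limited /
extensive disease):

* diagnosis — any ILD (limited or extensive) versus none, on all patients;
* staging — extensive versus limited, on the diseased subset only.

Four model families are compared:

* ``M`` and ``MSDSK`` — quantitative-CT logistic regressions on preselected
  intensity features (mean; mean + sd + skewness + kurtosis),
* ``LR-LR`` — logistic regression with embedded LR-based feature selection,
* ``ET-ET`` — extra-trees with embedded ET-based feature selection.

The data-driven families prune correlated features (greedy scan in rank
order by a tunable ranking statistic, Pearson-r cutoff), then Z-score and
Yeo-Johnson transform, then select features from an embedded model, then
classify. Hyperparameters are tuned by random search inside a nested CV:
a repeated stratified k-fold inner loop scores each sampled configuration
by mean ROC AUC, and a repeated stratified k-fold outer loop measures
generalization of the per-fold winners. All fitting — scalers, transform
parameters, pruning order, selection — is confined to training folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .radiomic_features import (
    FeatureTable,
    QCT_M_FEATURES,
    QCT_MSDSK_FEATURES,
)

FAMILIES = ("M", "MSDSK", "LR-LR", "ET-ET")
RANKINGS = ("extraction_order", "f_score", "kruskal_wallis")


class ModelingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Endpoints
# ---------------------------------------------------------------------------

@dataclass
class Endpoint:
    """A binary prediction task carved out of the three-class labels."""

    name: str                      # "diagnosis" | "staging"
    patient_ids: np.ndarray        # patients entering the task
    y: np.ndarray                  # binary outcome, aligned to patient_ids
    positive_class: str

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.y) - self.y.sum())


def make_endpoint(labels: pd.Series, name: str) -> Endpoint:
    """Build the diagnosis or staging endpoint from three-class labels.

    Diagnosis keeps the full cohort with limited + extensive as positives;
    staging keeps only diseased patients with extensive as positives.
    """
    lab = pd.Series(labels)
    bad = set(lab.unique()) - {"none", "limited", "extensive"}
    if bad:
        raise ModelingError(f"unknown labels {sorted(bad)}")
    if name == "diagnosis":
        ids = lab.index.to_numpy()
        y = lab.isin(["limited", "extensive"]).to_numpy().astype(int)
        positive = "ILD (limited or extensive)"
    elif name == "staging":
        sub = lab[lab != "none"]
        ids = sub.index.to_numpy()
        y = (sub == "extensive").to_numpy().astype(int)
        positive = "extensive"
    else:
        raise ModelingError(f"unknown endpoint {name!r}")
    if y.sum() == 0 or y.sum() == len(y):
        raise ModelingError(f"endpoint {name!r} has an empty class")
    return Endpoint(name=name, patient_ids=ids, y=y, positive_class=positive)


def make_endpoints(labels: pd.Series) -> dict[str, Endpoint]:
    return {n: make_endpoint(labels, n) for n in ("diagnosis", "staging")}


# ---------------------------------------------------------------------------
# Transformers
# ---------------------------------------------------------------------------

class ColumnPreselector(BaseEstimator, TransformerMixin):
    """Restrict the table to named columns (the qCT preselected features)."""

    def __init__(self, columns: Sequence[str] = ()):
        self.columns = columns

    def fit(self, X, y=None):
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ModelingError(f"preselected features missing from table: {missing}")
        return self

    def transform(self, X):
        return X[list(self.columns)]


class CorrelationPruner(BaseEstimator, TransformerMixin):
    """Greedy correlation-based feature pruning in rank order.

    Features are ranked by ``extraction_order`` (the column order:
    intensity, texture, then wavelets), the ANOVA F-score, or the
    Kruskal-Wallis H statistic, then scanned in rank order: a feature is
    kept iff its absolute Pearson r with every already-kept feature does
    not exceed ``cutoff``.
    """

    def __init__(self, cutoff: float = 0.9, ranking: str = "extraction_order"):
        self.cutoff = cutoff
        self.ranking = ranking

    def fit(self, X, y=None):
        if not (0.0 < self.cutoff <= 1.0):
            raise ModelingError(f"correlation cutoff {self.cutoff} outside (0, 1]")
        if self.ranking not in RANKINGS:
            raise ModelingError(f"unknown ranking {self.ranking!r}")
        Xv = np.asarray(X, dtype=float)
        n_feat = Xv.shape[1]
        order = self._rank(Xv, y)
        corr = np.corrcoef(Xv, rowvar=False)
        if n_feat == 1:
            corr = corr.reshape(1, 1)
        corr = np.nan_to_num(np.abs(corr), nan=0.0)
        kept: list[int] = []
        for idx in order:
            if all(corr[idx, j] <= self.cutoff for j in kept):
                kept.append(idx)
        self.kept_idx_ = sorted(kept)
        self.columns_ = (
            [X.columns[i] for i in self.kept_idx_]
            if hasattr(X, "columns") else self.kept_idx_
        )
        return self

    def _rank(self, Xv: np.ndarray, y) -> np.ndarray:
        n_feat = Xv.shape[1]
        if self.ranking == "extraction_order" or y is None:
            return np.arange(n_feat)
        y = np.asarray(y)
        if self.ranking == "f_score":
            score, _ = f_classif(Xv, y)
        else:  # kruskal_wallis
            score = np.empty(n_feat)
            groups = [Xv[y == g] for g in np.unique(y)]
            for j in range(n_feat):
                try:
                    score[j] = stats.kruskal(*(g[:, j] for g in groups)).statistic
                except ValueError:  # all values identical
                    score[j] = 0.0
        score = np.nan_to_num(score, nan=0.0)
        # stable sort: ties resolved by extraction order
        return np.argsort(-score, kind="stable")

    def transform(self, X):
        if hasattr(X, "columns"):
            return X.iloc[:, self.kept_idx_]
        return np.asarray(X)[:, self.kept_idx_]


class EmbeddedSelector(BaseEstimator, TransformerMixin):
    """Select features whose embedded-model importance clears a quantile.

    The embedded model is a logistic regression (importance = |coefficient|)
    or an extra-trees classifier (impurity importance). ``threshold`` is the
    quantile of the importance distribution below which features are
    dropped; at least one feature is always retained.
    """

    def __init__(self, estimator=None, threshold: float = 0.5):
        self.estimator = estimator
        self.threshold = threshold

    def fit(self, X, y=None):
        est = clone(self.estimator)
        est.fit(np.asarray(X, dtype=float), y)
        if hasattr(est, "coef_"):
            imp = np.abs(est.coef_).ravel()
        else:
            imp = est.feature_importances_
        cut = np.quantile(imp, self.threshold)
        keep = np.where(imp >= cut)[0]
        if keep.size == 0:
            keep = np.array([int(np.argmax(imp))])
        self.kept_idx_ = keep
        self.importances_ = imp
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.kept_idx_]


class YeoJohnsonTransformer(BaseEstimator, TransformerMixin):
    """Per-feature Yeo-Johnson power transform, lambda by maximum likelihood.

    The profile log-likelihood is evaluated on a lambda grid simultaneously
    for all features (vectorized) and the grid optimum is sharpened by
    parabolic interpolation. This keeps the transform fast enough to refit
    inside every inner cross-validation fold of a random search, where a
    per-feature scalar optimizer is the bottleneck.
    """

    GRID = np.linspace(-3.0, 5.0, 81)

    def fit(self, X, y=None):
        Xv = np.asarray(X, dtype=float)
        n, m = Xv.shape
        const = np.sum(np.sign(Xv) * np.log1p(np.abs(Xv)), axis=0)
        llf = np.empty((self.GRID.size, m))
        for gi, lam in enumerate(self.GRID):
            T = yeo_johnson(Xv, lam)
            var = T.var(axis=0)
            llf[gi] = -0.5 * n * np.log(np.maximum(var, 1e-300)) + (lam - 1.0) * const
        best = np.argmax(llf, axis=0)
        lambdas = self.GRID[best]
        # parabolic sharpening where the optimum is interior to the grid
        interior = (best > 0) & (best < self.GRID.size - 1)
        idx = np.where(interior)[0]
        if idx.size:
            h = self.GRID[1] - self.GRID[0]
            l0 = llf[best[idx], idx]
            lm = llf[best[idx] - 1, idx]
            lp = llf[best[idx] + 1, idx]
            denom = lm - 2.0 * l0 + lp
            ok = denom < -1e-12
            shift = np.zeros_like(l0)
            shift[ok] = 0.5 * h * (lm - lp)[ok] / denom[ok]
            lambdas[idx] = self.GRID[best[idx]] + np.clip(shift, -h, h)
        self.lambdas_ = lambdas
        return self

    def transform(self, X):
        Xv = np.asarray(X, dtype=float)
        out = np.empty_like(Xv)
        for j, lam in enumerate(self.lambdas_):
            out[:, j] = yeo_johnson(Xv[:, j], float(lam))
        return out


def yeo_johnson(values: np.ndarray, lmbda: float) -> np.ndarray:
    """Closed-form Yeo-Johnson power transform for a given lambda.

    Monotone for every lambda; lambda = 1 is the identity.
    """
    x = np.asarray(values, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    if lmbda != 0:
        out[pos] = ((x[pos] + 1.0) ** lmbda - 1.0) / lmbda
    else:
        out[pos] = np.log1p(x[pos])
    if lmbda != 2:
        out[~pos] = -(((-x[~pos] + 1.0) ** (2.0 - lmbda)) - 1.0) / (2.0 - lmbda)
    else:
        out[~pos] = -np.log1p(-x[~pos])
    return out


# ---------------------------------------------------------------------------
# Hyperparameter search spaces
# ---------------------------------------------------------------------------
# The search space is config-overridable: each entry maps a pipeline
# parameter to a sampler drawing one value from an rng.

def _lr_space(prefix: str) -> dict[str, Callable]:
    # l1_ratio 1.0 = lasso penalty, 0.0 = ridge (liblinear supports both)
    return {
        f"{prefix}__C": lambda rng: float(10.0 ** rng.uniform(-3, 3)),
        f"{prefix}__l1_ratio": lambda rng: float(rng.choice([1.0, 0.0])),
    }


def _et_space(prefix: str) -> dict[str, Callable]:
    return {
        f"{prefix}__n_estimators": lambda rng: int(rng.integers(100, 501)),
        f"{prefix}__max_depth": lambda rng: (
            None if rng.random() < 0.2 else int(rng.integers(2, 17))
        ),
        f"{prefix}__min_samples_leaf": lambda rng: int(rng.integers(1, 9)),
    }


def _prune_space() -> dict[str, Callable]:
    return {
        "prune__cutoff": lambda rng: float(rng.uniform(0.7, 0.99)),
        "prune__ranking": lambda rng: str(rng.choice(list(RANKINGS))),
    }


def _selector_space() -> dict[str, Callable]:
    return {"select__threshold": lambda rng: float(rng.uniform(0.25, 0.9))}


def search_space(family: str) -> dict[str, Callable]:
    if family in ("M", "MSDSK"):
        return _lr_space("clf")
    if family == "LR-LR":
        return {**_prune_space(), **_selector_space(),
                **_lr_space("select__estimator"), **_lr_space("clf")}
    if family == "ET-ET":
        return {**_prune_space(), **_selector_space(), **_et_space("clf")}
    raise ModelingError(f"unknown model family {family!r}")


def sample_params(
    family: str,
    rng: np.random.Generator,
    param_space: dict[str, Callable] | None = None,
) -> dict:
    space = search_space(family) if param_space is None else param_space
    return {k: sampler(rng) for k, sampler in space.items()}


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

def _lr(seed: int | None = None) -> LogisticRegression:
    # liblinear supports both L1 and L2 and is deterministic on small data
    return LogisticRegression(solver="liblinear", max_iter=2000, random_state=seed)


def build_pipeline(family: str, seed: int = 0) -> Pipeline:
    """Assemble the family's pipeline with default (pre-search) parameters.

    Scaling order is Z-score first, Yeo-Johnson second, for every family.
    """
    scale_steps = [
        ("scale", StandardScaler()),
        ("power", YeoJohnsonTransformer()),
    ]
    if family in ("M", "MSDSK"):
        cols = QCT_M_FEATURES if family == "M" else QCT_MSDSK_FEATURES
        return Pipeline(
            [("preselect", ColumnPreselector(cols))] + scale_steps
            + [("clf", _lr(seed))]
        )
    if family == "LR-LR":
        return Pipeline(
            [("prune", CorrelationPruner())] + scale_steps
            + [
                ("select", EmbeddedSelector(estimator=_lr(seed))),
                ("clf", _lr(seed)),
            ]
        )
    if family == "ET-ET":
        return Pipeline(
            [("prune", CorrelationPruner())] + scale_steps
            + [
                (
                    "select",
                    EmbeddedSelector(
                        estimator=ExtraTreesClassifier(
                            n_estimators=100, random_state=seed
                        )
                    ),
                ),
                ("clf", ExtraTreesClassifier(random_state=seed)),
            ]
        )
    raise ModelingError(f"unknown model family {family!r}")


def pipeline_parameters(pipe: Pipeline) -> dict[str, np.ndarray]:
    """Fitted parameters of every step, for leakage and determinism checks."""
    out: dict[str, np.ndarray] = {}
    for name, step in pipe.named_steps.items():
        for attr in ("mean_", "scale_", "lambdas_", "coef_", "intercept_",
                     "kept_idx_", "importances_", "feature_importances_"):
            if hasattr(step, attr):
                out[f"{name}.{attr}"] = np.asarray(getattr(step, attr))
        if hasattr(step, "columns_"):
            out[f"{name}.columns_"] = np.asarray(step.columns_, dtype=object)
    return out


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

class CVConfig(BaseModel):
    """Nested-CV protocol settings.

    Defaults are the full protocol: a 3x-repeated 10-fold inner loop with
    300 random-search samples and a 2x-repeated 5-fold outer loop. Folds
    are stratified by class — required for the small positive class of the
    staging endpoint.
    """

    model_config = ConfigDict(extra="forbid")

    outer_splits: int = Field(default=5, ge=2)
    outer_repeats: int = Field(default=2, ge=1)
    inner_splits: int = Field(default=10, ge=2)
    inner_repeats: int = Field(default=3, ge=1)
    n_search: int = Field(default=300, ge=1)


@dataclass
class NestedCVResult:
    """Outcome of one family x endpoint x feature-space nested CV."""

    family: str
    endpoint: str
    auc_tuning_mean: float
    auc_tuning_sd: float
    auc_testing_mean: float
    auc_testing_sd: float
    fold_aucs: list[float]
    predictions: pd.DataFrame         # repeat, fold, patient_id, y, score
    best_params: list[dict]
    seed: int

    def summary(self) -> dict:
        return {
            "family": self.family,
            "endpoint": self.endpoint,
            "auc_tuning_mean": self.auc_tuning_mean,
            "auc_tuning_sd": self.auc_tuning_sd,
            "auc_testing_mean": self.auc_testing_mean,
            "auc_testing_sd": self.auc_testing_sd,
            "seed": self.seed,
        }


def _clamped_splits(requested: int, y: np.ndarray) -> int:
    smallest = int(min(np.bincount(y.astype(int), minlength=2)))
    return max(2, min(requested, smallest))


def _inner_scores(
    pipe: Pipeline, params: dict, X: pd.DataFrame, y: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
) -> list[float]:
    scores = []
    for tr, va in splits:
        # degenerate folds (possible on very small cohorts): no AUC defined
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            continue
        p = clone(pipe).set_params(**params)
        p.fit(X.iloc[tr], y[tr])
        s = p.predict_proba(X.iloc[va])[:, 1]
        scores.append(roc_auc_score(y[va], s))
    return scores


def tune_on_training(
    family: str,
    X: pd.DataFrame,
    y: np.ndarray,
    cv: CVConfig,
    seed: int,
    param_space: dict[str, Callable] | None = None,
) -> tuple[dict, list[float], Pipeline]:
    """Random-search tuning confined to a training set.

    Samples ``cv.n_search`` configurations, scores each by mean ROC AUC over
    the repeated stratified inner folds, refits the winner on the full
    training set. Returns (best params, inner scores of the winner, fitted
    pipeline). Nothing outside ``X`` is touched, which is what makes the
    outer-loop estimate unbiased.
    """
    rng = np.random.default_rng(seed)
    inner_splits = _clamped_splits(cv.inner_splits, y)
    inner = RepeatedStratifiedKFold(
        n_splits=inner_splits, n_repeats=cv.inner_repeats,
        random_state=int(rng.integers(2**31)),
    )
    splits = list(inner.split(X, y))
    pipe = build_pipeline(family, seed=int(rng.integers(2**31)))
    best: tuple[float, dict, list[float]] | None = None
    for _ in range(cv.n_search):
        params = sample_params(family, rng, param_space)
        scores = _inner_scores(pipe, params, X, y, splits)
        mean = float(np.mean(scores)) if scores else -np.inf
        if best is None or mean > best[0]:
            best = (mean, params, scores)
    assert best is not None
    _, best_params, best_scores = best
    fitted = clone(pipe).set_params(**best_params)
    fitted.fit(X, y)
    return best_params, best_scores, fitted


def nested_cv(
    family: str,
    table: FeatureTable,
    endpoint: Endpoint,
    seed: int,
    cv: CVConfig | None = None,
    param_space: dict[str, Callable] | None = None,
) -> NestedCVResult:
    """Run the full nested cross-validation for one model family.

    Outer folds estimate generalization; the winning configuration of each
    outer-training set is refit and scored on the held-out outer-test fold.
    ``auc_tuning`` is the winner's inner-CV score (mean +- sd over outer
    folds of the per-fold inner means is reported as mean; sd pools the
    winners' inner-fold scores), ``auc_testing`` the mean +- sd of the outer
    test-fold AUCs. Deterministic given (table, endpoint, seed, cv).
    """
    cv = cv or CVConfig()
    X = table.values.loc[endpoint.patient_ids]
    y = endpoint.y
    rng = np.random.default_rng(seed)
    outer_splits = _clamped_splits(cv.outer_splits, y)
    outer = RepeatedStratifiedKFold(
        n_splits=outer_splits, n_repeats=cv.outer_repeats,
        random_state=int(rng.integers(2**31)),
    )
    fold_seeds = rng.integers(2**31, size=outer_splits * cv.outer_repeats)

    fold_aucs: list[float] = []
    tuning_means: list[float] = []
    tuning_scores: list[float] = []
    best_params: list[dict] = []
    pred_rows: list[pd.DataFrame] = []
    for k, (tr, te) in enumerate(outer.split(X, y)):
        params, inner_scores_, fitted = tune_on_training(
            family, X.iloc[tr], y[tr], cv, int(fold_seeds[k]), param_space
        )
        best_params.append(params)
        tuning_means.append(float(np.mean(inner_scores_)))
        tuning_scores.extend(inner_scores_)
        scores = fitted.predict_proba(X.iloc[te])[:, 1]
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(float(roc_auc_score(y[te], scores)))
        pred_rows.append(
            pd.DataFrame(
                {
                    "repeat": k // outer_splits,
                    "fold": k % outer_splits,
                    "patient_id": X.index[te],
                    "y": y[te],
                    "score": scores,
                }
            )
        )
    predictions = pd.concat(pred_rows, ignore_index=True)
    return NestedCVResult(
        family=family,
        endpoint=endpoint.name,
        auc_tuning_mean=float(np.mean(tuning_means)),
        auc_tuning_sd=float(np.std(tuning_scores)),
        auc_testing_mean=float(np.mean(fold_aucs)),
        auc_testing_sd=float(np.std(fold_aucs)),
        fold_aucs=fold_aucs,
        predictions=predictions,
        best_params=best_params,
        seed=seed,
    )


def run_model_grid(
    tables: dict[str, FeatureTable],
    endpoints: dict[str, Endpoint],
    families: Sequence[str],
    seed: int,
    cv: CVConfig | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], NestedCVResult]]:
    """Nested CV over feature spaces x endpoints x model families.

    Returns the grid report (one row per cell, AUC tuning and testing
    mean +- sd) and the per-cell results keyed by (space, endpoint, family).
    """
    rows: list[dict] = []
    results: dict[tuple[str, str, str], NestedCVResult] = {}
    for space_id in sorted(tables):
        for ep_name in sorted(endpoints):
            for family in families:
                res = nested_cv(
                    family, tables[space_id], endpoints[ep_name], seed=seed, cv=cv
                )
                results[(space_id, ep_name, family)] = res
                rows.append({"space": space_id, **res.summary()})
    return pd.DataFrame(rows), results
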