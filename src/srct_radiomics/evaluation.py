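"""Operating-point evaluation: averaged ROC, Youden cutoff, metric panel, PR.

The outer-loop predictions of the nested CV are turned into:

* a vertically averaged ROC curve (per-fold true-positive rates
  interpolated on a fixed false-positive-rate grid and averaged),
* the operating cutoff at the maximum of Youden's J = sensitivity +
  specificity - 1 on the averaged curve (ties resolved toward the more
  specific threshold),
* a metric panel at that cutoff — accuracy, sensitivity, specificity,
  PPV, NPV and the diagnostic likelihood ratios DLR+ / DLR- — with 95 %
  confidence intervals (Wald or exact Clopper-Pearson for proportions,
  the standard log-transform interval for likelihood ratios),
* precision-recall curves with step-interpolated area, the informative
  companion view under class imbalance.

Panel metrics are computed on pooled out-of-fold predictions, so every
patient contributes once per outer repetition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

Z95 = 1.959963984540054


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Averaged ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    """Vertically averaged ROC over outer folds on a fixed FPR grid."""

    fpr: np.ndarray             # grid, ascending, endpoints 0 and 1
    tpr: np.ndarray             # mean TPR per grid point
    thresholds: np.ndarray      # mean score threshold per grid point
    per_fold_auc: list[float]
    n_folds: int

    def auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def _fold_groups(predictions: pd.DataFrame) -> list[pd.DataFrame]:
    return [g for _, g in predictions.groupby(["repeat", "fold"], sort=True)]


def average_roc(predictions: pd.DataFrame, n_grid: int = 101) -> ROCCurve:
    """Average per-fold ROC curves vertically on a fixed FPR grid.

    ``predictions`` holds pooled outer-fold predictions with columns
    repeat, fold, y, score. Folds containing a single class are excluded
    (with a warning) since their ROC is undefined.
    """
    import warnings

    folds = _fold_groups(predictions)
    if len(folds) < 2:
        raise EvaluationError("need at least two outer folds to average")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs, thrs, aucs = [], [], []
    for g in folds:
        y, s = g["y"].to_numpy(), g["score"].to_numpy()
        if len(np.unique(y)) < 2:
            warnings.warn("excluding a single-class outer fold from ROC averaging")
            continue
        fpr, tpr, thr = roc_curve(y, s)
        thr = thr.astype(float).copy()
        thr[0] = s.max()         # roc_curve's leading sentinel is inf
        tprs.append(np.interp(grid, fpr, tpr))
        thrs.append(np.interp(grid, fpr, thr))
        aucs.append(float(np.trapezoid(tpr, fpr)))
    if not tprs:
        raise EvaluationError("no fold with both classes present")
    return ROCCurve(
        fpr=grid,
        tpr=np.mean(tprs, axis=0),
        thresholds=np.mean(thrs, axis=0),
        per_fold_auc=aucs,
        n_folds=len(tprs),
    )


def youden_cutoff(curve: ROCCurve) -> tuple[float, float, int]:
    """Score threshold at the maximum of Youden's J on the averaged curve.

    Returns (cutoff, J, grid index). Ties at the maximum resolve to the
    smallest FPR, i.e. the more specific operating point.
    """
    j = curve.tpr - curve.fpr
    if np.allclose(j, 0.0) and np.allclose(curve.tpr, curve.fpr):
        # a strictly diagonal curve still has a well-defined (useless) max;
        # only reject when thresholds are degenerate
        if np.allclose(curve.thresholds, curve.thresholds[0]):
            raise EvaluationError("degenerate constant scores: no usable cutoff")
    # first index within tolerance of the maximum = smallest FPR, i.e. the
    # more specific operating point; the tolerance absorbs float noise
    idx = int(np.flatnonzero(j >= j.max() - 1e-9)[0])
    return float(curve.thresholds[idx]), float(j[idx]), idx


# ---------------------------------------------------------------------------
# Metric panel
# ---------------------------------------------------------------------------

@dataclass
class MetricWithCI:
    value: float
    lo: float | None = None
    hi: float | None = None

    def as_tuple(self) -> tuple:
        return (self.value, self.lo, self.hi)


@dataclass
class OperatingPoint:
    """Confusion-matrix metrics at a fixed score cutoff, with 95 % CIs."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict[str, MetricWithCI] = field(default_factory=dict)

    @property
    def youden_j(self) -> float:
        return self.metrics["sensitivity"].value + self.metrics["specificity"].value - 1.0

    def to_record(self) -> dict:
        rec: dict = {"cutoff": self.cutoff, "TP": self.tp, "FP": self.fp,
                     "TN": self.tn, "FN": self.fn, "youden_j": self.youden_j}
        for name, m in self.metrics.items():
            rec[name] = m.value
            rec[f"{name}_ci_low"] = m.lo
            rec[f"{name}_ci_high"] = m.hi
        return rec


def _proportion_ci(k: int, n: int, method: str) -> tuple[float | None, float | None]:
    if n == 0:
        return None, None
    p = k / n
    if method == "wald":
        half = Z95 * math.sqrt(p * (1 - p) / n)
        # continuity guard at the boundary, where the Wald width collapses
        if k == 0 or k == n:
            half = max(half, 0.5 / n)
        return max(0.0, p - half), min(1.0, p + half)
    if method == "exact":  # Clopper-Pearson
        lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
        return lo, hi
    raise EvaluationError(f"unknown CI method {method!r}")


def _dlr_ci(
    dlr: float, sens: float, spec: float, n_pos: int, n_neg: int, positive: bool
) -> tuple[float | None, float | None]:
    """Log-method CI for a diagnostic likelihood ratio."""
    if not np.isfinite(dlr) or dlr <= 0:
        return None, None
    if positive:
        if sens in (0.0,) or spec in (1.0,):
            return None, None
        se = math.sqrt((1 - sens) / (sens * n_pos) + spec / ((1 - spec) * n_neg))
    else:
        if sens in (1.0,) or spec in (0.0,):
            return None, None
        se = math.sqrt(sens / ((1 - sens) * n_pos) + (1 - spec) / (spec * n_neg))
    return dlr * math.exp(-Z95 * se), dlr * math.exp(Z95 * se)


def metric_panel(
    y: np.ndarray,
    scores: np.ndarray,
    cutoff: float,
    ci_method: str = "wald",
) -> OperatingPoint:
    """Full operating-point panel at ``score >= cutoff`` positivity.

    Ratios with an empty denominator are reported as inf/NaN with their CIs
    suppressed rather than raising.
    """
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= cutoff).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n, n_pos, n_neg = len(y), tp + fn, tn + fp

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    sens = ratio(tp, n_pos)
    spec = ratio(tn, n_neg)
    acc = ratio(tp + tn, n)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    dlr_pos = sens / (1 - spec) if spec < 1 else float("inf")
    dlr_neg = (1 - sens) / spec if spec > 0 else float("inf")

    metrics = {
        "accuracy": MetricWithCI(acc, *_proportion_ci(tp + tn, n, ci_method)),
        "sensitivity": MetricWithCI(sens, *_proportion_ci(tp, n_pos, ci_method)),
        "specificity": MetricWithCI(spec, *_proportion_ci(tn, n_neg, ci_method)),
        "ppv": MetricWithCI(ppv, *_proportion_ci(tp, tp + fp, ci_method)),
        "npv": MetricWithCI(npv, *_proportion_ci(tn, tn + fn, ci_method)),
        "dlr_pos": MetricWithCI(
            dlr_pos, *_dlr_ci(dlr_pos, sens, spec, n_pos, n_neg, True)
        ),
        "dlr_neg": MetricWithCI(
            dlr_neg, *_dlr_ci(dlr_neg, sens, spec, n_pos, n_neg, False)
        ),
    }
    return OperatingPoint(cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn, metrics=metrics)


# ---------------------------------------------------------------------------
# Precision-recall
# ---------------------------------------------------------------------------

@dataclass
class PRCurve:
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    auc: float                  # step-interpolated (average precision)
    prevalence: float


def pr_curve(scores: np.ndarray, y: np.ndarray) -> PRCurve:
    """Precision-recall curve with step-interpolated area.

    The area equals average precision; a random scorer's PR AUC approaches
    the positive prevalence, which is the no-skill baseline to plot.
    """
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y.sum() == 0:
        raise EvaluationError("no positive labels: PR curve undefined")
    if y.sum() == len(y):
        raise EvaluationError("no negative labels: PR curve degenerate")
    precision, recall, thr = precision_recall_curve(y, scores)
    auc = float(average_precision_score(y, scores))
    return PRCurve(
        precision=precision, recall=recall, thresholds=thr, auc=auc,
        prevalence=float(y.mean()),
    )


# ---------------------------------------------------------------------------
# End-to-end model evaluation
# ---------------------------------------------------------------------------

def evaluate_predictions(
    predictions: pd.DataFrame, ci_method: str = "wald", n_grid: int = 101
) -> tuple[ROCCurve, OperatingPoint, PRCurve]:
    """Averaged ROC, Youden operating point, and PR curve for one model.

    The cutoff comes from the averaged ROC; the metric panel is computed on
    the pooled out-of-fold scores.
    """
    curve = average_roc(predictions, n_grid=n_grid)
    cutoff, _, _ = youden_cutoff(curve)
    panel = metric_panel(
        predictions["y"].to_numpy(), predictions["score"].to_numpy(),
        cutoff, ci_method=ci_method,
    )
    pr = pr_curve(predictions["score"].to_numpy(), predictions["y"].to_numpy())
    return curve, panel, pr


def plot_roc_pr(curve: ROCCurve, panel: OperatingPoint, pr: PRCurve, path) -> None:
    """ROC with the Youden point marked, and PR with the prevalence baseline."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(curve.fpr, curve.tpr, label=f"averaged ROC (AUC={curve.auc():.2f})")
    ax1.plot([0, 1], [0, 1], "k:", lw=0.8)
    sens = panel.metrics["sensitivity"].value
    spec = panel.metrics["specificity"].value
    ax1.plot([1 - spec], [sens], "ro", label=f"max Youden J={panel.youden_j:.2f}")
    ax1.set_xlabel("1 - specificity")
    ax1.set_ylabel("sensitivity")
    ax1.legend(loc="lower right", fontsize=8)
    ax2.plot(pr.recall, pr.precision, label=f"PR (AUC={pr.auc:.2f})")
    ax2.axhline(pr.prevalence, color="k", ls=":", lw=0.8, label="prevalence")
    ax2.set_xlabel("recall")
    ax2.set_ylabel("precision")
    ax2.set_ylim(0, 1.05)
    ax2.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
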