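"""Feature-table cleaning and univariate AUC screening.

Cleaning drops features with any missing value or fewer than five unique
values. Screening scores every remaining feature by the area under the ROC
curve computed from the Mann-Whitney U statistic, then folds AUCs below 0.5
to 1 - AUC so that predictive strength can be compared independently of the
direction of the effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .radiomic_features import FeatureTable


class ScreeningError(ValueError):
    pass


@dataclass
class ScreeningReport:
    """Folded univariate AUC per feature, plus the removal log."""

    endpoint: str
    condition: str                     # e.g. "2D@0.72"
    auc: pd.Series                     # folded AUC in [0.5, 1], one per kept feature
    raw_auc: pd.Series                 # unfolded AUC in [0, 1]
    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["feature", "reason"])
    )

    def summary(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "condition": self.condition,
            "n_features": int(self.auc.size),
            "median_folded_auc": float(self.auc.median()),
            "max_folded_auc": float(self.auc.max()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.auc.index, "folded_auc": self.auc.values,
             "auc": self.raw_auc.loc[self.auc.index].values}
        )


def clean_features(table: FeatureTable) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop features with missing values or fewer than five unique values.

    No imputation: a single missing entry removes the feature. Uniqueness is
    counted on exact float equality of the extracted values.
    """
    df = table.values
    if df.shape[0] < 1:
        raise ScreeningError("empty feature table")
    removed: list[dict] = []
    keep: list[str] = []
    for col in df.columns:
        vals = df[col]
        if vals.isna().any():
            removed.append({"feature": col, "reason": "missing"})
        elif vals.nunique(dropna=False) < 5:
            removed.append({"feature": col, "reason": "low_cardinality"})
        else:
            keep.append(col)
    if not keep:
        raise ScreeningError("all features removed by cleaning")
    kept = FeatureTable(
        values=df[keep].copy(),
        descriptors=[d for d in table.descriptors if d.name in set(keep)],
        labels=table.labels,
        space=table.space,
        resolution=table.resolution,
    )
    return kept, pd.DataFrame(removed, columns=["feature", "reason"])


def univariate_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC of a single feature from the Mann-Whitney U statistic.

    ``AUC = U1 / (n_pos * n_neg)`` with midrank tie handling, equal to
    P(X_pos > X_neg) + 0.5 P(X_pos = X_neg).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = values[labels], values[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ScreeningError("both classes must be nonempty")
    u1 = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u1) / (pos.size * neg.size)


def fold_auc(auc: float | np.ndarray) -> float | np.ndarray:
    """Fold an AUC about 0.5: ``max(auc, 1 - auc)``.

    Features whose high values indicate the negative class score below 0.5;
    folding makes predictive strength comparable regardless of direction.
    """
    return np.maximum(auc, 1.0 - auc) if np.ndim(auc) else max(auc, 1.0 - auc)


def screen_features(
    table: FeatureTable, y: pd.Series | np.ndarray, endpoint: str,
    condition: str = "",
) -> ScreeningReport:
    """Clean a table and compute folded univariate AUCs for an endpoint."""
    cleaned, removed = clean_features(table)
    yv = np.asarray(y).astype(bool)
    raw = pd.Series(
        {c: univariate_auc(cleaned.values[c].to_numpy(), yv)
         for c in cleaned.values.columns},
        name="auc",
    )
    folded = raw.apply(fold_auc)
    return ScreeningReport(
        endpoint=endpoint, condition=condition or f"{table.space}@{table.resolution:g}",
        auc=folded, raw_auc=raw, removed=removed,
    )


def auc_distributions(reports: list[ScreeningReport]) -> pd.DataFrame:
    """Summaries (median, max, count) of folded-AUC distributions per condition."""
    return pd.DataFrame([r.summary() for r in reports])


def plot_auc_distributions(reports: list[ScreeningReport], path) -> None:
    """Violin plot of folded-AUC distributions, one violin per condition/endpoint."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.6 * max(len(reports), 2) + 2, 4))
    data = [r.auc.values for r in reports]
    names = [f"{r.condition}\n{r.endpoint}" for r in reports]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(reports) + 1), names)
    ax.set_ylabel("folded univariate AUC")
    ax.set_ylim(0.45, 1.0)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
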