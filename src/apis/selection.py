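"""F-score feature ranking and selection.

The F-score of a feature contrasts its class means against its class
spreads.  Two variants are implemented:

* ``ratio`` (default):  F = |mean_hot - mean_non| / (sd_hot + sd_non)
* ``squared``:          F = (mean_hot - mean_non)^2 / (sd_hot^2 + sd_non^2)

Both satisfy the calibration anchor: two equal-SD samples whose mean
separation equals the average of the SDs score exactly 0.5.  Standard
deviations are the sample (n-1) kind by default.  This selection F-score is
unrelated to the F1 evaluation metric.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HOT",
    "NON_HOT",
    "FeatureMatrix",
    "FScoreReport",
    "f_score",
    "f_score_report",
    "select_features",
    "correlation_matrix",
]

HOT = "hot"
NON_HOT = "non_hot"


@dataclasses.dataclass
class FeatureMatrix:
    """Residue-by-feature matrix with a binary hot/non-hot label per row.

    ``X`` holds one named column per feature (NaN = missing value); ``y`` is
    aligned on the same index with values ``"hot"`` / ``"non_hot"``.
    """

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        self.y = self.y.reindex(self.X.index)
        bad = set(self.y.dropna().unique()) - {HOT, NON_HOT}
        if bad:
            raise ValueError(f"labels must be hot/non_hot, got {sorted(bad)}")
        all_missing = [c for c in self.X.columns if self.X[c].isna().all()]
        if all_missing:
            raise ValueError(f"all-missing feature columns: {all_missing}")

    @property
    def features(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n(self) -> int:
        return len(self.X)

    def to_tsv(self, path: str | Path) -> None:
        out = self.X.copy()
        out["label"] = self.y
        out.to_csv(path, sep="\t", index=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "label" not in df.columns:
            raise ValueError(f"{path}: no 'label' column")
        y = df.pop("label")
        return cls(X=df, y=y)

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, feature_columns: Sequence[str], label_column: str = "label"
    ) -> "FeatureMatrix":
        return cls(X=table[list(feature_columns)].copy(), y=table[label_column])


@dataclasses.dataclass
class FScoreReport:
    """Per-feature class statistics and the descending F-score ranking."""

    stats: pd.DataFrame  # columns: mean_hot, mean_non, sd_hot, sd_non, fscore

    @property
    def ranking(self) -> list[str]:
        # descending F-score, deterministic alphabetical tie-break
        order = self.stats.sort_values(
            by=["fscore", "feature"], ascending=[False, True], key=None
        )
        return list(order["feature"])

    def fscore(self, feature: str) -> float:
        row = self.stats.loc[self.stats["feature"] == feature, "fscore"]
        return float(row.iloc[0])


def _class_stats(values: np.ndarray, labels: np.ndarray, ddof: int):
    hot = values[labels == HOT]
    non = values[labels == NON_HOT]
    if len(hot) < 2 or len(non) < 2:
        raise ValueError("need >= 2 non-missing values per class")
    return (
        float(hot.mean()),
        float(non.mean()),
        float(hot.std(ddof=ddof)),
        float(non.std(ddof=ddof)),
    )


def f_score(
    values: Sequence[float] | np.ndarray | pd.Series,
    labels: Sequence[str] | np.ndarray | pd.Series,
    variant: Literal["ratio", "squared"] = "ratio",
    ddof: int = 1,
) -> float:
    """F-score of one feature against binary hot/non-hot labels.

    Missing values are dropped pairwise.  A zero-spread feature with unequal
    class means returns ``inf``; equal means return 0.  ``ddof=1`` gives
    sample SDs (default), ``ddof=0`` population SDs.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    present = set(labels)
    if present != {HOT, NON_HOT}:
        raise ValueError(f"need both classes present, got {sorted(present)}")
    mean_h, mean_n, sd_h, sd_n = _class_stats(values, labels, ddof)
    gap = abs(mean_h - mean_n)
    if variant == "ratio":
        denom = sd_h + sd_n
        if denom == 0:
            return math.inf if gap > 0 else 0.0
        return gap / denom
    if variant == "squared":
        denom = sd_h**2 + sd_n**2
        if denom == 0:
            return math.inf if gap > 0 else 0.0
        return gap**2 / denom
    raise ValueError(f"unknown F-score variant {variant!r}")


def f_score_report(
    matrix: FeatureMatrix,
    variant: Literal["ratio", "squared"] = "ratio",
    ddof: int = 1,
) -> FScoreReport:
    """F-score every feature column of a labeled matrix."""
    labels = matrix.y.to_numpy(dtype=object)
    rows = []
    for feature in matrix.features:
        values = matrix.X[feature].to_numpy(dtype=float)
        keep = np.isfinite(values)
        mean_h, mean_n, sd_h, sd_n = _class_stats(values[keep], labels[keep], ddof)
        rows.append(
            {
                "feature": feature,
                "mean_hot": mean_h,
                "mean_non": mean_n,
                "sd_hot": sd_h,
                "sd_non": sd_n,
                "fscore": f_score(values, labels, variant=variant, ddof=ddof),
            }
        )
    return FScoreReport(stats=pd.DataFrame(rows))


def select_features(
    report: FScoreReport, threshold: float = 0.60, k: int | None = None
) -> list[str]:
    """Features with F-score strictly above ``threshold``, best first.

    Ties break alphabetically; ``k`` truncates the list.  May be empty.
    """
    chosen = [f for f in report.ranking if report.fscore(f) > threshold]
    if k is not None:
        chosen = chosen[:k]
    return chosen


def correlation_matrix(
    matrix: FeatureMatrix, features: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations between features (NaN-aware).

    A zero-variance feature yields NaN entries (flagged undefined) rather
    than raising.
    """
    features = list(features) if features is not None else matrix.features
    sub = matrix.X[features]
    complete = sub.dropna()
    for pair_a in features:
        for pair_b in features:
            n_complete = sub[[pair_a, pair_b]].dropna().shape[0]
            if n_complete < 3:
                raise ValueError(
                    f"need >= 3 complete rows for pair ({pair_a}, {pair_b})"
                )
    corr = sub.corr(method="pearson", min_periods=3)
    # pandas leaves the diagonal at 1 even for constants; force NaN there
    for f in features:
        col = complete[f] if len(complete) else sub[f].dropna()
        if float(np.nanstd(sub[f].to_numpy(dtype=float))) == 0.0:
            corr.loc[f, :] = np.nan
            corr.loc[:, f] = np.nan
    return corr
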