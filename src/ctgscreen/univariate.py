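"""Single-feature screening benchmarks: ROC, Youden-optimal cut-offs.

Each feature is scored alone by a logistic model; since the fitted
probability is monotone in the feature, the ROC (and hence the AUC)
equals that of the raw feature.  The operating point is the cut-off
maximizing Youden's index J = SE + SP - 1, with ties broken toward
higher sensitivity (the screening orientation: IUGR is the positive
class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .features import FeatureTable


@dataclass
class UnivariateResult:
    feature: str
    auc: float
    cutoff: float
    se: float
    sp: float

    @property
    def youden_j(self) -> float:
        return self.se + self.sp - 1.0


def youden_index(se: float, sp: float) -> float:
    """Youden's J statistic for one operating point."""
    return se + sp - 1.0


def youden_optimal(scores: np.ndarray, labels: np.ndarray, feature: str = "") -> UnivariateResult:
    """ROC over all observed thresholds with the Youden-optimal cut-off.

    The score orientation is auto-chosen so AUC >= 0.5.  SE is the true
    positive (IUGR, +1) rate and SP the true negative (healthy, -1) rate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    if auc < 0.5:
        fpr, tpr, thr = roc_curve(labels, -scores, pos_label=1)
        auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    # argmax J, ties broken toward higher SE
    best = np.lexsort((tpr, j))[-1]
    return UnivariateResult(
        feature=feature,
        auc=auc,
        cutoff=float(thr[best]),
        se=float(tpr[best]),
        sp=float(1.0 - fpr[best]),
    )


def _logistic_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fitted class-1 probability of a single-feature logistic model.

    Falls back to the raw feature on non-convergence (e.g. perfect
    separation); either way the score is monotone in the feature.
    """
    try:
        model = LogisticRegression(C=np.inf, max_iter=1000)
        model.fit(x.reshape(-1, 1), y)
        return model.predict_proba(x.reshape(-1, 1))[:, 1]
    except Exception:
        return x.astype(float)


def univariate_table(table: FeatureTable) -> pd.DataFrame:
    """Per-feature AUC / SE / SP ranked by AUC (descending)."""
    rows = []
    y = table.y.to_numpy()
    for name in table.feature_names:
        scores = _logistic_scores(table.X[name].to_numpy(), y)
        res = youden_optimal(scores, y, feature=name)
        rows.append(
            {"feature": name, "AUC": res.auc, "SE": res.se, "SP": res.sp,
             "J": res.youden_j, "cutoff": res.cutoff}
        )
    return (
        pd.DataFrame(rows)
        .sort_values("AUC", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def correlation_screen(table: FeatureTable, threshold: float = 0.7):
    """Pearson correlation matrix plus pairs with |rho| >= threshold."""
    corr = table.X.corr()
    flagged = []
    names = list(corr.columns)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rho = corr.loc[a, b]
            if np.isfinite(rho) and abs(rho) >= threshold:
                flagged.append((a, b, float(rho)))
    return corr, flagged
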