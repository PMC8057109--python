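"""RBF-SVM classification with Maclaurin-expansion recursive feature
elimination, Youden-maximizing grid search and held-out evaluation.

The classifier is a soft-margin support vector machine with Gaussian
kernel K(x, z) = exp(-gamma ||x - z||^2).  Feature selection uses the
nonlinear extension of SVM-RFE: the RBF kernel is expanded in its
Maclaurin series and the first-order contribution of each feature to the
squared margin gives the elimination score

    score(j) = | gamma * sum_{i,k} a_i a_k (x_ij - x_kj)^2 |,
    a_i = alpha_i y_i,

so the feature with the smallest score is dropped, the model refitted,
and the path scanned for the cross-validated-J-optimal subset.
Hyperparameters (C, gamma) come from an exhaustive grid over
exponentially growing sequences 2^-15 ... 2^15, scored by stratified
10-fold cross-validated Youden's J (ties broken by higher sensitivity,
then smaller C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureTable

#: full grid exponents (31 values -> 961 cells) and the scaled-down grid
GRID_EXPONENTS = list(range(-15, 16))
COARSE_EXPONENTS = list(range(-15, 16, 3))
#: cross-validation: 10-fold, repeated 5x during search, 10x for the final model
CV_FOLDS = 10
CV_REPEATS_SEARCH = 5
CV_REPEATS_FINAL = 10
TRAIN_FRACTION = 0.6


def rbf_kernel(x: np.ndarray, z: np.ndarray, gamma: float) -> float | np.ndarray:
    """Gaussian kernel exp(-gamma ||x - z||^2)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x, z = np.asarray(x, float), np.asarray(z, float)
    return np.exp(-gamma * np.sum((x - z) ** 2, axis=-1))


@dataclass
class SVMModel:
    """Fitted RBF-SVM with its dual solution."""

    C: float
    gamma: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray  # alpha_i * y_i over support vectors
    bias: float
    svc: SVC

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(X)


def train_svm(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
              tol: float = 1e-3) -> SVMModel:
    """Solve the soft-margin dual for an RBF-SVM (deterministic)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to train")
    svc = SVC(C=C, gamma=gamma, kernel="rbf", tol=tol, cache_size=100)
    svc.fit(np.asarray(X, float), y)
    return SVMModel(
        C=C, gamma=gamma,
        support_vectors=svc.support_vectors_,
        dual_coef=svc.dual_coef_.ravel(),
        bias=float(svc.intercept_[0]),
        svc=svc,
    )


# ---------------------------------------------------------------------------
# RFE
# ---------------------------------------------------------------------------


def rfe_scores(model: SVMModel) -> np.ndarray:
    """First-order Maclaurin feature scores of a fitted model.

    For each feature j:  | gamma * sum_{i,k} a_i a_k (x_ij - x_kj)^2 |
    over support vectors, expanded as
    2 [ (sum a) (sum a x^2) - (sum a x)^2 ].
    """
    a = model.dual_coef
    sv = model.support_vectors
    s0 = a.sum()
    s1 = a @ sv
    s2 = a @ sv**2
    return np.abs(model.gamma * 2.0 * (s0 * s2 - s1**2))


@dataclass
class RFERankingResult:
    """Worst-first elimination order with the CV-J-optimal subset."""

    elimination_order: list[str]
    step_scores: list[dict[str, float]]
    path_j: dict[int, float]  # subset size -> mean CV J
    selected: list[str]


def _cv_j(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
          folds: int, repeats: int, seed: int) -> tuple[float, float, float]:
    """Mean Youden J, SE, SP over repeated stratified k-fold CV."""
    js, ses, sps = [], [], []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for tr, te in skf.split(X, y):
            if len(np.unique(y[tr])) < 2:
                continue
            model = train_svm(X[tr], y[tr], C, gamma)
            pred = model.predict(X[te])
            pos, neg = y[te] == 1, y[te] == -1
            if not pos.any() or not neg.any():
                continue
            se = np.mean(pred[pos] == 1)
            sp = np.mean(pred[neg] == -1)
            js.append(se + sp - 1.0)
            ses.append(se)
            sps.append(sp)
    if not js:
        return float("nan"), float("nan"), float("nan")
    return float(np.mean(js)), float(np.mean(ses)), float(np.mean(sps))


def rfe_rank(
    table: FeatureTable,
    C: float | None = None,
    gamma: float | None = None,
    folds: int = CV_FOLDS,
    repeats: int = 1,
    seed: int = 0,
    min_features: int = 1,
) -> RFERankingResult:
    """Rank all features by recursive elimination and pick the best subset.

    The SVM is refitted after each elimination at a fixed provisional
    (C, gamma), defaulting to C = 1 and gamma = 1 / n_features.  At every
    step the cross-validated J of the current subset is recorded; the
    selected subset is the smallest one attaining the maximal mean CV J
    along the path.  Score ties are broken by registry order.
    """
    names = list(table.feature_names)
    X_full = table.X.to_numpy(float)
    y = table.y.to_numpy()
    C = 1.0 if C is None else C
    gamma = 1.0 / len(names) if gamma is None else gamma

    remaining = list(range(len(names)))
    elimination: list[str] = []
    step_scores: list[dict[str, float]] = []
    path_j: dict[int, float] = {}
    subsets: dict[int, list[str]] = {}

    while len(remaining) >= max(min_features, 1):
        X = X_full[:, remaining]
        j, _, _ = _cv_j(X, y, C, gamma, folds, repeats, seed)
        path_j[len(remaining)] = j
        subsets[len(remaining)] = [names[i] for i in remaining]
        if len(remaining) == min_features:
            break
        model = train_svm(X, y, C, gamma)
        scores = rfe_scores(model)
        step_scores.append({names[i]: float(s) for i, s in zip(remaining, scores)})
        worst = int(np.argmin(scores))  # argmin keeps first (registry order) on ties
        elimination.append(names[remaining[worst]])
        remaining.pop(worst)

    best_j = max(v for v in path_j.values() if np.isfinite(v))
    best_size = min(k for k, v in path_j.items() if np.isfinite(v) and v >= best_j - 1e-12)
    # features never eliminated come last (most important)
    order = elimination + [n for n in names if n not in elimination]
    return RFERankingResult(order, step_scores, path_j, subsets[best_size])


def delta_j_scores(model: SVMModel, X: np.ndarray, y_sv: np.ndarray | None = None) -> np.ndarray:
    """Kernel-perturbation importance oracle (cross-check, not the ranking).

    For each feature j, 0.5 |a' H a - a' H^(-j) a| with H_ik =
    y_i y_k K(x_i, x_k) and alpha frozen from the current fit.
    """
    a = model.dual_coef  # alpha_i y_i  -> a' K a == (alpha y)' K (alpha y)
    sv = model.support_vectors
    d2 = ((sv[:, None, :] - sv[None, :, :]) ** 2)
    full = np.exp(-model.gamma * d2.sum(axis=2))
    ref = a @ full @ a
    out = np.empty(sv.shape[1])
    total = d2.sum(axis=2)
    for j in range(sv.shape[1]):
        K = np.exp(-model.gamma * (total - d2[:, :, j]))
        out[j] = 0.5 * abs(ref - a @ K @ a)
    return out


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


@dataclass
class GridSearchResult:
    grid: pd.DataFrame  # columns C, gamma, J, SE, SP
    C_opt: float
    gamma_opt: float
    J_opt: float


def grid_search(
    table: FeatureTable,
    exponents: list[int] | None = None,
    folds: int = CV_FOLDS,
    repeats: int = CV_REPEATS_SEARCH,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive (C, gamma) grid scored by repeated stratified CV.

    Cells are C = 2^i, gamma = 2^j over the exponent list (the full
    31-value sequence gives 961 cells).  The optimum maximizes mean J;
    ties prefer higher SE, then smaller C.
    """
    exponents = GRID_EXPONENTS if exponents is None else exponents
    X = table.X.to_numpy(float)
    y = table.y.to_numpy()
    rows = []
    for ic in exponents:
        for ig in exponents:
            C, gamma = 2.0**ic, 2.0**ig
            j, se, sp = _cv_j(X, y, C, gamma, folds, repeats, seed)
            rows.append({"C": C, "gamma": gamma, "log2_C": ic, "log2_gamma": ig,
                         "J": j, "SE": se, "SP": sp})
    grid = pd.DataFrame(rows)
    valid = grid.dropna(subset=["J"])
    best = valid.sort_values(
        ["J", "SE", "C"], ascending=[False, False, True], kind="stable"
    ).iloc[0]
    return GridSearchResult(grid, float(best["C"]), float(best["gamma"]), float(best["J"]))


# ---------------------------------------------------------------------------
# Split / evaluation
# ---------------------------------------------------------------------------


def split_train_test(
    table: FeatureTable, seed: int, train_fraction: float = TRAIN_FRACTION
) -> tuple[pd.Index, pd.Index]:
    """Stratified, seeded train/test split preserving the class ratio."""
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for label in (-1, 1):
        ids = table.y.index[table.y == label].to_numpy()
        perm = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    return pd.Index(train_ids), pd.Index(test_ids)


def _normal_ci(values: np.ndarray) -> tuple[float, float, float]:
    values = np.asarray(values, float)
    mean = values.mean()
    half = 1.96 * values.std(ddof=1) / np.sqrt(len(values))
    return float(mean), float(mean - half), float(mean + half)


@dataclass
class EvalReport:
    """Training-CV and held-out test metrics of the final model."""

    train_metrics: dict[str, tuple[float, float, float]]  # mean, lo, hi
    test_metrics: dict[str, float]
    confusion: dict[str, int]
    features: list[str]
    C: float
    gamma: float

    def to_dict(self) -> dict:
        return {
            "C": self.C, "gamma": self.gamma, "features": self.features,
            "train": {k: list(v) for k, v in self.train_metrics.items()},
            "test": self.test_metrics, "confusion": self.confusion,
        }


def evaluate(
    table: FeatureTable,
    train_ids: pd.Index,
    test_ids: pd.Index,
    C: float,
    gamma: float,
    folds: int = CV_FOLDS,
    repeats: int = CV_REPEATS_FINAL,
    seed: int = 0,
) -> EvalReport:
    """Final-model assessment: repeated-CV training metrics + held-out test.

    Training AUC/SE/SP are means with normal-approximation 95% CIs over
    the fold-level values of a ``folds x repeats`` stratified CV on the
    training set; the test metrics come from a single fit on the full
    training set applied to the untouched test subjects.
    """
    Xtr = table.X.loc[train_ids].to_numpy(float)
    ytr = table.y.loc[train_ids].to_numpy()
    Xte = table.X.loc[test_ids].to_numpy(float)
    yte = table.y.loc[test_ids].to_numpy()

    aucs, ses, sps, accs = [], [], [], []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for tr, te in skf.split(Xtr, ytr):
            model = train_svm(Xtr[tr], ytr[tr], C, gamma)
            pred = model.predict(Xtr[te])
            score = model.decision_function(Xtr[te])
            pos, neg = ytr[te] == 1, ytr[te] == -1
            if not pos.any() or not neg.any():
                continue
            ses.append(np.mean(pred[pos] == 1))
            sps.append(np.mean(pred[neg] == -1))
            accs.append(np.mean(pred == ytr[te]))
            aucs.append(roc_auc_score(ytr[te], score))
    train_metrics = {
        "AUC": _normal_ci(aucs), "SE": _normal_ci(ses), "SP": _normal_ci(sps),
        "accuracy": _normal_ci(accs),
    }

    final = train_svm(Xtr, ytr, C, gamma)
    pred = final.predict(Xte)
    tp = int(np.sum((pred == 1) & (yte == 1)))
    fn = int(np.sum((pred == -1) & (yte == 1)))
    tn = int(np.sum((pred == -1) & (yte == -1)))
    fp = int(np.sum((pred == 1) & (yte == -1)))
    n = len(yte)
    acc = (tp + tn) / n
    half = float(1.96 * np.sqrt(acc * (1 - acc) / n))
    test_metrics = {
        "accuracy": acc, "accuracy_ci_low": acc - half, "accuracy_ci_high": acc + half,
        "SE": tp / (tp + fn) if tp + fn else float("nan"),
        "SP": tn / (tn + fp) if tn + fp else float("nan"),
        "PPV": tp / (tp + fp) if tp + fp else float("nan"),
        "NPV": tn / (tn + fn) if tn + fn else float("nan"),
        "AUC": float(roc_auc_score(yte, final.decision_function(Xte))),
    }
    return EvalReport(
        train_metrics, test_metrics,
        {"TP": tp, "FN": fn, "TN": tn, "FP": fp},
        list(table.feature_names), C, gamma,
    )


def feature_importance(
    table: FeatureTable,
    train_ids: pd.Index,
    C: float,
    gamma: float,
    folds: int = CV_FOLDS,
    repeats: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-feature-out mean decrease in accuracy / SE / SP.

    For each feature the repeated-CV metrics are recomputed with that
    feature excluded; the decrease is reference minus reduced, with a
    normal-approximation 95% CI over fold-level differences.
    """
    sub = FeatureTable(table.X.loc[train_ids], table.y.loc[train_ids],
                       table.provenance)
    X = sub.X.to_numpy(float)
    y = sub.y.to_numpy()

    def fold_metrics(cols: np.ndarray) -> np.ndarray:
        out = []
        for r in range(repeats):
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
            for tr, te in skf.split(X, y):
                model = train_svm(X[tr][:, cols], y[tr], C, gamma)
                pred = model.predict(X[te][:, cols])
                pos, neg = y[te] == 1, y[te] == -1
                out.append([
                    np.mean(pred == y[te]),
                    np.mean(pred[pos] == 1) if pos.any() else np.nan,
                    np.mean(pred[neg] == -1) if neg.any() else np.nan,
                ])
        return np.asarray(out)

    all_cols = np.arange(X.shape[1])
    ref = fold_metrics(all_cols)
    rows = []
    for j, name in enumerate(sub.feature_names):
        red = fold_metrics(np.delete(all_cols, j))
        diff = ref - red  # paired by fold (same seeds -> same splits)
        row = {"feature": name}
        for k, metric in enumerate(("accuracy", "SE", "SP")):
            d = diff[:, k][np.isfinite(diff[:, k])]
            mean, lo, hi = _normal_ci(d)
            row[f"decrease_{metric}"] = mean
            row[f"decrease_{metric}_lo"] = lo
            row[f"decrease_{metric}_hi"] = hi
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values("decrease_accuracy", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def sex_excluded_variant(table: FeatureTable) -> FeatureTable:
    """The same pipeline inputs with fetal sex removed (31 features)."""
    return table.drop_features(["fetal_sex"])
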