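"""The 32-feature registry, per-subject table assembly and preprocessing.

Per-epoch features are averaged over each recording to give one vector
per subject; the cohort table is then Winsorized per feature in the
interval (Q1 - 3 IQR, Q3 + 3 IQR) and standardized to zero mean / unit
variance across the whole population (the leakage-free alternative of
fitting the scaler on the training split only is available via
``fit_on``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: domain tags: morphological/time, frequency, complexity, fetal-maternal
DOMAINS = ("MTd", "Fd", "Cd", "FMd")

#: ordered registry: feature name -> (domain, units)
REGISTRY: dict[str, tuple[str, str]] = {
    "FHR_mean": ("MTd", "bpm"),
    "FHR_std": ("MTd", "bpm"),
    "STV": ("MTd", "ms"),
    "II": ("MTd", ""),
    "Delta": ("MTd", "ms"),
    "LTI": ("MTd", "ms"),
    "#acc_large": ("MTd", "count"),
    "#acc_small": ("MTd", "count"),
    "#dec": ("MTd", "count"),
    "#contr": ("MTd", "count"),
    "LF_pow": ("Fd", "ms^2"),
    "MF_pow": ("Fd", "ms^2"),
    "HF_pow": ("Fd", "ms^2"),
    "ApEn": ("Cd", ""),
    "SampEn": ("Cd", ""),
    "LZC_bin": ("Cd", "bits"),
    "LZC_ter": ("Cd", "bits"),
    "AC_T1_s2": ("Cd", "bpm"),
    "DC_T1_s2": ("Cd", "bpm"),
    "DR_T1_s2": ("Cd", "bpm"),
    "AC_T5_s5": ("Cd", "bpm"),
    "DC_T5_s5": ("Cd", "bpm"),
    "DR_T5_s5": ("Cd", "bpm"),
    "AC_T9_s9": ("Cd", "bpm"),
    "DC_T9_s9": ("Cd", "bpm"),
    "DR_T9_s9": ("Cd", "bpm"),
    "AC_T40_s1": ("Cd", "bpm"),
    "DC_T40_s1": ("Cd", "bpm"),
    "DR_T40_s1": ("Cd", "bpm"),
    "GA_CTG": ("FMd", "weeks"),
    "fetal_sex": ("FMd", ""),
    "mat_age": ("FMd", "years"),
}

FEATURE_NAMES = list(REGISTRY)


def domain_counts() -> dict[str, int]:
    counts = {d: 0 for d in DOMAINS}
    for domain, _ in REGISTRY.values():
        counts[domain] += 1
    return counts


LABEL_CODES = {"healthy": -1, "iugr": 1}
SEX_CODES = {"male": 1, "female": 0}


@dataclass
class FeatureTable:
    """Cohort feature matrix with labels and preprocessing provenance."""

    X: pd.DataFrame  # subjects x features
    y: pd.Series  # -1 healthy / +1 IUGR, same index
    provenance: str = "raw"  # raw | winsorized | standardized
    winsor_bounds: pd.DataFrame | None = None
    scaler_mean: pd.Series | None = None
    scaler_std: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must share the subject index")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def drop_features(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(
            self.X.drop(columns=names), self.y, self.provenance,
            self.winsor_bounds, self.scaler_mean, self.scaler_std,
        )

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out["label"] = self.y.map({-1: "healthy", 1: "iugr"})
        out.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject_id")
        y = df.pop("label").map(LABEL_CODES)
        return cls(df, y)


def aggregate(
    epoch_features: dict[str, list[float]],
    recording_features: dict[str, float],
    metadata: dict,
) -> dict[str, float]:
    """Average per-epoch features and merge per-recording ones and metadata.

    ``epoch_features`` maps feature name -> per-epoch (or per-minute)
    values; NaN entries (unusable windows) are dropped before averaging.
    A feature with no finite value at all stays NaN, which later drops
    the subject from the table.
    """
    vec: dict[str, float] = {}
    for name, values in epoch_features.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        vec[name] = float(arr.mean()) if len(arr) else float("nan")
    vec.update(recording_features)
    vec["GA_CTG"] = float(metadata["ga_weeks"])
    vec["fetal_sex"] = float(SEX_CODES[metadata["fetal_sex"]])
    vec["mat_age"] = float(metadata["maternal_age"])
    return vec


def build_table(rows: dict[str, dict[str, float]], labels: dict[str, str]) -> FeatureTable:
    """Assemble the cohort table, dropping subjects with missing features."""
    X = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=FEATURE_NAMES)
    complete = X.notna().all(axis=1)
    X = X[complete]
    y = pd.Series({s: LABEL_CODES[labels[s]] for s in X.index}, name="label")
    return FeatureTable(X, y.loc[X.index])


def winsor_bounds(col: np.ndarray, k: float = 3.0) -> tuple[float, float]:
    """(Q1 - k IQR, Q3 + k IQR) with linearly interpolated quartiles."""
    q1, q3 = np.percentile(col, [25, 75])
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def winsorize(table: FeatureTable, k: float = 3.0) -> FeatureTable:
    """Clamp each feature to (Q1 - 3 IQR, Q3 + 3 IQR) over the cohort."""
    X = table.X.copy()
    bounds = {}
    for name in X.columns:
        lo, hi = winsor_bounds(X[name].to_numpy(), k)
        bounds[name] = (lo, hi)
        X[name] = X[name].clip(lo, hi)
    bdf = pd.DataFrame(bounds, index=["lower", "upper"]).T
    return FeatureTable(X, table.y, "winsorized", winsor_bounds=bdf)


def standardize(table: FeatureTable, fit_on: pd.Index | None = None) -> FeatureTable:
    """Per-feature z-scoring (ddof = 1).

    By default the scaler is fitted on the whole population; pass
    ``fit_on`` (e.g. the training index) for the leakage-free variant.
    Zero-variance features are set to 0.
    """
    fit_X = table.X.loc[fit_on] if fit_on is not None else table.X
    mean = fit_X.mean()
    std = fit_X.std(ddof=1)
    Z = table.X.sub(mean, axis=1)
    safe = std.where(std > 1e-12, 1.0)
    Z = Z.div(safe, axis=1)
    Z.loc[:, std <= 1e-12] = 0.0
    return FeatureTable(
        Z, table.y, "standardized",
        winsor_bounds=table.winsor_bounds, scaler_mean=mean, scaler_std=std,
    )


def preprocess(table: FeatureTable) -> FeatureTable:
    """Winsorize then standardize (the default cohort-level pipeline)."""
    return standardize(winsorize(table))


def import_datapor_csv(path, column_map: dict[str, str] | None = None) -> FeatureTable:
    """Import an externally deposited per-subject feature CSV.

    Columns are mapped onto the registry names via ``column_map`` (keys:
    CSV column names, values: registry names); a ``label`` or ``group``
    column supplies the class.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    label_col = "label" if "label" in df.columns else "group"
    y = df.pop(label_col).astype(str).str.lower().map(LABEL_CODES)
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    present = [c for c in FEATURE_NAMES if c in df.columns]
    X = df[present]
    y.index = X.index
    return FeatureTable(X, y)
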