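"""Cardiotocographic record containers, I/O, epoching and signal-quality rules.

A CTG monitor emits fetal heart rate (FHR) samples at 2 Hz in beats per
minute, each tagged with a tri-level signal-quality flag (optimal /
acceptable / insufficient, the monitor's green / yellow / red), optionally
alongside a uterine-activity channel.  Analysis proceeds on non-overlapping
1-min (120-sample) and 3-min (360-sample) epochs; epochs dominated by
insufficient-quality samples are discarded, isolated insufficient samples
are repaired by local averaging, and subjects without enough usable epochs
are excluded.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

FS_HZ = 2.0
#: epoch lengths in samples at 2 Hz: 1 min and 3 min
EPOCH_1MIN = 120
EPOCH_3MIN = 360
#: reject an epoch when red samples reach 5% of its length (6/120, 18/360)
RED_FRACTION = 0.05
#: reject an epoch containing a run of more than this many consecutive reds
MAX_RED_RUN = 5
#: subject inclusion: minimum usable epoch counts
MIN_USABLE_1MIN = 30
MIN_USABLE_3MIN = 10


class QualityFlag(enum.IntEnum):
    """Tri-level per-sample signal quality; higher is better."""

    INSUFFICIENT = 0
    ACCEPTABLE = 1
    OPTIMAL = 2

    @classmethod
    def from_token(cls, token: str) -> "QualityFlag":
        try:
            return _QUALITY_TOKENS[token.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown quality token {token!r}") from None

    @property
    def token(self) -> str:
        return self.name.lower()


_QUALITY_TOKENS = {
    "optimal": QualityFlag.OPTIMAL,
    "acceptable": QualityFlag.ACCEPTABLE,
    "insufficient": QualityFlag.INSUFFICIENT,
    "green": QualityFlag.OPTIMAL,
    "yellow": QualityFlag.ACCEPTABLE,
    "red": QualityFlag.INSUFFICIENT,
}

GROUPS = ("healthy", "iugr", "unknown")


@dataclass
class FHRRecord:
    """One subject's 2-Hz FHR trace with quality flags and metadata."""

    subject_id: str
    fhr: np.ndarray
    quality: np.ndarray
    uterine: np.ndarray | None = None
    group: str = "unknown"
    ga_weeks: float = float("nan")
    fetal_sex: str = "unknown"
    maternal_age: float = float("nan")

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.quality = np.asarray(self.quality, dtype=np.int8)
        if self.uterine is not None:
            self.uterine = np.asarray(self.uterine, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.fhr.ndim != 1:
            raise ValueError("fhr must be one-dimensional")
        if len(self.fhr) != len(self.quality):
            raise ValueError(
                f"channel length mismatch: {len(self.fhr)} fhr vs "
                f"{len(self.quality)} quality samples"
            )
        if self.uterine is not None and len(self.uterine) != len(self.fhr):
            raise ValueError("uterine channel length mismatch")
        if not np.all(np.isin(self.quality, (0, 1, 2))):
            raise ValueError("quality flags must be in {0, 1, 2}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")

    @property
    def n_samples(self) -> int:
        return len(self.fhr)

    @property
    def duration_min(self) -> float:
        return self.n_samples / FS_HZ / 60.0

    def red_mask(self) -> np.ndarray:
        return self.quality == QualityFlag.INSUFFICIENT


@dataclass(frozen=True)
class Epoch:
    """A 120- or 360-sample window with its quality verdict."""

    start_index: int
    length: int
    red_count: int
    max_red_run: int
    usable: bool

    @property
    def stop_index(self) -> int:
        return self.start_index + self.length


def max_run_length(mask: np.ndarray) -> int:
    """Longest run of consecutive True values."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return int((stops - starts).max())


def red_count_limit(length: int) -> int:
    """Red-sample count at which an epoch is rejected (5% of its length)."""
    return int(np.ceil(RED_FRACTION * length))


def reject_epoch(red_count: int, max_red_run: int, length: int) -> bool:
    """True when the epoch must be discarded.

    An epoch is unusable when it contains more than ``MAX_RED_RUN``
    consecutive insufficient-quality samples, or when its insufficient
    count reaches 5% of the window (6 of 120, 18 of 360).
    """
    return max_red_run > MAX_RED_RUN or red_count >= red_count_limit(length)


def segment(record: FHRRecord, length: int) -> list[Epoch]:
    """Partition a record into consecutive non-overlapping epochs.

    Windows start at sample 0; a trailing remainder shorter than ``length``
    is dropped.  Each epoch carries its red-sample statistics and the
    usability verdict.
    """
    if length not in (EPOCH_1MIN, EPOCH_3MIN):
        raise ValueError(f"epoch length must be {EPOCH_1MIN} or {EPOCH_3MIN}")
    red = record.red_mask()
    n_epochs = record.n_samples // length
    epochs = []
    for k in range(n_epochs):
        window = red[k * length : (k + 1) * length]
        red_count = int(window.sum())
        run = max_run_length(window)
        epochs.append(
            Epoch(
                start_index=k * length,
                length=length,
                red_count=red_count,
                max_red_run=run,
                usable=not reject_epoch(red_count, run, length),
            )
        )
    return epochs


def repair_isolated(record: FHRRecord) -> FHRRecord:
    """Replace isolated insufficient samples by a local moving average.

    An insufficient sample is *isolated* when both neighbours are
    non-insufficient (a red run of length 1).  It is replaced by the mean
    of the five nearest non-insufficient samples by index distance (ties
    broken toward earlier samples) and its flag upgraded to acceptable.
    Longer red runs are left for epoch rejection to handle.
    """
    red = record.red_mask()
    good_idx = np.flatnonzero(~red)
    if len(good_idx) < 5:
        raise ValueError("fewer than 5 non-insufficient samples; cannot repair")
    fhr = record.fhr.copy()
    quality = record.quality.copy()
    isolated = np.flatnonzero(
        red
        & np.concatenate(([True], ~red[:-1]))
        & np.concatenate((~red[1:], [True]))
    )
    for i in isolated:
        # stable sort keeps earlier indices first at equal distance
        order = np.argsort(np.abs(good_idx - i), kind="stable")
        nearest = good_idx[order[:5]]
        fhr[i] = record.fhr[nearest].mean()
        quality[i] = QualityFlag.ACCEPTABLE
    out = replace(record, fhr=fhr, quality=quality)
    return out


def include_subject(record: FHRRecord) -> bool:
    """Subject inclusion rule: >=30 usable 1-min and >=10 usable 3-min epochs."""
    n1 = sum(e.usable for e in segment(record, EPOCH_1MIN))
    n3 = sum(e.usable for e in segment(record, EPOCH_3MIN))
    return n1 >= MIN_USABLE_1MIN and n3 >= MIN_USABLE_3MIN


# ---------------------------------------------------------------------------
# CSV/JSON dialect
#
# One CSV row per sample with header  time_s,fhr_bpm,quality,uterine
# (the uterine column may be absent or empty), plus a JSON metadata sidecar
# {subject_id, group, ga_weeks, fetal_sex, maternal_age}.
# ---------------------------------------------------------------------------


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def read_record(path: str | Path, meta_path: str | Path | None = None) -> FHRRecord:
    """Read one record from a sample CSV plus its JSON metadata sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time_s", "fhr_bpm", "quality"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    try:
        quality = np.array(
            [QualityFlag.from_token(t) for t in df["quality"].astype(str)],
            dtype=np.int8,
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
    uterine = None
    if "uterine" in df.columns and df["uterine"].notna().any():
        uterine = df["uterine"].to_numpy(dtype=float)
    meta_file = Path(meta_path) if meta_path is not None else _meta_path(path)
    meta = {}
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
    return FHRRecord(
        subject_id=str(meta.get("subject_id", path.stem)),
        fhr=df["fhr_bpm"].to_numpy(dtype=float),
        quality=quality,
        uterine=uterine,
        group=meta.get("group", "unknown"),
        ga_weeks=float(meta.get("ga_weeks", float("nan"))),
        fetal_sex=meta.get("fetal_sex", "unknown"),
        maternal_age=float(meta.get("maternal_age", float("nan"))),
    )


def write_record(record: FHRRecord, path: str | Path) -> None:
    """Write one record in the CSV + JSON sidecar dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {
        "time_s": np.arange(record.n_samples) / FS_HZ,
        "fhr_bpm": record.fhr,
        "quality": [QualityFlag(q).token for q in record.quality],
    }
    if record.uterine is not None:
        data["uterine"] = record.uterine
    pd.DataFrame(data).to_csv(path, index=False)
    meta = {
        "subject_id": record.subject_id,
        "group": record.group,
        "ga_weeks": record.ga_weeks,
        "fetal_sex": record.fetal_sex,
        "maternal_age": record.maternal_age,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def read_cohort_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV with columns path,subject_id,group."""
    df = pd.read_csv(path)
    for col in ("path", "subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"manifest missing column {col!r}")
    return df
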