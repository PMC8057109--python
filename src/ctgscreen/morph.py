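"""Morphological and time-domain fetal heart rate features.

Covers the classical computerized-CTG quantities: a slowly varying FHR
baseline estimated by an iterative trimmed low-pass procedure in the style
of Mantel; acceleration / deceleration / uterine-contraction event counts;
and the beat-interval variability indices STV, Interval Index, Delta and
LTI computed on a 24-cells-per-minute mean beat-interval series in ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import EPOCH_1MIN, EPOCH_3MIN, FHRRecord, FS_HZ, segment

#: cells per minute of the beat-interval series (2.5 s = 5 samples per cell)
CELLS_PER_MIN = 24
CELL_SAMPLES = 5

#: event-detection thresholds (bpm peak excursion from baseline, samples)
ACC_LARGE_BPM = 15.0
ACC_SMALL_BPM = 10.0
DEC_BPM = 15.0
EVENT_MIN_SAMPLES = 30  # 15 s at 2 Hz
#: onset threshold: a sample belongs to a candidate event while its
#: excursion from baseline exceeds this (bpm); events are then classified
#: by their peak excursion
EVENT_ONSET_BPM = 5.0

#: contraction detector (implementation-defined): uterine excursion >= 30%
#: above the rolling 10-min tone baseline sustained >= 30 s
CONTR_REL_EXCURSION = 0.30
CONTR_MIN_SAMPLES = 60
CONTR_TONE_WIN_S = 600.0


@dataclass
class BaselineEstimate:
    """Per-sample baseline in bpm, aligned with the record."""

    baseline: np.ndarray
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class Event:
    kind: str  # acc_large | acc_small | dec | contraction
    start_index: int
    end_index: int
    peak_excursion: float


def _lowpass(x: np.ndarray, cutoff_hz: float = 0.0012) -> np.ndarray:
    # stiff enough that a single 20-bpm, 20-s acceleration (which the
    # >20-bpm trim rule cannot exclude) lifts the baseline by < 1 bpm
    b, a = sps.butter(2, cutoff_hz / (FS_HZ / 2.0), btype="low")
    return sps.filtfilt(b, a, x)


def estimate_baseline(
    record: FHRRecord,
    trim_bpm: float = 20.0,
    tol_bpm: float = 1.0,
    max_iter: int = 10,
) -> BaselineEstimate:
    """Iterative trimmed low-pass baseline estimate.

    The FHR trace is low-pass filtered, the estimate is seeded at the
    dominant mode of the filtered-signal histogram, and then samples
    deviating more than ``trim_bpm`` from the current baseline are
    replaced by interpolation and the filter re-applied, until the
    baseline changes by less than ``tol_bpm`` everywhere or ``max_iter``
    iterations have run.
    """
    x = record.fhr.astype(float)
    if np.ptp(x) < 1e-9:
        return BaselineEstimate(np.full_like(x, x[0]), True, 0)
    smooth = _lowpass(x)
    hist, edges = np.histogram(smooth, bins=np.arange(30.0, 250.0 + 1.0, 1.0))
    mode = edges[np.argmax(hist)] + 0.5
    baseline = np.full_like(x, mode)
    converged = False
    it = 0
    idx = np.arange(len(x))
    for it in range(1, max_iter + 1):
        keep = np.abs(x - baseline) <= trim_bpm
        if keep.sum() < 10:  # degenerate trim: keep closest decile
            keep = np.abs(x - baseline) <= np.quantile(np.abs(x - baseline), 0.1)
        filled = np.interp(idx, idx[keep], x[keep])
        new = _lowpass(filled)
        delta = np.max(np.abs(new - baseline))
        baseline = new
        if delta < tol_bpm:
            converged = True
            break
    baseline = np.clip(baseline, 50.0, 200.0)
    return BaselineEstimate(baseline, converged, it)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True."""
    padded = np.concatenate(([False], np.asarray(mask, bool), [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_events(
    record: FHRRecord,
    baseline: BaselineEstimate,
    onset_bpm: float = EVENT_ONSET_BPM,
    min_samples: int = EVENT_MIN_SAMPLES,
) -> list[Event]:
    """Detect accelerations, decelerations and uterine contractions.

    A candidate acceleration (deceleration) is a run of samples whose
    excursion above (below) the baseline exceeds ``onset_bpm`` for at
    least ``min_samples``; it is classified by its peak excursion:
    >= 15 bpm large acceleration, 10-15 bpm small acceleration, while
    decelerations require a peak depth >= 15 bpm.  Contractions are runs
    of the uterine channel at least 30% above its rolling 10-min tone
    baseline lasting >= 30 s.
    """
    dev = record.fhr - baseline.baseline
    events: list[Event] = []
    for start, stop in _runs(dev > onset_bpm):
        if stop - start < min_samples:
            continue
        peak = float(dev[start:stop].max())
        if peak >= ACC_LARGE_BPM:
            events.append(Event("acc_large", start, stop, peak))
        elif peak >= ACC_SMALL_BPM:
            events.append(Event("acc_small", start, stop, peak))
    for start, stop in _runs(-dev > onset_bpm):
        if stop - start < min_samples:
            continue
        depth = float((-dev[start:stop]).max())
        if depth >= DEC_BPM:
            events.append(Event("dec", start, stop, depth))
    if record.uterine is not None:
        ut = record.uterine.astype(float)
        win = int(CONTR_TONE_WIN_S * FS_HZ) | 1
        tone = sps.medfilt(ut, min(win, (len(ut) // 2) * 2 + 1))
        tone = np.maximum(tone, 1e-6)
        rel = (ut - tone) / tone
        for start, stop in _runs(rel > CONTR_REL_EXCURSION):
            if stop - start < CONTR_MIN_SAMPLES:
                continue
            events.append(
                Event("contraction", start, stop, float((ut - tone)[start:stop].max()))
            )
    return sorted(events, key=lambda e: e.start_index)


def event_counts(events: list[Event], has_uterine: bool) -> dict[str, float]:
    counts = {
        "#acc_large": 0.0,
        "#acc_small": 0.0,
        "#dec": 0.0,
        "#contr": 0.0 if has_uterine else float("nan"),
    }
    for e in events:
        key = {"acc_large": "#acc_large", "acc_small": "#acc_small",
               "dec": "#dec", "contraction": "#contr"}[e.kind]
        if not np.isnan(counts[key]):
            counts[key] += 1.0
    return counts


def event_sample_mask(events: list[Event], n: int) -> np.ndarray:
    """Boolean mask of samples inside acceleration/deceleration events."""
    mask = np.zeros(n, dtype=bool)
    for e in events:
        if e.kind in ("acc_large", "acc_small", "dec"):
            mask[e.start_index : e.end_index] = True
    return mask


def t24_series(
    record: FHRRecord,
    exclude_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean beat interval (ms) per 2.5-s cell; NaN marks excluded cells.

    Each full minute holds ``CELLS_PER_MIN`` cells of ``CELL_SAMPLES``
    samples; a cell is excluded (NaN) when any of its samples lies in an
    unusable 1-min epoch or in ``exclude_mask`` (event samples).
    """
    ms = 60000.0 / record.fhr
    n_cells = record.n_samples // CELL_SAMPLES
    cells = ms[: n_cells * CELL_SAMPLES].reshape(n_cells, CELL_SAMPLES).mean(axis=1)
    bad = np.zeros(record.n_samples, dtype=bool)
    for e in segment(record, EPOCH_1MIN):
        if not e.usable:
            bad[e.start_index : e.stop_index] = True
    if exclude_mask is not None:
        bad |= exclude_mask
    bad_cells = (
        bad[: n_cells * CELL_SAMPLES].reshape(n_cells, CELL_SAMPLES).any(axis=1)
    )
    cells[bad_cells] = np.nan
    return cells


def _per_minute(cells: np.ndarray, min_cells: int = 12):
    """Iterate over full minutes of the cell series that have enough data."""
    n_min = len(cells) // CELLS_PER_MIN
    for k in range(n_min):
        minute = cells[k * CELLS_PER_MIN : (k + 1) * CELLS_PER_MIN]
        valid = minute[~np.isnan(minute)]
        if len(valid) >= min_cells:
            yield minute, valid


def stv(cells: np.ndarray) -> float:
    """Short-term variability: per-minute mean |successive difference| (ms)."""
    vals = []
    for minute, _ in _per_minute(cells):
        d = np.abs(np.diff(minute))
        d = d[~np.isnan(d)]
        if len(d):
            vals.append(d.mean())
    return float(np.mean(vals)) if vals else float("nan")


def interval_index(cells: np.ndarray) -> float:
    """Interval Index: per-minute STV / SD of the minute's intervals."""
    vals = []
    for minute, valid in _per_minute(cells):
        d = np.abs(np.diff(minute))
        d = d[~np.isnan(d)]
        sd = valid.std(ddof=0)
        if len(d) and sd > 1e-12:
            vals.append(d.mean() / sd)
    return float(np.mean(vals)) if vals else float("nan")


def delta(cells: np.ndarray) -> float:
    """Delta: per-minute range (max - min) of the interval series (ms)."""
    vals = [valid.max() - valid.min() for _, valid in _per_minute(cells)]
    return float(np.mean(vals)) if vals else float("nan")


def lti(cells: np.ndarray, min_cells: int = 36) -> float:
    """Long-term irregularity over 3-min windows (ms).

    Per window, the interquartile range of m(j) = sqrt(t24(j)^2 +
    t24(j+1)^2) over valid adjacent cell pairs, averaged over windows.
    """
    win = 3 * CELLS_PER_MIN
    n_win = len(cells) // win
    vals = []
    for k in range(n_win):
        w = cells[k * win : (k + 1) * win]
        pair_ok = ~np.isnan(w[:-1]) & ~np.isnan(w[1:])
        if pair_ok.sum() < min_cells:
            continue
        m = np.sqrt(w[:-1][pair_ok] ** 2 + w[1:][pair_ok] ** 2)
        q1, q3 = np.percentile(m, [25, 75])
        vals.append(q3 - q1)
    return float(np.mean(vals)) if vals else float("nan")
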