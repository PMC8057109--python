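"""Per-record feature extraction: quality handling through all four domains."""

from __future__ import annotations

import numpy as np

from . import complexity, morph, spectral
from .features import aggregate
from .records import EPOCH_3MIN, FHRRecord, include_subject, repair_isolated, segment


def extract_record_features(
    record: FHRRecord,
    ar_order: int = spectral.DEFAULT_ORDER,
    spectral_domain: str = "ms",
) -> dict[str, float]:
    """Compute the per-subject feature vector of one CTG recording.

    The record is repaired (isolated insufficient samples), the baseline
    estimated and events detected on the full trace; the variability
    indices are computed on the 24-cells-per-minute beat-interval series
    with event samples excluded; spectral and entropy/LZC features are
    computed per usable 3-min epoch and averaged; PRSA capacities are
    computed once over the whole repaired bpm trace.

    ``spectral_domain`` selects the signal fed to the AR spectrum: the
    per-sample beat-interval series in ms (default) or the raw bpm trace.
    """
    rec = repair_isolated(record)
    baseline = morph.estimate_baseline(rec)
    events = morph.detect_events(rec, baseline)
    counts = morph.event_counts(events, rec.uterine is not None)

    ev_mask = morph.event_sample_mask(events, rec.n_samples)
    cells = morph.t24_series(rec, exclude_mask=ev_mask)

    epochs3 = segment(rec, EPOCH_3MIN)
    usable3 = [e for e in epochs3 if e.usable]
    spectral_sig = 60000.0 / rec.fhr if spectral_domain == "ms" else rec.fhr

    epoch_feats: dict[str, list[float]] = {
        k: [] for k in ("LF_pow", "MF_pow", "HF_pow", "ApEn", "SampEn",
                        "LZC_bin", "LZC_ter")
    }
    for e in usable3:
        seg_c = spectral_sig[e.start_index : e.stop_index]
        bp = spectral.band_powers(seg_c, order=ar_order)
        for k, v in bp.items():
            epoch_feats[k].append(v)
        seg_bpm = rec.fhr[e.start_index : e.stop_index]
        epoch_feats["ApEn"].append(complexity.apen(seg_bpm))
        epoch_feats["SampEn"].append(complexity.sampen(seg_bpm))
        epoch_feats["LZC_bin"].append(complexity.lzc(seg_bpm, "binary"))
        epoch_feats["LZC_ter"].append(complexity.lzc(seg_bpm, "ternary"))

    recording_feats: dict[str, float] = {
        "FHR_mean": float(rec.fhr.mean()),
        "FHR_std": float(rec.fhr.std(ddof=1)),
        "STV": morph.stv(cells),
        "II": morph.interval_index(cells),
        "Delta": morph.delta(cells),
        "LTI": morph.lti(cells),
        **counts,
        **complexity.prsa_features(rec.fhr),
    }

    meta = {
        "ga_weeks": rec.ga_weeks,
        "fetal_sex": rec.fetal_sex,
        "maternal_age": rec.maternal_age,
    }
    return aggregate(epoch_feats, recording_feats, meta)


def extract_cohort(records: list[FHRRecord], **kwargs):
    """Feature rows and labels for all records passing the inclusion rule.

    Returns (rows, labels, excluded_ids).
    """
    rows: dict[str, dict[str, float]] = {}
    labels: dict[str, str] = {}
    excluded: list[str] = []
    for rec in records:
        if not include_subject(rec):
            excluded.append(rec.subject_id)
            continue
        rows[rec.subject_id] = extract_record_features(rec, **kwargs)
        labels[rec.subject_id] = rec.group
    return rows, labels, excluded
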