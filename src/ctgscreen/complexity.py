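"""Complexity-domain features: entropies, Lempel-Ziv complexity and PRSA.

Approximate entropy (Pincus), sample entropy (Richman-Moorman) and
normalized Lempel-Ziv complexity (exhaustive-history parsing of the
sign-symbolized difference signal, binary or ternary alphabet) are
computed per 3-min epoch.  Phase-rectified signal averaging (PRSA)
isolates quasi-periodic accelerations/decelerations by anchor-aligned
averaging over the whole recording; the acceleration and deceleration
capacities (AC, DC) are Haar-wavelet slopes of the PRSA curve at scale s,
and the deceleration reserve is DR = AC + DC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: entropy defaults: pattern length m = 1, tolerance r = 0.1 x epoch SD
ENTROPY_M = 1
ENTROPY_R = 0.1
#: Lempel-Ziv difference-threshold factor (zero: pure sign symbolization)
LZC_P = 0.0
#: PRSA half-window (samples) and the four (T, s) parameter pairs
PRSA_L = 100
PRSA_TS_PAIRS = ((1, 2), (5, 5), (9, 9), (40, 1))


def _template_counts(x: np.ndarray, m: int, r: float, include_self: bool) -> np.ndarray:
    """Per-template counts of Chebyshev-matching templates of length m."""
    n = len(x)
    n_templates = n - m + 1
    # pairwise max over the m coordinates of |x_i+k - x_j+k|
    dist = np.abs(x[:, None] - x[None, :])
    cheb = dist[:n_templates, :n_templates].copy()
    for k in range(1, m):
        np.maximum(cheb, dist[k : k + n_templates, k : k + n_templates], out=cheb)
    match = cheb <= r
    counts = match.sum(axis=1).astype(float)
    if not include_self:
        counts -= 1.0
    return counts


def apen(x: np.ndarray, m: int = ENTROPY_M, r: float = ENTROPY_R) -> float:
    """Approximate entropy with self-matches included.

    ``r`` is a fraction of the signal standard deviation.  A
    zero-variance signal has ApEn 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd < 1e-12:
        return 0.0
    tol = r * sd
    phi = []
    for mm in (m, m + 1):
        c = _template_counts(x, mm, tol, include_self=True) / (len(x) - mm + 1)
        phi.append(np.log(c).mean())
    return float(phi[0] - phi[1])


def sampen(x: np.ndarray, m: int = ENTROPY_M, r: float = ENTROPY_R) -> float:
    """Sample entropy: -ln(A/B) with self-matches excluded.

    Template pairs are counted over the first ``n - m`` templates for both
    lengths (Richman-Moorman convention).  Returns NaN when no length-m
    or no length-(m+1) pair matches (undefined, not infinite).
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd < 1e-12:
        return 0.0
    tol = r * sd
    n = len(x)
    dist = np.abs(x[:, None] - x[None, :])
    nt = n - m  # templates compared at both lengths
    cheb_m = dist[:nt, :nt].copy()
    for k in range(1, m):
        np.maximum(cheb_m, dist[k : k + nt, k : k + nt], out=cheb_m)
    cheb_m1 = np.maximum(cheb_m, dist[m : m + nt, m : m + nt])
    b = int((cheb_m <= tol).sum()) - nt  # exclude self-pairs
    a = int((cheb_m1 <= tol).sum()) - nt
    if a <= 0 or b <= 0:
        return float("nan")
    return float(-np.log(a / b))


def symbolize(x: np.ndarray, alphabet: str, p: float = LZC_P) -> np.ndarray:
    """Symbolize successive differences of a signal.

    binary:  1 where the difference exceeds ``p * SD``, else 0.
    ternary: +1 / -1 where the difference exceeds +-``p * SD``, else 0.
    With p = 0 this reduces to (d > 0) and sign(d).
    """
    d = np.diff(np.asarray(x, dtype=float))
    thr = p * np.std(x)
    if alphabet == "binary":
        return (d > thr).astype(np.int8)
    if alphabet == "ternary":
        return (np.sign((d > thr).astype(np.int8) - (d < -thr).astype(np.int8))).astype(
            np.int8
        )
    raise ValueError("alphabet must be 'binary' or 'ternary'")


def lz76_complexity(symbols: np.ndarray) -> int:
    """Number of phrases in the Lempel-Ziv 1976 exhaustive-history parsing.

    Kaspar-Schuster formulation: scan the sequence, extending the current
    phrase while it occurs earlier in the string (as a substring of the
    prefix excluding the phrase's last symbol); each failure closes a
    phrase.
    """
    s = "".join(chr(66 + int(v)) for v in np.asarray(symbols).astype(int))
    if not s:
        return 0
    return _lz76(s)


def _lz76(s: str) -> int:
    """Exhaustive-history phrase count: a phrase grows while it already
    occurs as a substring of the history that excludes its last symbol."""
    n = len(s)
    c = 0
    i = 0
    while i < n:
        k = 1
        while i + k < n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


def lzc(x: np.ndarray, alphabet: str = "binary", p: float = LZC_P) -> float:
    """Normalized Lempel-Ziv complexity c(n) * log_alpha(n) / n of a signal."""
    symbols = symbolize(x, alphabet, p)
    n = len(symbols)
    if n < 2:
        return 0.0
    alpha = 2 if alphabet == "binary" else 3
    c = lz76_complexity(symbols)
    return float(c * (np.log(n) / np.log(alpha)) / n)


@dataclass
class PRSACurve:
    """Anchor-aligned average of the signal over windows [-L, L)."""

    x: np.ndarray  # length 2L; index L corresponds to the anchor (k = 0)
    n_anchors: int
    direction: str  # "acceleration" | "deceleration"
    L: int

    @property
    def empty(self) -> bool:
        return self.n_anchors == 0


def prsa_anchors(x: np.ndarray, T: int, direction: str) -> np.ndarray:
    """Indices i where the mean of x[i:i+T] moves past the mean of x[i-T:i].

    Strict inequality; only i with full T-sample context on both sides
    are eligible.
    """
    x = np.asarray(x, dtype=float)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(T, len(x) - T + 1)
    after = (cs[i + T] - cs[i]) / T
    before = (cs[i] - cs[i - T]) / T
    if direction == "acceleration":
        sel = after > before
    elif direction == "deceleration":
        sel = after < before
    else:
        raise ValueError("direction must be 'acceleration' or 'deceleration'")
    return i[sel]


def prsa_curve(
    x: np.ndarray, T: int, direction: str, L: int = PRSA_L
) -> PRSACurve:
    """Phase-rectified signal average around acceleration/deceleration anchors.

    Anchors closer than L samples to either record edge are skipped so
    every averaged window [i-L, i+L) is complete.
    """
    x = np.asarray(x, dtype=float)
    anchors = prsa_anchors(x, T, direction)
    anchors = anchors[(anchors >= L) & (anchors + L <= len(x))]
    if len(anchors) == 0:
        return PRSACurve(np.zeros(2 * L), 0, direction, L)
    # curve(k) = mean_a x[a + k]: a cross-correlation of x with the
    # anchor indicator, evaluated at lags -L .. L-1
    from scipy.signal import fftconvolve

    indicator = np.zeros(len(x))
    indicator[anchors] = 1.0
    corr = fftconvolve(x, indicator[::-1], mode="full")
    center = len(x) - 1
    curve = corr[center - L : center + L] / len(anchors)
    return PRSACurve(curve, len(anchors), direction, L)


def capacity(curve: PRSACurve, s: int) -> float:
    """Haar-wavelet capacity of a PRSA curve at scale s (bpm).

    ``(sum of the s samples at and after the anchor - sum of the s samples
    before it) / (2 s)``; positive for acceleration curves (AC), negative
    for deceleration curves (DC) by construction.
    """
    if curve.empty:
        return float("nan")
    if 2 * s > 2 * curve.L:
        raise ValueError("scale s exceeds the PRSA half-window")
    L = curve.L
    return float(
        (curve.x[L : L + s].sum() - curve.x[L - s : L].sum()) / (2.0 * s)
    )


def prsa_features(x: np.ndarray, pairs=PRSA_TS_PAIRS, L: int = PRSA_L) -> dict[str, float]:
    """AC/DC/DR at each configured (T, s) pair over a whole recording."""
    out: dict[str, float] = {}
    for T, s in pairs:
        acc = capacity(prsa_curve(x, T, "acceleration", L), s)
        dec = capacity(prsa_curve(x, T, "deceleration", L), s)
        out[f"AC_T{T}_s{s}"] = acc
        out[f"DC_T{T}_s{s}"] = dec
        out[f"DR_T{T}_s{s}"] = acc + dec
    return out
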