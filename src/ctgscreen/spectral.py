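"""Autoregressive spectral analysis of 3-min FHR epochs.

The power spectral density of each usable 3-min segment is modelled by an
autoregressive (AR) process fitted with the Levinson-Durbin recursion on
the biased autocorrelation sequence.  The AR spectrum is decomposed into
sinusoidal components via the poles of the model; each component's power
(the residue of the spectrum at its pole) is assigned to the band holding
its central frequency:

* LF (low frequency)       0.03 - 0.15 Hz
* MF (movement frequency)  0.15 - 0.5  Hz
* HF (high frequency)      0.5  - 1    Hz (Nyquist at 2 Hz sampling)

Components below 0.03 Hz (trend / very-low-frequency residue) are excluded
from all three bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import FS_HZ

BANDS = {"LF": (0.03, 0.15), "MF": (0.15, 0.5), "HF": (0.5, 1.0)}
DEFAULT_ORDER = 12


@dataclass
class ARModel:
    """AR(p) model: x[t] + sum_k a[k] x[t-k] = e[t], var(e) = sigma2."""

    a: np.ndarray  # coefficients a_1..a_p (a_0 = 1 implicit)
    sigma2: float
    order: int
    degenerate: bool = False

    def poles(self) -> np.ndarray:
        """Roots of z^p + a_1 z^{p-1} + ... + a_p (inside unit circle if stable)."""
        return np.roots(np.concatenate(([1.0], self.a)))

    def is_stable(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.poles()) < 1.0 - tol))

    def psd(self, freqs: np.ndarray, fs: float = FS_HZ) -> np.ndarray:
        """One-sided PSD (power per Hz) at the given frequencies."""
        w = 2.0 * np.pi * np.asarray(freqs) / fs
        k = np.arange(1, self.order + 1)
        A = 1.0 + np.exp(-1j * np.outer(w, k)) @ self.a.astype(complex)
        return 2.0 * self.sigma2 / fs / np.abs(A) ** 2


@dataclass
class SpectralComponents:
    """Pole-residue decomposition of an AR spectrum."""

    central_freqs: np.ndarray  # Hz, one per component
    powers: np.ndarray  # same units as input variance
    total_power: float
    band_powers: dict[str, float] = field(default_factory=dict)


def levinson_durbin(r: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Levinson-Durbin recursion on an autocorrelation sequence.

    Parameters
    ----------
    r : autocorrelation lags 0..order (at least).
    order : AR model order.

    Returns
    -------
    (a, sigma2): AR coefficients a_1..a_p and innovation variance.
    """
    r = np.asarray(r, dtype=float)
    if len(r) < order + 1:
        raise ValueError("need autocorrelation lags 0..order")
    a = np.zeros(order)
    err = r[0]
    if err <= 0:
        raise np.linalg.LinAlgError("non-positive zero-lag autocorrelation")
    for m in range(order):
        acc = r[m + 1] - np.dot(a[:m], r[m:0:-1])
        k = acc / err
        a_new = a.copy()
        a_new[m] = k
        a_new[:m] = a[:m] - k * a[m - 1 :: -1] if m else a_new[:m]
        a = a_new
        err *= 1.0 - k * k
        if err <= 0:
            err = max(err, 1e-15 * r[0])
    # sign convention: x[t] + sum a_k x[t-k] = e[t]
    return -a, float(err)


def biased_autocorr(x: np.ndarray, maxlag: int) -> np.ndarray:
    """Biased (1/N) autocorrelation estimate, lags 0..maxlag."""
    x = np.asarray(x, float)
    n = len(x)
    full = np.correlate(x, x, mode="full")[n - 1 : n + maxlag]
    return full / n


def ar_fit(x: np.ndarray, order: int = DEFAULT_ORDER, detrend: str = "linear") -> ARModel:
    """Fit an AR model to one epoch by Levinson-Durbin.

    The epoch is linearly detrended first (suppresses sub-0.03-Hz
    leakage).  A (near-)constant epoch yields a degenerate model with
    zero band powers rather than an error.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= order:
        raise ValueError("epoch shorter than the AR order")
    if detrend:
        x = sps.detrend(x, type=detrend)
    if np.std(x) < 1e-10:
        return ARModel(np.zeros(order), 0.0, order, degenerate=True)
    r = biased_autocorr(x, order)
    a, sigma2 = levinson_durbin(r, order)
    return ARModel(a, sigma2, order)


def spectral_decompose(model: ARModel, fs: float = FS_HZ) -> SpectralComponents:
    """Decompose an AR spectrum into components by pole residues.

    Each pole p_k of the AR transfer function contributes a spectral
    component of central frequency ``|arg(p_k)| / 2pi * fs`` and power
    equal to the residue of S(z)/z at p_k (complex pairs combined as
    2 Re(residue)).  The component powers sum to the process variance.
    """
    if model.degenerate:
        return SpectralComponents(
            np.array([]), np.array([]), 0.0, {b: 0.0 for b in BANDS}
        )
    if not model.is_stable(tol=0.0):
        raise ValueError("unstable AR model; reduce the model order")
    poles = model.poles()
    # B(z) = 1 + a_1 z + ... + a_p z^p has roots 1/p_k
    b = np.concatenate(([1.0], model.a))
    bp = np.polynomial.polynomial.polyval  # evaluates sum c_k z^k
    dcoef = np.arange(1, model.order + 1) * model.a
    residues = np.empty(len(poles), dtype=complex)
    for k, p in enumerate(poles):
        # res_{z=p} sigma2 / (z B(z) B(1/z)) = -sigma2 p / (B(p) B'(1/p))
        residues[k] = -model.sigma2 * p / (bp(p, b) * bp(1.0 / p, dcoef))
    freqs = np.abs(np.angle(poles)) / (2.0 * np.pi) * fs
    # combine conjugate pairs: keep poles with angle >= 0, double complex ones
    keep = np.angle(poles) >= -1e-12
    comp_f, comp_p = [], []
    seen_real = set()
    for k in np.flatnonzero(keep):
        p = poles[k]
        if abs(p.imag) < 1e-9:
            key = round(p.real, 9)
            if key in seen_real:
                # repeated real pole: residue formula still applies per root
                pass
            seen_real.add(key)
            comp_f.append(freqs[k])
            comp_p.append(residues[k].real)
        else:
            comp_f.append(freqs[k])
            comp_p.append(2.0 * residues[k].real)
    comp_f = np.asarray(comp_f)
    comp_p = np.asarray(comp_p)
    total = float(comp_p.sum())
    band_powers = {}
    for name, (lo, hi) in BANDS.items():
        in_band = (comp_f >= lo) & (comp_f < hi) if name != "HF" else (
            (comp_f >= lo) & (comp_f <= hi)
        )
        band_powers[name] = float(comp_p[in_band].sum())
    return SpectralComponents(comp_f, comp_p, total, band_powers)


def band_powers(x: np.ndarray, order: int = DEFAULT_ORDER) -> dict[str, float]:
    """LF/MF/HF band powers of one 3-min epoch signal."""
    model = ar_fit(x, order=order)
    comps = spectral_decompose(model)
    return {f"{b}_pow": comps.band_powers[b] for b in BANDS}


def integrate_psd_bands(model: ARModel, n_freq: int = 4096) -> dict[str, float]:
    """Band powers by trapezoidal integration of the AR PSD (cross-check)."""
    out = {}
    for name, (lo, hi) in BANDS.items():
        f = np.linspace(lo, hi, n_freq)
        out[name] = float(np.trapezoid(model.psd(f), f))
    return out
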