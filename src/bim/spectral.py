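"""Frequency-domain coupling and causality measures.

Parametric route: the VAR transfer matrix H(f) = [I - sum A_k e^{-j2пfk}]^{-1}
factorizes the spectral matrix P = H Sigma_U H*.  From P and H follow the
squared coherence, the directed coherence (normalized causal coupling,
meaningful under strict causality), and the Geweke spectral profiles of
total dependence, Granger causality and instantaneous causality.  Each
profile integrates back to its time-domain measure over normalized
frequency [0, 1/2] (spectral integration property), which licenses
band-limited information measures (e.g. LF/HF bands in cardiovascular
variability).

Non-parametric route: the weighted-covariance (Blackman-Tukey) spectral
estimator with a Parzen lag window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measures import cross_correlation
from .varmodel import ARXModel

__all__ = [
    "SpectralDecomposition",
    "BandIntegral",
    "transfer_and_psd",
    "coherence",
    "directed_coherence",
    "geweke_spectral",
    "band_integrate",
    "band_measures",
    "wc_psd",
    "parzen_truncation_lag",
    "parzen_window",
    "spectral_pipeline",
]

DEFAULT_NFREQ = 1001


@dataclass
class SpectralDecomposition:
    """Frequency grid plus PSD/transfer matrices and derived profiles.

    fgrid is normalized frequency in [0, 0.5] (multiply by fs for Hz).
    P is (n_f, 2, 2) Hermitian; H the (n_f, 2, 2) transfer matrix.
    Profiles are filled lazily by :func:`coherence`, :func:`directed_coherence`
    and :func:`geweke_spectral`.
    """

    fgrid: np.ndarray
    fs: float = 1.0
    P: np.ndarray | None = None
    H: np.ndarray | None = None
    sigma2: np.ndarray | None = None  # diagonal innovation variances used
    coh2: np.ndarray | None = None
    dc2_12: np.ndarray | None = None  # causal coupling 1 -> 2
    dc2_21: np.ndarray | None = None  # causal coupling 2 -> 1
    f_td: np.ndarray | None = None
    f_gc_12: np.ndarray | None = None
    f_gc_21: np.ndarray | None = None
    f_ic: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def f_hz(self) -> np.ndarray:
        return self.fgrid * self.fs

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: one row per frequency bin."""
        cols = {"f_norm": self.fgrid, "f_hz": self.f_hz}
        if self.P is not None:
            cols["P11"] = self.P[:, 0, 0].real
            cols["P22"] = self.P[:, 1, 1].real
            cols["ReP12"] = self.P[:, 0, 1].real
            cols["ImP12"] = self.P[:, 0, 1].imag
        for name in ("coh2", "dc2_12", "dc2_21", "f_td", "f_gc_12",
                     "f_gc_21", "f_ic"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)


@dataclass
class BandIntegral:
    """Information measures integrated over one frequency band (nats)."""

    band: tuple[float, float]  # Hz
    I_mir: float
    T_12: float
    T_21: float
    I_it: float
    significant: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"band_hz": list(self.band), "I_mir": self.I_mir, "T_12": self.T_12,
             "T_21": self.T_21, "I_it": self.I_it}
        if self.significant:
            d["significant"] = self.significant
        return d


def _grid(n_freq: int) -> np.ndarray:
    if n_freq < 64:
        raise ValueError("n_freq must be >= 64")
    return np.linspace(0.0, 0.5, n_freq)


def transfer_and_psd(model: ARXModel, n_freq: int = DEFAULT_NFREQ,
                     fs: float = 1.0) -> SpectralDecomposition:
    """Parametric PSD by spectral factorization P(f) = H(f) Sigma_U H(f)*.

    H(f) = [I - sum_k A_k e^{-j 2 pi f k}]^{-1} evaluated on a uniform grid
    over normalized frequency [0, 0.5], endpoints included.
    """
    if not model.stable:
        raise ValueError("marginally stable or unstable model: PSD undefined")
    f = _grid(n_freq)
    z = np.exp(-2j * np.pi * np.outer(f, np.arange(1, model.p + 1)))  # (n_f, p)
    Abar = np.tile(np.eye(2, dtype=complex), (n_freq, 1, 1))
    for k in range(model.p):
        Abar -= z[:, k, None, None] * model.A[k]
    det = Abar[:, 0, 0] * Abar[:, 1, 1] - Abar[:, 0, 1] * Abar[:, 1, 0]
    if np.any(np.abs(det) < 1e-12):
        raise ValueError("marginally stable: pole on the frequency grid")
    H = np.empty_like(Abar)
    H[:, 0, 0] = Abar[:, 1, 1] / det
    H[:, 1, 1] = Abar[:, 0, 0] / det
    H[:, 0, 1] = -Abar[:, 0, 1] / det
    H[:, 1, 0] = -Abar[:, 1, 0] / det
    P = H @ model.Sigma_U @ H.conj().transpose(0, 2, 1)
    # enforce exact Hermitian symmetry against rounding
    P = 0.5 * (P + P.conj().transpose(0, 2, 1))
    return SpectralDecomposition(fgrid=f, fs=fs, P=P, H=H,
                                 sigma2=np.diag(model.Sigma_U).copy(),
                                 meta={"n_freq": n_freq, "p": model.p})


def coherence(spec: SpectralDecomposition) -> np.ndarray:
    """Squared coherence |P12|^2 / (P11 P22); also stores f_td = -ln(1-coh2)."""
    if spec.P is None:
        raise ValueError("PSD not computed")
    P11 = spec.P[:, 0, 0].real
    P22 = spec.P[:, 1, 1].real
    if np.any(P11 <= 0) or np.any(P22 <= 0):
        raise ValueError("zero diagonal PSD: coherence undefined")
    coh2 = np.abs(spec.P[:, 0, 1]) ** 2 / (P11 * P22)
    coh2 = np.clip(coh2, 0.0, 1.0 - 1e-300)
    spec.coh2 = coh2
    spec.f_td = -np.log1p(-coh2)
    return coh2


def directed_coherence(spec: SpectralDecomposition,
                       model: ARXModel) -> tuple[np.ndarray, np.ndarray]:
    """Squared directed coherence in both directions.

    dc2_12 (influence of process 1 on process 2) uses the power
    decomposition P22 = s1^2 |H21|^2 + s2^2 |H22|^2, valid when the
    innovation covariance is diagonal (strict causality).  With correlated
    innovations the same diagonal-term formula is applied after a warning;
    the power interpretation is then only approximate.
    """
    if spec.H is None:
        raise ValueError("transfer matrix not computed")
    if not model.strictly_causal:
        warnings.warn(
            "innovation covariance is not diagonal: directed coherence "
            "computed from diagonal terms only; power interpretation is "
            "approximate", stacklevel=2)
    s1, s2 = np.diag(model.Sigma_U)
    h11 = np.abs(spec.H[:, 0, 0]) ** 2
    h12 = np.abs(spec.H[:, 0, 1]) ** 2
    h21 = np.abs(spec.H[:, 1, 0]) ** 2
    h22 = np.abs(spec.H[:, 1, 1]) ** 2
    spec.dc2_12 = s1 * h21 / (s1 * h21 + s2 * h22)
    spec.dc2_21 = s2 * h12 / (s2 * h12 + s1 * h11)
    return spec.dc2_12, spec.dc2_21


def geweke_spectral(spec: SpectralDecomposition, model: ARXModel):
    """Geweke spectral profiles of TD, GC (both directions) and IC.

    f_gc(1->2) = ln(P22 / (s2^2 |H22|^2)); f_ic is fixed by requiring the
    frequency-wise decomposition f_td = f_gc_12 + f_gc_21 + f_ic, i.e.
    f_ic = ln(s1^2 |H11|^2 s2^2 |H22|^2 / |P|).  With correlated
    innovations the GC/IC profiles can be negative at some frequencies;
    that is expected behaviour, not an error.
    """
    if spec.P is None or spec.H is None:
        raise ValueError("PSD/transfer matrix not computed")
    s1, s2 = np.diag(model.Sigma_U)
    P11 = spec.P[:, 0, 0].real
    P22 = spec.P[:, 1, 1].real
    detP = P11 * P22 - np.abs(spec.P[:, 0, 1]) ** 2
    h11 = s1 * np.abs(spec.H[:, 0, 0]) ** 2
    h22 = s2 * np.abs(spec.H[:, 1, 1]) ** 2
    spec.f_td = np.log(P11 * P22 / detP)
    spec.f_gc_12 = np.log(P22 / h22)
    spec.f_gc_21 = np.log(P11 / h11)
    spec.f_ic = np.log(h11 * h22 / detP)
    return spec.f_td, spec.f_gc_12, spec.f_gc_21, spec.f_ic


def band_integrate(spec: SpectralDecomposition, profile: np.ndarray,
                   band_hz: tuple[float, float]) -> float:
    """Integrate a spectral profile over a band (Hz) on the normalized axis.

    Trapezoidal rule with the band edges interpolated onto the grid, so
    adjacent bands tile exactly.  Whole-band integration of a Geweke
    profile yields the information measure (nats); twice that is the F
    measure.
    """
    lo, hi = band_hz
    if not (0 <= lo < hi <= spec.fs / 2 + 1e-12):
        raise ValueError(f"band {band_hz} outside [0, fs/2] = [0, {spec.fs / 2}]")
    f = spec.fgrid
    lo_n, hi_n = lo / spec.fs, hi / spec.fs
    inside = f[(f > lo_n) & (f < hi_n)]
    xs = np.concatenate([[lo_n], inside, [hi_n]])
    if xs.size < 2:
        raise ValueError("empty band on the frequency grid")
    ys = np.interp(xs, f, profile)
    return float(np.trapezoid(ys, xs))


def band_measures(spec: SpectralDecomposition,
                  band_hz: tuple[float, float]) -> BandIntegral:
    """Band-integrated information measures (nats) from the Geweke profiles."""
    if spec.f_td is None or spec.f_gc_12 is None:
        raise ValueError("Geweke profiles not computed")
    return BandIntegral(
        band=tuple(band_hz),
        I_mir=band_integrate(spec, spec.f_td, band_hz),
        T_12=band_integrate(spec, spec.f_gc_12, band_hz),
        T_21=band_integrate(spec, spec.f_gc_21, band_hz),
        I_it=band_integrate(spec, spec.f_ic, band_hz),
    )


def spectral_pipeline(model: ARXModel, n_freq: int = DEFAULT_NFREQ,
                      fs: float = 1.0) -> SpectralDecomposition:
    """PSD, coherence, directed coherence and Geweke profiles in one call."""
    spec = transfer_and_psd(model, n_freq=n_freq, fs=fs)
    coherence(spec)
    with warnings.catch_warnings():
        if not model.strictly_causal:
            warnings.simplefilter("ignore")
        directed_coherence(spec, model)
    geweke_spectral(spec, model)
    return spec


def parzen_window(k: np.ndarray, tau: int) -> np.ndarray:
    """Parzen lag window (piecewise cubic), w(0)=1, support |k| <= tau."""
    a = np.abs(np.asarray(k, float)) / tau
    w = np.zeros_like(a)
    inner = a <= 0.5
    outer = (a > 0.5) & (a <= 1.0)
    w[inner] = 1 - 6 * a[inner] ** 2 + 6 * a[inner] ** 3
    w[outer] = 2 * (1 - a[outer]) ** 3
    return w


_LAG_WINDOWS = {
    "parzen": parzen_window,
    "hanning": lambda k, tau: 0.5 * (1 + np.cos(np.pi * np.abs(k) / tau)),
    "hamming": lambda k, tau: 0.54 + 0.46 * np.cos(np.pi * np.abs(k) / tau),
}


def wc_psd(pair, truncation_lag: int, n_freq: int = DEFAULT_NFREQ,
           window: str = "parzen") -> SpectralDecomposition:
    """Weighted-covariance (Blackman-Tukey) PSD matrix estimate.

    P(f) = sum_{|k|<=tau} w(k) R(k) e^{-j2pi f k} with the biased (1/L)
    correlation estimates and a non-negative lag window (Parzen default).
    The two-sided integral of each diagonal estimate equals the sample
    variance (lag-0 Fourier identity).
    """
    L = pair.L
    tau = int(truncation_lag)
    if not 1 <= tau <= L - 1:
        raise ValueError(f"truncation lag must be in [1, {L - 1}]")
    if window not in _LAG_WINDOWS:
        raise ValueError(f"unknown window {window!r}")
    k = np.arange(0, tau + 1)
    w = _LAG_WINDOWS[window](k, tau)
    lags, R12 = cross_correlation(pair, tau)

    def _auto(y):
        return np.array([y[m:] @ y[: L - m] / L for m in range(tau + 1)])

    R11, R22 = _auto(pair.y1), _auto(pair.y2)
    f = _grid(n_freq)
    ph = np.exp(-2j * np.pi * np.outer(f, k))  # (n_f, tau+1)
    cosk = ph.real

    P11 = R11[0] + 2 * cosk[:, 1:] @ (w[1:] * R11[1:])
    P22 = R22[0] + 2 * cosk[:, 1:] @ (w[1:] * R22[1:])
    pos = R12[tau:]  # R12(k), k = 0..tau
    neg = R12[tau::-1]  # R12(-k), k = 0..tau
    P12 = (w[0] * pos[0]
           + ph[:, 1:] @ (w[1:] * pos[1:])
           + ph[:, 1:].conj() @ (w[1:] * neg[1:]))
    P = np.empty((n_freq, 2, 2), dtype=complex)
    P[:, 0, 0] = P11
    P[:, 1, 1] = P22
    P[:, 0, 1] = P12
    P[:, 1, 0] = np.conj(P12)
    return SpectralDecomposition(fgrid=f, fs=pair.fs, P=P,
                                 meta={"estimator": "weighted_covariance",
                                       "window": window, "tau": tau})


def parzen_truncation_lag(bandwidth: float, fs: float = 1.0) -> tuple[float, int]:
    """Truncation lag for a Parzen window of given spectral bandwidth.

    Inverts Bw = 1.273 fs / tau.  Returns (raw value, integer lag) where
    the integer lag is the raw value ceiled and floored at 1.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    raw = 1.273 * fs / bandwidth
    return raw, max(1, math.ceil(raw))
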