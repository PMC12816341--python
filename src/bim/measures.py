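"""Time-domain coupling and causality measures for linear bivariate models.

Geweke's log-variance-ratio measures: total dependence F_td, directional
Granger causalities F_gc, and instantaneous causality F_ic, satisfying
F_td = F_gc(1->2) + F_gc(2->1) + F_ic.  For jointly Gaussian processes
each F is twice the corresponding information measure: mutual information
rate I_mir, transfer entropies T, instantaneous transfer I_it (nats).

Also hosts the static correlation tools (Pearson coefficient, biased
cross-correlation function) and the Gaussian mutual-information closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .varmodel import ARXModel, RestrictedModel

__all__ = [
    "TimeDomainMeasures",
    "pearson",
    "cross_correlation",
    "mi_gaussian",
    "time_domain_measures",
]


@dataclass
class TimeDomainMeasures:
    """Geweke measures (F_*) and their information halves (I_*, T_*), nats.

    ``raw`` keeps unclipped values: finite-sample Granger-causality
    estimates can dip below zero; reported values are clipped at 0 while
    the raw estimate stays available for diagnostics.
    """

    F_td: float
    F_gc_12: float
    F_gc_21: float
    F_ic: float
    raw: dict = field(default_factory=dict)

    @property
    def I_mir(self) -> float:
        return self.F_td / 2.0

    @property
    def T_12(self) -> float:
        return self.F_gc_12 / 2.0

    @property
    def T_21(self) -> float:
        return self.F_gc_21 / 2.0

    @property
    def I_it(self) -> float:
        return self.F_ic / 2.0

    def as_dict(self, bits: bool = False) -> dict:
        scale = 1.0 / np.log(2.0) if bits else 1.0
        return {
            "F_td": self.F_td * scale,
            "F_gc_12": self.F_gc_12 * scale,
            "F_gc_21": self.F_gc_21 * scale,
            "F_ic": self.F_ic * scale,
            "I_mir": self.I_mir * scale,
            "T_12": self.T_12 * scale,
            "T_21": self.T_21 * scale,
            "I_it": self.I_it * scale,
        }


def pearson(pair) -> float:
    """Zero-lag Pearson correlation coefficient between the two series."""
    y1, y2 = pair.y1, pair.y2
    s1, s2 = y1.std(ddof=0), y2.std(ddof=0)
    if s1 < 1e-14 or s2 < 1e-14:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.mean((y1 - y1.mean()) * (y2 - y2.mean())) / (s1 * s2))
    return float(np.clip(r, -1.0, 1.0))


def cross_correlation(pair, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Biased sample cross-correlation R(k) = (1/L) sum y1_n y2_{n-k}.

    Returns (lags, R) for k = -max_lag..max_lag.  The 1/L normalization
    yields a positive-semidefinite sequence (the one the weighted-covariance
    spectral estimator requires); R(-k) equals the cross-correlation with
    the roles of the series exchanged.
    """
    L = pair.L
    if not 0 <= max_lag <= L - 1:
        raise ValueError(f"max_lag must be in [0, {L - 1}]")
    y1, y2 = pair.y1, pair.y2
    lags = np.arange(-max_lag, max_lag + 1)
    R = np.empty(lags.size)
    for idx, k in enumerate(lags):
        if k >= 0:
            R[idx] = y1[k:] @ y2[: L - k] / L
        else:
            R[idx] = y1[: L + k] @ y2[-k:] / L
    return lags, R


def mi_gaussian(rho: float) -> float:
    """Mutual information of a bivariate Gaussian: -0.5 ln(1 - rho^2) nats."""
    if abs(rho) >= 1.0:
        raise ValueError("degenerate distribution: |rho| must be < 1")
    return float(-0.5 * np.log1p(-rho * rho))


def time_domain_measures(
    full: ARXModel,
    r1: RestrictedModel,
    r2: RestrictedModel,
    clip: bool = False,
) -> TimeDomainMeasures:
    """Geweke time-domain measures from full + restricted model variances.

    F_td = ln(l1 l2 / |Sigma_U|), F_gc(1->2) = ln(l2 / s2^2),
    F_gc(2->1) = ln(l1 / s1^2), F_ic = ln(s1^2 s2^2 / |Sigma_U|),
    with l_i the restricted innovation variances and s_i^2 the full-model
    ones.  The decomposition F_td = F_gc_12 + F_gc_21 + F_ic is exact.
    """
    if r1.target != 1 or r2.target != 2:
        raise ValueError("r1 must restrict process 1 and r2 process 2")
    S = full.Sigma_U
    det = float(np.linalg.det(S))
    if det <= 0:
        raise ValueError("innovation covariance not positive definite")
    s1, s2 = float(S[0, 0]), float(S[1, 1])
    gc12 = float(np.log(r2.lambda2 / s2))
    gc21 = float(np.log(r1.lambda2 / s1))
    ic = float(np.log(s1 * s2 / det))
    td = gc12 + gc21 + ic  # identical to ln(l1 l2 / det) by construction
    raw = {"F_td": td, "F_gc_12": gc12, "F_gc_21": gc21, "F_ic": ic}
    if clip:
        gc12, gc21, ic, td = (max(v, 0.0) for v in (gc12, gc21, ic, td))
    return TimeDomainMeasures(F_td=td, F_gc_12=gc12, F_gc_21=gc21, F_ic=ic,
                              raw=raw)
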