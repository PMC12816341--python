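"""Seeded generators of bivariate AR benchmarks with known population measures.

Every estimator in this package can be checked against a ground truth: a
stable bivariate AR model is specified exactly, realizations are drawn
from it, and the population values of every coupling/causality measure
are computed analytically from the generating parameters
(:func:`population_measures`).  :func:`benchmark_physio` builds the
two-oscillator benchmark used throughout the tests: each process carries
AR(2) self-dynamics with a complex pole pair (one oscillator in the LF
range, one in the HF range of cardiovascular variability) and the
processes interact through lag-1 cross-couplings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import TimeSeriesPair
from .measures import time_domain_measures
from .report import MeasureReport
from .spectral import band_measures, spectral_pipeline
from .varmodel import ARXModel, companion, restrict_ss

__all__ = [
    "SimulationSpec",
    "simulate_arx",
    "benchmark_physio",
    "benchmark_unidirectional",
    "random_stable_model",
    "population_measures",
]


@dataclass
class SimulationSpec:
    """Ground-truth model plus realization settings."""

    model: ARXModel
    L: int = 2000
    n_transient: int = 1000
    seed: int | None = None
    fs: float = 1.0
    description: str = ""
    innovations: str = "gaussian"  # or "uniform"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.model.stable:
            raise ValueError("simulation requires a stable model")
        if self.innovations not in ("gaussian", "uniform"):
            raise ValueError("innovations must be 'gaussian' or 'uniform'")


def simulate_arx(spec: SimulationSpec) -> TimeSeriesPair:
    """Draw one realization of the bivariate AR model.

    Innovations are Gaussian by default (unit-variance uniform optionally,
    to probe estimator robustness), correlated through the Cholesky factor
    of Sigma_U.  ``n_transient`` initial samples are discarded.
    """
    model = spec.model
    rng = np.random.default_rng(spec.seed)
    p = model.p
    total = spec.L + spec.n_transient + p
    if spec.innovations == "gaussian":
        e = rng.standard_normal((total, 2))
    else:
        e = rng.uniform(-np.sqrt(3), np.sqrt(3), (total, 2))
    chol = np.linalg.cholesky(model.Sigma_U)
    u = e @ chol.T
    y = np.zeros((total, 2))
    A = model.A
    for n in range(p, total):
        acc = u[n].copy()
        for k in range(p):
            acc += A[k] @ y[n - 1 - k]
        y[n] = acc
    out = y[p + spec.n_transient:]
    return TimeSeriesPair(out[:, 0], out[:, 1], fs=spec.fs,
                          meta={"seed": spec.seed,
                                "description": spec.description})


def _ar2_coeffs(rho: float, f: float) -> tuple[float, float]:
    """AR(2) coefficients placing a complex pole pair at rho e^{+-j2pi f}."""
    return 2 * rho * np.cos(2 * np.pi * f), -rho * rho


def benchmark_physio(coupling_12: float = 0.5, coupling_21: float = 0.0,
                     rho1: float = 0.8, f1: float = 0.1,
                     rho2: float = 0.9, f2: float = 0.25,
                     Sigma_U: np.ndarray | None = None,
                     L: int = 2000, seed: int | None = None) -> SimulationSpec:
    """Two coupled stochastic oscillators mimicking LF/HF interactions.

    Process 1 oscillates at normalized frequency f1 (pole radius rho1),
    process 2 at f2 (radius rho2); cross-couplings act at lag 1 with gains
    ``coupling_12`` (1 -> 2) and ``coupling_21`` (2 -> 1).
    """
    for rho, f in ((rho1, f1), (rho2, f2)):
        if not 0 <= rho < 1:
            raise ValueError("pole radius must lie in [0, 1)")
        if not 0 < f < 0.5:
            raise ValueError("oscillation frequency must lie in (0, 0.5)")
    a11, a12 = _ar2_coeffs(rho1, f1)
    a21, a22 = _ar2_coeffs(rho2, f2)
    A = np.zeros((2, 2, 2))
    A[0, 0, 0], A[1, 0, 0] = a11, a12
    A[0, 1, 1], A[1, 1, 1] = a21, a22
    A[0, 1, 0] = coupling_12  # past of 1 drives present of 2
    A[0, 0, 1] = coupling_21
    Sigma = np.eye(2) if Sigma_U is None else np.asarray(Sigma_U, float)
    model = ARXModel(p=2, A=A, Sigma_U=Sigma)
    return SimulationSpec(model=model, L=L, seed=seed,
                          description="coupled stochastic oscillators")


def benchmark_unidirectional(c: float = 1.0,
                             Sigma_U: np.ndarray | None = None,
                             L: int = 2000,
                             seed: int | None = None) -> SimulationSpec:
    """Closed-form benchmark: Y1 white noise, Y2_n = c Y1_{n-1} + U2_n.

    With unit variances and c = 1 the population values are
    F_gc(1->2) = ln 2, T(1->2) = ln(2)/2, coherence^2 = 0.5 and a flat
    spectral Granger profile at ln 2.
    """
    A = np.zeros((1, 2, 2))
    A[0, 1, 0] = c
    Sigma = np.eye(2) if Sigma_U is None else np.asarray(Sigma_U, float)
    return SimulationSpec(model=ARXModel(p=1, A=A, Sigma_U=Sigma), L=L,
                          seed=seed, description="unidirectional white benchmark")


def _min_phase_diagonals(A: np.ndarray) -> bool:
    """True when each self-regression polynomial 1 - sum a_ii,k z^-k has all
    roots inside the unit circle.

    A stable VAR can still have a non-minimum-phase self-polynomial (the
    companion matrix is non-normal); in that case the one-process Wold
    innovation spectrum picks up the outside roots and the directional
    spectral profiles no longer integrate back to their time-domain
    measures.  The generator enforces this condition so population
    identities hold exactly.
    """
    p = A.shape[0]
    for i in (0, 1):
        roots = np.roots(np.concatenate([[1.0], -A[:, i, i]]))
        if p and np.any(np.abs(roots) >= 1.0 - 1e-8):
            return False
    return True


def random_stable_model(rng: np.random.Generator, p: int | None = None,
                        strictly_causal: bool = True,
                        max_radius: float = 0.9) -> ARXModel:
    """Random stable bivariate AR model (for property tests and identities).

    Coefficients are drawn Gaussian and, if needed, shrunk lag-wise
    (A_k <- A_k s^k) until the companion spectral radius is below
    ``max_radius``; that rescaling maps poles z -> z/s, so stability is
    reached in a few steps.  Draws are rejected until both self-regression
    polynomials are minimum phase (see :func:`_min_phase_diagonals`).
    Sigma_U is diagonal under strict causality, otherwise a random
    correlated SPD matrix.
    """
    if p is None:
        p = int(rng.integers(1, 5))
    for _ in range(500):
        A = rng.normal(scale=0.5, size=(p, 2, 2))
        for _ in range(200):
            rad = np.max(np.abs(np.linalg.eigvals(companion(A))))
            if rad < max_radius:
                break
            s = max_radius / rad * 0.95
            A = A * (s ** np.arange(1, p + 1))[:, None, None]
        if _min_phase_diagonals(A):
            break
    if strictly_causal:
        Sigma = np.diag(rng.uniform(0.5, 2.0, 2))
    else:
        r = rng.uniform(-0.7, 0.7)
        s1, s2 = rng.uniform(0.5, 2.0, 2)
        Sigma = np.array([[s1, r * np.sqrt(s1 * s2)],
                          [r * np.sqrt(s1 * s2), s2]])
    return ARXModel(p=p, A=A, Sigma_U=Sigma)


def population_measures(model: ARXModel, n_freq: int = 1001,
                        bands: list[tuple[float, float]] | None = None,
                        fs: float = 1.0) -> MeasureReport:
    """Ground-truth measures computed analytically from model parameters.

    Restricted innovation variances come from the exact state-space /
    Riccati route; spectral profiles from the factorized PSD.  The result
    is the oracle every estimator is tested against.
    """
    r1 = restrict_ss(model, 1)
    r2 = restrict_ss(model, 2)
    td = time_domain_measures(model, r1, r2)
    spec = spectral_pipeline(model, n_freq=n_freq, fs=fs)
    band_list = [band_measures(spec, b) for b in (bands or [(0.0, fs / 2)])]
    return MeasureReport(domain="population", measures=td, bands=band_list,
                         model_meta={"p": model.p,
                                     "spectral_radius": model.spectral_radius,
                                     "strictly_causal": model.strictly_causal})
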