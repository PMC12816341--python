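"""Model/Results interface tying the whole pipeline together.

``BivariateInteractionModel`` holds a preprocessed pair of series;
``fit()`` identifies the bivariate AR model (with optional order
selection), derives the restricted models, and returns a
``BivariateInteractionResults`` carrying the time-domain measures, the
spectral decomposition, band-integrated information measures, and methods
for surrogate significance testing, plotting and serialization.

Model-free estimates (KNN / binning / permutation) are available through
``estimate_modelfree`` on the model object, since they bypass the linear
fit entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import modelfree, surrogates
from .dataio import TimeSeriesPair, preprocess
from .measures import TimeDomainMeasures, time_domain_measures
from .report import MeasureReport
from .spectral import (DEFAULT_NFREQ, SpectralDecomposition, band_measures,
                       spectral_pipeline)
from .varmodel import (ARXModel, RestrictedModel, default_truncation,
                       identify_arx, restrict_ss, restrict_yw, select_order)

__all__ = ["BivariateInteractionModel", "BivariateInteractionResults"]


class BivariateInteractionModel:
    """Coupling/causality analysis of two stationary time series.

    Parameters
    ----------
    y1, y2 : array-like
        The two series (process 1 is the conventional "driver" in the
        1->2 direction labels).
    fs : float
        Sampling frequency; 1 gives a normalized frequency axis.
    labels : tuple of str
        Channel names used in summaries.
    demean, standardize, highpass_cutoff
        Preprocessing applied once at construction (see
        :func:`bim.dataio.preprocess`).
    """

    def __init__(self, y1, y2, fs: float = 1.0, labels=("y1", "y2"),
                 demean: bool = True, standardize: bool = False,
                 highpass_cutoff: float | None = None):
        pair = TimeSeriesPair(np.asarray(y1, float), np.asarray(y2, float),
                              fs=fs, labels=tuple(labels))
        self.pair = preprocess(pair, detrend=demean, standardize=standardize,
                               highpass_cutoff=highpass_cutoff)

    @classmethod
    def from_pair(cls, pair: TimeSeriesPair, **kw) -> "BivariateInteractionModel":
        return cls(pair.y1, pair.y2, fs=pair.fs, labels=pair.labels, **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, columns=None, fs: float = 1.0,
                       **kw) -> "BivariateInteractionModel":
        cols = list(df.columns[:2]) if columns is None else list(columns)
        return cls(df[cols[0]].to_numpy(float), df[cols[1]].to_numpy(float),
                   fs=fs, labels=(str(cols[0]), str(cols[1])), **kw)

    # -- linear route ------------------------------------------------------

    def fit(self, order: int | None = None, max_order: int = 8,
            criterion: str = "aic", restriction: str = "yw",
            q: int | None = None, n_freq: int = DEFAULT_NFREQ,
            bands: list[tuple[float, float]] | None = None,
            ) -> "BivariateInteractionResults":
        """Identify the linear model and compute every linear measure.

        ``order=None`` scans 1..max_order with the given information
        criterion.  ``restriction`` chooses the restricted-model route:
        "yw" (Yule-Walker, truncation q, default max(20, 2p)) or "ss"
        (state-space / Riccati, exact).
        """
        if order is None:
            order, curve = select_order(self.pair, max_order, criterion)
            order_meta = {"criterion": criterion, "max_order": max_order,
                          "curve": curve.tolist()}
        else:
            order_meta = {"criterion": "fixed"}
        arx = identify_arx(self.pair, order)
        if restriction == "yw":
            qq = q if q is not None else default_truncation(order)
            r1 = restrict_yw(arx, 1, qq)
            r2 = restrict_yw(arx, 2, qq)
        elif restriction == "ss":
            r1 = restrict_ss(arx, 1)
            r2 = restrict_ss(arx, 2)
        else:
            raise ValueError("restriction must be 'yw' or 'ss'")
        td = time_domain_measures(arx, r1, r2)
        spec = spectral_pipeline(arx, n_freq=n_freq, fs=self.pair.fs)
        band_defs = bands if bands is not None else []
        band_list = [band_measures(spec, b) for b in band_defs]
        return BivariateInteractionResults(
            model=self, arx=arx, restricted=(r1, r2), measures=td,
            spectral=spec, bands=band_list,
            meta={"order_selection": order_meta, "restriction": restriction})

    # -- model-free route --------------------------------------------------

    def estimate_modelfree(self, method: str = "knn", **kw):
        """KNN / binning / permutation estimates of T_12, T_21, I_it, I_mir."""
        fns = {"knn": modelfree.knn_measures,
               "binning": modelfree.binning_measures,
               "perm": modelfree.permutation_measures}
        if method not in fns:
            raise ValueError(f"method must be one of {sorted(fns)}")
        return fns[method](self.pair, **kw)


@dataclass
class BivariateInteractionResults:
    """Fitted linear model, measures, spectra and significance testing."""

    model: BivariateInteractionModel
    arx: ARXModel
    restricted: tuple[RestrictedModel, RestrictedModel]
    measures: TimeDomainMeasures
    spectral: SpectralDecomposition
    bands: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def pair(self) -> TimeSeriesPair:
        return self.model.pair

    def report(self) -> MeasureReport:
        return MeasureReport(domain="time", measures=self.measures,
                             bands=self.bands,
                             model_meta={"p": self.arx.p,
                                         "restriction": self.meta.get("restriction"),
                                         "L": self.pair.L,
                                         "fs": self.pair.fs})

    def test_significance(self, which: str = "T_12", n_s: int = 100,
                          alpha: float = 0.05, tau_min: int = 20,
                          seed: int | None = None,
                          band: tuple[float, float] | None = None):
        """Surrogate test of one measure (optionally band-integrated).

        ``which`` is one of T_12, T_21, I_it, I_mir.  The measure is
        re-estimated on every surrogate pair with the same model order and
        restriction route as this fit.
        """
        p = self.arx.p
        restriction = self.meta.get("restriction", "yw")
        fs = self.pair.fs

        def measure_fn(pair):
            m = BivariateInteractionModel.from_pair(pair)
            res = m.fit(order=p, restriction=restriction,
                        n_freq=self.spectral.fgrid.size if band else 64)
            if band is None:
                return getattr(res.measures, which)
            bm = band_measures(res.spectral, band)
            return getattr(bm, which)

        return surrogates.significance_test(
            self.pair, measure_fn, n_s=n_s, alpha=alpha, tau_min=tau_min,
            seed=seed)

    def summary(self) -> str:
        lab1, lab2 = self.pair.labels
        m = self.measures
        lines = [
            "Bivariate interaction analysis (linear parametric)",
            "=" * 52,
            f"series: {lab1}, {lab2}   L = {self.pair.L}   fs = {self.pair.fs}",
            f"VAR order p = {self.arx.p}   restriction = "
            f"{self.meta.get('restriction')}   stable = {self.arx.stable}",
            f"innovation covariance |Sigma_U| = "
            f"{np.linalg.det(self.arx.Sigma_U):.6g}",
            "-" * 52,
            "measure                     F (log-ratio)   I (nats)",
        ]
        rows = [("total dependence", m.F_td, m.I_mir),
                (f"GC {lab1} -> {lab2}", m.F_gc_12, m.T_12),
                (f"GC {lab2} -> {lab1}", m.F_gc_21, m.T_21),
                ("instantaneous", m.F_ic, m.I_it)]
        for name, F, I in rows:
            lines.append(f"{name:<28}{F:>13.4f}   {I:>8.4f}")
        for b in self.bands:
            lines.append(
                f"band {b.band[0]:.3g}-{b.band[1]:.3g} Hz: I_mir={b.I_mir:.4f} "
                f"T_12={b.T_12:.4f} T_21={b.T_21:.4f} I_it={b.I_it:.4f}")
        return "\n".join(lines)

    def plot_spectral(self, ax=None):
        """Plot the Geweke spectral profiles (TD, both GCs, IC)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 4, figsize=(12, 2.8), sharex=True)
        s = self.spectral
        f = s.f_hz
        names = [("f_td", "total dependence"), ("f_gc_12", "GC 1->2"),
                 ("f_gc_21", "GC 2->1"), ("f_ic", "instantaneous")]
        for a, (attr, title) in zip(np.ravel(ax), names):
            a.plot(f, getattr(s, attr), color="crimson")
            a.set_title(title)
            a.set_xlabel("f [Hz]" if s.fs != 1 else "normalized f")
        return ax
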