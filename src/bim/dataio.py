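"""Reading, writing and preprocessing of bivariate time series.

All downstream measures assume two aligned, zero-mean, wide-sense
stationary series sampled at a common rate.  :class:`TimeSeriesPair` is the
container enforcing that contract; :func:`preprocess` brings raw recordings
into it (detrending with a zero-phase high-pass filter, mean removal,
normalization to unit variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = ["TimeSeriesPair", "load_pair", "write_pair", "preprocess"]

#: shortest series length accepted; below this no measure here is meaningful
MIN_LENGTH = 50


@dataclass
class TimeSeriesPair:
    """Two aligned real-valued series with a common sampling frequency.

    Parameters
    ----------
    y1, y2 : ndarray
        Equal-length, finite, real-valued samples.
    fs : float
        Sampling frequency in Hz (or 1/beat for beat-to-beat series).
        Defaults to 1, which puts all spectral axes on normalized
        frequency in [0, 0.5].
    labels : tuple of str
        Short names for the two channels.
    """

    y1: np.ndarray
    y2: np.ndarray
    fs: float = 1.0
    labels: tuple[str, str] = ("y1", "y2")
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y1 = np.asarray(self.y1, dtype=float).ravel()
        self.y2 = np.asarray(self.y2, dtype=float).ravel()
        if self.y1.size != self.y2.size:
            raise ValueError(
                f"unequal lengths: y1 has {self.y1.size}, y2 has {self.y2.size}"
            )
        if self.y1.size < MIN_LENGTH:
            raise ValueError(
                f"series too short: {self.y1.size} samples, need >= {MIN_LENGTH}"
            )
        if not (np.all(np.isfinite(self.y1)) and np.all(np.isfinite(self.y2))):
            raise ValueError("non-finite values in input series")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")

    @property
    def L(self) -> int:
        return self.y1.size

    def data(self) -> np.ndarray:
        """Return the (L, 2) sample matrix [y1, y2]."""
        return np.column_stack([self.y1, self.y2])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.labels[0]: self.y1, self.labels[1]: self.y2})


def load_pair(
    path: str | Path,
    columns: Sequence[str | int] | None = None,
    fs: float = 1.0,
) -> TimeSeriesPair:
    """Read a two-column CSV/TSV file into a :class:`TimeSeriesPair`.

    The file must have a single header row and use '.' as decimal mark;
    the delimiter (comma or tab) is sniffed from the extension/content.
    ``columns`` selects two columns by name or position (default: first two).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        # wrong delimiter guess: retry with the other one
        df = pd.read_csv(path, sep="\t" if sep == "," else ",")
    if columns is None:
        columns = list(df.columns[:2])
    cols = []
    for c in columns:
        cols.append(df.columns[c] if isinstance(c, int) else c)
    if len(cols) != 2:
        raise ValueError("exactly two columns must be selected")
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"column {c!r} not found in {path.name}")
    sub = df[cols]
    for c in cols:
        col = pd.to_numeric(sub[c], errors="coerce")
        bad = np.nonzero(col.isna().to_numpy())[0]
        if bad.size:
            raise ValueError(
                f"column {c!r}: missing or non-numeric value at row {bad[0] + 2} "
                f"of {path.name}"
            )
    y1 = pd.to_numeric(sub[cols[0]]).to_numpy(float)
    y2 = pd.to_numeric(sub[cols[1]]).to_numpy(float)
    return TimeSeriesPair(y1, y2, fs=fs, labels=(str(cols[0]), str(cols[1])))


def write_pair(pair: TimeSeriesPair, path: str | Path) -> Path:
    """Write the pair as a delimited text file (inverse of :func:`load_pair`)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    pair.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


def _highpass(x: np.ndarray, cutoff_norm: float) -> np.ndarray:
    """First-order Butterworth high-pass applied forward-backward (zero phase).

    ``cutoff_norm`` is the cutoff in cycles/sample (normalized frequency,
    0 < f < 0.5).  filtfilt keeps the length and cancels the group delay.
    """
    if not 0 < cutoff_norm < 0.5:
        raise ValueError("highpass cutoff must lie in (0, 0.5) normalized frequency")
    b, a = signal.butter(1, 2 * cutoff_norm, btype="highpass")
    return signal.filtfilt(b, a, x)


def preprocess(
    pair: TimeSeriesPair,
    detrend: bool = True,
    standardize: bool = False,
    highpass_cutoff: float | None = None,
) -> TimeSeriesPair:
    """Bring a raw pair to the zero-mean (optionally unit-variance) contract.

    Steps, in order: zero-phase high-pass filtering when ``highpass_cutoff``
    (normalized frequency) is given, mean removal when ``detrend``, division
    by the sample standard deviation when ``standardize``.  Length is always
    preserved.  Demean + standardize is idempotent.
    """
    out = []
    for x, lab in zip((pair.y1, pair.y2), pair.labels):
        x = np.asarray(x, float)
        if highpass_cutoff is not None:
            x = _highpass(x, highpass_cutoff)
        if detrend or highpass_cutoff is not None:
            x = x - x.mean()
        if standardize:
            s = x.std(ddof=0)
            if s < 1e-14:
                raise ValueError(f"zero variance in series {lab!r}: cannot standardize")
            x = x / s
        out.append(x)
    meta = dict(pair.meta)
    meta["preprocess"] = {
        "detrend": bool(detrend),
        "standardize": bool(standardize),
        "highpass_cutoff": highpass_cutoff,
        "filter": "butterworth order 1, forward-backward (zero phase)"
        if highpass_cutoff is not None
        else None,
    }
    return replace(pair, y1=out[0], y2=out[1], meta=meta)
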