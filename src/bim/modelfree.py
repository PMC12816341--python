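"""Model-free estimation of transfer entropy, instantaneous transfer and
mutual information rate.

Three estimators of the same information-theoretic decomposition
MIR = TE(1->2) + TE(2->1) + IT:

* ``knn``     -- shared-radius k-nearest-neighbour estimator: neighbours are
  found once in the full joint space [Y1_n, Y2_n, past1, past2] under the
  Chebyshev norm, then counted by range search in every lower-dimensional
  projection, so the digamma bias terms cancel across entropy differences.
* ``binning`` -- plug-in entropies of uniformly quantized amplitudes.
* ``perm``    -- plug-in entropies of ordinal (rank) patterns.

Past states are represented by uniform embeddings (q lags spaced tau
samples apart) or by a non-uniform embedding selected greedily by
conditional mutual information with a shuffle-based stopping rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

__all__ = [
    "EmbeddingSpec",
    "Embedded",
    "ModelFreeMeasures",
    "build_embedding_uniform",
    "knn_entropy",
    "knn_measures",
    "quantize",
    "binning_measures",
    "rank_pattern",
    "permutation_measures",
    "select_embedding_nonuniform",
]


@dataclass
class EmbeddingSpec:
    """Which past samples represent the history of each process.

    ``candidates`` lists the (process, lag) pairs actually used, ordered;
    for a uniform embedding these are lags tau, 2*tau, ..., q*tau of both
    processes.
    """

    q: int
    tau: int = 1
    candidates: list[tuple[int, int]] = field(default_factory=list)
    mode: str = "uniform"

    def __post_init__(self):
        if self.q < 1 and self.mode == "uniform":
            raise ValueError("q must be >= 1")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if not self.candidates and self.mode == "uniform":
            self.candidates = [(proc, lag * self.tau)
                               for proc in (1, 2)
                               for lag in range(1, self.q + 1)]


@dataclass
class Embedded:
    """Aligned present values and past-state matrices (N usable samples)."""

    y1n: np.ndarray  # (N,)
    y2n: np.ndarray  # (N,)
    X1: np.ndarray  # (N, q) past of process 1, lags tau..q*tau
    X2: np.ndarray  # (N, q)

    @property
    def N(self) -> int:
        return self.y1n.size


@dataclass
class ModelFreeMeasures:
    """Transfer entropies, instantaneous transfer and MIR in nats."""

    T_12: float
    T_21: float
    I_it: float
    I_mir: float
    estimator: str
    hyperparams: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"T_12": self.T_12, "T_21": self.T_21, "I_it": self.I_it,
                "I_mir": self.I_mir, "estimator": self.estimator,
                "hyperparams": self.hyperparams}


def build_embedding_uniform(pair_or_data, q: int, tau: int = 1) -> Embedded:
    """Uniform delay embedding of both series.

    For each usable time n >= q*tau the past vector of process i is
    [y_i(n-tau), ..., y_i(n-q*tau)]; N = L - q*tau samples remain.
    """
    if isinstance(pair_or_data, np.ndarray):
        data = pair_or_data
    else:
        data = pair_or_data.data()
    L = data.shape[0]
    m = q * tau
    if L <= m + 1:
        raise ValueError(f"series too short: need L > {m + 1} for q={q}, tau={tau}")
    idx = np.arange(m, L)
    lag_cols = [idx - j * tau for j in range(1, q + 1)]
    X1 = np.column_stack([data[c, 0] for c in lag_cols])
    X2 = np.column_stack([data[c, 1] for c in lag_cols])
    return Embedded(y1n=data[idx, 0], y2n=data[idx, 1], X1=X1, X2=X2)


# ---------------------------------------------------------------------------
# k-nearest-neighbour estimator
# ---------------------------------------------------------------------------

def _strict_radius(d: np.ndarray) -> np.ndarray:
    """Largest radius strictly below d (neighbour counts use distance < d)."""
    return np.nextafter(d, 0.0)


def _count_within(X: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Per-point neighbour counts within radius r (max-norm, self excluded)."""
    tree = cKDTree(X)
    n = tree.query_ball_point(X, r, p=np.inf, return_length=True)
    return n - 1


def knn_entropy(x: np.ndarray, k: int = 10) -> float:
    """Kozachenko-Leonenko differential entropy estimate (nats).

    H = psi(N) - psi(k) + d <log eps_n>, eps_n twice the Chebyshev distance
    to the k-th neighbour.
    """
    X = np.asarray(x, float)
    if X.ndim == 1:
        X = X[:, None]
    N, d = X.shape
    if not 1 <= k < N:
        raise ValueError("k must satisfy 1 <= k < N")
    tree = cKDTree(X)
    dist, _ = tree.query(X, k=k + 1, p=np.inf)
    eps = 2.0 * dist[:, -1]
    if np.any(eps <= 0):
        raise ValueError("duplicate points: entropy estimate undefined "
                         "(consider jitter)")
    return float(digamma(N) - digamma(k) + d * np.mean(np.log(eps)))


def knn_measures(pair, spec: EmbeddingSpec | None = None, k: int = 10,
                 q: int = 3, tau: int = 1, jitter: bool = False,
                 seed: int = 0) -> ModelFreeMeasures:
    """Shared-radius KNN estimates of TE (both directions), IT and MIR.

    The k-th neighbour distance in the full joint space sets a per-sample
    radius; every projected count uses that same radius (strict
    inequality), so MIR = T_12 + T_21 + I_it holds exactly by construction.
    Each series is standardized internally before the Chebyshev search, so
    the estimates are invariant under affine rescaling of either series.
    ``jitter`` adds seeded uniform noise of amplitude 1e-10 sd to break
    massive ties in discrete-valued data; off by default.
    """
    if spec is not None:
        q, tau = spec.q, spec.tau
    data = pair.data().copy()
    data = (data - data.mean(axis=0)) / data.std(axis=0)
    if jitter:
        rng = np.random.default_rng(seed)
        data += rng.uniform(-1, 1, data.shape) * 1e-10 * data.std(axis=0)
    emb = build_embedding_uniform(data, q, tau)
    N = emb.N
    if not 1 <= k < N:
        raise ValueError(f"k={k} must be < number of embedded samples N={N}")

    full = np.column_stack([emb.y1n, emb.y2n, emb.X1, emb.X2])
    dist, _ = cKDTree(full).query(full, k=k + 1, p=np.inf)
    r = _strict_radius(dist[:, -1])
    if np.any(dist[:, -1] <= 0):
        raise ValueError("duplicate joint points: use jitter=True")

    n_1q = _count_within(emb.X1, r)
    n_2q = _count_within(emb.X2, r)
    n_12q = _count_within(np.column_stack([emb.X1, emb.X2]), r)
    n_1n1q = _count_within(np.column_stack([emb.y1n, emb.X1]), r)
    n_2n2q = _count_within(np.column_stack([emb.y2n, emb.X2]), r)
    n_1n12q = _count_within(np.column_stack([emb.y1n, emb.X1, emb.X2]), r)
    n_2n12q = _count_within(np.column_stack([emb.y2n, emb.X1, emb.X2]), r)

    psi = digamma
    T12 = float(np.mean(psi(n_2n12q + 1) - psi(n_12q + 1)
                        - psi(n_2n2q + 1) + psi(n_2q + 1)))
    T21 = float(np.mean(psi(n_1n12q + 1) - psi(n_12q + 1)
                        - psi(n_1n1q + 1) + psi(n_1q + 1)))
    IT = float(psi(k) + np.mean(psi(n_12q + 1) - psi(n_1n12q + 1)
                                - psi(n_2n12q + 1)))
    MIR = T12 + T21 + IT  # equals the direct shared-radius MIR estimator
    for name, v in (("T_12", T12), ("T_21", T21), ("I_it", IT), ("I_mir", MIR)):
        if not np.isfinite(v):
            raise ValueError(f"non-finite KNN estimate for {name} "
                             f"(N={N}, k={k}, q={q}, tau={tau})")
    return ModelFreeMeasures(T_12=T12, T_21=T21, I_it=IT, I_mir=MIR,
                             estimator="knn",
                             hyperparams={"k": k, "q": q, "tau": tau, "N": N})


# ---------------------------------------------------------------------------
# binning estimator
# ---------------------------------------------------------------------------

def quantize(series: np.ndarray, b: int) -> np.ndarray:
    """Uniform amplitude quantization onto the alphabet {1..b}.

    Value v maps to bin i iff w_min + (i-1) r <= v < w_min + i r with
    r = (w_max - w_min)/b; the maximum value closes the top bin (-> b).
    """
    x = np.asarray(series, float)
    if b < 2:
        raise ValueError("need at least 2 bins")
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-14:
        raise ValueError("constant series cannot be quantized")
    r = (hi - lo) / b
    sym = np.floor((x - lo) / r).astype(np.int64) + 1
    return np.minimum(sym, b)


def discrete_entropy(symbols: np.ndarray) -> float:
    """Plug-in Shannon entropy (nats) of rows of a discrete symbol matrix."""
    X = np.asarray(symbols)
    if X.ndim == 1:
        X = X[:, None]
    _, counts = np.unique(X, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def _plugin_decomposition(y1n, y2n, X1, X2, estimator, hyper):
    """TE/IT/MIR from plug-in entropies of discrete symbol blocks."""
    H = discrete_entropy
    c = np.column_stack
    H_12q = H(c([X1, X2]))
    H_1n12q = H(c([y1n, X1, X2]))
    H_2n12q = H(c([y2n, X1, X2]))
    T12 = H(c([y2n, X2])) - H(X2) - H_2n12q + H_12q
    T21 = H(c([y1n, X1])) - H(X1) - H_1n12q + H_12q
    IT = H_1n12q + H_2n12q - H_12q - H(c([y1n, y2n, X1, X2]))
    return ModelFreeMeasures(T_12=float(T12), T_21=float(T21), I_it=float(IT),
                             I_mir=float(T12 + T21 + IT),
                             estimator=estimator, hyperparams=hyper)


def binning_measures(pair, b: int = 3, q: int = 2,
                     tau: int = 1) -> ModelFreeMeasures:
    """TE/IT/MIR by uniform quantization and plug-in entropies.

    Each series is quantized once over its own range with b bins; the
    worst-case alphabet b^(2q+2) should stay comparable to the number of
    embedded samples (a warning is raised when b^(2q+1) exceeds it).
    """
    s1 = quantize(pair.y1, b)
    s2 = quantize(pair.y2, b)
    emb = build_embedding_uniform(np.column_stack([s1, s2]), q, tau)
    if b ** (2 * q + 1) > emb.N:
        warnings.warn(
            f"alphabet size b^(2q+1) = {b ** (2 * q + 1)} exceeds the "
            f"{emb.N} embedded samples: estimates will be strongly biased",
            stacklevel=2)
    return _plugin_decomposition(emb.y1n, emb.y2n, emb.X1, emb.X2,
                                 "binning", {"b": b, "q": q, "tau": tau,
                                             "N": emb.N})


# ---------------------------------------------------------------------------
# permutation estimator
# ---------------------------------------------------------------------------

def _rank_rows(W: np.ndarray) -> np.ndarray:
    """Rank pattern of every row; ties give the later element the smaller rank."""
    W = np.atleast_2d(np.asarray(W, float))
    n, d = W.shape
    tie = np.broadcast_to(-np.arange(d), (n, d))
    order = np.lexsort((tie, W), axis=1)
    ranks = np.empty((n, d), dtype=np.int64)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(1, d + 1), (n, d)),
                      axis=1)
    return ranks


def rank_pattern(window) -> np.ndarray:
    """Ordinal pattern of one window: rank of each element in ascending order.

    Equal values are resolved by giving the later element the smaller rank,
    e.g. [5, 5] -> [2, 1].
    """
    return _rank_rows(np.asarray(window, float)[None, :])[0]


def permutation_measures(pair, q: int = 3, tau: int = 1) -> ModelFreeMeasures:
    """TE/IT/MIR from ordinal patterns of the embedding vectors.

    Past states are the rank patterns of each process's q-sample window
    (alphabet q!); present-augmented states use the (q+1)-sample window
    including y_n (alphabet (q+1)!).  Entropy combination mirrors the
    binning estimator, with MIR composed as T_12 + T_21 + I_it.
    """
    if q < 2:
        warnings.warn("q >= 2 recommended for ordinal patterns (q=1 has a "
                      "single pattern)", stacklevel=2)
    emb = build_embedding_uniform(pair, q, tau)
    R1 = _rank_rows(emb.X1)  # q-patterns of process 1's past
    R2 = _rank_rows(emb.X2)
    R1n = _rank_rows(np.column_stack([emb.y1n, emb.X1]))  # (q+1)-patterns
    R2n = _rank_rows(np.column_stack([emb.y2n, emb.X2]))
    H = discrete_entropy
    c = np.column_stack
    H_12q = H(c([R1, R2]))
    H_1n12q = H(c([R1n, R2]))
    H_2n12q = H(c([R2n, R1]))
    T12 = H(R2n) - H(R2) - H_2n12q + H_12q
    T21 = H(R1n) - H(R1) - H_1n12q + H_12q
    IT = H_1n12q + H_2n12q - H_12q - H(c([R1n, R2n]))
    return ModelFreeMeasures(T_12=float(T12), T_21=float(T21), I_it=float(IT),
                             I_mir=float(T12 + T21 + IT), estimator="perm",
                             hyperparams={"q": q, "tau": tau, "N": emb.N})


# ---------------------------------------------------------------------------
# non-uniform embedding
# ---------------------------------------------------------------------------

def _ksg_cmi(x: np.ndarray, t: np.ndarray, Z: np.ndarray | None,
             k: int) -> float:
    """Shared-radius KNN conditional mutual information I(x; t | Z), nats."""
    cols = [x[:, None], t[:, None]]
    if Z is not None and Z.shape[1] > 0:
        cols.append(Z)
    J = np.column_stack(cols)
    N = J.shape[0]
    dist, _ = cKDTree(J).query(J, k=k + 1, p=np.inf)
    r = _strict_radius(dist[:, -1])
    if Z is not None and Z.shape[1] > 0:
        n_z = _count_within(Z, r)
        n_xz = _count_within(np.column_stack([x, Z]), r)
        n_tz = _count_within(np.column_stack([t, Z]), r)
        return float(digamma(k) + np.mean(digamma(n_z + 1) - digamma(n_xz + 1)
                                          - digamma(n_tz + 1)))
    n_x = _count_within(x[:, None], r)
    n_t = _count_within(t[:, None], r)
    return float(digamma(k) + digamma(N)
                 - np.mean(digamma(n_x + 1) + digamma(n_t + 1)))


def select_embedding_nonuniform(pair, target: int, q_max: int, tau: int = 1,
                                n_shuffles: int = 100, alpha: float = 0.05,
                                k: int = 10, seed: int = 0) -> EmbeddingSpec:
    """Greedy forward selection of the most informative past samples.

    Candidates are all (process, lag) terms with lags 1..q_max*tau.  At
    each step the candidate maximizing the conditional mutual information
    with the target's present state (given the already selected terms) is
    tested against the 100(1-alpha)th percentile of its CMI over
    ``n_shuffles`` random permutations of the target series; selection
    stops when the best candidate fails the test.  An empty embedding is a
    valid outcome (nothing predicts the target).
    """
    if target not in (1, 2):
        raise ValueError("target must be 1 or 2")
    rng = np.random.default_rng(seed)
    data = pair.data()
    L = data.shape[0]
    max_lag = q_max * tau
    if L <= max_lag + 1:
        raise ValueError("series too short for the requested candidate set")
    idx = np.arange(max_lag, L)
    t_present = data[idx, target - 1]
    cand_keys = [(proc, lag) for proc in (1, 2) for lag in range(1, max_lag + 1)]
    cand_cols = {key: data[idx - key[1], key[0] - 1] for key in cand_keys}

    selected: list[tuple[int, int]] = []
    Z: np.ndarray | None = None
    remaining = list(cand_keys)
    while remaining:
        cmis = np.array([_ksg_cmi(cand_cols[key], t_present, Z, k)
                         for key in remaining])
        best_i = int(np.argmax(cmis))
        best_key = remaining[best_i]
        observed = cmis[best_i]
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            null[s] = _ksg_cmi(cand_cols[best_key],
                               rng.permutation(t_present), Z, k)
        null.sort()
        rank = min(int(np.ceil((1 - alpha) * n_shuffles)), n_shuffles) - 1
        if observed <= null[rank]:
            break
        selected.append(best_key)
        Zcols = [cand_cols[key] for key in selected]
        Z = np.column_stack(Zcols)
        remaining.remove(best_key)
    return EmbeddingSpec(q=max(1, len(selected)), tau=tau,
                         candidates=selected, mode="nonuniform")
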