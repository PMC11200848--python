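"""Phase-space reconstruction: lag/dimension selection and delay embedding.

The lag ``tau`` is taken at the first local minimum of the auto mutual
information (AMI) curve; the dimension ``m`` via the false-nearest-neighbor
(FNN) criterion of Kennel et al.  ``embed`` builds the delayed vectors

    Y(j) = [y(j), y(j - tau), ..., y(j - (m-1) tau)]

for j = (m-1) tau + 1 ... N (1-based), giving n = N - (m-1) tau vectors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from mcomeda.io_preprocess import Signal

__all__ = [
    "EmbeddingParams",
    "EmbeddedSeries",
    "auto_mutual_information",
    "select_tau",
    "fnn_fractions",
    "select_m",
    "embed",
    "estimate_embedding",
]

#: Kennel et al. relative-increase threshold.
DEFAULT_R_TOL = 15.0
#: Kennel et al. attractor-size threshold.
DEFAULT_A_TOL = 2.0
#: Fraction of false neighbors below which a dimension is accepted.
DEFAULT_FNN_THRESHOLD = 0.05
#: Largest dimension tried during the FNN scan.
DEFAULT_M_MAX = 10


@dataclass(frozen=True)
class EmbeddingParams:
    """Selected (tau, m) plus the diagnostic curves that chose them."""

    tau: int
    m: int
    ami_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    fnn_fractions: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        object.__setattr__(self, "ami_curve", np.asarray(self.ami_curve, dtype=float))
        object.__setattr__(
            self, "fnn_fractions", np.asarray(self.fnn_fractions, dtype=float)
        )


@dataclass(frozen=True)
class EmbeddedSeries:
    """The n x m matrix of delay vectors from one scalar series."""

    vectors: np.ndarray
    tau: int
    m: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "vectors", np.asarray(self.vectors, dtype=float))
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


def _default_bins(n: int) -> int:
    return min(64, max(2, math.ceil(math.sqrt(n))))


def auto_mutual_information(
    sig: Signal | np.ndarray,
    max_lag: int | None = None,
    n_bins: int | None = None,
) -> np.ndarray:
    """Histogram plug-in auto mutual information, in bits, for lags 0..max_lag.

    Both marginals are binned on the same equal-width grid spanning the full
    series range, so AMI(0) equals the plug-in entropy of the binned signal.
    """
    y = sig.values if isinstance(sig, Signal) else np.asarray(sig, dtype=float)
    n = y.size
    if np.ptp(y) == 0:
        raise ValueError("constant signal: auto mutual information undefined")
    if max_lag is None:
        max_lag = min(n // 4, 100)
    if max_lag >= n / 2:
        raise ValueError(f"max_lag {max_lag} must be < N/2 = {n / 2:g}")
    if n_bins is None:
        n_bins = _default_bins(n)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(np.min(y), np.max(y), n_bins + 1)
    # digitize once; the lagged pairs reuse the same bin labels
    labels = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, n_bins - 1)
    ami = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = labels[: n - lag]
        b = labels[lag:]
        joint = np.zeros((n_bins, n_bins))
        np.add.at(joint, (a, b), 1.0)
        joint /= a.size
        px = joint.sum(axis=1)
        py = joint.sum(axis=0)
        nz = joint > 0
        ami[lag] = float(
            np.sum(joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz]))
        )
    return ami


def select_tau(ami: np.ndarray) -> int:
    """First local minimum of the AMI curve; global-minimum fallback.

    A lag ``l >= 1`` is a local minimum when ``ami[l] < ami[l-1]`` and
    ``ami[l] <= ami[l+1]``.  Without one, the global minimum is used; if the
    curve is monotone non-increasing the last lag is returned with a warning.
    """
    ami = np.asarray(ami, dtype=float)
    if ami.size < 3:
        raise ValueError("AMI curve must cover at least lags 0..2")
    for lag in range(1, ami.size - 1):
        if ami[lag] < ami[lag - 1] and ami[lag] <= ami[lag + 1]:
            return lag
    if np.all(np.diff(ami) <= 0):
        warnings.warn(
            "AMI monotone non-increasing: no local minimum, using max lag",
            stacklevel=2,
        )
        return ami.size - 1
    lag = int(np.argmin(ami[1:])) + 1
    warnings.warn(f"no AMI local minimum: falling back to global minimum at lag {lag}",
                  stacklevel=2)
    return lag


def _embed_values(y: np.ndarray, tau: int, m: int) -> np.ndarray:
    # row i corresponds to time index j = (m-1)*tau + i; column k holds y(j - k*tau)
    n = y.size - (m - 1) * tau
    cols = [y[(m - 1 - k) * tau: (m - 1 - k) * tau + n] for k in range(m)]
    return np.column_stack(cols)


def fnn_fractions(
    sig: Signal | np.ndarray,
    tau: int,
    m_max: int = DEFAULT_M_MAX,
    r_tol: float = DEFAULT_R_TOL,
    a_tol: float = DEFAULT_A_TOL,
    theiler: int | None = None,
) -> np.ndarray:
    """False-nearest-neighbor fraction for dimensions 1..m_max.

    For each candidate dimension the nearest neighbor of every vector
    (excluding temporal neighbors inside the Theiler window, default
    ``tau``) is found; the pair is a false neighbor when the extra
    coordinate added at dimension m+1 blows up the distance by the Kennel
    criteria (``r_tol`` on the relative increase, ``a_tol`` against the
    attractor size).
    """
    y = sig.values if isinstance(sig, Signal) else np.asarray(sig, dtype=float)
    n_total = y.size
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    min_len = m_max * tau + 2
    if n_total < min_len:
        raise ValueError(
            f"series of length {n_total} too short for m_max={m_max} at tau={tau}; "
            f"need >= {min_len} samples"
        )
    if theiler is None:
        theiler = tau
    attractor_size = float(np.std(y))
    if attractor_size == 0:
        raise ValueError("constant signal: FNN undefined")
    fractions = np.empty(m_max)
    for m in range(1, m_max + 1):
        vecs_next = _embed_values(y, tau, m + 1)
        n_next = vecs_next.shape[0]
        if n_next < 2:
            raise ValueError(
                f"series of length {n_total} leaves {n_next} vectors at m={m + 1}"
            )
        # restrict the m-dim search to vectors that still exist at m+1 so the
        # extra coordinate is always defined
        vecs = vecs_next[:, :m]
        dist = cdist(vecs, vecs)
        idx = np.arange(n_next)
        band = np.abs(idx[:, None] - idx[None, :]) <= theiler
        dist[band] = np.inf
        nn = np.argmin(dist, axis=1)
        d_m = dist[idx, nn]
        valid = np.isfinite(d_m)
        extra = np.abs(vecs_next[idx, m] - vecs_next[nn, m])
        d_next = np.sqrt(d_m[valid] ** 2 + extra[valid] ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(
                d_m[valid] > 0,
                extra[valid] / np.where(d_m[valid] > 0, d_m[valid], 1.0),
                np.where(extra[valid] > 0, np.inf, 0.0),
            )
        # pairs coincident up to rounding (exact recurrences of periodic
        # data) are true neighbors regardless of the epsilon-scale ratio
        coincident = d_next <= 1e-8 * attractor_size
        false = ~coincident & ((ratio > r_tol) | (d_next / attractor_size > a_tol))
        fractions[m - 1] = float(np.mean(false)) if valid.any() else 1.0
    return fractions


def select_m(
    fractions: np.ndarray, threshold: float = DEFAULT_FNN_THRESHOLD
) -> int:
    """Smallest dimension whose FNN fraction drops below ``threshold``.

    Falls back to the argmin with a warning when no dimension qualifies.
    The result is floored at 2: angular statistics need a plane.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size == 0:
        raise ValueError("empty FNN fraction array")
    below = np.flatnonzero(fractions < threshold)
    if below.size:
        m = int(below[0]) + 1
    else:
        m = int(np.argmin(fractions)) + 1
        warnings.warn(
            f"FNN never fell below {threshold}: using argmin dimension {m}",
            stacklevel=2,
        )
    if m < 2:
        warnings.warn("FNN selected m=1; clamping to the m=2 floor", stacklevel=2)
        m = 2
    return m


def embed(sig: Signal | np.ndarray, tau: int, m: int) -> EmbeddedSeries:
    """Build the n x m delay-vector matrix (n = N - (m-1) tau)."""
    y = sig.values if isinstance(sig, Signal) else np.asarray(sig, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if m < 1:
        raise ValueError("m must be >= 1")
    n = y.size - (m - 1) * tau
    if n < 1:
        raise ValueError(
            f"series of length {y.size} too short to embed at m={m}, tau={tau}"
        )
    vectors = _embed_values(y, tau, m)
    return EmbeddedSeries(vectors=vectors, tau=tau, m=m)


def estimate_embedding(
    sig: Signal,
    *,
    max_lag: int | None = None,
    n_bins: int | None = None,
    m_max: int = DEFAULT_M_MAX,
    r_tol: float = DEFAULT_R_TOL,
    a_tol: float = DEFAULT_A_TOL,
    fnn_threshold: float = DEFAULT_FNN_THRESHOLD,
) -> EmbeddingParams:
    """Run AMI -> tau and FNN -> m on one signal and bundle the diagnostics.

    The FNN scan is truncated when the series is too short for ``m_max``.
    """
    ami = auto_mutual_information(sig, max_lag=max_lag, n_bins=n_bins)
    tau = select_tau(ami)
    n = len(sig)
    feasible_m_max = min(m_max, max(2, (n - 2) // max(tau, 1)))
    fractions = fnn_fractions(sig, tau, m_max=feasible_m_max, r_tol=r_tol, a_tol=a_tol)
    m = select_m(fractions, threshold=fnn_threshold)
    return EmbeddingParams(tau=tau, m=m, ami_curve=ami, fnn_fractions=fractions)
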