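"""Coarse-graining across time scales and the area-under-curve summary.

The scale-``beta`` series averages consecutive non-overlapping blocks of
``beta`` samples (trailing remainder dropped).  The complexity index is
evaluated at every scale with the lag and dimension estimated once on the
original series; the multiscale summary is the trapezoidal area under the
index-vs-scale curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from mcomeda.comeda_core import comeda
from mcomeda.embedding import EmbeddingParams
from mcomeda.io_preprocess import Signal

__all__ = [
    "MultiscaleTrend",
    "coarse_grain",
    "max_scale",
    "default_beta_range",
    "multiscale_trend",
    "mcomeda",
]

#: Minimum coarse-grained length for long recordings (scale cap 20).
MIN_SAMPLES_LONG = 30
#: Minimum coarse-grained length for short recordings (scale cap 10).
MIN_SAMPLES_SHORT = 25
#: Preferred maximum scale factor when the series is long enough.
BETA_CAP = 20


@dataclass(frozen=True)
class MultiscaleTrend:
    """Complexity index per scale factor, with the (tau, m) reused."""

    betas: np.ndarray
    values: np.ndarray
    tau: int
    m: int
    lengths: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        betas = np.asarray(self.betas, dtype=int)
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=int))
        if betas.size and (betas[0] != 1 or np.any(np.diff(betas) <= 0)):
            raise ValueError("scale factors must strictly increase starting at 1")


def coarse_grain(sig: Signal | np.ndarray, beta: int) -> Signal | np.ndarray:
    """Average non-overlapping blocks of ``beta`` samples; remainder dropped.

    The output keeps the input's type; for a :class:`Signal` the sampling
    rate is divided by ``beta``.
    """
    is_signal = isinstance(sig, Signal)
    y = sig.values if is_signal else np.asarray(sig, dtype=float)
    if beta < 1:
        raise ValueError("beta must be >= 1")
    n_out = y.size // beta
    if n_out < 2:
        raise ValueError(
            f"coarse-graining at beta={beta} leaves {n_out} samples (< 2)"
        )
    if beta == 1:
        out = y.copy()
    else:
        out = y[: n_out * beta].reshape(n_out, beta).mean(axis=1)
    if is_signal:
        return Signal(values=out, fs=sig.fs / beta, meta=dict(sig.meta))
    return out


def max_scale(n: int, min_samples: int) -> int:
    """Largest scale factor keeping at least ``min_samples`` coarse samples."""
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    beta = n // min_samples
    if beta < 1:
        raise ValueError(
            f"series of length {n} cannot retain {min_samples} samples at any scale"
        )
    return beta


def default_beta_range(n: int) -> np.ndarray:
    """Scale range 1..20 when that keeps >= 30 samples, else 1..max_scale(n, 25)."""
    if n // BETA_CAP >= MIN_SAMPLES_LONG:
        beta_max = BETA_CAP
    else:
        beta_max = min(BETA_CAP, max_scale(n, MIN_SAMPLES_SHORT))
    return np.arange(1, beta_max + 1)


def multiscale_trend(
    sig: Signal,
    params: EmbeddingParams,
    beta_range: np.ndarray | list[int] | None = None,
    *,
    on_error: str = "raise",
) -> MultiscaleTrend:
    """Index per scale, reusing the scale-1 (tau, m) at every scale.

    ``on_error="truncate"`` stops at the last computable scale instead of
    raising when a high scale becomes degenerate.
    """
    if beta_range is None:
        betas = default_beta_range(len(sig))
    else:
        betas = np.asarray(beta_range, dtype=int)
    if on_error not in ("raise", "truncate"):
        raise ValueError("on_error must be 'raise' or 'truncate'")
    values: list[float] = []
    lengths: list[int] = []
    for beta in betas:
        try:
            coarse = coarse_grain(sig, int(beta))
            values.append(comeda(coarse, params))
            lengths.append(len(coarse))
        except ValueError as exc:
            if on_error == "truncate":
                warnings.warn(
                    f"trend truncated before beta={beta}: {exc}", stacklevel=2
                )
                betas = betas[: len(values)]
                break
            raise ValueError(f"scale beta={beta} failed: {exc}") from exc
    return MultiscaleTrend(
        betas=betas,
        values=np.asarray(values),
        tau=params.tau,
        m=params.m,
        lengths=np.asarray(lengths, dtype=int),
    )


def mcomeda(trend: MultiscaleTrend, *, normalized: bool = False) -> float:
    """Trapezoidal area under the index-vs-scale curve.

    ``normalized=True`` divides by the scale span ``beta_max - 1`` so the
    summary lands in [0, 1].
    """
    if trend.betas.size < 2:
        raise ValueError("AUC undefined for fewer than 2 scales")
    area = float(np.trapezoid(trend.values, trend.betas))
    if normalized:
        area /= float(trend.betas[-1] - trend.betas[0])
    return area


def plot_group_trends(trends, labels=None, ax=None):
    """Median +/- MAD group trend plot across a collection of trends.

    ``trends`` maps group label -> list of :class:`MultiscaleTrend` sharing
    one scale range.  Requires matplotlib (optional dependency).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, group in trends.items():
        mat = np.vstack([t.values for t in group])
        betas = group[0].betas
        med = np.median(mat, axis=0)
        mad = np.median(np.abs(mat - med), axis=0)
        ax.plot(betas, med, label=str(label))
        ax.fill_between(betas, med - mad, med + mad, alpha=0.2)
    ax.set_xlabel("scale factor")
    ax.set_ylabel("complexity index")
    ax.legend()
    return ax
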