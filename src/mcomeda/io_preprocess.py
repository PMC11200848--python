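"""Loading, resampling, tonic/phasic decomposition and normalization of EDA.

The canonical pre-processing chain is::

    load_signal -> resample_to(5 Hz) -> decompose_eda -> to_noiseless -> zscore

``preprocess`` wires the chain together.  Decomposition is pluggable: the
``"lowpass"`` backend (default) splits tonic/phasic with a zero-phase
low-pass filter; the ``"cvxeda"`` backend delegates to an externally
installed cvxEDA implementation when available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Signal",
    "DecomposedEDA",
    "load_signal",
    "resample_to",
    "decompose_eda",
    "to_noiseless",
    "zscore",
    "preprocess",
]

#: Default cutoff (Hz) separating tonic from phasic in the low-pass backend.
DEFAULT_TONIC_CUTOFF_HZ = 0.05

#: Analysis rate used throughout the EDA pipeline.
ANALYSIS_FS_HZ = 5.0


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled 1-D series with its sampling rate.

    Parameters
    ----------
    values : ndarray
        Sample values (skin conductance in µS, or unitless after z-score).
    fs : float
        Sampling rate in Hz, strictly positive.
    meta : dict
        Free-form provenance (subject id, condition label, source file).
    """

    values: np.ndarray
    fs: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("Signal values must be one-dimensional")
        if values.size < 2:
            raise ValueError("Signal must contain at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("Signal values must be finite")
        if not (self.fs > 0):
            raise ValueError("Sampling rate must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        """Recording duration in seconds."""
        return self.values.size / self.fs

    def with_values(self, values: np.ndarray, fs: float | None = None) -> "Signal":
        """Return a copy carrying ``values`` (and optionally a new rate)."""
        return replace(self, values=values, fs=self.fs if fs is None else fs)


@dataclass(frozen=True)
class DecomposedEDA:
    """Additive tonic + phasic + residual split of an EDA signal."""

    tonic: np.ndarray
    phasic: np.ndarray
    residual: np.ndarray
    fs: float
    backend: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("tonic", "phasic", "residual"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.tonic.shape == self.phasic.shape == self.residual.shape):
            raise ValueError("tonic, phasic and residual must share one shape")


def load_signal(
    path: str | Path,
    fs: float,
    column: int | str = 0,
    *,
    interpolate_nan: bool = False,
    max_nonfinite_frac: float = 0.05,
    meta: dict[str, Any] | None = None,
) -> Signal:
    """Read one channel of a delimited text/CSV file into a :class:`Signal`.

    ``column`` selects by position (int) or header name (str).  A header row
    is detected automatically.  Non-finite samples are linearly interpolated
    when ``interpolate_nan`` is set, otherwise they raise; more than
    ``max_nonfinite_frac`` non-finite samples always raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    header = "infer" if isinstance(column, str) else None
    try:
        if header is None:
            # sniff: a non-numeric first row means a header is present
            probe = pd.read_csv(path, header=None, nrows=1)
            try:
                float(probe.iloc[0, column if isinstance(column, int) else 0])
            except (TypeError, ValueError):
                header = 0
        frame = pd.read_csv(path, header=header)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no samples in {path}") from None
    if frame.empty:
        raise ValueError(f"no samples in {path}")
    if isinstance(column, str):
        if column not in frame.columns:
            raise KeyError(f"column {column!r} not found in {path}")
        series = frame[column]
    else:
        series = frame.iloc[:, column]
    values = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
    if np.all(~np.isfinite(values)):
        raise ValueError(f"column {column!r} of {path} is not numeric")
    n_bad = int(np.count_nonzero(~np.isfinite(values)))
    if n_bad:
        if n_bad / values.size > max_nonfinite_frac:
            raise ValueError(
                f"{n_bad}/{values.size} non-finite samples in {path} exceed the "
                f"{max_nonfinite_frac:.0%} limit"
            )
        if not interpolate_nan:
            raise ValueError(
                f"{n_bad} non-finite samples in {path}; pass interpolate_nan=True"
            )
        good = np.isfinite(values)
        values = np.interp(np.arange(values.size), np.flatnonzero(good), values[good])
    base_meta = {"source": str(path), "column": column}
    if meta:
        base_meta.update(meta)
    return Signal(values=values, fs=fs, meta=base_meta)


def _antialias_taps(up: int, down: int, cutoff_ratio: float = 0.8) -> np.ndarray:
    """Polyphase FIR taps with cutoff at ``cutoff_ratio`` of target Nyquist."""
    # operating rate is fs*up; target Nyquist is fs*up / (2*down)
    max_rate = max(up, down)
    cutoff = cutoff_ratio / (2 * max_rate)  # in cycles/sample at the high rate
    half_len = 10 * max_rate
    taps = sps.firwin(2 * half_len + 1, 2 * cutoff, window=("kaiser", 5.0))
    return taps


def resample_to(sig: Signal, target_fs: float) -> Signal:
    """Downsample ``sig`` to ``target_fs`` with zero-phase anti-alias filtering.

    Only downsampling is supported.  Output length is
    ``round(N * target_fs / fs)`` and the anti-alias cutoff sits at 0.4 of
    the target rate (0.8 of the new Nyquist).
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs > sig.fs:
        raise ValueError(
            f"upsampling not supported: target {target_fs} Hz > source {sig.fs} Hz"
        )
    if target_fs == sig.fs:
        return sig
    frac = Fraction(target_fs / sig.fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    taps = _antialias_taps(up, down)
    out = sps.resample_poly(sig.values, up, down, window=taps, padtype="line")
    n_out = int(round(sig.values.size * target_fs / sig.fs))
    out = out[:n_out]
    return sig.with_values(out, fs=target_fs)


def _lowpass_tonic(values: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"tonic cutoff {cutoff_hz} Hz must sit below Nyquist {nyq} Hz")
    sos = sps.butter(2, cutoff_hz / nyq, btype="low", output="sos")
    padlen = min(values.size - 1, int(3 * fs / cutoff_hz))
    return sps.sosfiltfilt(sos, values, padlen=padlen)


def decompose_eda(
    sig: Signal,
    backend: str = "lowpass",
    *,
    tonic_cutoff_hz: float = DEFAULT_TONIC_CUTOFF_HZ,
) -> DecomposedEDA:
    """Split an EDA signal into tonic, phasic and residual components.

    Backends
    --------
    ``"lowpass"``
        tonic = zero-phase low-pass of the signal (default cutoff
        ``0.05`` Hz), phasic = signal - tonic, residual = 0.
    ``"cvxeda"``
        Delegates to an installed ``cvxEDA`` implementation; raises with a
        pointer to the fallback when it is not importable.

    The additive reconstruction ``tonic + phasic + residual == input`` holds
    for every backend.
    """
    if sig.duration_s < 10.0:
        raise ValueError(
            f"decomposition needs >= 10 s of data, got {sig.duration_s:.2f} s"
        )
    if backend == "lowpass":
        tonic = _lowpass_tonic(sig.values, sig.fs, tonic_cutoff_hz)
        phasic = sig.values - tonic
        residual = np.zeros_like(sig.values)
    elif backend == "cvxeda":
        try:
            import cvxEDA  # type: ignore[import-not-found]
        except ImportError as exc:
            raise ImportError(
                "backend 'cvxeda' requires the external cvxEDA package; "
                "use backend='lowpass' as fallback"
            ) from exc
        r, p, t, *_ = cvxEDA.cvxEDA(sig.values, 1.0 / sig.fs)
        tonic = np.asarray(t, dtype=float)
        phasic = np.asarray(r, dtype=float)
        residual = sig.values - tonic - phasic
    else:
        raise ValueError(f"unknown decomposition backend {backend!r}")
    return DecomposedEDA(
        tonic=tonic,
        phasic=phasic,
        residual=residual,
        fs=sig.fs,
        backend=backend,
        meta=dict(sig.meta),
    )


def to_noiseless(dec: DecomposedEDA) -> Signal:
    """Reassemble the cleaned signal as tonic + phasic (residual dropped)."""
    return Signal(values=dec.tonic + dec.phasic, fs=dec.fs, meta=dict(dec.meta))


def zscore(sig: Signal) -> Signal:
    """Standardize to zero mean and unit sample standard deviation (ddof=1)."""
    sd = float(np.std(sig.values, ddof=1))
    if sd == 0.0 or not math.isfinite(sd):
        raise ValueError("degenerate: constant signal has zero standard deviation")
    return sig.with_values((sig.values - np.mean(sig.values)) / sd)


def preprocess(
    sig: Signal,
    *,
    target_fs: float = ANALYSIS_FS_HZ,
    backend: str = "lowpass",
    tonic_cutoff_hz: float = DEFAULT_TONIC_CUTOFF_HZ,
) -> Signal:
    """Full chain: resample -> decompose -> tonic+phasic -> z-score."""
    sig = resample_to(sig, target_fs)
    dec = decompose_eda(sig, backend, tonic_cutoff_hz=tonic_cutoff_hz)
    clean = to_noiseless(dec)
    try:
        return zscore(clean)
    except ValueError:
        warnings.warn("constant cleaned signal; skipping z-score", stacklevel=2)
        return clean
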