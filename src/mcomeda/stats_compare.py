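"""Group-comparison workflow and the sympathetic-band spectral index.

Per-stimulus scalar indices are averaged into a subjects x conditions
matrix, screened for normality (Lilliefors), compared with Friedman's test
and, when that rejects, with pairwise two-sided Wilcoxon signed-rank tests
under Bonferroni correction.  ``edasymp`` computes the mean power spectral
density of the skin-conductance signal in the 0.045-0.25 Hz sympathetic
band over non-overlapping 30-s windows.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

from mcomeda.io_preprocess import Signal

__all__ = [
    "ConditionMatrix",
    "TestReport",
    "edasymp",
    "aggregate_by_condition",
    "lilliefors",
    "friedman",
    "wilcoxon_signed_rank",
    "wilcoxon_pairwise_bonferroni",
]

#: Sympathetic EDA band in Hz.
SYMP_BAND = (0.045, 0.25)

#: Window length for the spectral index, seconds.
SYMP_WINDOW_S = 30.0

#: Sample size at or below which the exact signed-rank null is used.
WILCOXON_EXACT_N = 25


@dataclass(frozen=True)
class ConditionMatrix:
    """Subjects x conditions matrix of a scalar index."""

    values: np.ndarray
    subject_ids: tuple
    condition_labels: tuple

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "condition_labels", tuple(self.condition_labels))
        if values.shape != (len(self.subject_ids), len(self.condition_labels)):
            raise ValueError("matrix shape must be (n_subjects, n_conditions)")
        if not np.all(np.isfinite(values)):
            raise ValueError("condition matrix must be complete and finite")

    def column(self, label) -> np.ndarray:
        return self.values[:, self.condition_labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.subject_ids), columns=list(self.condition_labels)
        )


@dataclass(frozen=True)
class TestReport:
    """Outcome of the Friedman + pairwise signed-rank workflow."""

    friedman_chi2: float
    friedman_p: float
    pairwise_raw: dict = field(default_factory=dict)
    pairwise_adjusted: dict = field(default_factory=dict)
    normality: dict = field(default_factory=dict)
    n_comparisons: int = 0
    posthoc_run: bool = True

    def pairwise_table(self) -> pd.DataFrame:
        """Symmetric adjusted-p table, empty diagonal."""
        labels = sorted({lab for pair in self.pairwise_adjusted for lab in pair})
        table = pd.DataFrame(np.nan, index=labels, columns=labels)
        for (a, b), p in self.pairwise_adjusted.items():
            table.loc[a, b] = p
            table.loc[b, a] = p
        return table


def edasymp(
    sig: Signal,
    *,
    band: tuple[float, float] = SYMP_BAND,
    window_s: float = SYMP_WINDOW_S,
    taper: str = "hamming",
) -> float:
    """Mean in-band power spectral density over non-overlapping windows.

    Each full ``window_s`` chunk gets a tapered periodogram; PSD values at
    frequencies inside ``band`` are averaged, then the window values are
    averaged.  The trailing partial window is dropped.
    """
    win_len = int(round(window_s * sig.fs))
    if len(sig) < win_len:
        raise ValueError(
            f"signal of {sig.duration_s:.1f} s shorter than one {window_s:.0f}-s window"
        )
    if sig.fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {sig.fs} Hz too low for band {band}")
    n_windows = len(sig) // win_len
    per_window = np.empty(n_windows)
    for w in range(n_windows):
        chunk = sig.values[w * win_len: (w + 1) * win_len]
        freqs, psd = sps.periodogram(chunk, fs=sig.fs, window=taper, detrend="constant")
        in_band = (freqs >= band[0]) & (freqs <= band[1])
        per_window[w] = float(np.mean(psd[in_band]))
    return float(np.mean(per_window))


def aggregate_by_condition(
    records: Iterable[tuple] | pd.DataFrame,
) -> ConditionMatrix:
    """Average per-stimulus values into one cell per subject x condition.

    ``records`` is an iterable of ``(subject, condition, value)`` tuples or a
    DataFrame with columns ``subject``, ``condition``, ``value``.  Every
    subject must contribute at least one value to every condition.
    """
    if isinstance(records, pd.DataFrame):
        frame = records[["subject", "condition", "value"]].copy()
    else:
        frame = pd.DataFrame(records, columns=["subject", "condition", "value"])
    if frame.empty:
        raise ValueError("no records to aggregate")
    pivot = frame.pivot_table(
        index="subject", columns="condition", values="value", aggfunc="mean"
    )
    if pivot.isna().any().any():
        gaps = [
            f"{subj}:{cond}"
            for subj, row in pivot.iterrows()
            for cond, v in row.items()
            if pd.isna(v)
        ]
        raise ValueError("missing subject x condition cells: " + ", ".join(gaps))
    return ConditionMatrix(
        values=pivot.to_numpy(dtype=float),
        subject_ids=tuple(pivot.index),
        condition_labels=tuple(pivot.columns),
    )


def lilliefors(sample: np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Lilliefors test of normality: (statistic, p-value, reject at alpha)."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 5:
        raise ValueError("Lilliefors test needs n >= 5")
    if np.ptp(sample) == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = _sm_lilliefors(sample, dist="norm")
    return float(stat), float(p), bool(p < alpha)


def friedman(matrix: ConditionMatrix | np.ndarray) -> tuple[float, float]:
    """Friedman chi-square with average-rank tie correction and its p-value."""
    values = matrix.values if isinstance(matrix, ConditionMatrix) else np.asarray(matrix, float)
    n, k = values.shape
    if k < 2 or n < 2:
        raise ValueError("Friedman test needs >= 2 conditions and >= 2 subjects")
    ranks = spstats.rankdata(values, axis=1)
    if np.allclose(ranks, ranks[:, :1]):
        return 0.0, 1.0
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums ** 2) - 3.0 * n * (k + 1)
    # tie correction: average ranks shrink the null variance
    ties = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - ties / (n * k * (k ** 2 - 1))
    if correction <= 0:
        return 0.0, 1.0
    chi2 /= correction
    p = float(spstats.chi2.sf(chi2, k - 1))
    return float(chi2), p


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic via DP enumeration.

    Midranks are doubled to integers; the null distribution of W+ is built
    by convolving the +/- contribution of each rank.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(np.rint(2 * w_plus))
    p_low = float(pmf[: w2 + 1].sum())
    p_high = float(pmf[w2:].sum())
    return min(1.0, 2.0 * min(p_low, p_high))


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray,
    *,
    exact_max_n: int = WILCOXON_EXACT_N,
) -> tuple[float, float]:
    """Two-sided paired signed-rank test: (W+, p-value).

    Zero differences are dropped (classical convention), tied absolute
    differences get midranks.  The null is enumerated exactly for
    ``n <= exact_max_n`` reduced pairs and approximated by a tie-corrected
    normal otherwise.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero: p = 1", stacklevel=2)
        return 0.0, 1.0
    ranks = spstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return w_plus, _signed_rank_exact_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return w_plus, 1.0
    z = (w_plus - mean) / np.sqrt(var)
    return w_plus, float(2.0 * spstats.norm.sf(abs(z)))


def wilcoxon_pairwise_bonferroni(
    matrix: ConditionMatrix,
    alpha: float = 0.05,
    *,
    friedman_gate: bool = True,
) -> TestReport:
    """Friedman screen plus pairwise Bonferroni-corrected signed-rank tests.

    All ``k(k-1)/2`` unordered condition pairs are tested two-sided; each
    raw p is multiplied by the number of comparisons and capped at 1.  With
    ``friedman_gate=True`` (default) the post hoc tests only run when the
    Friedman p-value falls below ``alpha``.
    """
    labels: Sequence = matrix.condition_labels
    chi2, fried_p = friedman(matrix)
    normality = {}
    for lab in labels:
        col = matrix.column(lab)
        try:
            stat, p, reject = lilliefors(col, alpha)
        except ValueError:
            stat, p, reject = np.nan, np.nan, False
        normality[lab] = {"statistic": stat, "p": p, "reject_normal": reject}
    pairs = list(itertools.combinations(labels, 2))
    n_comparisons = len(pairs)
    raw: dict = {}
    adjusted: dict = {}
    posthoc = not (friedman_gate and fried_p >= alpha)
    if posthoc:
        for a, b in pairs:
            _, p = wilcoxon_signed_rank(matrix.column(a), matrix.column(b))
            raw[(a, b)] = p
            adjusted[(a, b)] = min(1.0, p * n_comparisons)
    return TestReport(
        friedman_chi2=chi2,
        friedman_p=fried_p,
        pairwise_raw=raw,
        pairwise_adjusted=adjusted,
        normality=normality,
        n_comparisons=n_comparisons,
        posthoc_run=posthoc,
    )
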