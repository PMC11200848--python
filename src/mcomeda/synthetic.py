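"""Seeded EDA-like signal and cohort generators for tests and benchmarks.

A synthetic recording is tonic level + slow sinusoidal drift, plus
Poisson-timed skin-conductance responses (log-normal amplitudes convolved
with a Bateman-shaped kernel), plus white measurement noise.  Cohorts share
per-subject random offsets across conditions so paired statistics see
within-subject pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

from mcomeda.io_preprocess import Signal

__all__ = ["SynthConfig", "bateman_kernel", "generate_eda", "generate_cohort"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic EDA recording."""

    duration_s: float = 120.0
    fs: float = 5.0
    scr_rate: float = 4.0  # events per minute
    scr_amp: float = 0.5  # mean SCR amplitude, µS
    rise_s: float = 0.75
    decay_s: float = 10.0
    tonic_level: float = 2.0  # µS
    tonic_drift: float = 0.2  # amplitude of the slow drift, µS
    drift_period_s: float = 90.0
    noise_sd: float = 0.05
    amp_cv: float = 0.5  # coefficient of variation of SCR amplitudes
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if not (self.decay_s > self.rise_s > 0):
            raise ValueError("need decay_s > rise_s > 0")
        if self.scr_rate < 0 or self.noise_sd < 0:
            raise ValueError("scr_rate and noise_sd must be non-negative")


def bateman_kernel(
    rise_s: float, decay_s: float, fs: float, length_s: float | None = None
) -> np.ndarray:
    """Peak-normalized biexponential SCR kernel ``exp(-t/decay) - exp(-t/rise)``.

    The kernel starts at 0, peaks at
    ``t* = ln(decay/rise) * rise * decay / (decay - rise)`` with value 1, and
    decays below 1% of the peak by ``length_s`` (default ``6 * decay_s``).
    """
    if not (decay_s > rise_s > 0):
        raise ValueError("need decay_s > rise_s > 0")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if length_s is None:
        length_s = 6.0 * decay_s
    t = np.arange(int(round(length_s * fs))) / fs
    h = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = h.max()
    if peak <= 0:
        raise ValueError("kernel degenerate for the given constants")
    return h / peak


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + cv ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_eda(cfg: SynthConfig, rng: np.random.Generator | None = None) -> Signal:
    """One reproducible synthetic EDA recording per the config."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    phase = rng.uniform(0, 2 * np.pi)
    tonic = cfg.tonic_level + cfg.tonic_drift * np.sin(
        2 * np.pi * t / cfg.drift_period_s + phase
    )
    phasic = np.zeros(n)
    if cfg.scr_rate > 0 and cfg.scr_amp > 0:
        n_events = rng.poisson(cfg.scr_rate * cfg.duration_s / 60.0)
        if n_events:
            onsets = rng.integers(0, n, size=n_events)
            mu, sigma = _lognormal_params(cfg.scr_amp, cfg.amp_cv)
            amps = rng.lognormal(mu, sigma, size=n_events)
            impulses = np.zeros(n)
            np.add.at(impulses, onsets, amps)
            kernel = bateman_kernel(cfg.rise_s, cfg.decay_s, cfg.fs)
            phasic = np.convolve(impulses, kernel)[:n]
    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
    values = tonic + phasic + noise
    meta = {"synthetic": True, "seed": cfg.seed}
    if cfg.label:
        meta["condition"] = cfg.label
    return Signal(values=values, fs=cfg.fs, meta=meta)


def generate_cohort(
    n_subjects: int,
    conditions: Sequence[SynthConfig],
    seed: int = 0,
    *,
    tonic_spread: float = 0.5,
    amp_spread: float = 0.3,
) -> Iterator[tuple[str, str, Signal]]:
    """Yield ``(subject_id, condition_label, Signal)`` for a paired cohort.

    Each subject draws a tonic-level offset and an SCR amplitude scale once
    and keeps them across conditions; child seeds derive deterministically
    from ``seed`` so the whole cohort is reproducible.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not conditions:
        raise ValueError("need at least 1 condition")
    root = np.random.SeedSequence(seed)
    subject_seqs = root.spawn(n_subjects)
    for s_idx, subject_seq in enumerate(subject_seqs):
        subject_id = f"S{s_idx + 1:02d}"
        offset_rng = np.random.default_rng(subject_seq)
        tonic_offset = offset_rng.normal(0.0, tonic_spread)
        amp_scale = float(np.exp(offset_rng.normal(0.0, amp_spread)))
        for c_idx, cond in enumerate(conditions):
            label = cond.label or f"C{c_idx + 1}"
            cfg = replace(
                cond,
                tonic_level=max(0.1, cond.tonic_level + tonic_offset),
                scr_amp=cond.scr_amp * amp_scale,
                label=label,
            )
            sig_rng = np.random.default_rng(subject_seq.spawn(1)[0])
            sig = generate_eda(cfg, rng=sig_rng)
            sig.meta["subject"] = subject_id
            yield subject_id, label, sig
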