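"""Single-scale angular-distance complexity index.

Pipeline: delay-embed the series, take the cosine of the angle between
every unordered pair of embedded vectors, estimate the density of those
cosines with a diffusion kernel density estimator, aggregate the density
into Sturges-rule bins, apply the quadratic Renyi entropy and normalize by
its upper bound ``log2(B)`` so the index lives in [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.fft import dct, idct

from mcomeda.embedding import EmbeddedSeries, EmbeddingParams, embed
from mcomeda.io_preprocess import Signal

__all__ = [
    "AngularDistances",
    "BinnedPDF",
    "pairwise_angular",
    "sturges_bins",
    "diffusion_pdf",
    "renyi2",
    "comeda",
]

#: Vectors with Euclidean norm below this are excluded from cosine pairs.
ZERO_NORM_THRESHOLD = 1e-12

#: Fraction of skipped pairs above which the attractor is declared degenerate.
MAX_SKIPPED_FRACTION = 0.01

#: Fine-mesh size of the diffusion KDE.
KDE_MESH_SIZE = 2 ** 14


@dataclass(frozen=True)
class AngularDistances:
    """Cosines of the angles between all unordered pairs of embedded vectors."""

    d: np.ndarray
    n_pairs: int
    n_skipped: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))


@dataclass(frozen=True)
class BinnedPDF:
    """Probability mass per equal-width bin over the observed cosine range."""

    edges: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))

    @property
    def n_bins(self) -> int:
        return self.p.size


def pairwise_angular(emb: EmbeddedSeries) -> AngularDistances:
    """Cosine similarity for every unordered pair of embedded vectors.

    Pairs in which either vector has near-zero norm are skipped and counted;
    more than 1% skipped pairs raises (degenerate attractor).
    """
    vectors = emb.vectors
    n = vectors.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 embedded vectors, got {n}")
    norms = np.linalg.norm(vectors, axis=1)
    ok = norms >= ZERO_NORM_THRESHOLD
    n_total = n * (n - 1) // 2
    if not ok.any():
        raise ValueError("degenerate attractor: all embedded vectors near zero")
    good = vectors[ok]
    g_norms = norms[ok]
    k = good.shape[0]
    gram = good @ good.T
    cos = gram / np.outer(g_norms, g_norms)
    iu = np.triu_indices(k, k=1)
    d = np.clip(cos[iu], -1.0, 1.0)
    n_pairs = d.size
    n_skipped = n_total - n_pairs
    if n_skipped > MAX_SKIPPED_FRACTION * n_total:
        raise ValueError(
            f"degenerate attractor: {n_skipped}/{n_total} pairs skipped for "
            "near-zero norm"
        )
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} near-zero-norm pairs", stacklevel=2)
    return AngularDistances(d=d, n_pairs=n_pairs, n_skipped=n_skipped)


def sturges_bins(n_samples: int) -> int:
    """Sturges rule: ``ceil(log2 n) + 1`` bins."""
    if n_samples < 2:
        raise ValueError("Sturges rule needs at least 2 samples")
    return int(math.ceil(math.log2(n_samples))) + 1


def _fixed_point(t: float, n: int, k2: np.ndarray, a2: np.ndarray) -> float:
    """Botev fixed-point map whose root gives the squared diffusion time."""
    ell = 7
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        f = 2.0 * np.pi ** (2 * ell) * np.sum(
            k2 ** ell * a2 * np.exp(-k2 * np.pi ** 2 * t)
        )
        for s in range(ell - 1, 1, -1):
            k0 = np.prod(np.arange(1, 2 * s, 2)) / np.sqrt(2.0 * np.pi)
            const = (1.0 + (0.5) ** (s + 0.5)) / 3.0
            time = (2.0 * const * k0 / (n * f)) ** (2.0 / (3.0 + 2.0 * s))
            f = 2.0 * np.pi ** (2 * s) * np.sum(
                k2 ** s * a2 * np.exp(-k2 * np.pi ** 2 * time)
            )
        return t - (2.0 * n * np.sqrt(np.pi) * f) ** (-0.4)


def _diffusion_density(
    data: np.ndarray,
    support: tuple[float, float],
    mesh_size: int = KDE_MESH_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian diffusion KDE with the improved-Sheather-Jones bandwidth.

    Returns (mesh centers, density) on ``mesh_size`` points spanning
    ``support``.  The density integrates to one over the support.
    """
    lo, hi = support
    span = hi - lo
    n_unique = np.unique(data).size
    hist, edges = np.histogram(data, bins=mesh_size, range=(lo, hi))
    weights = hist / data.size
    a = dct(weights, type=2, norm=None)
    k2 = np.arange(1, mesh_size, dtype=float) ** 2
    a2 = (a[1:] / 2.0) ** 2

    t_star = None
    for guess in (0.05, 0.1, 0.5, 1.0):
        try:
            t_star = optimize.brentq(
                _fixed_point,
                0.0,
                guess,
                args=(n_unique, k2, a2),
                xtol=1e-15,
                rtol=8.9e-16,
            )
            break
        except ValueError:
            continue
    if t_star is None or not np.isfinite(t_star) or t_star <= 0:
        # plug-in failure: fall back to Silverman's rule on the unit interval
        sd = float(np.std(data))
        h = 1.06 * max(sd, 1e-3) * n_unique ** (-0.2)
        t_star = (h / span) ** 2
    smoothed = a * np.exp(-np.arange(mesh_size, dtype=float) ** 2 * np.pi ** 2 * t_star / 2.0)
    density = idct(smoothed, type=2, norm=None) / (2.0 * span)
    density = np.clip(density, 0.0, None)
    mesh = (edges[:-1] + edges[1:]) / 2.0
    area = np.sum(density) * (span / mesh_size)
    if area <= 0:
        raise RuntimeError("diffusion KDE produced a null density")
    return mesh, density / area


def diffusion_pdf(
    d: AngularDistances | np.ndarray,
    n_bins: int,
    *,
    support: tuple[float, float] = (-1.0, 1.0),
) -> BinnedPDF:
    """Bin probabilities from a diffusion KDE of the cosine sample.

    The density is evaluated on a fine mesh clamped to the geometrically
    possible support [-1, 1]; the mesh mass is then aggregated into
    ``n_bins`` equal-width bins spanning the observed data range and
    renormalized to sum to one.  Identical samples yield the degenerate
    single-bin PDF ``p = [1]`` with a warning.
    """
    data = d.d if isinstance(d, AngularDistances) else np.asarray(d, dtype=float)
    if data.size < 10:
        raise ValueError(f"need >= 10 distance samples, got {data.size}")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    lo, hi = float(np.min(data)), float(np.max(data))
    if lo == hi:
        warnings.warn("all angular distances identical: degenerate PDF", stacklevel=2)
        return BinnedPDF(edges=np.array([lo, hi]), p=np.array([1.0]))
    mesh, density = _diffusion_density(data, support)
    edges = np.linspace(lo, hi, n_bins + 1)
    inside = (mesh >= lo) & (mesh <= hi)
    labels = np.clip(np.searchsorted(edges, mesh[inside], side="right") - 1, 0, n_bins - 1)
    p = np.zeros(n_bins)
    np.add.at(p, labels, density[inside])
    total = p.sum()
    if total <= 0:
        raise RuntimeError("all KDE mass fell outside the observed range")
    return BinnedPDF(edges=edges, p=p / total)


def renyi2(pdf: BinnedPDF | np.ndarray) -> float:
    """Quadratic Renyi entropy ``-log2(sum p_i^2)`` in bits."""
    p = pdf.p if isinstance(pdf, BinnedPDF) else np.asarray(pdf, dtype=float)
    return float(-np.log2(np.sum(p ** 2)))


def comeda(
    sig: Signal | np.ndarray,
    params: EmbeddingParams,
    *,
    return_stages: bool = False,
):
    """Normalized angular-distance complexity index in [0, 1].

    Composite of ``embed -> pairwise_angular -> sturges_bins(n_pairs) ->
    diffusion_pdf -> renyi2``, returning ``R2 / log2(B)``.  A degenerate
    single-bin PDF maps to index 0 with a warning.  With
    ``return_stages=True`` the intermediate distances and binned PDF are
    returned alongside the index.
    """
    emb = embed(sig, params.tau, params.m)
    dist = pairwise_angular(emb)
    n_bins = sturges_bins(dist.n_pairs)
    pdf = diffusion_pdf(dist, n_bins)
    if pdf.n_bins == 1:
        warnings.warn("degenerate single-bin PDF: index set to 0", stacklevel=2)
        value = 0.0
    else:
        value = renyi2(pdf) / math.log2(pdf.n_bins)
        value = float(min(max(value, 0.0), 1.0))
    if return_stages:
        return value, dist, pdf
    return value
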