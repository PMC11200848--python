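"""Naive brute-force reference implementations used as test oracles.

Every function here is written with explicit loops and textbook formulas,
independent of the vectorized code paths it checks.
"""

import itertools
import math

import numpy as np


def bin_index(value, edges):
    """Bin of ``value`` on half-open equal-width bins, last bin closed."""
    n_bins = len(edges) - 1
    for i in range(n_bins):
        if edges[i] <= value < edges[i + 1]:
            return i
    if value == edges[-1]:
        return n_bins - 1
    return None


def ami_bruteforce(y, max_lag, n_bins):
    """Plug-in mutual information per lag via an explicit 2-D histogram loop."""
    y = np.asarray(y, dtype=float)
    edges = np.linspace(y.min(), y.max(), n_bins + 1)
    out = []
    for lag in range(max_lag + 1):
        pairs = [(y[i], y[i + lag]) for i in range(len(y) - lag)]
        joint = np.zeros((n_bins, n_bins))
        for a, b in pairs:
            joint[bin_index(a, edges), bin_index(b, edges)] += 1
        joint /= len(pairs)
        mi = 0.0
        for i in range(n_bins):
            for j in range(n_bins):
                pij = joint[i, j]
                if pij > 0:
                    mi += pij * math.log2(pij / (joint[i].sum() * joint[:, j].sum()))
        out.append(mi)
    return np.array(out)


def embed_bruteforce(y, tau, m):
    """Delay vectors [y(j), y(j-tau), ..., y(j-(m-1)tau)] by explicit loop."""
    y = np.asarray(y, dtype=float)
    rows = []
    for j in range((m - 1) * tau, len(y)):  # 0-based start index
        rows.append([y[j - k * tau] for k in range(m)])
    return np.array(rows)


def fnn_bruteforce(y, tau, m_max, r_tol, a_tol, theiler):
    """All-pairs nearest-neighbor false-neighbor fractions, explicit loops."""
    y = np.asarray(y, dtype=float)
    sd = float(np.std(y))
    fractions = []
    for m in range(1, m_max + 1):
        vecs_next = embed_bruteforce(y, tau, m + 1)
        n = len(vecs_next)
        vecs = vecs_next[:, :m]
        n_false = 0
        n_valid = 0
        for i in range(n):
            best_j, best_d = None, math.inf
            for j in range(n):
                if abs(i - j) <= theiler:
                    continue
                d = math.sqrt(sum((vecs[i][k] - vecs[j][k]) ** 2 for k in range(m)))
                if d < best_d:
                    best_j, best_d = j, d
            if best_j is None:
                continue
            n_valid += 1
            extra = abs(vecs_next[i][m] - vecs_next[best_j][m])
            d_next = math.sqrt(best_d ** 2 + extra ** 2)
            if best_d > 0:
                ratio = extra / best_d
            else:
                ratio = math.inf if extra > 0 else 0.0
            if d_next <= 1e-8 * sd:
                continue  # coincident up to rounding: true neighbor
            if ratio > r_tol or d_next / sd > a_tol:
                n_false += 1
        fractions.append(n_false / n_valid if n_valid else 1.0)
    return np.array(fractions)


def cosine_pairs_bruteforce(vectors):
    """Cosine of the angle for every unordered pair, explicit double loop."""
    vectors = np.asarray(vectors, dtype=float)
    out = []
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            a, b = vectors[i], vectors[j]
            na = math.sqrt(sum(x * x for x in a))
            nb = math.sqrt(sum(x * x for x in b))
            out.append(sum(x * y for x, y in zip(a, b)) / (na * nb))
    return np.array(out)


def bin_masses_bruteforce(mesh, density, edges):
    """Aggregate mesh density into bins by explicit per-point assignment."""
    p = np.zeros(len(edges) - 1)
    for x, dens in zip(mesh, density):
        if x < edges[0] or x > edges[-1]:
            continue
        p[bin_index(x, edges)] += dens
    return p / p.sum()


def renyi2_bruteforce(p):
    total = 0.0
    for pi in p:
        total += pi * pi
    return -math.log2(total)


def shannon_bruteforce(p):
    return -sum(pi * math.log2(pi) for pi in p if pi > 0)


def wilcoxon_enumeration(x, y):
    """Two-sided exact signed-rank p via enumeration of all 2^n sign vectors."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    absd = np.abs(d)
    # midranks by explicit counting
    ranks = np.array(
        [1 + sum(1 for b in absd if b < a) + (sum(1 for b in absd if b == a) - 1) / 2
         for a in absd]
    )
    w_obs = sum(r for r, di in zip(ranks, d) if di > 0)
    count_low = count_high = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if w <= w_obs:
            count_low += 1
        if w >= w_obs:
            count_high += 1
    return min(1.0, 2.0 * min(count_low, count_high) / total)


def friedman_bruteforce(matrix):
    """Friedman chi-square for a tie-free matrix, textbook formula."""
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    rank_sums = np.zeros(k)
    for row in matrix:
        order = sorted(range(k), key=lambda c: row[c])
        for rank0, col in enumerate(order):
            rank_sums[col] += rank0 + 1
    chi2 = 12.0 / (n * k * (k + 1)) * sum(r * r for r in rank_sums) - 3.0 * n * (k + 1)
    return chi2
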