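"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately coded from first principles (allele enumeration,
pairwise comparison, textbook formulas with fsum) and do not call into the
package's statistic code paths.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np


def alleles_from_dosages(dosages: Sequence[int]) -> np.ndarray:
    """Expand dosages {0,1,2} into an explicit allele array; -1 is skipped."""
    alleles: List[int] = []
    for d in dosages:
        if d < 0:
            continue
        alleles.extend([1] * d + [0] * (2 - d))
    return np.array(alleles, dtype=np.int8)


def pi_pairwise(window_dosages: np.ndarray, window_length: int) -> float:
    """Per-bp mean pairwise difference over all allele pairs, site by site."""
    total = 0.0
    for site in window_dosages:
        a = alleles_from_dosages(site)
        n = len(a)
        if n < 2:
            continue
        diff = np.sum(a[:, None] != a[None, :]) / 2  # each pair counted once
        total += diff / (n * (n - 1) / 2)
    return total / window_length


def tajimas_d_textbook(window_dosages: np.ndarray) -> float:
    """Tajima's D from explicit alleles; requires a fixed allele count."""
    sites = [alleles_from_dosages(s) for s in window_dosages]
    sites = [a for a in sites if len(a) >= 2]
    ns = {len(a) for a in sites}
    assert len(ns) == 1, "oracle requires fixed n"
    n = ns.pop()
    seg = [a for a in sites if 0 < a.sum() < len(a)]
    S = len(seg)
    if S == 0 or n < 4:
        return math.nan
    theta_pi = 0.0
    for a in seg:
        diff = np.sum(a[:, None] != a[None, :]) / 2
        theta_pi += diff / (n * (n - 1) / 2) * 1.0
    # theta_pi as mean pairwise differences summed over sites (count units)
    a1 = math.fsum(1.0 / i for i in range(1, n))
    a2 = math.fsum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    theta_w = S / a1
    return (theta_pi - theta_w) / math.sqrt(e1 * S + e2 * S * (S - 1))


def hudson_fst_per_site(
    dosages_1: np.ndarray, dosages_2: np.ndarray
) -> float:
    """Hudson ratio-of-sums F_ST from explicit allele counts, per site."""
    num = 0.0
    den = 0.0
    for s1, s2 in zip(dosages_1, dosages_2):
        a1 = alleles_from_dosages(s1)
        a2 = alleles_from_dosages(s2)
        n1, n2 = len(a1), len(a2)
        if n1 < 2 or n2 < 2:
            continue
        p1 = a1.sum() / n1
        p2 = a2.sum() / n2
        num += (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den += p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0:
        return math.nan
    return num / den


def sw_affine_full_matrix(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> int:
    """Quadratic-space textbook affine-gap local alignment (Gotoh)."""
    m, n = len(a), len(b)
    NEG = float("-inf")
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open + gap_extend)
            F[i, j] = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open + gap_extend)
            ai, bj = a[i - 1], b[j - 1]
            s = match if (ai == bj and ai != "N") else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return int(best)


def random_window(
    rng: np.random.Generator,
    n_samples: int,
    max_sites: int = 200,
    missing_rate: float = 0.0,
) -> np.ndarray:
    """Random dosage window (n_sites x n_samples) with optional missingness."""
    n_sites = int(rng.integers(1, max_sites + 1))
    d = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(d.shape) < missing_rate
        d[mask] = -1
    return d
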