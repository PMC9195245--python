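"""Windowed two-group selective-sweep scan: π, Tajima's D, Hudson F_ST.

A putatively selected group (e.g. high-altitude accessions) is compared to a
reference group in sliding windows (default 50 kb, step 10 kb).  A sweep
leaves three signatures inside the swept interval: reduced nucleotide
diversity in the selected group (small π_high/π_low), an excess of rare
variants (negative Tajima's D), and elevated differentiation (high F_ST).
Windows in the extreme tails of all three statistics (default top/bottom 5%)
are selected and merged into sweep regions.

Statistics
----------
Per window of length L over biallelic sites with alt frequency p and allele
sample size n = 2 x (non-missing samples):

* π per bp  = Σ_sites 2 p (1−p) n/(n−1) / L   (unbiased per-site heterozygosity)
* Tajima's D = (θ̂_π − θ̂_W) / sqrt(e1 S + e2 S (S−1)), θ̂_W = S / a1, with the
  classical constants a1..e2 at the window's allele sample size
* F_ST: Hudson ratio-of-sums,
  N_s = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1),
  D_s = p1(1−p2) + p2(1−p1),  F_ST = Σ N_s / Σ D_s

With missing data the per-window allele sample size varies across sites;
Tajima's variance formula assumes a fixed n, so D uses the window's modal n
and excludes sites whose n deviates from it by more than 20% (configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .variant_io import MISSING, GeneModel, GenomeInterval

__all__ = [
    "GenotypeMatrix",
    "GroupAssignment",
    "TajimaConstants",
    "WindowStats",
    "SweepRegion",
    "tajima_constants",
    "site_allele_freq",
    "window_pi",
    "tajimas_d",
    "hudson_fst",
    "scan_windows",
    "select_sweep_windows",
    "merge_and_annotate",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites; entries are alt dosages {0,1,2} or -1."""

    samples: List[str]
    chroms: np.ndarray  # object/str, per site
    positions: np.ndarray  # int64, 1-based, per site
    dosages: np.ndarray  # (n_sites, n_samples) int8

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n_sites = len(self.positions)
        if self.dosages.shape != (n_sites, len(self.samples)):
            raise ValueError("dosage matrix shape mismatch")
        if len(self.chroms) != n_sites:
            raise ValueError("chrom/position length mismatch")
        for chrom in np.unique(self.chroms):
            p = self.positions[self.chroms == chrom]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in names], dtype=np.intp)


@dataclass
class GroupAssignment:
    """Sample -> {'high', 'low'} group labels."""

    assignment: Dict[str, str]

    def __post_init__(self) -> None:
        groups = set(self.assignment.values())
        if not {"high", "low"} <= groups:
            raise ValueError("both 'high' and 'low' groups must be non-empty")
        extra = groups - {"high", "low"}
        if extra:
            raise ValueError(f"unknown group labels: {sorted(extra)}")

    def members(self, group: str) -> List[str]:
        return [s for s, g in self.assignment.items() if g == group]


@dataclass(frozen=True)
class TajimaConstants:
    """Classical normalising constants for Tajima's D at allele sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 4:
        raise ValueError("Tajima constants require n >= 4")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class WindowStats:
    interval: GenomeInterval
    n_sites: int
    pi_high: float
    pi_low: float
    d_high: float  # nan when undefined (S = 0 or n < 4)
    d_low: float
    fst: float  # nan when denominator 0

    @property
    def pi_ratio(self) -> float:
        if self.pi_low == 0:
            return math.nan
        return self.pi_high / self.pi_low

    @property
    def d_diff(self) -> float:
        return self.d_high - self.d_low


@dataclass
class SweepRegion:
    interval: GenomeInterval
    windows: List[WindowStats]
    gene_ids: List[str] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.interval.length


# ---------------------------------------------------------------------------
# per-site and per-window statistics
# ---------------------------------------------------------------------------


def site_allele_freq(
    column: np.ndarray, group_idx: np.ndarray
) -> Tuple[float, int]:
    """Alt-allele frequency p and allele sample size n in a sample subset.

    n counts two alleles per non-missing sample; returns (nan, 0) when every
    group member is missing.
    """
    sub = np.asarray(column)[group_idx]
    called = sub != MISSING
    n = 2 * int(np.sum(called))
    if n == 0:
        return math.nan, 0
    p = float(np.sum(sub[called])) / n
    return p, n


def _site_arrays(
    matrix: GenotypeMatrix, group_idx: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised (p, n) across all sites for one group."""
    sub = matrix.dosages[:, group_idx]
    called = sub != MISSING
    n = 2 * called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n.astype(np.int64)


def _pi_terms(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site unbiased heterozygosity 2p(1-p)n/(n-1); 0 where undefined."""
    term = np.zeros_like(p, dtype=float)
    ok = (n >= 2) & np.isfinite(p)
    nn = n[ok].astype(float)
    term[ok] = 2.0 * p[ok] * (1.0 - p[ok]) * nn / (nn - 1.0)
    return term


def _window_mask(
    matrix: GenotypeMatrix, window: GenomeInterval
) -> np.ndarray:
    return (
        (matrix.chroms == window.chrom)
        & (matrix.positions >= window.start)
        & (matrix.positions <= window.end)
    )


def _group_idx(matrix: GenotypeMatrix, group: Sequence[str] | np.ndarray) -> np.ndarray:
    if isinstance(group, np.ndarray) and group.dtype != object:
        return group.astype(np.intp)
    return matrix.sample_indices(list(group))


def window_pi(
    matrix: GenotypeMatrix, group: Sequence[str], window: GenomeInterval
) -> float:
    """Per-bp nucleotide diversity of a group in one window.

    The denominator is the full window length (invariant sites are assumed
    absent from the SNP matrix and contribute zero to the numerator).
    """
    idx = _group_idx(matrix, group)
    mask = _window_mask(matrix, window)
    p, n = _site_arrays(matrix, idx)
    return float(np.sum(_pi_terms(p, n)[mask])) / window.length


def _tajimas_d_from_sites(
    p: np.ndarray, n: np.ndarray, max_n_dev: float = 0.2
) -> float:
    """Tajima's D from per-site (p, n) of one window; nan when undefined."""
    ok = (n >= 2) & np.isfinite(p)
    p, n = p[ok], n[ok]
    if len(n) == 0:
        return math.nan
    vals, counts = np.unique(n, return_counts=True)
    modal_n = int(vals[np.argmax(counts)])
    if modal_n < 4:
        return math.nan
    keep = np.abs(n - modal_n) <= max_n_dev * modal_n
    p, n = p[keep], n[keep]
    seg = (p > 0) & (p < 1)
    S = int(np.sum(seg))
    if S == 0:
        return math.nan
    theta_pi = float(np.sum(_pi_terms(p[seg], n[seg])))
    c = tajima_constants(modal_n)
    theta_w = S / c.a1
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (theta_pi - theta_w) / math.sqrt(var)


def tajimas_d(
    matrix: GenotypeMatrix,
    group: Sequence[str],
    window: GenomeInterval,
    max_n_dev: float = 0.2,
) -> float:
    """Tajima's D for one group in one window; nan when S = 0 or n < 4."""
    idx = _group_idx(matrix, group)
    mask = _window_mask(matrix, window)
    p, n = _site_arrays(matrix, idx)
    return _tajimas_d_from_sites(p[mask], n[mask], max_n_dev)


def _fst_terms(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Hudson per-site numerator and denominator; 0 where a group has n < 2."""
    ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    N = np.zeros_like(p1, dtype=float)
    D = np.zeros_like(p1, dtype=float)
    a, b = p1[ok], p2[ok]
    m1, m2 = n1[ok].astype(float), n2[ok].astype(float)
    N[ok] = (a - b) ** 2 - a * (1 - a) / (m1 - 1) - b * (1 - b) / (m2 - 1)
    D[ok] = a * (1 - b) + b * (1 - a)
    return N, D


def hudson_fst(
    matrix: GenotypeMatrix,
    group_high: Sequence[str],
    group_low: Sequence[str],
    window: GenomeInterval,
) -> float:
    """Hudson ratio-of-sums F_ST between two groups in one window."""
    i1 = _group_idx(matrix, group_high)
    i2 = _group_idx(matrix, group_low)
    mask = _window_mask(matrix, window)
    p1, n1 = _site_arrays(matrix, i1)
    p2, n2 = _site_arrays(matrix, i2)
    N, D = _fst_terms(p1, n1, p2, n2)
    denom = float(np.sum(D[mask]))
    if denom == 0:
        return math.nan
    return float(np.sum(N[mask])) / denom


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------


def scan_windows(
    matrix: GenotypeMatrix,
    groups: GroupAssignment,
    window_size: int = 50_000,
    step: int = 10_000,
    chrom_lengths: Optional[Dict[str, int]] = None,
    max_n_dev: float = 0.2,
) -> List[WindowStats]:
    """All window statistics on the step grid, per chromosome.

    Windows start at 1, 1+step, 1+2*step, ... and cover window_size bp;
    the grid runs while the full window fits on the chromosome
    (start + window_size − 1 <= chromosome end; end defaults to the last
    SNP position).
    """
    if not (window_size >= step >= 1):
        raise ValueError("require window_size >= step >= 1")
    hi_idx = matrix.sample_indices(groups.members("high"))
    lo_idx = matrix.sample_indices(groups.members("low"))
    p_hi, n_hi = _site_arrays(matrix, hi_idx)
    p_lo, n_lo = _site_arrays(matrix, lo_idx)
    pi_hi = _pi_terms(p_hi, n_hi)
    pi_lo = _pi_terms(p_lo, n_lo)
    fN, fD = _fst_terms(p_hi, n_hi, p_lo, n_lo)

    out: List[WindowStats] = []
    for chrom in dict.fromkeys(matrix.chroms.tolist()):  # preserve order
        cmask = matrix.chroms == chrom
        pos = matrix.positions[cmask]
        end = chrom_lengths[chrom] if chrom_lengths else int(pos[-1])
        c_pi_hi = np.concatenate([[0.0], np.cumsum(pi_hi[cmask])])
        c_pi_lo = np.concatenate([[0.0], np.cumsum(pi_lo[cmask])])
        c_fN = np.concatenate([[0.0], np.cumsum(fN[cmask])])
        c_fD = np.concatenate([[0.0], np.cumsum(fD[cmask])])
        cp_hi, cn_hi = p_hi[cmask], n_hi[cmask]
        cp_lo, cn_lo = p_lo[cmask], n_lo[cmask]
        start = 1
        while start + window_size - 1 <= end:
            w_end = start + window_size - 1
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, w_end, side="right"))
            denom = c_fD[hi] - c_fD[lo]
            out.append(
                WindowStats(
                    interval=GenomeInterval(chrom, start, w_end),
                    n_sites=hi - lo,
                    pi_high=(c_pi_hi[hi] - c_pi_hi[lo]) / window_size,
                    pi_low=(c_pi_lo[hi] - c_pi_lo[lo]) / window_size,
                    d_high=_tajimas_d_from_sites(
                        cp_hi[lo:hi], cn_hi[lo:hi], max_n_dev
                    ),
                    d_low=_tajimas_d_from_sites(
                        cp_lo[lo:hi], cn_lo[lo:hi], max_n_dev
                    ),
                    fst=(c_fN[hi] - c_fN[lo]) / denom if denom != 0 else math.nan,
                )
            )
            start += step
    return out


def matrix_from_records(samples: Sequence[str], records: Sequence) -> GenotypeMatrix:
    """Build a GenotypeMatrix from VariantRecords (e.g. from read_vcf)."""
    if not records:
        raise ValueError("no records")
    return GenotypeMatrix(
        samples=list(samples),
        chroms=np.array([r.chrom for r in records], dtype=object),
        positions=np.array([r.pos for r in records], dtype=np.int64),
        dosages=np.vstack([r.genotypes for r in records]).astype(np.int8),
    )


def read_groups(path: str) -> GroupAssignment:
    """Read a 2-column sample<TAB>group TSV (groups 'high'/'low')."""
    assignment = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, group = line.split("\t")[:2]
            assignment[sample] = group
    return GroupAssignment(assignment)


def write_groups(path: str, groups: GroupAssignment) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.assignment.items():
            fh.write(f"{sample}\t{group}\n")


def _tail_threshold(values: np.ndarray, q: float, tail: str) -> float:
    """Empirical order-statistic threshold selecting ~q of the values."""
    m = len(values)
    k = max(1, math.ceil(q * m))
    srt = np.sort(values)
    if tail == "upper":
        return float(srt[m - k])
    return float(srt[k - 1])


def select_sweep_windows(
    stats: Sequence[WindowStats],
    q: float = 0.05,
    mode: str = "intersection",
    pi_ratio_tail: str = "lower",
) -> List[WindowStats]:
    """Windows in the extreme q-tails of pi_ratio, D difference and F_ST.

    Selection directions: smallest q of π_high/π_low (strongest diversity
    reduction in the putatively selected group), most negative q of
    D_high − D_low, and largest q of F_ST.  Thresholds are empirical order
    statistics over windows where the statistic is defined; ties are
    included, so slightly more than q may be selected.  ``mode`` combines
    the three criteria: 'intersection' (default), 'union', or 'any-two'.

    A window whose D_high is undefined because the selected group has no
    segregating sites — while the reference group still does (D_low
    defined) — carries the strongest possible rare-variant signal and counts
    as hitting the D criterion, although it is excluded from the threshold
    quantile itself.
    """
    if mode not in {"intersection", "union", "any-two"}:
        raise ValueError("mode must be intersection, union or any-two")
    if pi_ratio_tail not in {"lower", "upper"}:
        raise ValueError("pi_ratio_tail must be 'lower' or 'upper'")
    defined = [
        w
        for w in stats
        if math.isfinite(w.pi_ratio) and math.isfinite(w.fst)
    ]
    if len(defined) < 20:
        raise ValueError("too few defined windows for a meaningful quantile")
    ratios = np.array([w.pi_ratio for w in defined])
    ddiffs = np.array([w.d_diff for w in defined])
    fsts = np.array([w.fst for w in defined])
    d_ok = np.isfinite(ddiffs)
    if not d_ok.any():
        raise ValueError("Tajima's D undefined in every window")
    t_ratio = _tail_threshold(ratios, q, pi_ratio_tail)
    t_ddiff = _tail_threshold(ddiffs[d_ok], q, "lower")
    t_fst = _tail_threshold(fsts, q, "upper")

    selected = []
    for w, r, d, f in zip(defined, ratios, ddiffs, fsts):
        hit_ratio = r <= t_ratio if pi_ratio_tail == "lower" else r >= t_ratio
        swept_out = math.isnan(w.d_high) and math.isfinite(w.d_low)
        hit_d = (math.isfinite(d) and d <= t_ddiff) or swept_out
        hits = int(hit_ratio) + int(hit_d) + int(f >= t_fst)
        if (
            (mode == "intersection" and hits == 3)
            or (mode == "union" and hits >= 1)
            or (mode == "any-two" and hits >= 2)
        ):
            selected.append(w)
    return selected


def merge_and_annotate(
    selected: Sequence[WindowStats],
    gene_models: Optional[Sequence[GeneModel]] = None,
) -> List[SweepRegion]:
    """Merge overlapping/abutting selected windows; attach overlapping genes.

    Genes overlapping a merged region by >= 1 bp are listed on it.  Returns
    regions sorted by (chrom, start).
    """
    if not selected:
        return []
    ordered = sorted(selected, key=lambda w: (w.interval.chrom, w.interval.start))
    regions: List[SweepRegion] = []
    cur = [ordered[0]]
    for w in ordered[1:]:
        prev = cur[-1]
        if (
            w.interval.chrom == prev.interval.chrom
            and w.interval.start <= _run_end(cur) + 1
        ):
            cur.append(w)
        else:
            regions.append(_make_region(cur))
            cur = [w]
    regions.append(_make_region(cur))

    if gene_models:
        from intervaltree import IntervalTree

        trees: Dict[str, IntervalTree] = {}
        for g in gene_models:
            t = trees.setdefault(g.interval.chrom, IntervalTree())
            # interval tree is half-open: [start, end + 1)
            t[g.interval.start : g.interval.end + 1] = g.gene_id
        for region in regions:
            tree = trees.get(region.interval.chrom)
            if tree is None:
                continue
            hits = tree[region.interval.start : region.interval.end + 1]
            region.gene_ids = sorted(h.data for h in hits)
    return regions


def _run_end(run: List[WindowStats]) -> int:
    return max(w.interval.end for w in run)


def _make_region(run: List[WindowStats]) -> SweepRegion:
    return SweepRegion(
        interval=GenomeInterval(
            run[0].interval.chrom,
            min(w.interval.start for w in run),
            max(w.interval.end for w in run),
        ),
        windows=list(run),
    )
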