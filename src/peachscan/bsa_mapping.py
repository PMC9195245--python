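"""Δ(SNP-index) bulked-segregant mapping (QTL-seq style).

Two phenotype pools from a cross are sequenced; at each marker the SNP index
of a pool is the fraction of its reads carrying the donor (resistant-parent)
allele.  Near a causal locus the resistant pool is enriched for the donor
allele while the susceptible pool is depleted, so Δ(SNP index) =
index_res − index_sus peaks there; elsewhere both pools drift around the
cross-expected value and Δ averages 0.  A sliding-window mean of Δ smooths
marker noise, and the candidate region is the maximal contiguous run of
windows with |mean Δ| above a genome-wide quantile threshold.

Referencing the index to the donor allele makes Δ positive at a resistance
locus; the 0.3/0.7 filter removes loci whose index is extreme in BOTH pools
(non-segregating or systematically biased sites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .variant_io import MISSING, GenomeInterval, VariantRecord

__all__ = [
    "PoolSite",
    "SnpIndexRecord",
    "BsaWindow",
    "select_informative_snps",
    "snp_index",
    "compute_indices",
    "filter_by_index",
    "delta_snp_index",
    "window_delta",
    "call_candidate_region",
]


@dataclass(frozen=True)
class PoolSite:
    """Per-locus pooled read counts of the donor vs. other allele."""

    chrom: str
    pos: int
    donor_res: int
    other_res: int
    donor_sus: int
    other_sus: int

    def __post_init__(self) -> None:
        if min(self.donor_res, self.other_res, self.donor_sus, self.other_sus) < 0:
            raise ValueError("read counts must be >= 0")


@dataclass(frozen=True)
class SnpIndexRecord:
    chrom: str
    pos: int
    index_res: float
    index_sus: float

    @property
    def delta(self) -> float:
        return self.index_res - self.index_sus


@dataclass(frozen=True)
class BsaWindow:
    interval: GenomeInterval
    mean_delta: float  # nan when the window holds no SNPs
    n_snps: int

    @property
    def is_empty(self) -> bool:
        return self.n_snps == 0


def select_informative_snps(
    parent_res: Iterable[VariantRecord],
    parent_sus: Iterable[VariantRecord],
    res_index: int = 0,
    sus_index: int = 0,
) -> List[Tuple[str, int, bool]]:
    """Sites where the two parents are homozygous for different alleles.

    ``parent_res`` / ``parent_sus`` are the same sites genotyped in the
    resistant (donor) and susceptible (recurrent) parent; ``res_index`` /
    ``sus_index`` select the parent's column within each record.  Returns
    (chrom, pos, donor_is_alt) with the donor allele taken from the
    resistant parent.
    """
    out: List[Tuple[str, int, bool]] = []
    for r_rec, s_rec in zip(parent_res, parent_sus):
        if (r_rec.chrom, r_rec.pos) != (s_rec.chrom, s_rec.pos):
            raise ValueError("parent record streams out of register")
        g_res = int(r_rec.genotypes[res_index])
        g_sus = int(s_rec.genotypes[sus_index])
        if g_res == MISSING or g_sus == MISSING:
            continue
        if g_res in (0, 2) and g_sus in (0, 2) and g_res != g_sus:
            out.append((r_rec.chrom, r_rec.pos, g_res == 2))
    return out


def snp_index(donor_count: int, other_count: int) -> float:
    """Fraction of pooled reads carrying the donor allele."""
    total = donor_count + other_count
    if total <= 0:
        raise ValueError("zero total depth: SNP index undefined")
    return donor_count / total


def compute_indices(sites: Iterable[PoolSite]) -> List[SnpIndexRecord]:
    """SNP indices for both pools; sites with zero depth in a pool are skipped."""
    out = []
    for s in sites:
        if s.donor_res + s.other_res == 0 or s.donor_sus + s.other_sus == 0:
            continue
        out.append(
            SnpIndexRecord(
                s.chrom,
                s.pos,
                snp_index(s.donor_res, s.other_res),
                snp_index(s.donor_sus, s.other_sus),
            )
        )
    return out


def filter_by_index(
    records: Iterable[SnpIndexRecord],
    low: float = 0.3,
    high: float = 0.7,
    mode: str = "both",
) -> List[SnpIndexRecord]:
    """Drop loci with an extreme SNP index in both pools.

    ``mode="both"`` (default) removes a locus iff its index is < ``low`` in
    both pools or > ``high`` in both pools — such loci carry no segregation
    signal.  ``mode="either"`` removes a locus if either pool is outside
    [low, high] (the stricter alternative reading).  Boundary values are
    kept (strict inequalities).
    """
    if mode not in {"both", "either"}:
        raise ValueError("mode must be 'both' or 'either'")
    out = []
    for r in records:
        if mode == "both":
            drop = (r.index_res < low and r.index_sus < low) or (
                r.index_res > high and r.index_sus > high
            )
        else:
            drop = (
                r.index_res < low
                or r.index_sus < low
                or r.index_res > high
                or r.index_sus > high
            )
        if not drop:
            out.append(r)
    return out


def delta_snp_index(record: SnpIndexRecord) -> float:
    """Δ(SNP index) = index_res − index_sus."""
    return record.index_res - record.index_sus


def window_delta(
    records: Sequence[SnpIndexRecord],
    window_size: int = 1_000_000,
    step: int = 100_000,
    chrom_lengths: Optional[dict] = None,
) -> List[BsaWindow]:
    """Sliding-window mean of Δ(SNP index).

    Windows start at 1, step, 2*step, ... per chromosome; a window covers
    [s, s + window_size − 1] and averages the Δ of SNPs inside it.  Windows
    with no SNPs carry mean nan and n_snps 0.  Window starts run while the
    window still begins at or before the chromosome end (by default the last
    SNP position).
    """
    if not (window_size >= step >= 1):
        raise ValueError("require window_size >= step >= 1")
    by_chrom: dict[str, list[SnpIndexRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    windows: List[BsaWindow] = []
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: r.pos)
        pos = np.array([r.pos for r in recs])
        delta = np.array([r.delta for r in recs])
        csum = np.concatenate([[0.0], np.cumsum(delta)])
        end = chrom_lengths[chrom] if chrom_lengths else int(pos[-1])
        start = 1
        while start <= end:
            w_end = start + window_size - 1
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, w_end, side="right"))
            n = hi - lo
            mean = (csum[hi] - csum[lo]) / n if n else math.nan
            windows.append(
                BsaWindow(GenomeInterval(chrom, start, w_end), mean, n)
            )
            start += step
    return windows


def pool_sites_from_vcf(
    path: str,
    res_pool: str,
    sus_pool: str,
    res_parent: str,
    sus_parent: str,
) -> List[PoolSite]:
    """Extract pooled donor/other allele depths from a BC1 VCF.

    Keeps sites where the parents are homozygous for different alleles
    (the informative markers of the cross), orients counts to the donor
    (resistant-parent) allele, and reads pool depths from the AD field.
    """
    import pysam

    sites: List[PoolSite] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            g_res = rec.samples[res_parent].get("GT")
            g_sus = rec.samples[sus_parent].get("GT")
            if g_res is None or g_sus is None:
                continue
            if None in g_res or None in g_sus:
                continue
            if len(set(g_res)) != 1 or len(set(g_sus)) != 1 or g_res == g_sus:
                continue
            donor_allele = g_res[0]  # 0 = ref, 1 = alt
            counts = []
            ok = True
            for pool in (res_pool, sus_pool):
                ad = rec.samples[pool].get("AD")
                if ad is None or len(ad) < 2 or any(a is None for a in ad[:2]):
                    ok = False
                    break
                donor = int(ad[donor_allele])
                other = int(ad[1 - donor_allele])
                counts.append((donor, other))
            if ok:
                sites.append(
                    PoolSite(rec.chrom, rec.pos, counts[0][0], counts[0][1],
                             counts[1][0], counts[1][1])
                )
    return sites


def write_pool_sites(path: str, sites: Sequence[PoolSite]) -> None:
    """Write pooled counts as the 6-column TSV dialect."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tdonor_res\tother_res\tdonor_sus\tother_sus\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.donor_res}\t{s.other_res}"
                f"\t{s.donor_sus}\t{s.other_sus}\n"
            )


def read_pool_sites(path: str) -> List[PoolSite]:
    """Read the 6-column pooled-count TSV."""
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "chrom")):
                continue
            chrom, pos, dr, orr, ds, os_ = line.split("\t")
            sites.append(
                PoolSite(chrom, int(pos), int(dr), int(orr), int(ds), int(os_))
            )
    return sites


def call_candidate_region(
    windows: Sequence[BsaWindow],
    threshold: Optional[float] = None,
    quantile: float = 0.95,
    max_gap: Optional[int] = None,
) -> Tuple[Optional[GenomeInterval], Optional[BsaWindow]]:
    """Candidate interval and peak window from windowed |mean Δ|.

    The threshold defaults to the genome-wide ``quantile`` of |mean Δ| over
    non-empty windows.  Passing windows on the same chromosome are grouped
    into runs, tolerating gaps up to ``max_gap`` bp (default: one window
    length) — with heavily overlapping windows on a fine step grid, passing
    windows separated by less than a window reflect the same underlying
    locus sampled with noise.  The call is the longest run, returned as the
    merged interval, together with the single window of maximal |mean Δ| as
    the most significant locus.  Ties in the peak break toward the smaller
    coordinate.  Returns (None, None) when no window passes or all windows
    are empty.
    """
    filled = [w for w in windows if not w.is_empty]
    if not filled:
        return None, None
    abs_means = np.array([abs(w.mean_delta) for w in filled])
    if threshold is None:
        threshold = float(np.quantile(abs_means, quantile))
    passing = [w for w in filled if abs(w.mean_delta) > threshold]
    if not passing:
        return None, None
    passing.sort(key=lambda w: (w.interval.chrom, w.interval.start))
    if max_gap is None:
        max_gap = passing[0].interval.length

    runs: List[List[BsaWindow]] = [[passing[0]]]
    for w in passing[1:]:
        prev = runs[-1][-1]
        if (
            w.interval.chrom == prev.interval.chrom
            and w.interval.start <= prev.interval.end + 1 + max_gap
        ):
            runs[-1].append(w)
        else:
            runs.append([w])
    best_run = max(runs, key=len)
    region = GenomeInterval(
        best_run[0].interval.chrom,
        best_run[0].interval.start,
        best_run[-1].interval.end,
    )
    best_val = max(abs(w.mean_delta) for w in passing)
    tied = [w for w in passing if abs(w.mean_delta) == best_val]
    peak = min(tied, key=lambda w: (w.interval.chrom, w.interval.start))
    return region, peak
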