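"""Seeded synthetic datasets with the statistical structure each stage assumes.

Every generator is deterministic given its seed and returns, alongside the
dataset, a machine-readable truth record describing the planted signal, so
end-to-end recovery can be scored without external data.

Generators
----------
* :func:`simulate_bc1` — a first-backcross mapping population: a donor parent
  carrying a dominant resistance allele crossed to a recurrent parent, the F1
  backcrossed to the recurrent parent.  Meiosis follows the Haldane map (no
  interference); offspring are pooled by phenotype and pool allele depths are
  binomial reads over the pool allele frequency.
* :func:`simulate_sweep` — a two-group genotype matrix with a planted sweep:
  background sites share a Beta-distributed allele frequency between groups;
  inside the sweep interval the high group's frequencies are warped toward
  the nearer boundary (p' = p^gamma or 1-(1-p)^gamma), which reduces pi,
  drives Tajima's D negative, and raises F_ST there.
* :func:`simulate_kmer_histogram` — Poisson k-mer coverage over G distinct
  true k-mers plus a depth-1 sequencing-error spike.
* :func:`simulate_codon_pairs` — codon alignments whose fourfold-degenerate
  third positions mutate to a transversion/transition with set probabilities.
* :func:`simulate_origin_fixture` — query genes diverged a little from their
  true donor species and more from all other donors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bsa_mapping import PoolSite
from .introgression import DonorCatalog
from .kmer_survey import KmerHistogram
from .molevol import FOURFOLD_PREFIXES, CodonAlignment
from .sweep_scan import GenotypeMatrix, GroupAssignment
from .variant_io import VariantRecord

__all__ = [
    "Bc1SimConfig",
    "SweepSimConfig",
    "simulate_bc1",
    "simulate_sweep",
    "simulate_kmer_histogram",
    "simulate_codon_pairs",
    "simulate_origin_fixture",
    "write_truth",
]

_BASES = np.array(list("ACGT"))


def write_truth(path: str, truth: dict) -> None:
    """Write a truth record as sidecar JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=int)


# ---------------------------------------------------------------------------
# BC1 bulked-segregant population
# ---------------------------------------------------------------------------


@dataclass
class Bc1SimConfig:
    """Backcross mapping-population simulation parameters.

    ``recomb_rate`` is in Morgans per bp (default 4e-8, i.e. 4 cM/Mb, a
    typical plant genome-wide average).  Pool sizes default to 20/20
    seedlings per phenotype class.
    """

    chrom: str = "chr2"
    chrom_length: int = 25_000_000
    n_markers: int = 500
    causal_pos: int = 6_500_000
    recomb_rate: float = 4e-8
    n_offspring: int = 200
    pool_size: int = 20
    depth: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.causal_pos <= self.chrom_length):
            raise ValueError("causal position outside chromosome")
        if self.pool_size > self.n_offspring:
            raise ValueError("pool size exceeds offspring count")


def simulate_bc1(
    config: Bc1SimConfig,
) -> Tuple[List[VariantRecord], List[PoolSite], dict]:
    """Simulate a BC1 cross and phenotype-pooled sequencing.

    The donor (resistant) parent is homozygous for the alt allele at every
    marker, the recurrent parent homozygous ref.  Each BC1 offspring is one
    recombinant F1 gamete (Haldane model) plus a recurrent-parent gamete, so
    genotypes are het or hom-recurrent.  Resistance is dominant: an
    offspring is resistant iff heterozygous at the causal marker.  Pools of
    ``pool_size`` per class are drawn after a seeded shuffle, and pooled
    donor-allele read counts at each marker are Binomial(depth, pool
    donor-allele frequency).

    Returns (parent VCF records for samples [donor_parent, recurrent_parent],
    pooled sites, truth record).
    """
    rng = np.random.default_rng(config.seed)
    spacing = config.chrom_length / (config.n_markers + 1)
    positions = np.unique(
        np.round(spacing * np.arange(1, config.n_markers + 1)).astype(np.int64)
    )
    positions = np.unique(np.append(positions, config.causal_pos))
    causal_idx = int(np.searchsorted(positions, config.causal_pos))
    n_mark = len(positions)

    for _attempt in range(20):
        # F1 gamete: donor-allele carrier state along the chromosome
        start = rng.integers(0, 2, size=config.n_offspring)
        dists = np.diff(positions).astype(float)
        c = 0.5 * (1.0 - np.exp(-2.0 * config.recomb_rate * dists))
        switches = rng.random((config.n_offspring, n_mark - 1)) < c
        het = np.empty((config.n_offspring, n_mark), dtype=np.int8)
        het[:, 0] = start
        het[:, 1:] = (start[:, None] + np.cumsum(switches, axis=1)) % 2
        resistant = het[:, causal_idx] == 1
        if resistant.sum() >= config.pool_size and (
            (~resistant).sum() >= config.pool_size
        ):
            break
    else:
        raise RuntimeError("could not populate both phenotype pools")

    res_members = rng.permutation(np.flatnonzero(resistant))[: config.pool_size]
    sus_members = rng.permutation(np.flatnonzero(~resistant))[: config.pool_size]

    def pool_counts(members: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        # each het individual carries 1 donor allele of 2
        freq = het[members].sum(axis=0) / (2.0 * len(members))
        donor = rng.binomial(config.depth, freq)
        return donor, config.depth - donor

    donor_res, other_res = pool_counts(res_members)
    donor_sus, other_sus = pool_counts(sus_members)

    sites = [
        PoolSite(
            config.chrom,
            int(positions[i]),
            int(donor_res[i]),
            int(other_res[i]),
            int(donor_sus[i]),
            int(other_sus[i]),
        )
        for i in range(n_mark)
    ]

    parent_records = [
        VariantRecord(
            chrom=config.chrom,
            pos=int(positions[i]),
            ref="A",
            alt="T",
            genotypes=np.array([2, 0], dtype=np.int8),  # donor hom alt
            depths=np.array([config.depth, config.depth], dtype=np.int32),
            gqs=np.array([99, 99], dtype=np.int32),
            mapping_quality=60.0,
        )
        for i in range(n_mark)
    ]

    truth = {
        "causal_pos": int(config.causal_pos),
        "chrom": config.chrom,
        "n_resistant": int(resistant.sum()),
        "n_susceptible": int((~resistant).sum()),
        "expected_delta_at_causal": 0.5,
        "config": asdict(config),
    }
    return parent_records, sites, truth


# ---------------------------------------------------------------------------
# two-group sweep matrix
# ---------------------------------------------------------------------------


@dataclass
class SweepSimConfig:
    """Two-group genotype-matrix simulation with a planted sweep.

    Background alt-allele frequencies are shared between groups and drawn
    from Beta(``beta_a``, ``beta_b``); genotypes are Binomial(2, p) per
    sample (Hardy-Weinberg, no structure).  Inside the sweep interval the
    high group's frequency is pushed toward the nearer boundary with
    exponent ``gamma`` (gamma = 1 is the null).
    """

    n_high: int = 10
    n_low: int = 27
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    snp_density: float = 1 / 500.0  # SNPs per bp
    beta_a: float = 0.5
    beta_b: float = 0.5
    sweep_start: int = 4_950_001
    sweep_end: int = 5_050_000
    gamma: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.sweep_start <= self.sweep_end <= self.chrom_length):
            raise ValueError("sweep interval outside chromosome")
        if min(self.n_high, self.n_low) < 2:
            raise ValueError("need >= 2 samples per group")


def _warp_frequency(p: np.ndarray, gamma: float) -> np.ndarray:
    """Push frequencies toward the nearer boundary (fixation) for gamma > 1."""
    low = p <= 0.5
    out = np.empty_like(p)
    out[low] = p[low] ** gamma
    out[~low] = 1.0 - (1.0 - p[~low]) ** gamma
    return out


def simulate_sweep(
    config: SweepSimConfig,
) -> Tuple[GenotypeMatrix, GroupAssignment, dict]:
    """Simulate the two-group matrix with a sweep planted in the high group."""
    rng = np.random.default_rng(config.seed)
    n_target = int(config.chrom_length * config.snp_density)
    draw = rng.integers(1, config.chrom_length + 1, size=int(n_target * 1.2) + 100)
    positions = np.unique(draw)
    while len(positions) < n_target:  # pragma: no cover - rare top-up
        extra = rng.integers(1, config.chrom_length + 1, size=n_target)
        positions = np.unique(np.append(positions, extra))
    positions = np.sort(rng.choice(positions, size=n_target, replace=False))

    p = rng.beta(config.beta_a, config.beta_b, size=n_target)
    in_sweep = (positions >= config.sweep_start) & (positions <= config.sweep_end)
    p_high = p.copy()
    p_high[in_sweep] = _warp_frequency(p[in_sweep], config.gamma)

    high = rng.binomial(2, p_high[:, None], size=(n_target, config.n_high))
    low = rng.binomial(2, p[:, None], size=(n_target, config.n_low))

    samples = [f"hi{i:02d}" for i in range(config.n_high)] + [
        f"lo{i:02d}" for i in range(config.n_low)
    ]
    matrix = GenotypeMatrix(
        samples=samples,
        chroms=np.array([config.chrom] * n_target, dtype=object),
        positions=positions,
        dosages=np.hstack([high, low]).astype(np.int8),
    )
    groups = GroupAssignment(
        {s: ("high" if s.startswith("hi") else "low") for s in samples}
    )
    truth = {
        "sweep_start": int(config.sweep_start),
        "sweep_end": int(config.sweep_end),
        "sweep_mid": int((config.sweep_start + config.sweep_end) // 2),
        "gamma": config.gamma,
        "n_sites": int(n_target),
        "config": asdict(config),
    }
    return matrix, groups, truth


# ---------------------------------------------------------------------------
# k-mer histogram
# ---------------------------------------------------------------------------


def simulate_kmer_histogram(
    genome_size: int,
    depth: float,
    error_fraction: float = 0.0,
    seed: int = 0,
    k: int = 17,
) -> Tuple[KmerHistogram, dict]:
    """Poisson k-mer coverage over a single-copy genome plus error singletons.

    Each of ``genome_size`` distinct true k-mers receives Poisson(``depth``)
    observations; ``error_fraction * genome_size * depth`` distinct error
    k-mers are added at depth 1 (sequencing errors generate near-unique
    k-mers).  The truth record tracks the exact instance total.
    """
    if genome_size < 10_000:
        raise ValueError("genome_size must be >= 1e4")
    rng = np.random.default_rng(seed)
    draws = rng.poisson(depth, size=genome_size)
    observed = draws[draws > 0]
    hist = np.bincount(observed)
    counts = {int(d): int(c) for d, c in enumerate(hist) if d >= 1 and c > 0}
    n_error = int(round(error_fraction * genome_size * depth))
    if n_error:
        counts[1] = counts.get(1, 0) + n_error
    truth = {
        "genome_size": int(genome_size),
        "depth": float(depth),
        "n_error_kmers": n_error,
        "total_instances": int(draws.sum()) + n_error,
    }
    return KmerHistogram(k=k, counts=counts), truth


# ---------------------------------------------------------------------------
# codon-aligned pairs
# ---------------------------------------------------------------------------

_NON_4D_CODONS = ("ATG", "TGG", "AAT", "GAT", "TTT", "CAT")


def simulate_codon_pairs(
    n_codons: int,
    tv_prob: float,
    ts_prob: float = 0.0,
    seed: int = 0,
    n_pairs: int = 1,
    non4d_fraction: float = 0.1,
) -> Tuple[List[CodonAlignment], dict]:
    """Codon alignments with controlled third-position substitution rates.

    Sequence A mixes fourfold-degenerate codons with a ``non4d_fraction``
    spike of non-degenerate codons; B copies A and, at each 4D codon's third
    position, mutates to a transversion with probability ``tv_prob`` or a
    transition with probability ``ts_prob``.  Non-degenerate codons are left
    untouched, so the pair stays codon-aligned.
    """
    if tv_prob + ts_prob > 1:
        raise ValueError("tv_prob + ts_prob must be <= 1")
    rng = np.random.default_rng(seed)
    prefixes = sorted(FOURFOLD_PREFIXES)
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

    pairs: List[CodonAlignment] = []
    planted_sites = 0
    planted_tv = 0
    for _ in range(n_pairs):
        a_codons: List[str] = []
        b_codons: List[str] = []
        for _ in range(n_codons):
            if rng.random() < non4d_fraction:
                codon = _NON_4D_CODONS[rng.integers(len(_NON_4D_CODONS))]
                a_codons.append(codon)
                b_codons.append(codon)
                continue
            prefix = prefixes[rng.integers(len(prefixes))]
            third = "ACGT"[rng.integers(4)]
            a_codons.append(prefix + third)
            planted_sites += 1
            u = rng.random()
            if u < tv_prob:
                partner = transversions[third][rng.integers(2)]
                b_codons.append(prefix + partner)
                planted_tv += 1
            elif u < tv_prob + ts_prob:
                b_codons.append(prefix + transition[third])
            else:
                b_codons.append(prefix + third)
        pairs.append(CodonAlignment("".join(a_codons), "".join(b_codons)))
    truth = {
        "tv_prob": tv_prob,
        "ts_prob": ts_prob,
        "planted_4d_sites": planted_sites,
        "planted_transversions": planted_tv,
    }
    return pairs, truth


# ---------------------------------------------------------------------------
# gene-origin fixture
# ---------------------------------------------------------------------------


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with a different random base with prob ``rate``."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hit:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def simulate_origin_fixture(
    n_genes: int,
    donor_divergences: Tuple[float, float] = (0.02, 0.10),
    seed: int = 0,
    donors: Sequence[str] = ("speciesA", "speciesB"),
    gene_length: int = 300,
) -> Tuple[Dict[str, str], DonorCatalog, dict]:
    """Query genes with a planted donor species.

    For each query gene a true donor is drawn; the query diverges from that
    donor's ortholog at ``donor_divergences[0]`` (near) and from every other
    donor's ortholog at ``donor_divergences[1]`` (far).  Returns (query
    sequences, donor catalog, truth labels).
    """
    if len(donors) < 1:
        raise ValueError("need >= 1 donor species")
    near, far = donor_divergences
    if not (0 <= near <= far <= 1):
        raise ValueError("require 0 <= near <= far <= 1")
    rng = np.random.default_rng(seed)
    queries: Dict[str, str] = {}
    catalog: Dict[str, Dict[str, str]] = {sp: {} for sp in donors}
    labels: Dict[str, str] = {}
    for g in range(n_genes):
        gid = f"gene{g:04d}"
        base = _BASES[rng.integers(4, size=gene_length)]
        true_donor = donors[rng.integers(len(donors))]
        labels[gid] = true_donor
        queries[gid] = "".join(_mutate(base, near, rng))
        for sp in donors:
            rate = 0.0 if sp == true_donor else far
            catalog[sp][f"{sp}_{gid}"] = "".join(_mutate(base, rate, rng))
    truth = {
        "labels": labels,
        "near_divergence": near,
        "far_divergence": far,
    }
    return queries, DonorCatalog(catalog), truth
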