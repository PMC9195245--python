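"""4DTv: transversion rate at fourfold-degenerate codon third positions.

For a codon-aligned pair of coding sequences, a site is eligible iff both
codons are fourfold degenerate under the standard genetic code, their first
two positions are identical, and neither codon contains a gap or ambiguity.
The statistic is the raw proportion

    4DTv = (# transversional differences at eligible third positions)
           / (# eligible third positions)

Transversions exchange a purine for a pyrimidine ({A,G} x {C,T}).  Because
transversions saturate slowly, 4DTv serves as a divergence proxy for dating
whole-genome duplication and speciation events; block values pool counts
over the gene pairs of a syntenic block (a ratio of sums, not a mean of
per-pair ratios).  No multiple-substitution correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

__all__ = [
    "FOURFOLD_PREFIXES",
    "CodonAlignment",
    "FourDTvResult",
    "is_fourfold_degenerate",
    "four_dtv",
    "block_four_dtv",
]

# codon families whose third position is free under the standard code
FOURFOLD_PREFIXES = frozenset(
    {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class CodonAlignment:
    """Two aligned coding sequences; equal length, divisible by 3."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")

    def codons(self) -> Iterable[Tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass(frozen=True)
class FourDTvResult:
    n_4d_sites: int
    n_transversions: int

    @property
    def value(self) -> Optional[float]:
        if self.n_4d_sites == 0:
            return None
        return self.n_transversions / self.n_4d_sites


def is_fourfold_degenerate(codon: str) -> bool:
    """True iff every base at the codon's third position encodes the same
    amino acid (standard genetic code).  Gaps/ambiguity codes -> False."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        return False
    return codon[:2] in FOURFOLD_PREFIXES


def _is_transversion(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PYRIMIDINES) or (
        a in _PYRIMIDINES and b in _PURINES
    )


def four_dtv(alignment: CodonAlignment) -> FourDTvResult:
    """Count eligible fourfold-degenerate sites and their transversions.

    Symmetric in the two sequences.  ``value`` is None when no site is
    eligible.
    """
    n_sites = 0
    n_tv = 0
    for ca, cb in alignment.codons():
        if not (is_fourfold_degenerate(ca) and is_fourfold_degenerate(cb)):
            continue
        if ca[:2] != cb[:2]:
            continue
        n_sites += 1
        if ca[2] != cb[2] and _is_transversion(ca[2], cb[2]):
            n_tv += 1
    return FourDTvResult(n_sites, n_tv)


def block_four_dtv(alignments: Sequence[CodonAlignment]) -> FourDTvResult:
    """Pooled 4DTv over the gene pairs of one syntenic block.

    Sums transversions and eligible sites across pairs before dividing —
    pairs with more eligible sites weigh more than in a mean of per-pair
    values.
    """
    if not alignments:
        raise ValueError("block must contain >= 1 alignment")
    n_sites = 0
    n_tv = 0
    for aln in alignments:
        r = four_dtv(aln)
        n_sites += r.n_4d_sites
        n_tv += r.n_transversions
    return FourDTvResult(n_sites, n_tv)
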