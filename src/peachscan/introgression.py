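"""Gene-origin assignment by best local-alignment score, plus pan-genome
gene-family presence/absence classification.

A hybrid genome's genes are traced to their putative parental species by
aligning each gene against candidate orthologs from every donor species and
assigning the gene to the species attaining the strictly highest local
alignment score.  Ties, or scores below a floor or within a margin of the
runner-up, yield ``"ambiguous"``.

The aligner is a self-contained affine-gap Smith–Waterman with BLASTN-like
defaults (match +1, mismatch −2, gap open −5, gap extend −2; a length-L gap
costs open + L*extend).  ``N`` never matches anything and scores as a
mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Scoring",
    "DonorCatalog",
    "OriginAssignment",
    "local_align_score",
    "assign_gene_origin",
    "summarize_origins",
    "classify_families",
    "read_fasta_dict",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_N_CODE = 4  # matches nothing, scores as mismatch


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class DonorCatalog:
    """Species -> {gene id: nucleotide sequence} candidate orthologs."""

    species: Dict[str, Dict[str, str]]

    def __post_init__(self) -> None:
        if len(self.species) < 1:
            raise ValueError("catalog is empty")
        for sp, genes in self.species.items():
            for gid, seq in genes.items():
                if not seq or set(seq.upper()) - set("ACGTN"):
                    raise ValueError(f"bad sequence for {sp}/{gid}")


@dataclass
class OriginAssignment:
    query_id: str
    scores: Dict[str, int]  # species -> best score
    assigned: str  # species name or "ambiguous"


def _encode(seq: str) -> np.ndarray:
    return np.array(
        [_BASE_CODE.get(b, _N_CODE) for b in seq.upper()], dtype=np.int8
    )


def _sw_python(a, b, match, mismatch, gap_open, gap_extend):
    """Affine-gap local alignment, plain-Python fallback."""
    m, n = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[neg] * (n + 1) for _ in range(m + 1)]  # gap in a (horizontal)
    F = [[neg] * (n + 1) for _ in range(m + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open + gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != _N_CODE) else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True)
    def _sw_numba(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
        m, n = len(a), len(b)
        H_prev = np.zeros(n + 1, dtype=np.float64)
        H_cur = np.zeros(n + 1, dtype=np.float64)
        E = np.full(n + 1, -1e18)
        F_prev = np.full(n + 1, -1e18)
        F_cur = np.full(n + 1, -1e18)
        best = 0.0
        for i in range(1, m + 1):
            H_cur[0] = 0.0
            E[0] = -1e18
            for j in range(1, n + 1):
                e = max(E[j - 1] + gap_extend, H_cur[j - 1] + gap_open + gap_extend)
                f = max(F_prev[j] + gap_extend, H_prev[j] + gap_open + gap_extend)
                if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                    s = match
                else:
                    s = mismatch
                h = H_prev[j - 1] + s
                if e > h:
                    h = e
                if f > h:
                    h = f
                if h < 0.0:
                    h = 0.0
                H_cur[j] = h
                E[j] = e
                F_cur[j] = f
                if h > best:
                    best = h
            H_prev, H_cur = H_cur, H_prev
            F_prev, F_cur = F_cur, F_prev
        return best

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def local_align_score(
    seq_a: str, seq_b: str, scoring: Scoring = Scoring()
) -> int:
    """Best affine-gap Smith–Waterman local alignment score.

    Symmetric in its arguments; an empty sequence scores 0.
    """
    if not seq_a or not seq_b:
        return 0
    a, b = _encode(seq_a), _encode(seq_b)
    args = (
        float(scoring.match),
        float(scoring.mismatch),
        float(scoring.gap_open),
        float(scoring.gap_extend),
    )
    if _HAVE_NUMBA:
        best = _sw_numba(a, b, *args)
    else:
        best = _sw_python(a, b, *args)
    return int(round(best))


def assign_gene_origin(
    query_id: str,
    query_seq: str,
    catalog: DonorCatalog,
    min_score: int = 0,
    margin: int = 0,
    scoring: Scoring = Scoring(),
) -> OriginAssignment:
    """Assign a query gene to the donor species with the best alignment score.

    Per species the score is the maximum over its candidate orthologs.  The
    assignment is the species with the strict maximum, provided its score is
    >= ``min_score`` and exceeds the runner-up by >= ``margin``; exact ties
    (and failures of either condition) give ``"ambiguous"``.  Invariant to
    catalog species ordering.
    """
    scores: Dict[str, int] = {}
    for sp in sorted(catalog.species):
        genes = catalog.species[sp]
        scores[sp] = max(
            (local_align_score(query_seq, seq, scoring) for seq in genes.values()),
            default=0,
        )
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_sp, best = ordered[0]
    second = ordered[1][1] if len(ordered) > 1 else float("-inf")
    if best < min_score or best == second or best - second < margin:
        assigned = "ambiguous"
    else:
        assigned = best_sp
    return OriginAssignment(query_id, scores, assigned)


def summarize_origins(
    assignments: Sequence[OriginAssignment],
) -> Dict[str, float]:
    """Fraction of queries assigned per species; 'ambiguous' is its own class."""
    if not assignments:
        raise ValueError("no assignments to summarize")
    counts: Dict[str, int] = {}
    for a in assignments:
        counts[a.assigned] = counts.get(a.assigned, 0) + 1
    total = len(assignments)
    return {k: v / total for k, v in sorted(counts.items())}


# ---------------------------------------------------------------------------
# pan-genome family presence/absence
# ---------------------------------------------------------------------------


def classify_families(matrix: pd.DataFrame) -> Tuple[pd.Series, Dict[str, int], Dict[str, int]]:
    """Classify gene families as core / dispensable / species-specific.

    ``matrix`` is families x species with 0/1 (or boolean) presence.  A
    family present in every species is *core*; present in exactly one is
    *specific* (to that species); anything in between is *dispensable*.

    Returns (per-family class Series, class counts, per-species specific
    counts).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 species columns")
    present = matrix.astype(bool)
    n_present = present.sum(axis=1)
    if (n_present == 0).any():
        raise ValueError("every family must be present in >= 1 species")
    n_species = matrix.shape[1]
    cls = pd.Series("dispensable", index=matrix.index, dtype=object)
    cls[n_present == n_species] = "core"
    cls[n_present == 1] = "specific"
    counts = {
        "core": int((cls == "core").sum()),
        "dispensable": int((cls == "dispensable").sum()),
        "specific": int((cls == "specific").sum()),
    }
    specific_rows = present.loc[cls == "specific"]
    per_species = {
        sp: int(specific_rows[sp].sum()) for sp in matrix.columns
    }
    return cls, counts, per_species


# ---------------------------------------------------------------------------
# FASTA convenience
# ---------------------------------------------------------------------------


def read_fasta_dict(path: str) -> Dict[str, str]:
    """Read a FASTA file into {id: uppercase sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
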