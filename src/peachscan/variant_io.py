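"""Variant and annotation I/O plus population-level SNP quality filtering.

Coordinates are 1-based inclusive throughout the package; BED input/output
converts at the boundary.  Genotypes are alt-allele dosages in {0, 1, 2},
with -1 marking a missing call — a missing genotype is never encoded as 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam

MISSING = -1

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeInterval:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class VariantRecord:
    """One biallelic site with per-sample dosages, depths and qualities.

    Arrays are aligned to the sample list returned alongside the records.
    ``genotypes`` holds alt-allele dosages; ``MISSING`` (-1) flags a missing
    call.  ``depths`` / ``gqs`` are -1 where the field is absent in the VCF.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: np.ndarray  # int8, dosage or MISSING
    depths: np.ndarray  # int32, -1 = absent
    gqs: np.ndarray  # int32, -1 = absent
    mapping_quality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def missing_fraction(self) -> float:
        gt = np.asarray(self.genotypes)
        return float(np.mean(gt == MISSING))


@dataclass
class GeneModel:
    """A gene with its span, strand, and ordered CDS intervals."""

    gene_id: str
    interval: GenomeInterval
    strand: str = "+"
    cds: List[GenomeInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        for c in self.cds:
            if not (
                c.chrom == self.interval.chrom
                and self.interval.start <= c.start
                and c.end <= self.interval.end
            ):
                raise ValueError(f"CDS {c} outside gene {self.interval}")

    @property
    def cds_length(self) -> int:
        return sum(c.length for c in self.cds)


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------


def _dosage(gt: Tuple) -> int:
    if gt is None or any(a is None for a in gt):
        return MISSING
    return int(sum(1 for a in gt if a != 0))


def read_vcf(
    path: str,
    samples: Optional[Sequence[str]] = None,
    multiallelic: str = "skip",
) -> Tuple[List[str], List[VariantRecord]]:
    """Read a VCF 4.x file into (sample names, sorted VariantRecords).

    Parameters
    ----------
    samples
        Optional subset of sample names to load, in the order given.
    multiallelic
        ``"skip"`` drops multi-allelic sites (the default: every downstream
        statistic assumes biallelic sites); ``"split"`` emits one biallelic
        record per alt allele, with other-alt calls set missing.
    """
    if multiallelic not in {"skip", "split"}:
        raise ValueError("multiallelic must be 'skip' or 'split'")
    with pysam.VariantFile(path) as vf:
        all_samples = list(vf.header.samples)
        if samples is None:
            keep = all_samples
        else:
            missing = set(samples) - set(all_samples)
            if missing:
                raise ValueError(f"samples not in VCF: {sorted(missing)}")
            keep = list(samples)
        idx = [all_samples.index(s) for s in keep]

        records: List[VariantRecord] = []
        last: Tuple[str, int] | None = None
        for rec in vf:
            if last is not None and rec.chrom == last[0] and rec.pos < last[1]:
                raise ValueError(f"VCF not sorted at {rec.chrom}:{rec.pos}")
            last = (rec.chrom, rec.pos)
            alts = rec.alts or ()
            if len(alts) == 0:
                continue
            if len(alts) > 1 and multiallelic == "skip":
                continue
            try:
                mq = rec.info.get("MQ", None)
            except (KeyError, ValueError):  # MQ not declared in header
                mq = None
            if isinstance(mq, tuple):
                mq = mq[0]
            for ai, alt in enumerate(alts, start=1):
                gts = np.full(len(keep), MISSING, dtype=np.int8)
                dps = np.full(len(keep), -1, dtype=np.int32)
                gqs = np.full(len(keep), -1, dtype=np.int32)
                for out_i, samp_i in enumerate(idx):
                    sd = rec.samples[keep[out_i]]
                    gt = sd.get("GT")
                    if gt is not None and not any(a is None for a in gt):
                        if all(a in (0, ai) for a in gt):
                            gts[out_i] = sum(1 for a in gt if a == ai)
                        # calls involving another alt stay missing for this split
                    dp = sd.get("DP")
                    if dp is not None:
                        dps[out_i] = int(dp)
                    gq = sd.get("GQ")
                    if gq is not None:
                        gqs[out_i] = int(gq)
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        genotypes=gts,
                        depths=dps,
                        gqs=gqs,
                        mapping_quality=float(mq) if mq is not None else None,
                    )
                )
    return keep, records


def write_vcf(
    path: str,
    samples: Sequence[str],
    records: Iterable[VariantRecord],
    contigs: Optional[Sequence[Tuple[str, int]]] = None,
) -> None:
    """Write records to a VCF 4.2 file (plain text or .gz by extension)."""
    records = list(records)
    header = pysam.VariantHeader()
    if contigs is None:
        seen: dict[str, int] = {}
        for r in records:
            seen[r.chrom] = max(seen.get(r.chrom, 0), r.pos)
        contigs = [(c, L + 1000) for c, L in seen.items()]
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for s in samples:
        header.add_sample(s)
    mode = "wz" if str(path).endswith(".gz") else "w"
    with pysam.VariantFile(path, mode, header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt),
            )
            if r.mapping_quality is not None:
                rec.info["MQ"] = float(r.mapping_quality)
            for i, s in enumerate(samples):
                g = int(r.genotypes[i])
                if g == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[g]
                if r.depths[i] >= 0:
                    rec.samples[s]["DP"] = int(r.depths[i])
                if r.gqs[i] >= 0:
                    rec.samples[s]["GQ"] = int(r.gqs[i])
            out.write(rec)


# ---------------------------------------------------------------------------
# population SNP filter
# ---------------------------------------------------------------------------


def filter_population_snps(
    records: Iterable[VariantRecord],
    min_mq: float = 20.0,
    min_dp: int = 5,
    min_gq: int = 5,
    max_missing: float = 0.2,
) -> List[VariantRecord]:
    """Apply population-level SNP quality filters.

    A site is kept when its mapping quality is >= ``min_mq`` and, after
    masking every sample call with depth < ``min_dp`` or genotype quality
    < ``min_gq`` (missing depth/quality fields count as failing), the
    missing-call fraction is < ``max_missing``.  The depth threshold is
    applied per sample — it masks that sample's call — because the
    missingness rule downstream is only meaningful after per-sample masking.
    The operation is idempotent.
    """
    out: List[VariantRecord] = []
    for rec in records:
        if rec.mapping_quality is None or rec.mapping_quality < min_mq:
            continue
        gts = np.array(rec.genotypes, dtype=np.int8, copy=True)
        called = gts != MISSING
        bad = (rec.depths < min_dp) | (rec.gqs < min_gq)
        gts[called & bad] = MISSING
        if np.mean(gts == MISSING) >= max_missing:
            continue
        out.append(replace(rec, genotypes=gts))
    return out


# ---------------------------------------------------------------------------
# gene models (GFF3 / BED6)
# ---------------------------------------------------------------------------


def read_gene_models(path: str) -> List[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/CDS) or BED6, by extension.

    BED half-open coordinates are converted to the 1-based inclusive internal
    convention (start + 1).
    """
    lower = str(path).lower()
    if lower.endswith((".bed", ".bed.gz")):
        return _read_bed6(path)
    return _read_gff3(path)


def _read_bed6(path: str) -> List[GeneModel]:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    models = []
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {i + 1}")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"feature_{i + 1}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            models.append(
                GeneModel(name, GenomeInterval(chrom, start0 + 1, end), strand)
            )
    return models


def _read_gff3(path: str) -> List[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = gene.id
        interval = GenomeInterval(gene.seqid, gene.start, gene.end)
        cds = []
        for c in db.children(gene, featuretype="CDS", order_by="start"):
            ci = GenomeInterval(c.seqid, c.start, c.end)
            if not (
                ci.chrom == interval.chrom
                and interval.start <= ci.start
                and ci.end <= interval.end
            ):
                raise ValueError(f"CDS {ci} outside gene {gid}")
            cds.append(ci)
        models.append(GeneModel(gid, interval, gene.strand or "+", cds))
    return models


def write_bed(path: str, models: Sequence[GeneModel]) -> None:
    """Write gene spans as BED6 (converting back to half-open coordinates)."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                f"{m.interval.chrom}\t{m.interval.start - 1}\t{m.interval.end}"
                f"\t{m.gene_id}\t.\t{m.strand}\n"
            )
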