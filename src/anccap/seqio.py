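"""Sequence/alignment containers, standard-format I/O and the MAPQ filter.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based convention happens only at the SAM boundary.  The SAM dialect
written here is the 11 mandatory columns with a full-length match CIGAR;
the reader additionally accepts soft-clipped alignments (clipped bases are
trimmed) but rejects indel CIGARs, since the downstream pileup assumes
column-aligned reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN-acgtn", "TGCAN-tgcan")


def revcomp(bases: str) -> str:
    """Reverse complement of a nucleotide string (N and ``-`` preserved)."""
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceSequence:
    """A named nucleotide sequence acting as ancestor, bait source or target.

    Parameters
    ----------
    id :
        Sequence identifier (FASTA header word).
    bases :
        Upper-case nucleotide string over ``{A, C, G, T}`` (``N`` tolerated
        in consensus-derived sequences).
    circular :
        Whether the molecule is circular.  Mitogenomes are generated
        circular but linearised at position 0 for every downstream step;
        no fragment spans the origin.
    cds :
        Optional CDS annotations as ``(name, start, end, strand)`` tuples
        in 0-based half-open coordinates, strand in ``{+, -}``.
    """

    id: str
    bases: str
    circular: bool = False
    cds: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("reference sequence must be non-empty")
        n = len(self.bases)
        for name, start, end, strand in self.cds:
            if not (0 <= start < end <= n):
                raise ValueError(f"CDS {name!r} interval [{start},{end}) outside [0,{n})")
            if strand not in "+-":
                raise ValueError(f"CDS {name!r} strand must be + or -")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignedRead:
    """A read with its reference placement.

    ``bases`` are stored in reference orientation (as in a SAM SEQ field);
    ``strand`` is ``-`` when the read derives from the reverse strand.
    In full-match mode ``end - start == len(bases)``.
    """

    name: str
    ref_id: str
    start: int
    end: int
    strand: str
    mapq: int
    bases: str
    duplicate: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read {self.name}: start must be < end")
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"read {self.name}: mapq {self.mapq} outside [0, 60]")
        if self.strand not in "+-":
            raise ValueError(f"read {self.name}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read all records of a FASTA file; duplicate ids are an error."""
    seqs: list[ReferenceSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        bases = str(rec.seq).upper()
        if not bases:
            raise ValueError(f"FASTA record {rec.id!r} has no sequence")
        seqs.append(ReferenceSequence(id=rec.id, bases=bases))
    return seqs


def write_fasta(seqs: Iterable[ReferenceSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SAM dialect

_ALLOWED_CIGAR_OPS = {0, 4, 7, 8}  # M, S, =, X


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Parse the SAM dialect into :class:`AlignedRead` records.

    Unmapped records are skipped (with a logged count); soft-clipped bases
    are trimmed; indel or reference-skip CIGAR operations raise, because the
    pileup downstream assumes every read base is column-aligned.
    """
    reads: list[AlignedRead] = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            if seg.is_unmapped:
                n_unmapped += 1
                continue
            ops = {op for op, _ in (seg.cigartuples or [])}
            bad = ops - _ALLOWED_CIGAR_OPS
            if bad:
                raise ValueError(
                    f"read {seg.query_name}: unsupported CIGAR operations {sorted(bad)}; "
                    "only column-aligned (match/soft-clip) reads are accepted"
                )
            bases = seg.query_alignment_sequence  # soft clips already trimmed
            reads.append(
                AlignedRead(
                    name=seg.query_name,
                    ref_id=seg.reference_name,
                    start=seg.reference_start,
                    end=seg.reference_end,
                    strand="-" if seg.is_reverse else "+",
                    mapq=seg.mapping_quality,
                    bases=bases.upper(),
                    duplicate=seg.is_duplicate,
                )
            )
    if n_unmapped:
        log.info("skipped %d unmapped records in %s", n_unmapped, path)
    return reads


def write_sam(reads: Iterable[AlignedRead], ref: ReferenceSequence, path: str | Path) -> None:
    """Write reads as minimal SAM (full-length match CIGAR, no qualities)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{ref.id}\tLN:{len(ref)}\n")
        for r in reads:
            if r.ref_id != ref.id:
                raise ValueError(f"read {r.name} references {r.ref_id!r}, header declares {ref.id!r}")
            flag = (16 if r.strand == "-" else 0) | (1024 if r.duplicate else 0)
            fh.write(
                f"{r.name}\t{flag}\t{r.ref_id}\t{r.start + 1}\t{r.mapq}\t"
                f"{len(r)}M\t*\t0\t0\t{r.bases}\t*\n"
            )


# ---------------------------------------------------------------------------
# MAPQ filter


def filter_mapq(reads: Sequence[AlignedRead], min_mapq: int = 30) -> list[AlignedRead]:
    """Drop reads with mapping quality below ``min_mapq`` (default Q30).

    The threshold is exclusive on the low side: a read at exactly
    ``min_mapq`` is retained.  Input order is preserved and the operation
    is idempotent.
    """
    return [r for r in reads if r.mapq >= min_mapq]
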