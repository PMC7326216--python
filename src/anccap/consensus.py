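"""Pileup construction, depth/majority consensus calling and numt screening.

The consensus rule is deliberately stringent: a base is called only where
read depth is at least ``min_depth`` (default 3) and a single allele
accounts for at least the ``majority`` fraction (default 0.90) of the
depth; every other position becomes N.  Mixed columns — the signature of
co-enriched nuclear copies of mitochondrial DNA (numts) — therefore drop
out of the consensus instead of being incorporated.  A second numt guard
translates CDS annotations with the vertebrate mitochondrial code and
reports internal stop codons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from anccap.seqio import AlignedRead, revcomp

log = logging.getLogger(__name__)

_ALPHABET = "ACGT-N"  # column order of the tally matrix; '-' is a read deletion
_INDEX = {b: i for i, b in enumerate(_ALPHABET)}


@dataclass
class PileupColumn:
    """Per-position tally over {A, C, G, T, deletion, N}.

    ``depth`` counts A/C/G/T/deletion observations; N is uninformative and
    never contributes to depth.
    """

    position: int
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(v for b, v in self.counts.items() if b != "N")


@dataclass
class ConsensusParams:
    min_depth: int = 3
    majority: float = 0.90

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.5 < self.majority <= 1.0:
            raise ValueError("majority must be in (0.5, 1.0]")


class Pileup:
    """Column tallies for one reference, backed by a (length, 6) count matrix."""

    def __init__(self, counts: np.ndarray):
        self.counts = counts

    def __len__(self) -> int:
        return self.counts.shape[0]

    def __getitem__(self, position: int) -> PileupColumn:
        row = self.counts[position]
        return PileupColumn(position=position, counts={b: int(row[i]) for i, b in enumerate(_ALPHABET)})

    @property
    def depth(self) -> np.ndarray:
        """Per-position depth (N excluded)."""
        return self.counts[:, :5].sum(axis=1)


def pileup(reads: Sequence[AlignedRead], ref_length: int) -> Pileup:
    """Tally read bases per reference position.

    Reads must be column-aligned (full-match placements); a read whose
    coordinates exceed ``ref_length`` is an error.
    """
    counts = np.zeros((ref_length, 6), dtype=np.int32)
    if reads:
        pos_parts, code_parts = [], []
        for r in reads:
            if r.end > ref_length:
                raise ValueError(f"read {r.name} ends at {r.end}, reference length {ref_length}")
            if len(r.bases) != len(r):
                raise ValueError(f"read {r.name}: bases/interval length mismatch")
            pos_parts.append(np.arange(r.start, r.end))
            code_parts.append(np.array([_INDEX[b] for b in r.bases], dtype=np.int64))
        pos = np.concatenate(pos_parts)
        codes = np.concatenate(code_parts)
        np.add.at(counts, (pos, codes), 1)
    return Pileup(counts)


@dataclass
class ConsensusSequence:
    """Called bases and depth for one reference.

    ``calls`` has one symbol per reference position over {A, C, G, T, N, -};
    a consensus deletion ('-') is excised from :attr:`sequence` but keeps
    its slot in ``calls`` and ``depth``.
    """

    ref_id: str
    calls: str
    depth: np.ndarray

    @property
    def sequence(self) -> str:
        return self.calls.replace("-", "")


def call_consensus(pile: Pileup, params: ConsensusParams, ref_id: str = "consensus") -> ConsensusSequence:
    """Apply the min-depth / majority rule to every pileup column.

    Position p is called allele X (a base or a deletion) iff
    ``depth(p) >= min_depth`` and ``count(X)/depth(p) >= majority``;
    otherwise N.  Because ``majority > 0.5`` at most one allele can
    qualify.  Mixed columns below the majority — e.g. a numt haplotype at
    >= (1 - majority) of the reads — are masked to N rather than called.
    """
    informative = pile.counts[:, :5]
    depth = informative.sum(axis=1)
    best_idx = informative.argmax(axis=1)
    best_count = informative.max(axis=1)
    callable_ = (depth >= params.min_depth) & (best_count >= params.majority * depth) & (depth > 0)
    symbols = np.array(list(_ALPHABET[:5]))
    calls = np.where(callable_, symbols[best_idx], "N")
    return ConsensusSequence(ref_id=ref_id, calls="".join(calls), depth=depth)


def completeness(cons: ConsensusSequence, params: ConsensusParams) -> tuple[float, float]:
    """Recovery statistics: (fraction of positions at >= min_depth, mean depth).

    These are the per-sample summary statistics of a capture experiment:
    how much of the mitogenome reaches callable depth, and the average
    depth over the whole molecule (computed after MAPQ filtering and
    deduplication, per the pipeline stage order).
    """
    if len(cons.calls) == 0:
        raise ValueError("empty consensus")
    frac = float((cons.depth >= params.min_depth).mean())
    return frac, float(cons.depth.mean())


def screen_stop_codons(
    seq: str,
    cds: Sequence[tuple[str, int, int, str]],
    table_id: int = 2,
) -> tuple[list[tuple[str, int]], dict[str, int]]:
    """Report internal stop codons in annotated CDS under a mito code.

    Translates each CDS (minus-strand CDS are reverse-complemented first)
    with the NCBI genetic code ``table_id`` (2 = vertebrate mitochondrial,
    where AGA/AGG are stops in addition to TAA/TAG) and returns every stop
    strictly before the final codon as ``(cds_name, codon_index)``.
    Codons containing N are skipped and counted separately per CDS.
    An internal stop in an otherwise intact mitochondrial gene is strong
    evidence that a nuclear copy leaked into the consensus.
    """
    stops = set(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)
    violations: list[tuple[str, int]] = []
    skipped: dict[str, int] = {}
    for name, start, end, strand in cds:
        sub = seq[start:end]
        if len(sub) % 3 != 0:
            raise ValueError(f"CDS {name!r} length {len(sub)} not divisible by 3")
        if strand == "-":
            sub = revcomp(sub)
        n_codons = len(sub) // 3
        n_skipped = 0
        for i in range(n_codons - 1):  # internal codons only
            codon = sub[3 * i : 3 * i + 3]
            if "N" in codon:
                n_skipped += 1
            elif codon in stops:
                violations.append((name, i))
        skipped[name] = n_skipped
    return violations, skipped


def strip_missing_columns(rows: Sequence[str]) -> list[str]:
    """Remove every alignment column containing a non-ACGT symbol in any row."""
    if not rows:
        return []
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError("ragged alignment")
    mat = np.array([list(r) for r in rows])
    keep = np.isin(mat, list("ACGT")).all(axis=0)
    if not keep.any():
        log.warning("strip_missing_columns: every column has missing data; empty alignment")
    return ["".join(row) for row in mat[:, keep]]


def write_consensus_fasta(cons: ConsensusSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{cons.ref_id}\n")
        seq = cons.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_depth_bedgraph(cons: ConsensusSequence, path: str | Path) -> None:
    """Depth vector as BED-graph-style TSV (ref, start, end, depth), runs merged."""
    d = cons.depth
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(d) + 1):
            if i == len(d) or d[i] != d[run_start]:
                fh.write(f"{cons.ref_id}\t{run_start}\t{i}\t{int(d[run_start])}\n")
                run_start = i
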