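"""PCR-duplicate removal keyed on joint 5' and 3' fragment coordinates.

Reads are duplicates when they share reference, start, end and strand —
i.e. both mapped fragment ends coincide.  This is stricter than
start-only duplicate marking and suited to degraded-DNA libraries, where
the natural fragment-end heterogeneity makes a joint-end collision from
distinct template molecules unlikely.  A plus-strand and a minus-strand
read with identical coordinates derive from different template strands
and are *not* duplicates.
"""

from __future__ import annotations

import logging
from typing import Sequence

from anccap.seqio import AlignedRead

log = logging.getLogger(__name__)

DuplicateKey = tuple[str, int, int, str]


def duplicate_key(read: AlignedRead) -> DuplicateKey:
    return (read.ref_id, read.start, read.end, read.strand)


def mark_duplicates_start_end(reads: Sequence[AlignedRead]) -> tuple[list[AlignedRead], int]:
    """Collapse reads sharing (ref, start, end, strand) to one representative.

    The representative is the read with the greatest number of non-N bases;
    ties are broken by input order.  Returns the unique reads (ordered by
    first occurrence of their key) and the number of removed duplicates.
    Reads must all map to a single reference; group by reference first
    otherwise.
    """
    refs = {r.ref_id for r in reads}
    if len(refs) > 1:
        raise ValueError(f"reads span multiple references {sorted(refs)}; group by reference first")
    best: dict[DuplicateKey, tuple[int, AlignedRead]] = {}
    order: list[DuplicateKey] = []
    for r in reads:
        key = duplicate_key(r)
        informative = len(r.bases) - r.bases.count("N")
        if key not in best:
            best[key] = (informative, r)
            order.append(key)
        elif informative > best[key][0]:
            best[key] = (informative, r)
    uniques = [best[k][1] for k in order]
    n_dup = len(reads) - len(uniques)
    log.info("dedup: %d unique, %d duplicates removed", len(uniques), n_dup)
    return uniques, n_dup
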