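"""Bait tiling across a reference and fragment-vs-bait identity scoring.

Baits are tiled at a fixed step (2 bp in the assay this mirrors, i.e.
consecutive probes shifted by two bases).  Identity of a library fragment
against the bait set — the quantity that drives hybridisation retention —
is the best ungapped match over all baits, both orientations and all
offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from anccap.seqio import ReferenceSequence, revcomp


def _encode(bases: str) -> np.ndarray:
    # raw ASCII codes; equality of codes is equality of bases, and N never
    # matches A/C/G/T
    return np.frombuffer(bases.encode("ascii"), dtype=np.uint8)


@dataclass
class BaitSet:
    """Baits tiled across a source sequence.

    Invariants: every bait is exactly ``bait_length`` long, starts are
    strictly increasing, and each bait is the substring of the source at
    its start.
    """

    source_id: str
    bait_length: int
    step: int
    baits: list[tuple[int, str]]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.baits)

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.baits], dtype=np.int64)

    def matrix(self) -> np.ndarray:
        """Bait sequences as a (n_baits, bait_length) uint8 matrix (cached)."""
        if self._matrix is None:
            self._matrix = np.vstack([_encode(seq) for _, seq in self.baits])
        return self._matrix


def design_baits(ref: ReferenceSequence, bait_length: int = 60, step: int = 2) -> BaitSet:
    """Tile baits of ``bait_length`` every ``step`` bp across ``ref``.

    For a linear source of length L this yields ``(L - bait_length)//step + 1``
    baits; when ``L - bait_length`` is not divisible by ``step`` one extra
    terminal bait is anchored at ``L - bait_length`` so the 3' end is covered.
    """
    L = len(ref)
    if bait_length > L:
        raise ValueError(f"bait_length {bait_length} exceeds reference length {L}")
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = list(range(0, L - bait_length + 1, step))
    if starts[-1] != L - bait_length:
        starts.append(L - bait_length)
    baits = [(s, ref.bases[s : s + bait_length]) for s in starts]
    return BaitSet(source_id=ref.id, bait_length=bait_length, step=step, baits=baits)


def candidate_baits_overlapping(baits: BaitSet, start: int, end: int) -> np.ndarray:
    """Indices of baits overlapping the interval [start, end)."""
    s = baits.starts
    return np.nonzero((s + baits.bait_length > start) & (s < end))[0]


def best_bait_identity(
    fragment: str,
    baits: BaitSet,
    candidates: np.ndarray | None = None,
) -> float:
    """Best ungapped identity of ``fragment`` against the bait set.

    The maximum over all baits (optionally restricted to ``candidates``
    indices), both orientations, and all ungapped offsets at which the
    shorter sequence lies fully within the longer, of
    ``matches / compared positions`` where the number of compared positions
    is ``min(len(fragment), bait_length)``.
    """
    if not fragment:
        raise ValueError("fragment must be non-empty")
    if len(baits) == 0:
        raise ValueError("bait set is empty")
    B = baits.matrix()
    if candidates is not None:
        if len(candidates) == 0:
            raise ValueError("empty candidate set")
        B = B[candidates]
    flen = len(fragment)
    bl = baits.bait_length
    best = 0
    for seq in (fragment, revcomp(fragment)):
        f = _encode(seq)
        if flen >= bl:
            # slide a bait-length window along the fragment
            wins = sliding_window_view(f, bl)  # (offsets, bl)
            m = (B[:, None, :] == wins[None, :, :]).sum(axis=2).max()
        else:
            # slide the fragment along each bait
            bwins = sliding_window_view(B, flen, axis=1)  # (n, offsets, flen)
            m = (bwins == f).sum(axis=2).max()
        best = max(best, int(m))
    return best / min(flen, bl)


def write_baits_fasta(baits: BaitSet, path: str | Path) -> None:
    """Write baits as FASTA with headers ``>source_id:start-end`` (0-based half-open)."""
    with open(path, "w") as fh:
        for start, seq in baits.baits:
            fh.write(f">{baits.source_id}:{start}-{start + baits.bait_length}\n{seq}\n")
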