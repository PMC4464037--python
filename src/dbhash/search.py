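"""Randomized k-mismatch search over the dB-hash index.

For each read, both strands are processed.  The read is split into
non-overlapping blocks of the index's block length ``m`` (plus one trailing
block anchored at the read end when the length is not a multiple of ``m``);
by pigeonhole, any occurrence with at most ``k`` mismatches leaves at most
``floor(k / t)`` of them in some non-overlapping block.  Each block's
squeezed fingerprint ball is enumerated and looked up in the index, candidate
read-start positions are derived from the hits, and every candidate is
verified against the plain packed text at full read length.  In sensitive
mode this is exhaustive: every text position within Hamming distance ``k``
is reported.  In quality mode the candidate ball of each block is restricted
to fingerprints that differ from the block's only at offsets fed by at least
one base with Phred quality <= q, trading a small loss of sensitivity on
high-quality mismatches (e.g. SNPs) for a much smaller search space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .hashing import (
    EncodedSequence,
    encode_sequence,
    enumerate_fingerprint_candidates,
    quality_mask,
    reverse_complement,
)
from .succinct_index import DbHashIndex


@dataclass
class Read:
    """A query read: raw sequence, its 2-bit encoding, optional qualities."""

    id: str
    sequence: str
    encoded: EncodedSequence = None  # type: ignore[assignment]
    qualities: Optional[np.ndarray] = None  # Phred scores, same length

    def __post_init__(self):
        if self.encoded is None:
            self.encoded = encode_sequence(self.sequence)
        if self.qualities is not None:
            self.qualities = np.asarray(self.qualities, np.int64)
            if len(self.qualities) != len(self.encoded):
                raise ValueError(
                    f"read {self.id}: quality length {len(self.qualities)} != "
                    f"sequence length {len(self.encoded)}"
                )

    def __len__(self) -> int:
        return len(self.encoded)


@dataclass(frozen=True)
class AlignmentResult:
    """One verified occurrence of a read (mismatches only, no gaps)."""

    read_id: str
    contig: str
    position: int  # 0-based, forward-strand leftmost
    strand: str  # '+' or '-'
    mismatches: int
    seed_block: int  # index of the block whose candidate produced the hit


def split_into_blocks(length: int, m: int) -> list[int]:
    """Block start offsets: 0, m, 2m, ... plus a trailing block at length - m
    when m does not divide the read length (overlapping, for coverage)."""
    if length < m:
        raise ValueError(f"read length {length} < block length {m}")
    t = length // m
    offsets = [i * m for i in range(t)]
    if length % m:
        offsets.append(length - m)
    return offsets


def errors_per_block(k: int, t: int) -> int:
    """Pigeonhole error budget per block: any placement of <= k mismatches
    among t non-overlapping blocks leaves some block with <= floor(k/t)."""
    if t < 1:
        raise ValueError("need at least one block")
    return k // t


def search_block(
    index: DbHashIndex,
    block: np.ndarray,
    offset: int,
    k_b: int,
    read_length: int,
    mask: Optional[np.ndarray] = None,
) -> set[int]:
    """Candidate read-start positions from one block's fingerprint ball."""
    if len(block) != index.m:
        raise ValueError(f"block length {len(block)} != index block length {index.m}")
    cands = enumerate_fingerprint_candidates(block, index.w, k_b, mask)
    max_start = index.n - read_length
    starts: set[int] = set()
    for f in cands:
        for p in index.lookup(f):
            s0 = int(p) - offset
            if 0 <= s0 <= max_start:
                starts.add(s0)
    return starts


def align_read(
    index: DbHashIndex,
    read: Read,
    k: int,
    mode: str = "sensitive",
    q: int = 15,
) -> list[AlignmentResult]:
    """All verified <= k-mismatch occurrences of the read, both strands.

    Results are deduplicated by (contig, position, strand) and sorted by
    mismatch count, then (contig order, position, strand).
    """
    if mode not in ("sensitive", "quality"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "quality" and read.qualities is None:
        mode = "sensitive"  # FASTA input: no qualities to exploit
    L = len(read)
    m, w = index.m, index.w
    if L < m:
        raise ValueError(f"read {read.id} shorter than block length {m}")
    offsets = split_into_blocks(L, m)
    k_b = errors_per_block(k, L // m)

    results: dict[tuple[int, int, str], AlignmentResult] = {}
    for strand in "+-":
        if strand == "+":
            syms = read.encoded.symbols
            quals = read.qualities
        else:
            syms = reverse_complement(read.encoded.symbols)
            quals = read.qualities[::-1] if read.qualities is not None else None

        # enumerate each block's candidates, then search cheapest blocks first
        per_block = []
        for bi, off in enumerate(offsets):
            block = syms[off : off + m]
            mask = (
                quality_mask(quals[off : off + m], w, q)
                if mode == "quality"
                else None
            )
            fps = enumerate_fingerprint_candidates(block, w, k_b, mask)
            per_block.append((len(fps), bi, off, fps))
        per_block.sort(key=lambda e: (e[0], e[1]))

        seen_starts: dict[int, int] = {}
        max_start = index.n - L
        for _, bi, off, fps in per_block:
            for f in fps:
                for p in index.lookup(f):
                    s0 = int(p) - off
                    if 0 <= s0 <= max_start:
                        seen_starts.setdefault(s0, bi)

        for s0, bi in seen_starts.items():
            span = index.contig_span(s0, L)
            if span is None:
                continue  # crosses a contig boundary: not a valid occurrence
            d = index.verify(syms, s0, k)
            if d is None:
                continue
            ci, local = span
            key = (ci, local, strand)
            prev = results.get(key)
            if prev is None or d < prev.mismatches:
                results[key] = AlignmentResult(
                    read.id, index.contigs[ci].name, local, strand, d, bi
                )

    order = {c.name: i for i, c in enumerate(index.contigs)}
    return sorted(
        results.values(),
        key=lambda a: (a.mismatches, order[a.contig], a.position, a.strand),
    )


def report_best(
    alignments: list[AlignmentResult],
) -> tuple[Optional[AlignmentResult], int]:
    """Primary alignment (minimal mismatches, deterministic tie-break by
    contig order / position / strand) and the count of co-optimal loci."""
    if not alignments:
        return None, 0
    best_d = min(a.mismatches for a in alignments)
    ties = sorted(
        (a for a in alignments if a.mismatches == best_d),
        key=lambda a: (a.contig, a.position, a.strand),
    )
    return ties[0], len(ties)
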