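"""Synthetic data: random references, Illumina-like reads, and evaluation.

The simulator emulates the study conditions the aligner is meant for:

* a random i.i.d. DNA reference with a chosen GC fraction;
* reads sampled uniformly in position and strand, with
  - *sequencing errors*: substitutions confined to low-quality bases
    (a fraction of bases is marked low-quality; each low-quality base
    miscalls with a fixed conditional probability), and
  - *SNP-like variants*: substitutions at high-quality bases, each base
    substituted independently with a small probability (default 0.005) —
    from the aligner's point of view a SNP is simply a high-quality mismatch;
* a truth record per read, sufficient to reconstruct every mutation.

The quality model is two-level (one value above the quality-aware threshold,
one below): the quality-aware search only discriminates at the threshold, so
two levels exercise every code path while keeping the model transparent.

Evaluation follows the standard criterion for simulated reads: an alignment
is correct iff contig and strand match the truth and the reported position is
within a tolerance (default 50 bases) of the true one; multi-mappers are
judged on their unique primary alignment, and unmapped reads form their own
category (neither correct nor incorrect).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pysam

from .hashing import decode_symbols, encode_sequence, reverse_complement
from .search import Read


@dataclass
class TruthRecord:
    read_id: str
    contig: str
    position: int  # 0-based forward-strand leftmost of the source window
    strand: str
    n_errors: int  # injected sequencing errors (low quality)
    n_snps: int  # injected SNP-like substitutions (high quality)


def random_genome(
    n: int,
    seed: int,
    gc_fraction: float = 0.5,
    n_contigs: int = 1,
    name_prefix: str = "chr",
) -> list[tuple[str, str]]:
    """Random i.i.d. DNA contigs with P(G or C) = gc_fraction."""
    if n < 1:
        raise ValueError("genome length must be positive")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    sizes = [n // n_contigs + (1 if i < n % n_contigs else 0) for i in range(n_contigs)]
    out = []
    for i, size in enumerate(sizes):
        sym = rng.choice(4, size=size, p=p).astype(np.uint8)
        out.append((f"{name_prefix}{i + 1}", decode_symbols(sym)))
    return out


def sample_reads(
    contigs: Sequence[tuple[str, str]],
    count: int,
    read_len: int,
    seed: int,
    error_rate: float = 0.1,
    low_q_fraction: float = 0.1,
    snp_rate: float = 0.005,
    q_threshold: int = 15,
    q_low: int = 8,
    q_high: int = 35,
    max_errors_per_read: Optional[int] = None,
) -> tuple[list[Read], list[TruthRecord]]:
    """Sample reads with position/strand truth and quality-correlated errors.

    ``low_q_fraction`` of bases get quality ``q_low`` (<= threshold); each of
    those miscalls with conditional probability ``error_rate``.  SNP-like
    substitutions hit any base with probability ``snp_rate`` and keep quality
    ``q_high``.  ``max_errors_per_read`` optionally caps the number of
    sequencing errors per read (for planted-read experiments); SNP sites are
    never also error sites.
    """
    if not (q_low <= q_threshold < q_high):
        raise ValueError("need q_low <= q_threshold < q_high")
    rng = np.random.default_rng(seed)
    enc = [(name, encode_sequence(seq).symbols) for name, seq in contigs]
    for name, sym in enc:
        if len(sym) < read_len:
            raise ValueError(f"contig {name} shorter than read length {read_len}")
    lengths = np.array([len(s) for _, s in enc], np.float64)
    contig_p = (lengths - read_len + 1) / (lengths - read_len + 1).sum()

    reads: list[Read] = []
    truth: list[TruthRecord] = []
    for i in range(count):
        ci = int(rng.choice(len(enc), p=contig_p))
        name, sym = enc[ci]
        pos = int(rng.integers(0, len(sym) - read_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        window = sym[pos : pos + read_len].copy()
        if strand == "-":
            window = reverse_complement(window).copy()

        snp_sites = rng.random(read_len) < snp_rate
        low_q = (rng.random(read_len) < low_q_fraction) & ~snp_sites
        err_sites = low_q & (rng.random(read_len) < error_rate)
        if max_errors_per_read is not None:
            where = np.flatnonzero(err_sites)
            if where.size > max_errors_per_read:
                keep = rng.choice(where, size=max_errors_per_read, replace=False)
                err_sites = np.zeros(read_len, bool)
                err_sites[keep] = True  # dropped sites stay low-quality, uncorrupted

        for sites in (snp_sites, err_sites):
            idx = np.flatnonzero(sites)
            if idx.size:
                # substitute with one of the three other symbols
                window[idx] = (window[idx] + rng.integers(1, 4, idx.size)) % 4
        quals = np.where(low_q, q_low, q_high).astype(np.int64)

        rid = f"read_{i:06d}"
        reads.append(Read(rid, decode_symbols(window), qualities=quals))
        truth.append(
            TruthRecord(
                rid, name, pos, strand, int(err_sites.sum()), int(snp_sites.sum())
            )
        )
    return reads, truth


def evaluate_alignments(
    truth: dict[str, TruthRecord], sam_path, tolerance: int = 50
) -> dict:
    """Classify each primary alignment against the truth.

    Correct iff contig and strand coincide and |position - true position| <=
    tolerance; results are aggregated overall and stratified by whether the
    read carries at least one SNP-like substitution.
    """
    strata = {
        "all": {"correct": 0, "incorrect": 0, "unmapped": 0},
        "with_snp": {"correct": 0, "incorrect": 0, "unmapped": 0},
        "without_snp": {"correct": 0, "incorrect": 0, "unmapped": 0},
    }
    seen = set()
    unknown = []
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            t = truth.get(rec.query_name)
            if t is None:
                unknown.append(rec.query_name)
                continue
            seen.add(rec.query_name)
            if rec.is_unmapped:
                cls = "unmapped"
            else:
                strand = "-" if rec.is_reverse else "+"
                ok = (
                    rec.reference_name == t.contig
                    and strand == t.strand
                    and abs(rec.reference_start - t.position) <= tolerance
                )
                cls = "correct" if ok else "incorrect"
            strata["all"][cls] += 1
            strata["with_snp" if t.n_snps > 0 else "without_snp"][cls] += 1
    if unknown:
        raise ValueError(f"reads absent from truth: {sorted(set(unknown))[:10]}")

    report = {"tolerance": tolerance, "n_truth": len(truth), "n_evaluated": len(seen)}
    for name, c in strata.items():
        total = sum(c.values())
        mapped = c["correct"] + c["incorrect"]
        report[name] = {
            **c,
            "total": total,
            "recall": c["correct"] / total if total else 0.0,
            "precision": c["correct"] / mapped if mapped else 0.0,
        }
    return report
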