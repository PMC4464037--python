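"""Readers and writers for the standard formats around the aligner.

FASTA/FASTQ parsing goes through Biopython's SeqIO (gzip detected by magic
bytes, not extension); SAM output goes through pysam.  The aligner is
mismatch-only, so CIGARs are always ``<len>M`` and the NM tag carries the
Hamming distance.  MAPQ convention: 37 for a unique best alignment, 0 when
several loci are co-optimal.
"""

from __future__ import annotations

import gzip
import sys
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pysam
from Bio import SeqIO

from .search import AlignmentResult, Read
from .succinct_index import ContigRecord

_GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[tuple[str, str]]:
    """Contigs as (name, sequence) pairs; duplicate names are rejected."""
    contigs: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate contig name {rec.id!r}")
            seen.add(rec.id)
            contigs.append((rec.id, str(rec.seq)))
    if not contigs:
        raise ValueError(f"{path}: no FASTA records found")
    return contigs


def read_fastq(path) -> Iterator[Read]:
    """Stream reads with Sanger Phred+33 qualities."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield Read(
                rec.id,
                str(rec.seq),
                qualities=np.asarray(rec.letter_annotations["phred_quality"], np.int64),
            )


def read_reads(path) -> Iterator[Read]:
    """Reads from FASTQ or FASTA (no qualities -> sensitive-mode alignment)."""
    with _open_text(path) as fh:
        head = fh.read(1)
    if head == ">":
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                yield Read(rec.id, str(rec.seq))
    else:
        yield from read_fastq(path)


def write_fasta(contigs: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name, seq in contigs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in (r.qualities if r.qualities is not None else []))
            if not qual:
                qual = "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM output

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _sam_header(contigs: list[ContigRecord], program_args: Optional[str]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.name, "LN": c.length} for c in contigs],
        "PG": [
            {
                "ID": "dbhash",
                "PN": "dbhash",
                "CL": program_args or " ".join(sys.argv),
            }
        ],
    }


def write_sam(
    records: Iterable[tuple[Read, list[AlignmentResult]]],
    contigs: list[ContigRecord],
    path,
    program_args: Optional[str] = None,
) -> dict[str, int]:
    """Emit one primary SAM record per read; returns summary counters.

    The primary alignment is the minimal-mismatch one (deterministic
    tie-break); MAPQ is 37 if it is unique at its mismatch count, else 0.
    Reads with no alignment are emitted as unmapped (FLAG 4).
    """
    from .search import report_best

    tid = {c.name: i for i, c in enumerate(contigs)}
    stats = {"reads": 0, "aligned": 0, "unique": 0, "multiple": 0, "unmapped": 0}
    header = pysam.AlignmentHeader.from_dict(_sam_header(contigs, program_args))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read, alignments in records:
            stats["reads"] += 1
            best, multiplicity = report_best(alignments)
            a = pysam.AlignedSegment(header)
            a.query_name = read.id
            if best is None:
                stats["unmapped"] += 1
                a.is_unmapped = True
                a.query_sequence = read.sequence
                if read.qualities is not None:
                    a.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(q + 33) for q in read.qualities)
                    )
            else:
                stats["aligned"] += 1
                stats["unique" if multiplicity == 1 else "multiple"] += 1
                a.reference_id = tid[best.contig]
                a.reference_start = best.position  # pysam converts to 1-based POS
                a.mapping_quality = 37 if multiplicity == 1 else 0
                a.cigarstring = f"{len(read)}M"
                if best.strand == "-":
                    a.is_reverse = True
                    a.query_sequence = read.sequence.translate(_COMPLEMENT)[::-1]
                    quals = (
                        read.qualities[::-1] if read.qualities is not None else None
                    )
                else:
                    a.query_sequence = read.sequence
                    quals = read.qualities
                if quals is not None:
                    a.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(q + 33) for q in quals)
                    )
                a.set_tag("NM", best.mismatches)
                a.set_tag("XM", multiplicity)
            out.write(a)
    return stats


# ---------------------------------------------------------------------------
# truth / evaluation tables

_TRUTH_COLUMNS = ["read_id", "contig", "position", "strand", "n_errors", "n_snps"]


def write_truth(records, path) -> None:
    with open(path, "wt") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.read_id}\t{r.contig}\t{r.position}\t{r.strand}\t"
                f"{r.n_errors}\t{r.n_snps}\n"
            )


def read_truth(path):
    from .simulate import TruthRecord

    out = {}
    with open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth columns {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rec = TruthRecord(f[0], f[1], int(f[2]), f[3], int(f[4]), int(f[5]))
            out[rec.read_id] = rec
    return out
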