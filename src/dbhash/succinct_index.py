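"""Succinct representation of the hash index (the dB-hash).

Instead of a position table keyed by fingerprints, the index stores the
Burrows-Wheeler transform of the *hashed* text ``h(T)`` in a wavelet tree
with rank support.  A hash lookup is then simulated by FM backward search
for the fingerprint in ``h(T)``, followed by sampled-suffix-array location.
The structure has three parts, none of them compressed:

* the BWT index: wavelet tree over ``BWT(h(T) + sentinel)``, cumulative
  symbol counts, and suffix-array samples (one pointer every ``s`` text
  positions, default 16) with a marking bit vector;
* the plain text, packed 3 bits per base in blocks of 8 symbols, used to
  verify candidate occurrences by Hamming distance;
* an auxiliary hash: precomputed backward-search intervals for every
  length-``w_aux`` fingerprint block, replacing the first ``w_aux``
  refinement steps of each lookup with one table access.

Word sizing follows ``w = ceil(log_sigma(m*n))`` clamped to ``[4, min(m, 32)]``
and ``w_aux <= log_sigma(n) - log_sigma(log n)`` so the auxiliary table stays
within an ``n``-bit budget.
"""

from __future__ import annotations

import logging
import math
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._bits import BitVector, WaveletTree
from .hashing import EncodedSequence, encode_sequence, hash_text

logger = logging.getLogger(__name__)

SENTINEL = -1  # lexicographically below every symbol; never queried

_MAGIC = b"DBHIDX01"
_VERSION = 1


# ---------------------------------------------------------------------------
# suffix array / BWT


def build_suffix_array(S: Sequence[int]) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort).

    ``S`` must end with a unique sentinel strictly smaller than every other
    symbol; the returned permutation sorts all suffixes lexicographically.
    """
    S = np.asarray(S, np.int64)
    n = len(S)
    if n == 0:
        raise ValueError("empty string")
    if S[n - 1] != S.min() or int((S == S[n - 1]).sum()) != 1:
        raise ValueError("string must end with a unique minimal sentinel")
    rank = np.unique(S, return_inverse=True)[1].astype(np.int64)
    k = 1
    sa = np.argsort(rank, kind="stable")
    while int(rank.max()) < n - 1:
        key2 = np.full(n, -1, np.int64)
        key2[:-k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        changed = np.empty(n, np.int64)
        changed[0] = 0
        changed[1:] = ((r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])).cumsum()
        rank = np.empty(n, np.int64)
        rank[sa] = changed
        k *= 2
    return sa


def bwt_from_sa(S: Sequence[int], sa: np.ndarray) -> np.ndarray:
    """BWT[i] = S[SA[i] - 1], wrapping the sentinel position."""
    S = np.asarray(S, np.int64)
    sa = np.asarray(sa, np.int64)
    return np.where(sa > 0, S[sa - 1], S[-1])


# ---------------------------------------------------------------------------
# packed plain text + verification


class PackedText:
    """Reference text packed 3 bits per symbol, 8 symbols per 32-bit block."""

    __slots__ = ("n", "words")

    def __init__(self, symbols: Optional[np.ndarray], _raw=None):
        if _raw is not None:
            self.n, self.words = _raw
            return
        symbols = np.asarray(symbols, np.uint32)
        self.n = len(symbols)
        padded = np.zeros(-(-max(self.n, 1) // 8) * 8, np.uint32)
        padded[: self.n] = symbols
        blocks = padded.reshape(-1, 8)
        words = np.zeros(len(blocks), np.uint32)
        for i in range(8):
            words |= blocks[:, i] << np.uint32(3 * i)
        self.words = words

    @classmethod
    def from_words(cls, n: int, words: np.ndarray) -> "PackedText":
        return cls(None, _raw=(n, np.asarray(words, np.uint32)))

    def unpack(self, start: int = 0, length: Optional[int] = None) -> np.ndarray:
        """Symbols in [start, start + length) as a uint8 array."""
        if length is None:
            length = self.n - start
        if start < 0 or start + length > self.n:
            raise ValueError(f"window [{start}, {start + length}) out of range")
        idx = np.arange(start, start + length)
        return ((self.words[idx >> 3] >> ((idx & 7) * 3)) & 7).astype(np.uint8)

    @property
    def payload_bits(self) -> int:
        return self.words.size * 32


def pack_text(T) -> PackedText:
    if isinstance(T, EncodedSequence):
        T = T.symbols
    return PackedText(T)


def hamming_verify(packed: PackedText, P, pos: int, k: int) -> Optional[int]:
    """Hamming distance between the text window at ``pos`` and pattern ``P``
    if it is <= k, else None.  Compares chunks of 8-symbol blocks with early
    exit once the running mismatch count exceeds k."""
    if isinstance(P, EncodedSequence):
        P = P.symbols
    P = np.asarray(P, np.uint8)
    L = len(P)
    if pos < 0 or pos + L > packed.n:
        raise ValueError(f"window [{pos}, {pos + L}) outside text of length {packed.n}")
    d = 0
    chunk = 64
    for off in range(0, L, chunk):
        end = min(off + chunk, L)
        d += int(np.count_nonzero(packed.unpack(pos + off, end - off) != P[off:end]))
        if d > k:
            return None
    return d


# ---------------------------------------------------------------------------
# auxiliary hash


@dataclass
class AuxiliaryHash:
    """Precomputed backward-search intervals for all length-``w_aux`` blocks.

    Entry ``u`` (read as a base-4 number, first symbol most significant) holds
    the suffix-array interval of rows prefixed by the symbol string ``u`` —
    exactly the interval reached after ``w_aux`` backward-search steps, i.e.
    the fingerprint digits a lookup consumes first.
    """

    w_aux: int
    lo: np.ndarray  # uint32, sigma**w_aux entries
    hi: np.ndarray


def aux_depth_bound(n_hashed: int) -> int:
    """Largest w_aux keeping the table within an n-bit budget:
    ``log_sigma(n) - log_sigma(log n)``, floored at 0."""
    if n_hashed < 4:
        return 0
    return max(0, int(math.floor(math.log(n_hashed / max(math.log2(n_hashed), 1.0), 4))))


# ---------------------------------------------------------------------------
# the index


@dataclass
class ContigRecord:
    name: str
    length: int
    offset: int  # start in the concatenated text


class DbHashIndex:
    """dB-hash index over a (multi-contig) reference.

    Contigs are concatenated at the coordinate level; no alignment may span a
    contig boundary (enforced at verification via :meth:`contig_span`), so the
    2-bit alphabet is kept free of separator symbols.  The block length ``m``
    is fixed at build time; queries must use blocks of exactly ``m`` symbols.
    """

    def __init__(self):
        # populated by build() / load()
        self.m = self.w = self.w_aux = self.s = 0
        self.n = 0  # total text length
        self.hlen = 0  # length of h(T) = n - m + w
        self.sentinel_row = 0
        self.contigs: list[ContigRecord] = []
        self.bwt_symbols: np.ndarray = np.empty(0, np.uint8)
        self.wt: WaveletTree = None  # type: ignore[assignment]
        self.C: np.ndarray = np.zeros(4, np.int64)
        self.marks: BitVector = None  # type: ignore[assignment]
        self.samples: np.ndarray = np.empty(0, np.uint32)
        self.aux: Optional[AuxiliaryHash] = None
        self.packed: PackedText = None  # type: ignore[assignment]
        self.n_run_starts: np.ndarray = np.empty(0, np.int64)
        self.n_run_lens: np.ndarray = np.empty(0, np.int64)

    # -- construction -------------------------------------------------------

    @classmethod
    def build(
        cls,
        contigs: Sequence[tuple[str, "str | EncodedSequence"]],
        m: int,
        w: Optional[int] = None,
        s: int = 16,
        w_aux: Optional[int] = None,
    ) -> "DbHashIndex":
        if m < 1:
            raise ValueError("block length m must be positive")
        if s < 1:
            raise ValueError("SA sampling step must be positive")
        idx = cls()
        names = set()
        parts: list[np.ndarray] = []
        n_pos: list[np.ndarray] = []
        offset = 0
        for name, seq in contigs:
            if name in names:
                raise ValueError(f"duplicate contig name {name!r}")
            names.add(name)
            enc = seq if isinstance(seq, EncodedSequence) else encode_sequence(seq)
            if len(enc) < m:
                logger.warning(
                    "skipping contig %s: length %d < block length %d", name, len(enc), m
                )
                continue
            idx.contigs.append(ContigRecord(name, len(enc), offset))
            parts.append(enc.symbols)
            if enc.n_positions.size:
                n_pos.append(enc.n_positions + offset)
            offset += len(enc)
        if not idx.contigs:
            raise ValueError(f"no contig of length >= m = {m}")
        T = np.concatenate(parts)
        idx.n = n = len(T)

        if w is None:
            w = math.ceil(math.log(m * n, 4))
        w = max(4, min(w, m, 32))
        if w > m:
            raise ValueError(f"fingerprint width w={w} exceeds block length m={m}")
        idx.m, idx.w, idx.s = m, w, s

        hT = hash_text(T, m, w)
        idx.hlen = len(hT)
        S = np.concatenate([hT.astype(np.int64), [SENTINEL]])
        sa = build_suffix_array(S)
        bwt = bwt_from_sa(S, sa)
        idx.sentinel_row = int(np.flatnonzero(bwt == SENTINEL)[0])
        bwt_sym = bwt.astype(np.int64)
        bwt_sym[idx.sentinel_row] = 0
        idx.bwt_symbols = bwt_sym.astype(np.uint8)
        idx.wt = WaveletTree(idx.bwt_symbols)
        counts = np.bincount(hT, minlength=4)[:4]
        idx.C = 1 + np.concatenate(([0], np.cumsum(counts)[:-1])).astype(np.int64)

        idx.marks = BitVector(sa % s == 0)
        idx.samples = sa[sa % s == 0].astype(np.uint32)

        if w_aux is None:
            w_aux = min(w - 1, aux_depth_bound(idx.hlen))
        idx.aux = build_aux_hash(idx, w_aux)
        idx.w_aux = w_aux

        idx.packed = PackedText(T)
        if n_pos:
            allN = np.concatenate(n_pos)
            breaks = np.flatnonzero(np.diff(allN) != 1)
            starts = allN[np.concatenate(([0], breaks + 1))]
            ends = allN[np.concatenate((breaks, [len(allN) - 1]))]
            idx.n_run_starts = starts.astype(np.int64)
            idx.n_run_lens = (ends - starts + 1).astype(np.int64)
        return idx

    @classmethod
    def from_fasta(cls, path, m: int, **kwargs) -> "DbHashIndex":
        from .io import read_fasta

        return cls.build(read_fasta(path), m, **kwargs)

    # -- FM machinery -------------------------------------------------------

    def _occ(self, c: int, i: int) -> int:
        """Occurrences of symbol c in BWT[0, i), sentinel excluded."""
        r = self.wt.rank(c, i)
        if c == 0 and i > self.sentinel_row:
            r -= 1
        return r

    def _lf(self, i: int) -> int:
        if i == self.sentinel_row:
            return 0
        c = self.wt.access(i)
        r = self._occ(c, i)
        return int(self.C[c]) + r

    def backward_search(self, f, use_aux: bool = True) -> tuple[int, int]:
        """Suffix-array interval [lo, hi) of rows prefixed by fingerprint f.

        A full-width query uses the auxiliary table for its trailing
        ``w_aux`` symbols, then ``w - w_aux`` refinement steps; queries
        shorter than ``w`` (including the empty one) are refined directly.
        """
        f = np.asarray(f, np.uint8)
        N = self.hlen + 1
        lo, hi = 0, N
        rest = f
        if (
            use_aux
            and self.aux is not None
            and self.aux.w_aux > 0
            and len(f) == self.w
        ):
            d = self.aux.w_aux
            key = 0
            for c in f[self.w - d :]:
                key = (key << 2) | int(c)
            lo, hi = int(self.aux.lo[key]), int(self.aux.hi[key])
            rest = f[: self.w - d]
        for c in rest[::-1]:
            if lo >= hi:
                return 0, 0
            c = int(c)
            lo = int(self.C[c]) + self._occ(c, lo)
            hi = int(self.C[c]) + self._occ(c, hi)
        return (lo, hi) if lo < hi else (0, 0)

    def locate(self, interval: tuple[int, int]) -> np.ndarray:
        """Text positions (in h(T)) of the rows in the interval, sorted.

        Each row is LF-walked to the nearest sampled row; a row whose suffix
        position is p reaches a sampled position after at most s - 1 steps.
        """
        lo, hi = interval
        out = np.empty(max(hi - lo, 0), np.int64)
        for j, row in enumerate(range(lo, hi)):
            steps = 0
            while not self.marks.get(row):
                row = self._lf(row)
                steps += 1
            out[j] = int(self.samples[self.marks.rank1(row)]) + steps
        out.sort()
        return out

    def lookup(self, f, use_aux: bool = True) -> np.ndarray:
        """All positions where fingerprint f occurs in h(T)."""
        return self.locate(self.backward_search(f, use_aux=use_aux))

    # -- coordinates --------------------------------------------------------

    @property
    def contig_offsets(self) -> np.ndarray:
        return np.array([c.offset for c in self.contigs], np.int64)

    def contig_span(self, start: int, length: int) -> Optional[tuple[int, int]]:
        """(contig index, local position) if [start, start+length) lies within
        a single contig, else None."""
        if start < 0 or start + length > self.n:
            return None
        offs = self.contig_offsets
        ci = int(np.searchsorted(offs, start, side="right")) - 1
        c = self.contigs[ci]
        if start + length > c.offset + c.length:
            return None
        return ci, start - c.offset

    def verify(self, P, pos: int, k: int) -> Optional[int]:
        """Hamming-verify pattern P against the plain text at pos (<= k)."""
        return hamming_verify(self.packed, P, pos, k)

    # -- accounting ---------------------------------------------------------

    def memory_report(self) -> dict[str, int]:
        """Core payload of each component, in bits (as stored)."""
        rep = {
            "wavelet_payload": self.wt.payload_bits,
            "rank_directories": self.wt.directory_bits + self.marks.directory_bits,
            "sa_marks": self.marks.payload_bits,
            "sa_samples": self.samples.size * 32,
            "aux_table": (self.aux.lo.size + self.aux.hi.size) * 32 if self.aux else 0,
            "packed_text": self.packed.payload_bits,
            "c_array": self.C.size * 64,
        }
        rep["total"] = sum(rep.values())
        return rep

    def bytes_per_symbol(self) -> float:
        return self.memory_report()["total"] / 8.0 / self.n

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<I", _VERSION))
            fh.write(
                struct.pack(
                    "<8Q",
                    self.n,
                    self.hlen,
                    self.m,
                    self.w,
                    self.w_aux,
                    self.s,
                    self.sentinel_row,
                    len(self.contigs),
                )
            )
            for c in self.contigs:
                nb = c.name.encode("utf-8")
                fh.write(struct.pack("<H", len(nb)))
                fh.write(nb)
                fh.write(struct.pack("<2Q", c.length, c.offset))
            _write_arr(fh, self.bwt_symbols, "<u1")
            fh.write(struct.pack("<Q", self.marks.n))
            _write_arr(fh, self.marks.words, "<u8")
            _write_arr(fh, self.samples, "<u4")
            _write_arr(fh, self.aux.lo if self.aux else np.empty(0, np.uint32), "<u4")
            _write_arr(fh, self.aux.hi if self.aux else np.empty(0, np.uint32), "<u4")
            fh.write(struct.pack("<Q", self.packed.n))
            _write_arr(fh, self.packed.words, "<u4")
            _write_arr(fh, self.n_run_starts, "<i8")
            _write_arr(fh, self.n_run_lens, "<i8")

    @classmethod
    def load(cls, path) -> "DbHashIndex":
        path = Path(path)
        idx = cls()
        with open(path, "rb") as fh:
            magic = fh.read(8)
            if magic != _MAGIC:
                raise ValueError(f"{path}: not a dbhash index (bad magic {magic!r})")
            (version,) = struct.unpack("<I", fh.read(4))
            if version != _VERSION:
                raise ValueError(f"{path}: unsupported index version {version}")
            (
                idx.n,
                idx.hlen,
                idx.m,
                idx.w,
                idx.w_aux,
                idx.s,
                idx.sentinel_row,
                n_contigs,
            ) = struct.unpack("<8Q", fh.read(64))
            for _ in range(n_contigs):
                (nlen,) = struct.unpack("<H", fh.read(2))
                name = fh.read(nlen).decode("utf-8")
                length, offset = struct.unpack("<2Q", fh.read(16))
                idx.contigs.append(ContigRecord(name, length, offset))
            idx.bwt_symbols = _read_arr(fh, "<u1")
            (marks_n,) = struct.unpack("<Q", fh.read(8))
            idx.marks = BitVector.from_words(marks_n, _read_arr(fh, "<u8"))
            idx.samples = _read_arr(fh, "<u4")
            aux_lo = _read_arr(fh, "<u4")
            aux_hi = _read_arr(fh, "<u4")
            (packed_n,) = struct.unpack("<Q", fh.read(8))
            idx.packed = PackedText.from_words(packed_n, _read_arr(fh, "<u4"))
            idx.n_run_starts = _read_arr(fh, "<i8")
            idx.n_run_lens = _read_arr(fh, "<i8")
        idx.wt = WaveletTree(idx.bwt_symbols)
        counts = np.bincount(idx.bwt_symbols, minlength=4)[:4].astype(np.int64)
        counts[0] -= 1  # sentinel is stored as symbol 0
        idx.C = 1 + np.concatenate(([0], np.cumsum(counts)[:-1]))
        idx.aux = AuxiliaryHash(idx.w_aux, aux_lo, aux_hi)
        return idx


def build_aux_hash(index: DbHashIndex, w_aux: int) -> AuxiliaryHash:
    """Precompute backward-search intervals for all sigma**w_aux blocks.

    Built by depth-wise extension: the interval of ``c + u`` is one backward
    step with symbol ``c`` from the interval of ``u``.
    """
    bound = aux_depth_bound(index.hlen)
    if w_aux < 0 or w_aux > bound:
        raise ValueError(f"w_aux={w_aux} outside [0, {bound}] for this index")
    N = index.hlen + 1
    lo = np.array([0], np.int64)
    hi = np.array([N], np.int64)
    for d in range(w_aux):
        size = 4**d
        nlo = np.zeros(4 * size, np.int64)
        nhi = np.zeros(4 * size, np.int64)
        for c in range(4):
            base = c * size
            for u in range(size):
                l, h = int(lo[u]), int(hi[u])
                if l < h:
                    l2 = int(index.C[c]) + index._occ(c, l)
                    h2 = int(index.C[c]) + index._occ(c, h)
                    if l2 < h2:
                        nlo[base + u], nhi[base + u] = l2, h2
        lo, hi = nlo, nhi
    return AuxiliaryHash(w_aux, lo.astype(np.uint32), hi.astype(np.uint32))


def _write_arr(fh, arr: np.ndarray, dtype: str) -> None:
    data = np.ascontiguousarray(arr).astype(dtype).tobytes()
    fh.write(struct.pack("<Q", arr.size))
    fh.write(data)


def _read_arr(fh, dtype: str) -> np.ndarray:
    (size,) = struct.unpack("<Q", fh.read(8))
    nbytes = size * np.dtype(dtype).itemsize
    return np.frombuffer(fh.read(nbytes), dtype=dtype).copy()
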