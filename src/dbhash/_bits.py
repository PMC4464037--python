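"""Plain (uncompressed) bit vectors with O(1) rank, packed into 64-bit words.

Rank directories are one cumulative popcount per word; no compression is
applied anywhere in the index.
"""

from __future__ import annotations

import numpy as np


class BitVector:
    """Static bit vector with rank support.

    Construction takes a boolean array; bit *i* lives in word ``i >> 6`` at
    bit ``i & 63`` (little-endian within the word).
    """

    __slots__ = ("n", "words", "_cum")

    def __init__(self, bits: np.ndarray, _raw: tuple | None = None):
        if _raw is not None:
            self.n, self.words = _raw
        else:
            bits = np.asarray(bits, bool)
            self.n = len(bits)
            padded = np.zeros(-(-max(self.n, 1) // 64) * 64, bool)
            padded[: self.n] = bits
            self.words = np.packbits(padded, bitorder="little").view(np.uint64)
        counts = np.bitwise_count(self.words).astype(np.int64)
        self._cum = np.concatenate(([0], np.cumsum(counts)))

    @classmethod
    def from_words(cls, n: int, words: np.ndarray) -> "BitVector":
        return cls(None, _raw=(n, np.asarray(words, np.uint64)))

    def get(self, i: int) -> int:
        return int(self.words[i >> 6] >> np.uint64(i & 63)) & 1

    def rank1(self, i: int) -> int:
        """Number of set bits in positions [0, i)."""
        wi, r = i >> 6, i & 63
        c = int(self._cum[wi])
        if r:
            c += (int(self.words[wi]) & ((1 << r) - 1)).bit_count()
        return c

    def rank0(self, i: int) -> int:
        return i - self.rank1(i)

    def to_array(self) -> np.ndarray:
        return np.unpackbits(self.words.view(np.uint8), bitorder="little")[: self.n].astype(bool)

    @property
    def payload_bits(self) -> int:
        return self.n  # logical bits; word padding is at most 63 bits

    @property
    def directory_bits(self) -> int:
        return self._cum.size * 64


class WaveletTree:
    """Two-level wavelet tree over the alphabet {0, 1, 2, 3}.

    The root bit vector holds the high bit of each symbol; symbols are routed
    to a left (0/1) or right (2/3) child holding the low bits in stable order.
    ``rank``/``access`` each cost a constant number of bit-vector ranks.
    """

    __slots__ = ("n", "bits0", "lo", "hi")

    def __init__(self, symbols: np.ndarray):
        symbols = np.asarray(symbols, np.uint8)
        if symbols.size and symbols.max() > 3:
            raise ValueError("wavelet tree alphabet is {0,1,2,3}")
        self.n = len(symbols)
        high = symbols >= 2
        self.bits0 = BitVector(high)
        self.lo = BitVector((symbols[~high] & 1).astype(bool))
        self.hi = BitVector((symbols[high] & 1).astype(bool))

    def rank(self, c: int, i: int) -> int:
        """Occurrences of symbol c in positions [0, i)."""
        if c >> 1:
            j = self.bits0.rank1(i)
            child = self.hi
        else:
            j = self.bits0.rank0(i)
            child = self.lo
        return child.rank1(j) if (c & 1) else child.rank0(j)

    def access(self, i: int) -> int:
        b0 = self.bits0.get(i)
        if b0:
            j = self.bits0.rank1(i)
            return 2 | self.hi.get(j)
        j = self.bits0.rank0(i)
        return self.lo.get(j)

    def to_array(self) -> np.ndarray:
        out = np.empty(self.n, np.uint8)
        high = self.bits0.to_array()
        out[~high] = self.lo.to_array()
        out[high] = 2 | self.hi.to_array()[: int(high.sum())]
        return out

    @property
    def payload_bits(self) -> int:
        # n log(sigma) bits of symbol payload across the two levels
        return self.bits0.payload_bits + self.lo.payload_bits + self.hi.payload_bits

    @property
    def directory_bits(self) -> int:
        return (
            self.bits0.directory_bits + self.lo.directory_bits + self.hi.directory_bits
        )
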