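"""Hamming-aware de Bruijn hashing of DNA strings.

The aligner's central object is the hash ``h_xor`` that folds a length-*m*
pattern over the alphabet ``{0,1,2,3}`` (A, C, G, T) into a length-*w*
*fingerprint* by symbol-wise XOR of a fixed set of width-*w* windows.  Two
properties make this hash useful for indexed approximate matching:

* **de Bruijn property** — shifting the pattern by one symbol shifts the
  fingerprint by one symbol, so the hash of a long text is itself a string
  (:func:`hash_text`) and pattern occurrences become fingerprint occurrences.
* **Hamming awareness** — a substitution in the pattern perturbs at most two
  fingerprint positions, so the Hamming ball of radius *k* around a pattern
  maps into a ball of radius ``2k`` around its fingerprint.  The set of
  fingerprints reachable with at most *k* substitutions can be enumerated
  directly in fingerprint space (:func:`enumerate_fingerprint_candidates`)
  without touching the pattern's exponentially larger Hamming ball.

A Phred-quality counterpart ``quality_mask`` marks fingerprint offsets fed by
at least one low-quality base; restricting enumeration to those offsets is the
quality-aware search heuristic.

Window decomposition
--------------------
With ``t = ceil(m / w)`` the windows are the ``t - 1`` aligned windows
``P[i*w : i*w + w)`` for ``i = 0 .. t-2`` plus the final window
``P[m-w : m)``.  When ``w | m`` these are exactly the disjoint aligned
windows; otherwise the final window overlaps the last aligned one by
``t*w - m`` symbols.  Every pattern position is covered by one or two
windows, which is what makes the hash Hamming-aware with constant 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

#: alphabet size of the 2-bit DNA encoding; a power of two so symbol XOR is closed
SIGMA = 4

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
# undefined bases get a numerical value inside the alphabet; positions recorded
_ENCODE[ord("N")] = 0
_ENCODE[ord("n")] = 0


@dataclass
class EncodedSequence:
    """DNA string over ``{0,1,2,3}`` plus the positions that were ``N``."""

    symbols: np.ndarray  # uint8, values in [0, 4)
    n_positions: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return decode_symbols(self.symbols)


def encode_sequence(raw: str | bytes) -> EncodedSequence:
    """Encode ``ACGTN`` text (case-insensitive) to 2-bit symbols.

    ``N`` encodes as 0 (A) and its positions are recorded on the side.
    Any other character is rejected with the offending position named.
    """
    if len(raw) == 0:
        raise ValueError("empty sequence")
    buf = np.frombuffer(raw.encode("ascii") if isinstance(raw, str) else raw, np.uint8)
    sym = _ENCODE[buf]
    bad = np.flatnonzero(sym == 255)
    if bad.size:
        pos = int(bad[0])
        raise ValueError(f"invalid character {chr(buf[pos])!r} at position {pos}")
    n_pos = np.flatnonzero((buf == ord("N")) | (buf == ord("n"))).astype(np.int64)
    return EncodedSequence(sym, n_pos)


def decode_symbols(symbols: np.ndarray) -> str:
    return _DECODE[np.asarray(symbols, np.uint8)].tobytes().decode("ascii")


def reverse_complement(symbols: np.ndarray) -> np.ndarray:
    """Reverse complement in 2-bit encoding: complement is ``3 - s``."""
    return (3 - np.asarray(symbols, np.uint8))[::-1]


def _as_symbols(P) -> np.ndarray:
    if isinstance(P, EncodedSequence):
        return P.symbols
    return np.asarray(P, np.uint8)


def window_starts(m: int, w: int) -> list[int]:
    """Start offsets of the hash windows for pattern length m and width w."""
    if w < 1 or w > m:
        raise ValueError(f"require 1 <= w <= m, got w={w}, m={m}")
    t = -(-m // w)
    return [i * w for i in range(t - 1)] + [m - w]


def hash_xor(P, w: int) -> np.ndarray:
    """Fingerprint ``h_xor(P)``: symbol-wise XOR of the hash windows of P."""
    s = _as_symbols(P)
    out = np.zeros(w, np.uint8)
    for st in window_starts(len(s), w):
        out ^= s[st : st + w]
    return out


def hash_xor_batch(P: np.ndarray, w: int) -> np.ndarray:
    """Row-wise :func:`hash_xor` of a 2-D array of patterns (one per row)."""
    P = np.asarray(P, np.uint8)
    out = np.zeros((P.shape[0], w), np.uint8)
    for st in window_starts(P.shape[1], w):
        out ^= P[:, st : st + w]
    return out


def hash_text(T, m: int, w: int) -> np.ndarray:
    """Extend the hash to a text: the unique string of length ``n - m + w``
    whose every width-*w* window at *i* equals ``hash_xor(T[i : i+m], w)``.

    Existence/uniqueness is exactly the de Bruijn property of ``hash_xor``.
    """
    s = _as_symbols(T)
    n = len(s)
    if n < m:
        raise ValueError(f"text length {n} shorter than block length {m}")
    out = np.empty(n - m + w, np.uint8)
    out[:w] = hash_xor(s[:m], w)
    if n > m:
        # position i + w - 1 of the output is the last fingerprint offset of
        # window i: XOR of T[i + j*w + w-1] over aligned windows j and T[i + m-1]
        t = -(-m // w)
        i = np.arange(1, n - m + 1)
        acc = np.zeros(n - m, np.uint8)
        for j in range(t - 1):
            acc ^= s[i + j * w + w - 1]
        acc ^= s[i + m - 1]
        out[w:] = acc
    return out


# ---------------------------------------------------------------------------
# quality-aware masking


def quality_mask(Q: Sequence[int], w: int, q: int = 15) -> np.ndarray:
    """Fold Phred qualities through the hash windows with OR.

    ``f_q`` sends a base to 3 if its quality is <= ``q`` (low) and to 0
    otherwise; the mask is the symbol-wise OR of ``f_q`` over the same window
    decomposition as :func:`hash_xor`.  Offset *i* of the mask is 3 iff at
    least one base feeding fingerprint offset *i* is low-quality.  The values
    0 and 3 are chosen for their binary forms (00 and 11), so OR on the mask
    is OR on the underlying bits.
    """
    Q = np.asarray(Q, np.int64)
    if Q.ndim != 1:
        raise ValueError("quality string must be one-dimensional")
    if np.any(Q < 0):
        raise ValueError("Phred qualities must be non-negative")
    fq = np.where(Q <= q, 3, 0).astype(np.uint8)
    mask = np.zeros(w, np.uint8)
    for st in window_starts(len(Q), w):
        mask |= fq[st : st + w]
    return mask


def passes_quality_filter(f: np.ndarray, h_B: np.ndarray, mask: np.ndarray) -> bool:
    """True iff fingerprint ``f`` differs from ``h_B`` only at masked offsets:
    ``(f XOR h_B) OR mask == mask``."""
    f = np.asarray(f, np.uint8)
    h_B = np.asarray(h_B, np.uint8)
    mask = np.asarray(mask, np.uint8)
    if not (len(f) == len(h_B) == len(mask)):
        raise ValueError("fingerprint / mask width mismatch")
    return bool(np.all(((f ^ h_B) | mask) == mask))


# ---------------------------------------------------------------------------
# squeezed Hamming-ball enumeration


@dataclass(frozen=True)
class ErrorEvent:
    """Fingerprint-space footprint of one substitution in the pattern.

    A substitution at pattern position *j* with symbol XOR ``value`` flips the
    fingerprint at one offset (position covered by a single hash window) or at
    two offsets (position in the overlap of the final window with the last
    aligned window, when ``w`` does not divide ``m``).
    """

    offsets: tuple[int, ...]  # one offset, or (b, b + m % w) for paired events
    value: int  # XOR difference in {1, 2, 3}

    def delta(self, w: int) -> np.ndarray:
        d = np.zeros(w, np.uint8)
        for o in self.offsets:
            d[o] ^= self.value
        return d


def error_events(m: int, w: int, mask: Optional[np.ndarray] = None) -> list[ErrorEvent]:
    """Universe of per-substitution fingerprint perturbations for (m, w).

    Single events exist at every offset; paired events exist only when
    ``w`` does not divide ``m``, at offset pairs ``(b, b + m % w)`` for
    ``b`` in the overlap ``[0, ceil(m/w)*w - m)``.  With a quality mask,
    only events whose offsets are all mask-covered are kept.
    """
    if not (1 <= w <= m):
        raise ValueError(f"require 1 <= w <= m, got w={w}, m={m}")
    t = -(-m // w)
    overlap = t * w - m  # 0 when w | m
    shift = m % w
    events: list[ErrorEvent] = []
    for e in (1, 2, 3):
        for o in range(w):
            events.append(ErrorEvent((o,), e))
        for b in range(overlap):
            events.append(ErrorEvent((b, b + shift), e))
    if mask is not None:
        mask = np.asarray(mask, np.uint8)
        events = [ev for ev in events if all(mask[o] == 3 for o in ev.offsets)]
    return events


_DELTA_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def fingerprint_deltas(
    m: int, w: int, k: int, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Unique XOR patterns reachable by composing at most *k* error events.

    Returns a 2-D uint8 array (one delta per row) always containing the zero
    row.  Cached per (m, w, k) in the unmasked case, since the delta set is
    independent of the pattern itself (``h_xor`` is XOR-linear).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    key = (m, w, k)
    if mask is None and key in _DELTA_CACHE:
        return _DELTA_CACHE[key]
    events = error_events(m, w, mask)
    seen: dict[bytes, None] = {np.zeros(w, np.uint8).tobytes(): None}
    for j in range(1, k + 1):
        for combo in combinations(events, j):
            d = np.zeros(w, np.uint8)
            for ev in combo:
                for o in ev.offsets:
                    d[o] ^= ev.value
            seen.setdefault(d.tobytes(), None)
    out = np.frombuffer(b"".join(seen.keys()), np.uint8).reshape(-1, w).copy()
    if mask is None:
        _DELTA_CACHE[key] = out
    return out


def enumerate_fingerprint_candidates(
    P, w: int, k: int, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """All fingerprints to be looked up for a k-mismatch search of P.

    The returned 2-D array is a superset of ``{hash_xor(P') : d_H(P, P') <= k}``
    (extra members are false-positive candidates later removed by text
    verification), has at most ``sum_{j<=k} (2*(SIGMA-1)*w)**j`` rows, and
    always contains ``hash_xor(P)``.  With a quality mask, only fingerprints
    that differ from ``hash_xor(P)`` at masked offsets are produced.
    """
    s = _as_symbols(P)
    hp = hash_xor(s, w)
    deltas = fingerprint_deltas(len(s), w, k, mask)
    return np.unique(hp[None, :] ^ deltas, axis=0)


def candidate_budget(w: int, k: int) -> int:
    """Upper bound ``sum_{j<=k} (2*(SIGMA-1)*w)**j`` on the candidate count."""
    return sum((2 * (SIGMA - 1) * w) ** j for j in range(k + 1))
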