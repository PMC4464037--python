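import numpy as np
import pytest

from dbhash import DbHashIndex, encode_sequence, random_genome


@pytest.fixture(scope="session")
def small_genome():
    """20 kb single-contig random reference."""
    return random_genome(20_000, seed=7)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return DbHashIndex.build(small_genome, m=20)


@pytest.fixture(scope="session")
def small_genome_symbols(small_genome):
    return encode_sequence(small_genome[0][1]).symbols


def hamming_ball(P, k):
    """All patterns within Hamming distance k of P (brute-force oracle)."""
    from itertools import combinations, product

    P = np.asarray(P, np.uint8)
    out = [P.copy()]
    m = len(P)
    for j in range(1, k + 1):
        for sites in combinations(range(m), j):
            for vals in product((1, 2, 3), repeat=j):
                Q = P.copy()
                for s, v in zip(sites, vals):
                    Q[s] ^= v
                out.append(Q)
    return out


def naive_hash(P, w):
    """Independent evaluator of the windowed-XOR hash: per-offset loops over
    the aligned windows and the final window."""
    P = np.asarray(P, np.uint8)
    m = len(P)
    t = -(-m // w)
    out = []
    for o in range(w):
        v = 0
        for i in range(t - 1):
            v ^= int(P[i * w + o])
        v ^= int(P[m - w + o])
        out.append(v)
    return np.array(out, np.uint8)


def full_scan_occurrences(genome_symbols, read_symbols, k):
    """Brute-force k-mismatch scan over both strands: set of
    (position, strand, distance)."""
    from numpy.lib.stride_tricks import sliding_window_view

    from dbhash import reverse_complement

    L = len(read_symbols)
    wv = sliding_window_view(genome_symbols, L)
    out = set()
    for strand, q in (("+", read_symbols), ("-", reverse_complement(read_symbols))):
        dist = np.count_nonzero(wv != q, axis=1)
        for p in np.flatnonzero(dist <= k):
            out.add((int(p), strand, int(dist[p])))
    return out
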