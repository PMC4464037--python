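"""Inside the succinct index: hashing the text, looking up a fingerprint,
and the space each component takes.

Demonstrates the chain pattern -> fingerprint -> backward-search interval ->
located positions -> verified occurrence, and prints the per-component
payload that makes the structure succinct (compare: an explicit hash table
of positions would cost 32-64 bits per text position).
"""

from dbhash import DbHashIndex, encode_sequence, hash_xor, random_genome

genome = random_genome(1_000_000, seed=42)
index = DbHashIndex.build(genome, m=20)
T = encode_sequence(genome[0][1]).symbols

# take a pattern from the text, hash it, and look it up
pos = 123_456
P = T[pos : pos + index.m]
f = hash_xor(P, index.w)
lo, hi = index.backward_search(f)
hits = index.lookup(f)
print(f"fingerprint {f.tolist()} of the block at {pos}:")
print(f"  suffix-array interval [{lo}, {hi}) -> {hi - lo} fingerprint hit(s) in h(T)")
print(f"  located positions: {hits.tolist()}")
for p in hits:
    d = index.verify(P, int(p), k=0)
    print(f"  position {p}: {'true occurrence' if d == 0 else 'false positive'} "
          f"(verified Hamming distance {d})")

rep = index.memory_report()
print(f"\nindex over n = {index.n:,} bp (m={index.m}, w={index.w}, "
      f"w_aux={index.w_aux}, s={index.s}):")
for name, bits in rep.items():
    if name != "total":
        print(f"  {name:>18}: {bits / 8 / index.n:6.3f} bytes/symbol")
print(f"  {'total':>18}: {rep['total'] / 8 / index.n:6.3f} bytes/symbol")
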