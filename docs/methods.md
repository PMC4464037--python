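# Methods

## Problem and approach

`dbhash` solves indexed approximate string matching with *k* mismatches for
short DNA reads: report every position of a reference text `T` (length *n*)
where a pattern `P` (length *m*) occurs with Hamming distance at most *k*.
Classical solutions trade space against sensitivity: hash indexes store a
position table per fingerprint (fast, sensitive, large — pointers cost
`n log n` bits), while BWT/FM indexes are succinct but natively support only
exact matching, forcing backtracking or block-splitting heuristics on top.

The package combines the two. A hash function that is simultaneously

* a **de Bruijn hash** — shifting the pattern one symbol shifts the
  fingerprint one symbol, so the hash of the whole text is itself a string
  `h(T)` of length `n - m + w`, and every occurrence of `P` in `T` induces an
  occurrence of `h(P)` in `h(T)` at the same position; and
* **Hamming-aware** — `d_H(P, P') <= k` implies
  `d_H(h(P), h(P')) <= 2k`, so the whole radius-*k* ball around `P` maps
  into a small, directly enumerable ball in fingerprint space

lets us index `h(T)` with an ordinary succinct FM index and simulate hash
lookups by backward search. Fingerprint matches that are not true pattern
occurrences (false positives) are removed by verifying candidates against the
plain text.

## The hash

Symbols are encoded A,C,G,T → 0,1,2,3; the alphabet size σ = 4 is a power of
two so symbol-wise XOR stays inside the alphabet. With `t = ceil(m/w)`, the
fingerprint of `P` is the symbol-wise XOR of the `t-1` aligned windows
`P[iw .. iw+w)` and the final window `P[m-w .. m)`:

    h(P)[o]  =  XOR_{i=0}^{t-2} P[i*w + o]  XOR  P[m-w + o]

When `w | m` the windows are exactly the disjoint aligned windows. Otherwise
the final window overlaps the last aligned one by `m' = t*w - m` symbols. The
ceiling reading of the window count is deliberate: it guarantees every
pattern position is covered by at least one window, so every substitution
perturbs the fingerprint — under a floor reading positions in
`[(floor(m/w)-1)w, m-w)` would be invisible to the hash, breaking both the
`2k` bound's tightness and candidate enumeration's completeness.

**Error-event geometry.** A substitution at position `j` with XOR value
`e ∈ {1,2,3}` flips the fingerprint at offset `j mod w` if `j` lies in an
aligned window, and at offset `j - (m-w)` if it lies in the final window.
Positions covered once yield *single* events; positions in the overlap yield
*paired* events at offsets `(b, b + m mod w)` for `b ∈ [0, m')`. Since each
substitution touches at most two offsets, `d_H(h(P), h(P')) <= 2k`.

**Candidate enumeration.** The fingerprints reachable from `h(P)` with at
most *k* substitutions are generated by composing at most *k* events from
the universe of `3(w + m') <= 6w` events (XOR-composition, deduplicated).
Any multiset of per-position events collapses to a set of distinct events of
no larger size (events sharing an offset signature merge by XOR), so subsets
of the universe suffice for completeness. The set size respects
`sum_{j<=k} (6w)^j`, exponentially smaller in *m* than the pattern-space
ball. The enumeration may include fingerprints not realized by any `P'` in
the ball (e.g. single events at offsets only reachable as paired); these are
harmless false-positive candidates removed at verification, and the delta set
is cached per `(m, w, k)` since it is independent of the pattern.

## The succinct index

The index stores three parts, none compressed (DNA is nearly incompressible,
so compression would buy little and cost time):

1. **BWT index.** `h(T)` plus a sentinel (lexicographically smallest) is
   suffix-sorted by numpy prefix doubling; the BWT is held in a two-level
   wavelet tree over {0,1,2,3} built on rank-supported bit vectors (packed
   64-bit words, one cumulative popcount per word). The sentinel's BWT cell
   is stored as symbol 0 with its row index kept aside and subtracted in
   rank queries. Backward search refines a suffix-array interval one symbol
   at a time from the last symbol of the fingerprint.
2. **Sampled suffix array.** Rows whose suffix position is `0 (mod s)`
   (default `s = 16`) are marked in a rank bit vector and their positions
   stored; `locate` LF-walks each row at most `s - 1` steps to a sample.
3. **Auxiliary hash.** Intervals for all `4^w_aux` fingerprint blocks are
   precomputed, replacing the first `w_aux` refinement steps of a full-width
   lookup by one table access. Because backward search consumes the query
   right-to-left, the table is keyed by the trailing `w_aux` fingerprint
   symbols — the digits a lookup consumes first. The depth respects
   `w_aux <= log_4(n) - log_4(log2 n)`, keeping the table within an `n`-bit
   budget; default `min(w - 1, bound)`.

The plain text is stored 3 bits per base in 8-symbol blocks and used for
candidate verification with early exit once the mismatch count exceeds *k*.
An accounting method reports the stored payload per component; on a 1 Mbp
input the total is ≈ 1.6 bytes/symbol (wavelet payload 2 bits, rank
directories ≈ 3 bits, SA marks + samples ≈ 3 bits, packed text 4 bits, aux
table ≈ 1 bit).

**Word sizing.** `w = ceil(log_4(m n))` clamped to `[4, min(m, 32)]` (so
`4^w - 1` fits a machine word). This balances fingerprint informativeness
(few random collisions: expected `n / 4^w ≈ 1/m` spurious hits per
fingerprint) against candidate-set growth in `w`.

**Contigs.** Multi-contig references are concatenated at the coordinate
level with no separator symbol; candidate alignments that would span a
contig boundary are discarded at verification. This keeps σ = 4 and is
equivalent to reserving an end-marker. `N` bases encode as 0 with their run
positions recorded; an optional CLI filter rejects alignments overlapping
long N runs (`--mask-n`).

**Serialization** is a versioned, magic-tagged little-endian binary holding
the BWT symbols, SA samples and marks, auxiliary table, packed text, contig
table, and build parameters `(m, w, w_aux, s)`; the wavelet tree and count
array are rebuilt on load in O(n) vectorized work, so save → load → save is
byte-identical.

## Search

A read of length `L >= m` is split into `t = floor(L/m)` non-overlapping
blocks (offsets `0, m, 2m, ...`) plus, when `m ∤ L`, one extra block anchored
at `L - m` for tail coverage. By pigeonhole, any occurrence with at most *k*
mismatches leaves at most `k_b = floor(k/t)` of them in some non-overlapping
block, so searching every block's radius-`k_b` fingerprint ball and verifying
each candidate start at full read length with bound *k* is exhaustive
(sensitive mode). Blocks are searched in ascending candidate-set size; both
strands are processed (the index stores only the forward text; the reverse
complement is a second query with reversed qualities). Results are
deduplicated by (contig, position, strand) and sorted by mismatch count with
deterministic tie-breaks; the primary alignment is the minimal-mismatch hit
with its co-optimal multiplicity annotated (MAPQ 37 unique / 0 multiple).

**Quality-aware mode.** Phred qualities are folded through the same window
decomposition with OR after thresholding (`f_q(x) = 3` if `x <= q` else 0,
default `q = 15`): mask offset *i* is 3 iff some base feeding fingerprint
offset *i* is low-quality. A candidate fingerprint is searched only if it
differs from the block's fingerprint at masked offsets —
`(f XOR h(B)) OR mask == mask` — implemented by restricting the event
universe to fully-masked events before composition. Under the assumption
that high-quality bases are rarely miscalled this prunes most of the ball;
the cost is possibly missing occurrences whose mismatches sit at high-quality
offsets in *every* block (e.g. some reads carrying SNPs). Quality-mode
output is always a subset of sensitive-mode output, and any read whose
mismatches are all low-quality (and within the pigeonhole budget) is
guaranteed to be found.

`k` can be given absolutely or as a fraction of read length (CLI
`--error-rate`, default 5%, rounded); the library API takes explicit `k`.

## Synthetic data

The simulator generates the conditions the aligner targets rather than a
full platform error model:

* random i.i.d. references with adjustable GC fraction (default 0.5);
* reads sampled uniformly in position and strand (contigs weighted by the
  number of valid start positions);
* a **two-level quality model**: a fraction of bases (default 0.1) receives
  a low Phred value (8), the rest a high value (35). The quality-aware
  search discriminates only at the threshold, so two levels exercise every
  code path; no attempt is made to mimic empirical Illumina quality decay
  along the read.
* **sequencing errors**: each low-quality base miscalls with a conditional
  probability (default 0.1, i.e. ≈ 1% of bases overall); errors never occur
  at high-quality bases, the idealization of "high quality ⇒ trusted call".
  An optional per-read cap supports planted-read experiments.
* **SNP-like variants**: every base is substituted with probability 0.005
  (the density used for validating quality-aware alignment against variant
  carrying reads), always at high quality — operationally a SNP is just a
  high-quality mismatch, modeled in the read rather than as a reference
  edit so truth records can label exactly which reads carry one.

Each read's truth record (contig, 0-based forward-strand start, strand,
error and SNP counts) is sufficient to reconstruct its mutations against the
reference. What passing tests on this generator do *not* show: robustness to
indels (out of scope by design — the aligner is mismatch-only), clipped
bases, adapter contamination, non-uniform coverage, or realistic quality
miscalibration (a real low-quality base is sometimes correct, a real
high-quality base sometimes wrong — the latter is exactly the SNP channel,
which the quality-aware mode intentionally tolerates losing a small fraction
of).

**Evaluation** follows the standard simulated-read criterion: an alignment
is correct iff contig and strand match the truth and the position differs by
at most 50 bases (tolerating clips/indel shifts in general pipelines);
multi-mappers are judged on their unique primary alignment; unmapped reads
are a separate category. Reports are stratified by SNP-carrying vs
SNP-free reads.

## Numerical and design choices

* Suffix arrays are built by prefix doubling on numpy `lexsort`
  (O(n log n), ~3.5 s per Mbp); the naive full-sort is the test oracle.
  Construction is unconstrained by the method — any correct algorithm works.
* Verification compares unpacked 64-symbol chunks with early exit; a
  word-parallel XOR-popcount over packed 3-bit blocks would be faster but
  verification is far from the bottleneck at library scale.
* Ties everywhere (co-optimal alignments, equal-size candidate sets) break
  deterministically by (contig order, position, strand) / block index, so
  identical inputs give byte-identical output.
* Degenerate inputs: reads shorter than `m` are unalignable and reported
  unmapped; contigs shorter than `m` are skipped with a warning; empty
  backward-search queries return the full interval; `w > m` is rejected.
* Problem sizes in the test and acceptance suites (100 kb genomes, 2000
  reads, 10^4-pair property samples) were chosen as the smallest scales at
  which every guarantee is exercised end to end, including multi-hit reads
  and both strands; the end-to-end check is against a vectorized brute-force
  scan of every text position on both strands, so agreement is exact set
  equality, not a statistical proxy.

## Known limitations

* Mismatch-only: no indel handling (CIGAR is always `<len>M`), no
  paired-end logic, no trimming, single-threaded.
* Sensitivity in quality mode is heuristic by construction; reads whose
  every block carries a high-quality mismatch can be missed.
* The index targets desk-scale references (up to tens of Mbp comfortably);
  gigabase genomes would want memory-mapped structures and a faster SA
  construction, both out of scope.
* MAPQ is a two-value convention (37 unique / 0 multiple), not a calibrated
  error probability.
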