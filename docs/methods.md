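# Methods

## Model and assumptions

`covasm` implements a greedy, coverage-arbitrated de Bruijn graph
assembler. Its working assumptions are the classical ones: reads are short
(tens to low hundreds of bp), sequence coverage is high enough (tens of ×)
that true genomic k-mers are seen many times while k-mers containing a
base-call error are seen once or twice, and substitution errors dominate
(no indel model). Under those assumptions the coverage of a k-mer is a
usable proxy for its trustworthiness, which is what the pipeline exploits
at three points: error pruning, edge weighting, and junction arbitration.

The double-stranded nature of DNA is handled by canonical folding: a k-mer
and its reverse complement are one object, stored as the lexicographically
smaller word (A<C<G<T). k must be **odd** so no k-mer equals its own
reverse complement and every node has two well-defined sides. Graph edges
are derived from k-mer *co-presence* (all eight one-base extensions of each
node are looked up in the table), not from threading reads through the
graph; two k-mers adjacent in the table are linked whether or not a single
read witnessed the junction. This is the simpler of the two conventions
and the one the rest of the design (periodic pruning, sharded counting)
fits naturally.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| k | 21 (CLI) | node word size, odd, hard floor 5, warning below 19; larger k resolves more repeats but needs more coverage |
| t_low | 1 | end-of-build prune threshold, count ≤ t_low removed; singletons are overwhelmingly error k-mers at ≥ 40× |
| t_high | off | optional repeat threshold, count ≥ t_high set aside as repeats; no universal default exists |
| P (interval) | off | mid-build prune period in *reads*; trades assembly quality for peak table size |
| t_mid | 1 | threshold used by the mid-build prune |
| shards S | 4096 | layout only; table contents are provably independent of S |
| min_contig_len | k | emission filter; evaluation applies the conventional 100 bp (36 bp reads) / 200 bp (75 bp reads) cutoff instead |
| min_identity | 0.98 | CGR mapping filter |
| seed_k | 31 | exact-seed size of the built-in CGR mapper |
| read_len L / coverage C | 75 / 80 (CLI) | simulator: n = round(C·g/L) reads |

## The synthetic-data generator

`sim_reads` emulates MetaSim-style shotgun sampling: uniform start
positions on [0, g−L], a fair coin per read for strand (reverse-complement
emitted for the minus strand), and either an error-free model or
independent per-position substitutions. The default substitution profile
is a linear ramp from 0.001 at the first cycle to 0.02 at the last — a
generic Illumina-like shape; any per-position vector can be supplied.
What it deliberately does **not** model: indels, quality-score realism,
paired-end structure, clone-size distributions, coverage biases (GC,
mappability), and circular genomes (sampling never wraps, so a circular
reference is treated as linear and its junction is simply never read).
Tests passing on these reads therefore certify algorithmic correctness,
not robustness to every artifact of real sequencing data.

Two helpers make ground-truth fixtures exact rather than probable:

* `random_genome(..., unique_kminus1=m)` rejection-samples a genome until
  every canonical m-mer occurs exactly once **and** no m-mer is its own
  reverse complement. The palindrome condition matters: an even-length
  palindromic m-mer lies on both strands at once, i.e. it *is* a
  double-stranded repeat, and it shows up in the graph as a hairpin
  junction that breaks the single-path guarantee.
* `tiling_reads(ref, L, C)` emits error-free reads at evenly spaced starts
  covering both genome ends. Uniform random sampling covers position 0
  only if a read starts exactly there (probability ≈ 1−e^(−C/L) per end),
  so "the assembly equals the genome" can only be asserted against a read
  layout that provably tiles it; random sampling is kept for every test
  where full tiling is not part of the claim.

## Numerical and algorithmic choices

* **Packed keys.** Words are packed 2 bits/base; the code assignment
  preserves lexicographic order, so canonical choice and all deterministic
  orderings are integer comparisons. k ≤ 31 uses a vectorized int64 path,
  larger k an arbitrary-precision rolling path with identical results.
* **Shard hash.** splitmix64 on the packed key; fixed, platform-independent.
* **Mid-build prune timing.** The prune scheduled after every P reads
  fires lazily, just before the next read is ingested. A prune falling
  exactly at stream end therefore never runs — the end-of-build prune
  subsumes it. A pruned key that reappears later re-enters at count 1.
* **Unitig coverage** is the member-count-weighted mean of member
  coverages (length-invariant, associative, so merging is idempotent).
* **Self-loops** (hairpins and one-node cycles) are recorded but never
  merged through and never eligible as preferred links; a side carrying a
  loop counts as a junction.
* **Tie-breaks.** Preferred-edge argmax ties break on the smaller
  extending base (A<C<G<T), then the smaller neighbor sequence. Coverage
  ties in junction arbitration resolve as "neighbor wins" (disconnect),
  which always makes progress. Nodes are scanned in ascending sequence
  order, LEFT before RIGHT, in passes to a fixpoint, so resolution is a
  pure function of the input graph.
* **Arbitration termination guard.** The raw rule — "higher-coverage JN1
  enforces JN2's pointer, otherwise disconnect" — does not terminate by
  itself: two high-coverage nodes flanking a low-coverage junction can
  enforce its pointer back and forth forever. An enforcement here only
  replaces JN2's pointer when JN1 strictly beats the pointer's current
  target on (coverage, then sequence); a contender that cannot beat the
  incumbent is disconnected instead. Every enforcement then strictly
  improves the slot it writes and every disconnection removes an edge, so
  the fixpoint (zero non-mutual preferred links, checked by a full scan)
  is reached within a link-count pass bound.
* **After a disconnection** the preferred links of both endpoints *and* of
  every node whose one-step look-ahead could have used the removed edge
  are recomputed before scanning continues.
* **Contig orientation.** Each contig is reported as the smaller of the
  spelled string and its reverse complement; paths start at the smallest
  unvisited terminal node and cycles are broken at their smallest node,
  making output files byte-reproducible.
* **Nx dialect.** Nx/NGx return the length at which the descending
  cumulative sum first *reaches* (≥) x% of the total (Nx) or of the
  reference length (NGx, 0 when unreached). The other convention ("last
  length before exceeding") can differ by one contig rank.
* **CGR mapper.** Contigs are placed by exact 31-mer seeding (both
  strands, seed stride 15) followed by ungapped extension along the
  diagonal; identity = matches / overlap length, best placement per
  contig. This is intentionally minimal — adequate for error-free and
  low-error synthetic contigs, not a substitute for a general aligner on
  diverged or rearranged sequence.
* **Parallelism.** `workers > 1` parallelizes k-mer extraction only;
  counter increments commute and prune points are barriers, so any worker
  count produces bit-identical tables. The single-worker path is the
  reference implementation.

## Problem sizes used by the test and acceptance runs

The suite exercises genomes of 0.5–10 kb at 10–40× coverage: large enough
that coverage statistics behave as the model assumes (mean k-mer depth
C·(L−k+1)/L ≈ 29 at C = 40, L = 75, k = 21), small enough that the whole
suite and the acceptance script each run in a couple of minutes on one
core. The pruning study uses twenty seeded 5 kb genomes at a 2% uniform
substitution rate; brute-force graph enumeration uses k = 3 over all DNA
strings of length ≤ 7 plus seeded unions of string pairs, capped at six
nodes per graph.

## Known limitations

* No tip removal or bubble popping: conflict arbitration is deliberately
  simpler than those procedures, and low-coverage debris contigs are left
  for the evaluation-stage length filter rather than excised from the
  graph.
* Single-end only; scaffolding and gap closure are out of scope (external
  scaffolders can consume the contig FASTA).
* Co-presence edges can join k-mers never observed adjacently in a read,
  which slightly overconnects the graph at junctions compared to
  read-threading assemblers.
* The CGR mapper is ungapped; a single indel in a contig truncates its
  credited mapping.
* Counting and graph stages are pure Python over dict shards: correct and
  deterministic, but sized for method study, not for multi-megabase
  genomes.
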