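"""Canonical k-mer extraction and the sharded k-mer coverage table.

A k-mer and its reverse complement name the same double-stranded word, so
only the lexicographically smaller of the two (under A<C<G<T) is stored.
Words are packed two bits per base; because the code assignment A=0, C=1,
G=2, T=3 is order-preserving, integer comparison of packed words equals
lexicographic comparison of the strings, and the canonical key is simply
``min(packed, packed_revcomp)``.

The coverage table is split into a fixed number of independent shards.  A
first hash picks the shard, an ordinary dict lookup inside the shard finds
the entry.  The shard count is a pure layout choice: table *contents* are
identical for any shard count, which the test suite checks.  Pruning can run
once at the end of counting or periodically every P reads while the table is
still being built; a key deleted mid-build that reappears later re-enters at
count 1.
"""

from __future__ import annotations

import itertools
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

import numpy as np

from .io_seq import Read

BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# byte translation: ACGT -> 0..3, everything else (incl. N) -> 4
_SEQ2CODE = bytearray([4]) * 256
for _b, _c in _CODE.items():
    _SEQ2CODE[ord(_b)] = _c
_SEQ2CODE = bytes(_SEQ2CODE)

#: numpy fast path is only valid while 2k bits fit in a signed 64-bit word
_FAST_K_MAX = 31


# ---------------------------------------------------------------------------
# packed-word primitives
# ---------------------------------------------------------------------------

def encode(word: str) -> int:
    """Pack a nucleotide string into a 2-bit-per-base integer.

    Raises ``ValueError`` on bases outside {A,C,G,T}.
    """
    v = 0
    for ch in word:
        try:
            v = (v << 2) | _CODE[ch]
        except KeyError:
            raise ValueError(f"non-ACGT base {ch!r} in {word!r}") from None
    return v


def decode(v: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(BASES[(v >> shift) & 3])
    return "".join(out)


def revcomp_packed(v: int, k: int) -> int:
    """Reverse complement of a packed k-length word."""
    r = 0
    for _ in range(k):
        r = (r << 2) | (3 - (v & 3))
        v >>= 2
    return r


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TRANS)[::-1]


_RC_TRANS = str.maketrans("ACGTN", "TGCAN")


def canonical_packed(v: int, k: int) -> int:
    return min(v, revcomp_packed(v, k))


def canonical(word: str) -> int:
    """Canonical packed key of a k-length word.

    Rejects (``ValueError``) words containing N or other ambiguity codes;
    the caller is expected to skip such windows.
    """
    return canonical_packed(encode(word), len(word))


def canonical_str(word: str) -> str:
    return min(word, revcomp(word))


# ---------------------------------------------------------------------------
# k-mer scanning
# ---------------------------------------------------------------------------

def _scan_fast(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical keys of all valid k-windows (numpy path, k <= 31)."""
    n = codes.size - k + 1
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    pow_f = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    pow_r = 4 ** np.arange(k, dtype=np.int64)
    fwd = win @ pow_f
    rc = (3 - win) @ pow_r
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    ok = (cs[k:] - cs[:-k]) == 0
    assert ok.size == n
    return np.minimum(fwd, rc)[ok]


def _scan_slow(codes: np.ndarray, k: int) -> List[int]:
    """Rolling canonical keys for arbitrary k (python ints)."""
    keys: List[int] = []
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = rc = 0
    run = 0  # valid bases accumulated
    for c in codes.tolist():
        if c >= 4:
            run = 0
            fwd = rc = 0
            continue
        fwd = ((fwd << 2) | c) & mask
        rc = (rc >> 2) | ((3 - c) << shift)
        run += 1
        if run >= k:
            keys.append(fwd if fwd <= rc else rc)
    return keys


def kmer_keys(seq: str, k: int) -> List[int]:
    """Canonical packed keys for every valid k-window of ``seq``.

    Windows containing a non-ACGT base are skipped; a sequence shorter than
    k yields nothing.
    """
    if len(seq) < k:
        return []
    codes = np.frombuffer(seq.encode("ascii").translate(_SEQ2CODE), dtype=np.uint8)
    if k <= _FAST_K_MAX:
        return _scan_fast(codes, k).tolist()
    return _scan_slow(codes, k)


# ---------------------------------------------------------------------------
# shard hashing
# ---------------------------------------------------------------------------

def _mix64(x: int) -> int:
    # splitmix64 finalizer; deterministic across runs and platforms
    x &= 0xFFFFFFFFFFFFFFFF
    x = (x ^ (x >> 30)) * 0xBF58476D1CE4E5B9 & 0xFFFFFFFFFFFFFFFF
    x = (x ^ (x >> 27)) * 0x94D049BB133111EB & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


def shard_hash(key: int) -> int:
    h = 0
    while True:
        h = _mix64(h ^ (key & 0xFFFFFFFFFFFFFFFF))
        key >>= 64
        if key == 0:
            return h


# ---------------------------------------------------------------------------
# prune configuration
# ---------------------------------------------------------------------------

@dataclass
class PruneConfig:
    """Thresholds for coverage-based k-mer pruning.

    t_low
        end-of-build threshold; keys with count <= t_low are removed
        (default 1: drop singletons, the bulk of base-call errors).
    t_high
        optional repeat threshold; keys with count >= t_high are moved to a
        repeat set and excluded from the graph.  Disabled by default.
    interval
        optional mid-build prune period, in reads processed.  Disabled by
        default.
    t_mid
        threshold applied at each mid-build prune (default 1).
    """

    t_low: int = 1
    t_high: Optional[int] = None
    interval: Optional[int] = None
    t_mid: int = 1

    def __post_init__(self) -> None:
        if self.t_low < 0:
            raise ValueError("t_low must be >= 0")
        if self.t_high is not None and self.t_high <= self.t_low:
            raise ValueError("t_high must exceed t_low")
        if self.interval is not None and self.interval <= 0:
            raise ValueError("prune interval must be positive")


# ---------------------------------------------------------------------------
# the coverage table
# ---------------------------------------------------------------------------

class CoverageTable:
    """Sharded map from canonical packed k-mer to its coverage count."""

    def __init__(self, k: int, n_shards: int = 4096):
        if k < 2:
            raise ValueError("k must be >= 2")
        if n_shards < 1:
            raise ValueError("need at least one shard")
        self.k = k
        self.n_shards = n_shards
        self.shards: List[Dict[int, int]] = [dict() for _ in range(n_shards)]
        self.reads_processed = 0
        self.reads_skipped = 0  # reads shorter than k

    # -- basic accessors ----------------------------------------------------

    def shard_of(self, key: int) -> int:
        return shard_hash(key) % self.n_shards

    @property
    def total_kmers(self) -> int:
        return sum(len(s) for s in self.shards)

    def get(self, key: int) -> Optional[int]:
        return self.shards[self.shard_of(key)].get(key)

    def __contains__(self, key: int) -> bool:
        return key in self.shards[self.shard_of(key)]

    def items(self) -> Iterator[Tuple[int, int]]:
        for s in self.shards:
            yield from s.items()

    def as_dict(self) -> Dict[int, int]:
        """Flat key->count view (shard layout erased)."""
        out: Dict[int, int] = {}
        for s in self.shards:
            out.update(s)
        return out

    @classmethod
    def from_counts(cls, counts: Dict[str, int], k: int,
                    n_shards: int = 4096) -> "CoverageTable":
        """Build a table from explicit word->count pairs (testing aid).

        Words are canonicalized; counts for a word and its reverse
        complement accumulate.
        """
        t = cls(k, n_shards)
        for word, c in counts.items():
            if len(word) != k:
                raise ValueError(f"word {word!r} is not length {k}")
            t._bump(canonical(word), c)
        return t

    def _bump(self, key: int, by: int = 1) -> None:
        d = self.shards[self.shard_of(key)]
        d[key] = d.get(key, 0) + by

    # -- ingestion ----------------------------------------------------------

    def add_kmers(self, keys: Iterable[int]) -> None:
        shards = self.shards
        ns = self.n_shards
        for key in keys:
            d = shards[shard_hash(key) % ns]
            d[key] = d.get(key, 0) + 1

    def add_read(self, read: Read) -> None:
        """Count every valid k-window of the read (canonical).

        Reads shorter than k are discarded; windows containing ambiguous
        bases are skipped.
        """
        if len(read.seq) < self.k:
            self.reads_skipped += 1
            self.reads_processed += 1
            return
        self.add_kmers(kmer_keys(read.seq, self.k))
        self.reads_processed += 1

    def prune_in_place(self, t_low: int) -> int:
        """Delete keys with count <= t_low; returns how many were removed."""
        removed = 0
        for s in self.shards:
            dead = [key for key, c in s.items() if c <= t_low]
            for key in dead:
                del s[key]
            removed += len(dead)
        return removed


def build_table(reads: Iterable[Read], k: int,
                prune_cfg: Optional[PruneConfig] = None,
                workers: int = 1,
                n_shards: int = 4096) -> CoverageTable:
    """Fold a read stream into a coverage table.

    With ``prune_cfg.interval`` set to P, all keys at or below
    ``prune_cfg.t_mid`` are deleted after every P reads.  The prune fires
    lazily, before the next read is ingested, so a prune falling exactly at
    stream end never runs — the end-of-build prune (:func:`prune`) subsumes
    it and is *not* applied here.

    ``workers`` > 1 parallelizes k-mer extraction; counter increments
    commute, so the result is identical to the single-worker path, which is
    the reference implementation.
    """
    table = CoverageTable(k, n_shards)
    interval = prune_cfg.interval if prune_cfg else None
    t_mid = prune_cfg.t_mid if prune_cfg else 1

    pending = False
    if workers <= 1:
        for read in reads:
            if pending:
                table.prune_in_place(t_mid)
                pending = False
            table.add_read(read)
            if interval and table.reads_processed % interval == 0:
                pending = True
        return table

    # parallel extraction: reads are consumed in segments bounded by the
    # prune period so the prune schedule matches the sequential path
    it = iter(reads)
    seg = interval if interval else 4096
    with ThreadPoolExecutor(max_workers=workers) as pool:
        while True:
            batch = list(itertools.islice(it, seg))
            if not batch:
                break
            if pending:
                table.prune_in_place(t_mid)
                pending = False
            for keys in pool.map(
                    lambda r: kmer_keys(r.seq, k) if len(r.seq) >= k
                    else None, batch, chunksize=64):
                if keys is None:
                    table.reads_skipped += 1
                else:
                    table.add_kmers(keys)
                table.reads_processed += 1
            if interval and table.reads_processed % interval == 0:
                pending = True
    return table


def prune(table: CoverageTable, t_low: int = 1,
          t_high: Optional[int] = None) -> Tuple[CoverageTable, Set[int]]:
    """End-of-build prune.

    Keys with count <= t_low are dropped (low coverage, presumed base-call
    errors); keys with count >= t_high, when the threshold is enabled, are
    returned as a repeat set and excluded from the surviving table.
    """
    out = CoverageTable(table.k, table.n_shards)
    out.reads_processed = table.reads_processed
    out.reads_skipped = table.reads_skipped
    repeats: Set[int] = set()
    for i, s in enumerate(table.shards):
        keep = out.shards[i]
        for key, c in s.items():
            if c <= t_low:
                continue
            if t_high is not None and c >= t_high:
                repeats.add(key)
                continue
            keep[key] = c
    return out, repeats


def coverage_histogram(table: CoverageTable) -> Dict[int, int]:
    """Map coverage value -> number of distinct keys at that coverage."""
    hist: Dict[int, int] = {}
    for _, c in table.items():
        hist[c] = hist.get(c, 0) + 1
    return hist


def dump_tsv(table: CoverageTable, path: str) -> None:
    """Write the table as two TSV columns (kmer, count), sorted by kmer."""
    with open(path, "w") as fh:
        fh.write("kmer\tcount\n")
        for key, c in sorted(table.items()):
            fh.write(f"{decode(key, table.k)}\t{c}\n")
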