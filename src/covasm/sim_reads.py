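"""Synthetic single-end read simulation.

Emulates MetaSim-style shotgun sampling: a chosen read length L, a target
sequence coverage C (so n = round(C*g/L) reads are drawn), uniformly random
start positions inside the linear reference, a uniformly random strand per
read (reverse-complemented on the minus strand), and either an error-free
model or per-position substitution errors.  Sequence coverage here means how
many times each reference base is expected to appear across the reads; it is
distinct from k-mer coverage.

The default substitution profile is a generic Illumina-like linear ramp from
0.1% at the first cycle to 2% at the last; any per-position vector can be
supplied.  Indels are not modelled and sampling never wraps around the
reference end (circular genomes are sampled as if linear).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .io_seq import Read, SeqRecord
from .kmer_table import BASES, canonical_str, revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ErrorModel:
    """Error-free ('exact') or per-position substitution errors.

    ``sub_prob`` holds one substitution probability per read position; it is
    only consulted when ``kind == "substitution"``.  A substituted base is
    replaced by one of the three other bases, uniformly.
    """

    kind: str = "exact"
    sub_prob: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("exact", "substitution"):
            raise ValueError(f"unknown error model kind {self.kind!r}")
        if self.sub_prob is not None:
            p = np.asarray(self.sub_prob, dtype=float)
            if ((p < 0) | (p > 1)).any():
                raise ValueError("substitution probabilities must be in [0,1]")

    @classmethod
    def exact(cls) -> "ErrorModel":
        return cls(kind="exact")

    @classmethod
    def illumina_like(cls, read_len: int, p_start: float = 0.001,
                      p_end: float = 0.02) -> "ErrorModel":
        """Linear ramp profile, rising toward the 3' end of the read."""
        return cls(kind="substitution",
                   sub_prob=np.linspace(p_start, p_end, read_len))

    @classmethod
    def uniform(cls, read_len: int, p: float) -> "ErrorModel":
        return cls(kind="substitution", sub_prob=np.full(read_len, p))

    def profile(self, read_len: int) -> np.ndarray:
        if self.sub_prob is None:
            return np.zeros(read_len)
        p = np.asarray(self.sub_prob, dtype=float)
        if p.size != read_len:
            raise ValueError(
                f"substitution profile length {p.size} != read length {read_len}")
        return p


@dataclass
class SimConfig:
    """Read length L, sequence coverage C, error model, and RNG seed."""

    read_len: int
    coverage: float
    error_model: ErrorModel = field(default_factory=ErrorModel.exact)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len <= 0:
            raise ValueError("read length must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


def random_genome(length: int, seed: int,
                  unique_kminus1: Optional[int] = None,
                  max_tries: int = 200) -> SeqRecord:
    """Uniform random genome, optionally repeat-free at a given word size.

    When ``unique_kminus1`` = m is set, the sequence is rejection-sampled
    until every canonical m-mer occurs exactly once and no m-mer equals its
    own reverse complement (an even-length palindrome sits on both strands
    at once, i.e. is a double-stranded repeat and a hairpin in the graph).
    This guarantees the de Bruijn graph at any odd k > m is a single path —
    a repeat-free assembly instance.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    m = unique_kminus1
    if m is not None and m > length:
        raise ValueError("unique word size exceeds genome length")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        codes = rng.integers(0, 4, size=length)
        seq = "".join(BASES[c] for c in codes)
        if m is None:
            return SeqRecord(f"random_g{length}_s{seed}", seq)
        windows = [seq[i:i + m] for i in range(length - m + 1)]
        words = {canonical_str(w) for w in windows}
        if (len(words) == len(windows)
                and all(w != revcomp(w) for w in windows)):
            return SeqRecord(f"random_g{length}_s{seed}", seq)
    raise RuntimeError(
        f"could not sample a genome of length {length} with unique canonical "
        f"{m}-mers after {max_tries} tries; increase the word size or shrink "
        f"the genome")


def simulate_reads(ref: SeqRecord, cfg: SimConfig) -> List[Read]:
    """Draw n = round(C*g/L) reads from a reference sequence.

    Start positions are uniform on [0, g-L], strands are fair coin flips,
    and substitution errors are applied independently per position according
    to the error model.  The same seed reproduces the read set exactly.
    """
    g = len(ref.seq)
    L = cfg.read_len
    if L > g:
        raise ValueError(f"read length {L} exceeds reference length {g}")
    n = round(cfg.coverage * g / L)
    rng = np.random.default_rng(cfg.seed)

    codes = np.frombuffer(ref.seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int8)
    for b, c in _CODE.items():
        lut[ord(b)] = c
    codes = lut[codes]

    starts = rng.integers(0, g - L + 1, size=n)
    strands = rng.integers(0, 2, size=n)  # 0 = plus, 1 = minus
    mat = codes[starts[:, None] + np.arange(L)[None, :]].astype(np.int8)
    minus = strands == 1
    mat[minus] = 3 - mat[minus, ::-1]

    prof = cfg.error_model.profile(L)
    if cfg.error_model.kind == "substitution":
        hit = rng.random((n, L)) < prof[None, :]
        hit &= mat >= 0  # never "correct" an N (only possible off-alphabet)
        nerr = int(hit.sum())
        if nerr:
            shift = rng.integers(1, 4, size=nerr).astype(np.int8)
            mat[hit] = (mat[hit] + shift) % 4

    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    reads = []
    for i in range(n):
        seq = base_arr[mat[i]].tobytes().decode("ascii")
        reads.append(Read(f"r{i}", seq))
    return reads


def tiling_reads(ref: SeqRecord, read_len: int, coverage: float) -> List[Read]:
    """Error-free reads at evenly spaced starts covering the whole reference.

    Emits n = round(C*g/L) plus-strand reads whose starts are spread evenly
    over [0, g-L] including both endpoints, so every base (and, when the
    spacing is below L-k+1, every k-mer) of the reference is sampled.
    Deterministic; the companion to :func:`simulate_reads` for fixtures
    where full tiling must be guaranteed rather than merely likely.
    """
    g = len(ref.seq)
    L = read_len
    if L > g:
        raise ValueError(f"read length {L} exceeds reference length {g}")
    n = round(coverage * g / L)
    if n < 1:
        raise ValueError("coverage too low to emit a single read")
    if n == 1:
        starts = [0]
    else:
        starts = [round(i * (g - L) / (n - 1)) for i in range(n)]
    return [Read(f"t{i}", ref.seq[s:s + L]) for i, s in enumerate(starts)]


def simulate_readset(refs: Sequence[SeqRecord], cfg: SimConfig) -> List[Read]:
    """Simulate over a multi-record reference, one record at a time.

    Each record gets round(C*g_r/L) reads from a record-specific substream
    of the seed; records shorter than the read length are skipped.
    """
    out: List[Read] = []
    for i, ref in enumerate(refs):
        if len(ref.seq) < cfg.read_len:
            continue
        sub = SimConfig(cfg.read_len, cfg.coverage, cfg.error_model,
                        seed=(cfg.seed * 1_000_003 + i) % (2 ** 31))
        reads = simulate_reads(ref, sub)
        for r in reads:
            r.id = f"{ref.id}_{r.id}"
        out.extend(reads)
    return out
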