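"""Assembly-quality statistics: Nx / NGx, largest contig, covered genome ratio.

Nx is the contig length at which the cumulative length of contigs sorted
longest-first reaches x% of the total assembly; NGx uses x% of the
*reference* length instead and is reported as 0 when the assembly is too
small to reach it.  "Reaches" is a >= comparison on the cumulative sum.

The covered genome ratio (CGR) maps each contig to the reference with a
built-in exact-seed, ungapped-extension aligner, discards contigs below a
length cutoff or below an identity cutoff (the conventional filters are 98%
identity and a 100/200-base minimum for 36/75 bp reads), and reports the
fraction of reference bases covered by at least one retained mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_seq import SeqRecord
from .kmer_table import revcomp


def nx(lengths: Sequence[int], x: float = 50) -> int:
    """Nx of a contig length multiset (x in percent, exclusive (0, 100))."""
    if not lengths:
        raise ValueError("Nx of an empty assembly is undefined")
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100)")
    ordered = sorted(lengths, reverse=True)
    threshold = x / 100 * sum(ordered)
    cum = 0
    for length in ordered:
        cum += length
        if cum >= threshold:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def ngx(lengths: Sequence[int], genome_len: int, x: float = 50) -> int:
    """NGx against a reference of ``genome_len`` bases; 0 when unreached."""
    if genome_len <= 0:
        raise ValueError("genome length must be positive")
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100)")
    threshold = x / 100 * genome_len
    cum = 0
    for length in sorted(lengths, reverse=True):
        cum += length
        if cum >= threshold:
            return length
    return 0


# ---------------------------------------------------------------------------
# covered genome ratio
# ---------------------------------------------------------------------------

def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_mapping(contig: np.ndarray, ref: np.ndarray,
                  index: Dict[bytes, List[int]], seed_k: int, stride: int
                  ) -> Optional[Tuple[float, int, int]]:
    """Best ungapped diagonal placement of ``contig`` on one reference.

    Returns (identity, ref_start, ref_end) of the highest-identity overlap,
    or None when no seed hits.  Identity = matches / overlap length.
    """
    m = contig.size
    if m < seed_k:
        return None
    diagonals = set()
    raw = contig.tobytes()
    for cpos in range(0, m - seed_k + 1, stride):
        for rpos in index.get(raw[cpos:cpos + seed_k], ()):
            diagonals.add(rpos - cpos)
    best: Optional[Tuple[float, int, int]] = None
    n = ref.size
    for d in sorted(diagonals):
        r0 = max(d, 0)
        r1 = min(d + m, n)
        if r1 <= r0:
            continue
        c0 = r0 - d
        matches = int((contig[c0:c0 + (r1 - r0)] == ref[r0:r1]).sum())
        ident = matches / (r1 - r0)
        cand = (ident, r1 - r0)
        if best is None or cand > (best[0], best[2] - best[1]):
            best = (ident, r0, r1)
    return best


def covered_genome_ratio(contigs: Sequence, reference: Sequence[SeqRecord],
                         min_identity: float = 0.98,
                         min_contig_len: int = 200,
                         seed_k: int = 31) -> float:
    """Fraction of reference bases covered by retained contig mappings.

    Contigs shorter than ``min_contig_len`` are discarded; each survivor is
    placed by exact seeding (both strands) plus ungapped extension, and kept
    only if its best mapping identity reaches ``min_identity``.
    """
    if not reference:
        raise ValueError("reference must be nonempty")
    refs = [_codes(r.seq) for r in reference]
    total = sum(r.size for r in refs)
    covered = [np.zeros(r.size, dtype=bool) for r in refs]

    indexes: List[Dict[bytes, List[int]]] = []
    for r in refs:
        idx: Dict[bytes, List[int]] = {}
        raw = r.tobytes()
        for pos in range(r.size - seed_k + 1):
            idx.setdefault(raw[pos:pos + seed_k], []).append(pos)
        indexes.append(idx)

    stride = max(1, seed_k // 2)
    for c in contigs:
        seq = c.seq if hasattr(c, "seq") else c
        if len(seq) < min_contig_len:
            continue
        best: Optional[Tuple[float, int, int, int]] = None
        for strand_seq in (seq, revcomp(seq)):
            arr = _codes(strand_seq)
            for ri, (r, idx) in enumerate(zip(refs, indexes)):
                hit = _best_mapping(arr, r, idx, seed_k, stride)
                if hit is None:
                    continue
                cand = (hit[0], hit[2] - hit[1], ri, hit[1], hit[2])
                if best is None or cand[:2] > (best[0], best[3] - best[2]):
                    best = (cand[0], cand[2], cand[3], cand[4])
        if best is not None and best[0] >= min_identity:
            covered[best[1]][best[2]:best[3]] = True

    return sum(int(c.sum()) for c in covered) / total


@dataclass
class AssemblyReport:
    """The standard contiguity panel plus covered genome ratio."""

    n_contigs: int
    total_len: int
    max_len: int
    n20: int
    n50: int
    n80: int
    ng50: int
    cgr: Optional[float] = None

    def as_dict(self) -> Dict[str, object]:
        return {"n_contigs": self.n_contigs, "total_len": self.total_len,
                "max_len": self.max_len, "N20": self.n20, "N50": self.n50,
                "N80": self.n80, "NG50": self.ng50, "CGR": self.cgr}

    def to_text(self) -> str:
        rows = [f"{k}\t{v if v is not None else 'NA'}"
                for k, v in self.as_dict().items()]
        return "\n".join(rows) + "\n"


def assembly_report(contigs: Sequence,
                    reference: Optional[Sequence[SeqRecord]] = None,
                    min_identity: float = 0.98,
                    min_contig_len: int = 200,
                    seed_k: int = 31) -> AssemblyReport:
    """Summarize an assembly; reference-based fields need ``reference``."""
    lengths = [len(c.seq) if hasattr(c, "seq") else len(c) for c in contigs]
    if not lengths:
        return AssemblyReport(0, 0, 0, 0, 0, 0, 0,
                              0.0 if reference else None)
    genome_len = sum(len(r.seq) for r in reference) if reference else None
    return AssemblyReport(
        n_contigs=len(lengths),
        total_len=sum(lengths),
        max_len=max(lengths),
        n20=nx(lengths, 20),
        n50=nx(lengths, 50),
        n80=nx(lengths, 80),
        ng50=ngx(lengths, genome_len, 50) if genome_len else 0,
        cgr=covered_genome_ratio(contigs, reference, min_identity,
                                 min_contig_len, seed_k)
        if reference else None,
    )
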