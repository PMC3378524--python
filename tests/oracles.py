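"""Independent brute-force oracles used across the test suite.

Everything here works on plain strings and dicts, deliberately avoiding the
package's packed-integer and graph machinery, so the two routes can be
compared.
"""

from collections import Counter
from typing import Dict, Iterable, List, Optional, Tuple

_RC = str.maketrans("ACGT", "TGCA")

LEFT, RIGHT = 0, 1


def rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def canon(s: str) -> str:
    return min(s, rc(s))


def kmer_census(seqs: Iterable[str], k: int) -> Counter:
    """Canonical k-mer counts; windows with non-ACGT bases skipped."""
    out: Counter = Counter()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if set(w) <= set("ACGT"):
                out[canon(w)] += 1
    return out


def neighbors(words: Iterable[str], word: str, side: int
              ) -> List[Tuple[str, int, str]]:
    """(neighbor canonical word, neighbor side, extending base) per overlap."""
    wordset = set(words)
    out = []
    for b in "ACGT":
        if side == RIGHT:
            w2 = word[1:] + b
            nbr_side_if_fwd = LEFT
        else:
            w2 = b + word[:-1]
            nbr_side_if_fwd = RIGHT
        c = canon(w2)
        if c in wordset:
            nbr_side = nbr_side_if_fwd if w2 == c else 1 - nbr_side_if_fwd
            out.append((c, nbr_side, b))
    return out


def edge_weight_oracle(counts: Dict[str, float], word: str, side: int,
                       base: str) -> float:
    """coverage(neighbor) + max coverage among its continuing neighbors."""
    if side == RIGHT:
        w2 = word[1:] + base
    else:
        w2 = base + word[:-1]
    cont = []
    for b2 in "ACGT":
        w3 = w2[1:] + b2 if side == RIGHT else b2 + w2[:-1]
        c3 = canon(w3)
        if c3 in counts:
            cont.append(counts[c3])
    return counts[canon(w2)] + (max(cont) if cont else 0.0)


def preferred_oracle(counts: Dict[str, float], word: str, side: int
                     ) -> Optional[Tuple[str, str]]:
    """(base, neighbor canonical) of the argmax-weight non-loop link."""
    best = None
    for c, _nbr_side, b in neighbors(counts, word, side):
        if c == word:
            continue
        key = (-edge_weight_oracle(counts, word, side, b),
               "ACGT".index(b), c)
        if best is None or key < best[0]:
            best = (key, (b, c))
    return best[1] if best else None


def connected(words: Iterable[str]) -> bool:
    words = list(words)
    if not words:
        return False
    seen = {words[0]}
    stack = [words[0]]
    while stack:
        w = stack.pop()
        for side in (LEFT, RIGHT):
            for c, _s, _b in neighbors(words, w, side):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
    return len(seen) == len(words)


def fold_table_oracle(reads: Iterable[str], k: int,
                      interval: Optional[int] = None,
                      t_mid: int = 1) -> Dict[str, int]:
    """Reference fold of the counting + periodic-prune schedule.

    The prune fires between reads: after every ``interval`` reads but only
    once another read actually follows.
    """
    table: Dict[str, int] = {}
    n = 0
    pending = False
    for seq in reads:
        if pending:
            table = {w: c for w, c in table.items() if c > t_mid}
            pending = False
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if set(w) <= set("ACGT"):
                c = canon(w)
                table[c] = table.get(c, 0) + 1
        n += 1
        if interval and n % interval == 0:
            pending = True
    return table


def nx_oracle(lengths: List[int], x: float) -> int:
    total = sum(lengths)
    cum = 0
    for length in sorted(lengths, reverse=True):
        cum += length
        if cum * 100 >= x * total:
            return length
    raise AssertionError


def ngx_oracle(lengths: List[int], g: int, x: float) -> int:
    cum = 0
    for length in sorted(lengths, reverse=True):
        cum += length
        if cum * 100 >= x * g:
            return length
    return 0
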