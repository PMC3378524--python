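"""FASTA/FASTQ reading and FASTA contig writing.

Parsing goes through Biopython's SeqIO; this module only adds format
auto-detection, transparent gzip, sequence sanitization (uppercase, every
character outside {A,C,G,T,N} mapped to N — downstream k-mer extraction
already skips N windows), and an error type that names the offending record.
Qualities are validated during FASTQ parsing but never used afterwards.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Union

from Bio import SeqIO

PathLike = Union[str, Path]

_SANITIZE = str.maketrans(
    {c: "N" for c in map(chr, range(256)) if c not in "ACGTN"})


@dataclass
class Read:
    """A single sequenced fragment."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}")


@dataclass
class SeqRecord:
    """A reference sequence (one FASTA record, e.g. one chromosome)."""

    id: str
    seq: str


class ParseError(ValueError):
    """Malformed input record."""


def sanitize(seq: str) -> str:
    return seq.upper().translate(_SANITIZE)


def _open_text(path: PathLike) -> io.TextIOBase:
    path = Path(path)
    raw = open(path, "rb")
    magic = raw.peek(2)[:2] if isinstance(raw, io.BufferedReader) else b""
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(raw))  # type: ignore[arg-type]
    return io.TextIOWrapper(raw)


def detect_format(path: PathLike) -> str:
    """'fasta' or 'fastq' from the first non-blank character."""
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                c = line[0]
                if c == ">":
                    return "fasta"
                if c == "@":
                    return "fastq"
                raise ParseError(
                    f"{path}: cannot detect format from leading {c!r}")
    return "fasta"  # empty file: arbitrary, parses to an empty stream


def parse_reads(path: PathLike, format: str = "auto") -> Iterator[Read]:
    """Stream reads from a FASTA or FASTQ file.

    Sequences are uppercased and non-ACGTN characters become N.  An empty
    file yields an empty stream.  A malformed record (e.g. FASTQ
    sequence/quality length mismatch) raises :class:`ParseError` naming the
    record position.
    """
    if format == "auto":
        format = detect_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    n = 0
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, format):
                n += 1
                qual = None
                if format == "fastq":
                    quals = rec.letter_annotations.get("phred_quality")
                    if quals is not None:
                        qual = "".join(chr(q + 33) for q in quals)
                yield Read(rec.id, sanitize(str(rec.seq)), qual)
        except ValueError as err:
            raise ParseError(f"{path}: record {n + 1}: {err}") from err


def read_reference(path: PathLike) -> List[SeqRecord]:
    """Load a (possibly multi-record) reference FASTA.

    Every record must have a nonempty sequence.
    """
    out: List[SeqRecord] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = sanitize(str(rec.seq))
            if not seq:
                raise ParseError(f"{path}: reference record {rec.id!r} is empty")
            out.append(SeqRecord(rec.id, seq))
    return out


def write_contigs(contigs: Sequence, path: PathLike, line_width: int = 70) -> None:
    """Write contigs as FASTA, headers carrying index/length/provenance.

    ``contigs`` may be :class:`covasm.contig_gen.Contig` objects or plain
    (id, seq) style records; anything with ``.seq`` works.
    """
    if line_width < 1:
        raise ValueError("line_width must be positive")
    with open(path, "w") as fh:
        for i, c in enumerate(contigs):
            seq = c.seq
            if not seq:
                raise ValueError(f"contig {i} has an empty sequence")
            nodes = getattr(c, "n_nodes", None)
            cov = getattr(c, "coverage", None)
            header = f">contig_{i} len={len(seq)}"
            if nodes is not None:
                header += f" nodes={nodes}"
            if cov is not None:
                header += f" cov={cov:.2f}"
            fh.write(header + "\n")
            for j in range(0, len(seq), line_width):
                fh.write(seq[j:j + line_width] + "\n")


def write_reads(reads: Iterable[Read], path: PathLike,
                format: str = "auto") -> None:
    """Write reads as FASTA or FASTQ (constant quality I when absent)."""
    path = Path(path)
    if format == "auto":
        suffix = path.name.lower()
        format = "fastq" if (suffix.endswith(".fq") or suffix.endswith(".fastq")
                             or suffix.endswith(".fq.gz")
                             or suffix.endswith(".fastq.gz")) else "fasta"
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "wt") as fh:  # type: ignore[operator]
        for r in reads:
            if format == "fastq":
                qual = r.qual or "I" * len(r.seq)
                fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
            else:
                fh.write(f">{r.id}\n{r.seq}\n")
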