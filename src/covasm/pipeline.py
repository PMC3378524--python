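"""End-to-end assembly orchestration.

Phases, in order: count canonical k-mers into the coverage table (with
optional periodic mid-build pruning) -> end-of-build prune -> build the
de Bruijn graph -> merge unitigs -> compute weights and preferred links ->
resolve conflicts -> emit contigs -> write FASTA.  Per-phase structure
counts are logged at INFO and returned; identical configuration gives
byte-identical output regardless of worker count.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

from . import contig_gen, dbg, edge_select, io_seq, kmer_table
from .contig_gen import Contig
from .io_seq import PathLike, Read
from .kmer_table import PruneConfig

logger = logging.getLogger("covasm")

K_WARN_FLOOR = 19  # typical sweeps start here
K_HARD_FLOOR = 5


@dataclass
class AssemblyConfig:
    """Everything one assembly run needs.

    ``workers=1`` is the reference execution path; higher counts only
    parallelize k-mer extraction and must not change any output.
    """

    k: int
    reads: List[PathLike] = field(default_factory=list)
    out: Optional[PathLike] = None
    gfa: Optional[PathLike] = None
    prune: Optional[PruneConfig] = field(default_factory=PruneConfig)
    min_contig_len: Optional[int] = None
    workers: int = 1
    seed: int = 0
    n_shards: int = 4096

    def __post_init__(self) -> None:
        if self.k < K_HARD_FLOOR:
            raise ValueError(f"k must be >= {K_HARD_FLOOR}")
        if self.k % 2 == 0:
            raise ValueError("k must be odd (a canonical k-mer must differ "
                             "from its reverse complement)")
        if self.k < K_WARN_FLOOR:
            logger.warning("k=%d is small; values below %d rarely assemble "
                           "well", self.k, K_WARN_FLOOR)
        if self.workers < 1:
            raise ValueError("workers must be >= 1")

    def validate_paths(self) -> None:
        for p in self.reads:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _read_stream(paths: Sequence[PathLike]) -> Iterable[Read]:
    for p in paths:
        yield from io_seq.parse_reads(p)


def run_assembly(cfg: AssemblyConfig,
                 reads: Optional[Iterable[Read]] = None
                 ) -> tuple[List[Contig], Dict[str, object]]:
    """Run the full pipeline; returns (contigs, per-phase statistics).

    ``reads`` may be given directly (in-memory pipeline); otherwise the
    configured files are streamed.  Contigs are written to ``cfg.out`` when
    set, and the (merged) graph to ``cfg.gfa`` when set.
    """
    stats: Dict[str, object] = {"k": cfg.k}
    if reads is None:
        cfg.validate_paths()
        reads = _read_stream(cfg.reads)

    def phase(name: str):
        logger.info("phase %s", name)
        return time.monotonic()

    t = phase("count")
    table = kmer_table.build_table(reads, cfg.k, cfg.prune,
                                   workers=cfg.workers, n_shards=cfg.n_shards)
    stats["reads"] = table.reads_processed
    stats["reads_skipped"] = table.reads_skipped
    stats["kmers_counted"] = table.total_kmers
    logger.info("counted %d distinct k-mers from %d reads (%.2fs)",
                table.total_kmers, table.reads_processed, time.monotonic() - t)

    t = phase("prune")
    repeats: set = set()
    if cfg.prune is not None:
        before = table.total_kmers
        table, repeats = kmer_table.prune(table, cfg.prune.t_low,
                                          cfg.prune.t_high)
        stats["kmers_pruned"] = before - table.total_kmers - len(repeats)
        stats["kmers_repeat"] = len(repeats)
    stats["kmers_surviving"] = table.total_kmers

    t = phase("graph")
    graph = dbg.build_graph(table)
    stats["graph_nodes"] = len(graph.nodes)
    stats["graph_links"] = graph.link_records()

    t = phase("merge")
    graph = dbg.merge_unitigs(graph)
    stats["unitig_nodes"] = len(graph.nodes)
    logger.info("merged into %d unitigs (%.2fs)", len(graph.nodes),
                time.monotonic() - t)

    t = phase("preferred")
    edge_select.assign_preferred(graph)
    events: List[edge_select.ArbitrationEvent] = []
    graph, passes = edge_select.resolve_conflicts(graph, events)
    stats["arbitration_events"] = len(events)
    stats["resolution_passes"] = passes
    stats["links_after_resolution"] = graph.link_records()
    for ev in events:
        logger.debug("arbitration: %s %s(%.1f) vs %s(%.1f) -> %s",
                     ev.action, ev.jn1, ev.cov1, ev.jn2, ev.cov2,
                     ev.new_preferred)

    t = phase("contigs")
    contigs = contig_gen.emit_contigs(graph, cfg.min_contig_len)
    stats["n_contigs"] = len(contigs)
    stats["assembly_len"] = sum(c.length for c in contigs)
    logger.info("emitted %d contigs, %d bp total (%.2fs)", len(contigs),
                stats["assembly_len"], time.monotonic() - t)

    if cfg.gfa is not None:
        dbg.write_gfa(graph, str(cfg.gfa))
    if cfg.out is not None:
        io_seq.write_contigs(contigs, cfg.out)
    return contigs, stats
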