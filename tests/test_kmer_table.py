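import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covasm import kmer_table as kt
from covasm.io_seq import Read
from covasm.sim_reads import random_genome, tiling_reads
from oracles import canon, fold_table_oracle, kmer_census, rc

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


def keys_to_words(table):
    return {kt.decode(key, table.k): c for key, c in table.items()}


# ---------------------------------------------------------------------------
# canonical encoding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("word,expect", [
    ("TTTT", "AAAA"),      # homopolymer folds to its reverse complement
    ("ACGT", "ACGT"),      # its own reverse complement
    ("ATTGG", "ATTGG"),    # revcomp CCAAT sorts later
])
def test_canonical_examples(word, expect):
    assert kt.decode(kt.canonical(word), len(word)) == expect


def test_canonical_rejects_ambiguous_bases():
    with pytest.raises(ValueError):
        kt.canonical("ACGNT")


@given(dna.filter(lambda s: len(s) >= 1))
@settings(max_examples=200, deadline=None)
def test_encode_decode_roundtrip_and_canonical_matches_strings(word):
    assert kt.decode(kt.encode(word), len(word)) == word
    assert kt.decode(kt.canonical(word), len(word)) == min(word, rc(word))


@given(dna)
@settings(max_examples=200, deadline=None)
def test_kmer_keys_match_string_census(seq):
    k = 5
    got = sorted(kt.decode(key, k) for key in kt.kmer_keys(seq, k))
    want = sorted(canon(seq[i:i + k]) for i in range(len(seq) - k + 1))
    assert got == want


def test_large_k_python_path_agrees_with_string_census():
    g = random_genome(300, seed=4).seq
    k = 37  # beyond the int64 fast path
    got = sorted(kt.decode(key, k) for key in kt.kmer_keys(g, k))
    want = sorted(canon(g[i:i + k]) for i in range(len(g) - k + 1))
    assert got == want


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def test_add_read_counts_canonical_windows():
    t = kt.CoverageTable(3)
    t.add_read(Read("r", "AGGCT"))
    assert keys_to_words(t) == {"AGG": 1, "GCC": 1, "AGC": 1}
    assert t.total_kmers == 3  # g - k + 1 for a repeat-free word


def test_short_read_discarded():
    t = kt.CoverageTable(3)
    t.add_read(Read("r", "AG"))
    assert t.total_kmers == 0
    assert t.reads_skipped == 1


def test_ambiguous_windows_skipped():
    t = kt.CoverageTable(3)
    t.add_read(Read("r", "ANG"))
    assert t.total_kmers == 0


def test_strand_invariance_of_counting():
    reads = [Read(f"r{i}", s) for i, s in
             enumerate(["ACGTTGCA", "GGGTTAC", "TTTTT"])]
    flipped = [Read(r.id, rc(r.seq)) for r in reads]
    a = kt.build_table(iter(reads), 5)
    b = kt.build_table(iter(flipped), 5)
    assert a.as_dict() == b.as_dict()


@pytest.mark.parametrize("n_shards", [1, 7, 4096])
def test_shard_count_is_invisible(n_shards):
    g = random_genome(400, seed=6).seq
    reads = [Read(f"r{i}", g[i:i + 40]) for i in range(0, 350, 13)]
    t = kt.build_table(iter(reads), 15, n_shards=n_shards)
    ref = kt.build_table(iter(reads), 15, n_shards=64)
    assert t.as_dict() == ref.as_dict()
    assert t.total_kmers == sum(len(s) for s in t.shards)


def test_workers_do_not_change_the_table():
    g = random_genome(2000, seed=7)
    reads = tiling_reads(g, 50, 10)
    seq_path = kt.build_table(iter(reads), 21, workers=1)
    par_path = kt.build_table(iter(reads), 21, workers=4)
    assert seq_path.as_dict() == par_path.as_dict()
    assert par_path.reads_processed == len(reads)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def test_prune_examples():
    t = kt.CoverageTable.from_counts({"AAACA": 1, "AAACC": 5}, 5)
    kept, repeats = kt.prune(t, t_low=1)
    assert keys_to_words(kept) == {"AAACC": 5} and repeats == set()

    t = kt.CoverageTable.from_counts({"AAACA": 1, "AAACC": 5}, 5)
    kept, _ = kt.prune(t, t_low=0)
    assert kept.as_dict() == t.as_dict()

    t = kt.CoverageTable.from_counts({"AAACA": 2, "AAACC": 500}, 5)
    kept, repeats = kt.prune(t, t_low=1, t_high=100)
    assert keys_to_words(kept) == {"AAACA": 2}
    assert {kt.decode(key, 5) for key in repeats} == {"AAACC"}


def test_prune_low_removes_exactly_singletons():
    g = random_genome(600, seed=8)
    reads = [Read(f"r{i}", g.seq[i * 3:i * 3 + 50]) for i in range(150)
             if len(g.seq[i * 3:i * 3 + 50]) >= 21]
    t = kt.build_table(iter(reads), 21)
    kept, _ = kt.prune(t, t_low=1)
    census = kmer_census([r.seq for r in reads], 21)
    assert keys_to_words(kept) == {w: c for w, c in census.items() if c > 1}


def test_periodic_prune_interval_beyond_stream_is_identity():
    reads = [Read(f"r{i}", random_genome(60, seed=20 + i).seq)
             for i in range(10)]
    plain = kt.build_table(iter(reads), 11)
    cfg = kt.PruneConfig(interval=len(reads) + 1)
    lazy = kt.build_table(iter(reads), 11, cfg)
    assert plain.as_dict() == lazy.as_dict()


def test_periodic_prune_hand_schedule():
    # after read 1 every key has count 1 and is deleted; read 2 re-enters
    # all three keys at count 1
    reads = [Read("a", "AGGCT"), Read("b", "AGGCT")]
    cfg = kt.PruneConfig(interval=1, t_mid=1)
    t = kt.build_table(iter(reads), 3, cfg)
    assert keys_to_words(t) == {"AGG": 1, "GCC": 1, "AGC": 1}


@pytest.mark.parametrize("interval", [1, 3, 7, None])
def test_periodic_prune_matches_reference_fold(interval):
    rng = np.random.default_rng(30)
    reads = [Read(f"r{i}",
                  "".join("ACGT"[c] for c in rng.integers(0, 4, 30)))
             for i in range(25)]
    cfg = kt.PruneConfig(interval=interval) if interval else None
    t = kt.build_table(iter(reads), 7, cfg)
    want = fold_table_oracle([r.seq for r in reads], 7, interval)
    assert keys_to_words(t) == want


def test_periodic_prune_never_increases_key_count():
    g = random_genome(1000, seed=31)
    reads = tiling_reads(g, 50, 8)
    base = kt.build_table(iter(reads), 21).total_kmers
    for interval in (5, 20, 80):
        pruned = kt.build_table(iter(reads), 21,
                                kt.PruneConfig(interval=interval))
        assert pruned.total_kmers <= base


def test_prune_config_validation():
    with pytest.raises(ValueError):
        kt.PruneConfig(t_low=-1)
    with pytest.raises(ValueError):
        kt.PruneConfig(t_low=2, t_high=2)
    with pytest.raises(ValueError):
        kt.PruneConfig(interval=0)


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

def test_histogram_examples():
    t = kt.CoverageTable.from_counts({"AAACA": 1, "AAACC": 1, "AAACG": 5}, 5)
    assert kt.coverage_histogram(t) == {1: 2, 5: 1}
    assert kt.coverage_histogram(kt.CoverageTable(5)) == {}


def test_histogram_mass_near_expected_kmer_depth():
    # error-free uniform coverage: expected k-mer depth is C*(L-k+1)/L
    from covasm.sim_reads import SimConfig, simulate_reads
    g = random_genome(8000, seed=33)
    L, C, k = 75, 40, 21
    reads = simulate_reads(g, SimConfig(L, C, seed=34))
    t = kt.build_table((r for r in reads), k)
    hist = kt.coverage_histogram(t)
    assert sum(hist.values()) == t.total_kmers
    expected = C * (L - k + 1) / L
    mean = sum(c * n for c, n in hist.items()) / sum(hist.values())
    assert abs(mean - expected) / expected < 0.10
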