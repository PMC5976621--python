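"""Trimming, filtering, ORF extraction and clustering against brute-force
oracles and their documented boundary behaviour."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from holopart import (FilterConfig, Transcript, TrimConfig, filter_length,
                      gc_fraction, greedy_cluster, longest_orf, n50,
                      trim_read)
from oracles import (greedy_cluster_brute, longest_orf_brute, n50_brute,
                     trim_brute)

CFG = TrimConfig()


# ---------------------------------------------------------------------------
# trim_read
# ---------------------------------------------------------------------------

def test_trim_high_quality_read_loses_only_headcrop():
    seq, quals = "A" * 50, [40] * 50
    out = trim_read(seq, quals, CFG)
    assert out is not None
    assert len(out[0]) == 40


def test_trim_short_read_dropped_at_boundary():
    # 35 bp at Q40: 25 bp after headcrop, <= 30 -> dropped
    assert trim_read("A" * 35, [40] * 35, CFG) is None


def test_trim_low_quality_tail_cut_by_window():
    quals = [40] * 10 + [40] * 40 + [10] * 10  # headcrop eats first 10
    seq = "A" * 60
    out = trim_read(seq, quals, CFG)
    oracle = trim_brute(seq, quals, CFG.headcrop, CFG.end_quality,
                        CFG.window_size, CFG.window_quality, CFG.min_length)
    assert out == oracle
    assert out is not None and len(out[0]) == 40


def test_trim_length_mismatch_rejected():
    with pytest.raises(ValueError):
        trim_read("ACGT", [40, 40, 40], CFG)


@given(st.lists(st.integers(min_value=2, max_value=40), min_size=1,
                max_size=120),
       st.integers(min_value=1, max_value=12))
def test_trim_matches_oracle_and_is_idempotent(quals, headcrop):
    """trim_read equals the independent rule replay and is a fixed point."""
    cfg = TrimConfig(headcrop=headcrop, end_quality=30, window_size=4,
                     window_quality=20, min_length=5)
    seq = "A" * len(quals)
    out = trim_read(seq, quals, cfg)
    assert out == trim_brute(seq, quals, cfg.headcrop, cfg.end_quality,
                             cfg.window_size, cfg.window_quality,
                             cfg.min_length)
    if out is not None:
        s, q = out
        assert len(s) <= len(seq)
        # a surviving read re-trimmed under headcrop=0 semantics of the
        # quality rules must already satisfy them: LEADING/TRAILING and
        # SLIDINGWINDOW leave it unchanged
        cfg2 = TrimConfig(headcrop=1, end_quality=cfg.end_quality,
                          window_size=cfg.window_size,
                          window_quality=cfg.window_quality,
                          min_length=cfg.min_length)
        again = trim_read("A" + s, [40] + q, cfg2)
        assert again == (s, q) or again is None


def test_trim_oracle_equivalence_bulk(rng):
    """1,000 random reads, random configs: implementation == oracle."""
    mismatches = 0
    for _ in range(1000):
        n = int(rng.integers(1, 150))
        quals = [int(x) for x in rng.integers(2, 41, size=n)]
        seq = "".join(rng.choice(list("ACGT"), size=n))
        cfg = TrimConfig(headcrop=int(rng.integers(1, 12)),
                         end_quality=int(rng.integers(10, 36)),
                         window_size=int(rng.integers(1, 8)),
                         window_quality=int(rng.integers(10, 36)),
                         min_length=int(rng.integers(1, 40)))
        got = trim_read(seq, quals, cfg)
        want = trim_brute(seq, quals, cfg.headcrop, cfg.end_quality,
                          cfg.window_size, cfg.window_quality, cfg.min_length)
        mismatches += got != want
    assert mismatches == 0


# ---------------------------------------------------------------------------
# filter_length / n50 / gc_fraction
# ---------------------------------------------------------------------------

def test_filter_length_boundary_and_order():
    ts = [Transcript(id=f"t{i}", seq="A" * L)
          for i, L in enumerate([299, 300, 1000])]
    kept = filter_length(ts)
    assert [len(t) for t in kept] == [300, 1000]
    assert filter_length([]) == []
    assert filter_length(ts[1:]) == ts[1:]


@pytest.mark.parametrize("lengths,expected", [
    ([8, 8, 4, 3, 3, 2, 2, 2], 8),
    ([1000], 1000),
    ([2, 2, 2, 2], 2),
])
def test_n50_worked_examples(lengths, expected):
    assert n50(lengths) == expected


def test_n50_empty_rejected():
    with pytest.raises(ValueError):
        n50([])


def test_n50_matches_brute_force_on_random_multisets(rng):
    for _ in range(1000):
        lengths = [int(x) for x in
                   rng.integers(1, 5000, size=int(rng.integers(1, 40)))]
        assert n50(lengths) == n50_brute(lengths)


@pytest.mark.parametrize("seq,expected", [
    ("ATGC", 0.5),
    ("GGCC", 1.0),
    ("ATGCN", 0.5),
    ("atgc", 0.5),
])
def test_gc_fraction(seq, expected):
    assert gc_fraction(seq) == pytest.approx(expected)


def test_gc_fraction_all_ambiguous_is_missing():
    assert gc_fraction("NNNN") is None


# ---------------------------------------------------------------------------
# longest_orf
# ---------------------------------------------------------------------------

def test_longest_orf_forward_100aa():
    t = Transcript(id="t", seq="ATG" + "GCT" * 99 + "TAA")
    orf = longest_orf(t)
    assert orf is not None
    assert orf.peptide == "M" + "A" * 99
    assert orf.strand == "+"
    assert (orf.end - orf.start + 1) % 3 == 0


def test_longest_orf_reverse_strand_same_peptide():
    from Bio.Seq import Seq
    fwd = "ATG" + "GCT" * 99 + "TAA"
    t = Transcript(id="t", seq=str(Seq(fwd).reverse_complement()))
    orf = longest_orf(t)
    assert orf is not None
    assert orf.peptide == "M" + "A" * 99
    assert orf.strand == "-"


def test_longest_orf_none_when_no_qualifying_orf():
    assert longest_orf(Transcript(id="t", seq="A" * 500)) is None


def test_longest_orf_matches_brute_force(rng):
    cfg = FilterConfig(min_orf_aa=5)
    agree = 0
    for _ in range(1000):
        n = int(rng.integers(30, 200))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        got = longest_orf(Transcript(id="t", seq=seq), cfg)
        want = longest_orf_brute(seq, cfg.min_orf_aa)
        if want is None:
            assert got is None
        else:
            strand_rank, frame, start, end, pep = want
            assert got is not None
            assert (got.strand, got.frame, got.start, got.end,
                    got.peptide) == ("+-"[strand_rank], frame, start, end, pep)
        agree += 1
    assert agree == 1000


# ---------------------------------------------------------------------------
# greedy_cluster
# ---------------------------------------------------------------------------

def _random_peptides(rng, n, lo, hi):
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    return [(f"p{i}",
             "".join(rng.choice(aas, size=int(rng.integers(lo, hi)))))
            for i in range(n)]


def test_cluster_identical_plus_unrelated(rng):
    items = [("a", "M" + "K" * 99), ("b", "M" + "K" * 99)]
    items += _random_peptides(rng, 1, 100, 101)
    clusters = greedy_cluster(items)
    assert len(clusters) == 2


def test_cluster_n_identical_copies_single_cluster():
    items = [(f"p{i}", "MKLVNQ" * 20) for i in range(7)]
    clusters = greedy_cluster(items)
    assert len(clusters) == 1
    assert sorted(clusters[0].members) == sorted(i for i, _ in items)


def test_cluster_matches_brute_oracle_random_inputs(rng):
    """Word-filtered clustering equals the unfiltered brute-force greedy
    oracle on 1,000 random small inputs."""
    cfg = FilterConfig(cluster_identity=0.95, cluster_word_size=10)
    for _ in range(1000):
        n = int(rng.integers(2, 7))
        items = _random_peptides(rng, n, 8, 40)
        # mix in near-duplicates so some clusters actually merge
        if n >= 3 and rng.uniform() < 0.6:
            src = items[0][1]
            items.append(("dup", src[:-1] + "A"))
        got = greedy_cluster(items, cfg)
        want = greedy_cluster_brute(items, cfg.cluster_identity)
        assert [sorted(c.members) for c in got] == \
            [sorted(m) for m in want]


def test_cluster_partition_is_exhaustive_and_disjoint(rng):
    items = _random_peptides(rng, 50, 90, 110)
    clusters = greedy_cluster(items)
    members = [m for c in clusters for m in c.members]
    assert sorted(members) == sorted(i for i, _ in items)
    reps = {c.representative for c in clusters}
    assert reps <= {i for i, _ in items}
    for c in clusters:
        assert c.representative in c.members


def test_cluster_word_filter_neutral_at_50_random_length100(rng):
    cfg = FilterConfig(cluster_identity=0.95, cluster_word_size=10)
    items = _random_peptides(rng, 50, 100, 101)
    filtered = greedy_cluster(items, cfg, use_word_filter=True)
    unfiltered = greedy_cluster(items, cfg, use_word_filter=False)
    assert [sorted(c.members) for c in filtered] == \
        [sorted(c.members) for c in unfiltered]
    assert len(filtered) == len(greedy_cluster_brute(items, 0.95))
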