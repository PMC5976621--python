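"""Exclusive-hit binning, the e-value sweep, the composition classifier
and the end-to-end partition."""

import numpy as np
import pytest

from holopart import (AlignmentHit, CompositionModel, PartitionConfig,
                      SimulationConfig, Transcript, bin_by_exclusive_hits,
                      gc_profile, generate_hit_table, generate_transcriptome,
                      partition_pipeline, segregate_ambiguous, sweep_cutoffs,
                      train_composition_classifier)
from holopart.partition import ConsistencyError, TrainingError

HOST = CompositionModel(label="host", gc_target=0.43)
SYM = CompositionModel(label="symbiont", gc_target=0.54)


def _hit(q, db, e):
    return AlignmentHit(query_id=q, subject_id="s", db_label=db,
                        pident=95.0, evalue=e, bitscore=100.0)


def _ts(*ids):
    return [Transcript(id=i, seq="ACGT" * 25) for i in ids]


# ---------------------------------------------------------------------------
# bin_by_exclusive_hits
# ---------------------------------------------------------------------------

def test_exclusive_binning_rules():
    transcripts = _ts("T1", "T2", "T3", "T4")
    hits = [
        _hit("T1", "host_db", 1e-20),
        _hit("T2", "host_db", 1e-20), _hit("T2", "symbiont_db", 1e-4),
        _hit("T4", "host_db", 1e-30), _hit("T4", "symbiont_db", 1e-30),
    ]
    bins = bin_by_exclusive_hits(hits, transcripts, cutoff=1e-5)
    assert bins["host_exclusive"] == ["T1", "T2"]  # T2's symbiont hit fails
    assert bins["ambiguous"] == ["T4"]
    assert bins["unclassified"] == ["T3"]


def test_exclusive_binning_cutoff_inclusive():
    bins = bin_by_exclusive_hits([_hit("T1", "symbiont_db", 1e-5)],
                                 _ts("T1"), cutoff=1e-5)
    assert bins["symbiont_exclusive"] == ["T1"]


def test_unknown_query_rejected():
    with pytest.raises(ConsistencyError):
        bin_by_exclusive_hits([_hit("ghost", "host_db", 1e-20)],
                              _ts("T1"), 1e-5)


# ---------------------------------------------------------------------------
# sweep_cutoffs
# ---------------------------------------------------------------------------

def _sweep_for(unclassified_by_cutoff):
    """Construct transcripts/hits realising the requested per-cutoff
    unclassified counts (cutoffs 1e-4, 1e-5, 1e-8, 1e-10)."""
    cutoffs = [1e-4, 1e-5, 1e-8, 1e-10]
    # transcripts whose single hit has e-value between adjacent cutoffs
    # become unclassified for every tighter cutoff
    n_total = max(unclassified_by_cutoff.values()) + 5
    counts = [unclassified_by_cutoff[c] for c in cutoffs]
    ts, hits = [], []
    tid = 0

    def add(n, evalue):
        nonlocal tid
        for _ in range(n):
            ts.append(Transcript(id=f"t{tid}", seq="ACGT" * 10))
            if evalue is not None:
                hits.append(_hit(f"t{tid}", "host_db", evalue))
            tid += 1

    add(counts[0], None)                      # never classified
    add(counts[1] - counts[0], 5e-5)          # pass only at 1e-4
    add(counts[2] - counts[1], 5e-6)          # pass at 1e-4, 1e-5
    add(counts[3] - counts[2], 5e-9)          # fail only at 1e-10
    add(n_total - counts[3], 1e-30)           # always pass
    return hits, ts


def test_sweep_minimum_unclassified_wins():
    hits, ts = _sweep_for({1e-4: 40, 1e-5: 45, 1e-8: 60, 1e-10: 70})
    chosen, table = sweep_cutoffs(hits, ts)
    assert chosen == 1e-4
    assert {c: v["n_unclassified"] for c, v in table.items()} == \
        {1e-4: 40, 1e-5: 45, 1e-8: 60, 1e-10: 70}


def test_sweep_tie_breaks_toward_stringent():
    hits, ts = _sweep_for({1e-4: 40, 1e-5: 40, 1e-8: 60, 1e-10: 70})
    chosen, _ = sweep_cutoffs(hits, ts)
    assert chosen == 1e-5


def test_sweep_degenerate_all_equal_picks_most_stringent():
    ts = _ts("a", "b")
    hits = [_hit("a", "host_db", 1e-30), _hit("b", "symbiont_db", 1e-40)]
    chosen, table = sweep_cutoffs(hits, ts)
    assert chosen == 1e-10
    assert len({tuple(v.values()) for v in table.values()}) == 1


def test_sweep_counts_conserve_input_size(rng):
    """Counts sum to n at every cutoff; unclassified is non-increasing as
    the cutoff loosens; ambiguous non-increasing as it tightens."""
    for _ in range(100):
        n = int(rng.integers(5, 60))
        ts = _ts(*[f"t{i}" for i in range(n)])
        hits = []
        for t in ts:
            for db in ("host_db", "symbiont_db"):
                for _h in range(int(rng.integers(0, 3))):
                    hits.append(_hit(t.id, db,
                                     10.0 ** rng.uniform(-40, -2)))
        _, table = sweep_cutoffs(hits, ts)
        cuts = sorted(table)  # ascending = tight to loose
        for c in cuts:
            assert sum(table[c].values()) == n
        unc = [table[c]["n_unclassified"] for c in cuts]
        assert all(a >= b for a, b in zip(unc, unc[1:]))
        amb = [table[c]["n_ambiguous"] for c in cuts]
        assert all(a <= b for a, b in zip(amb, amb[1:]))


# ---------------------------------------------------------------------------
# composition classifier
# ---------------------------------------------------------------------------

def _seqs(model, n, seed, length=1000):
    cfg = SimulationConfig(length_min=length, length_max=length, seed=seed)
    return [t.seq for t in generate_transcriptome(model, n, cfg, seed=seed)]


def test_classifier_separates_gc_classes():
    host = _seqs(HOST, 500, seed=7)
    sym = _seqs(SYM, 500, seed=8)
    model = train_composition_classifier(host, sym, seed=7)
    assert model.training_report["holdout_accuracy"] >= 0.95
    assert len(model.feature_order) == 4 ** model.k


def test_classifier_chance_level_on_identical_models():
    a = _seqs(HOST, 300, seed=1)
    b = _seqs(HOST, 300, seed=2)
    model = train_composition_classifier(a, b, seed=3)
    acc = model.training_report["holdout_accuracy"]
    n = model.training_report["holdout_size"]
    sd = (0.25 / n) ** 0.5
    assert abs(acc - 0.5) <= 3 * sd


def test_classifier_short_sequences_excluded():
    host = _seqs(HOST, 30, seed=4) + ["AC"]
    sym = _seqs(SYM, 30, seed=5)
    with pytest.warns(UserWarning, match="shorter than k"):
        model = train_composition_classifier(host, sym, seed=4)
    assert model.training_report["n_host"] == 30


def test_classifier_minimum_class_size():
    with pytest.raises(TrainingError, match="exclusive-hit-only"):
        train_composition_classifier(_seqs(HOST, 5, seed=1),
                                     _seqs(SYM, 30, seed=2), seed=1)


def test_segregate_ambiguous_accuracy():
    """200+200 labelled ambiguous synthetics classified at >= 0.95."""
    model = train_composition_classifier(_seqs(HOST, 300, seed=7),
                                         _seqs(SYM, 300, seed=8), seed=7)
    amb_host = {f"h{i}": s for i, s in enumerate(_seqs(HOST, 200, seed=9))}
    amb_sym = {f"s{i}": s for i, s in enumerate(_seqs(SYM, 200, seed=10))}
    out = segregate_ambiguous(model, {**amb_host, **amb_sym})
    correct = sum(out[k] == "host" for k in amb_host)
    correct += sum(out[k] == "symbiont" for k in amb_sym)
    assert correct / 400 >= 0.95
    assert segregate_ambiguous(model, {}) == {}


def test_single_host_like_ambiguous_sequence_goes_host():
    model = train_composition_classifier(_seqs(HOST, 300, seed=7),
                                         _seqs(SYM, 300, seed=8), seed=7)
    seq = _seqs(HOST, 1, seed=77)[0]
    assert segregate_ambiguous(model, {"x": seq}) == {"x": "host"}


# ---------------------------------------------------------------------------
# partition_pipeline
# ---------------------------------------------------------------------------

def _make_mixture(seed, p_cross=0.0, p_nohit=0.0):
    cfg = SimulationConfig(n_host=150, n_symbiont=150, p_hit_true=1.0,
                           p_hit_cross=p_cross, p_nohit=p_nohit,
                           evalue_log10_range=(-50, -5), seed=seed)
    host = generate_transcriptome(HOST, cfg.n_host, cfg, seed=seed)
    sym = generate_transcriptome(SYM, cfg.n_symbiont, cfg, seed=seed + 1)
    ts = host + sym
    hits, truth = generate_hit_table(ts, cfg)
    return ts, hits, truth


def test_partition_exhaustive_and_disjoint():
    ts, hits, _ = _make_mixture(seed=5, p_cross=0.2, p_nohit=0.2)
    result = partition_pipeline(hits, ts, seed=5)
    assert set(result.assignments) == {t.id for t in ts}
    counts = {b: sum(1 for v in result.assignments.values() if v == b)
              for b in ("host", "symbiont", "specific")}
    assert sum(counts.values()) == len(ts)


def test_partition_no_cross_hits_no_classifier_provenance():
    ts, hits, _ = _make_mixture(seed=6, p_cross=0.0, p_nohit=0.3)
    result = partition_pipeline(hits, ts, seed=6)
    assert "classifier" not in set(result.provenance.values())


def test_partition_all_ambiguous_all_classifier():
    ts, hits, _ = _make_mixture(seed=8, p_cross=1.0, p_nohit=0.0)
    with pytest.warns(UserWarning, match="untrainable"):
        result = partition_pipeline(hits, ts, seed=8)
    assert set(result.provenance.values()) == {"classifier"}


def test_partition_order_invariance():
    ts, hits, _ = _make_mixture(seed=9, p_cross=0.15, p_nohit=0.2)
    r1 = partition_pipeline(hits, ts, seed=9)
    rng = np.random.default_rng(0)
    ts2 = list(ts)
    rng.shuffle(ts2)
    hits2 = list(hits)
    rng.shuffle(hits2)
    r2 = partition_pipeline(hits2, ts2, seed=9)
    assert r1.assignments == r2.assignments


# ---------------------------------------------------------------------------
# gc_profile
# ---------------------------------------------------------------------------

def test_gc_profile_modes_recover_targets():
    cfg = SimulationConfig(length_min=300, length_max=3000, seed=31)
    host = generate_transcriptome(HOST, 2000, cfg, seed=31)
    sym = generate_transcriptome(SYM, 2000, cfg, seed=32)
    assignments = {t.id: t.true_label for t in host + sym}
    prof = gc_profile(assignments, host + sym)
    assert abs(prof["host"]["mode"] - 0.43) <= 0.02
    assert abs(prof["symbiont"]["mode"] - 0.54) <= 0.02
    for h in prof.values():
        assert h["masses"].sum() == pytest.approx(1.0)


def test_gc_profile_single_transcript():
    t = Transcript(id="x", seq="AATT" + "GGCC")  # GC 0.5
    prof = gc_profile({"x": "host"}, [t])
    assert prof["host"]["mode"] == pytest.approx(0.505)
    assert (prof["host"]["masses"] > 0).sum() == 1


def test_gc_profile_unknown_assignment_rejected():
    with pytest.raises(ConsistencyError):
        gc_profile({"ghost": "host"}, _ts("T1"))
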