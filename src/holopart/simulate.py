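"""Synthetic holobiont data with known ground truth.

Real coral metatranscriptomes mix host transcripts (GC mode near 0.43)
with dinoflagellate symbiont transcripts (GC mode near 0.54).  This
module emulates that mixture — transcripts, paired reads, two-database
alignment hit tables with controllable cross-database leakage and no-hit
fractions, annotation tables and ortholog-group tables with a plantable
taxon-set partition — so every downstream stage can be exercised and
verified offline against the planted truth.

All generators are deterministic in their seed; one master seed derives a
per-stage seed as ``master + stage_index``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import AlignmentHit, Transcript

__all__ = [
    "CompositionModel",
    "SimulationConfig",
    "HOST_MODEL",
    "SYMBIONT_MODEL",
    "demo_config",
    "generate_transcriptome",
    "generate_reads",
    "generate_hit_table",
    "generate_annotation_tables",
    "generate_orthogroup_rows",
]

_STAGE = {"transcriptome": 0, "reads": 1, "hits": 2, "annotations": 3}


@dataclass
class CompositionModel:
    """Base-composition model for one origin.

    Order-0 by default: i.i.d. bases with P(G) = P(C) = gc_target / 2 and
    P(A) = P(T) = (1 - gc_target) / 2.  Only the GC signal matters for the
    downstream composition classifier, so no higher-order structure is
    emitted unless requested.
    """

    label: str
    gc_target: float
    kmer_order: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must lie strictly in (0, 1)")
        if self.kmer_order != 0:
            raise NotImplementedError("only order-0 emission is implemented")

    @property
    def base_probs(self) -> np.ndarray:
        g = self.gc_target / 2
        a = (1 - self.gc_target) / 2
        return np.array([a, g, g, a])  # A C G T


HOST_MODEL = CompositionModel(label="host", gc_target=0.43)
SYMBIONT_MODEL = CompositionModel(label="symbiont", gc_target=0.54)


@dataclass
class SimulationConfig:
    """Joint configuration for the synthetic holobiont.

    Hit-table semantics: with probability ``p_nohit`` a transcript emits
    no hits at all; otherwise it hits its own reference database with
    (conditional) probability ``p_hit_true`` and, independently, also
    the other database with probability ``p_hit_cross``.  ``p_nohit_host`` /
    ``p_nohit_symbiont`` override ``p_nohit`` per origin, which lets a
    run plant unequal host/symbiont bin fractions at equal transcript
    counts.  E-values are drawn with log10(e) uniform on ``evalue_law``.
    """

    n_host: int = 2000
    n_symbiont: int = 2000
    length_min: int = 300
    length_max: int = 3000
    length_log_mean: float = 6.9
    length_log_sd: float = 0.6
    p_hit_true: float = 1.0
    p_hit_cross: float = 0.0
    p_nohit: float = 0.0
    p_nohit_host: float | None = None
    p_nohit_symbiont: float | None = None
    evalue_log10_range: tuple[float, float] = (-50.0, -3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_host < 0 or self.n_symbiont < 0:
            raise ValueError("transcript counts must be >= 0")
        if not 1 <= self.length_min <= self.length_max:
            raise ValueError("invalid length bounds")
        probs = [self.p_hit_true, self.p_hit_cross, self.p_nohit]
        probs += [p for p in (self.p_nohit_host, self.p_nohit_symbiont)
                  if p is not None]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.evalue_log10_range
        if lo > hi:
            raise ValueError("evalue_log10_range must be (low, high)")

    def nohit_for(self, label: str) -> float:
        if label == "host" and self.p_nohit_host is not None:
            return self.p_nohit_host
        if label == "symbiont" and self.p_nohit_symbiont is not None:
            return self.p_nohit_symbiont
        return self.p_nohit

    def stage_seed(self, stage: str) -> int:
        return self.seed + _STAGE[stage]


#: Fig-style demo defaults: equal origin sizes, per-origin no-hit rates
#: planting overall bin fractions host 0.24 / symbiont 0.29 / no-hit 0.47.
def demo_config(seed: int = 7) -> SimulationConfig:
    # e-values at or below the most permissive examined cutoff (1e-4), so
    # hit presence and bin membership coincide and the planted fractions
    # are the bin fractions up to binomial sampling noise
    return SimulationConfig(
        n_host=2000, n_symbiont=2000,
        p_hit_true=1.0, p_hit_cross=0.12,
        p_nohit_host=0.52, p_nohit_symbiont=0.42,
        evalue_log10_range=(-50.0, -5.0),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _draw_lengths(rng: np.random.Generator, n: int,
                  cfg: SimulationConfig) -> np.ndarray:
    raw = rng.lognormal(mean=cfg.length_log_mean, sigma=cfg.length_log_sd,
                        size=n)
    return np.clip(raw.astype(int), cfg.length_min, cfg.length_max)


def generate_transcriptome(
    model: CompositionModel,
    n: int,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    id_prefix: str | None = None,
) -> list[Transcript]:
    """Generate ``n`` labelled transcripts from a composition model.

    Lengths follow the configured clipped log-normal; bases are i.i.d.
    with the model's GC target.  Identifiers are unique within a call
    (``<label>_<i>``) and the run is deterministic for a fixed seed.
    """
    cfg = cfg or SimulationConfig()
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(cfg.stage_seed("transcriptome")
                                if seed is None else seed)
    lengths = _draw_lengths(rng, n, cfg)
    prefix = id_prefix or model.label
    probs = model.base_probs
    out = []
    for i, L in enumerate(lengths):
        seq = "".join(_BASES[rng.choice(4, size=int(L), p=probs)])
        out.append(Transcript(id=f"{prefix}_{i}", seq=seq,
                              true_label=model.label))
    return out


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def generate_reads(
    transcripts: Sequence[Transcript],
    n_pairs_per_transcript: int = 10,
    read_len: int = 100,
    quality_mean: float = 36.0,
    quality_sd: float = 0.0,
    seed: int = 1,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Paired-end reads from random fragments of each transcript.

    Read 1 is the forward fragment prefix, read 2 the reverse complement
    of the fragment suffix.  Qualities are Gaussian around
    ``quality_mean`` (clipped to [2, 40]; sd 0 gives a constant quality
    string).  Transcripts shorter than ``read_len`` are skipped with a
    warning.  Output is Phred+33 FASTQ records, deterministic in seed.
    """
    rng = np.random.default_rng(seed)
    r1: list[SeqRecord] = []
    r2: list[SeqRecord] = []
    for t in transcripts:
        if len(t) < read_len:
            warnings.warn(f"transcript {t.id!r} shorter than read_len; skipped")
            continue
        for p in range(n_pairs_per_transcript):
            start = int(rng.integers(0, len(t) - read_len + 1))
            frag = t.seq[start:start + read_len]
            for mate, seq in ((1, frag),
                              (2, str(Seq(frag).reverse_complement()))):
                if quality_sd > 0:
                    q = np.clip(rng.normal(quality_mean, quality_sd,
                                           read_len), 2, 40)
                else:
                    q = np.full(read_len, quality_mean)
                rec = SeqRecord(Seq(seq), id=f"{t.id}_r{p}/{mate}",
                                description="")
                rec.letter_annotations["phred_quality"] = [
                    int(x) for x in q]
                (r1 if mate == 1 else r2).append(rec)
    return r1, r2


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

def _synthetic_hit(rng: np.random.Generator, query: Transcript,
                   db_label: str, n: int,
                   log_e_range: tuple[float, float] = (-50.0, -3.0),
                   ) -> AlignmentHit:
    log_e = rng.uniform(*log_e_range)
    aln_len = max(50, int(len(query) * rng.uniform(0.3, 1.0)))
    return AlignmentHit(
        query_id=query.id,
        subject_id=f"{db_label}_ref_{n}",
        db_label=db_label,
        pident=float(np.round(rng.uniform(75, 100), 3)),
        evalue=float(10.0 ** log_e),
        bitscore=float(np.round(-log_e * 4 + rng.uniform(40, 60), 1)),
        length=aln_len, mismatch=int(rng.integers(0, 10)),
        gapopen=int(rng.integers(0, 3)),
        qstart=1, qend=aln_len, sstart=1, send=aln_len,
    )


def generate_hit_table(
    transcripts: Sequence[Transcript],
    cfg: SimulationConfig,
) -> tuple[list[AlignmentHit], dict[str, str]]:
    """Emulated two-database alignment hits plus the ground-truth table.

    Every transcript must carry a true label.  See
    :class:`SimulationConfig` for the hit-emission semantics.
    """
    if any(t.true_label not in ("host", "symbiont") for t in transcripts):
        raise ValueError("every transcript needs a true host/symbiont label")
    rng = np.random.default_rng(cfg.stage_seed("hits"))
    hits: list[AlignmentHit] = []
    truth: dict[str, str] = {}
    counter = 0
    for t in transcripts:
        truth[t.id] = t.true_label
        own_db = "host_db" if t.true_label == "host" else "symbiont_db"
        other_db = "symbiont_db" if own_db == "host_db" else "host_db"
        # draws happen unconditionally to keep the stream aligned per
        # transcript regardless of branch outcomes
        u_mask, u_true, u_cross = rng.uniform(size=3)
        masked = u_mask < cfg.nohit_for(t.true_label)
        if masked:
            continue
        if u_true < cfg.p_hit_true:
            hits.append(_synthetic_hit(rng, t, own_db, counter,
                                       cfg.evalue_log10_range))
            counter += 1
        if u_cross < cfg.p_hit_cross:
            hits.append(_synthetic_hit(rng, t, other_db, counter,
                                       cfg.evalue_log10_range))
            counter += 1
    return hits, truth


# ---------------------------------------------------------------------------
# Annotation and ortholog-group tables
# ---------------------------------------------------------------------------

def generate_orthogroup_rows(
    ortho_spec: Mapping[tuple[str, ...] | frozenset, int],
    min_members: int = 3,
    seed: int = 3,
) -> list[tuple[str, str, str]]:
    """(group_id, taxon, member_id) rows planting an exact Venn partition.

    ``ortho_spec`` maps a taxon subset (tuple of taxon names) to the
    number of groups whose member taxa are exactly that subset.  Each
    group receives at least ``min_members`` members spread over its taxa,
    so the downstream >=3-member filter keeps every planted group and the
    taxon-subset partition recovers the requested counts exactly.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str]] = []
    gid = 0
    for subset, count in ortho_spec.items():
        if count < 0:
            raise ValueError("ortho_spec counts must be >= 0")
        taxa = sorted(subset)
        if not taxa:
            raise ValueError("ortho_spec subsets must be non-empty")
        for _ in range(count):
            group = f"OG{gid:05d}"
            gid += 1
            n_members = max(min_members, len(taxa))
            n_members += int(rng.integers(0, 3))
            # every taxon in the subset appears at least once
            assign = list(taxa) + [taxa[int(rng.integers(0, len(taxa)))]
                                   for _ in range(n_members - len(taxa))]
            for m, taxon in enumerate(assign):
                rows.append((group, taxon, f"{group}_{taxon}_m{m}"))
    return rows


def generate_annotation_tables(
    assignments: Mapping[str, str],
    pathways: Mapping[str, Mapping[str, str]] | None = None,
    n_go_terms: int = 20,
    n_pfam_domains: int = 30,
    terms_per_member: int = 2,
    enriched_go: Mapping[str, str] | None = None,
    seed: int = 3,
) -> dict[str, object]:
    """Plant KO / GO / PFAM annotation structure over partitioned bins.

    ``assignments`` maps transcript id -> bin (host|symbiont|specific).
    ``pathways`` maps pathway_id -> {ko_id: category} with category in
    {host, symbiont, both, specific, unrepresented}; transcripts from the
    matching bins are annotated with each KO so the planted
    per-pathway category is exactly recoverable downstream.
    ``enriched_go`` maps term -> focal bin; that term is attached to half
    the focal bin's members and to a 5 % background elsewhere.

    Returns dict with keys ``ko`` (transcript->KO pairs), ``go``,
    ``pfam`` (member->term pairs), each a list of tuples.
    """
    rng = np.random.default_rng(seed)
    by_bin: dict[str, list[str]] = {}
    for tid, b in assignments.items():
        by_bin.setdefault(b, []).append(tid)
    for b in by_bin:
        by_bin[b].sort()

    ko_pairs: list[tuple[str, str]] = []
    if pathways:
        for pw, kos in pathways.items():
            for ko, category in kos.items():
                if category == "unrepresented":
                    continue
                bins = {"both": ["host", "symbiont"]}.get(category, [category])
                for b in bins:
                    members = by_bin.get(b)
                    if not members:
                        raise ValueError(
                            f"cannot plant {ko} in empty bin {b!r}")
                    tid = members[int(rng.integers(0, len(members)))]
                    ko_pairs.append((tid, ko))

    all_ids = sorted(assignments)
    go_pairs: list[tuple[str, str]] = []
    terms = [f"GO:{i:07d}" for i in range(n_go_terms)]
    for tid in all_ids:
        for t in rng.choice(n_go_terms, size=terms_per_member, replace=False):
            go_pairs.append((tid, terms[int(t)]))
    if enriched_go:
        for term, focal in enriched_go.items():
            members = by_bin.get(focal, [])
            for tid in members[: len(members) // 2]:
                go_pairs.append((tid, term))
            for tid in all_ids:
                if assignments[tid] != focal and rng.uniform() < 0.05:
                    go_pairs.append((tid, term))

    pfam_pairs: list[tuple[str, str]] = []
    domains = [f"PF{i:05d}" for i in range(n_pfam_domains)]
    for tid in all_ids:
        for d in rng.choice(n_pfam_domains, size=terms_per_member,
                            replace=False):
            pfam_pairs.append((tid, domains[int(d)]))

    return {"ko": sorted(set(ko_pairs)), "go": sorted(set(go_pairs)),
            "pfam": sorted(set(pfam_pairs))}
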