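"""Read trimming and post-assembly filtering.

The stages mirror a standard short-read metatranscriptome workflow:
Trimmomatic-style quality trimming of paired reads, removal of transcripts
under 300 bp, extraction of the single longest ATG-to-stop open reading
frame per transcript (minimum 100 aa), and CD-HIT-style greedy redundancy
clustering of the peptides at 95 % identity.  Assembly summaries (N50,
GC fraction) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import Transcript

__all__ = [
    "TrimConfig",
    "FilterConfig",
    "Orf",
    "Cluster",
    "trim_read",
    "trim_pairs",
    "filter_length",
    "n50",
    "gc_fraction",
    "longest_orf",
    "greedy_cluster",
]


@dataclass
class TrimConfig:
    """Quality-trimming parameters (Trimmomatic conventions, Phred scale).

    Steps apply in the order HEADCROP -> LEADING -> TRAILING ->
    SLIDINGWINDOW -> MINLEN.  Reads must end up strictly longer than
    ``min_length`` to survive.
    """

    headcrop: int = 10
    end_quality: int = 30
    window_size: int = 4
    window_quality: int = 20
    min_length: int = 30

    def __post_init__(self) -> None:
        for name in ("headcrop", "end_quality", "window_size",
                     "window_quality", "min_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TrimConfig.{name} must be > 0")


@dataclass
class FilterConfig:
    """Post-assembly filtering parameters."""

    min_transcript_bp: int = 300
    min_orf_aa: int = 100
    cluster_identity: float = 0.95
    cluster_word_size: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.cluster_identity <= 1:
            raise ValueError("cluster_identity must be in (0, 1]")


@dataclass
class Orf:
    """An open reading frame located on a transcript.

    ``start``/``end`` are 1-based inclusive coordinates on the forward
    strand covering start codon through stop codon; the peptide excludes
    the stop.
    """

    parent_id: str
    strand: str
    frame: int
    start: int
    end: int
    peptide: str


@dataclass
class Cluster:
    """A greedy cluster: the founding representative plus all members."""

    representative: str
    members: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Read trimming
# ---------------------------------------------------------------------------

def trim_read(seq: str, quals: Sequence[int],
              cfg: TrimConfig | None = None) -> tuple[str, list[int]] | None:
    """Trim one read; return (seq, quals) or None if dropped.

    HEADCROP removes a fixed prefix; LEADING/TRAILING strip end bases with
    quality below ``end_quality``; SLIDINGWINDOW scans 5'->3' with a
    ``window_size`` window and cuts the read at the start of the first
    window whose mean quality falls below ``window_quality`` (windows
    shorter than ``window_size`` are not evaluated); MINLEN keeps only
    reads longer than ``min_length``.
    """
    cfg = cfg or TrimConfig()
    if len(seq) != len(quals):
        raise ValueError("sequence and quality lengths differ")
    # HEADCROP
    seq, quals = seq[cfg.headcrop:], list(quals[cfg.headcrop:])
    # LEADING
    while quals and quals[0] < cfg.end_quality:
        seq, quals = seq[1:], quals[1:]
    # TRAILING
    while quals and quals[-1] < cfg.end_quality:
        seq, quals = seq[:-1], quals[:-1]
    # SLIDINGWINDOW
    w = cfg.window_size
    for i in range(len(quals) - w + 1):
        if sum(quals[i:i + w]) / w < cfg.window_quality:
            seq, quals = seq[:i], quals[:i]
            break
    # MINLEN
    if len(seq) <= cfg.min_length:
        return None
    return seq, quals


def trim_pairs(records: Iterable[SeqRecord],
               cfg: TrimConfig | None = None) -> list[SeqRecord]:
    """Trim FASTQ records, dropping reads that fail the length filter."""
    cfg = cfg or TrimConfig()
    out: list[SeqRecord] = []
    for rec in records:
        quals = rec.letter_annotations["phred_quality"]
        result = trim_read(str(rec.seq), quals, cfg)
        if result is None:
            continue
        seq, q = result
        new = SeqRecord(Seq(seq), id=rec.id, description="")
        new.letter_annotations["phred_quality"] = q
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# Length filter and summary statistics
# ---------------------------------------------------------------------------

def filter_length(transcripts: Iterable[Transcript],
                  cfg: FilterConfig | None = None) -> list[Transcript]:
    """Keep transcripts of length >= ``min_transcript_bp``, order preserved."""
    cfg = cfg or FilterConfig()
    return [t for t in transcripts if len(t) >= cfg.min_transcript_bp]


def n50(lengths: Sequence[int]) -> int:
    """N50: the smallest length L with sum(lengths >= L) >= half the total."""
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if 2 * acc >= total:
            return x
    raise AssertionError("unreachable")


def gc_fraction(seq: str) -> float | None:
    """(G+C) / unambiguous bases, case-insensitive; None if no A/C/G/T."""
    if not seq:
        raise ValueError("gc_fraction of an empty sequence is undefined")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    if denom == 0:
        return None
    return gc / denom


# ---------------------------------------------------------------------------
# ORF extraction
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _scan_frame(seq: str, frame: int, min_aa: int):
    """Yield (start_nt, end_nt) 0-based half-open ATG..stop ORFs in a frame."""
    n = len(seq)
    i = frame
    while i + 3 <= n:
        if seq[i:i + 3] == "ATG":
            j = i + 3
            while j + 3 <= n:
                if seq[j:j + 3] in _STOPS:
                    aa_len = (j - i) // 3
                    if aa_len >= min_aa:
                        yield i, j + 3
                    break
                j += 3
            # restart after this start codon; nested ATGs give shorter ORFs
            # within the same stop, so skipping to the stop would be wrong
            # only for overlapping frames -- we advance past this ATG.
        i += 3


def longest_orf(transcript: Transcript,
                cfg: FilterConfig | None = None) -> Orf | None:
    """Longest ATG-to-stop ORF (>= ``min_orf_aa`` aa incl. M) over 6 frames.

    Ties break toward the forward strand, then lower frame, then leftmost
    start.  Returns None when no frame holds a qualifying ORF; partial
    (start- or stop-less) coding regions are not considered.
    """
    cfg = cfg or FilterConfig()
    seq = transcript.seq.upper()
    n = len(seq)
    rc = str(Seq(seq).reverse_complement())
    best: tuple | None = None  # (-nt_len, strand_rank, frame, start)
    best_orf: Orf | None = None
    for strand_rank, (strand, s) in enumerate((("+", seq), ("-", rc))):
        for frame in range(3):
            for a, b in _scan_frame(s, frame, cfg.min_orf_aa):
                if strand == "+":
                    start, end = a + 1, b
                else:
                    # map [a, b) on the reverse complement to forward coords
                    start, end = n - b + 1, n - a
                key = (-(b - a), strand_rank, frame, start)
                if best is None or key < best:
                    peptide = str(Seq(s[a:b - 3]).translate())
                    best = key
                    best_orf = Orf(parent_id=transcript.id, strand=strand,
                                   frame=frame, start=start, end=end,
                                   peptide=peptide)
    return best_orf


# ---------------------------------------------------------------------------
# Greedy redundancy clustering
# ---------------------------------------------------------------------------

def _lcs_len(a: str, b: str) -> int:
    """Length of the longest common subsequence = max matches under a
    global alignment with free gaps and zero mismatch credit."""
    if len(a) < len(b):
        a, b = b, a
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        ap = cur.append
        p = prev
        for j, cb in enumerate(b):
            ap(p[j] + 1 if ca == cb else max(cur[j], p[j + 1]))
        prev = cur
    return prev[-1]


def _identity(a: str, b: str) -> float:
    """Exact matches over the shorter sequence length (CD-HIT convention)."""
    return _lcs_len(a, b) / min(len(a), len(b))


def _words(seq: str, w: int) -> set[str]:
    return {seq[i:i + w] for i in range(len(seq) - w + 1)}


def _word_filter_applicable(short_len: int, threshold: float, w: int) -> bool:
    """True when identity >= threshold forces a shared word of size w.

    With m = ceil(threshold * L) required matches over the shorter length
    L, matched runs shorter than w can contribute at most (w-1) matches
    each, and there are at most L - m + 1 runs; when m exceeds that bound
    a run of length >= w (a shared contiguous word) must exist, so a pair
    with no shared word cannot reach the threshold and may be skipped.
    """
    import math
    m = math.ceil(threshold * short_len)
    return m > (short_len - m + 1) * (w - 1)


def greedy_cluster(peptides: dict[str, str] | Sequence[tuple[str, str]],
                   cfg: FilterConfig | None = None,
                   use_word_filter: bool = True) -> list[Cluster]:
    """CD-HIT-style greedy incremental clustering.

    Peptides are sorted by decreasing length (ties by input order); each
    joins the first existing cluster whose representative shares at least
    ``cluster_identity`` identity (matches / shorter length), otherwise it
    founds a new cluster.  The ``cluster_word_size`` shared-word prefilter
    is applied only where it provably cannot change the result.
    """
    cfg = cfg or FilterConfig()
    items = list(peptides.items()) if isinstance(peptides, dict) else list(peptides)
    if not items:
        raise ValueError("greedy_cluster requires at least one peptide")
    order = sorted(range(len(items)), key=lambda i: (-len(items[i][1]), i))
    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    rep_words: list[set[str]] = []
    w = cfg.cluster_word_size
    for idx in order:
        pid, seq = items[idx]
        placed = False
        words = _words(seq, w) if use_word_filter else set()
        for ci, cluster in enumerate(clusters):
            rep = rep_seqs[ci]
            short_len = min(len(seq), len(rep))
            if (use_word_filter
                    and _word_filter_applicable(short_len, cfg.cluster_identity, w)
                    and not (words & rep_words[ci])):
                continue
            if _identity(seq, rep) >= cfg.cluster_identity:
                cluster.members.append(pid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=pid, members=[pid]))
            rep_seqs.append(seq)
            rep_words.append(_words(seq, w) if use_word_filter else set())
    return clusters
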