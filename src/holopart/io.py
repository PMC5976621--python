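"""Readers and writers for the file formats the pipeline touches.

Everything is plain text: FASTA (60-column wrapped), FASTQ (Phred+33),
BLAST tabular hits (outfmt-6 columns plus a trailing ``db_label`` column),
two-column mapping tables (member, term) and three-column ortholog-group
tables (group, taxon, member).  Readers validate and reject malformed input
rather than silently coercing it; every writer's output round-trips through
its reader.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Transcript",
    "AlignmentHit",
    "FormatError",
    "HIT_COLUMNS",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_hits",
    "write_hits",
    "read_mapping",
    "write_mapping",
    "read_orthogroups",
    "write_orthogroups",
    "read_truth",
    "write_truth",
]

# IUPAC nucleotide codes, upper- and lower-case accepted.
_NUC_ALPHABET = set("ACGTUNRYSWKMBDHVacgtunryswkmbdhv")

#: outfmt-6 column order plus the database label the pipeline adds.
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "db_label",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Transcript:
    """A nucleotide sequence record.

    ``true_label`` is populated only for synthetic data, where the
    generating origin (``host`` or ``symbiont``) is known.
    """

    id: str
    seq: str
    true_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("transcript id must be non-empty")
        if not self.seq:
            raise FormatError(f"transcript {self.id!r} has an empty sequence")
        bad = set(self.seq) - _NUC_ALPHABET
        if bad:
            raise FormatError(
                f"transcript {self.id!r} contains non-nucleotide "
                f"characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentHit:
    """One row of a tabular alignment result.

    Coordinate and count columns are carried opaquely; the pipeline only
    interprets ``query_id``, ``db_label``, ``evalue`` and ``bitscore``.
    """

    query_id: str
    subject_id: str
    db_label: str
    pident: float
    evalue: float
    bitscore: float
    length: int = 0
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"negative e-value for query {self.query_id!r}")
        if not 0.0 <= self.pident <= 100.0:
            raise FormatError(
                f"pident {self.pident} out of [0, 100] for query {self.query_id!r}"
            )


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a FASTA file into :class:`Transcript` records.

    The record id is the token before the first whitespace in the header,
    matching BLAST's query-id convention.  Duplicate ids and empty
    sequences are format errors.
    """
    records: list[Transcript] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(Transcript(id=rec.id, seq=str(rec.seq)))
    return records


def write_fasta(records: Iterable[Transcript], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA."""
    seqrecs = (
        SeqRecord(Seq(t.seq), id=t.id, description="") for t in records
    )
    with _open_text(path, "wt") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read Phred+33 FASTQ into Biopython records (qualities attached)."""
    with _open_text(path) as fh:
        return list(SeqIO.parse(fh, "fastq"))


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# Alignment hit tables
# ---------------------------------------------------------------------------

def read_hits(
    path: str | Path,
    expected_dbs: Sequence[str] = ("host_db", "symbiont_db"),
) -> list[AlignmentHit]:
    """Read a 13-column tab-separated hit table (outfmt-6 + db_label).

    E-values in scientific notation (``1e-180``) parse as floats.  A
    db_label outside ``expected_dbs`` or a non-numeric e-value is a
    format error.  An empty file yields an empty list.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, header=None,
                         dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        return []
    if df.isnull().any().any():
        raise FormatError(f"{path}: expected 13 tab-separated columns")
    bad_db = set(df["db_label"]) - set(expected_dbs)
    if bad_db:
        raise FormatError(f"{path}: unknown db_label(s) {sorted(bad_db)}")
    hits: list[AlignmentHit] = []
    for row in df.itertuples(index=False):
        try:
            evalue = float(row.evalue)
            pident = float(row.pident)
            bitscore = float(row.bitscore)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric field in row "
                              f"{row.qseqid!r}: {exc}") from exc
        hits.append(AlignmentHit(
            query_id=row.qseqid, subject_id=row.sseqid, db_label=row.db_label,
            pident=pident, evalue=evalue, bitscore=bitscore,
            length=int(row.length), mismatch=int(row.mismatch),
            gapopen=int(row.gapopen), qstart=int(row.qstart),
            qend=int(row.qend), sstart=int(row.sstart), send=int(row.send),
        ))
    return hits


def write_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for h in hits:
            fh.write("\t".join(str(v) for v in (
                h.query_id, h.subject_id, f"{h.pident:.3f}", h.length,
                h.mismatch, h.gapopen, h.qstart, h.qend, h.sstart, h.send,
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}", h.db_label,
            )) + "\n")


# ---------------------------------------------------------------------------
# Mapping tables (member -> term)
# ---------------------------------------------------------------------------

def read_mapping(path: str | Path) -> pd.DataFrame:
    """Read a two-column TSV of (member_id, term_id) pairs.

    Duplicate pairs are collapsed so the loaded table holds each
    (member, term) association once.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", names=["member_id", "term_id"],
                         header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["member_id", "term_id"], dtype=str)
    if df.isnull().any().any():
        raise FormatError(f"{path}: expected 2 tab-separated columns")
    return df.drop_duplicates(ignore_index=True)


def write_mapping(pairs: pd.DataFrame | Iterable[tuple[str, str]],
                  path: str | Path) -> None:
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.DataFrame(list(pairs), columns=["member_id", "term_id"])
    pairs.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Ortholog-group tables
# ---------------------------------------------------------------------------

def read_orthogroups(path: str | Path):
    """Read a three-column TSV (group_id, taxon, member_id).

    Returns an :class:`~holopart.orthogroups.OrthoGroupTable`.  A member
    listed twice within the same group is a format error.
    """
    from .orthogroups import OrthoGroupTable

    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t",
                         names=["group_id", "taxon", "member_id"],
                         header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return OrthoGroupTable.from_rows([])
    if df.isnull().any().any():
        raise FormatError(f"{path}: expected 3 tab-separated columns")
    dup = df.duplicated(subset=["group_id", "member_id"])
    if dup.any():
        first = df[dup].iloc[0]
        raise FormatError(
            f"{path}: member {first.member_id!r} listed twice in group "
            f"{first.group_id!r}"
        )
    return OrthoGroupTable.from_rows(df.itertuples(index=False))


def write_orthogroups(rows: Iterable[tuple[str, str, str]],
                      path: str | Path) -> None:
    """Write (group_id, taxon, member_id) rows as TSV."""
    with _open_text(path, "wt") as fh:
        for group_id, taxon, member_id in rows:
            fh.write(f"{group_id}\t{taxon}\t{member_id}\n")


# ---------------------------------------------------------------------------
# Ground-truth tables (synthetic data only)
# ---------------------------------------------------------------------------

def read_truth(path: str | Path) -> dict[str, str]:
    """Read a (transcript_id, true_label) TSV into a dict."""
    try:
        df = pd.read_csv(path, sep="\t", names=["transcript_id", "true_label"],
                         header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    if df["transcript_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate transcript id in truth table")
    return dict(zip(df["transcript_id"], df["true_label"]))


def write_truth(labels: dict[str, str], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for tid, label in labels.items():
            fh.write(f"{tid}\t{label}\n")
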