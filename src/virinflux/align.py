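"""Sequence/alignment I/O and a minimal ungapped local aligner.

Alignment interchange uses the 12-column tabular dialect (query, subject,
percent identity, alignment length, mismatches, gap opens, qstart, qend,
sstart, send, evalue, bitscore) with 1-based inclusive coordinates; a
subject start greater than the subject end encodes a minus-strand hit.
All internal pipeline arithmetic converts to 0-based half-open.

The built-in aligner (exact 11-mer seeds, ungapped extension, match +1 /
mismatch -2) exists so that synthetic data can be processed end to end;
externally produced tabular alignments are ingested through the same
record type and the pipeline treats both identically.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VIRUS = "virus"
CONTIG = "contig"
TRANSCRIPT = "transcript"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class AlignmentParseError(ValueError):
    """Raised for malformed tabular alignment rows; names the line."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment of a read against a subject sequence.

    Read and subject coordinates are 1-based inclusive; ``subject_start >
    subject_end`` encodes a minus-strand alignment (read coordinates are
    always forward).
    """

    read_id: str
    mate: int
    subject_id: str
    subject_kind: str
    read_start: int
    read_end: int
    subject_start: int
    subject_end: int
    score: float
    identity: float
    aln_length: int

    def __post_init__(self) -> None:
        if not (1 <= self.read_start <= self.read_end):
            raise ValueError(
                f"invalid read interval [{self.read_start}, {self.read_end}]"
            )
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if not (0.0 < self.identity <= 100.0):
            raise ValueError("identity must be in (0, 100]")

    @property
    def is_minus(self) -> bool:
        return self.subject_start > self.subject_end

    @property
    def strand(self) -> str:
        return "-" if self.is_minus else "+"

    @property
    def subject_lo(self) -> int:
        """Leftmost subject coordinate (1-based)."""
        return min(self.subject_start, self.subject_end)

    @property
    def subject_hi(self) -> int:
        return max(self.subject_start, self.subject_end)

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start + 1

    def subject_pos_at(self, read_pos: int) -> int:
        """Subject coordinate (1-based) aligned with ``read_pos`` (1-based)."""
        d = read_pos - self.read_start
        return self.subject_start - d if self.is_minus else self.subject_start + d


def _open_text(path_or_stream, mode: str = "rt"):
    if hasattr(path_or_stream, "read") or hasattr(path_or_stream, "write"):
        return path_or_stream, False
    path = str(path_or_stream)
    if path.endswith(".gz"):
        return gzip.open(path, mode), True
    return open(path, mode), True


def split_mate(query_id: str) -> tuple[str, int]:
    """Split a '/1' or '/2' mate suffix off a query identifier."""
    if query_id.endswith("/1") or query_id.endswith("/2"):
        return query_id[:-2], int(query_id[-1])
    return query_id, 1


def parse_tabular_alignments(
    source, subject_kind: str = CONTIG
) -> list[AlignmentRecord]:
    """Parse 12-column tabular alignments into :class:`AlignmentRecord`.

    Minus strand is inferred from sstart > send. Malformed rows raise
    :class:`AlignmentParseError` naming the offending line number.
    """
    stream, own = _open_text(source)
    records: list[AlignmentRecord] = []
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise AlignmentParseError(
                    f"line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                identity = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                score = float(fields[11])
            except ValueError as exc:
                raise AlignmentParseError(
                    f"line {lineno}: non-numeric field ({exc})"
                ) from None
            if qend < qstart:
                raise AlignmentParseError(
                    f"line {lineno}: qend < qstart ({qend} < {qstart})"
                )
            read_id, mate = split_mate(fields[0])
            records.append(
                AlignmentRecord(
                    read_id=read_id,
                    mate=mate,
                    subject_id=fields[1],
                    subject_kind=subject_kind,
                    read_start=qstart,
                    read_end=qend,
                    subject_start=sstart,
                    subject_end=send,
                    score=score,
                    identity=identity,
                    aln_length=length,
                )
            )
    finally:
        if own:
            stream.close()
    return records


def write_tabular_alignments(records: Iterable[AlignmentRecord], dest) -> None:
    """Write records in the 12-column tabular dialect (round-trips parse)."""
    stream, own = _open_text(dest, "wt")
    try:
        for r in records:
            mismatches = round(r.aln_length * (1.0 - r.identity / 100.0))
            stream.write(
                "\t".join(
                    [
                        f"{r.read_id}/{r.mate}",
                        r.subject_id,
                        f"{r.identity:.2f}",
                        str(r.aln_length),
                        str(mismatches),
                        "0",
                        str(r.read_start),
                        str(r.read_end),
                        str(r.subject_start),
                        str(r.subject_end),
                        "0.0",
                        f"{r.score:g}",
                    ]
                )
                + "\n"
            )
    finally:
        if own:
            stream.close()


def read_fasta(source) -> dict[str, str]:
    stream, own = _open_text(source)
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(stream, "fasta")}
    finally:
        if own:
            stream.close()


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], dest) -> None:
    stream, own = _open_text(dest, "wt")
    items = seqs.items() if isinstance(seqs, dict) else seqs
    try:
        SeqIO.write(
            (SeqRecord(Seq(s), id=name, description="") for name, s in items),
            stream,
            "fasta",
        )
    finally:
        if own:
            stream.close()


def read_fastq(source) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality string) triples."""
    stream, own = _open_text(source)
    try:
        for title, seq, qual in SeqIO.QualityIO.FastqGeneralIterator(stream):
            yield title.split()[0], seq.upper(), qual
    finally:
        if own:
            stream.close()


def write_fastq(reads: Iterable[tuple[str, str, str]], dest) -> None:
    stream, own = _open_text(dest, "wt")
    try:
        for name, seq, qual in reads:
            stream.write(f"@{name}\n{seq}\n+\n{qual}\n")
    finally:
        if own:
            stream.close()


class KmerIndex:
    """Exact k-mer position index over one subject sequence."""

    def __init__(self, subject: str, k: int = 11):
        if not subject:
            raise ValueError("empty subject sequence")
        self.subject = subject
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(subject) - k + 1):
            index.setdefault(subject[i : i + k], []).append(i)
        self.index = index

    def positions(self, kmer: str) -> list[int]:
        return self.index.get(kmer, ())


def _max_segments(
    matches: np.ndarray, match: int, mismatch: int, min_len: int
) -> list[tuple[int, int, int]]:
    """All disjoint maximal-scoring segments (start, end-exclusive, score).

    Kadane-style scan under the +match/-|mismatch| scheme, iterated on the
    remainder after removing each maximal segment.
    """
    scores = np.where(matches, match, mismatch).astype(np.int64)
    segments: list[tuple[int, int, int]] = []
    stack = [(0, len(scores))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < min_len:
            continue
        best = cur = 0
        best_s = best_e = cur_s = lo
        for i in range(lo, hi):
            if cur <= 0:
                cur = 0
                cur_s = i
            cur += scores[i]
            if cur > best:
                best, best_s, best_e = cur, cur_s, i + 1
        if best <= 0 or best_e - best_s < min_len:
            continue
        segments.append((best_s, best_e, int(best)))
        stack.append((lo, best_s))
        stack.append((best_e, hi))
    return segments


def local_align(
    read: str,
    subject: str,
    min_len: int = 28,
    *,
    read_id: str = "read",
    mate: int = 1,
    subject_id: str = "subject",
    subject_kind: str = VIRUS,
    seed_len: int = 11,
    match: int = 1,
    mismatch: int = -2,
    min_identity: float = 90.0,
    index: Optional[KmerIndex] = None,
    rc_index: Optional[KmerIndex] = None,
) -> list[AlignmentRecord]:
    """Ungapped local alignments of ``read`` against both strands of ``subject``.

    Exact ``seed_len``-mer seeds anchor candidate diagonals; each diagonal's
    maximal-scoring ungapped segments of length >= ``min_len`` and identity
    >= ``min_identity`` are reported, ordered by (score desc, subject start
    asc, strand).
    """
    if min_len < seed_len:
        raise ValueError(f"min_len must be >= seed length ({seed_len})")
    if not read or not subject:
        raise ValueError("empty sequence")

    results: list[AlignmentRecord] = []
    slen = len(subject)
    for strand, subj, idx in (
        ("+", subject, index),
        ("-", revcomp(subject), rc_index),
    ):
        if idx is None:
            idx = KmerIndex(subj, seed_len)
        diagonals: set[int] = set()
        for i in range(0, len(read) - seed_len + 1):
            for pos in idx.positions(read[i : i + seed_len]):
                diagonals.add(pos - i)
        for diag in diagonals:
            r_lo = max(0, -diag)
            r_hi = min(len(read), slen - diag)
            if r_hi - r_lo < min_len:
                continue
            rseg = read[r_lo:r_hi]
            sseg = subj[r_lo + diag : r_hi + diag]
            matches = np.frombuffer(rseg.encode(), dtype=np.uint8) == np.frombuffer(
                sseg.encode(), dtype=np.uint8
            )
            for seg_s, seg_e, score in _max_segments(matches, match, mismatch, min_len):
                length = seg_e - seg_s
                n_match = int(matches[seg_s:seg_e].sum())
                identity = 100.0 * n_match / length
                if identity < min_identity:
                    continue
                q_s = r_lo + seg_s  # 0-based on read
                s_s = q_s + diag  # 0-based on strand-oriented subject
                if strand == "+":
                    sstart, send = s_s + 1, s_s + length
                else:
                    sstart = slen - s_s
                    send = slen - (s_s + length) + 1
                results.append(
                    AlignmentRecord(
                        read_id=read_id,
                        mate=mate,
                        subject_id=subject_id,
                        subject_kind=subject_kind,
                        read_start=q_s + 1,
                        read_end=q_s + length,
                        subject_start=sstart,
                        subject_end=send,
                        score=float(score),
                        identity=identity,
                        aln_length=length,
                    )
                )
    results.sort(key=lambda r: (-r.score, r.subject_lo, r.strand, r.read_start))
    return results


def select_best_hit(
    records: Sequence[AlignmentRecord],
    kind: str,
    rng: np.random.Generator,
) -> Optional[AlignmentRecord]:
    """Best-scoring alignment of one read against one subject kind.

    Exact score ties are broken by a seeded uniform draw. Selection is done
    independently per subject kind (contigs vs transcripts), so callers pass
    pre-partitioned pools.
    """
    if not records:
        return None
    key = (records[0].read_id, records[0].mate)
    for r in records:
        if r.subject_kind != kind:
            raise ValueError(
                f"mixed subject kinds: expected {kind!r}, got {r.subject_kind!r}"
            )
        if (r.read_id, r.mate) != key:
            raise ValueError("records from different reads in one call")
    best = max(r.score for r in records)
    ties = [r for r in records if r.score == best]
    if len(ties) == 1:
        return ties[0]
    return ties[int(rng.integers(len(ties)))]
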