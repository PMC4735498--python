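"""Chimeric-read detection: host-virus junction evidence and filtering.

A read is accepted as an intra-read junction when it aligns to the viral
genome *only* over >= 16 bp, to a host reference *only* over >= 16 bp, the
two alignments together cover >= 95 read bases (130 for 151-bp reads), and
the signed overlap between the alignments lies in [-2, 20] (negative
values are untemplated bases between the alignments). Junctions falling
between the two mates of a pair are accepted when one mate is virus-only
and the other host-only, each over the same total-length threshold.

Host references are then vetted: assembled contigs must be corroborated by
transcript evidence, transcripts sharing a chimeric read with a retained
contig are redundant and dropped, and any reference supported by fewer
than three chimeric reads or by less than 75 bp of cumulative chimeric
alignment is discarded. Filtering iterates to a fixed point. PCR/optical
duplicates (identical outer fragment coordinates) and junctions sequenced
by both overlapping mates of one pair are collapsed, but the raw count is
kept, since the per-genome frequency estimator needs it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .align import CONTIG, TRANSCRIPT, VIRUS, AlignmentRecord

INTRA_READ = "intra_read"
INTER_READ = "inter_read"

#: total aligned read bases required, by read length
MIN_TOTAL = {101: 95, 151: 130}
MIN_EXCLUSIVE = 16
OVERLAP_RANGE = (-2, 20)


@dataclass(frozen=True)
class JunctionEvidence:
    """One chimeric read (or mate pair) supporting a host-virus junction."""

    read_id: str
    mate: int
    library_id: str
    kind: str  # intra_read | inter_read
    virus_aln: AlignmentRecord
    host_aln: AlignmentRecord
    host_only_len: int
    virus_only_len: int
    overlap_len: int
    read_length: int
    # junction identity (intra-read only; None for inter-read evidence)
    offset: Optional[int] = None
    virus_strand: str = "+"
    host_strand: str = "+"
    virus_position: Optional[int] = None  # 0-based on the reference
    contig_position: Optional[int] = None  # 0-based on the host reference
    side: Optional[str] = None  # left: read continues into the contig rightward
    # outer fragment coordinates for duplicate removal
    pair_id: Optional[str] = None
    virus_outer: Optional[int] = None
    host_outer: Optional[int] = None

    @property
    def host_id(self) -> str:
        return self.host_aln.subject_id


def _junction_geometry(
    virus: AlignmentRecord, host: AlignmentRecord, genome_length: Optional[int]
) -> dict:
    """Offset, strands, breakpoints and side for an intra-read junction.

    The offset is the strand-aware difference between virus and host
    coordinates aligned to the same read base; it is invariant across all
    reads covering the same junction and therefore identifies it.
    """
    v_sign = -1 if virus.is_minus else 1
    h_sign = -1 if host.is_minus else 1

    def vpos(p: int) -> int:
        return virus.subject_start + v_sign * (p - virus.read_start)

    def hpos(p: int) -> int:
        return host.subject_start + h_sign * (p - host.read_start)

    if host.is_minus:
        offset = vpos(0) + hpos(0)
    else:
        offset = vpos(0) - hpos(0)

    virus_first = virus.read_start <= host.read_start
    # junction read position: first base of the downstream alignment
    jp = host.read_start if virus_first else virus.read_start
    virus_bp = vpos(jp)
    host_bp = hpos(jp)
    if genome_length:
        virus_bp = (virus_bp - 1) % genome_length + 1
    # side: does the read continue into the contig toward higher contig
    # coordinates (left end of the inserted fragment) or lower (right end)?
    into_contig_right = (virus_first and not host.is_minus) or (
        not virus_first and host.is_minus
    )
    return {
        "offset": offset,
        "virus_strand": virus.strand,
        "host_strand": host.strand,
        "virus_position": virus_bp - 1,  # 0-based
        "contig_position": host_bp - 1,
        "side": "left" if into_contig_right else "right",
    }


def classify_intra_read(
    virus_best: AlignmentRecord,
    host_best: AlignmentRecord,
    read_length: int,
    *,
    library_id: str = "lib0",
    min_exclusive: int = MIN_EXCLUSIVE,
    min_total: Optional[int] = None,
    overlap_range: tuple[int, int] = OVERLAP_RANGE,
    genome_length: Optional[int] = None,
) -> tuple[Optional[JunctionEvidence], Optional[str]]:
    """Apply the intra-read junction criteria to one read's best alignments.

    Returns ``(evidence, None)`` on acceptance or ``(None, reason)`` naming
    the first failed criterion.
    """
    if (virus_best.read_id, virus_best.mate) != (host_best.read_id, host_best.mate):
        raise ValueError("virus and host alignments belong to different reads")
    if min_total is None:
        try:
            min_total = MIN_TOTAL[read_length]
        except KeyError:
            raise ValueError(
                f"no default total-alignment threshold for read length "
                f"{read_length}; pass min_total"
            ) from None

    v_len = virus_best.read_span
    h_len = host_best.read_span
    if virus_best.read_start <= host_best.read_start:
        overlap = virus_best.read_end - host_best.read_start + 1
    else:
        overlap = host_best.read_end - virus_best.read_start + 1
    virus_only = v_len - max(overlap, 0)
    host_only = h_len - max(overlap, 0)
    total = virus_only + host_only + overlap

    if virus_only < min_exclusive:
        return None, f"virus-only alignment {virus_only} < {min_exclusive}"
    if host_only < min_exclusive:
        return None, f"host-only alignment {host_only} < {min_exclusive}"
    if total < min_total:
        return None, f"total aligned {total} < {min_total}"
    if not (overlap_range[0] <= overlap <= overlap_range[1]):
        return None, f"overlap {overlap} outside {overlap_range}"

    geom = _junction_geometry(virus_best, host_best, genome_length)
    return (
        JunctionEvidence(
            read_id=virus_best.read_id,
            mate=virus_best.mate,
            library_id=library_id,
            kind=INTRA_READ,
            virus_aln=virus_best,
            host_aln=host_best,
            host_only_len=host_only,
            virus_only_len=virus_only,
            overlap_len=overlap,
            read_length=read_length,
            **geom,
        ),
        None,
    )


def classify_inter_read(
    mate1: dict[str, Optional[AlignmentRecord]],
    mate2: dict[str, Optional[AlignmentRecord]],
    read_length: int,
    *,
    library_id: str = "lib0",
    min_total: Optional[int] = None,
) -> tuple[Optional[JunctionEvidence], Optional[str]]:
    """Junctions falling between the two mates of a pair.

    Each mate's dict maps 'virus' / 'host' to its best alignment (or None:
    no alignment survived best-hit selection at the reporting threshold).
    One mate must be virus-only over >= the total threshold, the other
    host-only over the same threshold.
    """
    if min_total is None:
        min_total = MIN_TOTAL.get(read_length, None)
        if min_total is None:
            raise ValueError(f"no default threshold for read length {read_length}")

    def role(m: dict[str, Optional[AlignmentRecord]]) -> Optional[str]:
        v, h = m.get(VIRUS), m.get("host")
        if v is not None and h is None and v.read_span >= min_total:
            return VIRUS
        if h is not None and v is None and h.read_span >= min_total:
            return "host"
        return None

    r1, r2 = role(mate1), role(mate2)
    if {r1, r2} != {VIRUS, "host"}:
        return None, "mate roles not virus-only + host-only"
    vm = mate1 if r1 == VIRUS else mate2
    hm = mate2 if r1 == VIRUS else mate1
    v, h = vm[VIRUS], hm["host"]
    return (
        JunctionEvidence(
            read_id=v.read_id,
            mate=0,
            library_id=library_id,
            kind=INTER_READ,
            virus_aln=v,
            host_aln=h,
            host_only_len=h.read_span,
            virus_only_len=v.read_span,
            overlap_len=0,
            read_length=read_length,
            offset=None,
            virus_strand=v.strand,
            host_strand=h.strand,
            virus_position=None,
            contig_position=None,
            side=None,
            pair_id=v.read_id,
        ),
        None,
    )


@dataclass
class ContigSupport:
    contig_id: str
    n_chimeric_reads: int = 0
    cumulative_aln_len: int = 0
    corroborated: bool = False
    shares_read_with_contig: bool = False


def filter_host_references(
    evidence: Sequence[JunctionEvidence],
    corroborated: Optional[set[str]] = None,
    *,
    min_reads: int = 3,
    min_cumulative: int = 75,
    fixed_point: bool = True,
) -> tuple[set[str], list[JunctionEvidence]]:
    """Retain host references passing the support and redundancy rules.

    ``corroborated`` holds the ids of assembled contigs independently
    supported by transcript similarity (or a mate aligning to a
    transcript); transcripts corroborate themselves. Returns the retained
    reference ids and the evidence restricted to them.
    """
    corroborated = corroborated or set()
    current = list(evidence)
    while True:
        by_ref: dict[str, list[JunctionEvidence]] = {}
        for ev in current:
            by_ref.setdefault(ev.host_id, []).append(ev)

        retained: set[str] = set()
        for ref, evs in by_ref.items():
            kind = evs[0].host_aln.subject_kind
            if kind == CONTIG and ref not in corroborated:
                continue
            if len(evs) < min_reads:
                continue
            if sum(e.host_aln.read_span for e in evs) < min_cumulative:
                continue
            retained.add(ref)

        # transcripts sharing >= 1 chimeric read with a retained contig are
        # redundant candidates for the same insertion
        reads_on_contigs = {
            (e.read_id, e.mate)
            for e in current
            if e.host_aln.subject_kind == CONTIG and e.host_id in retained
        }
        drop = {
            e.host_id
            for e in current
            if e.host_aln.subject_kind == TRANSCRIPT
            and e.host_id in retained
            and (e.read_id, e.mate) in reads_on_contigs
        }
        retained -= drop
        filtered = [e for e in current if e.host_id in retained]
        if not fixed_point or len(filtered) == len(current):
            return retained, filtered
        current = filtered


def remove_duplicates(
    evidence: Sequence[JunctionEvidence],
) -> tuple[list[JunctionEvidence], int, int]:
    """Collapse technical duplicates of junction evidence.

    Two kinds are collapsed: (i) a junction sequenced by both overlapping
    mates of one pair (same pair, same junction identity) and (ii) PCR
    duplicates -- evidence whose fragments share identical outer
    coordinates on both the virus genome and the host reference. Returns
    (deduplicated evidence, number of duplicates removed, raw count).
    """
    raw = len(evidence)
    seen: set[tuple] = set()
    kept: list[JunctionEvidence] = []
    for ev in evidence:
        jkey = (ev.library_id, ev.host_id, ev.offset, ev.virus_strand, ev.host_strand)
        keys = [("pair", ev.pair_id or (ev.read_id,), jkey)]
        if ev.virus_outer is not None and ev.host_outer is not None:
            keys.append(("frag", ev.virus_outer, ev.host_outer, jkey))
        if any(k in seen for k in keys):
            continue
        seen.update(keys)
        kept.append(ev)
    return kept, raw - len(kept), raw
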