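"""End-to-end junction detection on a simulated (or in-memory) population.

Reads are streamed in pairs. Each read is first tested for a full-length
exact match to the circular viral reference through a seed-and-verify
k-mer lookup; such reads are viral and cannot be chimeric, which keeps the
hot path at a dictionary probe per read. Reads failing the exact test go
through the ungapped local aligner against the viral genome and every host
reference, best hits are selected per subject kind, and the intra-read /
inter-read junction criteria are applied. Reference filtering, duplicate
removal, junction collapsing and the per-library frequency estimate follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import chimera
from .align import CONTIG, VIRUS, AlignmentRecord, KmerIndex, local_align, revcomp, select_best_hit
from .chimera import INTRA_READ, JunctionEvidence
from .frequency import LibraryStats
from .junctions import Junction, collapse_junctions
from .synth import Population, ReadPair, SimulationConfig, read_pairs


@dataclass
class PipelineResult:
    evidence_prefilter: list[JunctionEvidence]  # before reference filtering
    evidence_raw: list[JunctionEvidence]  # after filtering, with duplicates
    evidence: list[JunctionEvidence]  # deduplicated
    junctions: list[Junction]
    stats: LibraryStats
    n_reads: int
    n_viral_reads: int
    n_duplicates_removed: int
    rejections: dict[str, int] = field(default_factory=dict)


class _ExactMatcher:
    """Seed-and-verify full-length exact matching against a circular genome."""

    def __init__(self, genome: str, read_length: int, probe: int = 21):
        self.lg = len(genome)
        self.probe = probe
        self.ext = genome + genome[: read_length + probe]
        idx: dict[str, int] = {}
        multi: dict[str, list[int]] = {}
        for i in range(self.lg):
            kmer = self.ext[i : i + probe]
            if kmer in idx:
                multi.setdefault(kmer, [idx[kmer]]).append(i)
            else:
                idx[kmer] = i
        self.idx = idx
        self.multi = multi

    def match_position(self, read: str) -> Optional[int]:
        """0-based start of a full-length exact match, or None."""
        pos = self.idx.get(read[: self.probe])
        if pos is None:
            return None
        if self.ext[pos : pos + len(read)] == read:
            return pos
        for p in self.multi.get(read[: self.probe], ()):
            if self.ext[p : p + len(read)] == read:
                return p
        return None


def run_pipeline(
    population: Population,
    config: SimulationConfig,
    pairs: Optional[Iterable[ReadPair]] = None,
    host_lineage_mode: str = "shared",
    min_aln_len: int = 28,
    corroborated: Optional[set[str]] = None,
    include_inter_in_nc: bool = False,
) -> PipelineResult:
    """Detect junctions in a population's reads and estimate Pj.

    ``corroborated`` defaults to all host references (the synthetic contig
    set is trusted); pass a subset to exercise the corroboration rule.
    """
    genome = population.reference.sequence
    lg = len(genome)
    L = config.read_length
    matcher = _ExactMatcher(genome, L)
    g2 = genome + genome[: L + 32]
    virus_idx = KmerIndex(g2, 11)
    virus_rc_idx = KmerIndex(revcomp(g2), 11)
    host_seqs = {c.contig_id: c.sequence for c in population.contigs}
    host_idx = {
        cid: (KmerIndex(seq, 11), KmerIndex(revcomp(seq), 11))
        for cid, seq in host_seqs.items()
    }
    tie_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(101,))
    )

    def align_read(seq: str, rid: str, mate: int):
        v_hits = local_align(
            seq,
            g2,
            min_aln_len,
            read_id=rid,
            mate=mate,
            subject_id="virus",
            subject_kind=VIRUS,
            index=virus_idx,
            rc_index=virus_rc_idx,
        )
        # drop duplicate hits from the wrapped copy of the origin
        v_hits = [h for h in v_hits if h.subject_lo <= lg]
        h_hits: list[AlignmentRecord] = []
        for cid, seq_c in host_seqs.items():
            idx, rc_idx = host_idx[cid]
            h_hits.extend(
                local_align(
                    seq,
                    seq_c,
                    min_aln_len,
                    read_id=rid,
                    mate=mate,
                    subject_id=cid,
                    subject_kind=CONTIG,
                    index=idx,
                    rc_index=rc_idx,
                )
            )
        v_best = select_best_hit(v_hits, VIRUS, tie_rng) if v_hits else None
        h_best = select_best_hit(h_hits, CONTIG, tie_rng) if h_hits else None
        return v_best, h_best

    if pairs is None:
        pairs = read_pairs(population, config)

    n_reads = 0
    n_viral = 0
    evidence: list[JunctionEvidence] = []
    rejections: dict[str, int] = {}
    match_position = matcher.match_position
    for pair in pairs:
        n_reads += 2
        seq1, seq2 = pair.seq1, pair.seq2
        p1 = match_position(seq1)
        s1 = "+"
        if p1 is None:
            p1 = match_position(revcomp(seq1))
            s1 = "-"
        p2 = match_position(seq2)
        s2 = "+"
        if p2 is None:
            p2 = match_position(revcomp(seq2))
            s2 = "-"
        if p1 is not None and p2 is not None:
            n_viral += 2  # both mates are exact full-length viral reads
            continue

        results = []
        for mate, seq, pos, strand in ((1, seq1, p1, s1), (2, seq2, p2, s2)):
            if pos is not None:
                n_viral += 1
                stub = AlignmentRecord(
                    read_id=pair.pair_id,
                    mate=mate,
                    subject_id="virus",
                    subject_kind=VIRUS,
                    read_start=1,
                    read_end=len(seq),
                    subject_start=pos + len(seq) if strand == "-" else pos + 1,
                    subject_end=pos + 1 if strand == "-" else pos + len(seq),
                    score=float(len(seq)),
                    identity=100.0,
                    aln_length=len(seq),
                )
                results.append((stub, None))
                continue
            v_best, h_best = align_read(seq, pair.pair_id, mate)
            if v_best is not None:
                n_viral += 1
            results.append((v_best, h_best))

        pair_evidence = []
        mate_info = []
        for v_best, h_best in results:
            mate_info.append({VIRUS: v_best, "host": h_best})
            if v_best is not None and h_best is not None:
                ev, reason = chimera.classify_intra_read(
                    v_best,
                    h_best,
                    L,
                    library_id=config.library_id,
                    genome_length=lg,
                )
                if ev is not None:
                    pair_evidence.append(ev)
                else:
                    rejections[reason] = rejections.get(reason, 0) + 1
        if pair_evidence:
            frag_key = _fragment_key(results, lg)
            for ev in pair_evidence:
                evidence.append(_with_pair_info(ev, pair.pair_id, frag_key))
        else:
            ev, _ = chimera.classify_inter_read(
                mate_info[0], mate_info[1], L, library_id=config.library_id
            )
            if ev is not None:
                evidence.append(ev)

    corroborated = (
        corroborated if corroborated is not None else set(host_seqs)
    )
    evidence_prefilter = evidence
    _, evidence = chimera.filter_host_references(evidence, corroborated)
    intra = [e for e in evidence if e.kind == INTRA_READ]
    nc_pool = evidence if include_inter_in_nc else intra
    nc = len(nc_pool)
    ov = (
        float(np.mean([e.overlap_len for e in intra])) if intra else 0.0
    )
    deduped, n_dup, _ = chimera.remove_duplicates(evidence)
    junctions = collapse_junctions(
        [e for e in deduped if e.kind == INTRA_READ], host_lineage_mode
    )
    stats = LibraryStats(
        library_id=config.library_id,
        Nc=nc,
        N=max(n_viral, 1),
        Lr=L,
        Lg=lg,
        Ov=ov,
    )
    return PipelineResult(
        evidence_prefilter=evidence_prefilter,
        evidence_raw=evidence,
        evidence=deduped,
        junctions=junctions,
        stats=stats,
        n_reads=n_reads,
        n_viral_reads=n_viral,
        n_duplicates_removed=n_dup,
        rejections=rejections,
    )


def _fragment_key(results, lg: int) -> tuple:
    coords = []
    for v_best, h_best in results:
        for b in (v_best, h_best):
            if b is not None:
                coords.append((b.subject_id, b.subject_lo % lg, b.subject_hi % lg))
    return tuple(sorted(coords))


def _with_pair_info(
    ev: JunctionEvidence, pair_id: str, frag_key: tuple
) -> JunctionEvidence:
    from dataclasses import replace

    return replace(
        ev, pair_id=pair_id, virus_outer=hash(frag_key), host_outer=hash(frag_key)
    )
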