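"""Junction collapsing, TE-end clustering, insertion-site logos,
microhomology statistics and host-contig coverage profiles.

A junction is identified by the coordinate offset between its viral and
host alignments, the viral strand, the host contig and -- for libraries
from independently infected host lineages -- the library. Reads sharing
that identity are treated as amplification of one original integration
event through viral replication and collapsed to a single junction.

Junctions piling up at one or two contig positions mark the ends of a
transposable element; clusters of at least 10 junctions are summarised by
a 30-bp sequence logo of the viral insertion sites. Junctions scattered
along a contig are instead characterised by the microhomology between the
viral flank and the host fragment at the breakpoint, and the observed
microhomology-length distribution is tested against a sampled null
(random 20-bp viral windows) with a Pearson chi-square test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .align import revcomp
from .chimera import INTRA_READ, JunctionEvidence

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SHARED_ANCESTOR = "shared"
INDEPENDENT_LINEAGES = "independent-lineages"


@dataclass
class Junction:
    """A deduplicated host-virus junction."""

    offset: int
    virus_strand: str
    host_strand: str
    contig_id: str
    library_scope: Optional[str]
    read_count: int
    representative: Optional[JunctionEvidence]
    virus_position: int
    contig_position: int
    side: str
    mechanism: str = "unclassified"
    microhomology_length: Optional[int] = None

    @property
    def junction_id(self) -> tuple:
        return (
            self.offset,
            self.virus_strand,
            self.host_strand,
            self.contig_id,
            self.library_scope,
        )


def collapse_junctions(
    evidence: Sequence[JunctionEvidence],
    host_lineage_mode: str = SHARED_ANCESTOR,
) -> list[Junction]:
    """Group deduplicated evidence into unique junctions.

    Reads with the same offset, viral strand and host contig (and library,
    when lineages are independent so identical junctions cannot be shared
    through a common ancestor) are counted as one junction; the
    representative read is the one with the best host alignment score.
    """
    if host_lineage_mode not in (SHARED_ANCESTOR, INDEPENDENT_LINEAGES):
        raise ValueError(f"unknown host_lineage_mode {host_lineage_mode!r}")
    groups: dict[tuple, list[JunctionEvidence]] = {}
    for ev in evidence:
        if ev.kind != INTRA_READ or ev.offset is None:
            continue
        scope = ev.library_id if host_lineage_mode == INDEPENDENT_LINEAGES else None
        key = (ev.offset, ev.virus_strand, ev.host_strand, ev.host_id, scope)
        groups.setdefault(key, []).append(ev)
    out = []
    for (offset, vs, hs, contig, scope), evs in groups.items():
        rep = max(evs, key=lambda e: (e.host_aln.score, e.read_id, e.mate))
        mh = rep.overlap_len
        out.append(
            Junction(
                offset=offset,
                virus_strand=vs,
                host_strand=hs,
                contig_id=contig,
                library_scope=scope,
                read_count=len(evs),
                representative=rep,
                virus_position=rep.virus_position,
                contig_position=rep.contig_position,
                side=rep.side,
                microhomology_length=mh,
            )
        )
    out.sort(key=lambda j: (j.contig_id, j.contig_position, j.offset))
    return out


@dataclass
class JunctionCluster:
    contig_id: str
    contig_end_position: int
    side: str
    members: list[Junction]
    n_distinct_virus_sites: int

    def __len__(self) -> int:
        return len(self.members)


def cluster_junction_sites(
    junctions: Sequence[Junction],
    min_cluster: int = 10,
    position_tolerance: int = 5,
) -> tuple[list[JunctionCluster], list[Junction]]:
    """Cluster one contig's junctions by contig position.

    Positions within ``position_tolerance`` of each other chain into one
    group; groups with at least ``min_cluster`` distinct viral sites become
    TE-end clusters, the rest are returned as scattered junctions.
    """
    if not junctions:
        return [], []
    contigs = {j.contig_id for j in junctions}
    if len(contigs) != 1:
        raise ValueError("junctions from multiple contigs in one call")
    ordered = sorted(junctions, key=lambda j: j.contig_position)
    groups: list[list[Junction]] = [[ordered[0]]]
    for j in ordered[1:]:
        if j.contig_position - groups[-1][-1].contig_position <= position_tolerance:
            groups[-1].append(j)
        else:
            groups.append([j])
    clusters: list[JunctionCluster] = []
    scattered: list[Junction] = []
    for group in groups:
        sites = {(j.virus_position, j.virus_strand) for j in group}
        if len(sites) >= min_cluster:
            sides = [j.side for j in group]
            side = max(set(sides), key=sides.count)
            pos = int(np.median([j.contig_position for j in group]))
            for j in group:
                j.mechanism = "transposition"
            clusters.append(
                JunctionCluster(
                    contig_id=group[0].contig_id,
                    contig_end_position=pos,
                    side=side,
                    members=group,
                    n_distinct_virus_sites=len(sites),
                )
            )
        else:
            scattered.extend(group)
    return clusters, scattered


@dataclass
class LogoMatrix:
    """Per-position base frequencies and information content (bits)."""

    frequencies: np.ndarray  # (width, 4) in A,C,G,T order
    information: np.ndarray  # (width,), 2 - H(p) bits, no small-sample correction
    n_sites: int
    width: int


def build_insertion_logo(
    cluster: JunctionCluster,
    viral_genome: str,
    width: int = 30,
    min_members: int = 10,
) -> LogoMatrix:
    """Sequence logo of the viral windows around a cluster's insertion sites.

    Each member contributes the ``width``-bp viral window centred on its
    insertion site (15 up + 15 down for width 30), reverse complemented for
    minus-strand junctions so logos of the two TE ends are comparable.
    """
    if len(cluster.members) < min_members:
        raise ValueError(
            f"cluster has {len(cluster.members)} members; {min_members} required"
        )
    lg = len(viral_genome)
    g2 = viral_genome + viral_genome[:width]
    half = width // 2
    counts = np.zeros((width, 4), dtype=float)
    n = 0
    for j in cluster.members:
        start = (j.virus_position - half) % lg
        window = g2[start : start + width]
        if j.virus_strand == "-":
            window = revcomp(window)
        for i, b in enumerate(window):
            if b in BASE_INDEX:
                counts[i, BASE_INDEX[b]] += 1
        n += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return LogoMatrix(frequencies=freqs, information=info, n_sites=n, width=width)


def microhomology_length(
    virus_through: str,
    host_fragment: str,
    untemplated_gap: int = 0,
    cap: int = 20,
) -> int:
    """Signed microhomology at a resolved junction.

    Both strings read through the junction in the same direction, anchored
    where the host fragment begins: ``virus_through`` is the viral sequence
    across the junction region (the end of the viral flank and its
    continuation) and ``host_fragment`` the host sequence leaving the
    junction. Their common prefix is the stretch attributable to both
    molecules: the microhomology. Returns 0 for a blunt join and -1/-2
    when the read showed that many bases matching neither molecule.
    """
    if untemplated_gap > 0:
        return -untemplated_gap
    k = 0
    for a, b in zip(virus_through, host_fragment):
        if a != b or k >= cap:
            break
        k += 1
    return min(k, cap)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def evidence_flanks(
    ev: JunctionEvidence,
    viral_genome: str,
    contig_seq: str,
    cap: int = 20,
) -> tuple[str, str]:
    """Viral and host sequences through an intra-read junction.

    Both strings are reconstructed from the reference sequences through the
    two alignments' coordinate frames (so they are error-free even if the
    read was not), oriented in the junction's reading direction and anchored
    at the inner host-alignment boundary; their common prefix is the
    junction's microhomology.
    """
    if ev.kind != INTRA_READ:
        raise ValueError("junction flanks require an intra-read junction")
    virus, host = ev.virus_aln, ev.host_aln
    lg, lc = len(viral_genome), len(contig_seq)

    def via(aln, ref: str, n: int, p: int) -> str:
        sign = -1 if aln.is_minus else 1
        out = []
        for rp in range(p, p + n):
            sp = aln.subject_start + sign * (rp - aln.read_start) - 1
            if ref is viral_genome:
                b = ref[sp % lg]
            elif 0 <= sp < lc:
                b = ref[sp]
            else:
                b = "N"  # beyond the contig: never matches
            out.append(_COMP[b] if aln.is_minus else b)
        return "".join(out)

    virus_first = virus.read_start <= host.read_start
    if virus_first:
        # anchor at the host alignment start: the overlap region lies ahead
        # of it on both coordinate frames, so the common prefix of the two
        # reconstructions is exactly the alignment overlap
        p = host.read_start
        virus_through = via(virus, viral_genome, cap, p)
        frag = via(host, contig_seq, cap, p)
    else:
        # mirrored junction: anchor at the host alignment end, reading
        # outward in the molecule direction
        p = host.read_end + 1
        virus_through = revcomp(via(virus, viral_genome, cap, p - cap))
        frag = revcomp(via(host, contig_seq, cap, p - cap))
    return virus_through, frag


def terminal_identity(host_end: str, window: str) -> int:
    """Common-prefix length of two junction-facing sequences."""
    k = 0
    for a, b in zip(host_end, window):
        if a != b:
            break
        k += 1
    return k


def null_microhomology_distribution(
    host_end_seqs: Sequence[str],
    viral_genome: str,
    n_random: int = 20,
    seed: int = 0,
    max_len: int = 20,
) -> np.ndarray:
    """Expected microhomology-length distribution under random joining.

    For each junction's 20-bp host-side terminal sequence (oriented away
    from the junction), the terminal identity with ``n_random`` random
    20-bp windows of the viral genome (oriented toward the junction) is
    recorded; counts over lengths 0..max_len are rescaled to the observed
    junction count.
    """
    if not host_end_seqs:
        raise ValueError("at least one junction sequence required")
    rng = np.random.default_rng(seed)
    lg = len(viral_genome)
    w = len(host_end_seqs[0])
    g2 = viral_genome + viral_genome[:w]
    counts = np.zeros(max_len + 1, dtype=float)
    for seq in host_end_seqs:
        starts = rng.integers(0, lg, size=n_random)
        for st in starts:
            k = terminal_identity(seq, g2[st : st + w])
            counts[min(k, max_len)] += 1
    return counts * (len(host_end_seqs) / counts.sum())


def microhomology_test(
    observed: np.ndarray,
    expected: np.ndarray,
    min_expected: float = 5.0,
) -> tuple[float, int, float, list[tuple[int, int]]]:
    """Pearson chi-square comparison of microhomology-length distributions.

    Both arrays cover lengths 0..K with equal totals, giving K degrees of
    freedom. Adjacent tail bins are merged until every expected count
    reaches ``min_expected`` (Cochran's rule; ``min_expected=0`` keeps all
    bins and the full df). Returns (statistic, df, upper-tail p, merges)
    where merges lists the (from_bin, into_bin) collapses applied.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have the same shape")
    if not math.isclose(obs.sum(), exp.sum(), rel_tol=1e-9, abs_tol=1e-6):
        raise ValueError("observed and expected totals differ")
    merges: list[tuple[int, int]] = []
    o, e = list(obs), list(exp)
    i = len(e) - 1
    while i > 0:
        if e[i] < min_expected or (e[i] == 0 and o[i] > 0):
            o[i - 1] += o[i]
            e[i - 1] += e[i]
            merges.append((i, i - 1))
            del o[i], e[i]
        i -= 1
    o_arr, e_arr = np.array(o), np.array(e)
    keep = e_arr > 0
    o_arr, e_arr = o_arr[keep], e_arr[keep]
    stat = float(((o_arr - e_arr) ** 2 / e_arr).sum())
    df = len(e_arr) - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p, merges


HOST_ONLY = "host_only"
CHIMERIC_LEFT = "chimeric_left"  # left part of the read is host sequence
CHIMERIC_RIGHT = "chimeric_right"


def contig_coverage(
    alignments: Iterable[tuple[int, int, str]],
    contig_length: int,
    window: int = 20,
    step: int = 10,
    classes: Sequence[str] = (HOST_ONLY, CHIMERIC_LEFT, CHIMERIC_RIGHT),
) -> dict[str, np.ndarray]:
    """Mean sequencing depth per sliding window, per chimera class.

    ``alignments`` yields (start, end, class) with 0-based half-open contig
    coordinates. Windows of ``window`` bp advance by ``step`` bp from
    position 0; a final partial window is averaged over its actual span.
    """
    depth = {c: np.zeros(contig_length + 1) for c in classes}
    for start, end, cls in alignments:
        if cls not in depth:
            raise ValueError(f"unknown alignment class {cls!r}")
        s = max(0, start)
        e = min(contig_length, end)
        if e > s:
            depth[cls][s] += 1
            depth[cls][e] -= 1
    n_windows = max(1, -(-max(contig_length - window, 0) // step) + 1)
    out = {}
    for cls, diff in depth.items():
        per_base = np.cumsum(diff[:-1])
        means = np.empty(n_windows)
        for i in range(n_windows):
            lo = i * step
            hi = min(lo + window, contig_length)
            means[i] = per_base[lo:hi].mean() if hi > lo else 0.0
        out[cls] = means
    return out
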