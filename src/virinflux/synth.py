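"""Synthetic viral populations carrying host DNA insertions.

Emulates the data-generating process the analysis assumes: a circular
~134-kb dsDNA viral genome sequenced as a population of genomes, a set of
host DNA transposons (terminal inverted repeats, family-specific target
motifs such as TTAA for piggyBac) plus uncharacterised host contigs, a
Poisson number of host-DNA insertions per genome produced either by
cut-and-paste transposition (with target-site duplication) or by
microhomology-mediated recombination, and paired-end short reads with
substitution errors and exact PCR duplicates.

Microhomology joins are constructed so the homologous bases appear once in
the recombinant molecule and are attributable to both parents: a join of
homology length k at virus position s uses a host fragment whose first k
bases equal the viral flank's last k bases, and the recombinant reads
``genome[:s] + fragment[k:] + genome[s:]``. The detected alignment overlap
at such a junction equals k plus any chance extension.

Every planted event is recorded in a truth table so detection,
classification and frequency estimation can be validated against known
ground truth. One seeded generator drives a run; per-stage substreams are
derived deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .align import revcomp, write_fastq

BASES = "ACGT"

# Default TE family catalogue: (family, target motif, TIR length).
# piggyBac inserts at TTAA, Harbinger at TAA/TTA, Mariner at TA.
TE_CATALOG = [
    ("piggybac", "TTAA", 13),
    ("harbinger", "TAA", 14),
    ("mariner", "TA", 28),
    ("sola", "TTAA", 20),
]

TRANSPOSITION = "transposition"
MICROHOMOLOGY = "microhomology"
BLUNT = "blunt"
UNTEMPLATED = "untemplated"


@dataclass
class SimulationConfig:
    """Parameters of one simulated sequencing experiment.

    ``lambda_insertions`` is the mean number of host-DNA insertions per
    viral genome (one insertion into a circular genome yields two
    host-virus junctions, so the junction rate per genome is twice this).
    ``target_depth`` is the fold-coverage per genome of the pool, so the
    viral reference is sequenced at about n_genomes * target_depth.
    """

    seed: int = 0
    genome_length: int = 133_926
    gc_content: float = 0.41
    n_te_families: int = 3
    te_length: int = 1500
    n_unknown_contigs: int = 2
    unknown_contig_length: int = 1200
    lambda_insertions: float = 0.05
    transposition_fraction: float = 0.93
    microhomology_geometric_p: float = 0.5
    blunt_fraction: float = 0.19
    untemplated_fraction: float = 0.16
    fragment_length_min: int = 300
    fragment_length_max: int = 1000
    n_genomes: int = 1000
    read_length: int = 101
    target_depth: float = 2.0
    error_rate: float = 0.0
    pcr_duplicate_rate: float = 0.0
    insert_size_mean: float = 300.0
    insert_size_sd: float = 25.0
    tsd: bool = True
    alphabet: str = "ACGT"
    library_id: str = "lib0"

    def __post_init__(self) -> None:
        if self.alphabet != "ACGT":
            raise ValueError("only the ACGT alphabet is supported")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        for name in (
            "n_te_families",
            "te_length",
            "n_genomes",
            "fragment_length_min",
            "fragment_length_max",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_unknown_contigs < 0:
            raise ValueError("n_unknown_contigs must be >= 0")
        for name in (
            "gc_content",
            "transposition_fraction",
            "blunt_fraction",
            "untemplated_fraction",
            "error_rate",
            "pcr_duplicate_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.blunt_fraction + self.untemplated_fraction > 1.0:
            raise ValueError("blunt + untemplated fractions exceed 1")
        if not (0.0 < self.microhomology_geometric_p <= 1.0):
            raise ValueError("microhomology_geometric_p must be in (0, 1]")
        if self.read_length not in (101, 151):
            raise ValueError("read_length must be 101 or 151")
        if self.lambda_insertions < 0:
            raise ValueError("lambda_insertions must be >= 0")
        if self.target_depth <= 0:
            raise ValueError("target_depth must be > 0")
        if self.insert_size_mean < self.read_length:
            raise ValueError("insert size must allow a full read per mate")
        if self.fragment_length_max < self.fragment_length_min:
            raise ValueError("fragment_length_max < fragment_length_min")
        if self.n_te_families > len(TE_CATALOG):
            raise ValueError(f"at most {len(TE_CATALOG)} TE families available")
        for _, _, tir in TE_CATALOG[: self.n_te_families]:
            if tir >= self.te_length / 2:
                raise ValueError("tir_length must be < te_length / 2")

    def substream(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage RNG derived from the run seed."""
        stages = {"genome": 0, "contigs": 1, "population": 2, "reads": 3}
        ss = np.random.SeedSequence(self.seed, spawn_key=(stages[stage],))
        return np.random.default_rng(ss)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in draws)


def scan_motif(genome: str, motif: str, circular: bool = True) -> list[int]:
    """All (overlap-tolerant) occurrence start positions of ``motif``.

    On a circular sequence, occurrences spanning the origin are reported at
    their 0-based start position on the unrolled reference.
    """
    text = genome + genome[: len(motif) - 1] if circular else genome
    out: list[int] = []
    i = text.find(motif)
    while i != -1 and i < len(genome):
        out.append(i)
        i = text.find(motif, i + 1)
    return out


@dataclass
class ViralGenome:
    sequence: str
    motif_map: dict[str, list[int]]

    def __len__(self) -> int:
        return len(self.sequence)


def generate_viral_genome(config: SimulationConfig) -> ViralGenome:
    """A circular random viral genome plus a map of TE target motifs."""
    rng = config.substream("genome")
    seq = _random_seq(rng, config.genome_length, config.gc_content)
    motifs = {m for _, m, _ in TE_CATALOG[: config.n_te_families]}
    motif_map = {m: scan_motif(seq, m) for m in sorted(motifs)}
    return ViralGenome(sequence=seq, motif_map=motif_map)


@dataclass
class Contig:
    contig_id: str
    sequence: str
    contig_class: str  # "te" or "undetermined"
    family: Optional[str] = None
    target_motif: Optional[str] = None
    tir_length: int = 0
    orf_interval: Optional[tuple[int, int]] = None

    def __len__(self) -> int:
        return len(self.sequence)


_STOPS = {"TAA", "TAG", "TGA"}


def _orf_placeholder(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + stop-free random codons + TAA: a transposase-like ORF stub."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def generate_host_contigs(config: SimulationConfig) -> list[Contig]:
    """Host TE contigs (with TIRs and an internal ORF) and unknown contigs.

    The 5' terminal inverted repeat is the reverse complement of the 3'
    TIR, as in class II DNA transposons; undetermined contigs carry no TIR
    annotation.
    """
    rng = config.substream("contigs")
    contigs: list[Contig] = []
    for fam_idx in range(config.n_te_families):
        family, motif, tir_len = TE_CATALOG[fam_idx]
        tir = _random_seq(rng, tir_len, config.gc_content)
        core_len = config.te_length - 2 * tir_len
        n_codons = max(10, (core_len // 3) - 20)
        orf = _orf_placeholder(rng, n_codons)
        pad = core_len - len(orf)
        left_pad = _random_seq(rng, pad // 2, config.gc_content)
        right_pad = _random_seq(rng, pad - pad // 2, config.gc_content)
        seq = tir + left_pad + orf + right_pad + revcomp(tir)
        orf_start = tir_len + len(left_pad)
        contigs.append(
            Contig(
                contig_id=f"te_{family}",
                sequence=seq,
                contig_class="te",
                family=family,
                target_motif=motif,
                tir_length=tir_len,
                orf_interval=(orf_start, orf_start + len(orf)),
            )
        )
    for i in range(config.n_unknown_contigs):
        contigs.append(
            Contig(
                contig_id=f"unknown_{i}",
                sequence=_random_seq(
                    rng, config.unknown_contig_length, config.gc_content
                ),
                contig_class="undetermined",
            )
        )
    return contigs


@dataclass
class TruthInsertion:
    """One planted insertion event (two host-virus junctions)."""

    genome_id: str
    mechanism: str
    virus_site: int  # 0-based position on the circular reference
    contig_id: str
    contig_interval: tuple[int, int]  # 0-based half-open, contig frame
    orientation: str  # "+" or "-"
    microhomology_length: int  # realized signed overlap, left junction
    tsd_length: int = 0
    # realized junction geometry (0-based, reference frame)
    virus_left: int = 0  # reference position of the left junction point
    virus_right: int = 0  # reference position where the genome resumes
    mh_left: int = 0
    mh_right: int = 0
    host_left: int = 0  # oriented-fragment start coordinate
    host_right: int = 0


@dataclass
class JunctionGeom:
    """Realized geometry of one junction on a recombinant molecule.

    ``x_end`` is the (0-based, exclusive) end on the recombinant of the
    maximal alignment of the molecule's first part; ``y_start`` the start
    of the second part's alignment. Their difference is the signed overlap
    a chimeric read shows at this junction.
    """

    x_end: int
    y_start: int
    side: str  # "left": virus then host; "right": host then virus
    truth: TruthInsertion

    @property
    def overlap(self) -> int:
        return self.x_end - self.y_start


@dataclass
class RecombinantGenome:
    genome_id: str
    sequence: str
    junctions: list[JunctionGeom]


@dataclass
class Population:
    reference: ViralGenome
    contigs: list[Contig]
    recombinants: list[RecombinantGenome]
    n_plain: int
    truth: list[TruthInsertion]
    n_redrawn: int = 0

    @property
    def n_genomes(self) -> int:
        return self.n_plain + len(self.recombinants)


def _extension(
    a: str, ai: int, step_a: int, b: str, bi: int, step_b: int, cap: int = 25
) -> int:
    """Length of exact identity walking ``a`` from ai and ``b`` from bi."""
    k = 0
    while k < cap:
        pa, pb = ai + step_a * k, bi + step_b * k
        if pa < 0 or pb < 0 or pa >= len(a) or pb >= len(b):
            break
        if a[pa] != b[pb]:
            break
        k += 1
    return k


@dataclass
class _Planned:
    truth: TruthInsertion
    splice_at: int  # reference coordinate where the insert is placed
    insert_seq: str
    # junction descriptors relative to the insert start on the recombinant:
    # (side, x_end_rel, y_start_rel)
    junctions: list[tuple[str, int, int]]


def _draw_transposition(
    rng: np.random.Generator,
    ref: str,
    te: Contig,
    motif_sites: list[int],
    config: SimulationConfig,
    genome_id: str,
) -> Optional[_Planned]:
    if not motif_sites:
        return None
    m = motif_sites[int(rng.integers(len(motif_sites)))]
    t = len(te.target_motif or "") if config.tsd else 0
    orientation = "+" if rng.random() < 0.5 else "-"
    te_seq = te.sequence if orientation == "+" else revcomp(te.sequence)
    splice_at = m + t
    insert_seq = te_seq + ref[m : m + t]
    # left junction: viral flank (ending with the motif) then the TE start;
    # the TE has no upstream contig context, so only the virus alignment can
    # extend, by chance, into the TE.
    r_ext = _extension(te_seq, 0, 1, ref, splice_at, 1)
    mh_left = r_ext
    # right junction: TE end then the duplicated motif, which aligns to the
    # reference from position m onward.
    l_ext = _extension(te_seq, len(te_seq) - 1, -1, ref, m - 1, -1)
    mh_right = l_ext
    truth = TruthInsertion(
        genome_id=genome_id,
        mechanism=TRANSPOSITION,
        virus_site=m,
        contig_id=te.contig_id,
        contig_interval=(0, len(te.sequence)),
        orientation=orientation,
        microhomology_length=mh_left,
        tsd_length=t,
        virus_left=splice_at,
        virus_right=m,
        mh_left=mh_left,
        mh_right=mh_right,
        host_left=0,
        host_right=len(te.sequence),
    )
    junctions = [
        ("left", r_ext, 0),
        ("right", len(te_seq), len(te_seq) - l_ext),
    ]
    return _Planned(truth, splice_at, insert_seq, junctions)


def _untemplated_bases(
    rng: np.random.Generator, n: int, forbid_first: str, forbid_last: str
) -> str:
    out = []
    for i in range(n):
        while True:
            b = BASES[int(rng.integers(4))]
            if i == 0 and b == forbid_first and n > 1:
                continue
            if i == n - 1 and b == forbid_last:
                continue
            if n == 1 and b in (forbid_first, forbid_last):
                continue
            out.append(b)
            break
    return "".join(out)


def _draw_recombination(
    rng: np.random.Generator,
    ref: str,
    contig: Contig,
    config: SimulationConfig,
    genome_id: str,
    margin: int,
) -> Optional[_Planned]:
    lg = len(ref)
    u = rng.random()
    if u < config.blunt_fraction:
        k = 0
    elif u < config.blunt_fraction + config.untemplated_fraction:
        k = -int(rng.integers(1, 3))
    else:
        k = min(20, int(rng.geometric(config.microhomology_geometric_p)))
    orientation = "+" if rng.random() < 0.5 else "-"
    oriented = contig.sequence if orientation == "+" else revcomp(contig.sequence)
    max_frag = min(config.fragment_length_max, len(oriented) - 50)
    if max_frag < config.fragment_length_min:
        return None
    frag_len = int(rng.integers(config.fragment_length_min, max_frag + 1))

    for _ in range(25):
        s = int(rng.integers(margin, lg - margin))
        if k > 0:
            probe = ref[s - k : s]
            starts = _find_all(oriented, probe, 2, len(oriented) - frag_len - 2)
            if not starts:
                continue
            q0 = starts[int(rng.integers(len(starts)))]
        else:
            q0 = int(rng.integers(2, len(oriented) - frag_len - 1))
        frag = oriented[q0 : q0 + frag_len]
        if k < 0:
            gap = _untemplated_bases(rng, -k, ref[s], oriented[q0 - 1])
            insert_seq = gap + frag
            x_end_rel = 0
            y_start_rel = len(gap)
            mh_left = -len(gap)
        elif k == 0:
            insert_seq = frag
            r_ext = _extension(frag, 0, 1, ref, s, 1)
            l_ext = _extension(oriented, q0 - 1, -1, ref, s - 1, -1)
            x_end_rel = r_ext
            y_start_rel = -l_ext
            mh_left = r_ext + l_ext
        else:
            # homologous bases appear once: splice fragment minus its first
            # k bases; the host alignment reaches k bases into the flank.
            insert_seq = frag[k:]
            r_ext = _extension(frag, k, 1, ref, s, 1)
            l_ext = _extension(oriented, q0 - 1, -1, ref, s - k - 1, -1)
            x_end_rel = r_ext
            y_start_rel = -(k + l_ext)
            mh_left = k + l_ext + r_ext
        # right junction: fragment end, then the genome resumes at s
        r_ext_h = _extension(oriented, q0 + frag_len, 1, ref, s, 1)
        l_ext_v = _extension(oriented, q0 + frag_len - 1, -1, ref, s - 1, -1)
        mh_right = r_ext_h + l_ext_v
        n_ins = len(insert_seq)
        junctions = [
            ("left", x_end_rel, y_start_rel),
            ("right", n_ins + r_ext_h, n_ins - l_ext_v),
        ]
        ci = (
            (q0, q0 + frag_len)
            if orientation == "+"
            else (len(oriented) - (q0 + frag_len), len(oriented) - q0)
        )
        mechanism = (
            MICROHOMOLOGY if mh_left > 0 else BLUNT if mh_left == 0 else UNTEMPLATED
        )
        truth = TruthInsertion(
            genome_id=genome_id,
            mechanism=mechanism,
            virus_site=s,
            contig_id=contig.contig_id,
            contig_interval=ci,
            orientation=orientation,
            microhomology_length=mh_left,
            virus_left=s,
            virus_right=s,
            mh_left=mh_left,
            mh_right=mh_right,
            host_left=q0,
            host_right=q0 + frag_len,
        )
        return _Planned(truth, s, insert_seq, junctions)
    return None


def _find_all(text: str, pattern: str, lo: int, hi: int) -> list[int]:
    out = []
    i = text.find(pattern, lo)
    while i != -1 and i <= hi:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def simulate_population(
    genome: ViralGenome, contigs: list[Contig], config: SimulationConfig
) -> Population:
    """Plant Poisson(lambda) insertions per genome and record the truth.

    With probability ``transposition_fraction`` an event is a transposition
    into a uniformly chosen occurrence of the family's target motif (with
    target-site duplication when enabled); otherwise a recombination join
    whose microhomology length is geometric (truncated to [1, 20]), with
    explicit mixture weights for blunt and untemplated joins. Events that
    cannot be placed (no motif occurrence, no homology match) are redrawn
    and counted in ``n_redrawn``.
    """
    rng = config.substream("population")
    ref = genome.sequence
    lg = len(ref)
    if config.lambda_insertions == 0:
        return Population(genome, contigs, [], config.n_genomes, [], 0)

    te_contigs = [c for c in contigs if c.contig_class == "te"]
    margin = max(config.read_length + 1, min(2 * config.read_length, lg // 8))
    sites_by_te = {
        c.contig_id: [
            m
            for m in genome.motif_map.get(c.target_motif or "", [])
            if margin <= m < lg - margin
        ]
        for c in te_contigs
    }
    min_sep = min(2 * (config.read_length + int(config.insert_size_mean)), lg // 4)

    truth: list[TruthInsertion] = []
    recombinants: list[RecombinantGenome] = []
    n_redrawn = 0
    ks = rng.poisson(config.lambda_insertions, size=config.n_genomes)
    for gi in np.nonzero(ks)[0]:
        gid = f"genome_{gi}"
        planned: list[_Planned] = []
        used: list[int] = []
        for _ in range(int(ks[gi])):
            ins = None
            for _attempt in range(200):
                if rng.random() < config.transposition_fraction and te_contigs:
                    te = te_contigs[int(rng.integers(len(te_contigs)))]
                    cand = _draw_transposition(
                        rng, ref, te, sites_by_te[te.contig_id], config, gid
                    )
                else:
                    contig = contigs[int(rng.integers(len(contigs)))]
                    cand = _draw_recombination(rng, ref, contig, config, gid, margin)
                if cand is None:
                    n_redrawn += 1
                    continue
                if all(abs(cand.splice_at - u) >= min_sep for u in used):
                    ins = cand
                    break
                n_redrawn += 1
            if ins is None:  # pragma: no cover - pathological configs only
                raise RuntimeError("could not place insertion without collision")
            used.append(ins.splice_at)
            planned.append(ins)
            truth.append(ins.truth)
        planned.sort(key=lambda p: p.splice_at)
        parts: list[str] = []
        geoms: list[JunctionGeom] = []
        prev = 0
        shift = 0
        for ins in planned:
            parts.append(ref[prev : ins.splice_at])
            p_start = ins.splice_at + shift
            for side, x_rel, y_rel in ins.junctions:
                geoms.append(
                    JunctionGeom(p_start + x_rel, p_start + y_rel, side, ins.truth)
                )
            parts.append(ins.insert_seq)
            shift += len(ins.insert_seq)
            prev = ins.splice_at
        parts.append(ref[prev:])
        recombinants.append(RecombinantGenome(gid, "".join(parts), geoms))
    n_plain = config.n_genomes - len(recombinants)
    return Population(genome, contigs, recombinants, n_plain, truth, n_redrawn)


@dataclass
class TruthRead:
    """A simulated read overlapping a planted junction."""

    read_id: str
    mate: int
    genome_id: str
    side: str
    # expected maximal alignment boundaries on the read (0-based half-open):
    # virus-part alignment ends at v_end, host-part alignment starts at
    # h_start for side=left; mirrored semantics for side=right.
    x_end: int
    y_start: int
    overlap: int
    truth: TruthInsertion
    is_duplicate: bool = False


@dataclass
class ReadPair:
    pair_id: str
    seq1: str
    seq2: str
    truth: list[TruthRead] = field(default_factory=list)
    is_duplicate: bool = False


def _pair_counts(
    rng: np.random.Generator, population: Population, config: SimulationConfig
) -> tuple[int, np.ndarray]:
    lg = len(population.reference.sequence)
    lengths = [population.n_plain * lg] + [
        len(r.sequence) for r in population.recombinants
    ]
    total_len = float(sum(lengths))
    total_pairs = int(
        round(config.target_depth * total_len / (2 * config.read_length))
    )
    probs = np.array(lengths) / total_len
    return total_pairs, rng.multinomial(total_pairs, probs)


def _apply_errors(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    pos = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for p in pos:
        alts = [b for b in BASES if b != out[p]]
        out[p] = alts[int(rng.integers(3))]
    return "".join(out)


def read_pairs(
    population: Population, config: SimulationConfig
) -> Iterator[ReadPair]:
    """Stream paired reads from the population at the configured depth.

    Fragments are drawn uniformly from each circular genome (origin-crossing
    fragments via sequence rotation; truth coordinates stay on the reference
    frame); read 2 is the reverse complement of the fragment end. A fraction
    of pairs is duplicated exactly, after error injection, emulating PCR
    duplicates.
    """
    rng = config.substream("reads")
    L = config.read_length
    total_pairs, counts = _pair_counts(rng, population, config)
    lg = len(population.reference.sequence)
    max_iso = int(config.insert_size_mean + 6 * config.insert_size_sd) + L
    genomes: list[tuple[str, str, list[JunctionGeom]]] = [
        ("plain", population.reference.sequence, [])
    ] + [(r.genome_id, r.sequence, r.junctions) for r in population.recombinants]

    pair_no = 0
    for (gid, seq, geoms), n_pairs in zip(genomes, counts):
        if n_pairs == 0:
            continue
        glen = len(seq)
        ext = seq + seq[: max_iso]
        starts = rng.integers(0, glen, size=n_pairs)
        isizes = np.clip(
            np.rint(
                rng.normal(config.insert_size_mean, config.insert_size_sd, n_pairs)
            ).astype(int),
            L,
            max_iso,
        )
        dup_draws = (
            rng.random(n_pairs) < config.pcr_duplicate_rate
            if config.pcr_duplicate_rate > 0
            else np.zeros(n_pairs, dtype=bool)
        )
        for st, isz, dup in zip(starts, isizes, dup_draws):
            st, isz = int(st), int(isz)
            r1 = _apply_errors(rng, ext[st : st + L], config.error_rate)
            r2 = _apply_errors(
                rng, revcomp(ext[st + isz - L : st + isz]), config.error_rate
            )
            pid = f"{gid}_{pair_no}"
            pair_no += 1
            truth_rows: list[TruthRead] = []
            for g in geoms:
                jp = max(g.x_end, g.y_start)
                delta = (jp - st) % glen
                if delta >= isz + 25:
                    continue
                for mate, m_lo in ((1, 0), (2, isz - L)):
                    # junction boundaries in this mate's read frame (the
                    # read frame is the fragment's forward frame; mate 2 is
                    # reverse complemented afterwards, which detection
                    # handles via strand); boundaries are anchored on the
                    # junction point so origin wrapping cannot split them
                    x = delta + (g.x_end - jp) - m_lo
                    y = delta + (g.y_start - jp) - m_lo
                    if max(x, y) <= 0 or min(x, y) >= L:
                        continue
                    truth_rows.append(
                        TruthRead(
                            read_id=pid,
                            mate=mate,
                            genome_id=gid,
                            side=g.side,
                            x_end=x,
                            y_start=y,
                            overlap=g.overlap,
                            truth=g.truth,
                            is_duplicate=bool(dup),
                        )
                    )
            yield ReadPair(pid, r1, r2, truth_rows, False)
            if dup:
                yield ReadPair(
                    pid + "dup",
                    r1,
                    r2,
                    [
                        TruthRead(
                            pid + "dup",
                            t.mate,
                            t.genome_id,
                            t.side,
                            t.x_end,
                            t.y_start,
                            t.overlap,
                            t.truth,
                            True,
                        )
                        for t in truth_rows
                    ],
                    True,
                )


def simulate_reads(
    population: Population,
    config: SimulationConfig,
    fastq1=None,
    fastq2=None,
) -> tuple[Optional[list[ReadPair]], list[TruthRead]]:
    """Materialize (or write) the paired reads plus the chimeric-read truth.

    With FASTQ paths given, reads are streamed to disk (Phred+33, fixed Q30
    placeholder qualities) and only the truth table is returned; otherwise
    all pairs are returned in memory.
    """
    truth: list[TruthRead] = []
    if fastq1 is not None and fastq2 is not None:
        qual = chr(30 + 33) * config.read_length

        def stream(which: int, dest):
            for pair in read_pairs(population, config):
                # regenerating both mates per file keeps memory flat
                seq = pair.seq1 if which == 1 else pair.seq2
                yield f"{pair.pair_id}/{which}", seq, qual

        write_fastq(stream(1, fastq1), fastq1)
        write_fastq(stream(2, fastq2), fastq2)
        for pair in read_pairs(population, config):
            truth.extend(pair.truth)
        return None, truth
    pairs = list(read_pairs(population, config))
    for p in pairs:
        truth.extend(p.truth)
    return pairs, truth
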