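"""Horizontal-transfer screen for virus-borne transposable elements.

A TE found integrated in viral genomes is a horizontal-transfer candidate
in another insect species when it aligns there with at least 85%
nucleotide identity over at least 100 bp. The neutral expectation under
vertical inheritance is taken from synonymous distances (dS) of conserved
single-copy genes between the same species pair, computed with the
non-corrected Nei-Gojobori (1986) method and expressed as a percent
similarity (1 - dS) x 100. A TE whose identity exceeds that neutral
similarity is inconsistent with vertical inheritance.

NG86 here: per codon, each position contributes the fraction of its three
single-base changes that are synonymous (changes to stop codons excluded
from the denominator); site counts are averaged between the two sequences.
Differences in codons differing at several positions are averaged over all
minimal substitution pathways, excluding pathways through stop codons
(falling back to all pathways if every one is blocked). dS is the raw
proportion Sd/S with no multiple-hit correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
BASES = "ACGT"


def _codon_map(table: CodonTable.CodonTable = _STANDARD) -> dict[str, Optional[str]]:
    """codon -> amino acid, None for stops."""
    mapping: dict[str, Optional[str]] = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = None
    return mapping


_DEFAULT_CODE = _codon_map()


@dataclass
class CodonAlignmentStats:
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    n_codons: int
    n_dropped: int  # codon pairs skipped (gaps, ambiguity, stops)
    dS: float = field(init=False)
    dN: float = field(init=False)

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise ValueError("no synonymous sites; dS undefined")
        self.dS = self.Sd / self.S
        self.dN = self.Nd / self.N if self.N > 0 else 0.0

    @property
    def percent_similarity(self) -> float:
        return (1.0 - self.dS) * 100.0


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Synonymous sites of one codon (stop changes out of the denominator)."""
    aa = _DEFAULT_CODE[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            alt_aa = _DEFAULT_CODE[alt]
            if alt_aa is None:
                continue
            valid += 1
            if alt_aa == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: Sequence[int]) -> Optional[tuple[float, float]]:
        cur = c1
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _DEFAULT_CODE[nxt] is None and nxt != c2:
                return None  # pathway through a stop codon
            if _DEFAULT_CODE[cur] == _DEFAULT_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [walk(order) for order in itertools.permutations(diff)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [
            _walk_through_stops(c1, c2, order)
            for order in itertools.permutations(diff)
        ]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def _walk_through_stops(c1: str, c2: str, order: Sequence[int]) -> tuple[float, float]:
    cur = c1
    sd = nd = 0.0
    for pos in order:
        nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
        if _DEFAULT_CODE[cur] == _DEFAULT_CODE[nxt]:
            sd += 1
        else:
            nd += 1
        cur = nxt
    return sd, nd


def nei_gojobori_ds(seq1: str, seq2: str) -> CodonAlignmentStats:
    """Non-corrected NG86 synonymous distance between two aligned CDSs.

    Sequences must be equal-length and in frame; codon pairs containing
    gaps, ambiguous bases or stop codons are dropped pairwise and counted.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    if len(seq1) % 3:
        raise ValueError("alignment length not divisible by 3")
    S = N = Sd = Nd = 0.0
    n_codons = n_dropped = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if (
            any(b not in BASES for b in c1 + c2)
            or _DEFAULT_CODE[c1] is None
            or _DEFAULT_CODE[c2] is None
        ):
            n_dropped += 1
            continue
        n_codons += 1
        s1, s2 = _syn_sites(c1), _syn_sites(c2)
        S += (s1 + s2) / 2.0
        N += 3.0 - (s1 + s2) / 2.0
        sd, nd = _pair_differences(c1, c2)
        Sd += sd
        Nd += nd
    return CodonAlignmentStats(S=S, N=N, Sd=Sd, Nd=Nd, n_codons=n_codons,
                               n_dropped=n_dropped)


HT_CANDIDATE = "HT-candidate"
VERTICAL = "consistent-with-vertical"


@dataclass
class HTCandidate:
    te_id: str
    species: str
    percent_identity: float  # best qualifying hit
    mean_identity: float
    n_copies: int  # hits >= min_length
    longest_copy: int
    neutral_percent_similarity: Optional[float] = None
    verdict: Optional[str] = None


def screen_te_hits(
    hits: Sequence[tuple[str, str, float, int]],
    min_identity: float = 85.0,
    min_length: int = 100,
) -> list[HTCandidate]:
    """HT candidates from per-species TE alignments.

    ``hits`` holds (te_id, species, percent identity, alignment length)
    tuples; a (TE, species) pair with at least one hit of >= min_identity
    over >= min_length becomes a candidate, reporting its copy count (hits
    >= min_length) and longest copy.
    """
    qualifying: dict[tuple[str, str], list[tuple[float, int]]] = {}
    long_enough: dict[tuple[str, str], list[tuple[float, int]]] = {}
    for te, sp, ident, length in hits:
        if length >= min_length:
            long_enough.setdefault((te, sp), []).append((ident, length))
            if ident >= min_identity:
                qualifying.setdefault((te, sp), []).append((ident, length))
    out = []
    for (te, sp), quals in sorted(qualifying.items()):
        copies = long_enough[(te, sp)]
        idents = [q[0] for q in quals]
        out.append(
            HTCandidate(
                te_id=te,
                species=sp,
                percent_identity=max(idents),
                mean_identity=sum(idents) / len(idents),
                n_copies=len(copies),
                longest_copy=max(l for _, l in copies),
            )
        )
    return out


@dataclass
class HTContrast:
    species: str
    mean_te_identity: float
    mean_neutral_similarity: float
    n_candidates: int
    n_genes: int


def contrast_te_vs_neutral(
    candidates: Sequence[HTCandidate],
    gene_ds: dict[str, Sequence[float]],
    margin: float = 0.0,
) -> tuple[list[HTCandidate], list[HTContrast]]:
    """Contrast TE identity with neutral similarity per species pair.

    ``gene_ds`` maps species to the per-gene synonymous distances against
    the focal species. Each candidate's verdict is HT-candidate when its
    identity exceeds the species' neutral percent similarity by more than
    ``margin``; candidates without gene data keep verdict None.
    """
    updated: list[HTCandidate] = []
    contrasts: list[HTContrast] = []
    by_species: dict[str, list[HTCandidate]] = {}
    for c in candidates:
        by_species.setdefault(c.species, []).append(c)
    for sp, cands in sorted(by_species.items()):
        ds_values = gene_ds.get(sp)
        neutral = None
        if ds_values:
            neutral = (1.0 - sum(ds_values) / len(ds_values)) * 100.0
        for c in cands:
            verdict = None
            if neutral is not None:
                verdict = (
                    HT_CANDIDATE
                    if c.percent_identity > neutral + margin
                    else VERTICAL
                )
            updated.append(
                HTCandidate(
                    te_id=c.te_id,
                    species=c.species,
                    percent_identity=c.percent_identity,
                    mean_identity=c.mean_identity,
                    n_copies=c.n_copies,
                    longest_copy=c.longest_copy,
                    neutral_percent_similarity=neutral,
                    verdict=verdict,
                )
            )
        if neutral is not None:
            contrasts.append(
                HTContrast(
                    species=sp,
                    mean_te_identity=sum(c.percent_identity for c in cands)
                    / len(cands),
                    mean_neutral_similarity=neutral,
                    n_candidates=len(cands),
                    n_genes=len(ds_values),
                )
            )
    return updated, contrasts
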