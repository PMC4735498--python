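"""Synthetic population generator: determinism, composition and statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from virinflux.align import revcomp
from virinflux.synth import (
    MICROHOMOLOGY,
    TRANSPOSITION,
    SimulationConfig,
    generate_host_contigs,
    generate_viral_genome,
    read_pairs,
    scan_motif,
    simulate_population,
)


def small_cfg(**kw):
    defaults = dict(
        seed=7,
        genome_length=10_000,
        n_genomes=50,
        lambda_insertions=0.1,
        target_depth=1.0,
        n_te_families=2,
        n_unknown_contigs=2,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(gc_content=1.5),
            dict(read_length=75),
            dict(lambda_insertions=-0.1),
            dict(genome_length=500),
            dict(alphabet="ACGU"),
            dict(te_length=24),  # TIR >= te_length/2
            dict(insert_size_mean=50.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)


class TestViralGenome:
    def test_identical_seed_gives_identical_genome(self):
        g1 = generate_viral_genome(small_cfg())
        g2 = generate_viral_genome(small_cfg())
        assert g1.sequence == g2.sequence
        assert g1.motif_map == g2.motif_map

    def test_gc_content_matches_request(self):
        g = generate_viral_genome(small_cfg(gc_content=0.40))
        gc = sum(b in "GC" for b in g.sequence) / len(g.sequence)
        assert abs(gc - 0.40) < 0.02

    def test_motif_map_is_exactly_the_rescan(self):
        g = generate_viral_genome(small_cfg())
        for motif, positions in g.motif_map.items():
            text = g.sequence + g.sequence[: len(motif) - 1]
            for p in positions:
                assert text[p : p + len(motif)] == motif
            assert positions == scan_motif(g.sequence, motif)

    def test_overlapping_occurrences_counted(self):
        assert scan_motif("TATAC", "TA", circular=False) == [0, 2]
        # circular: occurrence spanning the origin reported at its start
        assert scan_motif("ACGTT", "TTA", circular=True) == [3]


class TestHostContigs:
    def test_tir_is_reverse_complement_of_other_end(self):
        cfg = small_cfg()
        for c in generate_host_contigs(cfg):
            if c.contig_class == "te":
                t = c.tir_length
                assert t > 0
                assert c.sequence[:t] == revcomp(c.sequence[-t:])
            else:
                assert c.tir_length == 0 and c.family is None

    def test_family_target_motif_annotated(self):
        contigs = generate_host_contigs(small_cfg())
        pb = next(c for c in contigs if c.family == "piggybac")
        assert pb.target_motif == "TTAA"

    def test_unknown_contig_count_contract(self):
        contigs = generate_host_contigs(small_cfg(n_unknown_contigs=3))
        assert sum(c.contig_class == "undetermined" for c in contigs) == 3

    def test_orf_placeholder_is_open_reading_frame(self):
        contigs = generate_host_contigs(small_cfg())
        te = contigs[0]
        lo, hi = te.orf_interval
        orf = te.sequence[lo:hi]
        assert orf.startswith("ATG") and orf.endswith("TAA")
        assert all(
            orf[i : i + 3] not in ("TAA", "TAG", "TGA")
            for i in range(0, len(orf) - 3, 3)
        )


class TestPopulation:
    def test_zero_lambda_means_no_recombinants(self):
        cfg = small_cfg(lambda_insertions=0.0)
        g = generate_viral_genome(cfg)
        pop = simulate_population(g, generate_host_contigs(cfg), cfg)
        assert pop.recombinants == [] and pop.truth == []
        assert pop.n_plain == cfg.n_genomes

    def test_poisson_occupancy_law(self):
        # fraction of genomes with >= 1 insertion converges to 1 - exp(-lambda)
        lam = 0.05
        cfg = small_cfg(lambda_insertions=lam, n_genomes=100_000, seed=3)
        g = generate_viral_genome(cfg)
        pop = simulate_population(g, generate_host_contigs(cfg), cfg)
        p = 1 - math.exp(-lam)
        frac = len(pop.recombinants) / cfg.n_genomes
        sd = math.sqrt(p * (1 - p) / cfg.n_genomes)
        assert abs(frac - p) < 3 * sd

    def test_transposition_interval_spans_the_te_and_abuts_motif(self):
        cfg = small_cfg(lambda_insertions=0.5, transposition_fraction=1.0,
                        n_genomes=200)
        g = generate_viral_genome(cfg)
        contigs = generate_host_contigs(cfg)
        pop = simulate_population(g, contigs, cfg)
        te_len = {c.contig_id: len(c.sequence) for c in contigs}
        motif = {c.contig_id: c.target_motif for c in contigs if c.family}
        assert pop.truth, "no events planted"
        for t in pop.truth:
            assert t.mechanism == TRANSPOSITION
            assert t.contig_interval == (0, te_len[t.contig_id])
            m = motif[t.contig_id]
            assert g.sequence[t.virus_site : t.virus_site + len(m)] == m
            assert t.tsd_length == len(m)

    def test_microhomology_invariant_on_truth(self):
        # the viral flank's last k bases equal the fragment's first k bases
        cfg = small_cfg(
            lambda_insertions=0.5,
            transposition_fraction=0.0,
            blunt_fraction=0.0,
            untemplated_fraction=0.0,
            n_genomes=300,
            seed=5,
        )
        g = generate_viral_genome(cfg)
        contigs = generate_host_contigs(cfg)
        pop = simulate_population(g, contigs, cfg)
        seqs = {c.contig_id: c.sequence for c in contigs}
        planted = [t for t in pop.truth if t.mechanism == MICROHOMOLOGY]
        assert len(planted) > 50
        for t in planted:
            oriented = (
                seqs[t.contig_id]
                if t.orientation == "+"
                else revcomp(seqs[t.contig_id])
            )
            frag = oriented[t.host_left : t.host_right]
            k = t.microhomology_length
            assert k >= 1
            # at least the planted core of the homology (chance extension may
            # push the realized value beyond the geometric draw)
            core = min(k, 20)
            s = t.virus_site
            assert g.sequence[s - core : s] == frag[:core] or any(
                g.sequence[s - m : s] == frag[:m] for m in range(1, core + 1)
            )

    def test_determinism_of_population_and_reads(self):
        cfg = small_cfg(lambda_insertions=0.3, n_genomes=30, target_depth=0.5,
                        pcr_duplicate_rate=0.1, error_rate=0.001)
        g = generate_viral_genome(cfg)
        contigs = generate_host_contigs(cfg)
        p1 = simulate_population(g, contigs, cfg)
        p2 = simulate_population(g, contigs, cfg)
        assert [r.sequence for r in p1.recombinants] == [
            r.sequence for r in p2.recombinants
        ]
        pairs1 = [(p.pair_id, p.seq1, p.seq2) for p in read_pairs(p1, cfg)]
        pairs2 = [(p.pair_id, p.seq1, p.seq2) for p in read_pairs(p2, cfg)]
        assert pairs1 == pairs2


class TestReads:
    def test_error_free_reads_are_substrings_of_circular_genomes(self):
        cfg = small_cfg(lambda_insertions=0.2, n_genomes=40, target_depth=0.8)
        g = generate_viral_genome(cfg)
        pop = simulate_population(g, generate_host_contigs(cfg), cfg)
        doubled = {r.genome_id: r.sequence + r.sequence for r in pop.recombinants}
        ref2 = g.sequence + g.sequence
        for pair in read_pairs(pop, cfg):
            gid = pair.pair_id.rsplit("_", 1)[0]
            text = doubled.get(gid, ref2)
            assert pair.seq1 in text
            assert revcomp(pair.seq2) in text

    def test_read_pair_count_follows_coverage_identity(self):
        cfg = small_cfg(
            genome_length=10_000, n_genomes=10, target_depth=100.0,
            lambda_insertions=0.0,
        )
        g = generate_viral_genome(cfg)
        pop = simulate_population(g, generate_host_contigs(cfg), cfg)
        n = sum(1 for _ in read_pairs(pop, cfg))
        expected = 100 * 100_000 / (2 * 101)
        assert abs(n - expected) / expected < 0.01

    def test_pcr_duplicate_fraction_within_binomial_interval(self):
        cfg = small_cfg(
            genome_length=10_000, n_genomes=21, target_depth=96.0,
            lambda_insertions=0.0, pcr_duplicate_rate=0.1, seed=2,
        )
        g = generate_viral_genome(cfg)
        pop = simulate_population(g, generate_host_contigs(cfg), cfg)
        pairs = list(read_pairs(pop, cfg))
        originals = [p for p in pairs if not p.is_duplicate]
        dups = [p for p in pairs if p.is_duplicate]
        n = len(originals)
        lo, hi = stats.binom.interval(0.99, n, 0.1)
        assert lo <= len(dups) <= hi
        # duplicates are exact copies of their source pair
        by_id = {p.pair_id: p for p in originals}
        for d in dups[:50]:
            src = by_id[d.pair_id.removesuffix("dup")]
            assert (d.seq1, d.seq2) == (src.seq1, src.seq2)

    def test_truth_rows_flag_junction_spanning_reads(self, small_population):
        cfg, pop = small_population
        n_rows = 0
        for pair in read_pairs(pop, cfg):
            for t in pair.truth:
                n_rows += 1
                assert 0 < max(t.x_end, t.y_start) or min(t.x_end, t.y_start) < cfg.read_length
                assert t.overlap == t.x_end - t.y_start
        assert n_rows > 20
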