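"""Junction collapsing, clustering, logos, microhomology and coverage."""

import math

import numpy as np
import pytest
from scipy import stats

from virinflux.align import CONTIG, VIRUS
from virinflux.chimera import classify_intra_read
from virinflux.junctions import (
    CHIMERIC_LEFT,
    HOST_ONLY,
    Junction,
    JunctionCluster,
    build_insertion_logo,
    cluster_junction_sites,
    collapse_junctions,
    contig_coverage,
    microhomology_length,
    microhomology_test,
    null_microhomology_distribution,
    terminal_identity,
)

from conftest import make_record


def _evidence(read_id, library="lib0", host_id="c1", v_subj=1000, h_subj=50,
              host_score=None, mate=1):
    v = make_record(read_id=read_id, mate=mate, subject_kind=VIRUS,
                    read_start=41, read_end=101, subject_start=v_subj)
    h = make_record(read_id=read_id, mate=mate, subject_id=host_id,
                    subject_kind=CONTIG, read_start=1, read_end=42,
                    subject_start=h_subj, score=host_score)
    ev, reason = classify_intra_read(v, h, 101, library_id=library)
    assert reason is None
    return ev


def _junction(contig_pos, virus_pos, side="left", strand="+", reads=1, cid="c1"):
    return Junction(
        offset=virus_pos - contig_pos,
        virus_strand=strand,
        host_strand="+",
        contig_id=cid,
        library_scope=None,
        read_count=reads,
        representative=None,
        virus_position=virus_pos,
        contig_position=contig_pos,
        side=side,
    )


class TestCollapse:
    def test_same_offset_same_library_collapses_with_read_count(self):
        evs = [_evidence(f"r{i}") for i in range(3)]
        js = collapse_junctions(evs)
        assert len(js) == 1 and js[0].read_count == 3

    def test_representative_is_best_host_score(self):
        evs = [
            _evidence("r1", host_score=40),
            _evidence("r2", host_score=55),
            _evidence("r3", host_score=42),
        ]
        js = collapse_junctions(evs)
        assert js[0].representative.read_id == "r2"

    def test_independent_lineages_split_by_library(self):
        evs = [_evidence("r1", library="A"), _evidence("r2", library="B")]
        assert len(collapse_junctions(evs, "independent-lineages")) == 2
        assert len(collapse_junctions(evs, "shared")) == 1

    def test_read_counts_conserve_evidence(self):
        evs = [_evidence(f"r{i}", v_subj=1000 + 10 * (i % 4)) for i in range(12)]
        js = collapse_junctions(evs)
        assert sum(j.read_count for j in js) == len(evs)


class TestClustering:
    def test_two_te_ends_form_two_clusters(self):
        js = [_junction(1, 100 + 7 * i) for i in range(12)] + [
            _junction(4502, 3000 + 11 * i, side="right") for i in range(15)
        ]
        clusters, scattered = cluster_junction_sites(js, min_cluster=10)
        assert len(clusters) == 2 and scattered == []
        ends = sorted((c.contig_end_position, c.side, len(c)) for c in clusters)
        assert ends == [(1, "left", 12), (4502, "right", 15)]
        assert all(j.mechanism == "transposition" for c in clusters for j in c.members)

    def test_nine_junctions_stay_scattered(self):
        js = [_junction(10, 100 + 13 * i) for i in range(9)]
        clusters, scattered = cluster_junction_sites(js, min_cluster=10)
        assert clusters == [] and len(scattered) == 9

    def test_uniformly_spread_junctions_never_cluster(self):
        js = [_junction(100 * i, 50 * i) for i in range(30)]
        clusters, scattered = cluster_junction_sites(js, min_cluster=10)
        assert clusters == [] and len(scattered) == 30

    def test_cluster_counts_distinct_virus_sites_not_reads(self):
        # 12 junctions but only 5 distinct viral sites: not a cluster
        js = [_junction(1, 100 + (i % 5)) for i in range(12)]
        clusters, scattered = cluster_junction_sites(
            js, min_cluster=10, position_tolerance=5
        )
        assert clusters == []

    def test_position_tolerance_chains_nearby_sites(self):
        js = [_junction(1 + (i % 3), 100 + 17 * i) for i in range(12)]
        clusters, _ = cluster_junction_sites(js, min_cluster=10,
                                             position_tolerance=5)
        assert len(clusters) == 1


class TestLogo:
    def _cluster(self, junctions):
        return JunctionCluster("c1", 1, "left", list(junctions),
                               len({j.virus_position for j in junctions}))

    def test_identical_windows_reach_two_bits_everywhere(self):
        genome = "ACGT" * 300
        js = [_junction(1, 100 + 40 * i) for i in range(10)]  # same phase
        logo = build_insertion_logo(self._cluster(js), genome)
        assert np.allclose(logo.information, 2.0)

    def test_planted_motif_carries_the_information(self):
        rng = np.random.default_rng(12)
        genome = list("".join("ACGT"[i] for i in rng.integers(0, 4, 30_000)))
        sites = rng.choice(np.arange(100, 29_000), size=200, replace=False)
        for s in sites:
            genome[s - 4 : s] = list("TTAA")  # motif just upstream of breakpoint
        genome = "".join(genome)
        js = [_junction(1, int(s)) for s in sites]
        logo = build_insertion_logo(self._cluster(js), genome)
        motif_positions = [11, 12, 13, 14]  # breakpoint at 15; motif = [bp-4, bp)
        assert all(logo.information[p] >= 1.8 for p in motif_positions)
        others = [i for i in range(30) if i not in motif_positions]
        assert all(logo.information[i] <= 0.15 for i in others)
        top4 = set(np.argsort(logo.information)[-4:])
        assert top4 == set(motif_positions)

    def test_minus_strand_windows_are_reverse_complemented(self):
        genome = "".join(
            "ACGT"[i] for i in np.random.default_rng(3).integers(0, 4, 5000)
        )
        plus = [_junction(1, 200 + 31 * i) for i in range(10)]
        minus = [_junction(1, 200 + 31 * i, strand="-") for i in range(10)]
        lp = build_insertion_logo(self._cluster(plus), genome)
        lm = build_insertion_logo(self._cluster(minus), genome)
        assert np.allclose(lp.frequencies, lm.frequencies[::-1, ::-1])

    def test_small_cluster_refused(self):
        js = [_junction(1, 100 + 40 * i) for i in range(9)]
        with pytest.raises(ValueError, match="9 members"):
            build_insertion_logo(self._cluster(js), "ACGT" * 300)


class TestMicrohomology:
    def test_five_base_microhomology(self):
        # viral flank ends ACGTG; host fragment begins ACGTG, 6th base differs
        assert microhomology_length("ACGTGTCCAG", "ACGTGAAAA") == 5

    def test_blunt_junction_is_zero(self):
        assert microhomology_length("AAAAA", "CCCCC") == 0

    def test_untemplated_bases_are_negative(self):
        assert microhomology_length("AAAAA", "CCCCC", untemplated_gap=2) == -2
        assert microhomology_length("AAAAA", "CCCCC", untemplated_gap=1) == -1

    def test_capped_at_twenty(self):
        s = "ACGTG" * 6
        assert microhomology_length(s, s, cap=20) == 20


class TestNullDistribution:
    def test_disjoint_alphabets_put_all_mass_at_zero(self):
        dist = null_microhomology_distribution(["C" * 20] * 5, "A" * 1000, seed=1)
        assert dist[0] == pytest.approx(5.0) and dist[1:].sum() == 0

    def test_uniform_bases_follow_geometric_law(self):
        rng = np.random.default_rng(9)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000))
        seqs = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, 20)) for _ in range(2000)
        ]
        dist = null_microhomology_distribution(seqs, genome, n_random=20, seed=4)
        # P(length = 3) = 4^-3 * 3/4
        expected3 = 2000 * (1 / 64) * (3 / 4)
        assert abs(dist[3] - expected3) < 6
        assert dist[0] == pytest.approx(2000 * 0.75, rel=0.05)

    def test_fixed_seed_reproduces_distribution(self):
        genome = "ACGT" * 2500
        seqs = ["ACGTACGTACGTACGTACGT"] * 7
        d1 = null_microhomology_distribution(seqs, genome, seed=5)
        d2 = null_microhomology_distribution(seqs, genome, seed=5)
        assert np.array_equal(d1, d2)


class TestChiSquare:
    def test_equal_distributions_give_zero_statistic(self):
        obs = np.array([50.0, 30, 10, 5, 5] + [0] * 16)
        stat, df, p, _ = microhomology_test(obs, obs.copy())
        assert stat == 0 and p == pytest.approx(1.0)

    def test_single_displaced_bin_contributes_d2_over_e(self):
        exp = np.array([100.0, 50.0])
        obs = np.array([90.0, 60.0])
        stat, df, p, merges = microhomology_test(obs, exp, min_expected=0)
        assert stat == pytest.approx(10 ** 2 / 100 + 10 ** 2 / 50)
        assert df == 1 and merges == []

    def test_full_21_bins_keep_20_degrees_of_freedom(self):
        exp = np.linspace(40, 20, 21)
        obs = exp.copy()
        _, df, _, merges = microhomology_test(obs, exp, min_expected=0)
        assert df == 20 and merges == []

    def test_small_expected_bins_merge_into_tail(self):
        exp = np.array([100.0, 20.0, 3.0, 1.0])
        obs = np.array([99.0, 21.0, 2.0, 2.0])
        stat, df, p, merges = microhomology_test(obs, exp, min_expected=5)
        assert df == 1 and len(merges) == 2

    def test_mismatched_totals_rejected(self):
        with pytest.raises(ValueError):
            microhomology_test(np.array([1.0, 2.0]), np.array([1.0, 1.0]))

    def test_null_simulated_pvalues_are_uniform(self):
        # observed counts drawn from the expected distribution itself
        rng = np.random.default_rng(17)
        probs = np.array([(1 / 4) ** k * (3 / 4) for k in range(20)] + [(1 / 4) ** 20])
        n = 2000
        expected = probs * n
        pvals = []
        for _ in range(200):
            obs = rng.multinomial(n, probs).astype(float)
            _, _, p, _ = microhomology_test(obs, expected)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestContigCoverage:
    def test_single_read_covering_one_window(self):
        profiles = contig_coverage([(40, 60, HOST_ONLY)], contig_length=100)
        host = profiles[HOST_ONLY]
        # window grid: starts at 0, 10, ..., 80; read covers [40, 60)
        assert host[4] == pytest.approx(1.0)  # window [40, 60) fully covered
        assert host[3] == pytest.approx(0.5) and host[5] == pytest.approx(0.5)
        assert host[0] == 0 and host[8] == 0
        assert np.all(profiles[CHIMERIC_LEFT] == 0)

    def test_uniform_coverage_stays_in_poisson_band(self):
        rng = np.random.default_rng(23)
        contig_len = 2000
        reads = []
        depth = 100
        n_reads = depth * contig_len // 50
        for s in rng.integers(-49, contig_len, size=n_reads):
            reads.append((int(s), int(s) + 50, HOST_ONLY))
        prof = contig_coverage(reads, contig_len)[HOST_ONLY]
        interior = prof[10:-10]
        band = 3 * math.sqrt(depth)
        assert np.all(np.abs(interior - depth) < band)

    def test_empty_alignments_give_zero_profiles(self):
        profiles = contig_coverage([], contig_length=55)
        assert all(np.all(v == 0) for v in profiles.values())
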