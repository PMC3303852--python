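import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import viromekit as vk
from viromekit.synthdata import (ABUNDANCE_FAMILIES, Community, PanelSpec,
                                 ReadSimParams, make_panel, mutate_protein,
                                 parse_read_id, plant_marker,
                                 reverse_translate, sample_abundances,
                                 simulate_reads)


class TestSampleAbundances:
    def test_power_small_case(self):
        # a_i proportional to 1/i for S=3: (1, 1/2, 1/3) / (11/6)
        a = sample_abundances("power", 3, {"b": 1})
        np.testing.assert_allclose(a, [6 / 11, 3 / 11, 2 / 11])

    def test_single_virotype(self):
        np.testing.assert_allclose(sample_abundances("broken_stick", 1), [1.0])

    def test_exponential_closed_form(self):
        # independent recomputation: a_i = e^{-b i} / sum_j e^{-b j}
        b, S = 0.5, 4
        raw = [math.exp(-b * i) for i in range(1, S + 1)]
        expect = np.array(raw) / sum(raw)
        np.testing.assert_allclose(
            sample_abundances("exponential", S, {"b": b}), expect, rtol=1e-12)

    def test_broken_stick_closed_form(self):
        # expected ordered fractions: a_i = (1/S) sum_{k=i}^S 1/k
        S = 6
        expect = [sum(1 / k for k in range(i, S + 1)) / S
                  for i in range(1, S + 1)]
        np.testing.assert_allclose(
            sample_abundances("broken_stick", S), expect, rtol=1e-12)

    def test_unknown_family_lists_supported(self):
        with pytest.raises(ValueError, match="power"):
            sample_abundances("zipf", 3)

    def test_non_finite_params_rejected(self):
        with pytest.raises(ValueError):
            sample_abundances("power", 3, {"b": float("nan")})

    @settings(deadline=None, max_examples=40)
    @given(family=st.sampled_from(ABUNDANCE_FAMILIES),
           S=st.integers(min_value=1, max_value=200))
    def test_normalized_and_sorted(self, family, S):
        a = sample_abundances(family, S)
        assert abs(a.sum() - 1.0) < 1e-12
        assert np.all(np.diff(a) <= 1e-15)
        assert len(a) == S


class TestMakeCommunity:
    def test_single_genome(self):
        c = vk.make_community(1, 10000, "power", {"b": 1}, seed=1)
        assert c.S == 1
        assert len(c.genomes[0][1]) == 10000
        np.testing.assert_allclose(c.abundances, [1.0])

    def test_seed_determinism(self):
        c1 = vk.make_community(10, 1000, "power", {"b": 1}, seed=5)
        c2 = vk.make_community(10, 1000, "power", {"b": 1}, seed=5)
        c3 = vk.make_community(10, 1000, "power", {"b": 1}, seed=6)
        assert c1.genomes == c2.genomes
        assert c1.genomes != c3.genomes

    def test_rank1_abundance_closed_form(self):
        c = vk.make_community(300, 5000, "power", {"b": 1.2}, seed=7)
        norm = sum(i ** -1.2 for i in range(1, 301))
        assert c.abundances[0] == pytest.approx(1.0 / norm, rel=1e-12)

    def test_short_genomes_rejected(self):
        with pytest.raises(ValueError, match="500"):
            vk.make_community(2, 100, "power", {"b": 1})


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self):
        c = vk.make_community(1, 2000, "power", {"b": 1}, seed=2)
        rs = simulate_reads(c, ReadSimParams(n_reads=10, read_len=100, seed=3))
        genome = c.genomes[0][1]
        assert len(rs) == 10
        for rid, seq in rs:
            assert seq in genome
            truth = parse_read_id(rid)
            assert genome[truth["pos"]: truth["pos"] + 100] == seq

    def test_duplicate_construction(self, small_community):
        rs = simulate_reads(small_community, ReadSimParams(
            n_reads=100, read_len=100, dup_fraction=0.5, seed=4))
        dups = [rid for rid, _ in rs if parse_read_id(rid)["dup"] == 1]
        assert len(dups) == 50

    def test_zero_reads_empty(self, small_community):
        rs = simulate_reads(small_community,
                            ReadSimParams(n_reads=0, read_len=100, seed=1))
        assert len(rs) == 0

    def test_read_longer_than_genome_rejected(self, small_community):
        with pytest.raises(ValueError, match="read_len"):
            simulate_reads(small_community,
                           ReadSimParams(n_reads=5, read_len=5000, seed=1))

    def test_genome_share_tracks_abundance(self):
        genomes = vk.make_community(2, 2000, "power", {"b": 1}, seed=9).genomes
        comm = Community(genomes=genomes, abundances=np.array([0.9, 0.1]))
        n = 20000
        rs = simulate_reads(comm, ReadSimParams(n_reads=n, read_len=100, seed=5))
        share = sum(parse_read_id(r)["src"] == "g0" for r, _ in rs) / n
        sd = math.sqrt(0.9 * 0.1 / n)
        assert abs(share - 0.9) < 3 * sd

    def test_error_rate_applied(self, small_community):
        rs = simulate_reads(small_community, ReadSimParams(
            n_reads=50, read_len=100, error_rate=0.1, seed=6))
        genomes = dict(small_community.genomes)
        mism = 0
        for rid, seq in rs:
            t = parse_read_id(rid)
            ref = genomes[t["src"]][t["pos"]: t["pos"] + 100]
            mism += sum(a != b for a, b in zip(seq, ref))
        rate = mism / (50 * 100)
        assert 0.07 < rate < 0.13

    def test_seed_changes_output(self, small_community):
        p1 = ReadSimParams(n_reads=20, read_len=100, seed=1)
        p2 = ReadSimParams(n_reads=20, read_len=100, seed=2)
        r1 = simulate_reads(small_community, p1)
        r1b = simulate_reads(small_community, p1)
        r2 = simulate_reads(small_community, p2)
        assert r1.sequences == r1b.sequences
        assert r1.sequences != r2.sequences


class TestPlantMarker:
    @pytest.fixture()
    def marker(self, rng):
        return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))

    def test_zero_divergence_back_translates_exactly(self, small_community,
                                                     marker):
        planted, truth = plant_marker(small_community, marker, [0.0], seed=1)
        for (gid, seq), t in zip(planted.genomes, truth):
            insert = seq[t["locus"]: t["locus"] + 3 * len(marker)]
            assert insert == reverse_translate(marker)
            assert t["protein"] == marker

    def test_forced_mutation_count(self, small_community, marker):
        planted, truth = plant_marker(small_community, marker, [0.2], seed=2)
        for t in truth:
            diff = sum(a != b for a, b in zip(t["protein"], marker))
            assert diff == 40  # 0.2 * 200

    def test_pairwise_divergence_consistent(self, marker, rng):
        # independent mutations at 5% and 40%: direct count of differences
        m1 = mutate_protein(marker, 0.05, rng)
        m2 = mutate_protein(marker, 0.40, rng)
        diff = sum(a != b for a, b in zip(m1, m2)) / len(marker)
        # between d1+d2 minus maximal overlap and d1+d2
        assert 0.3 <= diff <= 0.45

    def test_marker_too_long_rejected(self, marker):
        c = vk.make_community(1, 500, "power", {"b": 1}, seed=1)
        with pytest.raises(ValueError, match="fit"):
            plant_marker(c, marker, [0.1], seed=1)


class TestMakePanel:
    def test_full_sharing_identical_communities(self):
        spec = PanelSpec(1, 2, 5, within_share=1.0, between_share=0.0, seed=1)
        panel, truth = make_panel(
            spec, ReadSimParams(n_reads=50, read_len=100, seed=1),
            genome_len=1000)
        v1, v2 = truth["genomes"].values()
        assert v1 == v2

    def test_no_between_group_sharing(self):
        spec = PanelSpec(2, 2, 10, within_share=0.5, between_share=0.0, seed=2)
        _, truth = make_panel(
            spec, ReadSimParams(n_reads=20, read_len=100, seed=1),
            genome_len=1000)
        g0 = truth["genomes"]["G0V0"] | truth["genomes"]["G0V1"]
        g1 = truth["genomes"]["G1V0"] | truth["genomes"]["G1V1"]
        assert not (g0 & g1)

    def test_within_jaccard_exceeds_between(self):
        spec = PanelSpec(3, 3, 20, within_share=0.6, between_share=0.05,
                         seed=11)
        _, truth = make_panel(
            spec, ReadSimParams(n_reads=20, read_len=100, seed=1),
            genome_len=1000)

        def jac(a, b):
            return len(a & b) / len(a | b)

        names = list(truth["genomes"])
        within, between = [], []
        for i, x in enumerate(names):
            for y in names[i + 1:]:
                j = jac(truth["genomes"][x], truth["genomes"][y])
                (within if truth["groups"][x] == truth["groups"][y]
                 else between).append(j)
        assert np.mean(within) > np.mean(between)

    def test_share_ordering_enforced(self):
        with pytest.raises(ValueError):
            PanelSpec(2, 2, 10, within_share=0.2, between_share=0.5)
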