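import numpy as np
import pytest

import viromekit as vk
from viromekit.seqio import ReadSet
from viromekit.specrich import (ContigSpectrum, LWParams, assemble_strict,
                                expected_spectrum, fit_richness)
from viromekit.synthdata import RankAbundanceModel


class TestContigSpectrum:
    def test_read_conservation_enforced(self):
        ContigSpectrum(counts=[3, 2, 1], n_reads=10)  # 3 + 4 + 3
        with pytest.raises(ValueError, match="conservation"):
            ContigSpectrum(counts=[3, 2, 1], n_reads=11)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContigSpectrum(counts=[-1, 1], n_reads=1)


class TestAssembleStrict:
    def test_disjoint_reads_stay_singletons(self, rng):
        rs = ReadSet(name="x", reads=[
            ("a", "".join(rng.choice(list("ACGT"), 100))),
            ("b", "".join(rng.choice(list("ACGT"), 100)))])
        contigs, spec = assemble_strict(rs)
        assert list(spec.counts) == [2]
        assert len(contigs) == 2

    def test_fifty_bp_overlap_merges(self, rng):
        g = "".join(rng.choice(list("ACGT"), 150))
        rs = ReadSet(name="x", reads=[("a", g[:100]), ("b", g[50:150])])
        contigs, spec = assemble_strict(rs)
        assert list(spec.counts) == [0, 1]
        assert contigs[0].sequence == g

    def test_tiling_reads_one_contig(self, rng):
        genome = "".join(rng.choice(list("ACGT"), 2000))
        starts = [19 * i for i in range(100)]  # 0..1881, 81-bp overlaps
        reads = [(f"r{i:03d}", genome[s: s + 100])
                 for i, s in enumerate(starts)]
        rs = ReadSet(name="tile", reads=reads)
        contigs, spec = assemble_strict(rs)
        assert len(contigs) == 1
        assert len(contigs[0].read_ids) == 100
        assert spec.counts[-1] == 1 and spec.max_q == 100
        assert contigs[0].sequence == genome[: starts[-1] + 100]

    def test_min_overlap_boundary(self, rng):
        g = "".join(rng.choice(list("ACGT"), 200))
        # overlap exactly 35: merges
        rs35 = ReadSet(name="x", reads=[("a", g[:100]), ("b", g[65:165])])
        _, spec35 = assemble_strict(rs35, min_overlap=35)
        assert list(spec35.counts) == [0, 1]
        # overlap 30 < 35: stays apart
        rs30 = ReadSet(name="y", reads=[("a", g[:100]), ("b", g[70:170])])
        _, spec30 = assemble_strict(rs30, min_overlap=35)
        assert list(spec30.counts) == [2]

    def test_matches_position_truth_islands(self):
        # error-free reads: contigs must be exactly the "islands" of
        # reads chained by >= t bp overlaps, computable from the true
        # start positions on the (circular) genome
        import viromekit as vk
        from viromekit.synthdata import parse_read_id

        l, t, L, n = 100, 35, 4000, 120
        comm = vk.make_community(1, L, "power", {"b": 1}, seed=21)
        rs = vk.simulate_reads(comm, vk.ReadSimParams(
            n_reads=n, read_len=l, circular=True, seed=22))
        pos = sorted(parse_read_id(rid)["pos"] for rid, _ in rs)
        links = [(pos[(i + 1) % n] - pos[i]) % L <= (l - t)
                 for i in range(n)]
        sizes = []
        if all(links):
            sizes = [n]
        else:
            start = links.index(False) + 1
            size = 1
            for k in range(n - 1):
                if links[(start + k) % n]:
                    size += 1
                else:
                    sizes.append(size)
                    size = 1
            sizes.append(size)
        want = np.bincount(sizes)[1:]
        _, spec = assemble_strict(rs, min_overlap=t)
        np.testing.assert_array_equal(spec.counts, want)

    def test_spectrum_conservation_on_simulations(self):
        for seed in range(3):
            comm = vk.make_community(10, 1500, "power", {"b": 1}, seed=seed)
            rs = vk.simulate_reads(comm, vk.ReadSimParams(
                n_reads=400, read_len=100, error_rate=0.01, seed=seed))
            _, spec = assemble_strict(rs)
            q = np.arange(1, spec.max_q + 1)
            assert int((q * spec.counts).sum()) == len(rs)


class TestExpectedSpectrum:
    LW = LWParams(read_len=100, min_overlap=35, avg_genome_len=10000)

    def test_zero_coverage_limit(self):
        model = RankAbundanceModel("power", 3, {"b": 1})
        E, _ = expected_spectrum(model, 2, LWParams(
            read_len=100, min_overlap=35, avg_genome_len=10**9), Q=4)
        assert E[0] == pytest.approx(2, rel=1e-4)
        assert np.all(E[1:] < 1e-3)

    def test_series_closure(self):
        model = RankAbundanceModel("exponential", 10, {"b": 0.3})
        n = 500
        E, tail = expected_spectrum(model, n, self.LW, Q=4000)
        total = (np.arange(1, 4001) * E).sum()
        assert total == pytest.approx(n, rel=1e-6)
        assert tail == pytest.approx(n - total, abs=1e-6)

    def test_tail_reported(self):
        model = RankAbundanceModel("power", 1, {"b": 1})
        n = 200
        E, tail = expected_spectrum(model, n, LWParams(
            read_len=100, min_overlap=35, avg_genome_len=2000), Q=3)
        assert tail > 0
        assert tail == pytest.approx(n - (np.arange(1, 4) * E).sum())

    def test_invalid_Q(self):
        with pytest.raises(ValueError):
            expected_spectrum(RankAbundanceModel("power", 1, {"b": 1}),
                              10, self.LW, Q=0)


class TestLWParams:
    def test_invariants(self):
        with pytest.raises(ValueError):
            LWParams(read_len=30, min_overlap=35, avg_genome_len=1000)
        assert LWParams(read_len=100, min_overlap=35,
                        avg_genome_len=1000).sigma == pytest.approx(0.65)


class TestFitRichness:
    LW = LWParams(read_len=100, min_overlap=35, avg_genome_len=5000)

    def test_self_consistency_on_exact_spectrum(self):
        # spectrum generated from the model's own expectation (rounded);
        # Q large enough that essentially no read mass is truncated
        lw = LWParams(read_len=100, min_overlap=35, avg_genome_len=50000)
        model = RankAbundanceModel("power", 100, {"b": 1.0})
        n = 10000
        E, _ = expected_spectrum(model, n, lw, Q=400)
        counts = np.round(E).astype(int)
        n_eff = int((np.arange(1, 401) * counts).sum())
        assert abs(n_eff - n) < 0.03 * n  # rounding only
        obs = ContigSpectrum(counts=counts, n_reads=n_eff)
        est = fit_richness(obs, lw)
        assert est.best_model.family == "power"
        assert 80 <= est.S_hat <= 125  # within the refinement grid cell
        assert est.evenness == pytest.approx(
            est.shannon / np.log(est.S_hat), rel=1e-9)

    def test_single_genome_spectrum(self):
        counts = np.zeros(200, dtype=int)
        counts[-1] = 1  # one contig of 200 reads
        obs = ContigSpectrum(counts=counts, n_reads=200)
        est = fit_richness(obs, self.LW)
        assert est.S_hat == 1
        assert est.evenness == 1.0  # convention for S_hat = 1

    def test_warns_on_tiny_spectrum(self):
        obs = ContigSpectrum(counts=[10], n_reads=10)
        with pytest.warns(UserWarning, match="poorly constrained"):
            fit_richness(obs, self.LW, families=("power",), S_max=100)

    def test_unknown_family_rejected(self):
        obs = ContigSpectrum(counts=[100], n_reads=100)
        with pytest.raises(ValueError, match="zipf"):
            fit_richness(obs, self.LW, families=("zipf",))

    def test_fit_table_covers_families_and_best_is_minimal(self):
        model = RankAbundanceModel("exponential", 30, {"b": 0.2})
        E, _ = expected_spectrum(model, 5000, self.LW, Q=40)
        counts = np.round(E).astype(int)
        obs = ContigSpectrum(counts=counts,
                             n_reads=int((np.arange(1, 41) * counts).sum()))
        est = fit_richness(obs, self.LW)
        fams = {row["family"] for row in est.fit_table}
        assert fams == set(vk.synthdata.ABUNDANCE_FAMILIES)
        assert est.fit_error == min(row["error"] for row in est.fit_table)
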