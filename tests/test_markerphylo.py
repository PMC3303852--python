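import networkx as nx
import pytest

from viromekit import markerphylo as mp
from viromekit import synthdata
from viromekit.experiments import make_marker_reference
from viromekit.seqio import ReadSet
from viromekit.specrich import Contig


@pytest.fixture(scope="module")
def marker():
    return make_marker_reference(seed=1)


class TestMarkerReference:
    def test_needs_three_rows(self):
        with pytest.raises(ValueError):
            mp.MarkerReference(name="m", ids=["a", "b"], rows=["AA", "AA"])

    def test_rows_same_length(self):
        with pytest.raises(ValueError, match="length"):
            mp.MarkerReference(name="m", ids=list("abc"),
                               rows=["AAA", "AA", "AAA"])

    def test_fasta_round_trip(self, marker, tmp_path):
        p = tmp_path / "ref.afa"
        with open(p, "w") as fh:
            for rid, row in zip(marker.ids, marker.rows):
                fh.write(f">{rid}\n{row}\n")
        back = mp.load_reference_alignment(p, name="m")
        assert back.ids == marker.ids
        assert back.rows == marker.rows


class TestRecruit:
    def test_verbatim_back_translation_recruited(self, marker):
        nt = synthdata.reverse_translate(marker.rows[0][:140])
        rs = ReadSet(name="x", reads=[("r0", nt)])
        rec = mp.recruit(rs, marker)
        assert len(rec) == 1
        assert rec[0].frame == 0

    def test_reverse_strand_frame_detected(self, marker):
        from Bio.Seq import Seq

        nt = synthdata.reverse_translate(marker.rows[0][:140])
        rc = str(Seq(nt).reverse_complement())
        rec = mp.recruit(ReadSet(name="x", reads=[("r0", rc)]), marker)
        assert len(rec) == 1
        assert rec[0].frame >= 3

    def test_random_reads_not_recruited(self, marker, rng):
        reads = [(f"r{i}", "".join(rng.choice(list("ACGT"), 420)))
                 for i in range(300)]
        rec = mp.recruit(ReadSet(name="x", reads=reads), marker)
        assert len(rec) <= 1  # false-recruit rate well under 1%

    def test_diverged_copy_recruited(self, marker, rng):
        prot = synthdata.mutate_protein(marker.rows[0], 0.2, rng)
        nt = synthdata.reverse_translate(prot)
        rec = mp.recruit(ReadSet(name="x", reads=[("r0", nt[60:480])]), marker)
        assert len(rec) == 1


class TestAssembleRecruited:
    def test_overlapping_recruits_merge(self, marker):
        nt = synthdata.reverse_translate(marker.rows[0])
        reads = [("a", nt[0:420]), ("b", nt[360:780])]
        rec = mp.recruit(ReadSet(name="x", reads=reads), marker)
        contigs = mp.assemble_recruited(rec)
        assert len(contigs) == 1
        assert sorted(contigs[0].read_ids) == ["a", "b"]

    def test_divergent_markers_never_coassemble(self, marker, rng):
        p1 = marker.rows[0]
        p2 = synthdata.mutate_protein(p1, 0.4, rng)
        reads = [("a", synthdata.reverse_translate(p1)[:420]),
                 ("b", synthdata.reverse_translate(p2)[:420])]
        rec = mp.recruit(ReadSet(name="x", reads=reads), marker)
        contigs = mp.assemble_recruited(rec)
        assert len(contigs) == 2

    def test_singleton_passthrough(self, marker):
        nt = synthdata.reverse_translate(marker.rows[0][:140])
        rec = mp.recruit(ReadSet(name="x", reads=[("solo", nt)]), marker)
        contigs = mp.assemble_recruited(rec)
        assert len(contigs) == 1
        assert contigs[0].read_ids == ["solo"]


class TestAlignToReference:
    def test_fragment_bounds(self, marker):
        frag = marker.rows[0][10:60]
        contig = Contig(read_ids=["c"],
                        sequence=synthdata.reverse_translate(frag))
        aligned, dropped = mp.align_to_reference([contig], marker)
        assert not dropped
        assert (aligned[0].start, aligned[0].end) == (10, 60)
        assert aligned[0].ref_id == marker.ids[0]

    def test_full_reference_spans_all_columns(self, marker):
        contig = Contig(read_ids=["c"],
                        sequence=synthdata.reverse_translate(marker.rows[0]))
        aligned, _ = mp.align_to_reference([contig], marker)
        assert (aligned[0].start, aligned[0].end) == (0, marker.n_columns)

    def test_short_fragment_dropped_with_reason(self, marker):
        contig = Contig(read_ids=["c"],
                        sequence=synthdata.reverse_translate(
                            marker.rows[0][:15]))
        aligned, dropped = mp.align_to_reference([contig], marker)
        assert not aligned
        assert dropped and "aa" in dropped[0]["reason"]

    def test_planted_locus_maps_back(self, marker, rng):
        frag = synthdata.mutate_protein(marker.rows[2][100:200], 0.05, rng)
        contig = Contig(read_ids=["c"], sequence=synthdata.reverse_translate(frag))
        aligned, _ = mp.align_to_reference([contig], marker)
        assert abs(aligned[0].start - 100) <= 2
        assert abs(aligned[0].end - 200) <= 2


class TestPartition:
    def test_single_window(self):
        comps = mp.interval_components([(0, 100), (10, 90), (5, 95)])
        assert comps == [[0, 1, 2]]

    def test_disjoint_halves(self):
        comps = mp.interval_components([(0, 50), (50, 100), (5, 45)])
        assert comps == [[0, 2], [1]]

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 30))
            bounds = []
            for _ in range(n):
                s = int(rng.integers(0, 300))
                bounds.append((s, s + int(rng.integers(10, 120))))
            got = mp.interval_components(bounds)
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    s1, e1 = bounds[i]
                    s2, e2 = bounds[j]
                    ov = min(e1, e2) - max(s1, s2)
                    if ov >= 0.5 * min(e1 - s1, e2 - s2):
                        g.add_edge(i, j)
            want = sorted(sorted(c) for c in nx.connected_components(g))
            assert sorted(got) == want

    def test_partition_is_exhaustive(self, marker, rng):
        frags = [(10, 80), (15, 90), (200, 300), (205, 305), (350, 380)]
        aligned = []
        for i, (s, e) in enumerate(frags):
            frag = marker.rows[0][s:e]
            contig = Contig(read_ids=[f"c{i}"],
                            sequence=synthdata.reverse_translate(frag))
            a, _ = mp.align_to_reference([contig], marker)
            aligned.extend(a)
        subs, small = mp.partition_subalignments(aligned, min_members=2)
        assigned = [m for s in subs + small for m in s.member_ids]
        assert sorted(assigned) == sorted(a.contig_id for a in aligned)
        assert len(subs) == 2 and len(small) == 1


class TestCurateBlocks:
    def _sub(self, rows, start=0):
        return mp.SubAlignment(start=start, end=start + len(rows[0]),
                               member_ids=[f"m{i}" for i in range(len(rows))],
                               member_rows=rows)

    def test_gap_free_unchanged(self):
        rows = ["ACDEFGHIKLMNPQRSTVWY" * 2] * 4
        cur = mp.curate_blocks(self._sub(rows))
        assert cur.rows == rows
        assert cur.n_columns == 40

    def test_all_gap_column_removed_flanks_joined(self):
        left = "ACDEFGHIKLMNPQRSTVWY"
        right = "YWVTSRQPNMLKIHGFEDCA"
        rows = [left + "-" + right] * 4
        cur = mp.curate_blocks(self._sub(rows))
        assert cur.rows == [left + right] * 4
        assert 20 not in cur.kept_columns

    def test_short_survivor_rejected(self):
        rows = ["ACDEFGHIKL" + "-" * 30] * 4
        with pytest.raises(mp.BlockCurationError, match="survive"):
            mp.curate_blocks(self._sub(rows))

    def test_curated_never_longer(self, rng):
        for _ in range(10):
            ncol = int(rng.integers(25, 60))
            rows = ["".join(rng.choice(list("ACDEFG-"), ncol))
                    for _ in range(6)]
            try:
                cur = mp.curate_blocks(self._sub(rows))
            except mp.BlockCurationError:
                continue
            assert cur.n_columns <= ncol


class TestRankAndSelect:
    def _cur(self, n_cols, n_ids, start):
        return mp.CuratedAlignment(
            ids=[f"s{i}" for i in range(n_ids)],
            rows=["A" * n_cols] * n_ids,
            kept_columns=list(range(start, start + n_cols)),
            source_interval=(start, start + n_cols))

    def test_keeps_all_when_fewer_than_k(self):
        subs = [self._cur(30, 5, 0), self._cur(50, 4, 10), self._cur(40, 6, 5)]
        sel = mp.rank_and_select(subs, k=10)
        assert [s.n_columns for s in sel] == [50, 40, 30]

    def test_member_count_breaks_ties(self):
        subs = [self._cur(30, 5, 0), self._cur(30, 9, 10)]
        sel = mp.rank_and_select(subs, k=10)
        assert len(sel[0].ids) == 9

    def test_permutation_invariant(self):
        subs = [self._cur(30, 5, 0), self._cur(30, 5, 10), self._cur(45, 2, 3)]
        a = mp.rank_and_select(subs, k=2)
        b = mp.rank_and_select(subs[::-1], k=2)
        assert [(s.n_columns, s.source_interval) for s in a] == \
            [(s.n_columns, s.source_interval) for s in b]


class TestBuildTree:
    def test_two_pair_topology_recovered(self, rng):
        base1 = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 120))
        base2 = synthdata.mutate_protein(base1, 0.5, rng)
        rows = [base1, synthdata.mutate_protein(base1, 0.05, rng),
                base2, synthdata.mutate_protein(base2, 0.05, rng)]
        cur = mp.CuratedAlignment(ids=["a1", "a2", "b1", "b2"], rows=rows,
                                  kept_columns=list(range(120)),
                                  source_interval=(0, 120))
        tree = mp.build_tree(cur, n_boot=50, seed=1)
        bips = mp._bipartitions(tree.tree, frozenset(cur.ids))
        canon = min((frozenset({"a1", "a2"}), frozenset({"b1", "b2"})),
                    key=lambda s: sorted(s))
        assert canon in bips
        assert tree.support[canon] >= 0.9

    def test_identical_sequences_zero_lengths(self):
        rows = ["ACDEFGHIKLMNPQRSTVWY"] * 4
        cur = mp.CuratedAlignment(ids=list("abcd"), rows=rows,
                                  kept_columns=list(range(20)),
                                  source_interval=(0, 20))
        with pytest.warns(UserWarning, match="identical"):
            tree = mp.build_tree(cur, n_boot=0, seed=0)
        for node in tree.tree.traverse():
            if node.length is not None:
                assert node.length == pytest.approx(0.0, abs=1e-9)

    def test_needs_four_rows(self):
        cur = mp.CuratedAlignment(ids=["a", "b", "c"], rows=["AA"] * 3,
                                  kept_columns=[0, 1], source_interval=(0, 2))
        with pytest.raises(ValueError):
            mp.build_tree(cur)

    def test_external_hook(self):
        rows = ["ACDEFGHIKL", "ACDEFGHIKV", "MNPQRSTVWY", "MNPQRSTVWF"]
        cur = mp.CuratedAlignment(ids=["a", "b", "c", "d"], rows=rows,
                                  kept_columns=list(range(10)),
                                  source_interval=(0, 10))

        def hook(ids, rows):
            return "((a:1,b:1):1,(c:1,d:1):1);"

        tree = mp.build_tree(cur, n_boot=5, seed=0,
                             method="external-ml-hook", external_hook=hook)
        names = {t.name for t in tree.tree.tips()}
        assert names == {"a", "b", "c", "d"}
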