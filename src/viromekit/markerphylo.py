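"""Marker-gene phylogeny of metagenomic reads.

Short shotgun reads never cover a full marker gene (capsid, terminase,
replication-initiator genes run 600-1500 bp), so placing virome reads in a
marker phylogeny takes a dedicated pipeline:

1. recruit reads homologous to the marker (six-frame translated search
   against the ungapped reference proteins, same significance cutoff as
   the cross-virome scorer);
2. assemble the recruits at high stringency (98% identity over >= 35 bp,
   so only same-virotype reads merge) to lengthen the fragments;
3. align each contig peptide to the fixed reference alignment (reference
   columns immutable; insertions relative to the reference are discarded
   and counted) and record its column bounds;
4. group contigs whose bounds overlap reciprocally (>= 50% of the shorter
   interval) into sub-alignments -- one tree per window instead of one
   per read;
5. curate each sub-alignment with a simple block filter (drop columns
   with > 50% gaps, keep runs of >= 10 surviving columns);
6. build a neighbor-joining tree per curated sub-alignment with bootstrap
   support from column resampling (an external maximum-likelihood hook
   can replace the built-in NJ).

All alignment coordinates are 0-based half-open reference columns;
everything downstream of recruitment lives in amino-acid space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from . import simsearch
from .seqio import ReadSet
from .specrich import Contig, assemble_strict

GAP = "-"

# recruitment searches a read against a whole reference panel (several
# proteins of marker length), a larger null space than the read-vs-read
# comparison the shared scorer default was calibrated for; 50 holds the
# false-recruit rate under 1e-3 for panels of ~8 x 400 aa references
# (null simulation with 420-bp reads; see docs/methods.md).
DEFAULT_RECRUIT_CUTOFF = 50


class BlockCurationError(ValueError):
    """Raised when too few alignment columns survive curation."""


@dataclass
class MarkerReference:
    """A named marker with its fixed reference protein alignment."""

    name: str
    ids: list[str]
    rows: list[str]                      # aligned aa rows, common length C
    groups: dict[str, str] = field(default_factory=dict)  # ref id -> clade

    def __post_init__(self) -> None:
        if len(self.ids) < 3:
            raise ValueError("marker reference needs >= 3 sequences")
        C = len(self.rows[0])
        if any(len(r) != C for r in self.rows):
            raise ValueError("reference alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def degapped(self) -> list[str]:
        return [r.replace(GAP, "") for r in self.rows]

    def column_maps(self) -> list[np.ndarray]:
        """Per reference: degapped residue index -> alignment column."""
        return [np.array([c for c, aa in enumerate(r) if aa != GAP])
                for r in self.rows]


def load_reference_alignment(path, name: str,
                             groups: dict[str, str] | None = None
                             ) -> MarkerReference:
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return MarkerReference(name=name, ids=ids, rows=rows, groups=groups or {})


@dataclass
class RecruitedRead:
    read_id: str
    sequence: str
    frame: int          # 0..2 forward, 3..5 reverse complement
    score: int
    best_ref: str


def recruit(rs: ReadSet, marker: MarkerReference,
            cutoff: int = DEFAULT_RECRUIT_CUTOFF) -> list[RecruitedRead]:
    """Reads with a significant translated hit against any reference."""
    if len(rs) == 0:
        return []
    qidx = simsearch.build_index(rs.sequences, kind="dna")
    tidx = simsearch.build_index(marker.degapped(), kind="protein")
    qi, ti, sc, qseg = simsearch.best_pair_scores(qidx, tidx)
    best: dict[int, tuple[int, int, int]] = {}
    for a, b, s, g in zip(qi, ti, sc, qseg):
        if s >= cutoff and (a not in best or s > best[a][0]):
            best[int(a)] = (int(s), int(b), int(g))
    out = []
    for a in sorted(best):
        s, b, g = best[a]
        rid, seq = rs.reads[a]
        out.append(RecruitedRead(
            read_id=rid, sequence=seq,
            frame=int(qidx.seg_frame[g]), score=s, best_ref=marker.ids[b],
        ))
    return out


def assemble_recruited(recruited: list[RecruitedRead],
                       min_identity: float = 0.98,
                       min_overlap: int = 35) -> list[Contig]:
    """Stringent assembly of recruited reads (delegates to the contig
    spectrum assembler; same thresholds group only same-virotype reads)."""
    if not recruited:
        return []
    rs = ReadSet(name="recruited",
                 reads=[(r.read_id, r.sequence) for r in recruited])
    contigs, _ = assemble_strict(rs, min_identity=min_identity,
                                 min_overlap=min_overlap)
    return contigs


@dataclass
class AlignedContig:
    contig_id: str
    peptide: str
    ref_id: str
    frame: int
    score: int
    start: int          # first reference column covered
    end: int            # past-the-last reference column
    row: str            # full-width aligned row (gaps outside the span)


def _sliding_best(seg: np.ndarray, ref: np.ndarray) -> tuple[int, int]:
    """Best ungapped placement of seg within ref: (score, offset).

    If seg is longer than ref, the roles swap and the returned offset is
    negative (seg overhangs ref on the left by -offset).
    """
    B = simsearch.BLOSUM62
    if len(seg) <= len(ref):
        win = np.lib.stride_tricks.sliding_window_view(ref, len(seg))
        scores = B[seg[None, :], win].sum(axis=1)
        o = int(scores.argmax())
        return int(scores[o]), o
    win = np.lib.stride_tricks.sliding_window_view(seg, len(ref))
    scores = B[ref[None, :], win].sum(axis=1)
    o = int(scores.argmax())
    return int(scores[o]), -o


def align_to_reference(contigs: list[Contig], marker: MarkerReference,
                       min_cols: int = 20
                       ) -> tuple[list[AlignedContig], list[dict]]:
    """Place each contig peptide on the reference alignment.

    Every stop-free six-frame peptide segment of the contig is slid
    ungapped along every degapped reference; the best-scoring placement
    wins.  Reference columns are immutable, so substitution-only peptides
    map 1:1 onto columns (no insertions to discard).  Contigs whose
    aligned span is shorter than ``min_cols`` columns are dropped and
    reported in the second return value.
    """
    refs = [simsearch._encode_peptide(r) for r in marker.degapped()]
    colmaps = marker.column_maps()
    C = marker.n_columns
    aligned, dropped = [], []
    for idx, contig in enumerate(contigs):
        cid = f"contig{idx:04d}"
        best = None
        for frame, _, seg in simsearch.six_frame_segments(contig.sequence,
                                                          min_len=10):
            enc = simsearch._encode_peptide(seg)
            for ri, ref in enumerate(refs):
                score, off = _sliding_best(enc, ref)
                if best is None or score > best[0]:
                    best = (score, ri, off, seg, frame)
        if best is None:
            dropped.append({"contig": cid, "reason": "no peptide segment"})
            continue
        score, ri, off, seg, frame = best
        if off < 0:  # trim the part of the peptide overhanging the reference
            seg = seg[-off:][: len(refs[ri])]
            off = 0
        seg = seg[: len(refs[ri]) - off]
        if len(seg) < min_cols:
            dropped.append({"contig": cid,
                            "reason": f"aligned span {len(seg)} aa < {min_cols}"})
            continue
        cmap = colmaps[ri]
        row = [GAP] * C
        for j, aa in enumerate(seg):
            row[cmap[off + j]] = aa
        start = int(cmap[off])
        end = int(cmap[off + len(seg) - 1]) + 1
        aligned.append(AlignedContig(
            contig_id=cid, peptide=seg, ref_id=marker.ids[ri], frame=frame,
            score=score, start=start, end=end, row="".join(row),
        ))
    return aligned, dropped


@dataclass
class SubAlignment:
    start: int
    end: int
    member_ids: list[str]
    member_rows: list[str]   # full-width rows (sliced at curation time)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def interval_components(bounds: list[tuple[int, int]],
                        min_reciprocal_overlap: float = 0.5) -> list[list[int]]:
    """Connected components of the interval-overlap graph: an edge joins
    two intervals when their overlap covers >= the given fraction of the
    shorter interval.  Deterministic, order-independent."""
    n = len(bounds)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        s1, e1 = bounds[i]
        for j in range(i + 1, n):
            s2, e2 = bounds[j]
            ov = min(e1, e2) - max(s1, s2)
            shorter = min(e1 - s1, e2 - s2)
            if shorter > 0 and ov >= min_reciprocal_overlap * shorter:
                parent[find(j)] = find(i)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return sorted(comps.values(), key=lambda c: c[0])


def partition_subalignments(aligned: list[AlignedContig], min_members: int = 2,
                            min_reciprocal_overlap: float = 0.5,
                            coverage_frac: float = 0.75
                            ) -> tuple[list[SubAlignment], list[SubAlignment]]:
    """Partition aligned contigs into sub-alignments by bound overlap.

    Every contig lands in exactly one connected component of the
    reciprocal-overlap graph.  Components with >= min_members become
    sub-alignments whose interval is the longest contiguous column run
    covered by >= ``coverage_frac`` of the members; smaller components
    are returned separately (second value), not silently dropped.
    """
    bounds = [(a.start, a.end) for a in aligned]
    kept, small = [], []
    for comp in interval_components(bounds, min_reciprocal_overlap):
        members = [aligned[i] for i in comp]
        cov_lo = min(a.start for a in members)
        cov_hi = max(a.end for a in members)
        cover = np.zeros(cov_hi - cov_lo, dtype=int)
        for a in members:
            cover[a.start - cov_lo : a.end - cov_lo] += 1
        need = int(np.ceil(coverage_frac * len(members)))
        ok = cover >= need
        # longest contiguous run of sufficiently covered columns (leftmost tie)
        best_run, cur_start, best = (0, 0), None, 0
        for i, flag in enumerate(np.append(ok, False)):
            if flag and cur_start is None:
                cur_start = i
            elif not flag and cur_start is not None:
                if i - cur_start > best:
                    best = i - cur_start
                    best_run = (cur_start, i)
                cur_start = None
        s, e = best_run[0] + cov_lo, best_run[1] + cov_lo
        sub = SubAlignment(start=int(s), end=int(e),
                           member_ids=[a.contig_id for a in members],
                           member_rows=[a.row for a in members])
        (kept if len(members) >= min_members else small).append(sub)
    return kept, small


@dataclass
class CuratedAlignment:
    ids: list[str]
    rows: list[str]
    kept_columns: list[int]   # original reference columns retained
    source_interval: tuple[int, int]

    @property
    def n_columns(self) -> int:
        return len(self.kept_columns)


def curate_blocks(sub: SubAlignment, marker: MarkerReference | None = None,
                  max_gap_frac: float = 0.5, min_run: int = 10,
                  min_cols: int = 20) -> CuratedAlignment:
    """Simplified block curation of a sub-alignment (plus references).

    Columns with a gap fraction above ``max_gap_frac`` are dropped; only
    maximal runs of >= ``min_run`` surviving consecutive columns are kept
    and concatenated.  Raises :class:`BlockCurationError` when fewer than
    ``min_cols`` columns survive.
    """
    ids = list(sub.member_ids)
    rows = [r[sub.start : sub.end] for r in sub.member_rows]
    if marker is not None:
        ids += list(marker.ids)
        rows += [r[sub.start : sub.end] for r in marker.rows]
    if len(rows) < 4:
        raise ValueError("block curation needs >= 4 rows")
    M = np.array([list(r) for r in rows])
    gap_frac = (M == GAP).mean(axis=0)
    ok = gap_frac <= max_gap_frac
    keep: list[int] = []
    i = 0
    ncol = len(ok)
    while i < ncol:
        if ok[i]:
            j = i
            while j < ncol and ok[j]:
                j += 1
            if j - i >= min_run:
                keep.extend(range(i, j))
            i = j
        else:
            i += 1
    if len(keep) < min_cols:
        raise BlockCurationError(
            f"only {len(keep)} columns survive curation (< {min_cols}) in "
            f"window [{sub.start}, {sub.end})"
        )
    curated_rows = ["".join(M[r, keep]) for r in range(len(rows))]
    return CuratedAlignment(
        ids=ids, rows=curated_rows,
        kept_columns=[sub.start + int(c) for c in keep],
        source_interval=(sub.start, sub.end),
    )


def rank_and_select(subs: list[CuratedAlignment], k: int = 10
                    ) -> list[CuratedAlignment]:
    """The k longest curated alignments (ties: more members, then lower
    start column).  Deterministic under input permutation."""
    return sorted(
        subs,
        key=lambda c: (-c.n_columns, -len(c.ids), c.source_interval[0]),
    )[:k]


@dataclass
class SupportedTree:
    tree: TreeNode
    support: dict[frozenset, float]   # canonical bipartition -> support
    method: str
    n_boot: int

    def newick(self) -> str:
        return str(self.tree).strip()


def _p_distance_matrix(rows: list[str]) -> np.ndarray:
    n = len(rows)
    D = np.zeros((n, n))
    arr = np.array([list(r) for r in rows])
    valid = arr != GAP
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nv = int(both.sum())
            if nv == 0:
                D[i, j] = D[j, i] = 1.0
                continue
            mism = int((arr[i, both] != arr[j, both]).sum())
            D[i, j] = D[j, i] = mism / nv
    return D


def _bipartitions(tree: TreeNode, all_leaves: frozenset) -> set[frozenset]:
    out = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        comp = all_leaves - clade
        if len(clade) < 2 or len(comp) < 2:
            continue
        canon = min((clade, comp), key=lambda s: sorted(s))
        out.add(canon)
    return out


def build_tree(curated: CuratedAlignment, n_boot: int = 100, seed: int = 0,
               method: str = "nj-builtin",
               external_hook=None) -> SupportedTree:
    """Phylogenetic tree over a curated sub-alignment.

    Built-in path: pairwise amino-acid p-distances (pairwise deletion of
    gap columns), neighbor joining, and bootstrap support as the fraction
    of ``n_boot`` column-resampled replicate trees containing each
    bipartition of the point tree.  ``method='external-ml-hook'`` calls
    ``external_hook(ids, rows) -> newick_str`` for the point tree instead
    (support still from built-in NJ replicates).
    """
    if len(curated.ids) < 4:
        raise ValueError("tree building needs >= 4 sequences")

    def _nj_from_rows(rows: list[str]) -> TreeNode:
        D = _p_distance_matrix(rows)
        if np.all(D == 0):
            warnings.warn("all sequences identical; tree has zero-length edges")
        dm = DistanceMatrix(D, ids=curated.ids)
        return nj(dm)

    if method == "external-ml-hook":
        if external_hook is None:
            raise ValueError("external-ml-hook method needs external_hook")
        point = TreeNode.read([external_hook(curated.ids, curated.rows)])
    elif method == "nj-builtin":
        point = _nj_from_rows(curated.rows)
    else:
        raise ValueError(f"unknown method {method!r}")

    leaves = frozenset(curated.ids)
    point_bips = _bipartitions(point, leaves)
    support: dict[frozenset, float] = {}
    if n_boot >= 1:
        rng = np.random.default_rng(seed)
        counts = {b: 0 for b in point_bips}
        ncol = curated.n_columns
        row_arr = np.array([list(r) for r in curated.rows])
        for _ in range(n_boot):
            cols = rng.integers(0, ncol, size=ncol)
            rows_b = ["".join(r) for r in row_arr[:, cols]]
            rep = _nj_from_rows(rows_b)
            for b in _bipartitions(rep, leaves):
                if b in counts:
                    counts[b] += 1
        support = {b: c / n_boot for b, c in counts.items()}
    return SupportedTree(tree=point, support=support, method=method,
                         n_boot=n_boot)
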