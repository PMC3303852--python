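"""Translated (six-frame) similarity search between read sets.

This is the engine behind cross-virome scoring and marker-gene read
recruitment.  Nucleotide reads are translated in all six frames, peptides
are split at stop codons, and pairs of peptide segments sharing an exact
amino-acid k-mer seed are extended ungapped along the seed diagonal under
BLOSUM62 (the substitution-only error model upstream makes gapped
extension unnecessary).  The score of a read pair is the best segment-pair
segment score over all frames and diagonals.

A read "hits" a target read set when its best score against any target
read reaches a significance cutoff.  The default cutoff is calibrated so
that a pair of unrelated random 100-bp reads scores above it less than
1e-3 of the time (see :func:`calibrate_score_cutoff`); reads with a
byte-identical partner in the target always hit (a self-alignment is
trivially significant regardless of stop-codon segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from scipy import sparse

SEED_K = 5

# raw ungapped BLOSUM62 score cutoff for a significant translated hit.
# calibrate_score_cutoff(fp=1e-3) gives 37 for 100-bp reads and 45 for
# 420-bp reads; the larger value is the default so the false-hit rate
# stays below 1e-3 in both read-length regimes (see docs/methods.md).
DEFAULT_SCORE_CUTOFF = 45

_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(_AA_ORDER)}
_NX = 20  # index for unknown residue


def _blosum62() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    B = np.full((21, 21), -4, dtype=np.int32)
    for a in _AA_ORDER:
        for b in _AA_ORDER:
            B[_AA_INDEX[a], _AA_INDEX[b]] = int(m[a, b])
    return B


BLOSUM62 = _blosum62()

_STD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP = dict(_STD_TABLE.forward_table)
for _c in _STD_TABLE.stop_codons:
    _CODON_MAP[_c] = "*"

_RC = str.maketrans("ACGTN", "TGCAN")


def translate_frame(seq: str, frame: int) -> str:
    """Translate one frame (0..2 forward, 3..5 reverse complement)."""
    if frame >= 3:
        seq = seq.translate(_RC)[::-1]
        frame -= 3
    s = seq[frame:]
    return "".join(
        _CODON_MAP.get(s[i : i + 3], "X") for i in range(0, len(s) - 2, 3)
    )


def six_frame_segments(seq: str, min_len: int = SEED_K
                       ) -> list[tuple[int, int, str]]:
    """Stop-codon-split peptide segments of length >= min_len, all frames.

    Returns (frame, aa_offset_within_frame, peptide) triples; frames 0..2
    are forward, 3..5 reverse complement.
    """
    out = []
    for frame in range(6):
        off = 0
        for seg in translate_frame(seq, frame).split("*"):
            if len(seg) >= min_len:
                out.append((frame, off, seg))
            off += len(seg) + 1
    return out


def _encode_peptide(p: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(aa, _NX) for aa in p], dtype=np.uint8)


@dataclass
class PeptideIndex:
    """Seed index over the peptide segments of a collection of sequences."""

    n_items: int
    seg_read: np.ndarray        # segment -> source item index
    seg_start: np.ndarray       # segment -> offset in the concatenated residues
    seg_len: np.ndarray
    seg_frame: np.ndarray       # segment -> reading frame (0 for proteins)
    seg_aaoff: np.ndarray       # segment -> aa offset within its frame
    residues: np.ndarray        # concatenated encoded segments
    kmer_codes: np.ndarray      # sorted k-mer codes
    kmer_seg: np.ndarray        # parallel: segment of each k-mer
    kmer_off: np.ndarray        # parallel: offset of each k-mer in its segment
    sequences: list[str] | None = None  # original nucleotide seqs (for identity)


def _kmer_codes(enc: np.ndarray, k: int = SEED_K) -> np.ndarray:
    # base-21 rolling codes; segments shorter than k yield none
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 21 + enc[j : j + n]
    return codes


def build_index(items: list[str], kind: str = "dna") -> PeptideIndex:
    """Index nucleotide reads (six-frame translated) or protein sequences."""
    seg_read, seg_parts, seg_frame, seg_aaoff = [], [], [], []
    for i, s in enumerate(items):
        if kind == "dna":
            segs = six_frame_segments(s)
        else:
            segs = [(0, 0, seg) for seg in s.split("*") if len(seg) >= SEED_K]
        for frame, off, seg in segs:
            seg_read.append(i)
            seg_frame.append(frame)
            seg_aaoff.append(off)
            seg_parts.append(_encode_peptide(seg))
    seg_read = np.array(seg_read, dtype=np.int64)
    seg_frame = np.array(seg_frame, dtype=np.int64)
    seg_aaoff = np.array(seg_aaoff, dtype=np.int64)
    seg_len = np.array([len(p) for p in seg_parts], dtype=np.int64)
    seg_start = np.concatenate([[0], np.cumsum(seg_len)[:-1]]) if len(seg_len) \
        else np.empty(0, dtype=np.int64)
    residues = np.concatenate(seg_parts) if seg_parts else np.empty(0, dtype=np.uint8)

    codes_parts, segs_idx, offs = [], [], []
    for si, p in enumerate(seg_parts):
        c = _kmer_codes(p)
        codes_parts.append(c)
        segs_idx.append(np.full(len(c), si, dtype=np.int64))
        offs.append(np.arange(len(c), dtype=np.int64))
    codes = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.int64)
    kseg = np.concatenate(segs_idx) if segs_idx else np.empty(0, np.int64)
    koff = np.concatenate(offs) if offs else np.empty(0, np.int64)
    order = np.argsort(codes, kind="stable")
    return PeptideIndex(
        n_items=len(items), seg_read=seg_read, seg_start=seg_start,
        seg_len=seg_len, seg_frame=seg_frame, seg_aaoff=seg_aaoff,
        residues=residues,
        kmer_codes=codes[order], kmer_seg=kseg[order], kmer_off=koff[order],
        sequences=list(items) if kind == "dna" else None,
    )


def _candidate_diagonals(q: PeptideIndex, t: PeptideIndex
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique (query_segment, target_segment, diagonal) sharing a seed."""
    if len(q.kmer_codes) == 0 or len(t.kmer_codes) == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z, z
    qc, qs, qo = q.kmer_codes, q.kmer_seg, q.kmer_off
    lo = np.searchsorted(t.kmer_codes, qc, side="left")
    hi = np.searchsorted(t.kmer_codes, qc, side="right")
    cnt = hi - lo
    keep = cnt > 0
    if not keep.any():
        z = np.empty(0, dtype=np.int64)
        return z, z, z
    lo, cnt = lo[keep], cnt[keep]
    qs, qo = qs[keep], qo[keep]
    t_pos = np.repeat(lo, cnt) + _ragged_arange(cnt)
    q_seg_m = np.repeat(qs, cnt)
    q_off_m = np.repeat(qo, cnt)
    t_seg_m = t.kmer_seg[t_pos]
    t_off_m = t.kmer_off[t_pos]
    diag = q_off_m - t_off_m
    max_len = max(int(q.seg_len.max()), int(t.seg_len.max()), 1)
    # pack (qseg, tseg, diag) into one int64 key for a fast unique
    width_t = len(t.seg_len)
    packed = (q_seg_m * width_t + t_seg_m) * (2 * max_len + 1) \
        + (diag + max_len)
    uniq = np.unique(packed)
    diag_u = uniq % (2 * max_len + 1) - max_len
    rest = uniq // (2 * max_len + 1)
    return rest // width_t, rest % width_t, diag_u


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    total = int(counts.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(counts)[:-1]
    out[ends] = 1 - counts[:-1]
    return np.cumsum(out)


def best_pair_scores(q: PeptideIndex, t: PeptideIndex
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best ungapped BLOSUM62 diagonal score per (query item, target item).

    Returns parallel arrays (query_idx, target_idx, score,
    best_query_segment) for all pairs sharing at least one seed; the last
    array gives the query segment (hence frame) of the winning alignment.
    """
    qseg, tseg, diag = _candidate_diagonals(q, t)
    if len(qseg) == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z, z, z
    q_lo = np.maximum(0, diag)
    t_lo = q_lo - diag
    L = np.minimum(q.seg_len[qseg] - q_lo, t.seg_len[tseg] - t_lo)
    best = np.zeros(len(qseg), dtype=np.int64)
    # chunk by diagonal length to bound the padded width
    order = np.argsort(L, kind="stable")
    for chunk in np.array_split(order, max(1, len(order) // 8192)):
        if len(chunk) == 0:
            continue
        W = int(L[chunk].max())
        idx = np.arange(W)[None, :]
        mask = idx < L[chunk, None]
        qi = (q.seg_start[qseg[chunk]] + q_lo[chunk])[:, None] + idx
        ti = (t.seg_start[tseg[chunk]] + t_lo[chunk])[:, None] + idx
        qi = np.where(mask, qi, 0)
        ti = np.where(mask, ti, 0)
        s = BLOSUM62[q.residues[qi], t.residues[ti]].astype(np.int64)
        s = np.where(mask, s, -(10**6))
        running = np.zeros(len(chunk), dtype=np.int64)
        bst = np.zeros(len(chunk), dtype=np.int64)
        for j in range(W):  # Kadane across the batch
            running = np.maximum(running + s[:, j], 0)
            bst = np.maximum(bst, running)
        best[chunk] = bst

    q_item = q.seg_read[qseg]
    t_item = t.seg_read[tseg]
    pair = q_item * t.n_items + t_item
    # argmax per pair: sort by (pair, score) and take the last of each run
    srt = np.lexsort((best, pair))
    pair_s = pair[srt]
    last = np.nonzero(np.append(pair_s[1:] != pair_s[:-1], True))[0]
    winners = srt[last]
    return (pair_s[last] // t.n_items, pair_s[last] % t.n_items,
            best[winners], qseg[winners])


def hit_matrix(q: PeptideIndex, t: PeptideIndex,
               cutoff: int = DEFAULT_SCORE_CUTOFF) -> sparse.csr_matrix:
    """Boolean sparse matrix: entry (i, j) true iff query read i has a
    significant translated hit against target read j.

    Byte-identical nucleotide sequences are always hits.
    """
    qi, ti, sc, _ = best_pair_scores(q, t)
    keep = sc >= cutoff
    rows, cols = list(qi[keep]), list(ti[keep])
    if q.sequences is not None and t.sequences is not None:
        t_by_seq: dict[str, list[int]] = {}
        for j, s in enumerate(t.sequences):
            t_by_seq.setdefault(s, []).append(j)
        for i, s in enumerate(q.sequences):
            for j in t_by_seq.get(s, ()):
                rows.append(i)
                cols.append(j)
    data = np.ones(len(rows), dtype=bool)
    return sparse.csr_matrix((data, (rows, cols)), shape=(q.n_items, t.n_items))


def calibrate_score_cutoff(read_len: int = 100, n_pairs: int = 5000,
                           fp: float = 1e-3, seed: int = 0) -> int:
    """Smallest integer cutoff at which fewer than ``fp`` of random
    unrelated read pairs of ``read_len`` bp score as hits."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    mk = lambda: bases[rng.integers(0, 4, size=read_len)].tobytes().decode()
    reads_a = [mk() for _ in range(n_pairs)]
    reads_b = [mk() for _ in range(n_pairs)]
    scores = np.zeros(n_pairs, dtype=np.int64)
    ia = build_index(reads_a)
    ib = build_index(reads_b)
    qi, ti, sc, _ = best_pair_scores(ia, ib)
    paired = qi == ti  # only the matched pair counts as "a pair"
    np.maximum.at(scores, qi[paired], sc[paired])
    return int(np.quantile(scores, 1.0 - fp)) + 1
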