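"""Species-richness estimation from the contig spectrum.

The central object is the contig spectrum: after a deliberately stringent
overlap assembly of a virome (98% identity over at least 35 bp, so that
only reads from the same virotype co-assemble), ``c_q`` counts the contigs
built from exactly q reads.  The spectrum is the sufficient statistic for
community structure under shotgun-coverage theory: for a virotype sampled
by ``n_i`` reads of length ``l`` on an (average) genome of length ``L``,
with per-virotype coverage ``c_i = n_i * l / L`` and overlap factor
``sigma = 1 - t/l`` (``t`` the minimum detectable overlap), the expected
number of q-read contigs is

    E[c_q] = sum_i n_i * exp(-2 c_i sigma) * (1 - exp(-c_i sigma))^(q-1)

Species richness is estimated by finding, over the classical
rank-abundance families, the abundance model whose expected spectrum best
matches the observed one (weighted least squares, approximate Poisson
weights); the richness S of the winning model is the estimate, and the
fitted abundance vector yields the Shannon index H and Pielou evenness J.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .seqio import ReadSet
from .synthdata import ABUNDANCE_FAMILIES, RankAbundanceModel


@dataclass
class ContigSpectrum:
    """counts[q-1] = number of contigs made of exactly q reads."""

    counts: np.ndarray
    n_reads: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("contig spectrum counts must be non-negative")
        q = np.arange(1, len(self.counts) + 1)
        if int((q * self.counts).sum()) != self.n_reads:
            raise ValueError(
                f"spectrum violates read conservation: sum q*c_q = "
                f"{int((q * self.counts).sum())} != n_reads = {self.n_reads}"
            )

    @property
    def max_q(self) -> int:
        return len(self.counts)


@dataclass
class LWParams:
    """Shotgun-coverage model parameters: read length l, minimum overlap t,
    average genome length L (all bp)."""

    read_len: int
    min_overlap: int = 35
    avg_genome_len: float = 50000.0

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap < self.read_len <= self.avg_genome_len:
            raise ValueError(
                "need 0 < min_overlap < read_len <= avg_genome_len, got "
                f"t={self.min_overlap}, l={self.read_len}, L={self.avg_genome_len}"
            )

    @property
    def sigma(self) -> float:
        return 1.0 - self.min_overlap / self.read_len


@dataclass
class Contig:
    read_ids: list[str]
    sequence: str


# ---------------------------------------------------------------------------
# stringent overlap assembly

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_BASE2BIT = np.zeros(256, dtype=np.int64)
_BASE2BIT[ord("C")] = 1
_BASE2BIT[ord("G")] = 2
_BASE2BIT[ord("T")] = 3


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    total = int(counts.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(counts)[:-1]
    out[ends] = 1 - counts[:-1]
    return np.cumsum(out)


def _candidates_fixed(seqs: list[str], min_identity: float, min_overlap: int,
                      k: int) -> list[tuple[int, int, int]]:
    """Verified overlap candidates (overlap, a, b) for equal-length reads.

    Fully vectorised: rolling 2-bit k-mer codes locate each read's prefix
    inside every other read, giving candidate suffix(a)/prefix(b) overlaps
    o = l - p, verified by ungapped mismatch counting grouped by offset.
    """
    n = len(seqs)
    l = len(seqs[0])
    R = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, l)
    M = _BASE2BIT[R]
    n_pos = l - k + 1
    C = np.zeros((n, n_pos), dtype=np.int64)
    for j in range(k):
        C = C * 4 + M[:, j : j + n_pos]
    prefix = C[:, 0].copy()
    order = np.argsort(prefix, kind="stable")
    sorted_prefix = prefix[order]
    flat = C[:, : l - min_overlap + 1].ravel()  # only offsets giving o >= t
    lo = np.searchsorted(sorted_prefix, flat, side="left")
    hi = np.searchsorted(sorted_prefix, flat, side="right")
    cnt = hi - lo
    keep = np.nonzero(cnt)[0]
    if len(keep) == 0:
        return []
    n_off = l - min_overlap + 1
    a_pos = keep // n_off
    p_pos = keep % n_off
    cnt_k = cnt[keep]
    b_idx = order[np.repeat(lo[keep], cnt_k) + _ragged_arange(cnt_k)]
    a_idx = np.repeat(a_pos, cnt_k)
    p = np.repeat(p_pos, cnt_k)
    ok = a_idx != b_idx
    a_idx, b_idx, p = a_idx[ok], b_idx[ok], p[ok]

    out: list[tuple[int, int, int]] = []
    for pv in np.unique(p):
        sel = p == pv
        o = l - int(pv)
        max_mm = int(np.floor((1.0 - min_identity) * o))
        a_s, b_s = a_idx[sel], b_idx[sel]
        mism = (R[a_s, pv:] != R[b_s, :o]).sum(axis=1)
        good = mism <= max_mm
        out.extend(zip([o] * int(good.sum()),
                       a_s[good].tolist(), b_s[good].tolist()))
    return out


def _candidates_generic(seqs: list[str], min_identity: float, min_overlap: int,
                        k: int) -> list[tuple[int, int, int]]:
    """Verified overlap candidates for arbitrary-length reads (dict index)."""
    n = len(seqs)
    lens = [len(s) for s in seqs]
    enc = [_encode(s) for s in seqs]
    index: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(seqs):
        for p in range(lens[i] - k + 1):
            index.setdefault(s[p : p + k], []).append((i, p))
    out: list[tuple[int, int, int]] = []
    for b in range(n):
        if lens[b] < k:
            continue
        prefix = seqs[b][:k]
        for a, p in index.get(prefix, ()):
            if a == b:
                continue
            o = lens[a] - p
            if o < min_overlap:
                continue
            o_eff = min(o, lens[b])
            max_mm = int(np.floor((1.0 - min_identity) * o_eff))
            mm = int((enc[a][p : p + o_eff] != enc[b][:o_eff]).sum())
            if mm <= max_mm:
                out.append((o_eff, a, b))
    return out


def assemble_strict(rs: ReadSet, min_identity: float = 0.98, min_overlap: int = 35,
                    seed_k: int | None = None) -> tuple[list[Contig], ContigSpectrum]:
    """Greedy overlap-merge assembly at high stringency.

    Candidate suffix/prefix overlaps of length >= ``min_overlap`` between
    reads are enumerated by exact k-mer seeding on read prefixes and
    verified ungapped (mismatch fraction <= 1 - min_identity; the
    simulator's substitution-only error model makes gapped overlaps
    unnecessary).  Candidates are then merged longest-overlap-first (ties
    by read order), each read end being consumed at most once, which is
    the greedy "repeatedly join the best remaining pair" policy.  A read
    fully contained in another read's suffix window is absorbed.

    Returns contigs (with reconstructed sequences, taking the earlier
    read's base at overlap mismatches) and the contig spectrum.
    """
    n = len(rs)
    if n == 0:
        return [], ContigSpectrum(counts=np.zeros(0, dtype=int), n_reads=0)
    if seed_k is None:
        seed_k = min(20, min_overlap)
    seqs = rs.sequences
    lens = [len(s) for s in seqs]
    if len(set(lens)) == 1:
        cand = _candidates_fixed(seqs, min_identity, min_overlap, seed_k)
    else:
        cand = _candidates_generic(seqs, min_identity, min_overlap, seed_k)
    candidates = sorted((-o, a, b, o) for o, a, b in cand)

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    right_free = [True] * n   # read's suffix end not yet merged into a successor
    left_free = [True] * n    # read's prefix end not yet merged onto a predecessor
    succ: dict[int, tuple[int, int]] = {}  # a -> (b, overlap)
    contained: dict[int, int] = {}         # b -> a (b absorbed into a)

    for _, a, b, o in candidates:
        if find(a) == find(b):
            continue
        if o >= lens[b]:
            # containment: b lies inside a's suffix window
            if not left_free[b] or not right_free[b]:
                continue
            left_free[b] = right_free[b] = False
            contained[b] = a
            parent[find(b)] = find(a)
            continue
        if not right_free[a] or not left_free[b]:
            continue
        right_free[a] = False
        left_free[b] = False
        succ[a] = (b, o)
        parent[find(b)] = find(a)

    # group reads by component and rebuild chain sequences
    comp: dict[int, list[int]] = {}
    for i in range(n):
        comp.setdefault(find(i), []).append(i)

    ids = rs.ids
    contigs: list[Contig] = []
    for members in comp.values():
        chain_members = [i for i in members if i not in contained]
        heads = [i for i in chain_members if left_free[i]]
        # exactly one chain head per component
        i = heads[0]
        seq_parts = [seqs[i]]
        order = [i]
        while i in succ:
            j, o = succ[i]
            seq_parts.append(seqs[j][o:])
            order.append(j)
            i = j
        read_ids = [ids[j] for j in order] + [ids[j] for j in members
                                                 if j in contained]
        contigs.append(Contig(read_ids=read_ids, sequence="".join(seq_parts)))

    sizes = np.array([len(c.read_ids) for c in contigs])
    counts = np.bincount(sizes, minlength=sizes.max() + 1)[1:]
    return contigs, ContigSpectrum(counts=counts, n_reads=n)


# ---------------------------------------------------------------------------
# expected contig spectrum and model fitting

def expected_spectrum(model: RankAbundanceModel, n: int, lw: LWParams,
                      Q: int) -> tuple[np.ndarray, float]:
    """Expected contig spectrum E[c_q], q = 1..Q, under the coverage model.

    Returns the length-Q vector and the truncated tail mass
    ``n - sum_q q E[c_q]`` (reads expected in contigs of more than Q
    reads); the full series satisfies sum_q q E[c_q] = n exactly.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    a = model.abundances()
    n_i = a * n
    c_i = n_i * lw.read_len / lw.avg_genome_len
    sigma = lw.sigma
    e = np.exp(-c_i * sigma)            # per-virotype island-end factor
    base = n_i * e * e                  # E contribution at q = 1
    ratio = 1.0 - e
    E = np.empty(Q)
    term = base.copy()
    for qi in range(Q):                 # O(Q*S), no Q-by-S allocation
        E[qi] = term.sum()
        term *= ratio
    tail = float(n - (np.arange(1, Q + 1) * E).sum())
    return E, tail


@dataclass
class RichnessEstimate:
    S_hat: int
    best_model: RankAbundanceModel
    fit_error: float
    shannon: float
    evenness: float
    fit_table: list[dict] = field(default_factory=list)


def _objective(family: str, S: int, params: dict, obs: np.ndarray,
               obs_tail_reads: float, n: int, lw: LWParams) -> float:
    """Weighted squared error between observed and expected spectra.

    The spectrum is compared bin-by-bin for q = 1..Q (Q = length of
    ``obs``) with approximate Poisson weights 1/max(E, 1); read mass in
    contigs of more than Q reads is compared as a single aggregate bin, so
    deeply covered virotypes (which produce very large contigs) still
    constrain the fit without inflating Q.
    """
    model = RankAbundanceModel(family, S, params)
    E, tail = expected_spectrum(model, n, lw, Q=len(obs))
    w = 1.0 / np.maximum(E, 1.0)
    err = float((w * (obs - E) ** 2).sum())
    err += (obs_tail_reads - tail) ** 2 / max(tail, 1.0)
    return err


_PARAM_BOUNDS = {
    "power": ("b", 0.01, 4.0),
    "exponential": ("b", 1e-4, 2.0),
    "logarithmic": ("x", 1e-4, 1.0 - 1e-9),
    "lognormal": ("sigma", 0.05, 6.0),
}


def _fit_family_at_S(family: str, S: int, obs: np.ndarray, obs_tail: float,
                     n: int, lw: LWParams) -> tuple[float, dict]:
    if family == "broken_stick":
        return _objective(family, S, {}, obs, obs_tail, n, lw), {}
    name, lo, hi = _PARAM_BOUNDS[family]
    res = optimize.minimize_scalar(
        lambda v: _objective(family, S, {name: v}, obs, obs_tail, n, lw),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-3},
    )
    return float(res.fun), {name: float(res.x)}


def _log_grid(lo: float, hi: float, per_decade: int) -> np.ndarray:
    n_pts = max(2, int(np.ceil(np.log10(hi / lo) * per_decade)) + 1)
    g = np.unique(np.round(np.logspace(np.log10(lo), np.log10(hi), n_pts)).astype(int))
    return g[g >= 1]


def fit_richness(obs: ContigSpectrum, lw: LWParams,
                 families: tuple[str, ...] = ABUNDANCE_FAMILIES,
                 S_max: int | None = None, Q_fit: int = 30) -> RichnessEstimate:
    """Estimate species richness by rank-abundance model fitting.

    For each family, the richness S is searched on a log grid (coarse pass
    over [1, S_max], then a refinement pass at >= 40 points per decade
    around the coarse optimum) with the family's shape parameter optimised
    at every S by bounded scalar minimisation.  The observed spectrum is
    compared on q = 1..Q_fit plus an aggregate bin for read mass in larger
    contigs.  The family with the lowest weighted squared error wins.
    Deterministic throughout.
    """
    if obs.n_reads < 100:
        warnings.warn(
            f"contig spectrum from only {obs.n_reads} reads; the richness "
            "estimate will be poorly constrained (>= 100 recommended)"
        )
    unknown = set(families) - set(ABUNDANCE_FAMILIES)
    if unknown:
        raise ValueError(f"unknown families {sorted(unknown)}")
    n = obs.n_reads
    Q = min(Q_fit, obs.max_q)
    y = obs.counts[:Q].astype(float)
    q_idx = np.arange(1, Q + 1)
    y_tail = float(n - (q_idx * y).sum())
    if S_max is None:
        S_max = max(10 * n, 1000)

    table: list[dict] = []
    best = None
    for family in families:
        coarse = _log_grid(1, S_max, per_decade=8)
        errs = [(_fit_family_at_S(family, int(S), y, y_tail, n, lw), int(S))
                for S in coarse]
        (err0, p0), S0 = min(errs, key=lambda t: (t[0][0], t[1]))
        pos = int(np.searchsorted(coarse, S0))
        lo = int(coarse[max(0, pos - 1)])
        hi = int(coarse[min(len(coarse) - 1, pos + 1)])
        fine = _log_grid(lo, hi, per_decade=40)
        errs_f = [(_fit_family_at_S(family, int(S), y, y_tail, n, lw), int(S))
                  for S in fine]
        (err1, p1), S1 = min(errs_f, key=lambda t: (t[0][0], t[1]))
        if err1 <= err0:
            err_best, p_best, S_best = err1, p1, S1
        else:
            err_best, p_best, S_best = err0, p0, S0
        row = {"family": family, "S": S_best, "params": p_best, "error": err_best}
        table.append(row)
        if best is None or err_best < best["error"]:
            best = row
    if best is None or not np.isfinite(best["error"]):
        raise RuntimeError(
            "no rank-abundance family converged; last objective values: "
            + ", ".join(f"{r['family']}={r['error']:.3g}" for r in table)
        )
    model = RankAbundanceModel(best["family"], best["S"], best["params"])
    a = model.abundances()
    H = float(-(a * np.log(a)).sum())
    J = H / np.log(model.S) if model.S > 1 else 1.0
    return RichnessEstimate(
        S_hat=model.S, best_model=model, fit_error=float(best["error"]),
        shannon=H, evenness=float(J), fit_table=table,
    )


def write_spectrum_tsv(spec: ContigSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("q\tc_q\n")
        for q, c in enumerate(spec.counts, start=1):
            fh.write(f"{q}\t{int(c)}\n")
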