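"""Cross-virome similarity, bootstrap clustering and richness ANOVA.

Virome panels (equally sized, equally trimmed read subsamples) are
cross-compared with the translated similarity engine: the similarity of
viromes A and B is the symmetrised fraction of reads with a significant
translated hit in the other virome,

    score(A, B) = 1/2 * ( |{r in A : hit(r, B)}| / |A|
                        + |{r in B : hit(r, A)}| / |B| )

which is bounded in [0, 1], symmetric, and invariant to the common
subsample size.  Viromes are then hierarchically clustered on
distance = 1 - score with average linkage, and the support of each clade
of the point-estimate tree is the plain bootstrap probability: the
fraction of trees, rebuilt from within-virome read resamples (with
replacement, at fixed n), that contain the same leaf bipartition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import simsearch
from .seqio import ReadSet


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: np.ndarray
    scorer_config: dict = field(default_factory=dict)
    # per ordered pair (i, j): sparse boolean read-level hit matrix of
    # virome i's reads against virome j's reads (kept for bootstrapping)
    hit_matrices: dict | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = v


@dataclass
class SupportedDendrogram:
    labels: list[str]
    linkage: np.ndarray                 # scipy linkage matrix (average)
    support: dict[frozenset, float]     # clade leaf set -> bootstrap fraction
    n_boot: int

    def clades(self) -> list[frozenset]:
        return _linkage_clades(self.linkage, self.labels)

    def newick(self) -> str:
        n = len(self.labels)
        names: dict[int, str] = {i: self.labels[i] for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        clades = {i: frozenset([self.labels[i]]) for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(0.0, h - heights[a])
            lb = max(0.0, h - heights[b])
            node = n + k
            clades[node] = clades[a] | clades[b]
            sup = self.support.get(clades[node])
            lab = "" if sup is None else f"{sup:.2f}"
            names[node] = f"({names[a]}:{la:.5f},{names[b]}:{lb:.5f}){lab}"
            heights[node] = h
        return names[2 * n - 2] + ";"


def _score_pair(hits_ab, hits_ba) -> float:
    frac_a = hits_ab.getnnz(axis=1).astype(bool).mean()
    frac_b = hits_ba.getnnz(axis=1).astype(bool).mean()
    return 0.5 * (frac_a + frac_b)


def cross_score(A: ReadSet, B: ReadSet,
                cutoff: int = simsearch.DEFAULT_SCORE_CUTOFF) -> float:
    """Symmetrised translated hit-fraction similarity of two viromes."""
    if len(A) == 0 or len(B) == 0:
        raise ValueError("cannot score an empty virome")
    _warn_unnormalized([A, B])
    ia = simsearch.build_index(A.sequences)
    ib = simsearch.build_index(B.sequences)
    return _score_pair(simsearch.hit_matrix(ia, ib, cutoff),
                       simsearch.hit_matrix(ib, ia, cutoff))


def cross_score_from_hits(a_ids, b_ids, hits_ab, hits_ba,
                          e_max: float = 1e-3, bit_min: float = 50.0,
                          variant: str = "hit_fraction") -> float:
    """Virome similarity from externally produced hit tables.

    ``hits_ab`` lists translated-search hits of virome A's reads against
    virome B (and vice versa), in the tabular hit-table layout used by
    :mod:`viromekit.taxcomp`.  A read hits when some alignment passes
    e-value <= ``e_max`` and bit score >= ``bit_min`` (inclusive).  The
    default variant is the symmetrised hit fraction in [0, 1]; the
    ``'bitscore_sum'`` variant averages each read's best significant bit
    score instead (unbounded, dominated by conserved genes -- provided
    for comparability, not as the default).
    """
    a_ids, b_ids = list(a_ids), list(b_ids)
    if not a_ids or not b_ids:
        raise ValueError("cannot score an empty virome")

    def _per_read(hits, ids):
        sig = hits[(hits["e_value"] <= e_max) & (hits["bit_score"] >= bit_min)]
        if variant == "hit_fraction":
            found = set(sig["query_id"])
            return np.fromiter((rid in found for rid in ids), dtype=float,
                               count=len(ids)).mean()
        if variant == "bitscore_sum":
            best = sig.groupby("query_id")["bit_score"].max()
            return float(np.mean([best.get(rid, 0.0) for rid in ids]))
        raise ValueError(f"unknown variant {variant!r}")

    return 0.5 * (_per_read(hits_ab, a_ids) + _per_read(hits_ba, b_ids))


def _warn_unnormalized(panel: list[ReadSet]) -> None:
    import warnings

    sizes = {len(rs) for rs in panel}
    lens = {len(seq) for rs in panel for _, seq in rs}
    if len(sizes) > 1 or len(lens) > 1:
        warnings.warn(
            "viromes are not normalised subsamples (same n, same read "
            "length); similarity scores may not be comparable"
        )


def similarity_matrix(panel: list[ReadSet],
                      cutoff: int = simsearch.DEFAULT_SCORE_CUTOFF
                      ) -> SimilarityMatrix:
    """All-vs-all symmetric similarity matrix of a virome panel."""
    if len(panel) < 2:
        raise ValueError("need at least 2 viromes")
    labels = [rs.name for rs in panel]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate virome labels in panel: {labels}")
    _warn_unnormalized(panel)
    indexes = [simsearch.build_index(rs.sequences) for rs in panel]
    m = len(panel)
    values = np.eye(m)
    hits: dict = {}
    for i, j in itertools.combinations(range(m), 2):
        # the pairwise segment score is symmetric, so one direction suffices
        hits[(i, j)] = simsearch.hit_matrix(indexes[i], indexes[j], cutoff)
        hits[(j, i)] = hits[(i, j)].T.tocsr()
        values[i, j] = values[j, i] = _score_pair(hits[(i, j)], hits[(j, i)])
    for i in range(m):
        # every read has a byte-identical partner in its own virome
        hits[(i, i)] = sparse.identity(len(panel[i]), dtype=bool, format="csr")
        values[i, i] = 1.0
    return SimilarityMatrix(labels=labels, values=values,
                            scorer_config={"cutoff": cutoff},
                            hit_matrices=hits)


def _linkage_clades(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    n = len(labels)
    sets: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for k, (a, b, _, _) in enumerate(Z):
        s = sets[int(a)] | sets[int(b)]
        sets[n + k] = s
        out.append(s)
    return out


def _average_linkage(values: np.ndarray) -> np.ndarray:
    d = 1.0 - values
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return hierarchy.average(squareform(d, checks=False))


def _bootstrap_matrix(m: SimilarityMatrix, rng) -> np.ndarray:
    """Similarity matrix after within-virome read resampling, recomputed
    from the stored read-level hit matrices (no re-alignment needed).

    When all viromes hold the same number of reads (the normalised
    subsample setting) one index vector per replicate is shared across
    viromes -- the analogue of resampling the rows of a data matrix once
    per replicate, as multiscale-bootstrap clustering tools do -- so a
    panel of identical viromes stays identical under resampling."""
    hits = m.hit_matrices
    k = len(m.labels)
    sizes = [hits[(i, i)].shape[0] for i in range(k)]
    if len(set(sizes)) == 1:
        shared = rng.integers(0, sizes[0], size=sizes[0])
        resamples = [shared] * k
    else:
        resamples = [rng.integers(0, s, size=s) for s in sizes]
    incl_counts = [np.bincount(r, minlength=s)
                   for r, s in zip(resamples, sizes)]
    values = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        h_ij = hits[(i, j)]
        h_ji = hits[(j, i)]
        # read r of virome i hits resampled virome j iff any of its hit
        # partners survives the resample
        hit_i = (h_ij @ incl_counts[j]) > 0
        hit_j = (h_ji @ incl_counts[i]) > 0
        frac_i = hit_i[resamples[i]].mean()
        frac_j = hit_j[resamples[j]].mean()
        values[i, j] = values[j, i] = 0.5 * (frac_i + frac_j)
    return values


def cluster_viromes(m: SimilarityMatrix, n_boot: int = 100,
                    seed: int = 0) -> SupportedDendrogram:
    """Average-linkage dendrogram on 1 - score, with plain bootstrap
    support per clade (read-level resampling within each virome).

    Requires ``m`` to carry its read-level hit matrices (as produced by
    :func:`similarity_matrix`) when ``n_boot >= 1``.
    """
    Z = _average_linkage(m.values)
    point_clades = _linkage_clades(Z, m.labels)
    if n_boot < 1:
        import warnings

        warnings.warn("n_boot = 0: point tree only, support undefined")
        return SupportedDendrogram(labels=m.labels, linkage=Z,
                                   support={}, n_boot=0)
    if m.hit_matrices is None:
        raise ValueError(
            "bootstrap support needs read-level hit matrices; build the "
            "matrix with similarity_matrix()"
        )
    rng = np.random.default_rng(seed)
    counts = {c: 0 for c in point_clades}
    for _ in range(n_boot):
        vb = _bootstrap_matrix(m, rng)
        for c in _linkage_clades(_average_linkage(vb), m.labels):
            if c in counts:
                counts[c] += 1
    support = {c: counts[c] / n_boot for c in point_clades}
    return SupportedDendrogram(labels=m.labels, linkage=Z,
                               support=support, n_boot=n_boot)


def richness_anova(values, groups) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA of a richness measure across
    environment groups; returns (F, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must be parallel")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    if all(len(s) == 1 for s in samples):
        raise ValueError("all groups have a single member: no within-group "
                         "variance to test against")
    grand = values.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b = len(uniq) - 1
    df_w = len(values) - len(uniq)
    if ss_between == 0:
        return 0.0, 1.0
    if ss_within == 0:
        return float("inf"), 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p


def write_matrix_tsv(m: SimilarityMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("virome\t" + "\t".join(m.labels) + "\n")
        for lab, row in zip(m.labels, m.values):
            fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
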