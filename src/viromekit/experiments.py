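"""Synthetic end-to-end validation experiments.

Each function here runs one of the package's desk-scale study designs on
synthetic communities and returns plain dicts of measured quantities.
They are shared by the test suite, the acceptance script and the
``analysis/`` drivers, so the numbers those report are always produced by
the same code paths.

Problem sizes are chosen so each experiment finishes in minutes on one
core while keeping the statistics meaningful; docs/methods.md discusses
the choices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clusterdiv, markerphylo, specrich, synthdata, taxcomp, viromecomp
from .seqio import ReadSet
from .synthdata import Community, RankAbundanceModel, ReadSimParams, parse_read_id

# ---------------------------------------------------------------------------
# naive quadratic clustering reference (validation oracle)


def _semi_global_distance(query: str, target: str) -> int:
    """Plain DP edit distance of query as an infix of target (free target
    start/end gaps).  Deliberately simple; used only to validate the
    production clustering path."""
    m, n = len(query), len(target)
    tgt = np.frombuffer(target.encode(), dtype=np.uint8)
    idx = np.arange(n + 1, dtype=np.int64)
    prev = np.zeros(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        c = np.empty(n + 1, dtype=np.int64)
        c[0] = i
        # candidates from deletion (prev[j]+1) and (mis)match (diag)
        c[1:] = np.minimum(prev[1:] + 1, prev[:-1] + (tgt != ord(query[i - 1])))
        # left-to-right insertion chain: cur[j] = min_k<=j (c[k] + j - k)
        prev = idx + np.minimum.accumulate(c - idx)
    return int(prev.min())


def naive_identity(a: str, b: str) -> float:
    """Reference identity: same convention as the production scorer but
    via explicit dynamic programming."""
    if (len(a), a) <= (len(b), b):
        query, target = a, b
    else:
        query, target = b, a
    d = _semi_global_distance(query, target)
    return max(0.0, 1.0 - d / len(query))


def naive_greedy_cluster(rs: ReadSet, threshold: float) -> list[list[str]]:
    """Quadratic re-implementation of the clustering policy (length
    descending, id ascending; first matching centroid in creation order)."""
    order = sorted(rs.reads, key=lambda r: (-len(r[1]), r[0]))
    centroids: list[tuple[str, str]] = []
    members: list[list[str]] = []
    for rid, seq in order:
        for ci, (_, cseq) in enumerate(centroids):
            if naive_identity(seq, cseq) >= threshold:
                members[ci].append(rid)
                break
        else:
            centroids.append((rid, seq))
            members.append([rid])
    return members


def clustering_oracle_experiment(seed: int = 0, n_instances: int = 100) -> dict:
    """Production greedy clustering vs the naive quadratic reference on
    random instances, plus threshold monotonicity (0.98 / 0.90 / 0.75)."""
    rng = np.random.default_rng(seed)
    agree = 0
    mono_ok = 0
    sizes = []
    for inst in range(n_instances):
        # mostly small instances, a few large ones
        if inst % 33 == 32:
            n_reads = int(rng.integers(200, 501))
        else:
            n_reads = int(rng.integers(10, 90))
        sizes.append(n_reads)
        S = int(rng.integers(2, 5))
        comm = synthdata.make_community(
            S, int(rng.integers(500, 900)), "power", {"b": 1.0},
            seed=int(rng.integers(0, 2**31 - 1)))
        p = ReadSimParams(
            n_reads=n_reads, read_len=int(rng.integers(55, 85)),
            error_rate=float(rng.uniform(0, 0.05)),
            seed=int(rng.integers(0, 2**31 - 1)))
        rs = synthdata.simulate_reads(comm, p, name=f"inst{inst}")
        thr = float(rng.choice([0.75, 0.90, 0.98]))
        sol = clusterdiv.greedy_cluster(rs, thr)
        ref = naive_greedy_cluster(rs, thr)
        got = sorted(sorted(m) for _, m in sol.clusters)
        want = sorted(sorted(m) for m in ref)
        agree += got == want
        counts = [clusterdiv.greedy_cluster(rs, t).n_clusters
                  for t in (0.98, 0.90, 0.75)]
        mono_ok += counts[0] >= counts[1] >= counts[2]
    return {
        "agreement_fraction": agree / n_instances,
        "monotonicity_fraction": mono_ok / n_instances,
        "n_instances": n_instances,
        "max_instance_size": max(sizes),
    }


# ---------------------------------------------------------------------------
# expected contig spectrum vs simulation

# (S, community coverage, n reads): genome length follows from the
# coverage identity L = n*l/(cov*S).  Read counts are kept moderate so the
# integer-position lattice corrections stay below Monte-Carlo resolution;
# see docs/methods.md.
LW_GRID = (
    (1, 0.2, 150),
    (1, 1.0, 50),
    (1, 3.0, 100),
    (20, 0.2, 200),
    (20, 1.0, 150),
    (20, 3.0, 600),
)
# rank-abundance law of the simulated communities: steep power law for
# the multi-virotype grid so per-virotype coverage spans a wide range
LW_POWER_B = {1: 1.0, 20: 1.5}
LW_READ_LEN = 100
LW_MIN_OVERLAP = 35
# entries with expected count below this have skewed per-replicate
# distributions and unreliable Monte-Carlo SE estimates (the usual
# expected-count rule for normal approximations)
LW_MIN_EXPECTED = 2.0


def lw_agreement_experiment(seed: int = 0, reps: int = 500,
                            grid=LW_GRID) -> dict:
    """Mean simulated contig spectra (circular genomes, Poisson read
    arrivals -- the regime the coverage model describes) against the
    analytic expectation, per entry in Monte-Carlo standard errors.

    Entries are compared up to the largest q with expected count >=
    LW_MIN_EXPECTED; sparser entries have no usable Monte-Carlo error
    estimate.  Also checks the series closure sum_q q E[c_q] = n.
    """
    l, t = LW_READ_LEN, LW_MIN_OVERLAP
    results = []
    rng = np.random.default_rng(seed)
    for S, cov, n in grid:
        L = int(round(n * l / (cov * S)))
        b = LW_POWER_B.get(S, 1.0)
        base = int(rng.integers(0, 2**30))
        specs, maxq = [], 0
        for r in range(reps):
            comm = synthdata.make_community(S, L, "power", {"b": b},
                                            seed=base + r)
            p = ReadSimParams(n_reads=n, read_len=l, circular=True,
                              seed=base + reps + r, allocation="poisson")
            rs = synthdata.simulate_reads(comm, p)
            _, sp = specrich.assemble_strict(rs, min_identity=0.98,
                                             min_overlap=t)
            specs.append(sp.counts)
            maxq = max(maxq, len(sp.counts))
        M = np.zeros((reps, maxq))
        for i, s in enumerate(specs):
            M[i, : len(s)] = s
        mean = M.mean(axis=0)
        se = M.std(axis=0, ddof=1) / np.sqrt(reps)
        lw = specrich.LWParams(read_len=l, min_overlap=t, avg_genome_len=L)
        model = RankAbundanceModel("power", S, {"b": b})
        E, _ = specrich.expected_spectrum(model, n, lw, Q=maxq)
        Q = int(np.max(np.nonzero(E >= LW_MIN_EXPECTED)) + 1)
        z = (mean[:Q] - E[:Q]) / np.maximum(se[:Q], 1e-12)
        results.append({"S": S, "coverage": cov, "n": n, "L": L, "Q": Q,
                        "max_abs_z": float(np.abs(z).max())})
    # closure of the full series (Q large enough to capture all mass)
    lw = specrich.LWParams(read_len=l, min_overlap=t, avg_genome_len=2000)
    model = RankAbundanceModel("power", 5, {"b": 1.0})
    n_cl = 400
    E, tail = specrich.expected_spectrum(model, n_cl, lw, Q=5000)
    closure_rel = abs((np.arange(1, 5001) * E).sum() - n_cl) / n_cl
    return {"configs": results,
            "max_abs_z": max(r["max_abs_z"] for r in results),
            "closure_relative_error": float(closure_rel),
            "reps": reps}


# ---------------------------------------------------------------------------
# richness recovery

RECOVERY_S = 300
RECOVERY_B = 1.1
RECOVERY_GENOME_LEN = 5000
RECOVERY_N_READS = 20000
RECOVERY_READ_LEN = 100


def _estimate_richness(S: int, seed: int) -> int:
    comm = synthdata.make_community(S, RECOVERY_GENOME_LEN, "power",
                                    {"b": RECOVERY_B}, seed=seed)
    rs = synthdata.simulate_reads(
        comm, ReadSimParams(n_reads=RECOVERY_N_READS,
                            read_len=RECOVERY_READ_LEN, seed=seed + 1))
    _, spectrum = specrich.assemble_strict(rs)
    lw = specrich.LWParams(read_len=RECOVERY_READ_LEN, min_overlap=35,
                           avg_genome_len=RECOVERY_GENOME_LEN)
    return specrich.fit_richness(spectrum, lw).S_hat


def richness_recovery_experiment(seed: int = 0, n_seeds: int = 10) -> dict:
    """Full loop: power-law community (S=300, b=1.1) -> 20,000 100-bp
    reads -> stringent assembly -> model fit; S_hat per seed."""
    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(0, 2**30)) for _ in range(n_seeds)]
    hats = [_estimate_richness(RECOVERY_S, s) for s in seeds]
    return {"S_true": RECOVERY_S, "S_hats": hats,
            "median_S_hat": float(np.median(hats)), "n_seeds": n_seeds}


def richness_ordering_experiment(seed: int = 0, n_seeds: int = 10,
                                 S_low: int = 50, S_high: int = 500) -> dict:
    """Does a richer community yield the larger estimate, seed by seed?"""
    rng = np.random.default_rng(seed + 1)
    ordered = 0
    pairs = []
    for _ in range(n_seeds):
        s1 = int(rng.integers(0, 2**30))
        s2 = int(rng.integers(0, 2**30))
        lo = _estimate_richness(S_low, s1)
        hi = _estimate_richness(S_high, s2)
        pairs.append((lo, hi))
        ordered += lo < hi
    return {"S_low": S_low, "S_high": S_high, "pairs": pairs,
            "ordered_fraction": ordered / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# virome panel recovery

PANEL_GROUPS = 3
PANEL_VIROMES_PER_GROUP = 3
PANEL_GENOMES_PER_VIROME = 20
PANEL_WITHIN_SHARE = 0.6
PANEL_BETWEEN_SHARE = 0.05
PANEL_N_READS = 2000
PANEL_READ_LEN = 100
PANEL_GENOME_LEN = 5000


def panel_recovery_experiment(seed: int = 0, n_seeds: int = 10,
                              n_boot: int = 100) -> dict:
    """Fig.-3-style group recovery: 3 groups x 3 viromes with controlled
    genome sharing; a seed counts as recovered when all three group
    clades appear in the point dendrogram with bootstrap support >= 0.8."""
    rng = np.random.default_rng(seed)
    recovered = 0
    details = []
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**30))
        spec = synthdata.PanelSpec(
            n_groups=PANEL_GROUPS, viromes_per_group=PANEL_VIROMES_PER_GROUP,
            genomes_per_virome=PANEL_GENOMES_PER_VIROME,
            within_share=PANEL_WITHIN_SHARE, between_share=PANEL_BETWEEN_SHARE,
            seed=s)
        panel, truth = synthdata.make_panel(
            spec, ReadSimParams(n_reads=PANEL_N_READS,
                                read_len=PANEL_READ_LEN, seed=s + 1),
            genome_len=PANEL_GENOME_LEN)
        m = viromecomp.similarity_matrix(panel)
        # structural invariants, checked on every panel
        assert np.allclose(m.values, m.values.T)
        assert all(m.values[i, i] >= m.values[i].max() for i in range(len(panel)))
        dend = viromecomp.cluster_viromes(m, n_boot=n_boot, seed=s + 2)
        sups = []
        for g in range(PANEL_GROUPS):
            clade = frozenset(v for v, gg in truth["groups"].items() if gg == g)
            sups.append(dend.support.get(clade, 0.0))
        details.append(sups)
        recovered += all(sp >= 0.8 for sp in sups)
    return {"recovered_fraction": recovered / n_seeds,
            "supports": details, "n_seeds": n_seeds, "n_boot": n_boot}


# ---------------------------------------------------------------------------
# taxonomy worked example

def taxonomy_example_tables() -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Hand-crafted hit tables exercising every decision branch: the
    significance boundaries (e = 1e-3, bit = 50 inclusive), the best-hit
    tie rules, the viral rescue, GAAS eligibility (identity and coverage)
    and the 1/genome-length weighting."""
    reads = [f"r{i:02d}" for i in range(1, 11)]

    def row(q, s, pid, aln, e, bit, taxon, glen=np.nan):
        return dict(query_id=q, subject_id=s, percent_identity=pid,
                    aln_len=aln, mismatches=0, gap_opens=0, q_start=1,
                    q_end=aln, s_start=1, s_end=aln, e_value=e,
                    bit_score=bit, subject_taxon_path=taxon,
                    subject_genome_len=glen)

    nr = pd.DataFrame([
        row("r01", "vp1", 90, 33, 1e-4, 60, "Viruses;Caudovirales;Myoviridae"),
        row("r02", "bp1", 95, 33, 1e-2, 200, "Bacteria;Firmicutes"),
        row("r03", "bp2", 95, 33, 1e-6, 49, "Bacteria;Firmicutes"),
        row("r04", "bp3", 80, 33, 1e-3, 50, "Bacteria;Proteobacteria"),
        row("r04", "bp4", 80, 33, 5e-2, 30, "Bacteria;Proteobacteria"),
        row("r05", "bp5", 70, 33, 1e-9, 80, "Bacteria;Actinobacteria"),
        row("r05", "vp2", 70, 33, 1e-7, 70, "Viruses;Caudovirales;Podoviridae"),
        row("r06", "vp3", 75, 33, 1e-8, 60, "Viruses;Caudovirales;Siphoviridae"),
        row("r06", "bp6", 75, 33, 1e-5, 60, "Bacteria;Firmicutes"),
        row("r07", "ep1", 85, 33, 1e-6, 90, "Eukarya;Fungi"),
        row("r08", "ap1", 85, 33, 1e-6, 70, "Archaea;Euryarchaeota"),
        row("r10", "vp4", 88, 33, 1e-9, 120, "Viruses;Phycodnaviridae"),
    ])
    viral = pd.DataFrame([
        # eligible: pid >= 50, aln >= 0.2 * 100 -> families X and Y,
        # genome lengths 5 kb and 50 kb give the 10/11 vs 1/11 split
        row("r01", "gx", 80, 30, 1e-5, 60, "Viruses;FamilyX", 5000),
        row("r04", "gy", 75, 40, 1e-6, 65, "Viruses;FamilyY", 50000),
        row("r06", "gz", 49, 40, 1e-6, 60, "Viruses;FamilyZ", 8000),  # pid fail
        row("r08", "gw", 80, 15, 1e-6, 55, "Viruses;FamilyW", 9000),  # cov fail
        row("r10", "gv", 45, 10, 1e-4, 52, "Viruses;FamilyV", 7000),  # both fail
    ])
    return nr, viral, reads


def taxonomy_example_results() -> dict:
    """Run the full decision logic on the hand-crafted tables."""
    nr, viral, reads = taxonomy_example_tables()
    status = taxcomp.call_known(nr, set(reads))
    known = {r for r, s in status.items() if s == "known"}
    domains, fractions = taxcomp.domain_breakdown(nr, known)
    rescue = taxcomp.viral_rescue(domains, viral)
    viral_like = {r for r, v in rescue.items() if v}
    gaas_input = viral[viral["query_id"].isin(viral_like)].copy()
    gaas_input["query_len"] = 100
    composition = taxcomp.gaas_affiliate(gaas_input)
    tvd = taxcomp.composition_compare({"A": 0.5, "B": 0.5},
                                      {"A": 0.75, "B": 0.25})["tvd"]
    return {
        "known": sorted(known),
        "known_fraction": len(known) / len(reads),
        "domain_fractions": fractions,
        "domains": dict(domains),
        "viral_like": sorted(viral_like),
        "composition": composition,
        "tvd_example": tvd,
    }


# ---------------------------------------------------------------------------
# marker phylogeny recovery

MARKER_LEN_AA = 400
MARKER_N_PER_CLADE = 4
MARKER_ROOT_DIV = 0.18
MARKER_WITHIN_DIV = 0.10
MARKER_N_GENOMES = 10
MARKER_GENOME_LEN = 5000
MARKER_N_READS = 5000
MARKER_READ_LEN = 420
MARKER_DIVERGENCES = tuple(np.round(np.linspace(0.05, 0.4, 10), 3))


def make_marker_reference(seed: int = 0) -> markerphylo.MarkerReference:
    """Synthetic two-clade terminase-like protein family: a random
    ancestor, two clade ancestors diverged from it, and per-clade
    reference sequences diverged from each clade ancestor.  Substitution
    only, so the reference alignment is the ungapped sequence matrix."""
    rng = np.random.default_rng(seed)
    aa = list(synthdata._AA_ALPHABET)
    root = "".join(rng.choice(aa, MARKER_LEN_AA))
    ids, rows, groups = [], [], {}
    for clade in ("A", "B"):
        anc = synthdata.mutate_protein(root, MARKER_ROOT_DIV, rng)
        for i in range(MARKER_N_PER_CLADE):
            rid = f"ref{clade}{i}"
            ids.append(rid)
            rows.append(synthdata.mutate_protein(anc, MARKER_WITHIN_DIV, rng))
            groups[rid] = clade
    return markerphylo.MarkerReference(name="TerL-like", ids=ids, rows=rows,
                                       groups=groups)


def marker_recovery_experiment(seed: int = 0, n_seeds: int = 10,
                               n_boot: int = 100) -> dict:
    """Fig.-S5-style pipeline recovery on planted marker copies.

    Per seed: 10 genomes carry copies of a clade-A reference protein at
    divergences 0.05-0.4; after recruitment, assembly, alignment,
    partitioning, curation and tree building, every copy at divergence
    <= 0.2 must be recruited, and every contig built purely from
    low-divergence (<= 0.2) copies must sit on the clade-A side of a
    bipartition with bootstrap support >= 0.8.
    """
    rng = np.random.default_rng(seed)
    per_seed = []
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**30))
        srng = np.random.default_rng(s)
        marker = make_marker_reference(seed=s)
        a_refs = {r for r, g in marker.groups.items() if g == "A"}
        b_refs = {r for r, g in marker.groups.items() if g == "B"}
        genomes = [(f"g{i}", synthdata._BASES[
            srng.integers(0, 4, MARKER_GENOME_LEN)].tobytes().decode())
            for i in range(MARKER_N_GENOMES)]
        comm = Community(genomes=genomes,
                         abundances=np.full(MARKER_N_GENOMES,
                                            1.0 / MARKER_N_GENOMES))
        planted, truth = synthdata.plant_marker(
            comm, marker.rows[0], list(MARKER_DIVERGENCES), seed=s + 1)
        rs = synthdata.simulate_reads(
            planted, ReadSimParams(n_reads=MARKER_N_READS,
                                   read_len=MARKER_READ_LEN, seed=s + 2),
            name="markersim")
        recruited = markerphylo.recruit(rs, marker)
        rec_genomes = {parse_read_id(r.read_id)["src"] for r in recruited}
        div_of = {t["genome"]: t["divergence"] for t in truth}
        low_div = {g for g, d in div_of.items() if d <= 0.2}
        all_low_recruited = low_div <= rec_genomes

        contigs = markerphylo.assemble_recruited(recruited)
        aligned, _ = markerphylo.align_to_reference(contigs, marker)
        subs, _ = markerphylo.partition_subalignments(aligned)
        curated = []
        for sub in subs:
            try:
                curated.append(markerphylo.curate_blocks(sub, marker))
            except markerphylo.BlockCurationError:
                continue
        selected = markerphylo.rank_and_select(curated, k=10)
        contig_srcs = {}
        for idx, c in enumerate(contigs):
            contig_srcs[f"contig{idx:04d}"] = {
                parse_read_id(r)["src"] for r in c.read_ids}
        placed, n_low_contigs = 0, 0
        for cur in selected:
            tree = markerphylo.build_tree(cur, n_boot=n_boot, seed=s + 3)
            leaf_set = frozenset(cur.ids)
            for cid in cur.ids:
                srcs = contig_srcs.get(cid)
                if srcs is None or not all(div_of[g] <= 0.2 for g in srcs):
                    continue
                n_low_contigs += 1
                for bip, sup in tree.support.items():
                    side = bip if cid in bip else leaf_set - bip
                    if (cid in side and a_refs <= side
                            and not (b_refs & side) and sup >= 0.8):
                        placed += 1
                        break
        per_seed.append({
            "all_low_divergence_recruited": bool(all_low_recruited),
            "n_recruited": len(recruited),
            "n_low_divergence_contigs": n_low_contigs,
            "n_placed": placed,
            "ok": bool(all_low_recruited and n_low_contigs > 0
                       and placed == n_low_contigs),
        })
    frac = sum(p["ok"] for p in per_seed) / n_seeds
    return {"recovered_fraction": frac, "per_seed": per_seed,
            "n_seeds": n_seeds}
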