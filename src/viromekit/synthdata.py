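"""Synthetic viral communities, shotgun reads, virome panels and
marker-bearing genomes.

Every downstream stage of the toolkit (clustering, contig-spectrum richness
estimation, cross-virome comparison, marker phylogeny) is exercised on data
from this module, so it encodes the statistical structure those analyses
assume:

* virotype abundances follow one of the classical rank-abundance laws
  (power, exponential, logarithmic/log-series, lognormal, broken stick);
* shotgun reads are drawn genome-proportionally with uniform start
  positions, i.i.d. substitution errors, and an optional admixture of
  exact duplicate reads (emulating the duplicate artefacts of emulsion
  PCR pyrosequencing);
* panels of viromes share genomes within and between groups at controlled
  rates, giving a ground truth for similarity-based clustering;
* genomes can carry a reverse-translated, controllably diverged copy of a
  protein marker gene, giving a ground truth for phylogenetic placement.

Read ids carry their ground truth in a parseable form:
``<name>_r<serial>|src:<genome_id>|pos:<start>|dup:<0or1>``.
Use :func:`parse_read_id` rather than splitting by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .seqio import ReadSet

ABUNDANCE_FAMILIES = ("power", "exponential", "logarithmic", "lognormal", "broken_stick")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# one codon per amino acid for reverse translation (standard code)
_CODON_OF_AA = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
_AA_ALPHABET = "".join(sorted(_CODON_OF_AA))


def sample_abundances(family: str, S: int, params: dict | None = None) -> np.ndarray:
    """Relative abundances of ``S`` virotypes under a rank-abundance law.

    All families are deterministic constructions (the lognormal uses
    quantile slicing at probabilities (i - 1/2)/S rather than sampling),
    returning a sorted, normalised vector a_1 >= a_2 >= ... >= a_S.

    Parameters per family: ``power`` exponent ``b > 0`` (a_i prop. i^-b);
    ``exponential`` rate ``b > 0`` (a_i prop. e^{-b i}); ``logarithmic``
    log-series parameter ``0 < x < 1`` (a_i prop. x^i / i); ``lognormal``
    shape ``sigma > 0``; ``broken_stick`` none.
    """
    if family not in ABUNDANCE_FAMILIES:
        raise ValueError(
            f"unknown abundance family {family!r}; supported: {ABUNDANCE_FAMILIES}"
        )
    if S < 1:
        raise ValueError("S must be >= 1")
    params = dict(params or {})
    for v in params.values():
        if not np.isfinite(v):
            raise ValueError(f"non-finite parameter in {params}")
    i = np.arange(1, S + 1, dtype=float)
    if family == "power":
        b = float(params.get("b", 1.0))
        if b <= 0:
            raise ValueError("power exponent b must be > 0")
        a = i ** (-b)
    elif family == "exponential":
        b = float(params.get("b", 0.5))
        if b <= 0:
            raise ValueError("exponential rate b must be > 0")
        # a_i prop. e^{-b i}; compute relative to i=1 for numerical range
        a = np.exp(-b * (i - 1.0))
    elif family == "logarithmic":
        x = float(params.get("x", 0.9))
        if not 0 < x < 1:
            raise ValueError("logarithmic parameter x must be in (0, 1)")
        a = x ** (i - 1.0) / i
    elif family == "lognormal":
        sigma = float(params.get("sigma", 1.0))
        if sigma <= 0:
            raise ValueError("lognormal sigma must be > 0")
        p = (i - 0.5) / S
        a = stats.lognorm.ppf(1.0 - p, s=sigma)
    else:  # broken_stick
        a = np.cumsum(1.0 / i[::-1])[::-1] / S
    a = np.sort(a)[::-1]
    return a / a.sum()


@dataclass
class RankAbundanceModel:
    """A rank-abundance law with its parameters and richness S."""

    family: str
    S: int
    params: dict = field(default_factory=dict)

    def abundances(self) -> np.ndarray:
        return sample_abundances(self.family, self.S, self.params)


@dataclass
class Community:
    """A set of viral genomes with sorted, normalised relative abundances."""

    genomes: list[tuple[str, str]]  # (id, nucleotide sequence)
    abundances: np.ndarray
    model: RankAbundanceModel | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.genomes) != len(self.abundances) or len(self.genomes) < 1:
            raise ValueError("genomes and abundances must have equal length >= 1")
        if abs(self.abundances.sum() - 1.0) > 1e-12:
            raise ValueError("abundances must sum to 1")
        if np.any(np.diff(self.abundances) > 1e-15):
            raise ValueError("abundances must be sorted in decreasing order")
        for gid, seq in self.genomes:
            if set(seq) - set("ACGT"):
                raise ValueError(f"genome {gid!r} contains non-ACGT symbols")

    @property
    def S(self) -> int:
        return len(self.genomes)

    def genome_lengths(self) -> np.ndarray:
        return np.array([len(seq) for _, seq in self.genomes])


@dataclass
class ReadSimParams:
    """Shotgun read simulation parameters.

    ``read_len`` is the fixed read length in bp (a single int) or a
    ``(mean, sd)`` pair for Gaussian-length reads.  ``error_rate`` is the
    per-base substitution probability; indels are not modelled.
    ``dup_fraction`` of the output reads are verbatim copies of already
    emitted reads.  ``circular`` controls whether read start positions wrap
    around the genome end.  ``allocation`` chooses how reads are split
    across genomes: 'multinomial' (the default) samples source genomes
    read by read; 'exact' gives each genome its expected count
    (largest-remainder rounding); 'poisson' draws independent Poisson
    counts with mean a_i * n_reads per genome (total then varies), which
    makes the per-genome read process exactly the Poisson arrival process
    assumed by shotgun-coverage theory.
    """

    n_reads: int
    read_len: int | tuple[float, float]
    error_rate: float = 0.0
    dup_fraction: float = 0.0
    circular: bool = False
    seed: int = 0
    allocation: str = "multinomial"

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0 <= self.dup_fraction < 1:
            raise ValueError("dup_fraction must be in [0, 1)")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.allocation not in ("multinomial", "exact", "poisson"):
            raise ValueError(
                "allocation must be 'multinomial', 'exact' or 'poisson'")


def make_community(S: int, genome_len: int | tuple[int, int], family: str,
                   params: dict | None = None, seed: int = 0) -> Community:
    """Random uniform-composition genomes with law-driven abundances."""
    if S < 1:
        raise ValueError("S must be >= 1")
    if isinstance(genome_len, tuple):
        lo, hi = genome_len
    else:
        lo = hi = int(genome_len)
    if lo < 500:
        raise ValueError("genome_len must be >= 500 bp")
    rng = np.random.default_rng(seed)
    genomes = []
    width = len(str(S - 1)) if S > 1 else 1
    for i in range(S):
        L = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        seq = _BASES[rng.integers(0, 4, size=L)].tobytes().decode()
        genomes.append((f"g{i:0{width}d}", seq))
    a = sample_abundances(family, S, params)
    return Community(genomes=genomes, abundances=a,
                     model=RankAbundanceModel(family, S, dict(params or {})),
                     seed=seed)


def _allocate_counts(a: np.ndarray, n: int, rng, mode: str) -> np.ndarray:
    if mode == "multinomial":
        return rng.multinomial(n, a)
    if mode == "poisson":
        return rng.poisson(a * n)
    # largest-remainder deterministic allocation
    raw = a * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def simulate_reads(community: Community, p: ReadSimParams,
                   name: str = "sim", biome: str = "other") -> ReadSet:
    """Shotgun reads from a community.

    Reads are drawn genome-proportionally to abundance, with uniform start
    positions (wrapping iff ``circular``), i.i.d. substitution errors, and
    a trailing block of exact duplicate reads.  Read ids encode the source
    genome, start position and duplicate status (see module docstring).
    """
    rng = np.random.default_rng(p.seed)
    lengths = community.genome_lengths()
    fixed_len = isinstance(p.read_len, (int, np.integer))
    if fixed_len and p.read_len > lengths.min():
        raise ValueError(
            f"read_len {p.read_len} exceeds shortest genome ({lengths.min()} bp)"
        )
    if p.n_reads == 0:
        return ReadSet(name=name, reads=[], biome=biome)

    n_dup = int(round(p.dup_fraction * p.n_reads))
    n_orig = p.n_reads - n_dup
    counts = _allocate_counts(community.abundances, n_orig, rng, p.allocation)

    genome_arrays = [np.frombuffer(seq.encode(), dtype=np.uint8)
                     for _, seq in community.genomes]
    reads: list[tuple[str, str]] = []
    serial = 0
    for gi, n_g in enumerate(counts):
        if n_g == 0:
            continue
        gid = community.genomes[gi][0]
        g = genome_arrays[gi]
        L = len(g)
        for _ in range(int(n_g)):
            rl = int(p.read_len) if fixed_len else max(
                1, int(round(rng.normal(p.read_len[0], p.read_len[1]))))
            if rl > L:
                raise ValueError(f"read length {rl} exceeds genome {gid} ({L} bp)")
            if p.circular:
                start = int(rng.integers(0, L))
                idx = (start + np.arange(rl)) % L
                arr = g[idx].copy()
            else:
                start = int(rng.integers(0, L - rl + 1))
                arr = g[start : start + rl].copy()
            if p.error_rate > 0:
                mask = rng.random(rl) < p.error_rate
                n_err = int(mask.sum())
                if n_err:
                    # shift each erroneous base by 1..3 in base space
                    cur = np.searchsorted(_BASES, arr[mask])
                    arr[mask] = _BASES[(cur + rng.integers(1, 4, size=n_err)) % 4]
            rid = f"{name}_r{serial:06d}|src:{gid}|pos:{start}|dup:0"
            reads.append((rid, arr.tobytes().decode()))
            serial += 1
    # shuffle originals so duplicates sample the whole pool uniformly
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    for _ in range(n_dup):
        src_id, src_seq = reads[int(rng.integers(0, len(reads)))]
        src_g = parse_read_id(src_id)["src"]
        src_pos = parse_read_id(src_id)["pos"]
        rid = f"{name}_r{serial:06d}|src:{src_g}|pos:{src_pos}|dup:1"
        reads.append((rid, src_seq))
        serial += 1
    return ReadSet(name=name, reads=reads, biome=biome)


def parse_read_id(rid: str) -> dict:
    """Decode the ground-truth suffix of a simulated read id."""
    body, *fields = rid.split("|")
    out: dict = {"read": body}
    for f in fields:
        k, _, v = f.partition(":")
        out[k] = int(v) if k in ("pos", "dup") else v
    return out


def plant_marker(community: Community, marker_protein: str,
                 divergence_levels: list[float], seed: int = 0,
                 ) -> tuple[Community, list[dict]]:
    """Insert a diverged, reverse-translated marker copy into each genome.

    Genome i receives a copy of ``marker_protein`` mutated at exactly
    ``round(d_i * len)`` amino-acid positions (d_i cycling through
    ``divergence_levels``), reverse-translated and written over a random
    in-genome locus (genome length is conserved).  Returns the modified
    community and a truth table of (genome_id, divergence, locus, strand,
    planted protein).
    """
    m = len(marker_protein)
    if m < 100:
        raise ValueError("marker must be >= 100 aa")
    for d in divergence_levels:
        if not 0 <= d < 0.6:
            raise ValueError("divergence levels must be in [0, 0.6)")
    if set(marker_protein) - set(_AA_ALPHABET):
        raise ValueError("marker contains non-standard amino acids")
    rng = np.random.default_rng(seed)
    nt_len = 3 * m
    genomes = []
    truth = []
    for gi, (gid, seq) in enumerate(community.genomes):
        if nt_len > len(seq):
            raise ValueError(
                f"marker ({nt_len} nt) does not fit in genome {gid} ({len(seq)} bp)"
            )
        d = float(divergence_levels[gi % len(divergence_levels)])
        prot = mutate_protein(marker_protein, d, rng)
        insert = reverse_translate(prot, rng)
        locus = int(rng.integers(0, len(seq) - nt_len + 1))
        new_seq = seq[:locus] + insert + seq[locus + nt_len:]
        genomes.append((gid, new_seq))
        truth.append({"genome": gid, "divergence": d, "locus": locus,
                      "strand": "+", "protein": prot})
    out = Community(genomes=genomes, abundances=community.abundances,
                    model=community.model, seed=community.seed)
    return out, truth


def mutate_protein(protein: str, divergence: float, rng) -> str:
    """Substitute exactly round(divergence * len) positions to new residues."""
    n_mut = int(round(divergence * len(protein)))
    if n_mut == 0:
        return protein
    pos = rng.choice(len(protein), size=n_mut, replace=False)
    chars = list(protein)
    for p in pos:
        choices = [aa for aa in _AA_ALPHABET if aa != chars[p]]
        chars[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def reverse_translate(protein: str, rng=None) -> str:
    """Protein to nucleotide using one fixed codon per amino acid."""
    return "".join(_CODON_OF_AA[aa] for aa in protein)


@dataclass
class PanelSpec:
    """Layout of a multi-virome panel with controlled genome sharing.

    Viromes of the same group share ``within_share`` of their genomes;
    viromes of different groups share ``between_share`` (realised as a
    panel-wide common pool).  The remainder of each virome's genome set is
    private.
    """

    n_groups: int
    viromes_per_group: int
    genomes_per_virome: int
    within_share: float
    between_share: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.between_share <= self.within_share <= 1:
            raise ValueError(
                "need 0 <= between_share <= within_share <= 1, got "
                f"between={self.between_share}, within={self.within_share}"
            )
        if min(self.n_groups, self.viromes_per_group, self.genomes_per_virome) < 1:
            raise ValueError("panel dimensions must be >= 1")


def make_panel(spec: PanelSpec, read_params: ReadSimParams,
               genome_len: int = 5000) -> tuple[list[ReadSet], dict]:
    """Simulate a panel of viromes with a known group structure.

    Returns the list of ReadSets (named ``G<g>V<v>``, biome set per group)
    and a truth dict with group labels and per-virome genome id sets.
    Genome abundances within each virome are uniform, so every genome is
    equally discoverable.
    """
    rng = np.random.default_rng(spec.seed)
    G = spec.genomes_per_virome
    n_common = int(round(spec.between_share * G))
    n_group = int(round(spec.within_share * G)) - n_common
    n_priv = G - n_common - n_group

    def _random_genome(gid: str) -> tuple[str, str]:
        seq = _BASES[rng.integers(0, 4, size=genome_len)].tobytes().decode()
        return (gid, seq)

    common = [_random_genome(f"common{i:03d}") for i in range(n_common)]
    biomes = ["freshwater", "seawater", "hypersaline_med", "eukaryote_associated",
              "other"]
    panel: list[ReadSet] = []
    truth: dict = {"groups": {}, "genomes": {}}
    for g in range(spec.n_groups):
        core = [_random_genome(f"grp{g}core{i:03d}") for i in range(n_group)]
        for v in range(spec.viromes_per_group):
            priv = [_random_genome(f"grp{g}v{v}priv{i:03d}") for i in range(n_priv)]
            genomes = common + core + priv
            comm = Community(
                genomes=genomes,
                abundances=np.full(len(genomes), 1.0 / len(genomes)),
            )
            vname = f"G{g}V{v}"
            p = ReadSimParams(
                n_reads=read_params.n_reads, read_len=read_params.read_len,
                error_rate=read_params.error_rate,
                dup_fraction=read_params.dup_fraction,
                circular=read_params.circular,
                seed=int(rng.integers(0, 2**31 - 1)),
                allocation=read_params.allocation,
            )
            rs = simulate_reads(comm, p, name=vname,
                                biome=biomes[g % len(biomes)])
            panel.append(rs)
            truth["groups"][vname] = g
            truth["genomes"][vname] = {gid for gid, _ in genomes}
    return panel, truth
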