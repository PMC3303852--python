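"""Taxonomic decision logic over homology-search hit tables.

Works on externally produced tabular hit tables (BLAST outfmt-6 style, 12
standard columns plus two extensions: the subject taxonomic path and the
subject genome length).  The logic mirrors the standard virome workflow:

* a read is "known" iff it has at least one hit with e-value <= 1e-3 AND
  bit score >= 50 (inclusive thresholds);
* known reads are assigned the domain of their best hit (highest bit
  score, ties by lower e-value then lexicographic subject id);
* reads whose best hit is non-viral but which also hit a complete viral
  genome significantly are rescued as "similar to at least one viral
  sequence" (proviruses and transferred genes are otherwise miscounted
  as cellular);
* family composition of the viral-like fraction follows the GAAS-style
  rule: eligible hits need >= 50% identity and alignment length >= 20% of
  the query length; the top eligible hit per read contributes weight
  1 / subject_genome_length to its family (longer genomes yield more
  reads per particle, so raw read counts over-represent them).
"""

from __future__ import annotations

import warnings

import pandas as pd

E_VALUE_MAX = 1e-3
BIT_SCORE_MIN = 50.0
GAAS_MIN_IDENTITY = 50.0     # percent
GAAS_MIN_COVERAGE = 0.20     # fraction of query length

OUTFMT6_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "aln_len", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "e_value", "bit_score",
]
EXTENSION_COLUMNS = ["subject_taxon_path", "subject_genome_len"]

DOMAINS = ("Viruses", "Bacteria", "Archaea", "Eukarya")


def read_hit_table(path) -> pd.DataFrame:
    """Read a 12+2-column tab-separated hit table (no header)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=OUTFMT6_COLUMNS + EXTENSION_COLUMNS)
    return validate_hit_table(df)


def validate_hit_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in OUTFMT6_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"hit table missing column {col!r}")
    if (df["e_value"] < 0).any():
        raise ValueError("negative e-values in hit table")
    if (df["bit_score"] < 0).any():
        raise ValueError("negative bit scores in hit table")
    if ((df["percent_identity"] < 0) | (df["percent_identity"] > 100)).any():
        raise ValueError("percent_identity outside [0, 100]")
    return df


def _significant(df: pd.DataFrame) -> pd.DataFrame:
    return df[(df["e_value"] <= E_VALUE_MAX) & (df["bit_score"] >= BIT_SCORE_MIN)]


def call_known(hits: pd.DataFrame, reads: set[str]) -> pd.Series:
    """'known'/'unknown' status per read id.

    A read is known iff it has >= 1 hit passing both significance
    thresholds; reads absent from the table are unknown.
    """
    sig = set(_significant(hits)["query_id"])
    return pd.Series(
        {rid: ("known" if rid in sig else "unknown") for rid in reads},
        name="status",
    )


def _domain_of(path: str) -> str:
    head = path.split(";")[0].strip()
    if head not in DOMAINS:
        raise ValueError(f"unknown domain {head!r} in taxon path {path!r}")
    return head


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per query: max bit score, ties by min e-value, then by
    lexicographic subject id."""
    df = hits.sort_values(
        ["query_id", "bit_score", "e_value", "subject_id"],
        ascending=[True, False, True, True], kind="mergesort",
    )
    return df.groupby("query_id", sort=False).head(1)


def domain_breakdown(hits: pd.DataFrame, known: set[str]
                     ) -> tuple[pd.Series, dict[str, float]]:
    """Domain of the best significant hit per known read, plus the panel
    fractions over known reads (summing to 1)."""
    sig = _significant(hits)
    sig = sig[sig["query_id"].isin(known)]
    best = best_hits(sig)
    domains = best.set_index("query_id")["subject_taxon_path"].map(_domain_of)
    domains.name = "domain"
    counts = domains.value_counts()
    total = int(counts.sum())
    fractions = {d: float(counts.get(d, 0)) / total if total else 0.0
                 for d in DOMAINS}
    return domains, fractions


def viral_rescue(nr_domains: pd.Series, viral_hits: pd.DataFrame) -> pd.Series:
    """Per-read boolean: 'similar to at least one viral sequence'.

    True for reads whose best protein-database hit is already viral, and
    for reads with a non-viral best hit that also hit a complete viral
    genome at the same significance thresholds.
    """
    viral_ok = set(_significant(viral_hits)["query_id"])
    out = {}
    for rid, dom in nr_domains.items():
        out[rid] = (dom == "Viruses") or (rid in viral_ok)
    return pd.Series(out, name="viral_rescue")


def gaas_affiliate(viral_hits: pd.DataFrame,
                   protein_space: bool = False) -> dict[str, float]:
    """Family composition by genome-length-normalised top-hit counting.

    Eligibility: percent identity >= 50 and alignment length >= 20% of the
    query length (``protein_space=True`` multiplies aln_len by 3 for
    protein-space alignments of nucleotide queries).  Per read, the top
    eligible hit (max bit score) contributes 1/subject_genome_len to the
    family named by the last element of the subject taxon path; the
    composition is the normalised per-family weight sum.
    """
    df = viral_hits.copy()
    if "query_len" not in df.columns:
        raise ValueError(
            "gaas_affiliate needs query lengths: add a 'query_len' column "
            "(e.g. hits.assign(query_len=...))"
        )
    aln_nt = df["aln_len"] * (3 if protein_space else 1)
    eligible = df[(df["percent_identity"] >= GAAS_MIN_IDENTITY)
                  & (aln_nt >= GAAS_MIN_COVERAGE * df["query_len"])]
    top = best_hits(eligible)
    weights: dict[str, float] = {}
    for _, row in top.iterrows():
        family = row["subject_taxon_path"].split(";")[-1].strip()
        L = row.get("subject_genome_len")
        if pd.isna(L) or L is None:
            warnings.warn(
                f"missing subject genome length for {row['subject_id']!r}; "
                "counting the read with weight 1"
            )
            w = 1.0
        else:
            w = 1.0 / float(L)
        weights[family] = weights.get(family, 0.0) + w
    total = sum(weights.values())
    return {fam: w / total for fam, w in weights.items()} if total else {}


def composition_compare(observed: dict[str, float],
                        reference: dict[str, float]) -> dict:
    """Per-family differences and total variation distance between two
    family compositions (label spaces are united with zeros)."""
    fams = sorted(set(observed) | set(reference))
    diffs = {f: observed.get(f, 0.0) - reference.get(f, 0.0) for f in fams}
    tvd = 0.5 * sum(abs(d) for d in diffs.values())
    return {"differences": diffs, "tvd": tvd}
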