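"""Sequence I/O for virome read sets.

A virome is handled as a :class:`ReadSet`: an ordered, named collection of
nucleotide reads with a biome label attached (freshwater, seawater,
hypersaline, eukaryote-associated ...).  All downstream comparisons assume
viromes have been normalised the same way -- exact duplicates removed and,
for cross-virome work, subsampled to a common read number and length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

VALID_BIOMES = frozenset(
    {
        "freshwater",
        "seawater",
        "hypersaline_low",
        "hypersaline_med",
        "hypersaline_high",
        "eukaryote_associated",
        "other",
    }
)

_ALPHABET = frozenset("ACGTN")


@dataclass
class ReadSet:
    """Named, ordered collection of uppercase nucleotide reads."""

    name: str
    reads: list[tuple[str, str]] = field(default_factory=list)
    biome: str = "other"

    def __post_init__(self) -> None:
        if self.biome not in VALID_BIOMES:
            raise ValueError(
                f"unknown biome {self.biome!r}; expected one of {sorted(VALID_BIOMES)}"
            )
        seen: set[str] = set()
        cleaned = []
        for rid, seq in self.reads:
            if rid in seen:
                raise ValueError(f"duplicate read id {rid!r} in ReadSet {self.name!r}")
            seen.add(rid)
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for read {rid!r}")
            if not _ALPHABET.issuperset(seq):
                bad = sorted(set(seq) - _ALPHABET)
                raise ValueError(f"read {rid!r} contains non-ACGTN symbols {bad}")
            cleaned.append((rid, seq))
        self.reads = cleaned

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.reads]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.reads]


def read_sequences(path, fmt: str = "fasta", name: str | None = None,
                   biome: str = "other") -> ReadSet:
    """Parse a FASTA or FASTQ file into a ReadSet (order preserved).

    FASTQ quality strings are discarded: none of the analyses here use
    base-level quality.  Duplicate ids and malformed records are rejected.
    """
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}; use 'fasta' or 'fastq'")
    path = str(path)
    try:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, fmt)]
    except ValueError as exc:  # biopython reports the offending record
        raise ValueError(f"malformed {fmt} file {path}: {exc}") from exc
    label = name if name is not None else path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return ReadSet(name=label, reads=records, biome=biome)


def write_fasta(rs: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in rs:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(rs: ReadSet, path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in rs:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def dedup_exact(rs: ReadSet) -> tuple[ReadSet, int]:
    """Remove exact duplicate reads (identical full-length sequence).

    The first occurrence of each sequence is kept; read ids are ignored in
    the comparison.  Returns the deduplicated set and the number removed,
    so kept + removed always equals the input size.
    """
    seen: set[str] = set()
    kept = []
    for rid, seq in rs:
        if seq in seen:
            continue
        seen.add(seq)
        kept.append((rid, seq))
    out = ReadSet(name=rs.name, reads=kept, biome=rs.biome)
    return out, len(rs) - len(kept)


def subsample(rs: ReadSet, n: int, trim_len: int | None = None, seed: int = 0,
              trim_mode: str = "window") -> ReadSet:
    """Uniform subsample of ``n`` reads without replacement, optionally
    length-normalised to ``trim_len`` bp.

    Reads shorter than ``trim_len`` are excluded from eligibility before
    sampling.  ``trim_mode='window'`` takes a random contiguous window of
    each sampled read (avoids 5'-bias); ``'prefix'`` takes the first
    ``trim_len`` bases.
    """
    if trim_mode not in ("window", "prefix"):
        raise ValueError(f"trim_mode must be 'window' or 'prefix', got {trim_mode!r}")
    rng = np.random.default_rng(seed)
    if trim_len is None:
        eligible = list(range(len(rs)))
    else:
        if trim_len < 1:
            raise ValueError("trim_len must be >= 1")
        eligible = [i for i, (_, seq) in enumerate(rs) if len(seq) >= trim_len]
    if n > len(eligible):
        raise ValueError(
            f"requested {n} reads but only {len(eligible)} eligible "
            f"(of {len(rs)} total) in {rs.name!r}"
        )
    chosen = rng.choice(len(eligible), size=n, replace=False)
    out = []
    for idx in chosen:
        rid, seq = rs.reads[eligible[int(idx)]]
        if trim_len is not None:
            if trim_mode == "prefix":
                seq = seq[:trim_len]
            else:
                start = int(rng.integers(0, len(seq) - trim_len + 1))
                seq = seq[start : start + trim_len]
        out.append((rid, seq))
    return ReadSet(name=rs.name, reads=out, biome=rs.biome)
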